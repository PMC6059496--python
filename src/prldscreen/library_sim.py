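"""Synthetic mutagenesis-screen generator.

Emulates the wet-lab screen end to end: degenerate-codon windows are
sampled and translated, each isolate's adenine phenotype is drawn from an
additive per-residue propensity model with a logistic link, colony counts
are emitted around the classification threshold, and initially negative
isolates may later convert to the prion state under a second scale. All
randomness flows through one numpy Generator so a single integer seed
reproduces a screen exactly.

The generative model: a window with residues r_1..r_L has latent score
S = sum_i w(r_i) under the true scale; it is latently positive with
probability 1 / (1 + exp(-(S - theta) / tau)), emits a Poisson colony
count with mean mu_pos (positive) or mu_neg (negative), and is *labelled*
by the observed colony-count rule (> threshold), so boundary
misclassification is part of the simulation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.special import expit
from scipy.optimize import brentq

from .propensity import AminoAcidScale, ScaleCoverageError
from .screen import PhenotypeLabel, ScreenConfig, classify_isolate, partition_libraries
from .seqcore import (
    NUCLEOTIDES,
    STOP,
    DegenerateCodonSpec,
    PeptideWindow,
    nnb_scheme,
    translate,
)


class SimulationError(RuntimeError):
    """The simulation hit a state its policy forbids."""


@dataclass(frozen=True)
class IsolateRecord:
    """One screened library member.

    ``colony_count`` is the SC-ade colony count of the initial plating;
    ``secondary_ade_plus`` records whether an initially negative isolate
    later grew on SC-ade (the prion screen); ``curable_by_GuHCl`` is True
    for prions, False for constitutive ADE+, None when not assayed.
    """

    peptide: PeptideWindow
    colony_count: int
    label: PhenotypeLabel
    curable_by_GuHCl: bool | None = None
    secondary_ade_plus: bool = False

    def __post_init__(self) -> None:
        if self.colony_count < 0:
            raise ValueError("colony count must be non-negative")
        if self.label is PhenotypeLabel.PRION and self.curable_by_GuHCl is not True:
            raise ValueError("a PRION label requires GuHCl curability")


@dataclass(frozen=True)
class PhenotypeModel:
    """Generative parameters of the synthetic screen.

    ``true_scale``: per-residue weights summed over the window.
    ``theta``/``tau``: offset and width of the logistic link (dimensionless,
    tau > 0). ``mu_pos``/``mu_neg``: Poisson colony-count means for latent
    positives/negatives (colonies; mu_pos > mu_neg so the > threshold rule
    separates them). The optional prion arm gives each initially negative
    isolate conversion probability
    prion_max * logistic((S2 - prion_theta) / prion_tau) under
    ``prion_scale``.
    """

    true_scale: AminoAcidScale
    theta: float = 0.0
    tau: float = 1.0
    mu_pos: float = 20.0
    mu_neg: float = 1.0
    prion_scale: AminoAcidScale | None = None
    prion_theta: float = 0.0
    prion_tau: float = 1.0
    prion_max: float = 0.1

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.prion_tau <= 0:
            raise ValueError("prion_tau must be positive")
        if not self.mu_pos > self.mu_neg >= 0:
            raise ValueError("need mu_pos > mu_neg >= 0")
        if not 0.0 <= self.prion_max <= 1.0:
            raise ValueError("prion_max is a probability")


def window_score(peptide: PeptideWindow | str, scale: AminoAcidScale) -> float:
    """Additive latent score of a window under a scale."""
    residues = str(peptide)
    try:
        return sum(scale[aa] for aa in residues)
    except ScaleCoverageError:
        raise


def _as_rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _sample_codon_batch(
    spec: DegenerateCodonSpec, n_windows: int, window_len: int, rng: np.random.Generator
) -> list[str]:
    """Sample ``n_windows`` degenerate regions (window_len codons each)."""
    n_codons = n_windows * window_len
    cols = []
    for vec in spec.position_probs:
        cols.append(rng.choice(4, size=n_codons, p=np.asarray(vec)))
    bases = np.array(list(NUCLEOTIDES))
    dna = np.char.add(np.char.add(bases[cols[0]], bases[cols[1]]), bases[cols[2]])
    windows = ["".join(dna[i * window_len : (i + 1) * window_len]) for i in range(n_windows)]
    return windows


def sample_library(
    spec: DegenerateCodonSpec,
    n: int,
    window_len: int = 8,
    seed: int | np.random.Generator = 0,
    stop_policy: str = "reject_resample",
) -> list[PeptideWindow]:
    """Sample peptide windows from a degenerate codon scheme.

    ``stop_policy`` controls windows whose degenerate region contains a
    stop codon: ``reject_resample`` (default) redraws them, matching a
    screen that only ever sequences viable full-length fusions;
    ``drop`` discards them (returning <= n windows); ``error`` raises
    :class:`SimulationError` on the first stop.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    if window_len < 1:
        raise ValueError("window_len must be at least 1")
    if stop_policy not in ("reject_resample", "drop", "error"):
        raise ValueError(f"unknown stop_policy {stop_policy!r}")
    rng = _as_rng(seed)

    kept: list[PeptideWindow] = []
    needed = n
    serial = 0
    while needed > 0:
        for dna in _sample_codon_batch(spec, needed, window_len, rng):
            serial += 1
            pep = translate(dna)
            if STOP in pep:
                if stop_policy == "error":
                    raise SimulationError(f"stop codon sampled in window {serial} ({dna})")
                continue  # drop now; reject_resample refills below
            kept.append(PeptideWindow(pep, source_id=f"iso{serial:06d}"))
        if stop_policy == "reject_resample":
            needed = n - len(kept)
        else:
            needed = 0
    return kept


def assign_phenotype(
    peptide: PeptideWindow,
    model: PhenotypeModel,
    seed: int | np.random.Generator = 0,
    config: ScreenConfig = ScreenConfig(),
) -> IsolateRecord:
    """Draw one isolate's initial phenotype under the generative model.

    The label comes from the observed colony-count rule, not directly
    from the latent Bernoulli, so counts near the threshold can flip the
    call. Constitutive positives are GuHCl-incurable by construction.
    """
    rng = _as_rng(seed)
    s = window_score(peptide, model.true_scale)
    p_pos = float(expit((s - model.theta) / model.tau))
    latent_positive = rng.random() < p_pos
    count = int(rng.poisson(model.mu_pos if latent_positive else model.mu_neg))
    label = classify_isolate(count, config)
    curable = False if label is PhenotypeLabel.ADE_PLUS else None
    return IsolateRecord(peptide=peptide, colony_count=count, label=label, curable_by_GuHCl=curable)


def simulate_screen(
    spec: DegenerateCodonSpec,
    n: int,
    model: PhenotypeModel,
    seed: int | np.random.Generator = 0,
    window_len: int = 8,
    config: ScreenConfig = ScreenConfig(),
) -> tuple[list[IsolateRecord], list[IsolateRecord], list[IsolateRecord]]:
    """Simulate a full screen of ``n`` isolates.

    Returns the three disjoint libraries (constitutive ADE+, naive ade-,
    prion). Prion conversion is only attempted for initially negative
    isolates, mirroring the screening order; converted isolates are
    re-labelled PRION with a curable secondary phenotype.
    """
    rng = _as_rng(seed)
    records: list[IsolateRecord] = []
    for pep in sample_library(spec, n, window_len=window_len, seed=rng):
        rec = assign_phenotype(pep, model, seed=rng, config=config)
        if rec.label is PhenotypeLabel.ADE_MINUS and model.prion_scale is not None:
            s2 = window_score(pep, model.prion_scale)
            p_conv = model.prion_max * float(expit((s2 - model.prion_theta) / model.prion_tau))
            if rng.random() < p_conv:
                rec = replace(
                    rec,
                    label=PhenotypeLabel.PRION,
                    secondary_ade_plus=True,
                    curable_by_GuHCl=True,
                )
        records.append(rec)
    return partition_libraries(records, config)


def simulate_paired_libraries(
    spec: DegenerateCodonSpec,
    model: PhenotypeModel,
    n_per_library: int,
    seed: int | np.random.Generator = 0,
    window_len: int = 8,
    config: ScreenConfig = ScreenConfig(),
    max_screened: int = 1_000_000,
) -> tuple[list[IsolateRecord], list[IsolateRecord]]:
    """Screen isolates until the ADE+ and ade- libraries each hold a quota.

    Mirrors sequencing a fixed number of randomly selected isolates per
    library. Raises :class:`SimulationError` if ``max_screened`` isolates
    do not suffice (e.g. a model with a vanishing positive rate).
    """
    rng = _as_rng(seed)
    sel: list[IsolateRecord] = []
    ref: list[IsolateRecord] = []
    screened = 0
    batch = max(4 * n_per_library, 100)
    while (len(sel) < n_per_library or len(ref) < n_per_library) and screened < max_screened:
        ade_plus, ade_minus, _ = simulate_screen(
            spec, batch, model, seed=rng, window_len=window_len, config=config
        )
        screened += batch
        sel.extend(ade_plus)
        ref.extend(ade_minus)
    if len(sel) < n_per_library or len(ref) < n_per_library:
        raise SimulationError(
            f"screened {screened} isolates without filling both libraries "
            f"({len(sel)} ADE+, {len(ref)} ade-)"
        )
    return sel[:n_per_library], ref[:n_per_library]


def calibrate_theta(
    scale: AminoAcidScale,
    spec: DegenerateCodonSpec | None = None,
    target_positive_fraction: float = 0.35,
    tau: float = 1.0,
    window_len: int = 8,
    n_mc: int = 20_000,
    seed: int = 0,
) -> float:
    """Offset theta giving a target latent-positive fraction.

    Solves E[logistic((S - theta)/tau)] = target by root-finding over a
    Monte Carlo sample of window scores under the (stop-rejecting)
    degenerate scheme. The ~35% default matches the positive rate the
    fusion-library screens observed.
    """
    if not 0.0 < target_positive_fraction < 1.0:
        raise ValueError("target fraction must be in (0, 1)")
    spec = spec or nnb_scheme()
    windows = sample_library(spec, n_mc, window_len=window_len, seed=seed)
    scores = np.array([window_score(w, scale) for w in windows])

    def positive_fraction(theta: float) -> float:
        return float(np.mean(expit((scores - theta) / tau)))

    lo = float(scores.min()) - 50.0 * tau
    hi = float(scores.max()) + 50.0 * tau
    return float(brentq(lambda t: positive_fraction(t) - target_positive_fraction, lo, hi))


# ---------------------------------------------------------------------------
# Isolate TSV I/O

_TSV_HEADER = "id\tpeptide\tcolony_count\tlabel\tsecondary_ade_plus\tcurable\n"


def write_isolates(records: Iterable[IsolateRecord], path: str | Path) -> None:
    """Write isolates as TSV; round-trip stable with :func:`read_isolates`."""
    with open(path, "w") as handle:
        handle.write(_TSV_HEADER)
        for rec in records:
            curable = "" if rec.curable_by_GuHCl is None else str(int(rec.curable_by_GuHCl))
            handle.write(
                f"{rec.peptide.source_id}\t{rec.peptide.residues}\t{rec.colony_count}"
                f"\t{rec.label.value}\t{int(rec.secondary_ade_plus)}\t{curable}\n"
            )


def read_isolates(path: str | Path) -> list[IsolateRecord]:
    """Read an isolate TSV written by :func:`write_isolates`."""
    records: list[IsolateRecord] = []
    with open(path) as handle:
        header = handle.readline()
        if header != _TSV_HEADER:
            raise ValueError(f"unexpected isolate TSV header: {header!r}")
        for line in handle:
            line = line.rstrip("\n")
            if not line:
                continue
            rec_id, pep, count, label, secondary, curable = line.split("\t")
            records.append(
                IsolateRecord(
                    peptide=PeptideWindow(pep, source_id=rec_id),
                    colony_count=int(count),
                    label=PhenotypeLabel(label),
                    curable_by_GuHCl=None if curable == "" else bool(int(curable)),
                    secondary_ade_plus=bool(int(secondary)),
                )
            )
    return records
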