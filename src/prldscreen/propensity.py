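"""Per-amino-acid log-odds propensity estimation from library pairs.

A selected library (constitutive ADE+ or [PRION+]) is compared against the
naive ade- reference library. For each amino acid the odds ratio

    OR = [f_sel / (1 - f_sel)] / [f_ref / (1 - f_ref)]

is formed from per-residue frequencies, and the propensity score is
ln(OR): the degradation propensity DP_aa for the ADE+ comparison, the
prion propensity PP_aa for the [PRION+] comparison. Grouped rows pool the
counts of physicochemically similar residues. Enrichment p-values come
from the two-sided Fisher exact test; zero cells are handled with the
Haldane-Anscombe correction (add 0.5 to all four cells of the affected
2x2 table) so every score is finite.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy.stats import fisher_exact

from .seqcore import AMINO_ACIDS, CANONICAL_GROUPS, AminoAcidGroup, PeptideWindow


class EstimationError(ValueError):
    """A propensity table cannot be estimated from the given libraries."""


class ScaleCoverageError(KeyError):
    """A residue is missing from an amino-acid scale."""


@dataclass(frozen=True)
class LibraryCounts:
    """Residue occurrence counts for one sequenced library.

    ``counts`` maps amino acid -> occurrences across all windows;
    ``n_isolates`` and ``window_len`` record the library geometry, so the
    total number of scored residues is ``n_isolates * window_len``.
    """

    counts: Mapping[str, int]
    n_isolates: int
    window_len: int

    @property
    def total(self) -> int:
        return self.n_isolates * self.window_len

    def count(self, residues: str | Iterable[str]) -> int:
        """Pooled count over one or more residues (for group rows)."""
        return sum(self.counts.get(aa, 0) for aa in residues)


def count_residues(peptides: Sequence[PeptideWindow]) -> LibraryCounts:
    """Tally residue occurrences over same-length peptide windows."""
    peptides = list(peptides)
    if not peptides:
        return LibraryCounts(counts={}, n_isolates=0, window_len=0)
    lengths = {len(p) for p in peptides}
    if len(lengths) > 1:
        raise ValueError(f"mixed window lengths {sorted(lengths)}; windows must be uniform")
    counts: dict[str, int] = {}
    for pep in peptides:
        for aa in pep:
            counts[aa] = counts.get(aa, 0) + 1
    return LibraryCounts(counts=counts, n_isolates=len(peptides), window_len=lengths.pop())


def odds_ratio(f_sel: float, f_ref: float) -> float:
    """Odds ratio between a selected and a reference frequency.

    Both frequencies must lie strictly inside (0, 1); callers with zero
    counts should pseudocount first (see :func:`build_propensity_table`).
    """
    for name, f in (("f_sel", f_sel), ("f_ref", f_ref)):
        if not 0.0 < f < 1.0:
            raise ValueError(
                f"{name}={f} outside (0, 1); apply a pseudocount before forming odds ratios"
            )
    return (f_sel / (1.0 - f_sel)) / (f_ref / (1.0 - f_ref))


def propensity_score(or_value: float) -> float:
    """Natural log of an odds ratio (DP_aa or PP_aa)."""
    if or_value <= 0:
        raise ValueError(f"odds ratio must be positive, got {or_value}")
    return math.log(or_value)


def exact_enrichment_test(count_sel: int, total_sel: int, count_ref: int, total_ref: int) -> float:
    """Two-sided Fisher exact p-value for a residue enrichment 2x2 table.

    The table is [[count_sel, total_sel - count_sel],
                  [count_ref, total_ref - count_ref]]; two-sidedness sums
    all tables with the observed margins whose point (hypergeometric)
    probability does not exceed that of the observed table. Degenerate
    tables with a zero margin return p = 1 by convention.
    """
    for name, c, t in (("selected", count_sel, total_sel), ("reference", count_ref, total_ref)):
        if c < 0 or t < 0 or c > t:
            raise ValueError(f"invalid {name} counts: {c} of {t}")
    table = [[count_sel, total_sel - count_sel], [count_ref, total_ref - count_ref]]
    row1 = sum(table[0])
    row2 = sum(table[1])
    col1 = table[0][0] + table[1][0]
    col2 = table[0][1] + table[1][1]
    if min(row1, row2, col1, col2) == 0:
        return 1.0
    return float(fisher_exact(table, alternative="two-sided")[1])


def _pseudocounted_cells(
    count_sel: int, total_sel: int, count_ref: int, total_ref: int
) -> tuple[float, float, float, float, bool]:
    """2x2 cells (a, b, c, d) with Haldane-Anscombe 0.5 added iff any is zero."""
    a = float(count_sel)
    b = float(total_sel - count_sel)
    c = float(count_ref)
    d = float(total_ref - count_ref)
    if min(a, b, c, d) == 0.0:
        return a + 0.5, b + 0.5, c + 0.5, d + 0.5, True
    return a, b, c, d, False


def build_propensity_table(
    sel: LibraryCounts,
    ref: LibraryCounts,
    groups: Sequence[AminoAcidGroup] = CANONICAL_GROUPS,
    pseudocount_policy: str = "haldane",
    scale_kind: str = "degradation",
    context: str = "other",
) -> pd.DataFrame:
    """Per-residue and grouped propensity table from two count libraries.

    Returns a DataFrame with one row per canonical residue plus one per
    group, columns ``residue, is_group, f_sel, f_ref, odds_ratio, score,
    p_value, pseudocounted``. Frequencies are computed after any
    pseudocounting, so every score is finite; p-values always use the raw
    counts. ``scale_kind`` and ``context`` are recorded in ``df.attrs``.
    """
    if pseudocount_policy not in ("haldane", "none"):
        raise ValueError(f"unknown pseudocount policy {pseudocount_policy!r}")
    if sel.total == 0 or ref.total == 0:
        raise EstimationError("both libraries must be non-empty to estimate propensities")

    rows = []
    entries: list[tuple[str, str, bool]] = [(aa, aa, False) for aa in AMINO_ACIDS]
    entries += [(g.name, "".join(sorted(g.members)), True) for g in groups]
    for name, members, is_group in entries:
        c_sel = sel.count(members)
        c_ref = ref.count(members)
        if pseudocount_policy == "haldane":
            a, b, c, d, pseudo = _pseudocounted_cells(c_sel, sel.total, c_ref, ref.total)
        else:
            a, b, c, d, pseudo = float(c_sel), float(sel.total - c_sel), float(c_ref), float(ref.total - c_ref), False
        f_sel = a / (a + b)
        f_ref = c / (c + d)
        or_value = odds_ratio(f_sel, f_ref)
        rows.append(
            {
                "residue": name,
                "is_group": is_group,
                "f_sel": f_sel,
                "f_ref": f_ref,
                "odds_ratio": or_value,
                "score": propensity_score(or_value),
                "p_value": exact_enrichment_test(c_sel, sel.total, c_ref, ref.total),
                "pseudocounted": pseudo,
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["scale_kind"] = scale_kind
    df.attrs["context"] = context
    return df


def table_from_frequencies(
    f_sel: Mapping[str, float],
    f_ref: Mapping[str, float],
    groups: Sequence[AminoAcidGroup] = CANONICAL_GROUPS,
    group_frequencies: tuple[Mapping[str, float], Mapping[str, float]] | None = None,
    scale_kind: str = "degradation",
    context: str = "other",
) -> pd.DataFrame:
    """Propensity table from per-residue frequencies (published-table mode).

    Used when only (rounded) frequencies are available rather than raw
    counts, e.g. to regenerate the published score columns. Group rows sum
    member frequencies unless explicit group frequencies are supplied.
    No exact test is possible without counts, so ``p_value`` is NaN.
    """
    missing = [aa for aa in AMINO_ACIDS if aa not in f_sel or aa not in f_ref]
    if missing:
        raise EstimationError(f"frequencies missing for residues: {missing}")
    rows = []
    for aa in AMINO_ACIDS:
        or_value = odds_ratio(f_sel[aa], f_ref[aa])
        rows.append(
            {
                "residue": aa,
                "is_group": False,
                "f_sel": f_sel[aa],
                "f_ref": f_ref[aa],
                "odds_ratio": or_value,
                "score": propensity_score(or_value),
                "p_value": float("nan"),
                "pseudocounted": False,
            }
        )
    for g in groups:
        if group_frequencies is not None:
            gf_sel = group_frequencies[0][g.name]
            gf_ref = group_frequencies[1][g.name]
        else:
            gf_sel = sum(f_sel[aa] for aa in g.members)
            gf_ref = sum(f_ref[aa] for aa in g.members)
        or_value = odds_ratio(gf_sel, gf_ref)
        rows.append(
            {
                "residue": g.name,
                "is_group": True,
                "f_sel": gf_sel,
                "f_ref": gf_ref,
                "odds_ratio": or_value,
                "score": propensity_score(or_value),
                "p_value": float("nan"),
                "pseudocounted": False,
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["scale_kind"] = scale_kind
    df.attrs["context"] = context
    return df


@dataclass(frozen=True)
class AminoAcidScale:
    """A named per-residue score map (log-odds propensities).

    ``kind`` is ``"degradation"`` or ``"prion"``; ``context`` names the
    parent domain the scale was estimated in (A1, A2, Sup35, other). A
    complete scale covers all 20 canonical residues with finite values.
    """

    name: str
    values: Mapping[str, float]
    kind: str = "degradation"
    context: str = "other"

    def __post_init__(self) -> None:
        for aa, v in self.values.items():
            if not math.isfinite(v):
                raise ValueError(f"non-finite score for residue {aa!r}")

    def __getitem__(self, residue: str) -> float:
        try:
            return self.values[residue]
        except KeyError:
            raise ScaleCoverageError(
                f"residue {residue!r} not covered by scale {self.name!r}"
            ) from None

    def __contains__(self, residue: str) -> bool:
        return residue in self.values

    @property
    def complete(self) -> bool:
        return all(aa in self.values for aa in AMINO_ACIDS)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "name": self.name,
            "kind": self.kind,
            "context": self.context,
            "values": dict(sorted(self.values.items())),
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "AminoAcidScale":
        payload = json.loads(Path(path).read_text())
        return cls(
            name=payload["name"],
            values=payload["values"],
            kind=payload.get("kind", "degradation"),
            context=payload.get("context", "other"),
        )


def score_to_scale(table: pd.DataFrame, name: str = "") -> AminoAcidScale:
    """Extract the 20 per-residue scores of a propensity table as a scale."""
    residue_rows = table.loc[~table["is_group"]]
    values = dict(zip(residue_rows["residue"], residue_rows["score"]))
    missing = [aa for aa in AMINO_ACIDS if aa not in values]
    if missing:
        raise EstimationError(f"table incomplete; missing residues: {missing}")
    return AminoAcidScale(
        name=name or f"{table.attrs.get('context', 'other')}_{table.attrs.get('scale_kind', 'degradation')}",
        values=values,
        kind=table.attrs.get("scale_kind", "degradation"),
        context=table.attrs.get("context", "other"),
    )


def write_propensity_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a propensity table as TSV (published-table column order)."""
    out = table[["residue", "is_group", "f_sel", "f_ref", "odds_ratio", "score", "p_value", "pseudocounted"]]
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")
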