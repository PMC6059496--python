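"""Additive peptide scoring and rational construct design.

A peptide's score on a propensity scale is the plain sum of its
per-residue log-odds values — the same additive rule used to pick
degradation-promoting and inert peptides from an independent mutagenesis
dataset. Construct editing covers the two rational series studied in the
screen's follow-ups: progressive hydrophobic insertion (V, L, M cycled)
and composition swaps between Q/N and G. Coordinates are 1-based
inclusive; insertions occur before the given position.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

from .propensity import AminoAcidScale, ScaleCoverageError
from .seqcore import AMINO_ACIDS, PeptideWindow

#: Cycling order for hydrophobic insertions: the three large aliphatics
#: most over-represented in the degradation library, in that order.
HYDROPHOBIC_CYCLE = "VLM"


@dataclass(frozen=True)
class ConstructEdit:
    """A recorded edit: an insertion or a substitution set.

    ``position`` is a 1-based residue index into the parent (insertions
    occur before it); ``payload`` is the inserted string for insertions,
    or a ``(from_set, to_pattern)`` pair for substitution sets.
    """

    kind: str
    position: int
    payload: object

    def __post_init__(self) -> None:
        if self.kind not in ("insertion", "substitution_set"):
            raise ValueError(f"unknown edit kind {self.kind!r}")
        if self.position < 1:
            raise IndexError("positions are 1-based")


def score_peptide(peptide: PeptideWindow | str, scale: AminoAcidScale) -> float:
    """Sum of per-residue scale values; linear in concatenation."""
    residues = str(peptide)
    total = 0.0
    for aa in residues:
        total += scale[aa]  # raises ScaleCoverageError for uncovered residues
    return total


def rank_candidates(
    peptides: Iterable[PeptideWindow | str],
    scale: AminoAcidScale,
    direction: str = "descending",
) -> list[tuple[str, float]]:
    """Stable sort of peptides by additive score.

    ``direction`` selects descending (high scorers first; default) or
    ascending order; exact score ties break lexicographically by peptide.
    """
    if direction not in ("descending", "ascending"):
        raise ValueError(f"direction must be 'ascending' or 'descending', got {direction!r}")
    scored = [(str(p), score_peptide(p, scale)) for p in peptides]
    reverse = direction == "descending"
    return sorted(scored, key=lambda item: ((-item[1] if reverse else item[1]), item[0]))


def _check_parent(parent: str) -> None:
    for pos, aa in enumerate(parent, start=1):
        if aa not in AMINO_ACIDS:
            raise ValueError(f"non-canonical residue {aa!r} at parent position {pos}")


def insert_hydrophobics(parent: str, position: int, n: int, cycle: str = HYDROPHOBIC_CYCLE) -> str:
    """Insert n hydrophobic residues (cycling V, L, M, V, ...) before ``position``.

    Mirrors the progressive hydrophobic-insertion construct series; the
    result is ``n`` residues longer with all parent residues in order.
    """
    _check_parent(parent)
    if n < 0:
        raise ValueError("n must be non-negative")
    if not 1 <= position <= len(parent) + 1:
        raise IndexError(f"position {position} outside [1, {len(parent) + 1}]")
    insert = "".join(cycle[i % len(cycle)] for i in range(n))
    return parent[: position - 1] + insert + parent[position - 1 :]


def substitute_composition(
    parent: str,
    from_set: Iterable[str],
    to_pattern: str,
    fraction: str = "full",
    selector: Sequence[int] | None = None,
) -> str:
    """Replace residues in ``from_set`` by cycling through ``to_pattern``.

    ``fraction="full"`` replaces every match (e.g. all Q/N -> G, or all
    G -> alternating Q/N); ``"partial"`` replaces the deterministic
    default subset — every second match in sequence order — unless
    ``selector`` supplies explicit 1-based parent positions to edit.
    Length and all non-matching positions are preserved. An empty
    selection under ``"partial"`` warns and returns the parent unchanged.
    """
    _check_parent(parent)
    from_set = frozenset(from_set)
    if not from_set:
        raise ValueError("from_set must be non-empty")
    if not to_pattern:
        raise ValueError("to_pattern must be non-empty")
    if fraction not in ("full", "partial"):
        raise ValueError(f"fraction must be 'full' or 'partial', got {fraction!r}")

    matches = [i for i, aa in enumerate(parent, start=1) if aa in from_set]
    if fraction == "full":
        chosen = matches
    elif selector is not None:
        bad = [p for p in selector if p not in matches]
        if bad:
            raise ValueError(f"selector positions {bad} do not match residues in {sorted(from_set)}")
        chosen = sorted(selector)
    else:
        chosen = matches[1::2]  # every second match (ranks 2, 4, ...)
    if not chosen:
        if fraction == "partial":
            warnings.warn("no positions selected for substitution; returning parent unchanged")
        return parent

    out = list(parent)
    for k, pos in enumerate(chosen):
        out[pos - 1] = to_pattern[k % len(to_pattern)]
    return "".join(out)


def scan_windows(
    domain: str,
    scale: AminoAcidScale,
    window_len: int = 8,
    step: int = 1,
) -> list[tuple[int, float]]:
    """Score every window of a domain; returns (1-based start, score) pairs."""
    _check_parent(domain)
    if window_len > len(domain):
        raise ValueError(f"window_len {window_len} exceeds domain length {len(domain)}")
    if step < 1:
        raise ValueError("step must be positive")
    results = []
    for start0 in range(0, len(domain) - window_len + 1, step):
        results.append((start0 + 1, score_peptide(domain[start0 : start0 + window_len], scale)))
    return results
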