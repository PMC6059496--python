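"""Sequence alphabets, genetic code, and degenerate-codon arithmetic.

Shared foundation for the mutagenesis-screen pipeline: strict one-letter
amino-acid alphabet, the standard genetic code (via Biopython), the
position-wise nucleotide probability model of a degenerate codon scheme,
and FASTA/TSV I/O for short peptide windows.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq
from Bio.SeqIO import parse as fasta_parse
from Bio.SeqIO import write as fasta_write
from Bio.SeqRecord import SeqRecord

#: The 20 canonical amino acids, one-letter codes.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

#: Stop symbol used in translated sequences.
STOP: str = "*"

NUCLEOTIDES: str = "ACGT"


class AlphabetError(ValueError):
    """A sequence contains a symbol outside the permitted alphabet."""


class FrameError(ValueError):
    """A nucleotide sequence length is not a multiple of three."""


@dataclass(frozen=True)
class AminoAcidGroup:
    """A named group of physicochemically similar residues.

    The five canonical groups used throughout the screen analysis are
    Aromatic (FWY), Charged (DEKR), Hydrophobic (ILMV, the large
    aliphatics), Polar (GHST) and QN. Alanine, cysteine and proline
    belong to no group.
    """

    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        bad = self.members - set(AMINO_ACIDS)
        if bad:
            raise AlphabetError(f"non-canonical residues in group {self.name!r}: {sorted(bad)}")

    def __contains__(self, residue: str) -> bool:
        return residue in self.members


CANONICAL_GROUPS: tuple[AminoAcidGroup, ...] = (
    AminoAcidGroup("Aromatic", frozenset("FWY")),
    AminoAcidGroup("Charged", frozenset("DEKR")),
    AminoAcidGroup("Hydrophobic", frozenset("ILMV")),
    AminoAcidGroup("Polar", frozenset("GHST")),
    AminoAcidGroup("QN", frozenset("QN")),
)


@dataclass(frozen=True)
class PeptideWindow:
    """A short mutagenized peptide segment (8 residues in the screen).

    Only the 20 canonical one-letter codes are accepted; a stop symbol or
    ambiguity code anywhere is an :class:`AlphabetError`. ``source_id`` is
    a free-text isolate/record identifier.
    """

    residues: str
    source_id: str = ""

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise ValueError("peptide window must contain at least one residue")
        for pos, aa in enumerate(self.residues, start=1):
            if aa not in AMINO_ACIDS:
                raise AlphabetError(
                    f"record {self.source_id!r}: non-canonical residue {aa!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.residues)

    def __iter__(self):
        return iter(self.residues)

    def __str__(self) -> str:
        return self.residues


@dataclass(frozen=True)
class DegenerateCodonSpec:
    """Position-wise nucleotide probabilities of a degenerate codon.

    ``position_probs`` holds three probability vectors over (A, C, G, T),
    one per codon position; each must sum to 1 within 1e-12.
    """

    position_probs: tuple[tuple[float, float, float, float], ...]
    label: str = ""

    def __post_init__(self) -> None:
        if len(self.position_probs) != 3:
            raise ValueError("a codon has exactly three positions")
        for pos, vec in enumerate(self.position_probs, start=1):
            if len(vec) != 4:
                raise ValueError(f"position {pos}: need one probability per nucleotide (ACGT)")
            if any(p < 0 for p in vec):
                raise ValueError(f"position {pos}: negative probability")
            if abs(sum(vec) - 1.0) > 1e-12:
                raise ValueError(f"position {pos}: probabilities sum to {sum(vec)}, not 1")

    def codon_probability(self, codon: str) -> float:
        """Probability of drawing ``codon`` under this scheme."""
        if len(codon) != 3 or any(b not in NUCLEOTIDES for b in codon):
            raise AlphabetError(f"not a codon over ACGT: {codon!r}")
        p = 1.0
        for vec, base in zip(self.position_probs, codon):
            p *= vec[NUCLEOTIDES.index(base)]
        return p


def nnb_scheme() -> DegenerateCodonSpec:
    """The screen's mutagenesis scheme: N at codon positions 1-2, B at 3.

    All four nucleotides are equiprobable at the first two positions; the
    third position is uniform over C/G/T (A excluded), which limits stop
    codons to TAG (1 of the 48 supported codons).
    """
    n = (0.25, 0.25, 0.25, 0.25)
    b = (0.0, 1.0 / 3.0, 1.0 / 3.0, 1.0 / 3.0)
    return DegenerateCodonSpec((n, n, b), label="NNB")


def uniform_codon_scheme() -> DegenerateCodonSpec:
    """Uniform distribution over all 64 codons (NNN)."""
    n = (0.25, 0.25, 0.25, 0.25)
    return DegenerateCodonSpec((n, n, n), label="NNN")


def translate(dna: str) -> str:
    """Translate a DNA string under the standard genetic code.

    Stops are rendered as ``"*"``. Raises :class:`AlphabetError` for
    non-ACGT characters and :class:`FrameError` if the length is not a
    multiple of three.
    """
    for ch in dna:
        if ch not in NUCLEOTIDES:
            raise AlphabetError(f"non-ACGT character {ch!r} in nucleotide sequence")
    if len(dna) % 3 != 0:
        raise FrameError(f"sequence length {len(dna)} is not a multiple of 3")
    return str(Seq(dna).translate(table=standard_dna_table))


def codon_aa_distribution(spec: DegenerateCodonSpec) -> dict[str, float]:
    """Exact amino-acid (plus stop) distribution of one degenerate codon.

    Enumerates all codons with nonzero probability under ``spec`` and sums
    probabilities by translated symbol. The result maps each of the 21
    symbols (20 amino acids and ``"*"``) with nonzero mass to its
    probability; values sum to 1 within 1e-12.
    """
    dist: dict[str, float] = {}
    for codon_tuple in itertools.product(NUCLEOTIDES, repeat=3):
        codon = "".join(codon_tuple)
        p = spec.codon_probability(codon)
        if p == 0.0:
            continue
        aa = translate(codon)
        dist[aa] = dist.get(aa, 0.0) + p
    return dist


def residue_distribution(spec: DegenerateCodonSpec, conditioned_on_no_stop: bool = False) -> dict[str, float]:
    """Amino-acid distribution of one codon, optionally excluding stops.

    With ``conditioned_on_no_stop`` the stop mass is removed and the
    remaining probabilities renormalized — the per-residue distribution of
    windows sampled under a stop-rejecting policy.
    """
    dist = codon_aa_distribution(spec)
    if not conditioned_on_no_stop:
        return dist
    p_stop = dist.pop(STOP, 0.0)
    scale = 1.0 - p_stop
    return {aa: p / scale for aa, p in dist.items()}


# ---------------------------------------------------------------------------
# Peptide I/O

def read_peptides(path: str | Path, format: str = "fasta") -> list[PeptideWindow]:
    """Read peptide windows from FASTA or two-column (id, peptide) TSV.

    FASTA descriptions are split at the first whitespace for the
    ``source_id``. Any non-canonical residue raises :class:`AlphabetError`
    naming the record and position.
    """
    path = Path(path)
    windows: list[PeptideWindow] = []
    if format == "fasta":
        with open(path) as handle:
            for rec in fasta_parse(handle, "fasta"):
                windows.append(PeptideWindow(str(rec.seq).upper(), source_id=rec.id))
    elif format == "tsv":
        with open(path) as handle:
            for line in handle:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) == 1:
                    rec_id, seq = "", fields[0]
                else:
                    rec_id, seq = fields[0], fields[1]
                if rec_id == "id" and seq == "peptide":  # header row
                    continue
                windows.append(PeptideWindow(seq.upper(), source_id=rec_id))
    else:
        raise ValueError(f"unknown peptide format {format!r} (expected 'fasta' or 'tsv')")
    return windows


def write_peptides(windows: Iterable[PeptideWindow], path: str | Path, format: str = "fasta") -> None:
    """Write peptide windows; round-trip stable with :func:`read_peptides`."""
    path = Path(path)
    windows = list(windows)
    if format == "fasta":
        records = [
            SeqRecord(Seq(w.residues), id=w.source_id or f"pep{i}", description="")
            for i, w in enumerate(windows, start=1)
        ]
        with open(path, "w") as handle:
            fasta_write(records, handle, "fasta")
    elif format == "tsv":
        with open(path, "w") as handle:
            handle.write("id\tpeptide\n")
            for i, w in enumerate(windows, start=1):
                handle.write(f"{w.source_id or f'pep{i}'}\t{w.residues}\n")
    else:
        raise ValueError(f"unknown peptide format {format!r} (expected 'fasta' or 'tsv')")
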