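"""Isolate classification and library partitioning.

Turns raw screen observations (colony counts on adenine-deficient medium,
guanidine-curability of secondary ADE+ growth) into the three analysis
libraries: constitutive ADE+, naive ade-, and [PRION+].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence, TYPE_CHECKING

if TYPE_CHECKING:  # pragma: no cover
    from .library_sim import IsolateRecord

logger = logging.getLogger(__name__)


class PhenotypeLabel(str, Enum):
    """Library assignment of a screened isolate."""

    ADE_PLUS = "ADE_PLUS"   # constitutive growth without adenine (degradation phenotype)
    ADE_MINUS = "ADE_MINUS"  # naive, no growth without adenine
    PRION = "PRION"         # initially ade-, later ADE+ and GuHCl-curable

    def __str__(self) -> str:
        return self.value


@dataclass(frozen=True)
class ScreenConfig:
    """Classification rules of the screen.

    ``colony_threshold``: an isolate is ADE+ iff strictly more than this
    many colonies appear on SC-ade (default 5; exactly 5 is called ade-,
    the conservative reading of the "more than 5" / "fewer than 5" rule).
    ``require_curability_for_prion``: prion calls must be confirmed by
    guanidine curing (default True).
    """

    colony_threshold: int = 5
    require_curability_for_prion: bool = True

    def __post_init__(self) -> None:
        if self.colony_threshold < 0:
            raise ValueError("colony_threshold must be non-negative")


def classify_isolate(colony_count: int, config: ScreenConfig = ScreenConfig()) -> PhenotypeLabel:
    """Initial adenine phenotype from the SC-ade colony count.

    ADE_PLUS iff ``colony_count > config.colony_threshold``.
    """
    if colony_count < 0:
        raise ValueError(f"colony count must be non-negative, got {colony_count}")
    if colony_count > config.colony_threshold:
        return PhenotypeLabel.ADE_PLUS
    return PhenotypeLabel.ADE_MINUS


def partition_libraries(
    records: Iterable["IsolateRecord"],
    config: ScreenConfig = ScreenConfig(),
) -> tuple[list["IsolateRecord"], list["IsolateRecord"], list["IsolateRecord"]]:
    """Partition isolates into (ade_plus, ade_minus, prion) libraries.

    The three lists are disjoint and jointly exhaustive. Isolates whose
    colony count exceeds the threshold join the constitutive ADE+ library
    regardless of curability. Initially negative isolates that later grew
    on SC-ade join the prion library only if their secondary phenotype was
    cured by GuHCl (or curability is not required); a prion candidate with
    unknown curability is kept in ade- with a logged warning, never
    silently dropped.
    """
    ade_plus: list["IsolateRecord"] = []
    ade_minus: list["IsolateRecord"] = []
    prion: list["IsolateRecord"] = []
    for rec in records:
        if classify_isolate(rec.colony_count, config) is PhenotypeLabel.ADE_PLUS:
            ade_plus.append(rec)
            continue
        if rec.secondary_ade_plus:
            if rec.curable_by_GuHCl is True or not config.require_curability_for_prion:
                prion.append(rec)
                continue
            if rec.curable_by_GuHCl is None:
                logger.warning(
                    "isolate %r: secondary ADE+ growth but unknown GuHCl curability; "
                    "excluded from the prion library",
                    rec.peptide.source_id,
                )
        ade_minus.append(rec)
    return ade_plus, ade_minus, prion
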