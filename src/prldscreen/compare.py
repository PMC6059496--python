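"""Cross-scale comparison: degradation propensity vs prion propensity.

The central question this layer answers: which residues make a domain
aggregation-prone without making it degradation-prone? Each residue's
mean degradation score (averaged over the A1 and A2 screen contexts) is
set against an external prion-propensity reference scale, with a Spearman
rank correlation (midranks for ties; exact permutation p-value at small
n, t-approximation otherwise).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from scipy.stats import t as t_dist

from .propensity import AminoAcidScale
from .seqcore import AMINO_ACIDS, CANONICAL_GROUPS

#: Largest n for which the permutation null is enumerated exactly.
EXACT_PERMUTATION_MAX_N = 9


class ComparisonError(ValueError):
    """Two scales cannot be compared or averaged."""


def average_scales(a: AminoAcidScale, b: AminoAcidScale) -> AminoAcidScale:
    """Per-residue arithmetic mean of two scales of the same kind."""
    if a.kind != b.kind:
        raise ComparisonError(f"cannot average scales of different kinds: {a.kind!r} vs {b.kind!r}")
    if set(a.values) != set(b.values):
        raise ComparisonError("scales cover different residue sets")
    values = {aa: (a[aa] + b[aa]) / 2.0 for aa in a.values}
    context = a.context if a.context == b.context else f"{a.context}+{b.context}"
    return AminoAcidScale(
        name=f"mean({a.name},{b.name})", values=values, kind=a.kind, context=context
    )


def spearman_rank(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with a small-n exact permutation p-value.

    rho is the Pearson correlation of midranks. For n <= 9 the two-sided
    p doubles the smaller one-sided tail of the exact permutation null
    (capped at 1); for larger n the usual t-approximation with n - 2
    degrees of freedom is used. Constant input has no defined rank
    correlation and raises :class:`ComparisonError`.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d vectors")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    rx = rankdata(x)
    ry = rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise ComparisonError("rank correlation undefined for a constant vector")
    rho = float(np.corrcoef(rx, ry)[0, 1])

    if n <= EXACT_PERMUTATION_MAX_N:
        # Under H0 all orderings of one rank vector are equally likely; only
        # the cross-product term varies across permutations.
        perms = np.array(list(permutations(ry)))
        cross = perms @ rx
        sx = np.sqrt(np.sum((rx - rx.mean()) ** 2))
        sy = np.sqrt(np.sum((ry - ry.mean()) ** 2))
        rhos = (cross - n * rx.mean() * ry.mean()) / (sx * sy)
        eps = 1e-12
        upper = float(np.mean(rhos >= rho - eps))
        lower = float(np.mean(rhos <= rho + eps))
        p = min(1.0, 2.0 * min(upper, lower))
    else:
        if abs(rho) == 1.0:
            p = 0.0
        else:
            t_stat = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
            p = float(2.0 * t_dist.sf(abs(t_stat), df=n - 2))
    return rho, p


def _group_of(residue: str) -> str:
    for g in CANONICAL_GROUPS:
        if residue in g:
            return g.name
    return ""


@dataclass(frozen=True)
class ScaleComparison:
    """Per-residue degradation-vs-prion comparison with its rank statistics.

    ``table`` has one row per residue: x (prion propensity, the external
    reference), y (mean degradation score), group (canonical group name
    or empty). ``rho``/``p_rho`` are the Spearman statistics over the
    20 residues.
    """

    table: pd.DataFrame
    rho: float
    p_rho: float


def compare_scales(prion_ref: AminoAcidScale, degradation: AminoAcidScale) -> ScaleComparison:
    """Build the degradation-vs-prion comparison for the 20 residues."""
    missing = [aa for aa in AMINO_ACIDS if aa not in prion_ref or aa not in degradation]
    if missing:
        raise ComparisonError(f"scales incomplete; missing residues: {missing}")
    rows = [
        {"residue": aa, "x": prion_ref[aa], "y": degradation[aa], "group": _group_of(aa)}
        for aa in AMINO_ACIDS
    ]
    table = pd.DataFrame(rows)
    rho, p = spearman_rank(table["x"].to_numpy(), table["y"].to_numpy())
    return ScaleComparison(table=table, rho=rho, p_rho=p)


def plot_scale_comparison(comparison: ScaleComparison, path: str) -> None:
    """Scatter of degradation vs prion propensity, colored by residue group."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {
        "Aromatic": "tab:purple",
        "Charged": "tab:red",
        "Hydrophobic": "tab:blue",
        "Polar": "tab:green",
        "QN": "tab:orange",
        "": "tab:gray",
    }
    fig, ax = plt.subplots(figsize=(5, 4))
    for _, row in comparison.table.iterrows():
        ax.scatter(row["x"], row["y"], color=colors[row["group"]], s=30)
        ax.annotate(row["residue"], (row["x"], row["y"]), fontsize=8,
                    xytext=(3, 3), textcoords="offset points")
    ax.set_xlabel("prion propensity (external reference)")
    ax.set_ylabel("mean degradation propensity ln(OR)")
    ax.set_title(f"Spearman rho = {comparison.rho:.2f} (p = {comparison.p_rho:.3g})")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
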