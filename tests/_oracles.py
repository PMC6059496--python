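"""Independent brute-force oracles used across the test suite.

Everything here is written against the mathematical definition only and
never calls the package code it checks.
"""

from fractions import Fraction
from itertools import permutations
from math import comb


#: Standard genetic code, hard-coded independently of any library.
CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def fisher_two_sided_exact(a: int, b: int, c: int, d: int) -> Fraction:
    """Two-sided Fisher p by exhaustive hypergeometric enumeration.

    Sums the point probabilities of every 2x2 table with the observed
    margins whose probability does not exceed the observed table's.
    Exact rational arithmetic throughout.
    """
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if min(r1, r2, c1, b + d) == 0:
        return Fraction(1)
    denom = comb(n, c1)
    p_obs = Fraction(comb(r1, a) * comb(r2, c1 - a), denom)
    total = Fraction(0)
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        p_k = Fraction(comb(r1, k) * comb(r2, c1 - k), denom)
        if p_k <= p_obs:
            total += p_k
    return total


def _rank(values):
    """Midranks, from the definition."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        mean_rank = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = mean_rank
        i = j + 1
    return ranks


def _pearson(u, v):
    n = len(u)
    mu = sum(u) / n
    mv = sum(v) / n
    cov = sum((a - mu) * (b - mv) for a, b in zip(u, v))
    su = sum((a - mu) ** 2 for a in u) ** 0.5
    sv = sum((b - mv) ** 2 for b in v) ** 0.5
    return cov / (su * sv)


def spearman_exact(x, y):
    """(rho, two-sided permutation p) by full enumeration of n! orderings.

    rho is the Pearson correlation of midranks; p doubles the smaller
    one-sided tail, capped at 1.
    """
    rx = _rank(list(x))
    ry = _rank(list(y))
    rho = _pearson(rx, ry)
    rhos = [_pearson(rx, list(perm)) for perm in permutations(ry)]
    eps = 1e-12
    upper = sum(r >= rho - eps for r in rhos) / len(rhos)
    lower = sum(r <= rho + eps for r in rhos) / len(rhos)
    return rho, min(1.0, 2.0 * min(upper, lower))
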