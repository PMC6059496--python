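"""Score peptides additively and design rational constructs.

A window's score is the sum of its residues' log-odds values; positive
sums predict degradation of the prion-like domain, negative sums predict
stability.
"""

from prldscreen import (
    insert_hydrophobics,
    published_scale,
    rank_candidates,
    score_peptide,
    substitute_composition,
)

a2 = published_scale("a2_degradation")

candidates = ["LVIAGDIS", "YISVYVAG", "LYVITNFI", "SRGDRSSG", "GIRRDCGC", "SGNYNDFG"]
print("peptides ranked by predicted degradation propensity:")
for pep, score in rank_candidates(candidates, a2):
    print(f"  {pep}  {score:+.2f}")
# The three hydrophobic-rich peptides score far above the charge-rich ones;
# SGNYNDFG (the wild-type A2 window) scores strongly negative, matching its
# stable ade- phenotype.

wt = "SGNYNDFG"
print("\nprogressive hydrophobic insertion (V,L,M cycling) raises the score:")
for n in range(0, 8):
    mutant = insert_hydrophobics(wt, position=5, n=n)
    print(f"  n={n}  {mutant:<15s}  {score_peptide(mutant, a2):+.2f}")

print("\ncomposition swaps:")
print("  Q/N -> G :", substitute_composition("QNSQG", "QN", "G"))
print("  G -> Q/N :", substitute_composition("GGSGG", "G", "QN"))
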