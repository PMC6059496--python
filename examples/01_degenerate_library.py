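"""Sample a degenerate-codon mutant library and inspect its composition.

The mutagenesis scheme randomizes 8 codons with all four nucleotides
equiprobable at the first two positions and C/G/T at the third, so TAG is
the only reachable stop codon (1 of 48 codons).
"""

from prldscreen import codon_aa_distribution, nnb_scheme, residue_distribution, sample_library

scheme = nnb_scheme()

dist = codon_aa_distribution(scheme)
print(f"P(stop) per codon  = {dist['*']:.5f}  (exactly 1/48)")
print(f"P(Leu)  per codon  = {dist['L']:.5f}  (exactly 4/48)")

windows = sample_library(scheme, n=5000, window_len=8, seed=1)
n_residues = len(windows) * 8
obs_leu = sum(w.residues.count("L") for w in windows) / n_residues
expected_leu = residue_distribution(scheme, conditioned_on_no_stop=True)["L"]
print(f"observed Leu frequency in 5000 stop-free windows = {obs_leu:.4f}")
print(f"stop-conditioned enumeration value               = {expected_leu:.4f}")
# The sampled library matches the exact enumeration distribution of the
# scheme conditioned on containing no premature stop codon.
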