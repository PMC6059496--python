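"""Simulate a full screen and recover the true propensity scale.

The generator uses the published A2 degradation scale as ground truth:
each sampled window's summed score sets its probability of a constitutive
ADE+ phenotype through a logistic link, colony counts are Poisson, and
the observed more-than-5-colonies rule assigns libraries. Estimating
ln(OR) per residue from the simulated libraries should recover the truth.
"""

from prldscreen import (
    AMINO_ACIDS,
    PhenotypeModel,
    build_propensity_table,
    calibrate_theta,
    count_residues,
    nnb_scheme,
    published_scale,
    score_to_scale,
    simulate_paired_libraries,
    spearman_rank,
)

scheme = nnb_scheme()
truth = published_scale("a2_degradation")
theta = calibrate_theta(truth, scheme, target_positive_fraction=0.35, seed=0)
model = PhenotypeModel(true_scale=truth, theta=theta)
print(f"calibrated theta = {theta:.3f} (targets ~35% constitutive positives)")

sel, ref = simulate_paired_libraries(scheme, model, n_per_library=2000, seed=1)
table = build_propensity_table(
    count_residues([r.peptide for r in sel]),
    count_residues([r.peptide for r in ref]),
)
estimated = score_to_scale(table)

rho, _ = spearman_rank([truth[a] for a in AMINO_ACIDS], [estimated[a] for a in AMINO_ACIDS])
print(f"Spearman rho(true, estimated) over 20 residues = {rho:.3f}")
top5 = sorted(AMINO_ACIDS, key=lambda a: -estimated[a])[:5]
print(f"top-5 estimated degradation promoters: {top5}")
# With 2000 sequenced isolates per library the rank order is recovered
# almost perfectly and the large aliphatics (I, L, M, V) head the list.
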