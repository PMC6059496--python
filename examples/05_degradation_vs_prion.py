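"""Compare degradation propensity against an external prion propensity scale.

Averages the two screen-derived degradation scales (A1 and A2 contexts)
and correlates them with the bundled third-party prion propensity
reference. The interesting residues are those that promote aggregation
without promoting degradation.
"""

from prldscreen import average_scales, compare_scales, papa_scale, published_scale

mean_deg = average_scales(
    published_scale("a1_degradation"), published_scale("a2_degradation")
)
comparison = compare_scales(papa_scale(), mean_deg)

print(f"Spearman rho = {comparison.rho:.3f}, p = {comparison.p_rho:.4f}")
y = dict(zip(comparison.table.residue, comparison.table.y))
print("mean degradation scores:")
print("  aromatics + Q/N :", {aa: round(y[aa], 2) for aa in "FWYQN"})
print("  large aliphatics:", {aa: round(y[aa], 2) for aa in "ILMV"})
# Degradation and prion propensity correlate positively overall, but the
# aromatics and Q/N sit well below the aliphatics on the degradation axis:
# they promote aggregation while largely escaping the degradation machinery.
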