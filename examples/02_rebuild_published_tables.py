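"""Regenerate the published propensity scores from the printed frequencies.

Each score is ln(OR) where OR = [f_sel/(1-f_sel)] / [f_ref/(1-f_ref)]:
positive means over-represented in the selected library (degradation- or
prion-promoting), negative means under-represented.
"""

from prldscreen import published_table

for kind in ("degradation", "prion"):
    table = published_table(kind, "A2")
    print(f"\nA2 {kind} propensities (recomputed from printed frequencies):")
    groups = table.loc[table.is_group, ["residue", "f_sel", "f_ref", "score"]]
    print(groups.to_string(index=False, float_format="%.3f"))

# The hydrophobic (ILMV) group dominates the degradation comparison
# (ln OR ~ +1.31) while the aromatic group dominates the prion comparison
# (~ +0.87); Q/N is depleted in both selected libraries.
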