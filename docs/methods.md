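# Methods

## The estimation model

The screen compares residue composition between a phenotype-selected library
and a naive reference library of short mutagenized windows (8 residues by
default). For amino acid *a*, let *f_sel* and *f_ref* be its per-residue
frequencies (count / (isolates × window length)) in the two libraries. The
propensity score is the log odds ratio

    score(a) = ln( [f_sel/(1−f_sel)] / [f_ref/(1−f_ref)] )

— the degradation propensity when the selected library is the constitutive
ADE+ set, the prion propensity when it is the [PRION+] set. The score is
antisymmetric under swapping the libraries, and a peptide's predicted
phenotype strength is the plain sum of its residues' scores (additive, no
positional weighting). Group rows (Aromatic FWY, Charged DEKR, Hydrophobic
ILMV, Polar GHST, QN; A/C/P ungrouped) pool member counts into a single 2×2
comparison, which sharpens the enrichment tests at the cost of per-residue
resolution.

Enrichment p-values use the two-sided Fisher exact test on the 2×2 count
table, with two-sidedness defined by summing all tables (at fixed margins)
whose point hypergeometric probability does not exceed the observed one;
degenerate tables with an empty margin return p = 1. The test choice is an
assumption of this package — any exact 2×2 test would be defensible — and the
per-residue p-values of the bundled published tables cannot be recomputed
here because the underlying library sizes are not part of the bundled data.

**Zero counts.** When any cell of a residue's 2×2 table is zero, 0.5 is added
to all four cells (Haldane–Anscombe) before frequencies and odds ratios are
formed, and the row is flagged `pseudocounted`. Rows without zeros are left
untouched, so the correction never perturbs the well-populated regime.
P-values always use the raw counts.

**Published-table mode.** When only rounded frequencies are available (the
bundled tables print 3 decimals), the same formula is applied to them
directly. Each printed frequency carries up to ±0.0005 rounding error, which
propagates to roughly ±0.05 on ln(OR) at typical frequencies — but grows
sharply for very small frequencies (at f ≈ 0.007 it approaches ±0.1). The
test suite therefore checks printed-score agreement both with a flat ±0.05
band (which one extreme low-frequency row genuinely exceeds) and with exact
interval propagation of the rounding error (which every row satisfies).

## The synthetic screen generator

The generator stands in for every wet-lab step, so the estimation pipeline is
testable end to end. What it emulates, and its defaults:

- **Mutagenesis.** Windows of 8 codons drawn from a degenerate scheme;
  the default scheme has all four nucleotides equiprobable at codon positions
  1–2 and C/G/T equiprobable at position 3 (exactly 1/3 each; printed "33%"
  figures are treated as rounding). TAG is then the only reachable stop
  codon, with probability 1/48 per codon. Stop-containing windows are
  rejected and resampled by default — a screen only sequences viable,
  full-length fusions — which conditions the residue distribution on
  stop-freedom (renormalized enumeration probabilities). `drop` and `error`
  policies are available for studying that bias; the expected `drop`
  retention for 8 codons is (47/48)^8 ≈ 0.845.
- **Phenotype.** A window with summed true score S is latently positive with
  probability 1/(1+exp(−(S−θ)/τ)). The offset θ is calibrated by Monte Carlo
  root-finding so that ~35% of isolates are positive, matching the positive
  rate the fusion-library screens observed; the width τ defaults to 1.0 (the
  natural scale of the logistic; the calibration constraint cannot fix both
  parameters, and unit width leaves realistic phenotype noise near the
  boundary).
- **Colony counts.** Poisson with mean μ_pos = 20 (latent positives) or
  μ_neg = 1 (negatives), and the observed classification rule — strictly
  more than 5 colonies — assigns the label. With these defaults
  misclassification at the boundary is rare but nonzero
  (P[Poisson(1) > 5] ≈ 6×10⁻⁴), and both means are configurable to study the
  boundary directly. Exactly 5 colonies is classified negative (conservative
  reading of the published "more than 5" / "fewer than 5" rule; the boundary
  is configurable).
- **Prion conversion.** Only initially negative isolates are eligible
  (matching the screening order). Conversion probability is
  p_max · logistic((S₂−θ₂)/τ₂) under a second (prion) scale, with
  p_max = 0.1 by default — large relative to the per-generation spontaneous
  rate in vivo, but representative of a screen that replates ~10⁶ cells and
  so recovers rare events; it keeps prion libraries small relative to the
  other two while still populated at simulation scale.
- **Determinism.** One integer seed drives a single numpy Generator through
  sampling, phenotype, counts and conversion; identical config + seed gives
  byte-identical serialized output.

What the generator does **not** emulate: PCR/sequencing errors and indels
(non-canonical or off-length windows are rejected, not modeled), growth
kinetics, protein levels and degradation time-courses, plasmid dynamics, and
any positional or epistatic sequence effects — phenotype depends on
composition only. Passing recovery tests therefore show that the estimator
inverts this compositional generative model at realistic library sizes, not
that real screens are free of positional effects or selection artifacts.

Simulation sizes in the tests follow the acceptance conditions: 2000
sequenced isolates per library for parameter recovery, 5000 windows for
composition checks, and 20 replicate screens of 300 isolates per library for
the monotonicity check.

## Construct design conventions

Coordinates are 1-based; insertions occur before the given position.
Hydrophobic insertions cycle V→L→M (the three aliphatics most
over-represented in the degradation library, in that order; the cycling
order is this package's convention since only the residue set is fixed by
the screen design). Composition swaps replace every matched residue
(`full`) or a deterministic subset (`partial`: every second match, or an
explicit user-supplied position list) by cycling through the replacement
pattern, e.g. G→Q,N,Q,N…; alternation is again a convention where the
original constructs fixed only the composition change.

## Cross-scale comparison

The degradation axis is the per-residue mean of the A1- and A2-context
degradation scales; the prion axis is an external reference scale bundled as
third-party constants (see the citation inside
`src/prldscreen/data/papa_prion_propensity.json`). Spearman rho uses midranks
for ties; the two-sided p-value doubles the smaller one-sided tail of the
exact permutation null for n ≤ 9 (all n! orderings enumerated) and uses the
t-approximation with n−2 degrees of freedom above that. Rank correlation on a
constant vector is undefined and raises rather than returning NaN. The
comparison against the external scale is treated as qualitative: the
reference values come from a different reporter context, so tests gate only
the sign of the correlation and the characteristic pattern (aromatics and
Q/N scoring far below the aliphatics on the degradation axis), not an exact
coefficient.

## Numerical notes and limitations

- Odds ratios require frequencies strictly inside (0,1); callers are directed
  to pseudocounting rather than silently clamping.
- Candidate ranking breaks exact score ties lexicographically so output is
  stable across runs and platforms.
- Scores are computed in double precision; bundled "published" scales carry
  the printed 2-decimal values so that downstream sums match the printed
  tables exactly.
- The estimator treats residues independently; because window composition is
  multinomial, selection on one residue induces weak negative correlations in
  the estimated scores of the others. At the tested library sizes this bias
  is well below the sampling noise, but it is inherent to composition-based
  log-odds estimation.
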