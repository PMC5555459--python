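# Methods

This note documents the models, estimators and numerical choices behind
`nucmorph`, and what the synthetic-data tests do and do not demonstrate.

## Morphometry

Objects (nuclei, chromocenters) are measured on 8-bit 2D images against a
label mask. Traits per object:

* **Area** — pixel count of the label.
* **Intensity** — mean 8-bit level over the object's pixels. Optical-density
  style reports call this *density*; output tables carry both column names
  for the same number.
* **Perimeter** — outline length in pixel units. Default estimator is the
  Crofton 4-direction formula (scikit-image), which is close to unbiased on
  digital discs, so the isoperimetric inequality holds up to raster error
  (measured roundness of digital discs is 0.99–1.00 for radii 20–100). A
  naive boundary-pixel count is available as `perimeter_method=
  "boundary_count"` for compatibility with older macro outputs; it
  systematically underestimates the Euclidean length of diagonal boundaries
  and is not used by default.
* **Roundness** — `perimeter² / (4π·area)`; exactly 1 for an ideal circle,
  larger for irregular outlines.
* **Heterogeneity** — fraction of the object's pixels whose intensity
  deviates strictly more than 10% from the object mean. The band is
  relative to each object's own mean. Note the polarity convention is
  "fraction of deviating pixels": a *high* value means many pixels deviate.
  Some narrative descriptions of this trait use the opposite wording ("low
  value = high heterogeneity"); the formula above is what is computed.

**Relative heterochromatin fraction (RHF).** The background-corrected share
of a nucleus's DAPI signal held in its chromocenters:

    RHF = Σ_cc [area_cc · (intensity_cc − background)]
          / [area_nu · (intensity_nu − background)]

The numerator sums over all chromocenters of the nucleus — RHF is the
proportion of DNA in chromocenters, which requires the sum. Background is
the median intensity outside all nuclei (excluding a 2-px dilation rim),
estimated per image. The ratio is clipped to [0, 1] with a warning, since
pixel noise can push per-object estimates marginally outside. A nucleus
whose mean does not exceed background is an error, not a zero.

Per-nucleus chromocenter traits are unweighted means over that nucleus's
chromocenters; a nucleus without chromocenters reports RHF 0 and missing
(NaN) chromocenter averages rather than zeros.

## Segmentation

Nuclei: Gaussian smoothing (σ = 1 px default) → global Otsu threshold →
fill holes → drop objects < 200 px → drop border-touching objects (their
area/perimeter would be truncated) → 8-connected labelling. A constant
image yields an empty mask. Because Otsu is a relative criterion, the
nucleus mask is invariant under a constant intensity shift (up to 8-bit
clipping).

Chromocenters: within each nucleus, pixels strictly brighter than
`mean + k·SD` of that nucleus's raw pixel intensities (k = 2 default),
blobs < 4 px removed, labelled 8-connected, each mapped to its parent
nucleus. The threshold is per-nucleus so that dim and bright nuclei are
treated symmetrically; a global variant (pooled mean/SD over all nucleus
pixels) is exposed via `cc_threshold_scope="global"`. Hole filling applies
to the nucleus outline only, not to chromocenter blobs.

A caveat of the `mean + k·SD` rule: when chromocenters occupy a large
fraction of the nucleus (strongly compacted nuclei), the bimodal intensity
histogram inflates the SD and the threshold approaches the chromocenter
level itself, making detection unstable. At the chromocenter area fractions
the generator emulates (< 10% of nucleus area) the margin between threshold
and chromocenter level is several times the pixel noise.

## Synthetic data

Images: elliptical nuclei (semi-axes 26–40 px) containing 6–10
non-overlapping chromocenter discs (radius 2.5–4 px, ≥ 3 px apart) on a
flat background, i.i.d. Gaussian noise clipped to the 8-bit range.
Default levels — background 10, nucleus 90, chromocenters +80 — emulate
deliberately underexposed DAPI captures (foreground at 30–50% of the gray
scale). Ground-truth masks are the exact rasterizations. Not emulated:
intra-nuclear texture, nucleoli, uneven illumination, touching nuclei,
out-of-focus blur. Passing segmentation tests therefore demonstrate
correctness of the thresholding logic, not robustness to real microscopy
artifacts.

Genotypes: a selfed biparental RIL population on an arbitrary cM map.
Along each chromosome the homozygous genotype is a two-state Markov chain:
first marker A/B with probability ½, switch probability between markers
d cM apart equal to the selfed-RIL (Haldane–Waddington) recombination
fraction R = 2r/(1+2r) with Haldane r = (1−e^(−2d/100))/2. This reproduces
the stationary behaviour of repeated selfing without simulating meioses.
No segregation distortion, residual heterozygosity, dominance or epistasis.

Traits: line value = Σᵢ aᵢxᵢ + N(0, σ²_line) with xᵢ = ±1 at the marker
nearest each planted QTL; per-nucleus value = line value + N(0, σ²_nucleus).
The generator returns the planted broad-sense heritability
(Σaᵢ² + σ²_line)/(Σaᵢ² + σ²_line + σ²_nucleus), using Var(x) = 1 at allele
frequency ½. Default population sizes mirror the experimental design the
pipeline targets: 46 lines, ≥ 26 nuclei from ≥ 2 plants per line.

## Population statistics

* **Outlier removal** — two published variants, both single-pass:
  `percentile95` keeps the central 95% empirical interval (used before QTL
  mapping); `sd2` keeps values within mean ± 2·SD (used for distribution
  summaries). SD is computed once; the rules are not iterated.
* **Heritability** — one-way ANOVA method-of-moments: σ²_within = MSW,
  σ²_between = max(0, (MSB − MSW)/n₀) with the unbalanced-design correction
  n₀ = (N − Σnᵢ²/N)/(k−1); H² = σ²_b/(σ²_b + σ²_w). In a one-way layout this
  coincides with the type-3 ANOVA decomposition. The estimator's sampling
  SD at 50 lines × 30 nuclei and H² = 0.3 is ≈ 0.05, so recovery tests pool
  over a 20-seed envelope (mean error ≤ 0.1) rather than asserting every
  seed individually.
* **Correlations** — pairwise Pearson r over per-line means (parental lines
  and F1 can be appended as single averaged rows); two-sided p; star levels
  at 0.05/0.01/0.001/0.0001; no multiple-testing correction (raw star
  levels are reported). Constant traits yield NaN edges, reported but never
  significant. GraphML export via networkx.
* **Transgression ratio** — 100·min/max over per-line means; requires
  strictly positive means.
* **Two-group tests** — Welch t (Satterthwaite df); 2×2 Pearson χ² on
  above/below a size cutoff without continuity correction (flag to enable);
  Shapiro–Wilk as the normality check (the choice of normality test is a
  convention here, not a derived requirement). A compact-letter display
  over pairwise Welch tests is provided as a reporting utility.

## QTL mapping

Composite interval mapping by Haley–Knott regression on a 1 cM grid:

1. **Genotype probabilities.** P(A) at each grid position conditional on the
   nearest non-missing flanking markers, treating the genotype as the Markov
   chain above (two-segment ratio for interior positions, single-flank
   transition beyond terminal markers; probability ½ with a warning on a
   chromosome with no data). At observed markers the probability is the
   indicator. Scores are 2·P(A) − 1.
2. **Cofactors.** Forward/backward stepwise OLS on the (imputed) marker
   scores: add the smallest partial-F p-value while p < p_in (0.05), then
   drop included markers with p > p_out (0.05); capped at ⌊√n⌋ cofactors to
   guard rank deficiency at small n. Deterministic tie-breaks (smaller p,
   then lower marker index); collinear candidates are skipped. Note that
   with ~100 correlated markers this procedure picks up a few spurious
   cofactors on pure noise (median ≈ 3 at n = 100) — inherent to stepwise
   entry at p = 0.05, and accounted for by the permutation threshold, which
   re-runs selection inside each permutation.
3. **Scan.** At each position, cofactors within 10 cM on the same
   chromosome are deactivated; the phenotype (line means) is regressed on
   the active cofactors plus the genotype score.
   LOD = (n/2)·log₁₀(RSS_reduced/RSS_full); ADD is the score coefficient
   (A-allele effect vs the population mean; class means differ by 2·ADD);
   R² = 100·(RSS_reduced − RSS_full)/TSS, with TSS of the line means as the
   default denominator (`r2_denominator="reduced"` switches to the local
   residual variance). Positions with < 3 residual df are skipped with a
   warning; a constant phenotype yields an all-zero profile.
4. **Threshold.** Genome-wide maximum LOD over phenotype permutations
   (1000 by default, 95th empirical percentile at α = 0.05; linear-
   interpolated quantile). Cofactors are re-selected within each
   permutation — the statistically valid null; reusing the observed
   cofactors is available as a documented fast approximation. Fewer than 20
   permutations is an error.
5. **Calls.** Maximal runs of contiguous grid positions with LOD ≥
   threshold; start/end are the run borders, top the leftmost LOD maximum;
   LOD/ADD/R² are reported at the top. Runs never span chromosomes.
   Colocation of two calls = same chromosome and intersecting closed
   intervals.

Haley–Knott regression was chosen over EM maximum likelihood: for
homozygous RIL data at moderate effect sizes the LOD difference is
negligible, and the regression form is testable in closed form (with zero
cofactors the scan reduces exactly to single-marker regression at marker
positions, verified to 10⁻⁸). Haldane's map function and the 1 cM walking
step are the conventional defaults for this mapping family.

## NIL confirmation

An introgression replaces the recurrent-parent allele (A) by the donor
allele (B), so a QTL with additive effect ADD (A-allele effect) predicts a
NIL-vs-background shift of −sign(ADD): the expected direction is *down*
for ADD > 0 and *up* for ADD < 0. Effects are Welch-tested; p < 0.01 is a
strong call, 0.01 ≤ p < 0.05 weak, otherwise ns. Any significance level in
the expected direction confirms.

Border refinement: QTL interval ∩ union of confirming introgressions,
minus the introgressions of covering NILs that showed no effect. The
subtraction uses only *covering* ns NILs, so refinement can only narrow the
interval; when the remainder is disconnected the individual segments are
kept alongside their overall hull. When several confirming NILs disagree on
borders, the union-then-subtract rule above is the documented convention.
A screen for significant NIL effects whose introgressions intersect no
called QTL for that trait flags loci the genome scan missed.

## Problem sizes used in the checks

The automated checks run at desk scale, chosen to exercise the estimators
at the population sizes the pipeline targets: 100 rendered fixtures of 4
nuclei (512×512, noise SD up to 5) for segmentation; 100 two-nucleus
fixtures for RHF; 46-line populations on a 5×100 cM map with 5 cM marker
spacing for mapping; 200-permutation thresholds; 500 null traits for the
type-I-error check; 100 seeds for detection power; 20 seeds for
heritability; 50 seeds for the NIL round trip.

## Known limitations

* 2D single-channel images only; no Z-stacks, no touching-nuclei splitting,
  no nucleolus handling.
* The heterogeneity polarity convention and the R² denominator in QTL
  reports are conventions with more than one defensible choice; both are
  explicit config options or documented above.
* Heritability is method-of-moments, not REML; adequate for the one-way
  design, not for unbalanced multi-factor designs.
* Stepwise cofactor selection is greedy; it is validated against an
  independent brute-force stepwise oracle, not against an exhaustive
  best-subset search.
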