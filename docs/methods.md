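# Methods

## Overview

`frogclock` builds and interrogates DNA-methylation age clocks for *Xenopus
tropicalis* targeted bisulfite sequencing (TBS) data. The pipeline consumes a
CpG beta-value matrix (sites × samples) with a parallel read-coverage matrix
and per-sample metadata (age, strain, housing tank, life stage), and runs:

1. coverage filtering,
2. removal of genotype-artifact CpGs (trimodal sites caused by segregating
   germline C→T variants),
3. elastic-net age-clock training and nested cross-validation,
4. per-site Spearman age association with FDR control,
5. chromatin-state enrichment of age-associated CpGs,
6. expression analysis of genes proximal to those CpGs, and
7. pairwise genetic divergence summaries from a genotype-call matrix.

A first-class synthetic-data generator (`frogclock.synthdata`) produces
cohorts with known ground truth for every one of these stages, and the test
suite and `scripts/acceptance.py` score the pipeline against those planted
effects.

## Artifact-site model and filter

A CpG overlapping a segregating C→T variant shows apparent methylation near
1.0 in CC homozygotes, near 0.5 in CT heterozygotes, and essentially 0 in TT
homozygotes (no methylatable cytosine remains). The filter fits univariate
Gaussian mixtures with 1 and 3 components to each site's beta values and
flags a site when

- `BIC(1) − BIC(3) > 90` (default threshold, exposed as a flag), and
- at least one sample has a vanishingly small value (`< 0.006`), the TT
  fingerprint. Trimodality alone is not enough: a site clustered at, say,
  {0.2, 0.5, 0.9} is left alone.

BIC uses the full free parameterisation, `p_k = 3k − 1` (k means, k
variances, k−1 weights), so `p_1 = 2`, `p_3 = 8`. EM uses D²-weighted
(k-means++-style) seeding with 5 restarts, tolerance 1e-4 on the total
log-likelihood change, a maximum of 200 iterations, and a variance floor of
1e-6. The implementation runs one EM vectorised across all sites
simultaneously with converged sites dropping out of the batch; this is what
makes screening a whole matrix take seconds rather than tens of minutes.
Constant-valued sites cannot be trimodal and are never flagged.

## Elastic-net clocks and cross-validation

The clock is `ŷ = Xw + b` minimising
`(1/2n)‖y − Xw − b‖² + α(ρ‖w‖₁ + (1−ρ)/2‖w‖₂²)` with ρ = 0.5. Features are
not standardised: beta values already live on a common [0, 1] scale (a flag
can re-enable scaling through the underlying solver if desired). α is tuned
on a 100-point log-spaced grid from α_max (the smallest penalty that zeroes
every coefficient, computed from the centred data) down by a factor of 1e-4.

Because every tank houses frogs of a single age and strain, tank, age and
strain are confounded. Three nested-CV schemes quantify this:

- **LOO**: leave-one-sample-out outer folds; inner 5-fold CV (seeded,
  recorded) tunes α per outer fold.
- **LOTO**: leave-one-tank-out outer folds; inner tuning is itself
  leave-one-tank-out on the training tanks. When a training split contains a
  single tank, the inner scheme falls back to a seeded random 2-fold split
  (logged).
- **Shuffled LOTO**: tank labels are permuted uniformly across samples
  (preserving the multiset of tank sizes) and the full LOTO procedure is
  rerun; 5 repeats by default. If shuffled LOTO performs like LOO, the
  LOO–LOTO gap is attributable to tank structure rather than to training-set
  size.

Log-age clocks regress `ln(age)` and back-transform predictions with `exp`
before computing metrics, so MedAE (median absolute error) and Pearson r are
always reported on the year scale. The final model tunes α by LOTO over the
full cohort, refits on all samples, and serialises to JSON (sites,
coefficients, intercept, α, ρ, age transform). Prediction on an external
matrix requires intersecting site universes first (`io_formats.
intersect_sites`) and errors on missing model sites; predictions are never
clipped.

## Age association and selection

Per-site Spearman correlation with age is computed on mid-ranks (average
ties) over adult samples only — tadpoles are globally shifted at many CpGs
and are excluded from selection, though they remain in clock training. The
two-sided p-value uses the t approximation `t = r·sqrt((n−2)/(1−r²))` with
n−2 df (|r| = 1 ⇒ p = 0); an exact-permutation option exists for tiny n.
Constant sites report r = 0, p = 1 with a flag. P-values are BH-adjusted and
sites with adjusted p < 0.001 are classed positive or negative by the sign
of r.

## Chromatin-state enrichment

Each CpG is assigned to the chromatin state whose half-open interval
contains it (sites outside every interval go to a sentinel "unannotated"
state). Per state, enrichment is
`log2((n_sel_in/n_sel) / (n_bg_in/n_bg))`, flagged undefined when any count
in the ratio is zero. Significance is a two-sided Fisher exact test on
{selected, background∖selected} × {in state, not in state}; the two-sided
p is the hypergeometric probability mass of all tables (at the observed
margins) no more probable than the observed one, computed directly from the
pmf over the support — this keeps screening many states over large
backgrounds cheap and is verified exhaustively against combinatorial
enumeration in the tests. BH runs across states within each direction
(joint correction available via a flag). The recommended background is all
sites passing a lower coverage bound (10×) after artifact filtering,
including the selected sites.

## Proximal-gene expression

Significant CpGs map to the nearest gene TSS on the same chromosome within
5 kb (signed distance positive downstream of the TSS in gene orientation;
exact ties resolve deterministically to the gene earliest in (chrom,
tss_pos, gene_id) order). Gene ids translate through a two-column orthology
map into the expression atlas's namespace, deduplicating and logging drops.
Per tissue, the gene set's per-gene mean log1pCP10k values are compared
against all genes with a two-sided Wilcoxon rank-sum test — exact
enumeration when both groups have ≤ 12 untied values, normal approximation
with tie correction otherwise — plus `log2(mean_set/mean_all)`. The
background includes the set genes by default (a flag excludes them), which
is also why large-sample comparisons always take the tie-corrected
asymptotic path.

## Genotype divergence

Divergence between two samples is 100 × (discordant genotype calls) /
(callable sites), skipping sites with a missing call in either sample while
keeping the global callable-site denominator. Tank-level summaries average
cross-tank pairs; the diagonal averages distinct within-tank pairs and is 0
(flagged by construction) for single-frog tanks. Any genotype mismatch
counts as one difference; no allele-dosage weighting.

## Synthetic cohorts

`SynthConfig` defaults emulate the study design: 34 tanks of 6 frogs, ages
uniform on 0.25–10.9 years, one age and strain per tank.

- **Trend sites** follow `μ_ij = logistic(β0_j + β1_j·age_i + u_{t(i),j})`
  with per-site slopes |β1| ~ U(0.5, 1.5) × `slope_scale` (default 0.2
  logit-units/year), baselines centred so mid-cohort methylation is
  moderate, and per-(tank, site) effects `u` ~ N(0, `tank_sd`). Measurement
  noise is Beta(μφ, (1−μ)φ) with concentration φ = 50; a beta law is the
  natural bounded, overdispersed choice and φ is a free parameter of the
  config since real per-site variance structure varies.
- **Artifact sites** draw per-(strain, site) T-allele frequencies around
  `t_allele_freq` (default 0.5, SD 0.15, clipped to [0.05, 0.95]),
  Hardy-Weinberg genotypes per sample, and emit values at modes 0.95 (CC)
  and 0.5 (CT) with SD 0.01; TT values are |N(0.0005, 0.001)| capped below
  0.006 so the TT fingerprint is always below the filter's cutoff — a wider
  TT jitter would contradict the biology the mode represents (no cytosine
  to methylate).
- **Coverage** is negative-binomial (mean 300, dispersion 5) floored at
  100×, matching a matrix that has already passed the coverage filter.
- **Context fixtures**: each site gets its own segmentation interval
  (intervals tile each chromosome), with a planted design that puts 50% of
  positive-class sites into a designated state while adjusting the
  remaining sites so the overall background fraction is exactly 10% — the
  planted log2 enrichment is therefore log2(0.5/0.1) ≈ 2.32 up to rounding.
  Every positive-class site gets a gene TSS within 5 kb whose expression is
  scaled by 0.5 in all tissues; background genes sit far from all sites.
  The homolog map is a bijection into the expression namespace.
- **RNG discipline**: one child stream per output object (cohort, site
  parameters, methylation, genotypes, context), all derived from the master
  seed, so changing the number of sites never perturbs the cohort, and a
  fixed seed reproduces every output byte-identically.

What the generator does **not** emulate: read-level bisulfite conversion
error, chromosome-scale autocorrelation of methylation, nonlinear age
trajectories (logit-linear only), age-dependent variance, or relatedness
structure beyond strain labels. Passing tests therefore demonstrate that the
implementation recovers the effects it assumes, not that those assumptions
describe any particular real colony.

## Benchmark problem sizes

The test suite and acceptance script use these cohort scales, chosen once as
the package's standard benchmark conditions:

- artifact-filter recovery: 192 frogs (32 tanks × 6), 1000 sites, 10%
  artifacts, 5 seeds;
- clock recovery (no tank effects): 192 frogs, 2000 sites, 20% trend sites,
  φ = 50;
- tank-confounding ordering: 60 frogs (10 tanks × 6), 400 sites, tank_sd =
  0.5 — tank shifts comparable to ~2.5 years of aging signal, a strongly
  confounded regime; 5 master seeds;
- enrichment recovery: 96 frogs, 3000 sites planted / 30000 sites null (the
  null bound |log2| ≤ 0.2 needs several thousand selected sites for the
  binomial noise of state assignment to sit inside the band);
- type-I calibration: 100 frogs (20 tanks × 5), 2000 null sites.

## Numerical choices and edge cases

- Elastic-net solves use coordinate descent (scikit-learn) at tolerance
  1e-4, max 1000 iterations; convergence warnings at the smallest grid
  alphas are suppressed as they do not affect the selected α.
- Invariance of fitted coefficients to site order holds to solver
  tolerance; the tests verify it at tightened tolerance.
- Beta values are clipped to [1e-6, 1 − 1e-6] at generation; readers reject
  (rather than clip) out-of-range input.
- All interval and position arithmetic is 0-based half-open; a boundary
  position belongs to the interval starting at it. Matrix TSV positions are
  read as 0-based (`--one-based` converts on load).
- Median uses the standard mean-of-central-order-statistics convention for
  even n.
- BH adjustment validates p ∈ [0, 1] and is exactly the step-up procedure.

## Known limitations

- The ΔBIC threshold (90) was hand-chosen upstream of this package; its
  operating characteristics outside the 192-sample scale are not
  characterised here, though the threshold is exposed everywhere.
- Exact replication of a specific clock's coefficient list depends on the
  α grid and inner-fold seeds used originally; only the procedure, not any
  unrecorded seed, is reproducible.
- LOTO inner tuning degenerates with very few tanks (2-fold fallback);
  interpret α stability accordingly.
- The Wilcoxon comparison operates on per-gene tissue means, not cell-level
  values.
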