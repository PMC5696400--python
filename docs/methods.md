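# Methods

This note documents the statistical procedures hybzone implements, the
choices made where the methods literature leaves the design open, what the
synthetic-data generator does and does not emulate, and the numerical
conventions that matter for reproducing results.

## Hybrid index

**Model.** An individual's allele copies are treated as independent draws
from the mixture h·p_A + (1−h)·p_B of the two parental allele-frequency
distributions, with h the proportion of ancestry from species A (h = 1
pure A).  This ignores the pairing of copies into genotypes, which is the
standard simplification for this estimator: it is exact for pure parents
and F1-pool gametes, and a close approximation for later-generation
hybrids.  Missing loci are simply skipped (the likelihood is a sum over
typed copies).

**Reference frequencies.** p_A and p_B are estimated from pooled allopatric
samples with add-α smoothing, p = (count + α)/(copies + α·K), over the
union allele set of both references, optionally extended by alleles seen in
the individuals to be scored (K is the universe size).  Default α = 0.5
(Jeffreys-like).  Without smoothing, a private allele in the query forces
ĥ to a boundary with infinite confidence; with it, every observed allele
has positive probability in both species.  α = 0 reproduces raw
proportions and is available for exact closed-form work.  An allele never
seen during fitting receives the pseudo-count probability α/(copies + α·(K+1))
on the fly; with α = 0 this is an error rather than a silent zero.

**Optimization.** ℓ(h) is evaluated on a grid of step 1e−3 and the maximum
refined by bounded scalar minimization to tolerance 1e−6.  The grid bounds
the refinement bracket, and both boundary values are checked explicitly so
that monotone likelihoods return exactly h = 0 or 1.  Mixture
probabilities are floored at 1e−300 inside the optimizer so that boundary
evaluations with unsmoothed diagnostic frequencies stay finite.

**Confidence interval.** The 95% CI is the profile-likelihood region
{h : ℓ(h) ≥ ℓ(ĥ) − 1.92}, the χ²₁ half-deviance; endpoints are located by
bisection (Brent) to 1e−6 and clamped to [0, 1].  Clamping is what makes
the classification phrase "the CI extends to 0 or 1" meaningful.  A
consequence worth stating: when the true ancestry is exactly 0 or 1, the
clamped interval covers the truth with probability near 1 (the likelihood
is almost surely monotone there), so coverage calibration should be read
pooled across interior and boundary ancestries, or on interior ancestries
alone; both are asserted in the test suite.

**Classification.** Two rules, as used in contact-zone practice: the F1
boundary rule flags ĥ ∈ [0.25, 0.75] (bounds inclusive; the interval is
calibrated by laboratory-bred F1s, and knowingly admits some backcross
progeny — no disambiguation is attempted); the CI rule flags individuals
whose interval excludes both 0 and 1 as hybrids of undetermined class.
The advanced-generation proportion is the difference of the two per-region
proportions, clipped at 0 with a warning if the rules disagree in the
aggregate.  A locus-exclusion option (`drop_loci` / `exclude_loci`)
supports sensitivity analyses such as removing markers with high
null-allele frequencies; no null-allele estimator is provided.

## Randomization test for hybrid-proportion differences

The statistic is the difference in the proportion of flagged hybrids
between two regions.  Individuals are reassigned between the pair without
replacement; the count landing in group 1 is then hypergeometric, and the
null is sampled directly from that law (distributionally identical to
permuting the pooled indicator vector, and much faster).  The p-value is
(1 + #{null meeting the criterion})/(n_reps + 1) — the add-one convention
guarantees p > 0 — with criterion |null| ≥ |observed| (two-sided, default)
or null ≥ observed (one-sided; both modes are first-class because the
sidedness used in prior reports of such tests is often unstated).

Because the null is discrete and the criterion includes ties, the test is
slightly conservative: at two groups of 100 with hybrid probability 0.2
its exact type-I rate at α = 0.05 is 0.0329 (obtainable by total
enumeration).  This is deliberate — the tie-inclusive rule is what makes
the degenerate no-hybrids comparison return p = 1 — and the direction of
the error is safe.  Mid-p variants were considered and rejected for that
reason.

**Multiple testing.** Sequential Bonferroni (Holm): the i-th smallest
p-value is significant iff p_(i) ≤ α/(m−i+1) and all smaller ones were.
Implemented directly (with ≤ at the boundary) and cross-checked against
statsmodels in the tests.  Censored table entries like "<.00001" are
parsed as 1e−6 with a censored flag, which preserves their rank for the
step-down.

## Maternal asymmetry

Maternal-species labels of F1 hybrids (an input; in practice derived from
maternally inherited mitochondrial sequence) are tallied per region and
pooled, unknowns excluded with a logged count.  The test is the exact
two-sided binomial at null proportion ½ by tail doubling,
p = min(1, 2·min(P(X ≤ k_min), P(X ≥ k_max))); at p₀ = ½ every common
two-sided convention coincides, which is why printed values from such
tables are exactly reproducible.  The n > 15 threshold is a reporting
flag, not a computational gate — all regions are computed.

## Population structure

* **Diversity.** Unbiased expected heterozygosity
  H_exp = (2n/(2n−1))(1 − Σp²) per locality × locus; Nei's
  G_is = 1 − H_obs/H_exp, pooled over loci by summing both heterozygosities.
  The permutation test shuffles allele copies among individuals within the
  locality (H_exp is invariant), one-sided for heterozygote deficit with
  mid-p tie handling.  One-sided was chosen because a two-sided |G_is|
  criterion is tie-bound at small n and produces p-values stacked at 1,
  and because heterozygote deficit (null alleles, Wahlund effect) is the
  alternative of interest; mid-p keeps the null distribution close to
  uniform, which the tests verify by KS.
* **Fst.** Pairwise multi-allelic Weir–Cockerham θ, ratio of sums of the
  a / (a+b+c) variance components over alleles and loci; negative
  estimates are kept (they are informative about sampling noise).  θ is
  the estimator the field's standard software computes, as distinct from
  Wright's island-model parameter.
* **Rst.** Slatkin's allele-size statistic: per locus, S̄ is the mean
  squared size difference over all copy pairs in the pooled pair of
  localities and S_w over within-locality pairs; Rst = Σ(S̄−S_w)/ΣS̄.
  Allele identifiers are integer representative fragment sizes (bin
  midpoints), which is what makes this statistic computable downstream of
  fragment binning.
* **PCoA.** Gower double-centering −½·J·D²·J, symmetric eigendecomposition,
  axes ordered by descending eigenvalue, coordinates scaled by √λ.
  Percent variance is relative to the sum of positive eigenvalues;
  negative eigenvalues (non-Euclidean input) are excluded from the
  denominator, matching common spreadsheet-tool behaviour.
* **Geographic distance.** Haversine with mean Earth radius 6371.0088 km
  for GPS coordinates; planar Euclidean for synthetic planar layouts,
  selected by the metadata's coordinate-system flag.  The two cannot be
  mixed in one matrix.
* **Mantel.** Pearson correlation of the off-diagonal upper triangles;
  the null jointly permutes rows and columns of the second matrix;
  one-tailed for positive association, add-one p.  Raw Fst is the default
  response; Fst/(1−Fst) linearization is a flag.
* **IBD residual randomization.** OLS of pairwise Fst on geographic
  distance; the statistic is the mean residual over pairs involving at
  least one sympatric locality minus the mean over allopatric–allopatric
  pairs.  The null permutes the sympatric/allopatric labels across
  localities (the regression, and hence the residuals, are fixed; only the
  pair classes change); one-tailed add-one p.  The default 200
  randomizations give p-granularity 1/201, adequate for a yes/no verdict
  but coarse near conventional thresholds; the CLI recommends ≥ 9,999.
  Hybrids (union of both classification flags) are removed from all
  localities before the per-species IBD fits.

## Acoustics and character displacement

Calls are corrected to 14 °C by subtracting b·(T−14) with b the
per-population OLS slope of the variable on temperature (populations with
fewer than 3 recordings, or no temperature spread, fall back to the pooled
within-species slope).  Subtracting the fitted temperature effect is the
only correction consistent with a linear model, and it makes re-correction
the identity (OLS residuals are orthogonal to the regressor).

Hybrid index is regressed on the natural log of each corrected call
variable (log because call characters are ratio-scale and
right-skewed; h itself is not transformed).  Model choice among {PR},
{PN}, {PR+PN} is by AIC and BIC over the same observations; variables
collinear to machine precision are flagged and the joint model skipped.

Regional displacement is D_RCD = √[(ΔPR̄)² + (ΔPN̄)²], the Euclidean
distance between a sympatric region's corrected means and the pooled
allopatric baseline of the same species, by default on raw corrected means
(the two characters have different units; a z-standardized option exists
and should be preferred when the characters' scales differ grossly).
Regressions of regional admixture (F1, CI, and CI−F1 metrics) on D_RCD
use every recorded male, not only genotyped ones, and refuse to run with
fewer than 3 regions; with the 6–10 regional replicates typical of a
contact zone they are intrinsically low-powered, and the test suite
documents the width of the null r² distribution at n = 8 rather than
pretending otherwise.

## Cluster-number choice (ΔK)

Given a table of replicate log-probabilities per K (produced by any
clustering program; generating such tables is out of scope), ΔK(K) =
|L̄(K+1) − 2L̄(K) + L̄(K−1)| / sd(L(K)), with the sample (n−1) SD,
undefined at the grid ends, and flagged infinite (with a warning) when the
replicate SD is zero.  The best K maximizes ΔK, ties toward smaller K.

## Synthetic contact zone

The generator emulates the data structure the pipeline assumes, at the
study scale the package targets:

* **Parental pools.** 12 loci, 6–32 alleles each (alternating tetra- and
  dinucleotide size ladders); per locus an ancestral frequency vector from
  a symmetric Dirichlet, then one Balding–Nichols Dirichlet draw per
  species with concentration ancestral·(1−F)/F.  F_div is a one-knob
  control of between-species Fst (default 0.4: strongly diverged species
  with many nearly private alleles, appropriate for species pairs separated
  for millions of years).  A `diagnostic` switch fixes the species on
  disjoint allele subsets for closed-form work.
* **Layout.** The default layout has 16 allopatric species-A localities
  pooling to 188 reference individuals, 7 species-B localities pooling to
  80, and ten sympatric focal regions along a contact line, each with
  co-located species-A and species-B samples and a region-specific hybrid
  mix (hybrid-rich, hybrid-poor, intermediate).  Coordinates are planar km.
* **Drift / IBD.** Locality frequencies accumulate Balding–Nichols
  stepping-stone steps along each species' range (chained by coordinate,
  step F = drift_scale × inter-locality distance, capped at 0.4), so
  divergence grows with separation and Mantel correlations are genuinely
  positive.  Independent per-locality drift with variance proportional to
  distance from an origin was considered and rejected: it makes pairwise
  divergence depend on the *sum* of the two localities' drift, which is
  uncorrelated with their separation, and therefore produces no isolation
  by distance.
* **Hybrid classes.** pure, F1, F2, and first-generation backcrosses, with
  gamete pools drawn per locus (backcross: one parental copy, one 50/50
  copy — so the realized ancestry fraction of a backcross has SD 1/(4√L),
  not the iid-Bernoulli value).  F1 maternal labels are species B with
  probability `maternal_asymmetry` (default 0.74); later generations are
  "unknown".
* **Calls.** value = intercept + slope·h + b_T·(T−14) + displacement·h
  (sympatric localities of the displaced species only) + Gaussian noise;
  temperatures are Normal(14, 3).  Defaults put pulse rate at 6–12 pulses/s
  and pulse number at 8–12 across the ancestry range with unit noise SD.
* **What it does not emulate.** Mutation, linkage, genealogical noise
  (no coalescent), genotyping artefacts (null alleles, dropout,
  stutter), uneven detectability of males, and measurement error in
  temperature.  Passing tests therefore demonstrate the correctness and
  calibration of the estimators under the stated generative model, not
  robustness to those real-data pathologies.

Every stochastic stage takes an explicit seed; `sim_zone` derives
independent per-stage streams (frequencies, drift, individuals, calls)
from one master seed, and the pipeline records all derived seeds in its
run log.

## Problem sizes used in validation

The test-suite and acceptance-script simulations use: 500 individuals
(100 per ancestry class) for CI-coverage calibration against references of
188 + 80; exhaustive enumeration of all randomization configurations with
n₁+n₂ ≤ 12 at 20,000 replicates each; 1,000 null pairs of 100+100 for the
type-I rate; 500 null zones of 10 localities (199 label permutations) and
100 planted-effect zones (999 permutations) for the IBD randomization; and
a reduced four-locality zone for the byte-level determinism check.  These
sizes keep the full validation run to a few minutes on one CPU while
leaving Monte-Carlo error well below the decision margins of each check.

## Known limitations

* The mixture likelihood treats allele copies as independent given h, so
  CIs are mildly anti-conservative for genotype-structured hybrids
  (e.g. F1s, whose copies are perfectly anticorrelated by origin).
* The F1 boundary rule cannot distinguish F1s from F2s or some backcrosses
  at 12 loci; class posteriors are explicitly out of scope.
* Reported pairwise-test p-values are Monte-Carlo (add-one) estimates;
  with the default 100,000 replicates their SE at p ≈ 0.05 is ≈ 0.0007.
* The IBD randomization conditions on the fitted regression; uncertainty
  in the slope itself is not propagated (matching the procedure it
  implements).
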