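# Methods

## Data model

A dataset is a fixed 38-item symptom catalog plus one record per patient:
age in years, a binary occurrence indicator per item (missing allowed),
and conditional ordinal ratings — severity on 1–4 and distress on 0–4 —
defined only where the symptom occurred. A defined rating next to an
absent or missing occurrence is treated as a data error, not as data. The
sample is dichotomized at an age cutoff (default 60 years, the WHO
convention for the older population); the cutoff is inclusive on the older
side and ages may be non-integer.

Missing occurrence responses are retained and handled pairwise downstream;
descriptive tests use per-analysis complete cases. Both choices matter
little for near-complete data (the motivating sample had occurrence
ratings for 1329 of 1343 patients) but are stated here because they are
choices.

## Descriptive layer

Occurrence is compared per item with Fisher's exact test (two-sided,
conditional on both margins); conditional severity/distress with the
Mann–Whitney U test using midranks, tie-corrected variance and continuity
correction — exact enumeration is used only as a test oracle at small n,
since the target use has hundreds of observations per group; continuous
covariates with a two-sample t (Welch by default; a pooled option exists
because either variant is defensible). Significance is an unadjusted
two-sided p < 0.05 by convention of the motivating analysis; a Bonferroni
option is exposed but off by default, so the per-item significance count
must be read as unadjusted. Rankings are "top k with ties" under dense
ranking: tied items share a rank and all ties at an included rank are
listed, so a top-10 list can exceed 10 entries.

## Latent threshold model and tetrachoric correlations

Binary occurrence items are modelled as dichotomizations of standard
normal latents: item i is present when its latent y_i exceeds a threshold
τ_i, so the marginal occurrence probability is 1 − Φ(τ_i), and the
association between two items is the correlation ρ of their latents — the
tetrachoric correlation.

Estimation is two-step maximum likelihood, the standard large-sample
practice: thresholds are fixed from the margins by normal quantiles, then
ρ maximizes the multinomial log-likelihood of the four cells, solved by a
bounded scalar search on (−0.999, 0.999) to |Δρ| < 1e-6. Bivariate-normal
rectangle probabilities use Owen's T function (closed form up to a 1-d
smooth integral scipy evaluates to near machine precision; verified
against scipy's bivariate normal CDF at < 1e-15). If a 2×2 table has a
zero cell, 0.5 is added to all four cells and the pair is logged; a zero
*margin* (an item always or never present in the pairwise-complete data)
leaves the pair undefined and is reported as an error rather than papered
over.

Pairwise estimation does not guarantee a positive semidefinite matrix.
When the smallest eigenvalue falls below −1e-8 the matrix is repaired by
eigenvalue clipping at 1e-8, reassembly, and rescaling to unit diagonal —
chosen over alternating projections for simplicity at this scale — and the
repair (flag, minimum eigenvalue before, Frobenius change) is recorded in
the estimate's metadata, since smoothing ahead of factoring is an
analysis-relevant event.

## Factor extraction and rotation

Unweighted least squares extraction minimizes the sum of squared
off-diagonal residuals of R − ΛΛ′, implemented as iterated principal-axis
factoring: communalities seeded from squared multiple correlations, the
reduced matrix eigendecomposed, the top-k factors kept, communalities
updated, repeated until the largest communality change is below 1e-6
(cap 10,000 iterations: each iteration is one 38×38 eigendecomposition,
and weakly separated trailing factors converge slowly — the older-group
population matrix needs several thousand). Communalities reaching 1 are
capped and flagged as Heywood cases. The ULS objective is non-increasing
across iterations and is asserted so in the tests.

Geomin rotation minimizes Q(Λ) = Σ_i (Π_j (λ²_ij + ε))^{1/k} over oblique
rotations by the gradient projection algorithm, with ε = 0.01 (the common
default for item sets of this size; configurable). Geomin is multi-modal,
so rotation restarts from 30 random orthonormal matrices (seed-controlled)
plus the identity; the best criterion is kept and the number of starts
agreeing within 1e-5 is reported rather than hidden. Column signs are
fixed so each factor's largest-|loading| entry is positive, and columns
are ordered by descending sum of squared loadings for determinism. Rotated
oblique loadings are regression coefficients, not correlations: values
above 1 are legitimate and are not truncated (the reference younger table
prints 1.049 for difficulty breathing).

Solutions are fitted for 2–8 factors and a diagnostics table (residual
RMSR, adequately defined factors, unassigned items, Heywood count,
rotation-start agreement) is emitted. The factor count itself is a
judgement call about interpretability that cannot be automated from fit
alone; the package pins k = 8 by default — the count selected for both
groups in the motivating analysis — and keeps the human step explicit
through the diagnostics.

## Cluster rules, stability, consistency

A cluster is a factor with at least two symptoms at |λ| ≥ 0.40; the
threshold is inclusive and applied to absolute loadings (no negative
meaningful loadings appear in the reference tables, so absolute-value
thresholding is the conservative generalization). Cross-loading is
permitted: a symptom meeting the threshold on several factors joins each.
Members are ordered by |λ| descending with ties broken by catalog order
and flagged, because member order feeds the consistency rule.

Clusters from two groups are matched one-to-one by maximizing total shared
membership (exhaustive assignment up to 6×6, Hungarian algorithm beyond;
ties break toward larger summed |λ| of shared symptoms). *Stability* is
operationalized as a matched pair sharing ≥ 2 at-threshold symptoms — two
being the minimum cluster-defining size; the motivating analysis asserts
stability narratively without a formal rule, so this operationalization is
the package's own and is stated in every report. *Consistency* follows the
published rule: with k = 2 when the larger cluster of the pair has ≤ 3
symptoms and k = 3 otherwise, the pair is consistent when the top-k
highest-loading symptoms coincide in both groups' top-k sets. Ties at the
k-th loading expand the top set and flag the verdict. This reading — both
top-k sets, not mere membership of the counterpart cluster — reproduces
all eight published verdicts (2/3, 3/3, 3/3, 2/2, 1/2, 2/2, 0/2, 3/3);
the membership-only alternative does not (it would pass the fatigue
cluster that the published table scores 2/3).

## Synthetic-data generator

The generator draws factor scores f ~ N(0, Φ), item latents
y = Λf + e with residual variances 1 − Λ_iΦΛ_i′ (so every latent is
standard normal), and occurrence y_i > τ_i. The calibrated per-group
defaults place each reference-cluster symptom on its cluster at the
printed loading — clipped into [−0.95, 0.95] so residual variances stay
nonnegative — zeros elsewhere, thresholds that reproduce the printed
occurrence rates exactly (τ_i = Φ⁻¹(1 − p_i)), Φ = 0.2 off the diagonal so
the oblique code path is exercised, and group sizes 741/602. Ages are
uniform on [30, 59.9] and [60, 85]; only group membership matters
downstream. Severity and distress are cut from the latent exceedance
y_i − τ_i at fixed cutpoints (half-normal quartiles for severity,
quintiles for distress) — a deliberately simple single-latent stand-in,
since no dependence structure for the conditional ratings is published
and the factoring uses occurrence only.

What the generator does **not** emulate: the strong general positive
manifold of real symptom data (a uniform Φ = 0.2 understates it, which is
why simulated symptom-count SDs of ~4 undershoot the observed ~7),
unmodelled minor factors and doublets, item-level missingness, and any
severity/distress dependence beyond the shared latent. Passing recovery
tests therefore show that the estimation chain is correct under its own
assumptions — not that eight factors would be recoverable from any real
sample of this size.

## Problem sizes and what the experiments show

The test suite and acceptance script use: n = 50,000 for marginal
calibration (tolerance 0.006 ≈ 3 binomial SEs), n = 10,000–20,000 for
pairwise calibration, n = 5,000 for full-structure recovery, n = 600 per
group for the study-scale recovery experiment, and 200 replicates for null
calibration of the Fisher battery.

Recovery at the study's own per-group scale (n = 600) deserves a caveat
stated plainly: the tetrachoric matrix then carries element noise of
RMSE ≈ 0.07, enough that the weak three-item clusters (loadings ≈ 0.5 on
low-occurrence symptoms) cannot be pinned to Tucker congruence ≥ 0.95 —
in some replicates the eighth extracted factor is captured by noise
entirely. The same pipeline reaches congruence ≥ 0.998 on the exact
population matrix and ≥ 0.95 on every factor at n = 5,000, which
localizes the shortfall in the data, not the estimator. The acceptance
script reports the n = 600 experiment honestly (typically 0 of 20
replicates clear 0.95 on all eight factors; median worst-factor
congruence ≈ 0.7) rather than at a size chosen to flatter it.

## Determinism and numerical conventions

Every stochastic step takes an explicit seed (generator, rotation
restarts); there are no wall-clock defaults, and rerunning a pipeline
configuration reproduces artifacts byte for byte. Numeric artifacts are
written at full precision; 3-decimal loadings and 1-decimal percentages
are display conventions applied in rendered tables only. Degenerate
inputs fail loudly with the offending item, pair or stage named.

## Known limitations

- Stability's "≥ 2 shared symptoms" operationalization is this package's
  formalization of a narrative criterion; alternative rules (e.g.
  congruence-based matching) would be defensible.
- The Mann–Whitney normal approximation is weakest for tiny groups
  (n ≤ 10), where the exact enumeration used as a test oracle would be the
  better tool.
- Polychoric correlations for severity/distress dimensions, confirmatory
  models, robust WLSMV-type estimators, and automated factor retention
  (parallel analysis, scree) are out of scope.
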