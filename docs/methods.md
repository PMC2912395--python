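# Methods

This note documents the statistical models implemented in `methclass`,
the choices made where the methodology was genuinely open, what the
synthetic-data generator does and does not emulate, and the known limits
of both.

## Data model

The unit of data is the *average beta value*: a per-sample, per-CpG
methylation fraction in [0, 1], assembled from paired fluorescence
channels as `β = max(Cy5, 0) / (|Cy3| + |Cy5| + 100)` (Cy5 methylated,
Cy3 unmethylated; the +100 offset stabilizes low-intensity cells and
keeps β strictly below 1). Betas are analyzed raw — no normalization step
exists anywhere in the pipeline. Missing betas are propagated, never
imputed, except where a stage explicitly opts in (clustering).

QC applies three filters in a fixed order: (1) a sample passes when
strictly more than 75% of its loci have detection p < 1e-5; (2) loci
whose median detection p exceeds 0.05 are dropped (median of an even
count is the midpoint of the two central values); (3) all chromosome-X
loci are dropped. A locus failing both locus rules is attributed to the
detection rule, so the report's counts partition the input exactly.

## Locus-by-locus scanning

Each CpG is regressed on a covariate of interest (optionally adjusted,
dummy-coding categoricals) under a quasi-binomial model: mean
μ = logistic(Xb), variance φ·μ(1−μ). The fit is iteratively reweighted
least squares; the scale φ is the Pearson chi-square divided by n−p, and
the covariate coefficient is tested against a t distribution with n−p
degrees of freedom — the quasi-likelihood convention, adopted because no
reference distribution is canonical for this model. Fits are
complete-case per locus. Betas of exactly 0 or 1 are admitted (the
working weights are clipped, not the data). Separation or non-convergence
yields a *flagged* fit (missing statistics) rather than an exception; a
saturated fit (zero residual dispersion) keeps its exact coefficient with
missing inference.

Multiplicity: q-values. π0, the fraction of true nulls, is estimated on
the grid λ = 0.05, 0.10, …, 0.95 via π0(λ) = #{p > λ}/(m(1−λ)), smoothed
by a cubic least-squares fit evaluated at λ = 1 and clamped to (0, 1];
then q_i = min over {j : p_j ≥ p_i} of π0·m·p_j/rank_j, which makes q
monotone in p. Fixing π0 = 1 reproduces Benjamini–Hochberg exactly (this
is a tested identity). The smoother is the default; a fixed-π0 mode is a
config option.

The *sign trend* summary counts negative/positive/zero coefficients over
non-flagged fits and runs a two-sided binomial test of sign symmetry. It
exists because weak array-wide exposure effects (a small shift at every
locus) can be decisive in aggregate while almost no individual locus
passes an FDR threshold.

## Recursively partitioned mixture model (RPMM)

Samples are clustered by recursive binary splitting. At each node a
two-component mixture of independent per-locus Beta distributions is fit
by fuzzy EM:

- E-step: responsibilities ∝ mixing weight × ∏_j Beta(x_ij; a_cj, b_cj),
  computed in log space;
- M-step: mixing weight from weighted responsibilities; per-locus shape
  pairs by weighted maximum likelihood — Newton iteration on the digamma
  score system, initialized at method-of-moments, vectorized across loci.

The weighted observed-data log-likelihood is checked to be non-decreasing
every iteration (slack 1e-6 relative); a violation raises, as it can only
indicate an implementation defect. Convergence is declared when the
largest responsibility change falls below `tol` (default 1e-6).

A split is accepted iff BIC(two components) < BIC(one component) at that
node, with free parameters 2·(#loci) per component plus (#components − 1)
mixing weights, and effective n = total membership weight reaching the
node. Recursion also stops at `max_depth` (default 4 — eight classes need
depth 3; one spare level), when a node's effective size is below
2·`min_node_size`, or when a child would fall below `min_node_size`
(default 5, matching the smallest class sizes such a study reports).
Terminal nodes are the classes, ordered by depth-first traversal; a
sample's membership in a class is the product of its responsibilities
along the path, so rows of W sum to 1 by construction. Hard labels are
argmax with ties to the lower class index.

Numerical choices: betas are clamped to [1e-6, 1−1e-6] before likelihood
evaluation (the beta density is unbounded or zero at the boundary);
degenerate loci (all values equal) get a capped concentration (1e4) with
a warning; shape estimates are confined to [1e-3, 1e6]. Split
initialization bipartitions the node's samples at the weighted median of
the first principal coordinate of pairwise Manhattan distances, with the
eigenvector's sign fixed by a sample-order-invariant rule — fits are
therefore deterministic and equivariant to row permutation, with no
random restarts. Missing betas are only admitted with
`impute_missing=True` (per-locus mean imputation, flagged in
diagnostics).

`classify` descends the stored split tree, recomputing each node's
two-component posterior from its fitted parameters. Classifying the
training matrix therefore reproduces the training membership matrix
exactly; a flat mixture over terminal classes would not, because parent
densities are not constrained to equal the mixture of their children.

The terminal class count is a *diagnostic, not an invariant*: with J loci
the BIC penalty for one extra split is ≈ (2J+1)·log n, so classes
contributing less log-likelihood than that — in particular very small
classes at moderate separation — are merged. The recovery benchmark
(4 classes, 150×500, concentration 20, mean separation ≥ 0.2) is the
regime where exact recovery is expected and tested.

## Class–covariate permutation tests

Hard class labels stay fixed; the covariate is permuted B = 10,000 times
(complete cases only). Continuous covariates use the midrank
Kruskal–Wallis statistic with tie correction; categorical covariates the
Pearson chi-square of the class × level table after dropping zero-margin
levels. p = (1 + #{stat_b ≥ stat_obs})/(B + 1): the add-one keeps p valid
and strictly positive, with resolution 1e-4 at the default B. Because the
covariate's value multiset is fixed under permutation, the null
statistics are computed from precomputed midranks / expected counts —
identical in value to the public statistics (a tested identity) but
O(n) per permutation. Asymptotic chi-square p-values are reported as a
diagnostic column only.

## Ridge multinomial regression of class membership

Membership (one hard label per sample; one class as referent with
coefficients fixed at zero) is modeled with multinomial logits. All
non-intercept coefficients share an L2 penalty λ·Σb²; continuous
covariates are standardized internally first — shared shrinkage is only
meaningful on a common scale — and coefficients are back-transformed for
reporting. The penalized likelihood is maximized by damped Newton
iterations to gradient norm < 1e-8; the penalized objective is monotone
over iterations (tested). At λ = 0 a singular information matrix
(separation) raises with advice to penalize.

λ is selected from a grid by minimizing
BIC(λ) = −2·loglik_unpenalized(at the penalized estimate) + df_eff(λ)·log n,
with df_eff = trace[H(H + 2λP)⁻¹] (H the unpenalized information at the
estimate, P the non-intercept indicator): the full parameter count at
λ = 0, shrinking monotonically as λ grows. Ties go to the larger λ. A
naive parameter-count alternative exists as an option.

Wald tests use the inverse *penalized* information as the coefficient
covariance (the naive penalized choice; a sandwich variant was considered
and left out of scope). The overall test for a covariate is the quadratic
form of its (K−1) coefficients against the corresponding covariance
block, referred to chi-square with K−1 df; per-class z-tests accompany
it. Both are computed on the standardized fitting scale, where they are
invariant to covariate units.

The default referent is the median-size class — neither the largest nor
the smallest, so contrasts are stable in both directions; it is
user-overridable. Probability curves evaluate softmax probabilities along
a covariate grid with the remaining design columns held at user-supplied
reference values (no silent defaults; a means/medians convenience is
shown in the examples); declared transforms (identity, sqrt, log1p)
support modeling intake variables on a compressed scale. Changing the
referent leaves fitted probabilities unchanged at λ = 0 (tested to 1e-8);
at λ > 0 the penalty breaks exact invariance because it is imposed on
referent-relative contrasts.

## Hierarchical clustering view

Exploratory clustering selects the k most variable loci (default 750;
ties broken by locus ID), computes pairwise Manhattan distances over
samples, and merges by average linkage (UPGMA), so each merge height is
the average inter-cluster distance. Columns are ordered by a second
clustering pass by default. Heatmaps use the blue/yellow convention
(blue = methylated). Missing betas are mean-imputed per locus before
distance computation, flagged upstream.

## Synthetic studies: what is and is not emulated

The generator draws, per study: a covariate table with the marginal
distributions typical of a breast-tumor surgical cohort (age ~ N(59, 11.6)
within 30–91; zero-inflated lognormal alcohol; gamma folate and tumor
size; categorical race/stage/grade/receptor status at cohort-typical
frequencies; ~72% postmenopausal); latent class labels — by default from
the 8-class mixing proportions 68/39/23/14/5/4/4/5 over 162, with class
probabilities linked to standardized age, alcohol, folate and tumor size
through a multinomial logistic model (the planted directions: size →
class 2 up; alcohol → classes 3/8 up, 2/4 down; folate → class 6 up;
late classes younger); per-locus beta values from
class-specific Beta distributions — bimodal base means, Normal(0, 1)
logit offsets at 30% of loci, fixed concentration a+b = 20; and exposure
effects as additive logit-scale mean shifts with consistently signed,
gamma-distributed per-locus magnitudes (alcohol −0.05, folate +0.05,
size +0.12 per SD, averaged over loci) — dietary exposures as weak
array-wide trends, tumor size as a stronger signal. Within-class
dispersion is not reported for such arrays, so concentration is an
explicit free parameter rather than an asserted study value.

Raw signals invert the beta formula exactly: a total intensity
S ≥ 100β/(1−β) is chosen per cell, giving Cy5 = β(S+100) and
Cy3 = S − Cy5 ≥ 0; betas at 1 are clamped to 1−1e-6 first (the offset
makes β = 1 unreachable at finite intensity). Planted failing loci get
detection p > 0.05 in ~70% of samples. Covariate missingness is
completely at random (per-covariate missing counts are reported by such
studies without a mechanism).

Fixed seed implies bit-identical output. The default design reproduces
the printed array accounting exactly: 1505 loci − 8 detection failures −
84 X-linked = 1413 autosomal loci in 773 of 803 genes (failing loci are
drawn one-per-gene from multi-locus genes so no gene is lost to QC).

Not emulated: bead-level replicate structure (the ~30 replicate
measurements behind each average beta), chip/batch effects, spatial
artifacts, covariate correlation structure beyond the class link, and
realistic linkage between neighboring CpGs. Passing tests on this
generator therefore demonstrate the *statistical machinery* — calibration,
FDR control, parameter recovery, determinism — not performance on any
real cohort; in particular the number of classes RPMM reports on real
arrays depends on structure this generator does not claim to match, and
is surfaced as a diagnostic.

## Problem sizes used by the acceptance script

The script runs the study-scale design (162 × 1505) once end to end, the
class-recovery benchmark at 150 × 500 over 10 seeds, and the scan
calibration at n = 160 with 200 null loci × 20 replicates plus 30 planted
effects among 300 loci × 5 replicates — sizes chosen to estimate each
rate with useful precision on a single CPU in seconds per stage.

## Known limitations

- The EM split uses one deterministic initialization; pathological nodes
  could in principle converge to a local optimum a random-restart scheme
  would escape. Determinism was deliberately chosen over restarts.
- Storey's smoother is a cubic polynomial fit over the λ grid, not a
  smoothing spline with data-driven df; on small m the π0 estimate is
  coarse (it is clamped to (0, 1]).
- The quasi-binomial t reference with n−p df is a convention; other df
  choices change borderline p-values.
- Wald p-values at λ > 0 inherit shrinkage bias from the penalized
  covariance: they are conservative for strongly shrunk coefficients.
- The pipeline's stratified mode refits the tree inside the stratum; it
  does not propagate uncertainty from the unstratified fit.
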