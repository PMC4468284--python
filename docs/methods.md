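# Methods

This note documents the statistical procedures implemented in `mrrmrr`,
the defaults and numerical choices, what the synthetic benchmark does and
does not emulate, and known limitations.

## Least weighted squares regression and the robust correlation

For a simple regression V = β₀ + β₁U + e, the LWS estimator minimizes
Σᵢ wᵢ e²₍ᵢ₎ where e²₍₁₎ ≤ … ≤ e²₍ₙ₎ are the ordered squared residuals and
w₁ ≥ … ≥ wₙ ≥ 0 are rank weights. Three weight schemes are provided, plus
a uniform scheme that reduces the estimator to ordinary least squares and
is used to verify the classical limit:

- **linear**: wᵢ = (n−i+1)/n. Any positive rescaling of the weights leaves
  the derived correlation unchanged (the formula is scale-free in w), so
  the normalization is immaterial and is asserted as a test property.
- **logistic**: w(t) = 1/(1 + exp(s(t−c))) at t = (i−½)/n, defaults
  s = 20, c = 0.5 — near-1 weights for the better half of ranks, near-0
  for the worse half.
- **adaptive** (default): 0/1 trimming weights estimated from the data.
  The squared residuals are scaled by the high-breakdown estimate
  s² = median(e²)/χ²₁(0.5) and their order statistics compared with
  χ²₁((i−½)/n) quantiles; a contiguous upper tail whose scaled values
  exceed `margin` (default 2.5) times the theoretical quantile is trimmed,
  never more than n − ⌊(n+3)/2⌋ observations. On clean normal residuals
  the trimmed fraction is almost always zero, so the fit coincides with
  least squares (full efficiency); gross outliers are trimmed entirely.
  The margin is a parameter because no canonical closed form exists for
  this rule; its default was fixed a priori from the quantile-comparison
  construction.

**Initialization.** A fast LTS search: 500 random 2-point subsets give
candidate lines, each improved by 2 concentration steps (refit on the
h = ⌊(n+3)/2⌋ best-fitting points — the maximal-breakdown choice for two
parameters), the best 10 concentrated to convergence; all counts are
configurable. The LWS iteration then alternates rank-weight assignment and
weighted least squares; the fixed point is defined on the
observation-to-rank permutation (ties broken by observation index), not on
coefficients, so floating-point chatter cannot oscillate. Cap: 100
iterations; on cap the best-objective iterate is returned flagged
`converged=False`.

**Robust correlation.** r_LWS = b₁·√(Σwᵢ(Uᵢ−Ū_w)²)/√(Σwᵢ(Vᵢ−V̄_w)²) with
weighted means over the final weights, clipped to [−1, 1] (the raw ratio
can exceed 1 in finite samples). It is invariant to positive affine
transforms of either variable and sign-equivariant. For relevance the
binary label vector (coded 1/2) is the regression response. The
asymptotic distribution of the adaptive version on bivariate normal data
is normal and centred at ρ; the implementation's tests assert normality,
mean recovery, and a variance within a factor 4 of the delta-method scale
(1−ρ²)²/n without pinning the constant.

## Shrinkage of the correlation matrix and regularized redundancy

The sample correlation matrix R̃ of the selected set plus the candidate is
shrunk toward the identity, R\* = (1−λ\*)R̃ + λ\*I, with the analytic
intensity computed from standardized columns zₖᵢ and products
wₖᵢⱼ = zₖᵢzₖⱼ:

    S*ᵢⱼ = n/(n−1)·mean_k wₖᵢⱼ,
    var̂(S*ᵢⱼ) = n/(n−1)³ · Σ_k (wₖᵢⱼ − w̄ᵢⱼ)²,
    λ* = clamp(Σ_{i<j} var̂(S*ᵢⱼ) / Σ_{i<j} (S*ᵢⱼ)², 0, 1),

the distribution-free minimizer of the mean squared error of R\*; a zero
denominator (no estimated correlation at all) returns λ\* = 1. The
intensity is recomputed for every candidate set — every entry of R\*
depends on all columns considered jointly — and the redundancy of a
candidate Z against the set S is the quadratic form

    r̃*(Z, S) = R*_ZT' (R*_TT)⁻¹ R*_ZT

computed through the eigendecomposition of the *unshrunken* correlation
of S: eig(R\*ₜₜ) = (1−λ\*)θᵢ + λ\*, eigenvectors unchanged, so the matrix
is invertible whenever λ\* > 0 even for |S| ≫ n. The quadratic form is the
squared-correlation-scale measure in [0, 1]; no square root is taken. With
a user-fixed λ = 0 and a singular R̃ₜₜ, eigenvalues below 1e−12 are
dropped (pseudo-inverse) and the value clipped to [0, 1].

Two redundancy modes exist because a per-member sum of a set-level
measure admits two readings: `multiple` (default) uses the set-level
multiple correlation above — the measure that actually captures
multivariate structure — while `pairwise_mean` averages the jointly
shrunken pairwise correlations |(1−λ\*)r̃(Xₖ, Z)|. The mode is recorded in
all outputs.

## Forward search, classical baselines, evaluation

Relevance values for all p columns are computed once and cached (the LWS
fit per column dominates the cost); for the regularized redundancy, two
p × p cross-product matrices are precomputed so each candidate's λ\* and
quadratic form cost O(s²). The uncached reference path (`step_score`) is
retained and tested for exact agreement. Ties are broken by smallest
column index everywhere; the trace is deterministic given the seed.

Classical baselines behind the same interface: |r|, |r_S|, mutual
information of equal-frequency 3-bin discretizations (bins configurable;
MI exists as a comparison baseline — discretization loses information by
construction), two-sample Kolmogorov–Smirnov p-value (large = similar
distributions = redundant) and the exact two-sided sign-test p-value on
nonzero paired differences. Classical set redundancy averages over all
ordered pairs including the diagonal, so a singleton set has redundancy 1;
the constant offset cannot change the forward-search argmax.

Evaluation: two-class LDA with pooled within-class covariance, equal
priors by default (configurable to empirical), and a ridge guard
(1e−6·trace/d on the diagonal) applied only when the covariance is
numerically singular; with `ridge=0` singularity is a hard error.
Leave-one-out cross-validation reports sensitivity (group-1 correct
rate), specificity (group-2), and accuracy = (SE+SP)/2. By default the
variable set is selected once on the full data and only the LDA is
cross-validated — the protocol of selecting a reduced variable set first —
which is optimistically biased since every held-out sample influenced the
selection; `nested=True` reruns the selection inside each fold and is the
unbiased (slower) protocol. The permutation-null test demonstrates both
facts. γ is scanned over a grid (default 0–2 in steps of 0.1; γ > 1 is
allowed because relevance and redundancy need not share a scale) and the
best γ maximizes LOOCV accuracy, ties to the smallest γ.

## Synthetic benchmark and noise models

The generator emulates a small two-group omics study: unit-variance
columns in consecutive equicorrelated blocks (default block size 10,
ρ = 0.2 — a mild, realistic within-pathway correlation), class-2 means
shifted by `effect` SDs on the informative columns, which are placed one
per block so that each signal carries a block of correlated but
uninformative neighbours. Benchmark defaults: n₁ = n₂ = 24, p = 500,
10 informative columns at effect 1.5, benchmark seed 12345 — a desk-scale
rendition of a 48-sample whole-genome design (p is kept at 500 so the
full γ grid runs in seconds; it is configurable upward). Noise models,
added i.i.d. to every cell with N(a, b) read as mean/variance:
N(0, 0.1); the contaminated normal Δ·N(0, 0.01) + (1−Δ)·N(0, 1) with
Δ = 0.85; Cauchy with density c/(π(x²+c²)), c = 0.002. Noise studies
default to 10 replications.

What the generator does **not** emulate: heavy-tailed or skewed marginal
distributions, platform artifacts (probe effects, normalization,
batch structure), heteroscedastic variables, or label noise. Passing the
benchmark therefore shows correct mechanics and the intended robustness
ordering under the stated contamination laws, not performance on any real
assay.

## Known limitations

- **Binary-response leverage degeneracy.** With the labels as response,
  the maximal-breakdown LTS/LWS objective can be driven to ~0 by a fit
  through one class's points plus a single extreme leverage observation in
  the other class (h = ⌊(n+3)/2⌋ ≈ n/2 is exactly one class plus one point
  in a balanced design). The adaptive weights then trim the remaining
  honest points and |r_LWS| ≈ 1 spuriously for that column. Heavy-tailed
  cell noise (the Cauchy model) on unit-scale data occasionally creates
  such leverage points, and a handful of affected columns can enter the
  selection; in the bundled sensitivity study this can cost the robust
  pipeline a few accuracy points relative to the Pearson baseline under
  Cauchy noise, while it matches or beats it under Gaussian and
  contaminated-normal noise. This is a genuine property of
  maximal-breakdown trimmed fits with a two-valued response, not a
  numerical artifact; users concerned by it can lower the trimming bound
  (larger h) or use the linear/logistic weights, at a robustness cost.
- Only two groups are supported; a robust multi-group relevance (e.g. a
  robust ANOVA statistic) is out of scope.
- Only simple (one-regressor) LWS regression is implemented — the
  correlation coefficient needs nothing more.
- The non-nested LOOCV default reproduces the select-then-validate
  protocol and overstates generalization accuracy; use `nested=True` for
  honest error estimates.
- Measures are not standardized to a common scale, so useful γ values
  depend on the measure pair; that is why γ is grid-searched.
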