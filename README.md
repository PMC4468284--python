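# mrrmrr — robust regularized variable selection for noisy two-group data

`mrrmrr` selects a small, interpretable set of variables from a
high-dimensional numeric matrix observed in two groups (n samples, p
variables, n ≪ p allowed) — the situation of gene-expression,
metabolomic, or biometric studies where a classifier must be built from
tens of samples and hundreds to tens of thousands of correlated, noisy
variables. It implements **MRRMRR** (Minimum Regularized Redundancy
Maximum Robust Relevance), a robust, regularized variant of the classical
minimum-redundancy maximum-relevance (MRMR) forward search, together with
the classical MRMR baselines, an LDA / leave-one-out cross-validation
harness, and a synthetic two-group generator with three additive-noise
contamination models for sensitivity studies.

## The method

The forward search starts from the most relevant variable and repeatedly
adds the candidate **Z** maximizing

    Rel(Y, Z) − γ · Red(Z, S),        γ ≥ 0,

until the selected set *S* reaches a fixed size *m*.

**Relevance** is the robust correlation |r<sub>LWS</sub>(X, Y)| derived
from the least weighted squares (LWS) regression of the labels on the
variable: the fit minimizes a weighted sum of *ordered* squared residuals
(weights nonincreasing in residual rank — data-adaptive 0/1 trimming,
linearly decreasing, or logistic), initialized by a fast least trimmed
squares (LTS) fit with h = ⌊(n+3)/2⌋. With adaptive weights the
estimator keeps a high breakdown point (≥ min(ε⁰, (⌊(n+1)/2⌋−2)/n))
while remaining fully efficient on clean normal data, and

    r_LWS = b₁ · √(Σ wᵢ(Uᵢ−Ū_w)²) / √(Σ wᵢ(Vᵢ−V̄_w)²) ∈ [−1, 1]

reduces exactly to Pearson's r under uniform weights.

**Redundancy** is a regularized squared multiple correlation. The sample
correlation matrix R̃ of (S, Z) is shrunk toward the identity,
R\* = (1−λ\*)R̃ + λ\*I, with the analytic, distribution-free intensity λ\*
(the ratio of the summed variance estimates of the pairwise correlations
to their summed squares, clamped to [0, 1]). Because
eig(R\*ₜₜ) = (1−λ\*)θᵢ + λ\* ≥ λ\*, the quadratic form

    r̃*(Z, S) = R*_ZT' (R*_TT)⁻¹ R*_ZT ∈ [0, 1]

is well defined even when |S| exceeds n, and is computed through the
eigendecomposition fast path.

γ is chosen by leave-one-out cross-validation with linear discriminant
analysis (equal priors, pooled covariance); accuracy = (SE + SP)/2.

## Worked example

Simulate a 48 × 200 two-group matrix with 5 informative variables
(columns 1, 11, 21, 31, 41 in 1-based naming; mean shift 1.5 SD), select
5 variables with MRRMRR, and evaluate a γ grid:

```bash
mrrmrr simulate --n1 24 --n2 24 --p 200 --p-inf 5 --effect 1.5 --seed 7 --out demo.csv
mrrmrr select --input demo.csv --labels group --m 5 --gamma 0.5 --seed 7 --out demo_sel.tsv
# selected: V31 V21 V41 V1 V11
cat demo_sel.tsv
# rank  index  name  relevance  redundancy  score
# 1     30     V31   0.70309…   0           0.70309…
# 2     20     V21   0.59067…   0.03702…    0.57216…
# 3     40     V41   0.63241…   0.31706…    0.47388…
# 4     0      V1    0.57354…   0.23766…    0.45471…
# 5     10     V11   0.51646…   0.14365…    0.44464…
mrrmrr evaluate --input demo.csv --labels group --m 5 --gamma-grid 0,0.3,0.9 --seed 7 --out demo_cv.tsv
# best gamma 0 with LOOCV accuracy 0.9583
```

All five planted signals are recovered (the `relevance` column is
|r<sub>LWS</sub>| with adaptive weights; `redundancy` is r̃\* against the
already-selected set; `score` is their γ-weighted difference). The
cross-validation report shows sensitivity 1.00 and specificity 0.917 at
every γ on this easy instance, i.e. accuracy 0.958. Each command also
writes a `*.manifest.json` with the resolved configuration, seed, and
input digests.

The same functionality is available as a scikit-learn transformer:

```python
from mrrmrr import MRRMRRSelector
sel = MRRMRRSelector(n_features_to_select=10, gamma=0.5, random_state=0)
X_reduced = sel.fit_transform(X, y)   # sel.selected_, sel.steps_, sel.support_
```

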