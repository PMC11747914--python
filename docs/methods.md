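# Methods

This note states the statistical model and estimators implemented in
`morphotype`, the package's numerical conventions, and known limitations.
Symbols: N participants, R regions per measure, V = 4 structural measures.

## 1. Synthetic cohort generator

The generator is scoped to *tabular morphometrics*: it emits participants ×
regions tables per measure, never images. For each measure with R regions:

- Region scales: means µ_r around a measure-typical value (thickness ~2.5,
  areas/volumes at their own scales), SDs σ_r jittered ±20%.
- Subgroups: labels are a balanced permutation of {0, …, k−1}. A fraction
  (default 0.5) of regions is "affected"; cluster c's mean on affected
  region r is shifted by (c − (k−1)/2) · mean_shift · σ_r times a random
  per-region sign. The random signs are essential: a common-signed shift
  moves participants *along* the pooled region-pair regression line, which
  the (unsigned) Cook's-distance graphs cannot see; sign-varying shifts
  change each participant's regional *profile* and are visible.
- Correlation: residuals are multivariate normal with uniform correlation
  base_corr (default 0.3); a fraction (default 0.1) of region pairs has its
  correlation perturbed by ±edge_effect in non-reference clusters, with the
  matrix repaired to the nearest positive-definite correlation (eigenvalue
  clipping + rescaling).
- Nuisance: batch b applies gamma_{b,r} · σ_r additively and delta_{b,r}
  multiplicatively to the residual (the ComBat model class); ages are
  uniform on [6, 18] with a shared polynomial basis (default degree 2) and
  region-specific random coefficients; sex adds a linear region-specific
  term.
- Phenotypes: eight bounded instrument-like scores; the second planted
  subgroup gets higher inattention/hyperactivity medians and lower adaptive
  functioning and IQ (effect size `phenotype_effect` SD). Diagnosis labels
  (ASD/ADHD/TD at 262:171:132 proportions) are drawn independently of the
  subgroups by default, or "enriched" towards them with a mixing
  probability.

Everything is drawn from one `numpy.random.default_rng(seed)`; identical
configs are bit-identical.

## 2. Harmonization

Applied per measure in the order batch → sex → age.

**Batch (parametric empirical-Bayes location/scale).** Standardize each
region by its pooled (weighted grand) mean and pooled variance (ddof = 0
throughout, so that identical batches recover multiplicative factors of
exactly 1). Batch location estimates γ̂ get a normal prior, scale estimates
δ̂² an inverse-gamma prior (moment-matched across regions; the prior is
pinned when the cross-region variance of δ̂² is numerically zero), solved by
fixed-point iteration (tol 1e-4, ≤100 iterations). Requirements: ≥2 batches
with ≥3 members each, no zero-variance regions; a single batch is a warned
no-op. Note the EB correction is deliberately not idempotent: shrinkage
leaves a small remainder, and re-application contracts it (verified by a
contraction test rather than an exact-fixed-point test).

**Sex.** Per-region OLS on a centred indicator; the grand mean is restored.

**Age.** Per-region polynomial of degree 1–3 selected by shuffled k-fold CV
(default 5 folds) on mean squared prediction error, with a parsimony rule:
the lowest degree whose CV error is within 1% (relative) of the minimum
wins. Nested polynomials tie in CV whenever higher-order terms are null, so
without the tolerance the selected degree would be decided by fold noise.
Age is centred/scaled before fitting for conditioning only; residuals keep
the grand mean.

## 3. Association graphs

For an (ordered) region pair (a, b), regress b on a across participants.
With residual e_i, leverage h_ii of the design [1, x], p = 2 parameters and
residual variance s² (denominator n − 2), Cook's distance is

D_i = e_i² · h_ii / (p · s² · (1 − h_ii)²).

The pair deviation is the average of the two regression directions, and the
edge weight is w = exp(−D̄² / 2σ²) with σ the median of all strictly
positive deviations of the measure (median heuristic; a fixed override is
available). Weights are clamped below at 1e-12 — extreme outliers would
otherwise underflow to exactly 0 — and the diagonal is 1. Perfect-fit pairs
(s² ≈ 0) contribute zero deviation with a warning. The whole (N, R, R)
computation is vectorized; it matches a per-pair leave-one-out refit oracle
to 1e-10.

## 4. Participant similarity

The graph Laplacian is unnormalized, L = Deg − W with the diagonal of W
ignored; eigenvalues are clipped at 0 (they are nonnegative up to roundoff)
and sorted. The lambda distance between participants is the Euclidean
distance of their sorted spectra — a pseudo-metric (isospectral non-identical
graphs get distance 0). Affinities use the SNF-style locally scaled kernel
W_ij = exp(−d_ij² / (µ ε_ij)) with ε_ij = (mean of i's K nearest distances +
mean of j's + d_ij)/3; outputs are floored at 1e-12 and symmetrized.

## 5. Fusion

Standard SNF: full kernel P = W_ij / (2 Σ_{l≠i} W_il) off-diagonal with
diagonal 1/2; sparse kernel S row-normalized over each row's K largest
affinities (stable argsort, ties to the lower index). Update per view:
P_v ← S_v · mean of the other views' P · S_vᵀ, then symmetrize, add I and
re-normalize. After t_max = 20 iterations the fused matrix is the
symmetrized view average. With m identical inputs the update degenerates to
single-view diffusion, so the result is independent of m (tested exactly).
Diffusion smooths: rank correlation between an input affinity and the fused
matrix is strong but deliberately not asserted near 1 (measured Spearman ρ ≈
0.66–0.79 on structured affinities, for this and for a per-step-unnormalized
variant alike).

## 6. Embedding, consensus, model selection

**Graph-convolutional autoencoder** (plain numpy, analytic gradients, Adam
with lr 0.01, β = 0.9/0.999). Encoder Z = Â·relu(Â X W₁ + b₁) W₂ + b₂ with
Â = D^{−1/2} W D^{−1/2} of the fused matrix and X the z-scored concatenated
regional features (N × ΣR_v). Two decoders: an inner-product adjacency
decoder scored by binary cross-entropy against the fused network's
symmetrized 20-nearest-neighbour graph, and a linear feature decoder scored
by MSE. The adjacency term is down-weighted (weight 0.1): at weight 1 the
inner-product term dominates the geometry and destroys the regional-feature
signal (measured ARI vs truth collapsing from 1.0 to ≈0). Defaults: hidden
64, embedding dimension 32, 150 epochs. 150 is a diminishing-returns choice,
not a plateau — the loss still drifts down slowly beyond it, with no
measurable gain in recovery, while consensus cost scales linearly in epochs.
Training is bit-reproducible from its seed.

**Consensus.** Runs cycle a grid of (µ, K, seed) configurations up to the
budget (default 100): re-kernelize the per-measure spectral distances,
re-fuse, embed (cached per configuration — the cache is shared across
candidate k, so a k sweep mostly re-runs k-means), k-means with a
run-derived seed. Co-assignment fractions form the consensus matrix; final
labels cut an average-linkage tree of (1 − consensus) at k. Failed runs are
excluded; >10% failures is an error.

**Choosing k.** For each candidate k, Davies–Bouldin (min), silhouette
(max) and Calinski–Harabasz (max) are computed on a reference embedding with
the consensus labels; majority vote, three-way splits defer to silhouette.
Silhouette is recorded as missing when a cluster is a singleton.

## 7. Post-hoc statistics

- Agreement: NMI with arithmetic normalization (defined as 0 when either
  partition is constant), adjusted Rand, homogeneity and completeness
  (scikit-learn implementations behind the package's interface).
- Continuous variables: Shapiro–Wilk per group at α = 0.05 routes two
  normal groups to Welch's t, everything else to Kruskal–Wallis with tie
  correction; group medians and IQRs are always reported; Cohen's d uses
  the n−1-weighted pooled SD, sign = first group − second.
- Categorical: Pearson chi-squared without continuity correction; zero
  marginals are errors naming the row/column.
- Edgewise: Kruskal–Wallis per region pair on edge weights,
  Benjamini–Hochberg step-up (with monotonicity enforcement) across all
  edges of the measure; significant edges are reported with the sign of the
  cluster-median difference and Cohen's d.

## 8. Numerical conventions

- All randomness flows from named seeds in the config; no global state.
- Variance conventions: ddof = 0 in ComBat standardization (see §2),
  ddof = 1 in Cohen's d and regression s² (n − 2).
- Floors/clamps: association weights ≥ 1e-12, kernel affinities ≥ 1e-12,
  Laplacian eigenvalues ≥ 0, sigmoid logits clipped at ±30.
- Derived seeds stay below 2³¹ for cross-platform RNG safety.

## 9. Limitations

- The lambda distance is a pseudo-metric on graph spectra; participants
  with isospectral but different graphs are indistinguishable at that stage
  (the joint feature decoder mitigates this downstream).
- Cook's-distance graphs are blind to subgroup differences that move
  participants along the pooled regression line (common-signed global mean
  shifts); the method detects profile and covariance differences.
- Single-edge detection power in the edgewise screen is low at typical
  cohort sizes; the clustering pools evidence across all edges, but the
  per-edge battery should be read as conservative.
- The ComBat step assumes the location/scale batch model and ≥3
  participants per batch; nonlinear scanner effects are out of scope.
- The generator plants multivariate-normal residuals and polynomial age
  trends only; heavy-tailed or site-by-age interaction structure is not
  simulated.
- No claims are made about clinical validity of subtypes; all quantitative
  statements in this repository are measured on synthetic cohorts with
  known ground truth, except the published sex-by-group contingency
  statistic, which is recomputed from its printed counts.
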