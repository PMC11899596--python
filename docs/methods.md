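# Methods

## The model

CPM treats the connectome as a bag of candidate predictors. For subjects
i = 1..N with edge vectors x_i ∈ R^E (the vectorized COI upper triangle),
target y_i, confound design Z_i and family label f_i, each cross-validation
fold proceeds:

1. **Family exclusion.** Training subjects sharing a family with any test
   subject are dropped (train-side only, so each subject is still predicted
   exactly once). Relatives share both phenotype and connectome structure;
   leaving them in lets the model score on familial resemblance rather than
   a generalizable brain–behavior mapping.
2. **Edge selection.** For each edge, the partial correlation r_e of edge
   and target given the confounds: both are residualized on [1 | Z] and the
   residuals correlated. Two-sided p from t = r√(df/(1−r²)), df = N−2−q.
   Edges with p ≤ α (default 0.05) split by sign of r into a positive and a
   negative network. The threshold is a signal-to-noise filter, not an
   inference; significance of the final prediction comes from permutation.
3. **Model.** Network strengths S±_i = Σ_{e∈mask±} x_ie; ordinary least
   squares of y on [1, S+, S−]. An empty mask drops its regressor (β
   recorded as 0); with both empty the fold predicts the training mean and
   is flagged.
4. **Prediction and evaluation.** Held-out subjects are predicted from
   their own strengths; after all k folds, the evaluation statistic is
   Pearson's r of the pooled out-of-fold predictions against observations.

**Permutation inference.** The target vector is shuffled and the entire
pipeline (folds, exclusion, selection, fit) re-run m times;
P = #(r_null ≥ r_obs)/m, the plain proportion (an optional (b+1)/(m+1)
estimator avoids exact zeros but is off by default). With m = 199 and a
true null, P ≤ 0.05 has probability exactly 10/200 = 0.05. Permutation
orders are pre-drawn from the master seed before dispatch, so results are
bit-identical for any worker count. Two scopes are provided: the default
whole-sample shuffle, and a variant that shuffles targets only within each
test fold; the whole-sample shuffle is the standard exchangeability
argument and is what the calibration tests certify.

**Tangent-space connectivity.** Subject covariances are estimated with the
Ledoit–Wolf shrinkage estimator (convex combination of the sample
covariance with μI, μ = tr(S)/P, analytically optimal weight; always SPD
for non-constant data), then mapped to the tangent space at the group
reference G (affine-invariant geometric mean, fixed-point iteration
G ← G^{1/2} expm(mean_i logm(G^{−1/2} C_i G^{−1/2})) G^{1/2}, initialized
at the arithmetic mean, tol 1e−7 on the Frobenius norm of the mean log,
max 50 iterations). The reference is fitted on all subjects by default,
mirroring common practice in the field's tooling; a leakage-safe variant
would refit per training fold (the covariance reference leaks no target
information, only marginal connectivity structure, so the default is the
conventional trade-off). No Fisher z-transform is applied anywhere.
Condition matrices are embedded per condition and then averaged.

**Confound encoding.** Gender → one binary indicator, ethnicity → one-hot
with the first (sorted) level dropped, age numeric; the intercept is always
added by model code. Both the target and (by default) the edges are
residualized — mathematically a partial correlation — with df reduced by q.
A target-only mode is available.

**Networks.** Per-fold selections are aggregated by selection frequency;
an edge enters the consensus at frequency ≥ threshold (default 1.0, the
strictest convention; the recovery analyses below use 0.5). Edge weight is
the mean nuisance-adjusted r over selecting folds. Weighted degree sums
|weight| over a node's masked incident edges by default so positive and
negative networks are comparable; frequency and unit weights are
selectable. Top-node selection takes ceil(fraction × group size) nodes,
ties broken by parcel id. Overlap networks are element-wise mask products;
their significance defaults to the hypergeometric tail over the COI edge
universe (a permutation mode shuffling edge positions is provided); every
output labels the method used.

## The synthetic cohort

The generator emulates the statistical structure the pipeline must cope
with, not fMRI physics. For subject i with standardized latent trait z_i:

- Σ_i = Σ₀ + effect_size · z_i · Δ + W_{fam(i)}, where Σ₀ is compound
  symmetry (variance `base_var` = 2, correlation `base_corr` = 0.1), Δ is
  ±1 on the planted positive/negative COI edges, and W_f is a
  family-shared symmetric perturbation on COI edges (sd `family_edge_sd` =
  0.06). Eigenvalues are floored for SPD; a spec whose flooring would move
  eigenvalues by more than 10% of the largest is rejected.
- T timepoints are drawn i.i.d. from N(0, Σ_i); edges are the COI entries
  of the sample covariance (options: population covariance, correlation).
- The trait is family-clustered: z = √icc·f_fam + √(1−icc)·e, icc =
  `family_trait_icc` (default 0.3).
- Confounds (binary gender, numeric age, 3-level ethnicity) load on a
  shared latent correlated with the trait at `confound_strength` (0.3);
  the observed target adds `confound_strength` × (standardized encoded
  confound score) and `noise_sd` (0.5) measurement noise to z, scaled to
  BMI-like units (26.5 ± 4).

Defaults — 300 subjects in 60 families of 5, 44 parcels (10 cerebellar /
30 cortical / 4 subcortical, COI universe 385 edges), T = 200, 15 + 15
planted edges, effect_size 0.12 — are the desk-scale reference condition.
effect_size 0.12 makes a planted edge's trait-driven spread comparable to
the sample-covariance sampling noise at T = 200 (edge–target correlations
≈ 0.4–0.5, a strong but not degenerate effect), while keeping every
subject covariance SPD without material flooring; base_var = 2 provides
the eigenvalue headroom for the worst-case trait draw. family_edge_sd =
0.06 gives families a shared connectome signature of the same order as the
sampling noise — the mechanism (shared idiosyncrasies plus clustered
trait) by which relatives genuinely leak into each other's predictions.

What the generator does **not** emulate: hemodynamic response, temporal
autocorrelation, motion and scanner artifacts, site effects, non-Gaussian
edge distributions, and signal planted in correlation (rather than
covariance) space — correlation-kind pipelines therefore see an attenuated
effect. Passing tests certify the statistical machinery, not robustness to
these real-data features.

## Problem sizes and numerical choices

- **Cross-validation.** k defaults to 128 (capped at N with a warning).
  The desk-scale analyses in the test suite and acceptance script use
  k = 8–16: with N = 300 and k = 128, any two training folds share ≈ 99%
  of their subjects, so cross-fold consensus degenerates to full-sample
  selection and its false-positive rate is pinned at the selection α; at
  k = 8 each fold trains on a substantially different subsample (family
  exclusion further diversifies folds) and the 50% consensus acts as a
  true replication filter, which is what makes planted-edge recovery
  clean. This is a property of consensus aggregation worth knowing when
  choosing k.
- **Null calibration** runs 100 independent trait-free cohorts (N = 200,
  m = 199 permutations, k = 8) and checks the empirical level against the
  exact binomial interval; the leakage demonstration uses trait ICC 0.5
  with no planted effect, where exclusion-off runs inflate r by ≈ 0.13 on
  average.
- **SPD handling.** Matrix functions use symmetric eigendecompositions;
  validation floors eigenvalues below 1e−10·λmax with a warning and
  rejects genuinely indefinite input. The geometric mean warns and returns
  the last iterate on non-convergence.
- **Degenerate cases.** Constant edge columns get (r = 0, p = 1) with a
  warning; empty selections fall back to train-mean prediction and are
  flagged; a run fails if more than 10% of folds are unusable; failed
  permutation replicates are dropped with m adjusted and recorded.
- **Determinism.** A single seed governs fold assignment and every
  stochastic step; identical configuration and seed reproduce predictions,
  selections and null distributions byte-for-byte regardless of worker
  count.

## Known limitations

- The parcel count is data-driven; published whole-brain parcellations of
  this design disagree internally about their total (the constituent
  counts 360 + 54 + 100 sum to 514), so no count is hard-coded.
- The tangent reference fitted on all subjects is a deliberate, documented
  departure from strict train/test separation (see above).
- The hypergeometric overlap test assumes exchangeable edge positions
  within the COI universe; spatially clustered networks violate this, and
  the permutation mode only partially relaxes it.
- Whether condition matrices should be averaged before or after tangent
  embedding is a genuine modeling choice; the package embeds per condition
  and averages in tangent space, where averaging is the natural linear
  operation.
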