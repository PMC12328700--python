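# Methods

This note records the model, its assumptions, and the numerical and design
choices made where the procedure was genuinely open. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Robust Aitchison PCA

**Transform.** Counts are compositional: only ratios are informative, and
zeros are censored observations, not measured absences. The robust centered
log-ratio (RCLR) therefore logs only nonzero counts and centers each sample
by the mean log of its *observed* features. The transform is invariant to
per-sample scaling (verified by property test), and a sample with no nonzero
count has no geometric mean and is rejected by name.

**Zero handling.** PCA cannot consume missing entries. Absent entries are
filled with 0 — after CLR centering, 0 is the sample's own mean log-ratio,
the least-informative completion — and the observation mask is kept on the
`RclrMatrix`. Full matrix-completion (OptSpace-style) robust PCA is
deliberately not implemented: at the cohort sizes this package targets, the
zero-fill-plus-PCA route is simpler, exactly reproducible, and feeds the
same downstream contracts (orthonormal loadings, leakage-safe held-out
projection). This is a documented simplification, not an equivalence claim.

**Embedding.** The filled matrix is feature-mean-centered and decomposed
with scikit-learn's exact-SVD PCA. Component signs are fixed so the
largest-magnitude loading of each component is positive (cross-platform
reproducibility). Defaults: prevalence threshold 25 samples; 256 components,
automatically capped at `n_samples − 1` with a warning (a cohort of n
samples supports at most n − 1 components — the reason small shotgun-skin
cohorts use 64). Held-out samples are projected with training-fold loadings
(`transform_new`), so test folds never influence the embedding;
`cross_validate(rpca_fit="all")` exposes the alternative convention of
fitting the unsupervised embedding once before splitting.

## The transformer

One token per principal component: a j-dimensional score vector is expanded
by a learned linear map to j tokens of width `projection_dim = 4` and every
token is L2-normalized to the unit sphere. Each block applies two gated
residual updates — attention, then MLP — renormalizing after each, so token
norms are invariants of depth (asserted to 1e-5 in tests).

Choices the architecture description left open:

- **Attention width.** Eight heads cannot divide 4-wide tokens. Attention
  runs in an internal width (`attention_width`, default `nhead × 1 = 8`)
  reached by learned up/down projections around the sub-layer; the printed
  head count and token width are both honored, and the width is
  configurable.
- **Residual gains.** α_A and α_M are learnable scalars (one pair per
  block) initialized at 0.05: blocks start near the identity, which keeps
  early training stable. At α = 0 a block is exactly the identity on
  unit-norm input (contract test at 1e-7).
- **Norm.** Per-token L2 normalization; exact zero tokens are left at zero
  (guarded by a 1e-12 epsilon) rather than dividing by zero.
- **MLP.** Two linear layers, hidden width 4 × token width, exact GELU.
- **Pooling.** Global average pooling over the projection axis, returning
  one scalar per component position (the reading most consistent with
  "across the projection dimensions"); pooling over the sequence axis is
  kept behind `pool_axis="sequence"`.
- **Multi-task wiring.** The shared encoder output feeds the classification
  head directly; the regression branch applies one additional normalized
  attention block, pools it, concatenates the pooled vector with the class
  scores, and feeds the linear regression head. The extra "attention layer"
  is interpreted as one more normalized block; this is flagged as an
  interpretation, and the concatenation is the package's choice of
  combination operator.

**Engine.** The network runs on a ~350-line numpy reverse-mode autograd
(`trpca._autograd`) in float64, with fused softmax and L2-norm primitives.
Every gradient is checked against central finite differences in the test
suite, including the full multi-task loss. The tape is released after each
backward pass so training memory stays flat.

## Training and evaluation

- Losses: MSE (regression), cross-entropy (classification), their unweighted
  sum (multi-task). Optimizers: AdamW (default 1e-3, weight decay 0.01) for
  single-task models; plain SGD at the stated 9e-3 for multi-task. All runs
  step a cosine-annealing-with-warm-restarts schedule per epoch (period 10,
  doubling, η_min 0); the rate returns exactly to its base value at each
  restart (contract test).
- **Target standardization.** Ages are z-scored on the training fold and the
  transform inverted at prediction. With raw ages (~mean 54 y) and
  unit-scale optimizer steps, the output bias alone would need ~10⁴ steps to
  reach the target range; standardization is the standard remedy and is
  invisible at the interface.
- Batch size 64, 100 epochs, no early stopping (fixed-epoch training is the
  documented behavior; divergence raises an error suggesting the usual
  hyperparameter adjustments). These were fixed once and are overridable.
- CV schemes: KFold, GroupKFold (subject-grouped; disjointness asserted in
  the pipeline itself), StratifiedKFold, StratifiedGroupKFold; 10 folds by
  default. Residuals are prediction − truth, so positive means "older than
  chronological age".
- Baselines run on the same RPCA embedding and the same folds as the
  transformer by default — a representation-controlled comparison; percent
  improvement is computed per fold against the best reference model and
  reported mean ± sd.

## Shapley attribution and back-projection

`shap` ships no numpy-only estimator in this environment, so attribution is
an in-package interventional permutation-Shapley: for each test sample and
each of `n_permutations` random component orderings, the sample's values are
inserted one at a time into every background row and the prediction
increments are averaged. The estimator is additive by construction (base
value + attributions = prediction exactly, a tested invariant) and exact for
models linear in the components — the closed-form oracle used in tests. The
background is capped at 100 training samples; everything is seeded.

Component attributions are mapped to taxa by the dot product with the PCA
loading matrix. Because the map is linear, global (per-feature mean)
importances of a linear surrogate equal `wᵀ·loadings` exactly (tested at
1e-6). Heatmap preparation normalizes per sample by max |importance|
(switchable to a global max), restricts to the top 50 features by |global
mean|, and orders rows and columns by average-linkage hierarchical
clustering on Euclidean distance. Cross-model agreement is the Pearson
correlation of global importance vectors (flattened per-sample matrices are
available via `level="per_sample"`); zero-variance vectors yield NaN, never
0. Feature–age correlations use ln(count + 1): the pseudocount keeps zero
counts in the analysis and is stated here because no convention was given.

## Residual statistics

Paired concordance is the squared Pearson correlation of per-subject
residual vectors — equivalently the R² of the simple regression between
them. It is sign-blind (anti-correlated residuals also give R² = 1), which
is documented at the call site. Permutation tests use standard rank
statistics — Kruskal–Wallis H (upper tail; H is a non-negative omnibus
statistic) for categorical variables, Spearman ρ (two-sided on |ρ|) for
continuous — with `p = (1 + #extreme)/(B + 1)` over B = 1000 label
permutations, so the smallest attainable p is 1/(B+1) and the null
distribution is super-uniform (calibration verified by simulation).
Constant residuals carry no rank information and return statistic 0, p = 1.
Missing metadata is dropped pairwise per variable with the effective n
reported; BH-FDR is applied across the variable set.

## Synthetic cohorts

The generator draws subject ages uniformly on 18–90 years, gives each
subject a latent age deviation δ ~ N(0, `subject_deviation_sd`), and builds
expected log-abundances as baseline N(0,1) plus, for informative taxa, a
slope of ±`effect_size` natural-log units per decade of *effective* age
(age + δ), alternating sign across the informative block. Group labels add
class offsets on a disjoint feature block. Observed counts are multinomial
draws at a uniform random depth (2 000–10 000) over the softmax of these
log-abundances plus N(0, 0.5) per-observation noise, with a 20 % structural-
zero mask — the simplest law that is compositional, overdispersed and
zero-inflated. δ shifts the features but not the recorded chronological
age, so an accurate age model inherits δ in its residuals; paired designs
share subjects, ages and δ across two disjoint feature dictionaries, making
residual-concordance analyses testable by construction.

Free parameters were fixed once at values a microbiome analyst would call a
strong, clean signal (slope 1.0/decade against 0.5 dispersion): recovery
tests should probe the pipeline, not the noise floor. For paired-residual
recovery the dominant-latent regime uses `subject_deviation_sd = 15` years:
propagating count noise through the oracle regression leaves ~6 years of
residual noise per modality, and 15 ≫ 6 gives the latent-dominated regime
the analysis expects (sd = 0 is the matched null). What a green test
establishes is that each stage recovers structure the generator provably
contains; it says nothing about real microbial ecology, taxon names,
phylogeny or body-site effects, which the generator does not attempt.

## Known limitations

- No matrix-completion RPCA; zeros are filled, not imputed.
- No early stopping or hyperparameter search; fixed-epoch training can
  underfit or overfit extremes of cohort size.
- Permutation Shapley is exact only for linear models; for the transformer
  it is an estimate whose variance falls as `n_permutations` grows.
- The paired-residual R² is sign-blind by definition.
- Training is CPU-bound float64 numpy: cohorts beyond ~10⁴ samples or
  embeddings beyond ~512 components will be slow.
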