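# trpca

Transformer models for host-age prediction from microbiome count tables,
built on robust Aitchison PCA embeddings, with interpretable feature
back-projection and age-residual statistics.

## The problem

Microbial community composition shifts systematically with host age, and a
"microbiome age clock" — a model predicting chronological age from a stool,
saliva or skin sample — is a candidate biological-age indicator: a person
whose predicted age exceeds their chronological age (ΔAge > 0) carries an
"older" microbiome. Building such clocks from amplicon or shotgun count
tables is awkward: the data are compositional (only relative information),
zero-rich, high-dimensional, and repeated samples from one subject are not
independent. This package implements one modelling route end to end:

1. **RPCA embedding.** Features seen in fewer than 25 samples are dropped;
   counts are transformed with the robust centered log-ratio (RCLR),

   `rclr(x)_f = ln x_f − mean_{f′: x_{f′}>0} ln x_{f′}`,

   taking logs of nonzero counts only and centering each sample by the mean
   log of its observed features; PCA of the (zero-filled, feature-centered)
   RCLR matrix yields per-sample component scores `[PC₁ … PC_j]` (default
   j = 256) and an orthonormal loading matrix.
2. **TRPCA network.** The score vector is expanded by a linear multi-view
   projection into j tokens of width 4 (one token per principal component),
   each L2-normalized, and passed through a normalized transformer block with
   learnable residual gains:

   `h_A = Norm(x + α_A·(Attention(x) − x))`,
   `h_M = Norm(x + α_M·(MLP(x) − x))`,

   followed by global average pooling over the projection axis and a linear
   regression head (MSE loss, AdamW), classification head (cross-entropy),
   or a joint multi-task pair of heads (summed losses, SGD at 9e-3), all
   under a cosine-annealing-with-warm-restarts schedule. Cross-validation is
   subject-grouped (GroupKFold, 10 folds) so no host appears in both train
   and test; the embedding is refit on every training fold.
3. **Baselines.** SVR, gradient boosting, k-NN, an MLP and random forest at
   fixed benchmark hyperparameters, on the same embedding and folds, with
   per-fold percent-improvement summaries.
4. **Interpretability.** Shapley-value attributions of the trained model over
   principal components (a seeded permutation estimator, exact for linear
   models) are mapped back to taxa with
   `FeatureImportance (n×k) = ShapMatrix (n×j) · Loadings (j×k)`;
   positive mean importance marks features associated with older predictions.
5. **Residual statistics.** Squared Pearson correlation of per-subject age
   residuals across paired modalities (e.g. 16S vs shotgun), and permutation
   sensitivity tests of residuals against metadata (Kruskal–Wallis /
   Spearman, 1000 permutations, Benjamini–Hochberg FDR).

A deterministic synthetic-cohort generator (zero-inflated multinomial counts
over softmax log-abundances, age-trending taxa, repeated measures, group
shifts, and a shared per-subject age-deviation latent) makes every stage
testable without external data.

## Worked example

```bash
trpca simulate --seed 7 --out cohort/            # 150 subjects x 2 samples
trpca cv --counts cohort/counts.tsv --metadata cohort/metadata.tsv \
         --pca-dim 64 --folds 10 --seed 0 --out cv/
```

On the bundled synthetic cohort (seed 7, 300 samples, 300 features, 30 of
them age-informative) the grouped 10-fold run prints:

```
{"mae_mean": 6.452, "mae_sd": 0.369, "r2_mean": 0.847, "r2_sd": 0.031,
 "null_mae_mean": 17.64, "null_mae_sd": 2.124,
 "mae_overall": 6.452, "r2_overall": 0.855}
```

i.e. the model predicts held-out subjects' ages to ±6.5 years where always
guessing the training-fold mean age would err by ±17.6 years, explaining
86 % of the age variance. `cv/per_sample.tsv` holds per-sample predictions
and signed residuals (prediction − truth); `trpca benchmark`,
`trpca explain` and `trpca sensitivity` continue the analysis from there.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the whole pipeline from scratch on freshly generated synthetic
cohorts — embedding, grouped cross-validated training, the baseline suite,
Shapley back-projection, paired-residual concordance and a sensitivity
scan — printing a summary of what it computed and writing the results file.

## Layout

| module | contents |
| --- | --- |
| `trpca.data_io` | count-table / metadata I/O (TSV, BIOM 2.1), relative-abundance conversion, alignment |
| `trpca.rpca` | prevalence filter, RCLR, PCA embedding, held-out projection |
| `trpca.model` | the transformer (multi-view projection, normalized blocks, heads) |
| `trpca.training` | CV splits, optimizers/scheduler, metrics, cross-validated pipeline |
| `trpca.baselines` | the five reference regressors, percent improvement |
| `trpca.interpret` | Shapley attribution, loading back-projection, summaries |
| `trpca.stats` | paired residual R², permutation tests, BH-FDR |
| `trpca.synth` | synthetic cohort generator |

See `docs/methods.md` for the modelling assumptions and numerical choices.
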