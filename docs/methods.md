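# Methods

## Model

The joint VAE maps the concatenated input `t = [x, y]` — the metabolite
block `x` and the expression block `y`, both rescaled per feature to
[0, 1] — into a k-dimensional diagonal-Gaussian latent space:

```
encoder   h1 = act(W1 t + b1)
          h2 = act(W2 [h1, t] + b2)        # skip connection to the input
          mu = Wm h2 + bm
          log s2 = Wv h2 + bv
sampling  z = mu + eps * exp(log s2 / 2),  eps ~ N(0, I)
decoder   d1 = act(U1 z + c1)
          d2 = act(U2 d1 + c2)
          t' = sigmoid(U3 d2 + c3)
```

The loss is

```
L = (1/n) sum_i ||t_i - t'_i||^2
    + beta * (1/n) sum_i (1/2) sum_j (s_ij^2 + mu_ij^2 - log s_ij^2 - 1)
```

i.e. the mean over samples of the squared Euclidean reconstruction
error (sum over features within a sample), plus a weighted closed-form
KL divergence of the posterior from the standard-normal prior. Training
is full-batch Adam with analytic gradients (no autodiff framework);
gradients are verified against central finite differences in the test
suite to relative error below 1e-4.

## Parameter defaults and rationale

- `latent_dim = 8`, `hidden = (64, 32)`: the studies involved are small
  (tens to low hundreds of samples, 35 features), so the network is kept
  small; the decoder mirrors the encoder widths in reverse.
- `beta = 0.1` with a 100-iteration linear KL warm-up. With the
  per-sample-sum reconstruction convention above, `beta` corresponds to
  `2 * sigma_eps^2` of an implicit Gaussian likelihood; the empirical
  per-feature residual scale of these data puts that at roughly
  0.05–0.1. At `beta = 1` the KL term dominates on this loss scale and
  the posterior collapses (latent means contract to ~1e-3 spread and
  carry no condition information); `beta = 0.1` plus warm-up keeps the
  two terms balanced. Both the collapse and the recovery are exercised
  in the test suite indirectly through the classification floor.
- `learning_rate = 1e-3`, `iterations = 500`: Adam's conventional rate;
  500 full-batch iterations more than halve the loss on the default
  synthetic study and the convergence tracker (validation-loss change
  below `tol = 1e-4` for `patience = 20` consecutive iterations)
  reports where the trace flattens.
- Glorot-uniform initialisation; ReLU hidden activations (a linear mode
  exists for diagnostics: with `beta = 0` and linear activations the
  model reduces to a deterministic autoencoder and reconstructs a
  rank-1 logit dataset to ~1e-6 mean squared error).
- Random forest: 500 trees, sqrt-p feature subsampling, stratified
  5-fold cross-validation; per-condition one-vs-rest accuracy,
  precision, recall and F1 are computed from the pooled out-of-fold
  predictions. t-SNE: perplexity 30, 1000 iterations, exact method,
  PCA initialisation; the perplexity is lowered automatically (with a
  warning) when `n <= 3 * perplexity`. LASSO: coordinate descent with
  soft-thresholding on the objective
  `(1/2n)||r - b0 - X b||^2 + lambda ||b||_1`, tolerance 1e-8, with a
  KKT stationarity check; `lambda = 0.01` by default.

## Preprocessing

1. Metabolite concentrations: `ln(x + 1)` (concentrations are positive
   and right-skewed). Gene TPMs: per-gene z-score (ddof = 1); constant
   genes are dropped with a warning.
2. Batch correction: parametric empirical-Bayes location/scale
   adjustment (ComBat) per modality, with the biological condition as a
   preserved covariate. Implemented in-package: per-feature OLS on the
   batch + covariate design, standardisation against the pooled
   variance, per-batch additive/multiplicative effect estimates shrunk
   toward normal / inverse-gamma priors by the standard EB iteration,
   then removed. Confounded batch/condition designs and singleton
   batches are rejected up front.
3. Outlier flagging on group-centred residuals (so well-separated
   conditions are not themselves mistaken for outliers): a sample is
   flagged if its score on either of the first two principal components
   exceeds 3 MAD-scaled robust standard deviations from the median, or
   if it is the singleton of a 2-cluster average-linkage cut whose
   merge height exceeds 3x the median merge height.
4. Per-feature min-max rescale to [0, 1], matching the decoder's
   sigmoid output range. All transform parameters are stored so values
   can be mapped back to the corrected raw scale exactly.

## Synthetic data generator

The generator emulates the study design the analysis assumes: six
exercise conditions, paired metabolome (15 metabolites) and
transcriptome (20 genes) per sample. Group means of the six energy
metabolites (ATP, ADP, AMP, NADH, NAD+, NADP) and of SIRT1 are anchored
to the published per-condition values; the remaining features use
plausible baselines with condition effects oriented by the underlying
physiology. Noise is multiplicative log-normal with
`sigma = sqrt(ln(1 + cv^2))`, centred at `-sigma^2/2` so the noise has
unit mean and empirical group means converge to the configured means.
Batch effects are injected on the log scale as per-batch location/scale
distortions — exactly the model the EB correction assumes and removes.

What the generator does **not** emulate: feature-feature correlation
structure within a condition (features are conditionally independent
given the group), count-based sampling noise in TPMs, time-course
dynamics (the published post-exercise time course is shipped only as a
printed-mean table), and any real-animal biological variability beyond
a common coefficient of variation. Classification numbers obtained on
synthetic data are therefore a property of the configured effect sizes,
not a re-estimate of the published real-data metrics.

## Validation statistics

Paired t-tests (n-1 df, two-sided), classical one-way ANOVA
(`F = MS_between / MS_within`; the `F = t^2` identity for two groups is
tested), and percent-change / fold arithmetic on the shipped
group-mean tables. Published t/F statistics themselves are not
recomputable from printed means alone and are flagged as such in the
validation report; they are recomputed only on per-sample synthetic
data. Degenerate inputs (zero-variance differences, zero within-group
variance) return flagged sentinel results instead of dividing by zero.

## Numerical choices

- Sigmoid evaluated in the numerically stable two-branch form.
- Per-stage seeds are derived from the global seed via
  `numpy.random.SeedSequence` and recorded in the run manifest, so any
  stage is independently reproducible.
- Matrices are written with `%.17g` formatting and round-trip
  bit-exactly through the text readers.
- ANOVA/t p-values are floored at the smallest positive double rather
  than returning 0.

## Limitations

- The real per-sample data are not deposited; all sample-level results
  in this repository are on synthetic data as described above.
- The VAE trains full-batch; for sample sizes far beyond this study's
  scale a mini-batch loop would be needed.
- Some published summary percentages are mutually inconsistent with the
  printed table means (e.g. a stated 28% ATP decrease vs 18.9% from
  the printed means); the package always reports the arithmetic value
  computed from the printed cells.
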