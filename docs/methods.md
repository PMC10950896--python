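# Methods

This note records the models, the synthetic data law, and the numerical
choices behind `potency-uq`, in enough detail to reproduce or challenge
them.

## Problem setting

Compound potency prediction is a regression task: given a folded binary
fingerprint (default width 2048 bits) of a compound, predict its pIC50
(−log10 IC50/M) against one protein target. An *activity class* is the set
of compounds measured against one target; large curated classes hold
upward of 1000 compounds whose potency distribution is unimodal with the
mode in the intermediate (micromolar, pIC50 ≈ 5.5–7.5) range. Models of
interest attach a predictive variance σᵢ² to each prediction, and the
analysis asks how that claimed uncertainty relates to actual error.

## Synthetic activity classes

### Generative law

Each class is drawn from a latent linear bit-weight law:

1. `n_signal_bits` (default 64) positions are chosen among the `n_bits`
   fingerprint positions and ordered along a *ladder* of latent coordinates
   q spanning [−0.35, 1.35].
2. Each compound carries a latent potency factor u ~ Beta(3, 3) on [0, 1].
   It sets signal bit j with probability 0.9·exp(−(qⱼ−u)²/(2·0.18²)) — a
   Gaussian window centred at u. Because the ladder is wider than the
   u-range, windows never truncate and the expected signal-bit count is
   flat in u.
3. Background bits are i.i.d. with the probability that brings the overall
   expected density to `bit_density` (default 0.05, ≈ 102 set bits per
   2048-bit fingerprint).
4. pIC50 = intercept + Σⱼ wⱼ·bitⱼ + ε, ε ~ N(0, `noise_sd`), with weights
   wⱼ increasing along the ladder. The raw weighted sum is affinely
   rescaled so the realized labels are centred at 6.5 with a spread chosen
   from the normal quantile of `central_mass` (shrunk 20% as a
   finite-sample margin), so the central bin (5.5, 7.5] holds at least
   `central_mass` (default 0.5) of the compounds. Labels are clipped (not
   rejected) at `potency_range` (default [4, 10]), mimicking assay
   floor/ceiling.

The rescaled weights, intercept and signal positions are recorded on the
returned `ActivityClass`, so tests can evaluate the Bayes-optimal
predictor exactly; at `noise_sd = 0` the label is an exact function of the
fingerprint.

### Why a latent gradient

The label is strictly linear in the bits, but the bits are *not*
independent: the window construction makes fingerprint overlap decay
smoothly with the latent potency difference of two compounds. This was a
deliberate, empirically forced choice. With i.i.d. bits, Tanimoto
similarity between compounds is dominated by background-bit noise and a
Tanimoto-kNN regressor is no better than the class mean (R² ≈ 0); with a
monotone latent *density* (more potent compounds set more bits), kNN
collapses the other way (R² ≈ −1.5) through the classic Tanimoto size bias
— compounds with many set bits become everyone's nearest neighbor. The
sliding-window design keeps the per-compound bit count flat, removes the
size bias, and yields the accuracy regime observed on real activity
classes (ensemble R² ≈ 0.6–0.75, single tree clearly worse, Tanimoto-kNN
in between). There is deliberately no discrete cluster or analogue-series
structure: the latent factor is continuous.

### What the generator does not emulate

Real activity classes contain analogue series (strong local structure),
heteroscedastic assay noise, interference compounds, and inter-feature
correlations from real chemistry. Passing tests on synthetic classes
therefore validate the *machinery* (models, metrics, bookkeeping) and the
qualitative phenomena (bin-wise confidence heterogeneity, ensemble vs
single-model ordering), not quantitative claims about any particular
experimental data set.

### Calibration-controlled prediction sets

`generate_prediction_set` produces (yᵢ, ŷᵢ, σᵢ²) triples without any
model: reported σᵢ comes from a configurable positive law, and the true
error is drawn with standard deviation c·σᵢ. By construction c = 1 is
perfectly calibrated (miscalibration areas → 0 as n grows), c > 1 is
over-confident, c < 1 under-confident, and the empirical 1σ coverage is
2Φ(1/c) − 1. These sets are the ground-truth oracle for every calibration
metric.

## Models

- **Ensembles**: `n_estimators` members (grid 100/150/200), each fit on
  ⌈max_samples·n⌉ compounds sampled *without* replacement by default (a
  `bootstrap` flag switches to with-replacement) and ⌈max_features·n_bits⌉
  bit positions. DT members are sklearn `DecisionTreeRegressor`s; all
  members of one ensemble share a single derived tree seed so that
  members fit on identical data are bit-identical (a degenerate ensemble
  has exactly zero variance). kNN members use Tanimoto distance computed
  by bit-matrix algebra; two all-zero fingerprints have distance 0.
  Prediction is the member mean; uncertainty is the **population (1/n)
  variance** across members — fixed by convention and pinned by tests.
  The continuous subsampling fractions are searched on the grid
  {0.05, 0.25, 0.50, 0.75, 1.00} (overridable), k ∈ {1, 3, 5}, by 5-fold
  cross-validated MSE with first-occurrence tie-breaking.
- **FFNN + MC dropout**: ReLU hidden stacks (large 1000-1000-100-10, small
  300-300), dropout (10/20/50%) between all hidden layers — none on input
  or output — active during training *and* prediction; Adam lr 1e-3, batch
  32, 600 epochs, MSE loss; no early stopping. Prediction = mean/population
  variance over 100 stochastic passes. Networks consume raw 0/1 bits.
- **MVE**: same stacks with two output heads. The variance head emits
  log-variance, exponentiated and floored at 1e-6, with its bias
  initialized at ln var(y) so the initial predictive spread matches the
  labels; the mean-head bias starts at the label mean. Loss is the
  per-sample Gaussian NLL; Adam lr 1e-3, batch 32, max 4000 epochs,
  stopping when the monitored loss has not improved for 100 consecutive
  epochs. The monitor is the epoch-mean *training* loss by default and is
  configurable to a held-out validation split (10%) with best-weight
  restore. Gradients are clipped to global norm 5; non-finite losses abort
  with diagnostics.

The networks are implemented as a compact numpy feed-forward stack
(explicit forward/backward passes and an Adam optimizer); the
architectures above are small enough that dense BLAS matmuls on one CPU
cover every profile used here.

### Scale profiles

`paper` uses the full architectures and epoch budgets above. `desk` (the
default for tests and the acceptance script) substitutes, by explicit
opt-in and never silently: small 300-300 stacks, 50 epochs, and for MVE
validation-split early stopping (patience 10). The validation monitor at
desk scale is load-bearing: an over-parameterized MVE net interpolates a
~1400-compound synthetic training set within a handful of epochs, and
train-loss monitoring then lets the variance head collapse toward the
floor (mean σ ≈ 0.05 against a true noise sd of 0.5); stopping at the
validation-NLL optimum recovers σ ≈ 0.7–0.8, between the irreducible noise
(0.5) and the model's actual predictive error.

## Metrics: numerical choices

- **Calibration grid**: n_levels = 99 levels p = 0.01…0.99, x(p) =
  Φ⁻¹((1+p)/2). Coverage uses the strict inequality |ŷᵢ−yᵢ| < x·σᵢ
  (boundary ties are measure-zero for continuous data).
- **Quadrature and endpoints**: A and A_abs are trapezoidal integrals of
  the (absolute) deviation over p ∈ [0, 1]. The p = 0 node is the exact
  limit 0 (coverage at confidence 0 is zero under strict counting). The
  p = 1 node carries the *last observed* coverage (deviation o_K − 1), the
  step extension of the empirical curve: a degenerate zero-coverage curve
  then attains A = −0.5 and A_abs = 0.5 exactly — the analytic maximum —
  while for calibrated curves the endpoint term is O(h²) ≈ 5·10⁻⁵.
  |A| ≤ A_abs ≤ 0.5 holds node-wise on every curve.
- **Sign convention**: A < 0 ⇔ over-confident (observed coverage below
  expected). Asserted by tests on c-inflated synthetic sets.
- **NLL variance floor**: 1e-10 pIC50² guards ln σ² against collapsed
  ensembles; the number of floored compounds is reported alongside.
- **R²** uses the test-set label mean for SS_tot and signals zero label
  variance explicitly rather than returning NaN.
- **Spearman ρ** is evaluated from the covariance-of-ranks definition with
  average ranks for ties; with no ties it coincides with
  1 − 6Σd²/(n(n²−1)), and scipy's implementation serves as an independent
  cross-check in the tests, never as the implementation.

## Bin-wise analysis and training-set modification

Bin-wise coverage stratifies by **true** (not predicted) pIC50, default 12
equal-width bins over [4, 10] (0.5 log-unit each, configurable); values
outside the range clamp into the terminal bins; bins are left-open/
right-closed. A bin is labelled over-confident when its within-1σ fraction
falls below 2Φ(1)−1 = 0.6827, under-confident above; empty bins carry no
label. Pooling bin fractions with bin counts reproduces whole-set coverage
exactly (conservation, tested).

Modification operates on the three bins pIC50 ≤ 5.5, (5.5, 7.5], > 7.5 —
the boundary compound at 5.5 belongs to the low bin and survives
reduction, the one at 7.5 to the central bin and is removed. (Prose
descriptions of the reduced range as "5–7" circulate; the operational
definition used here is the (5.5, 7.5] central bin.) Balancing keeps the
smallest bin whole and minority-samples the others uniformly without
replacement, seeded. Modification applies to the *training* portion only,
after splitting; the same split is reused across all models and
modification modes of one experiment cell so models are compared on
identical data.

## Curation rules

Mass cut-off strict (< 1000 Da; records lacking a mass are dropped in the
default strict mode), potency window inclusive at both bounds (default
10 pM–10 μM, configurable — published phrasings of this window are
ambiguous, so the bounds are explicit config). Replicates of one
compound-target pair are averaged on the pIC50 scale (arithmetic mean of
logs = geometric mean of molar potencies) and discarded entirely when
their span exceeds tenfold; the span criterion is itself a log-scale rule,
which is why averaging is done on the log scale. Structural-alert
filtering (PAINS, medicinal-chemistry rules, aggregator filters) requires
published external filter sets and is delegated to a user predicate hook.

## Problem sizes

Default experiment sizes used by the test suite and the acceptance script:
synthetic classes of 1000–2000 compounds, 10 random 70/30 splits,
ensembles of 100 members, calibration oracles at n = 10⁵, desk-profile
networks as above. These sizes were chosen so the full suite and the
acceptance script each complete in a few minutes on a single CPU while
keeping every Monte-Carlo tolerance at ≥ 3 standard errors.

## Known limitations

- The generator's latent-gradient law is a stand-in with the right
  statistical shape, not a claim about any experimental database.
- Network training determinism is guaranteed by seeding within this
  implementation; across BLAS builds, bit-exact reproducibility of
  network weights is not guaranteed (ensembles and all non-network paths
  are bit-exact).
- ρ between squared error and ensemble variance on synthetic classes is
  near zero — the homoscedastic label noise gives member-disagreement
  variance little error signal to rank; on heteroscedastic real data this
  correlation is typically positive.
- No post-hoc recalibration (temperature/variance scaling) is provided;
  the modification experiments re-train instead.
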