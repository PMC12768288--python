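# Methods

`seedstack` implements a complete multimodal seed-variety classification
workflow: Raman spectra and image-derived numeric features are
preprocessed, reduced per modality by competitive adaptive reweighted
sampling (CARS), fused by early (feature-level) concatenation, and
classified by a two-layer stacking ensemble whose six base learners are
hyperparameter-tuned with the Kepler Optimization Algorithm (KOA). This
note records the model choices, the defaults and why they were chosen,
and what the synthetic data generator does and does not emulate.

## Data model and synthetic generator

The pipeline consumes two aligned tables: a spectrum table (samples ×
Raman intensities on a fixed wavenumber grid) and an image-feature table
(samples × 43 named features in three blocks: 18 geometric, 7 texture,
18 color). The default grid covers 400–1800 cm⁻¹ at 2 cm⁻¹ steps under a
half-open convention `[400, 1800)`, giving exactly 700 channels; an
inclusive grid would give 701, and the half-open choice is what makes
the channel count match the feature count the rest of the workflow
assumes.

No public dataset of this kind exists, so the generator is a stand-in
built from the statistical structure the pipeline assumes rather than
from measured seeds:

* **Spectra** are a gentle polynomial baseline plus a shared set of 12
  Gaussian bands at plausible biochemical positions (starch skeletal and
  C–O–C modes, phenylalanine ring breathing at 1002 cm⁻¹, amide III,
  CH₂ deformation, the amide I region, lipid ester carbonyl). Varieties
  differ in *relative band intensities* — each class multiplies the base
  band heights by `1 + class_separation · z` with a fixed per-class
  pattern `z` — not in band positions, which is how cultivar differences
  in composition express themselves in Raman data. Channel noise is iid
  Gaussian.
* **Image features** are multivariate normal per class around means of
  realistic magnitude for a ~4 mm seed, sharing one covariance with
  within-block correlation 0.3 and per-feature coefficient of variation
  `image_cv`.

Defaults are 7 classes × 100 samples, `class_separation = 0.065`,
`noise_sd = 5`, `image_separation = 0.03`, `image_cv = 0.12`. These were
calibrated once so that a correctly implemented pipeline lands in a
non-trivial regime: individual tuned classifiers reach roughly 0.70–0.89
test accuracy and the stacked ensemble roughly 0.85–0.93, mirroring the
relative ordering (weak trees, strong kernel/ensemble models, stack at
or above the best single model) that motivates stacking in the first
place. Band widths (σ 3.5–8 cm⁻¹) were chosen so the informative support
is a realistic minority of the grid and CARS selections land in the
tens of channels.

What the generator does **not** emulate: fluorescence background drift,
cosmic spikes, detector nonlinearity, pixel-level image segmentation
error, class imbalance, or correlated noise between modalities. Passing
tests therefore demonstrate correctness of the algorithms under the
generator's assumptions, not instrument-level robustness.

A second generator (`recovery_spec`) produces feature-selection ground
truth: exactly `n_informative` sub-channel-width bands whose per-class
height pattern is a randomly permuted linear contrast, so every
informative channel separates at least two classes by the full
modulation span while the contrast direction varies. The generated spec
records the informative channel ids for scoring.

## Preprocessing

Spectra are smoothed row-wise with a Savitzky–Golay filter, window 15
and polynomial order 3; boundary samples use scipy's polynomial-fit
extrapolation, so any polynomial of degree ≤ 3 is a fixed point
everywhere. Both modalities are then scaled per feature by max–min
normalization `x' = (x − min)/(max − min)`.

The scaling statistics are fitted **on the training split only** and
applied unchanged to test data; transformed test values outside [0, 1]
are kept (no clipping), and a constant training column maps to 0.
Fitting the scaler before the split would leak test-range information
into training; the leakage-safe ordering is a deliberate design choice
here, and the pipeline's data-flow audit asserts it.

## CARS feature selection

For `m` features and `N = 20` sampling runs, run `i` retains the
fraction

    r_i = a·e^(−k·i),   a = (m/2)^(1/(N−1)),   k = ln(m/2)/(N−1),

so `r_1 = 1` (all features enter) and `m·r_N = 2` (two features remain at
the end) — both identities hold to machine precision and are tested as
properties. Each run: (1) fit a PLS regression on a Monte-Carlo row
subsample (`mc_sample_ratio = 0.8`) of the currently retained features
and take `|coefficient|` as the feature weight, (2) keep the
top-weighted `round(r_i·m)` features (enforced elimination), (3) draw
`round(r_i·m)` features with replacement with probability ∝ weight and
keep the unique draws (adaptive reweighted sampling), (4) score the
resulting subset by pooled K-fold RMSECV of a PLS regression on all
rows. The subset with the lowest RMSECV wins; ties go to the earliest
run, which is deterministic and favours the larger subset.

Label encoding for PLS is integer codes 1…C by default — consistent with
multiclass RMSECV magnitudes around 1.5 on a 7-class problem — with
one-hot available. The recovery experiments use one-hot: an integer
target is a single linear contrast and is blind to class differences
that are non-monotone in the (arbitrary) class order, which the
permuted-contrast ground truth deliberately contains. PLS defaults:
10 components (capped by rank with a warning), 5 CV folds.

## Kepler Optimization Algorithm

KOA is a population metaheuristic: candidate solutions are planets, the
incumbent best is the Sun. Two position updates exist: an *orbital* move

    X_i(t+1) = X_i(t) + F·V_i(t) + (Fg_i(t) + |r|)·U ⊙ (X_S − X_i(t))

and a *distance-adaptive* move around the planet–Sun–peer centroid
`M = (X_i + X_S + X_a)/3`

    X_i(t+1) = X_i(t)⊙U₁ + (1−U₁)⊙(M + h·(M − X_b)).

The published description of this optimizer fixes only these two
equations and the symbol roles; every generating rule is this package's
own design, kept explicit and overridable in `KOAConfig`:

* gravity `Fg = e_i · μ(t) · m_i/(R² + ε)` with eccentricities
  `e_i ~ U(0,1)`, gravity constant `μ(t) = 0.1·exp(−15·t/T)`, planet
  mass `m_i` the min–max-normalized fitness, and `R` the planet–Sun
  distance normalized by the search-box diagonal;
* direction flag `F = ±1` with probability ½; `|r| ~ U(0,1)`; masks
  `U`, `U₁` elementwise Bernoulli(½);
* velocity `V = u·(X_a − X_b) + σ(t)·span·𝒩(0,1)` from two random peers
  plus a jitter term decaying as `0.05·exp(−6·t/T)` — the peer
  difference self-anneals as the population contracts, the jitter keeps
  late-stage local exploration alive;
* regulating parameter `h = exp(−4·t/T)·𝒩(0,1)`, and the per-planet
  choice between the two moves is tied to the same envelope:
  P(orbital) = 1/(1 + exp(−4·t/T)), so early generations favour the
  exploratory distance-adaptive move and late generations the pull
  toward the Sun;
* bound handling by clamping; per-planet greedy acceptance (a move is
  kept only if it improves that planet) and an elitist Sun, which makes
  the best-fitness history non-increasing by construction;
* non-finite objective values are treated as +∞ with a warning.

With the study budget (population 10, 50 iterations) the optimizer
reaches a median best below 1e-2 on the 2-D sphere over 20 seeds and
beats equal-budget uniform random search on both sphere and Rosenbrock;
both facts are asserted in the test suite rather than assumed.

## Hyperparameter tuning of the base learners

Six families with their search ranges (integers rounded on decode,
positions clamped by the optimizer):

| family | parameters |
|---|---|
| DT   | max_depth {1..100}, max_features [0.1, 1] |
| SVM  | C [1, 1000], gamma [0.1, 1] (RBF) |
| KNN  | n_neighbors {1..100}, p {1..5} |
| MLP  | two hidden layers k1, k2 {10..100} |
| RF   | n_estimators {1..100}, max_depth {1..100}, max_features [0.1, 1] |
| GBDT | n_estimators {1..100}, max_depth {1..100}, max_features [0.1, 1] |

The tuning fitness is the misclassification rate on a fixed stratified
25% holdout of the tuning data. A k-fold CV fitness is available
(`TuningConfig(fitness="cv")`) and is the statistically smoother choice;
the holdout default trades a little fitness variance for a 3–5× smaller
fit count, which is what keeps the full six-family tuning at the study
budget practical on one CPU. Either way the split, the model seeds and
the optimizer seed derive from one seed, so tuning is a deterministic
function of (family, data, seed). Fitness values are cached by decoded
parameters; the continuous `max_features` dimension is bucketed at 0.05
for the cache key only, since the fitness is flat below that resolution
and the bucketing turns converged-population evaluations into cache
hits.

Implementation notes: the GBDT family is backed by scikit-learn's
histogram-based gradient boosting classifier (same knobs, an order of
magnitude faster at these sample sizes), with internal early stopping
(15% validation, patience 5); the MLP uses early stopping likewise; the
KNN clamps `n_neighbors` to the fitted sample count so the whole search
range is feasible on small folds.

## Stacking ensemble

Standard two-layer stacking with out-of-fold (OOF) meta-features:
stratified 4:1 train/test split; k = 5 stratified folds over the
training set; each base learner is fitted k times on k−1 folds and
predicts the held-out fold, so every training sample has exactly one OOF
prediction per base learner. Meta-features default to predicted
*labels*, one-hot encoded for the meta-learner (per-class probabilities
are available via `meta_feature_mode="probabilities"`). After the OOF
pass the base learners are refitted on the full training set for
inference.

The meta-learner is selected combinatorially among the same six tuned
families: each candidate is scored by stratified CV *on the training
split's OOF meta-features*, ranked by accuracy with ties broken by the
fixed order DT, SVM, KNN, MLP, RF, GBDT. Ranking candidates on the test
set would leak test information into a modelling decision, so the test
split plays no role in selection; the pipeline reports both the
selection (CV) table and the test-set comparison table of all six
candidate stacks, which is the honest version of picking the winner off
the comparison table.

## Evaluation

Per-class precision/recall/F1 are one-vs-rest forms computed from the
confusion-matrix marginals; overall accuracy is trace/total; macro
summaries are unweighted class means (with balanced classes macro ≈
weighted). Zero-denominator classes yield 0 with a warning. One-vs-rest
ROC AUC uses midrank tie handling; classes absent from the evaluated
labels are reported missing and excluded from the macro mean with a
warning. Model-to-model comparisons use
`100·(value − reference)/reference` rounded to two decimals. All metric
paths are verified against brute-force counting oracles on randomized
instances.

## Problem sizes and runtime envelope

The end-to-end experiments run the default synthetic conditions
(7 × 100 samples, 700 + 43 features) with a tuning budget of population
10 × 20 iterations per family and 5 evaluation seeds; the
feature-recovery experiment uses 200 channels, 5 informative, 3 × 70
samples, 20 seeds. These sizes keep a full verification pass on a single
CPU in the tens of minutes while preserving the qualitative structure of
the full-scale study (the paper-scale tuning budget of 50 iterations is
the package default in `KOAConfig` and remains available through
`RunConfig(koa_iterations=50)`).

## Known limitations

* Generator realism as discussed above; synthetic pass rates do not
  certify performance on instrument data.
* The KOA generating rules are one principled realization of the
  published update equations; other realizations (different h schedules,
  velocity laws) are legitimate and may explore differently.
* CARS with integer-coded PLS targets under-weights class structure that
  is non-monotone in the class ordering; one-hot encoding is provided
  and preferred when the class order is arbitrary.
* The holdout tuning fitness is noisier than k-fold CV; for final
  production fits prefer `fitness="cv"`.
* Meta-learner selection on OOF meta-features reuses the same OOF matrix
  for all candidates; a fully nested re-generation per CV fold would be
  stricter but multiplies base-learner fits by the fold count.
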