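# Methods

## Problem and model

The package targets longitudinal passive-sensing panels: P participants
observed weekly for up to T weeks, each week carrying feature vectors from Z
sensor modalities and an integer symptom score in [0, 27] (PHQ-9-like). The
prediction target at week m is the change score ΔW_m = W_m − W_{m−1},
defined only when weeks m−1 and m are both scored and consecutive —
differencing across a gap would conflate multi-week with weekly change, so
gaps simply produce no target. After 0/1 encoding (1 iff ΔW_m > 0) the task
is binary: did symptoms worsen this week?

The framework is a *ranking* procedure, not a single estimator. It
deliberately over-generates predictions — every nonempty modality subset ×
every suite algorithm × four cross-validation strategies — and then filters
by a single discrete statistic, the hamming distance between each encoded
prediction tensor and the encoded truth. Model selection therefore uses the
held-out labels themselves, both in the per-participant best-algorithm rule
(minimum absolute sum error over a participant's held-out slots, summed
across all splits of a strategy) and in the hamming ranking. This mirrors
the procedure the framework was designed around and is the default; a
`honest_selection` switch instead scores algorithms on only the first
(chronological) half of each participant's held-out slots, limiting label
reuse to past weeks. Because selection sees test labels, the reported
per-strategy metrics are optimistically biased; the package's comparisons
(framework vs singular strategies, baselines) share that bias, so *relative*
statements remain meaningful while absolute values should not be read as
generalization estimates.

## Cross-validation strategies

* **LOPO** — hold out all of one participant; train on everyone else
  (cold-start regime).
* **LTXO** — hold out one week across all participants.
* **ATU** — per participant, an expanding window: the first w0 weeks predict
  week w0+1, then the window grows by T weeks and repeats. Training slots
  always strictly precede the predicted week. Defaults w0 = 2, T = 1: the
  reference description's example (weeks 1–2 → week 3) fixes w0, while its
  increment ("e.g. 2 weeks") is ambiguous, so the step is configurable and
  covered at T = 2 in tests.
* **LOTPO** — per participant, leave one week out and train on all their
  other weeks, past and future. Participants with fewer than
  `lotpo_min_units` (default 3) target weeks are skipped: with fewer, the
  training fold degenerates to a single point.

Within one strategy the predicted slots partition the target slots exactly
once (property-tested against brute-force slot enumeration).

## Stage-1 preprocessing

Per fusion set: optional signed log1p on configured skewed features, KNN
imputation (k = 5, Euclidean distance on mutually present features; k is not
stated by the reference procedure and 5 is the conventional default),
zero-variance column drop, correlated-column pruning (keep the first column
in deterministic order of any pair with |r| > 0.9 — "highly correlated" is
otherwise unspecified), then z-scoring. Two fitting modes exist:

* `global_preprocessing=True` fits once per fusion set on all rows — the
  reference procedure's order (preprocess in stage 1, model in stage 2);
* the default `False` refits inside every training fold, so held-out rows
  never contribute statistics (leakage-audited in tests).

The bundled harnesses use the global mode, which is both the reference
behaviour and roughly an order of magnitude cheaper across 63 fusion sets.

## Ranking and ensembling

Encoded candidates per strategy are all 2^Z − 1 per-combination tensors plus
one mean-aggregate per cardinality (`fusion_scope="both"`; the reference
material describes cardinality aggregation but names individual combinations
in its results, so both candidate families compete). Ranking is ascending in
D_u with ties broken by smaller cardinality then scope name. Strategy
weights are w_k = (1/(D_k+ε)) / Σ_j (1/(D_j+ε)), ε = 1e-9 — the simplest
monotone-decreasing choice consistent with "weights based on minimum hamming
distance"; `softmax_neg_distance` is provided as an alternative. The fused
fraction at a slot renormalizes weights over the strategies that cover it
(ATU never covers the first w0 weeks; dropping those slots would discard
user-agnostic coverage). Exactly 0.5 encodes to 1 (`half_up`, configurable).
An `ensemble_on_raw` switch averages raw regression values instead of
encoded votes before a single final encoding.

## Regression suite

The default suite mirrors the seven classical regressors the framework was
designed with: linear regression, elastic net, random forest, AdaBoost,
extra trees, gradient boosting, XGBoost, all seeded (random state 42 by
default). Any object with `fit(X, y)`/`predict(X)` plugs in. The bundled
experiment harnesses and the acceptance script use a compact two-member
linear suite (`ols`, closed-form `ridge`): the full sweep is
63 fusion sets × 4 strategies × ~10^3 splits ≈ 2.5 × 10^5 model fits per
run, and lightweight linear members keep a complete run under ~20 s on one
CPU while still exercising per-participant best-model selection. The full
suite is exercised on small panels in the unit tests.

## Synthetic cohort generator

`simulate_cohort` emulates the regime the framework targets, not any real
dataset. Per participant: a latent severity deviation follows a stationary
AR(1), x_t = ρ x_{t−1} + √(1−ρ²) ε_t (ρ = 0.8), around a participant offset
~ N(0, τ²), τ = 1; the weekly score is clamp(round(10 + 3·(offset + x_t)),
0, 27). Observed weeks form a contiguous block from week 1 of length
~ N(13, 3²) clipped to [5, 24], matching ~13 observed weeks per participant
out of 24. Six modalities (calls 15, location 12, screen 10, conversation
14, fitbit 2, wifi 8 features — 61 total) have fixed per-feature loadings;
informative modalities (calls, location, screen, conversation by default)
load on both the severity level z_t and the observed weekly score change,
noise modalities (fitbit, wifi) on neither. Features that track only the
current level cannot determine a week-over-week change even noiselessly, so
the change loading is what makes the low-noise limit learnable; behaviourally
it corresponds to streams that reflect shifts in state, not just state.
Per-participant lognormal scale factors (σ_log = 0.4) give the heterogeneous
feature scales typical of sensor data. Feature cells are forced to exact 0
with probability π = 0.35 (matching the 35% zero-sparsity of the motivating
dataset; realized sparsity concentrates to π, tested at ±0.02) and dropped
(missing) with probability μ = 0.05. Everything is drawn from one
`numpy.random.default_rng(seed)`, so identical configs reproduce
byte-identical panels.

What the generator does **not** emulate: raw sensor streams and their
feature formulas, non-linear feature–symptom links, informative missingness,
measurement drift, or mid-study enrolment. Passing tests show the pipeline's
mechanics and its behaviour under the stated statistical structure — they do
not certify performance on real cohorts.

## Evaluation conventions

Metrics are per-user accuracy, recall and F1 (positive class = worsening),
then mean and sample SD (ddof = 1) across users. A user with no positive
truth weeks has recall = F1 = 0 and is still counted; users with no covered
slots are excluded and reported. Published figures for this family of
methods report per-user SDs exceeding the [0, 1] metric range; that
aggregation is not recoverable and is not reproduced here. In the baseline
harness (leave-one-participant-out classical classifiers on the encoded
target) the train-vs-test accuracy gap is the overfitting diagnostic; the
framework's own gap is structurally 0 in this harness because every
framework prediction is out-of-fold.

## Numerical choices and degenerate inputs

Ties in best-model selection break by suite order; ranking ties by
cardinality then scope name; a fused fraction of exactly 0.5 rounds up.
Zero-variance and fold-wise all-missing columns are dropped with a warning
(a feature absent from the *whole* dataset is an error). Degenerate training
folds (0 rows) leave their slots unpredicted with a warning. Weights with a
zero distance are finite via ε and give that strategy weight ≈ 1.
Participants missing more than 60% of their sensor cells over scored weeks
are excluded before modeling (configurable).

## Problem sizes used in tests

Unit and property tests run on panels of 2–12 participants and 4–12 weeks;
the framework-vs-singular check runs the full reference regime (45
participants, 24 weeks, 63 fusion sets) over 5 seeds; sensor-selection
recovery uses 20 replicates of a 12-participant, 3-modality, low-noise
(σ = 0.1, π = μ = 0) configuration. These sizes are the package's chosen
test conditions and are stated here so results can be reproduced exactly.
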