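# Methods

This note documents the models, statistics and design decisions behind
`actiga`, in the spirit of a package vignette: what is computed, under which
assumptions, and where genuine choices had to be made.

## Input data model

A measurement is one week of minute-epoch wrist actigraphy: activity counts
(piezoelectric, integrated per minute) and light (lux), i.e. a 2 × 10,080
matrix, labelled with the gestational age (GA, weeks) at which the week was
recorded. Preprocessing:

- recordings without light, with any break in the 1-minute grid, or shorter
  than one day are dropped (reason codes `no_light`, `gap`, `too_short`);
- the series is aligned to midnight: everything before the *second* midnight
  is discarded (the possibly partial first day and one full day — device
  placement effects concentrate there), then exactly the next 10,080 epochs
  are kept; recordings that would need trailing padding are excluded, so a
  usable recording needs at least 8 days;
- both channels are log-pseudocount transformed, `log10(x + 1)`;
- sleep is scored per epoch by the Oakley weighted moving sum
  `s_t = 0.04(a_{t-2}+a_{t+2}) + 0.20(a_{t-1}+a_{t+1}) + a_t`, zero-padded
  at the ends, sleep iff `s_t < θ` with θ = 80;
- metadata: continuous missing values are mean-imputed using train-split
  means only; categorical missingness becomes an explicit `"missing"` level;
- splits are always by patient, never by sample.

Open interpretation (flagged, not silently guessed): whether the original
procedure dropped a leading *full* day when a recording starts exactly at
00:00. We discard everything before the second midnight unconditionally, so
a midnight-start recording also loses its first day.

## Circadian summary metrics

IS (interdaily stability) is computed on the raw count channel binned to 60
minutes: `IS = (N·Σ_h(x̄_h − x̄)²)/(p·Σ_i(x_i − x̄)²)` over p = 24 hour-of-day
bins; 1 for a perfectly repeating day. IV (intradaily variability) is the
normalized first-difference variance at native 1-min resolution:
`IV = (N·Σ(x_i − x_{i−1})²)/((N−1)·Σ(x_i − x̄)²)` ∈ [0, 4], ≈2 for white
noise. Both are *undefined* (an error, not 0) for constant input. M10/L5 are
the best contiguous 10-h/5-h windows of the average 24-h profile with
circular wrap-around; RA = (M10−L5)/(M10+L5). The multi-bin variants
ISm/IVm average IS/IV over all bin widths up to 60 min that divide the day
evenly — one interpretation of an underspecified convention, exposed as a
parameter. Weekend means use Saturday+Sunday of the recording's local
calendar; timestamps are wall-clock with no DST handling (the synthetic
clock is fixed-offset, and the week grid must stay uniform).

## The clock

An InceptionTime-style regressor: N Inception blocks (default 9), each a
1×1 bottleneck convolution followed by parallel same-padded convolutions at
kernel sizes {9, 19, 39} epochs (≈10/20/40-minute receptive fields) plus a
max-pool branch with a 1×1 convolution, concatenated and layer-normalized
(normalization across channels per time position — a deliberate swap from
batch normalization), with a residual 1×1-conv shortcut every third block.
Global average pooling over time yields the embedding (default 128-d, the
branch width being embed_dim/4); a linear(128→64)–ReLU–linear(64→1) head
outputs GA. The loss is

    L_m = λ₂ · (1/m) · Σ (y − ŷ)² + λ₁ · Σ |y − ŷ|,   λ₁ = 1e−6, λ₂ = 0.001,

optimized with Adam; a reduce-on-plateau schedule (factor 0.5, patience 10
epochs on validation loss) engages only after a minimum of 200 epochs, and
the best-on-validation parameters are retained. λ₂ additionally acts as Adam
L2 weight decay (both readings of the regulariser are stated in the source
formulation; both are implemented and the flag `weight_decay_as_lambda2`
chooses — see Numerical notes for the default rationale).

The network, backpropagation and Adam are implemented directly in numpy
(channels-first activations; convolutions as per-tap BLAS matmuls). This
keeps the package dependency-light and — importantly — gives exact input
gradients for attribution. Gradients are verified against finite differences
in float64 in the test suite.

### Augmentation

Five operators at the stated defaults: none; jitter (i.i.d. N(0, 0.03²));
scaling (one α ~ N(1, 0.2²) per channel — "per series" read as per channel
of a multivariate sample, matching the univariate convention of the
augmentation literature; α is not clipped, negative draws are a ~3e−7
event); window warping (a random 10% window stretched or compressed by 2 or
1/2 via linear interpolation, then the series re-interpolated to length L);
slicing (a random contiguous 90% crop re-interpolated to L). Rotation is
excluded by design. Selection schemes: one random operator or all operators
in random order, refreshed per epoch or per mini-batch; the default is one
random operator per epoch, and the draw is a pure function of
(seed, epoch[, batch]) so the full augmentation stream is reproducible and
auditable from the training history. At inference, test-time augmentation
averages predictions over the operator set with one fixed-seed draw per
stochastic operator (n_draws configurable).

## Error analysis

Signed error e = ŷ − y partitions samples into higher (e > τ), lower
(e < −τ) and low-error groups; τ is either fixed (10 weeks) or "balance"
(0.5-week grid minimizing |#higher − #lower|, ties to the smaller τ).
Enrichment of a variable in a group compares the observed count with
`expected = total_count × group_size / n`; the effect is (O/E − 1)×100.
Significance comes from permutations of group labels preserving group
sizes (≥1000 iterations enforced unless forced). Two p-value constructions
are provided: the default follows the stated procedure literally — a
Mann-Whitney U test of bootstrap draws of the observed statistic against
the permutation null — while `method="tail"` is the conventional exact
permutation p-value (r+1)/(n+1), which is the calibrated choice and the one
used wherever calibration matters. Cross-group variable screening uses
ANOVA across error groups (Kruskal–Wallis in the two-group cohort-table
mode) for continuous variables and Fisher's exact (2×2) or χ² tests for
categorical ones, Bonferroni-corrected; degenerate variables are reported
untestable rather than dropped. The correlation network has one node per
variable (size −log10 corrected p) and an edge wherever the mixed
association score reaches 0.6; using the mixed score (not plain ρ) lets
categorical variables enter the graph.

## Mixed association and evaluation metrics

Pairwise association on [0, 1] by declared kind: |Spearman ρ|
(continuous–continuous), |Goodman–Kruskal γ| (ordinal–ordinal), Cramér's V
(nominal pairs — a concrete choice for the unstated "scaled χ²"), and for
categorical–continuous pairs a logistic regression on the continuous
variable with SMOTE rebalancing inside CV folds only, scored as
2·|AUROC − ½| (micro one-vs-rest when multiclass; for binary targets
micro-averaging reduces to plain AU-ROC). Constant variables yield an
explicitly undefined score. SMOTE is implemented as k-NN convex-combination
oversampling of minority classes. Evaluation metrics: adjusted balanced
accuracy (mean over classes of (sensitivity+specificity)/2; a class with no
negatives contributes its sensitivity alone), adjusted AU-PRC
((AUPRC − prevalence)/(1 − prevalence), clipped below at 0 with the raw
value reported), and predictability — a k-NN model (k=5) under 5-fold
patient-grouped CV, scored as AU-ROC for classification and |Spearman ρ|
for regression.

## Attribution

Integrated gradients with the all-zero signal as baseline (zero counts on
the log scale = "no activity", the natural reference; no baseline is
prescribed in the source). Quadrature: with normalization layers the path
integrand g(α) = df(b + α(x−b))/dα is steepest near the baseline, and the
textbook uniform right-endpoint grid needs ~10⁶ steps to reach 0.1%
completeness there. The default grid is therefore a midpoint rule under the
substitution α = u³, which concentrates nodes near α = 0 and meets the
completeness axiom |ΣIG − (f(x) − f(b))| < 0.1%·|f(x) − f(b)| at 256 steps
(default n = 64 for exploratory maps); the uniform right-endpoint grid is
available as an option. Importance is |IG| summed over both channels (activity-only is an
option). Zero-proportions use tolerance 1e−8 exactly. Clock strata:
morning 06–12, evening 18–24, daytime 06–18 (configurable; the labels are
used without definition in the source figures).

## Phenotyping

DTW is the classic dynamic-programming recursion with squared local cost
and unit steps (numba-compiled), validated against exhaustive warping-path
enumeration on short series. Full-resolution weekly DTW is O(L²) and
unnecessary; the distance-matrix helper downsamples to 30-minute bin means
(length 336) by default, with the bin width configurable. Embeddings are
compared by Manhattan distance. The neighbor graph uses Gaussian affinities
`w_ij = exp(−d_ij²/(σ_i σ_j))` with local bandwidth σ_i = distance to the
k-th neighbor (k = 15) — the standard neighbor-graph reading of an
"affine transformation" into a graph — and Leiden modularity communities at
resolution 1.0 with a fixed seed; a degenerate all-zero distance matrix is
one community by definition. Cluster×variable-level enrichment reuses the
observed/expected machinery with exact permutation tails and Bonferroni
correction.

## The synthetic cohort

The generator emulates the study conditions — by default 1,083 patients,
1–3 week-long measurements each at 1-minute epochs, GA uniform on [5, 40]
weeks, a 14.1% PTB+ subgroup — with a mechanism sufficient for testing, not
a physiological model:

- base day: rectangular wake 07:00–23:00 at `diurnal_amplitude` (150)
  counts over a nocturnal floor of 2, smoothed with a 60-minute kernel
  (produces realistic M10/L5 contrast without committing to a parametric
  family);
- GA effect: daily rest grows by `ga_rest_slope/7` minutes per GA week
  (default 15 weekly minutes per week — increasing rest with advancing
  pregnancy), implemented by symmetric shrinking of the wake window;
- counts: `round(profile × lognormal(0, 0.35))` — right-skewed nonnegative
  integers, as piezo counts are; light = clipped 0.5×activity + noise;
- PTB+ disruption (strength 0.6): per day, Poisson(3·s) daytime rest bouts
  of 20–70 min (fatigue naps), Poisson(4·s) nocturnal activity bouts, and
  7-fold inflated day-to-day phase jitter. This lowers interdaily stability
  and biases apparent rest upward, so a rest-based clock over-predicts GA
  for PTB+ — the planted analogue of the higher-than-actual error
  enrichment;
- metadata: six variable categories (sleep, activity, stress, comorbidity,
  social, outcome) with planted monotone links to the fragmentation level
  and two deliberately null social variables.

What passing tests on this cohort do *not* show: that a clock trained on
real pregnancies attains any particular accuracy. The generator has a
single dominant GA mechanism (rest duration) and clean metadata; real
cohorts carry device artefacts, behavioural confounders and far weaker
signal (the reference cohort's error is several weeks). The synthetic
cohort demonstrates that the pipeline recovers planted structure with the
correct sign and calibrated statistics, at desk scale.

## Numerical notes and desk-scale configuration

- Determinism: every stochastic component takes an explicit seed; a fixed
  seed reproduces cohorts, initial parameters, the augmentation stream and
  fitted results bit-identically on one platform. Compute dtype is float32
  (float64 available for gradient checking).
- Output-bias initialization: the prediction head's bias starts at the
  train-mean GA. With channelwise layer normalization the initial
  embedding is almost sample-independent, so early optimisation otherwise
  spends hundreds of Adam steps traversing the offset; mean-initialization
  removes that plateau.
- Weight decay: with the printed loss, gradients carry the λ₂ = 1e−3
  factor while Adam normalizes steps per-parameter, so an additional L2
  decay of the same λ₂ is *not* negligible relative to the data term.
  Both readings are implemented; `weight_decay_as_lambda2` defaults to the
  setting validated by the parameter-recovery suite.
- Desk-scale runs (tests, examples) use a reduced clock: weekly signals
  bin-averaged 7× to length 1,440, 2 blocks, 32-d embedding, full-batch
  optimisation at learning rate 0.02–0.03, 300 epochs on 120 patients. Full
  batches matter at this scale: escaping the layer-norm plateau needs a
  consistent gradient direction, and with only ~70 training samples
  minibatch noise keeps Adam's second-moment estimate inflated enough to
  stall the escape within the epoch budget. The full-length L = 10,080,
  9-block, 128-d default remains available.
- Degenerate inputs raise or are reported as undefined (constant series in
  IS/IV, zero expected counts, single-class labels, all-missing columns) —
  never silently coerced to 0.

## Known limitations

- The numpy engine is single-process and CPU-bound; full-scale training
  (9 blocks, L = 10,080, thousands of samples) is possible but slow.
- Sleep scoring is raw per-epoch Oakley; bout aggregation and rescoring
  rules are out of scope, and all sleep/wake stratifications consume the
  raw epoch mask.
- The Mann-Whitney permutation p-value construction is implemented for
  fidelity but is not exactly calibrated; the tail method is used where
  calibration is asserted.
- DTW clustering at full minute resolution is quadratic; the default
  30-minute binning is a tractability choice, not part of the method
  definition.
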