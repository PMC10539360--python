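# actiga

A gestational-age "clock" and risk-phenotyping toolkit for week-long
wrist-worn actigraphy during pregnancy.

## The problem

Pregnant individuals wearing a wrist actigraph produce minute-epoch,
two-channel recordings (piezoelectric activity counts and light in lux).
Classic nonparametric circadian summaries — interdaily stability (IS),
intradaily variability (IV), relative amplitude (RA) — barely separate
pregnancies that end preterm (PTB+) from those that reach term. `actiga`
instead treats the whole week as the unit of analysis:

1. **Clock.** An Inception-block 1-D convolutional regressor maps a
   log-transformed 2 × 10,080 weekly matrix to a scalar gestational age
   (GA, weeks), trained with the composite loss
   `L_m = λ₂·(1/m)·Σ(y−ŷ)² + λ₁·Σ|y−ŷ|` (λ₁ = 1e−6, λ₂ = 0.001), Adam,
   reduce-on-plateau scheduling (patience 10 after a 200-epoch minimum),
   and five time-series augmentations (none / jitter σ=0.03 / per-channel
   scaling α~N(1,0.2²) / 10% window warping by 2 or ½ / 90% slicing) with
   test-time averaging.
2. **Error as signal.** The signed error ŷ−y partitions samples into
   higher-/lower-/low-error groups at a threshold τ (10 weeks, or balanced).
   Clinical variables are screened for enrichment via observed/expected
   ratios — effect = (O/E − 1)×100 — with label-permutation significance
   (≥1000 iterations), ANOVA/Kruskal–Wallis/Fisher/χ² cross-group tests,
   Bonferroni correction, and a variable correlation network (edges at
   mixed-association ≥ 0.6).
3. **Attribution.** Integrated gradients give per-minute importance
   (|IG| summed over channels), stratified by Oakley sleep/wake (θ=80),
   time-of-day, and weekday/weekend.
4. **Phenotyping.** The clock's 128-d global-average-pooled embedding
   (a 160× compression of the week) feeds a Manhattan-distance kNN graph
   with Leiden community detection; clusters are screened for metadata
   enrichment and compared against DTW clustering of the raw series and
   kNN "predictability" of each metadata variable under patient-grouped
   5-fold cross-validation.

No real cohort is bundled. A synthetic-cohort generator plants a GA-dependent
rest drift and a rhythm-disrupted PTB+ subgroup so that every module —
through the full pipeline — is testable from scratch.

## Worked example

```python
import actiga as ag
from actiga import io as aio
from actiga.simulate import SimulationConfig, generate_cohort
from actiga.clock import ClockConfig, GestationalAgeClock
from actiga.augment import AugmentationScheme

cfg = SimulationConfig(n_patients=120, measurements_per_patient=1, days=8, seed=11)
recordings, metadata, truth = generate_cohort(cfg)
samples = [aio.make_sample(r, m.sample_id, m.ga_weeks)
           for r, m in zip(recordings, truth.measurements.itertuples())]
dataset = aio.split_by_patient(samples, (0.6, 0.15, 0.25), seed=11)

clock = GestationalAgeClock(
    dataset,
    ClockConfig(n_blocks=2, embed_dim=32, bottleneck_dim=12, kernel_sizes=(9, 19, 39),
                learning_rate=0.03, min_epochs=200, max_epochs=300,
                batch_size=128, input_length=1440, seed=11),
    AugmentationScheme(seed=11),
    downsample=7,          # 10,080-min week -> 1,440 seven-minute bins
)
results = clock.fit()
print(results.summary())
```

prints (desk-scale configuration; ~7 minutes on one CPU):

```
Gestational-age clock  (Inception-block 1-D conv regressor)
============================================================
blocks: 2   embedding: 32-d   kernels: (9, 19, 39)
parameters: 14,305
loss: lambda2*MSE + lambda1*sum|r|  (lambda1=1e-06, lambda2=0.001)
epochs run: 300   best val loss: 0.025248
train: n=72   MAE=4.44 weeks  Spearman rho=0.933
  val: n=18   MAE=4.16 weeks  Spearman rho=0.950
 test: n=30   MAE=4.55 weeks  Spearman rho=0.946
```

The held-out Spearman ρ = 0.95 shows the clock recovered the planted
GA–rest drift; the residual error is dominated by the disrupted PTB+
subgroup, whose GA is systematically over-predicted:

```python
from actiga.enrichment import assign_error_groups, oe_effect
records = results.predict_all()
grouping = assign_error_groups(records, tau="balance")
# PTB+ samples are enriched in the higher-than-actual error group
# (oe_ratio > 1) and depleted in the lower-than-actual group (< 1).
```

On this cohort the balanced threshold is τ = 4.5 weeks and the PTB+
observed/expected ratio is 2.12 in the higher-than-actual group versus
0.85 in the lower-than-actual group (permutation p = 0.009) — the planted
direction.

## Command line

A thin CLI wraps the library:

```bash
actiga simulate --out runs/sim --n-patients 40 --seed 1
actiga run-all --config config.yaml --out runs/full
actiga metrics --manifest runs/full/samples/manifest.csv --out metrics.csv
```

Subcommands: `simulate | preprocess | metrics | train | predict |
analyze-errors | explain | associate | phenotype | run-all | validate`.
See `docs/methods.md` for the scientific details and design decisions.
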