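# Methods

## Problem

Glaucoma progressively thins the retinal nerve fiber layer (RNFL). Spectral-
domain OCT measures this as a circumpapillary profile: 768 equally spaced
thickness samples (μm) on a circle around the optic nerve head, plotted in
TSNIT order (temporal → superior → nasal → inferior → temporal). `rnflcast`
forecasts the profile at a future visit — either all 768 samples or the 7
global/sectoral averages (G, T, TS, TI, N, NS, NI) — from the profiles of
two earlier visits, and evaluates forecasts with the clustered structure of
longitudinal eye data taken seriously.

## Data model and preprocessing

A scan is a 768-vector with a missing-sample mask; an eye is a time-ordered
series of scans with diagnosis (normal / suspect / glaucoma), baseline 24-2
visual-field mean deviation (MD, dB), sex, race and age metadata.

Preprocessing:

* **Repair.** Missing or invalid (non-finite, negative) samples are filled
  by linear interpolation between the nearest valid samples on each side,
  *circularly* across the 0/767 seam — the scan is a ring, so a gap touching
  index 0 borrows from index 767's side. A profile with all 768 samples
  invalid cannot be repaired and is excluded.
* **Truncation.** After filling, values above 300 μm (segmentation
  blow-ups) are set to exactly 300 μm; the bound is inclusive. Valid
  in-range samples are never altered, so preprocessing is idempotent.
* **Laterality.** Left eyes (OS) are mirrored into the right-eye (OD) frame
  at ingest by index reversal about the temporal anchor (index 0 fixed,
  sample *i* → 768 − *i* mod 768), an involution. Models therefore see one
  anatomical orientation.

### Sector convention

The instrument convention names the sectors but not the machine-readable
boundaries, so the package fixes one layout explicitly: with the temporal
anchor at index 0 and 768/360 ≈ 2.133 samples per degree, T spans 90°
centered on the anchor, TS/NS/NI/TI span 45° each, and N spans 90° centered
nasally. All boundaries land on exact integers:

| sector | degrees | indices | size |
|---|---|---|---|
| T | 315–45 | 672–767, 0–95 | 192 |
| TS | 45–90 | 96–191 | 96 |
| NS | 90–135 | 192–287 | 96 |
| N | 135–225 | 288–479 | 192 |
| NI | 225–270 | 480–575 | 96 |
| TI | 270–315 | 576–671 | 96 |

The six sectors partition the ring, so the size-weighted sector mean equals
the global mean G — a property the test suite asserts to 1e-9 μm.

## Triplets and the leakage contract

The supervised unit is a **triplet**: scans from three visits of one eye,
the first two as inputs and the third as the target, with each consecutive
inter-visit gap in [183, 548] days (≈ 6–18 months, inclusive; months are
converted at 183/548 days because the data model stores days).

* **Training** enumerates *every* gap-valid ordered visit triple and, when
  a visit holds repeated scans, every scan permutation — maximizing the
  training set.
* **Testing** first retains a single seeded-random scan per visit, then
  enumerates triples on the retained scans, then enforces that the map
  (input1, input2) → target is a function: when one retained input pair
  admits several gap-valid targets, the earliest target is kept and later
  ones are dropped (logged). The tie-break is a package convention; only
  uniqueness is required.
* **Partitioning** is at patient level (default 80/20, half-up rounding of
  the train count), both eyes of a patient travelling together, so no
  participant contributes to both sides. A validation subset (default 10%
  of train_val patients) can be carved out the same way for CNN monitoring.
* Scans flagged `quality_ok = False` are excluded before any enumeration.

## Models

All methods consume the two preprocessed input profiles only — no clinical
or demographic covariates — and share one train/predict contract
(`RNFLForecastModel(...).fit()` → `RNFLForecastResults`).

* **carry_forward** — the clinical no-change comparator: the prediction is
  input2 exactly (or its sector averages).
* **LR / SVR / GBR** — flat regressors on the 1536-element concatenation
  (input1 then input2). Each of the 768 (or 7) output dimensions is an
  independent single-output regression on shared features; for LR the
  joint multi-output least-squares fit is used since it coincides with
  per-output fits. SVR uses an RBF kernel with C = 1 and ε = 0.01 on
  inputs and targets divided by 100 (ε = 0.01 in scaled units is a 1 μm
  insensitive tube; a tube an order of magnitude wider than the task's
  error scale would make the method insensitive to exactly the differences
  being studied). GBR defaults to 300 trees, depth 3, learning rate 0.05.
  LR and GBR run on raw μm.
* **CNN** — a two-channel 1D convolutional network on the (2 × 768) stack:
  four convolution → ReLU → max-pool(2) blocks (channels 16/32/64/64,
  kernels 7/5/5/3, zero 'same' padding), flatten, one 768-unit
  fully connected ReLU layer, and a linear head of 768 or 7 outputs.
  Training: Adam at learning rate 0.001, mean-squared-error loss, 100
  epochs by default, batch 32, inputs and targets divided by 100. The
  engine is implemented in numpy with hand-derived backward passes, which
  makes training bit-reproducible under a fixed seed (verified by a
  finite-difference gradient check in the tests).

  *Augmentation.* Each training draw applies one random integer circular
  shift in [−5, +5] to both input channels **and**, in 768-vector mode, the
  same shift to the target — shifting inputs but not pointwise targets
  would corrupt supervision. Circular shifts match the ring topology. In
  sector mode shifts are disabled because sector labels are not
  shift-equivariant.

  *FC width.* Narrow hidden layers (e.g. 256→128) bottleneck the 768-dim
  output and converge an order of magnitude slower on a noise-free
  near-identity task; a single 768-unit hidden layer reached held-out MAE
  ~0.7 μm where the narrow stack plateaued near 4 μm. The wide single
  layer is therefore the default; all internals are overridable.

## Evaluation

Pooled over every element of every evaluated triplet:

* MAE = mean |ŷ − y| (μm);
* MRE = 100 · mean(|ŷ − y| / y) (%), excluding elements with y < 1 μm
  (near-zero denominators explode the ratio; exclusions are counted in the
  report) — MAE and R² keep all elements;
* R² = 1 − SSres/SStot with one SStot about the grand mean of y per
  (model, stratum) cell. R² is therefore invariant when predictions and
  targets are translated together.

Uncertainty and testing respect patients as the independent unit:

* **95% CIs**: nonparametric patient-level bootstrap (patients resampled
  with replacement, all their triplets carried along), percentile interval,
  1000 resamples, seeded.
* **Model comparisons**: two-sided sign-flip permutation of per-triplet MAE
  differences with patient-level blocks (all of a patient's triplets flip
  together), 10,000 permutations. The p-value counts permuted |T| ≥
  observed |T| plus the identity, so identical error sets give p = 1.
* **Subgroup comparisons**: patient-level group-label permutation.
* No multiple-testing correction is applied; the report states how many
  comparisons were made.

Strata: overall; sex; the two largest self-reported race groups; diagnosis;
glaucoma severity by the MD dichotomy (mild: MD > −6.0 dB; moderate to
advanced: MD ≤ −6.0 dB); and a median split on baseline age when ages are
present. Empty strata report n = 0 with null metrics rather than erroring.

## Synthetic cohort generator

Real longitudinal RNFL cohorts of this kind are not public, so the
generator produces cohorts with the statistical structure the pipeline
assumes, plus the noiseless truth real data never offers:

* **Shape.** Noiseless truth per eye = temporal baseline (~60 μm) + two
  Gaussian humps (amplitude ~80 μm, width ~55 samples) at the superior and
  inferior poles (indices 192 and 576), with per-eye jitter in level,
  amplitude and hump position; suspect/glaucoma eyes carry a reduced
  amplitude factor. These defaults put healthy baseline sector means in the
  ranges published for comparable cohorts; they are package choices, not
  measured values, and all are config-overridable.
* **Progression.** Each eye declines linearly at a diagnosis-dependent
  global rate (defaults: normal −0.3, suspect −0.6, glaucoma −1.5 μm/yr,
  eye-level sd 0.25) — values typical of the progression literature, since
  the source cohort publishes no rates. Half of glaucoma eyes (default)
  additionally carry a focal wedge arc (40–90 samples) thinning 2 μm/yr
  faster. Thickness is floored at 50 μm (an "RNFL floor" below which
  thinning is not measurable); the floor never raises a baseline already
  below it, so truth is non-increasing whenever all rates are ≤ 0.
* **Measurement.** Observed = truth + noise of total sd 3 μm, mixed from a
  ring-correlated component (white noise smoothed with a circular Gaussian
  kernel, correlation length 8 samples) and a white per-sample component
  (30% of the variance). The white component reflects per-sample
  segmentation/speckle jitter; a purely smoothed noise model would be
  unrealistically rank-deficient at high spatial frequency and makes flat
  1536-feature regression numerically degenerate. Artifacts: missing
  samples (rate 0.002), >300 μm spikes (rate 0.0005, bounded by 400 μm),
  and occasional bad-quality scans (2%).
* **Visits.** Semi-annual (183 ± 25 days), 3–6 visits per eye, 15% of
  visits with a repeated scan — matching the ~4 scans/eye scale of the
  motivating studies. ~74% of patients contribute both eyes.
* **Metadata.** Sex (54% female), race (55/33/10/2% white/black/asian/
  other), age ~ N(68.8, 8) years; MD baseline by diagnosis (normal −0.5 ±
  1, suspect −1.5 ± 1.5, glaucoma −4.5 ± 4 dB) so both severity strata are
  populated.
* **Determinism.** One global seed drives per-patient/per-eye
  `SeedSequence` child streams, so enlarging the cohort never reshuffles
  existing eyes.

What the generator does **not** emulate: raw OCT speckle or B-scan imagery,
device quality scores, visual-field test-point maps, floor-related
measurement-variance changes, or inter-device differences. Passing tests on
synthetic cohorts therefore demonstrate the pipeline's contracts
(leakage-freedom, oracle-exact sectorization, rule recovery, calibrated
inference) and qualitative model behavior — not clinical accuracy on real
eyes.

## The standard benchmark and its known result

`rnflcast.benchmark.run_benchmark` fixes one recipe: 200 patients at
generator defaults, 80/20 patient split, all five methods, held-out pooled
metrics. Reduced desk-scale budgets: GBR runs 60 trees, learning rate 0.1,
4% feature subsampling, 50% row subsampling per output; the CNN trains 25
epochs. At this scale the suite asserts the qualitative ordering: SVR, GBR
and the CNN all beat the carry-forward comparator, and GBR/CNN beat LR.

Ordinary least squares itself does **not** beat carry-forward here, and the
package documents this as a finding rather than hiding it: with only the
two thickness vectors as features (p = 1536), noisy inputs and patient-level
splits, OLS sits in the regime where estimation variance (peaking near
n ≈ p, the double-descent region) exceeds the few-μm signal; measured
held-out MAE stays above the comparator for every training-set size a
single CPU can reach. This mirrors the poor flat-LR behavior reported for
this task on real data.

## Numerical and degenerate-input conventions

* Truncation bound inclusive at 300 μm; MRE denominator floor 1 μm;
  severity threshold: mild ⇔ MD > −6.0 dB.
* Split rounding: half-up on the train count; both partitions forced
  non-empty.
* Test-triplet conflict tie-break: earliest target wins.
* All-identical SVR feature rows produce a warning, not a silent constant.
* Non-finite CNN loss aborts training with a diagnostic.
* Bootstrap/permutation procedures reject single-patient inputs and empty
  groups with explicit messages.

## Known limitations

* The CNN at the reduced 25-epoch budget is a few tenths of a μm behind
  GBR/SVR on the benchmark's fixed seed and its accuracy varies by ~1 μm
  across cohort draws — on some draws it trails even carry-forward. The
  full-scale published result this mirrors has the CNN leading on the
  sector task; closing that gap needs the full 100-epoch budget (and
  ideally several training-seed restarts), which the desk-scale benchmark
  deliberately does not spend. Synthetic profiles are also smoother than
  real ones, which narrows the advantage convolutional features can offer.
* Sector boundaries are a declared convention; other instruments shift the
  temporal anchor or sector widths, and results are only comparable under
  one fixed convention.
* The generator's linear-decline-with-floor model omits visit-to-visit
  clinical variability (media opacity, centration) that real cohorts show.
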