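# rnflcast

Forecasting circumpapillary retinal nerve fiber layer (RNFL) thickness from
longitudinal OCT imaging.

Glaucoma management leans on OCT circle scans around the optic nerve head:
768 equally spaced RNFL thickness samples (μm) in TSNIT order, usually
summarized as a global mean plus six sector averages (G, T, TS, TI, N, NS,
NI). Because glaucomatous thinning is slow, clinicians wait across visits
to see it. `rnflcast` is for researchers studying whether the *future*
profile can be predicted from the recent past: given the profiles at two
prior visits (6–18 months apart), it forecasts the full 768-point profile
— or the 7 sector averages — at a later visit, and evaluates forecasts
against a carry-forward comparator with the clustered structure of eye data
(triplets within eyes within patients) taken seriously.

The supervised unit is the **triplet** (input visit 1, input visit 2,
target visit), built leakage-free: training/test partitions are at patient
level (both eyes travel together), training enumerates all gap-valid scan
permutations, and the test set retains one random scan per visit and keeps
the (input1, input2) → target map a function. Models under one
fit/predict contract:

* `carry_forward` — prediction ≡ input2 (the clinical no-change baseline);
* `lr`, `svr`, `gbr` — flat regressors on the 1536-element concatenation
  of the two input profiles, one independent regression per output;
* `cnn` — a two-channel 1D convolutional network on the (2 × 768) stack:
  4 × (conv → ReLU → max-pool), a 768-unit fully connected layer, linear
  head; Adam (lr 0.001), MSE loss, ±5-sample circular shift augmentation.
  Implemented in numpy with hand-derived backprop, so training is
  bit-reproducible under a fixed seed.

Real cohorts of this kind are not public, so the package includes a
synthetic longitudinal cohort generator (double-hump TSNIT shape,
diagnosis-dependent linear thinning with focal wedges and an RNFL floor,
ring-correlated measurement noise, missing-sample and spike artifacts,
demographic and visual-field metadata) that exposes the noiseless ground
truth for oracle testing. See `docs/methods.md` for the model and every
numerical convention.

## Worked example

```python
from rnflcast import (CohortConfig, generate_cohort, preprocess_cohort, make_split,
                      build_training_triplets, build_test_triplets,
                      RNFLForecastModel, triplets_to_arrays, compute_metrics)

cohort, truth = generate_cohort(CohortConfig(n_patients=40, seed=11))
pre = preprocess_cohort(cohort)                      # repair, truncate, mirror OS->OD
split = make_split(pre, train_fraction=0.8, seed=11)
train = build_training_triplets(split.select(pre, "train_val"))
test = build_test_triplets(split.select(pre, "test"), seed=11)
print(f"{len(pre)} eyes, {len(train)} training and {len(test)} test triplets")

res = RNFLForecastModel(train, method="gbr", target_mode="sector7",
                        hyperparams={"n_estimators": 60, "max_features": 0.04}).fit(seed=0)
print(res.summary())

_, _, y = triplets_to_arrays(test, "sector7")
m = compute_metrics(res.predict_triplets(test), y)
cf = RNFLForecastModel([], method="carry_forward", target_mode="sector7").fit()
m_cf = compute_metrics(cf.predict_triplets(test), y)
print(f"GBR           MAE {m.mae_um:.2f} um  MRE {m.mre_percent:.2f} %  R2 {m.r2:.3f}")
print(f"carry-forward MAE {m_cf.mae_um:.2f} um  MRE {m_cf.mre_percent:.2f} %  R2 {m_cf.r2:.3f}")
```

prints

```
67 eyes, 298 training and 23 test triplets
RNFL Forecast Results
=====================================================
method:            gbr
target mode:       sector7 (7 outputs)
training triplets: 298
seed:              0
...
GBR           MAE 1.72 um  MRE 1.97 %  R2 0.986
carry-forward MAE 1.29 um  MRE 1.48 %  R2 0.992
```

MAE/MRE/R² are pooled over all sector values of all test triplets. At this
small size carry-forward is still the method to beat on sector averages —
averaging ~100 samples suppresses measurement noise, so the no-change
baseline errs only by the true one-year thinning (~1–1.5 μm). The picture
changes on the full 768-point task at the standard benchmark scale (200
patients): there SVR and GBR beat carry-forward, the reduced-epoch CNN
usually does, and ordinary least squares on 1536 raw features does not —
a documented finding, not a bug (see `docs/methods.md`).

The same pipeline is scriptable from the shell:

```bash
rnflcast simulate --n-patients 40 --seed 11 --out runs/sim
rnflcast run-all --config config.yaml --out runs/full
```

`run-all` writes the cohort CSVs, split and triplet manifests, model
artifacts, predictions, a stratified evaluation report (overall / sex /
race / diagnosis / MD-severity cells with patient-level bootstrap CIs and
permutation p-values) and overlay/scatter figures into one
self-describing run directory.

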