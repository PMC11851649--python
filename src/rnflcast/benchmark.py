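"""The package's standard synthetic forecasting benchmark.

One fixed experimental recipe — generate a 200-patient synthetic cohort at
the generator defaults (glaucoma global slope −1.5 μm/yr, measurement noise
3 μm), split 80/20 at patient level, build training/test triplets, train
every requested method, and score held-out predictions — so that model
comparisons quoted anywhere in the package all come from the same place.

Desk-scale budgets: the gradient-boosting ensemble runs with 60 trees,
learning rate 0.1, 4% feature subsampling and 50% row subsampling per output
dimension, and the CNN trains for 25 epochs. These are the package's own
reduced problem sizes for a laptop-class single CPU; the model defaults
(300 trees, 100 epochs) remain available through ``hyperparams``.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .evaluation import compute_metrics
from .models import RNFLForecastModel, triplets_to_arrays
from .profiles import preprocess_cohort
from .synthetic import CohortConfig, generate_cohort
from .triplets import build_test_triplets, build_training_triplets, make_split

BENCHMARK_N_PATIENTS = 200
BENCHMARK_GBR_PARAMS = {
    "n_estimators": 60,
    "learning_rate": 0.1,
    "max_features": 0.04,
    "subsample": 0.5,
}
BENCHMARK_CNN_EPOCHS = 25


def run_benchmark(
    seed: int,
    methods: Sequence[str] = ("carry_forward", "lr", "svr", "gbr", "cnn"),
    target_mode: str = "vector768",
    n_patients: int = BENCHMARK_N_PATIENTS,
    cnn_epochs: int = BENCHMARK_CNN_EPOCHS,
) -> dict:
    """Run the standard benchmark and return per-method held-out metrics.

    Returns a dict with cohort/triplet counts and, per method, pooled MAE
    (μm), MRE (%) and R² on the held-out test triplets, plus the per-triplet
    MAE arrays needed for paired comparisons.
    """
    config = CohortConfig(n_patients=n_patients, seed=seed)
    cohort, _ = generate_cohort(config)
    pre = preprocess_cohort(cohort)
    split = make_split(pre, train_fraction=0.8, seed=seed)
    train = build_training_triplets(split.select(pre, "train_val"))
    test = build_test_triplets(split.select(pre, "test"), seed=seed)
    _, _, y = triplets_to_arrays(test, target_mode)

    hyperparams: dict[str, dict] = {
        "gbr": dict(BENCHMARK_GBR_PARAMS),
        "cnn": {"epochs": cnn_epochs},
    }
    out: dict = {
        "seed": seed,
        "target_mode": target_mode,
        "n_eyes": len(pre),
        "n_train_triplets": len(train),
        "n_test_triplets": len(test),
        "methods": {},
    }
    for method in methods:
        model = RNFLForecastModel(
            [] if method == "carry_forward" else train,
            method=method,
            target_mode=target_mode,
            hyperparams=hyperparams.get(method),
        )
        res = model.fit(seed=seed)
        pred = res.predict_triplets(test)
        m = compute_metrics(pred, y)
        out["methods"][method] = {
            "mae_um": m.mae_um,
            "mre_percent": m.mre_percent,
            "r2": m.r2,
            "per_triplet_mae": np.abs(pred - y).mean(axis=1),
            "fit_seconds": res.diagnostics.get("fit_seconds"),
        }
    return out
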