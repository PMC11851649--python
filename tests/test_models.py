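"""Forecasting models: featurization, rule recovery, the carry-forward
comparator, CNN training contract and model persistence."""

import numpy as np
import pytest

from rnflcast import (
    RNFLForecastModel,
    RNFLProfile,
    VisitScan,
    build_test_triplets,
    build_training_triplets,
    compute_metrics,
    featurize_flat,
    generate_cohort,
    make_split,
    preprocess_cohort,
    sector_means,
    triplets_to_arrays,
)
from rnflcast.models import _circular_shift_batch
from rnflcast.triplets import Triplet
from conftest import make_noise_free_config, make_progressing_noise_free_config


def _triplet_from_values(v1, v2, vt, eye_id="E1", patient_id="P1"):
    def scan(values, t):
        return VisitScan(patient_id=patient_id, eye_id=eye_id, laterality="OD",
                         visit_time=t, scan_index_within_visit=0,
                         profile=RNFLProfile(values=np.asarray(values, dtype=float)))
    return Triplet(input1=scan(v1, 0), input2=scan(v2, 200), target=scan(vt, 400))


def _split_triplets(cohort, seed=0):
    pre = preprocess_cohort(cohort)
    split = make_split(pre, 0.8, seed=seed)
    train = build_training_triplets(split.select(pre, "train_val"))
    test = build_test_triplets(split.select(pre, "test"), seed=seed)
    return train, test


def _linear_rule_triplets(triplets):
    """Replace each target profile by 2*input2 - input1 (exact linear rule)."""
    out = []
    for t in triplets:
        target_values = np.clip(2 * t.input2.profile.values - t.input1.profile.values, 0, 300)
        target = VisitScan(patient_id=t.patient_id, eye_id=t.eye_id,
                           laterality=t.target.laterality,
                           visit_time=t.target.visit_time,
                           scan_index_within_visit=t.target.scan_index_within_visit,
                           profile=RNFLProfile(values=target_values))
        out.append(Triplet(input1=t.input1, input2=t.input2, target=target))
    return out


# -- featurization -----------------------------------------------------------

def test_flat_row_orders_input1_then_input2():
    t = _triplet_from_values(np.full(768, 100.0), np.full(768, 80.0), np.full(768, 70.0))
    row, y = featurize_flat(t)
    assert np.array_equal(row[:768], np.full(768, 100.0))
    assert np.array_equal(row[768:], np.full(768, 80.0))
    assert np.array_equal(y, np.full(768, 70.0))


def test_sector7_target_is_sector_means_oracle(rng):
    vt = rng.uniform(30, 200, 768)
    t = _triplet_from_values(np.full(768, 100.0), np.full(768, 90.0), vt)
    _, y = featurize_flat(t, target_mode="sector7")
    expected = sector_means(RNFLProfile(values=vt)).as_array()
    np.testing.assert_allclose(y, expected, atol=1e-12)
    const = _triplet_from_values(np.full(768, 100.0), np.full(768, 90.0), np.full(768, 90.0))
    _, y_const = featurize_flat(const, target_mode="sector7")
    assert y_const == pytest.approx(np.full(7, 90.0))


def test_featurize_rejects_unpreprocessed():
    bad = np.full(768, 100.0)
    bad[5] = np.nan
    t = _triplet_from_values(bad, np.full(768, 90.0), np.full(768, 80.0))
    with pytest.raises(ValueError, match="preprocess"):
        featurize_flat(t)


# -- carry-forward comparator ------------------------------------------------

def test_carry_forward_returns_input2_exactly(rng):
    res = RNFLForecastModel([], method="carry_forward").fit()
    v1, v2 = rng.uniform(30, 200, 768), rng.uniform(30, 200, 768)
    assert np.array_equal(res.predict(v1, v2), v2)


def test_carry_forward_sector7_constant():
    res = RNFLForecastModel([], method="carry_forward", target_mode="sector7").fit()
    out = res.predict(np.full(768, 100.0), np.full(768, 95.0))
    assert out == pytest.approx(np.full(7, 95.0))


# -- flat regressor rule recovery --------------------------------------------

def test_lr_memorizes_single_triplet():
    t = _triplet_from_values(np.full(768, 100.0), np.full(768, 90.0),
                             np.linspace(50, 150, 768))
    res = RNFLForecastModel([t], method="lr").fit()
    pred = res.predict_triplets([t])
    np.testing.assert_allclose(pred[0], np.linspace(50, 150, 768), atol=1e-6)


def test_lr_recovers_identity_rule_on_held_out_eyes():
    cohort, _ = generate_cohort(make_noise_free_config(prob_extra_scan_per_visit=0.0))
    train, test = _split_triplets(cohort)
    _, _, y = triplets_to_arrays(test)
    res = RNFLForecastModel(train, method="lr").fit()
    mae = compute_metrics(res.predict_triplets(test), y).mae_um
    assert mae < 0.5


def test_lr_recovers_linear_extrapolation_rule_on_cohort():
    cohort, _ = generate_cohort(make_progressing_noise_free_config(prob_extra_scan_per_visit=0.0))
    train, test = _split_triplets(cohort)
    x1, x2, _ = triplets_to_arrays(test)
    assert np.abs(x1 - x2).max() > 0.5  # progression makes the rule non-trivial
    train = _linear_rule_triplets(train)
    test = _linear_rule_triplets(test)
    _, _, y = triplets_to_arrays(test)
    res = RNFLForecastModel(train, method="lr").fit()
    mae = compute_metrics(res.predict_triplets(test), y).mae_um
    assert mae < 0.5


def test_lr_identifies_linear_rule_globally_from_rich_data(rng):
    """With full-rank training variation (n > 1536), OLS identifies the
    extrapolation rule itself and generalizes to arbitrary profiles."""
    n = 1800
    x1 = rng.uniform(40, 100, (n, 768))
    x2 = rng.uniform(80, 140, (n, 768))
    train = [_triplet_from_values(a, b, 2 * b - a, eye_id=f"E{i}", patient_id=f"P{i}")
             for i, (a, b) in enumerate(zip(x1, x2))]
    res = RNFLForecastModel(train, method="lr").fit()
    pred = res.predict(np.full(768, 100.0), np.full(768, 90.0))
    assert np.abs(pred - 80.0).max() < 1.0


def test_svr_warns_on_degenerate_identical_features():
    t = _triplet_from_values(np.full(768, 100.0), np.full(768, 90.0), np.full(768, 85.0))
    with pytest.warns(UserWarning, match="identical"):
        RNFLForecastModel([t, t, t], method="svr").fit()


def test_gbr_bit_reproducible_under_seed():
    cohort, _ = generate_cohort(make_noise_free_config(n_patients=10))
    train, _ = _split_triplets(cohort)
    probe = train[:5]
    hp = {"n_estimators": 10, "max_features": 0.05}
    a = RNFLForecastModel(train, method="gbr", target_mode="sector7", hyperparams=hp).fit(seed=3)
    b = RNFLForecastModel(train, method="gbr", target_mode="sector7", hyperparams=hp).fit(seed=3)
    assert np.array_equal(a.predict_triplets(probe), b.predict_triplets(probe))


# -- CNN ---------------------------------------------------------------------

TINY_CNN = {"conv_channels": (4, 4), "kernel_sizes": (5, 3), "fc_sizes": (32,), "epochs": 3}


def test_cnn_rejects_malformed_input():
    cohort, _ = generate_cohort(make_noise_free_config(n_patients=6))
    train, _ = _split_triplets(cohort)
    res = RNFLForecastModel(train, method="cnn", hyperparams=TINY_CNN).fit(seed=0)
    with pytest.raises(ValueError):
        res.predict_batch(np.ones((2, 100)), np.ones((2, 100)))
    with pytest.raises(ValueError):
        res.predict_batch(np.ones((2, 768)), np.ones((3, 768)))


def test_cnn_training_reproducible_given_seed():
    cohort, _ = generate_cohort(make_noise_free_config(n_patients=8))
    train, test = _split_triplets(cohort)
    a = RNFLForecastModel(train, method="cnn", hyperparams=TINY_CNN).fit(seed=11)
    b = RNFLForecastModel(train, method="cnn", hyperparams=TINY_CNN).fit(seed=11)
    assert a.diagnostics["loss_history"] == pytest.approx(b.diagnostics["loss_history"], rel=1e-12)
    assert np.array_equal(a.predict_triplets(test), b.predict_triplets(test))


def test_cnn_predictions_finite_and_right_shape(small_preprocessed):
    train = build_training_triplets(small_preprocessed[:10])
    res = RNFLForecastModel(train, method="cnn", target_mode="sector7",
                            hyperparams=TINY_CNN).fit(seed=0)
    pred = res.predict_triplets(train[:5])
    assert pred.shape == (5, 7)
    assert np.isfinite(pred).all()


def test_circular_shift_moves_both_channels_and_target():
    x = np.arange(2 * 2 * 8, dtype=float).reshape(2, 2, 8)
    y = np.arange(2 * 8, dtype=float).reshape(2, 8)
    shifts = np.array([2, -1])
    xs = _circular_shift_batch(x, shifts)
    ys = _circular_shift_batch(y, shifts)
    for b, s in enumerate(shifts):
        np.testing.assert_array_equal(xs[b, 0], np.roll(x[b, 0], s))
        np.testing.assert_array_equal(xs[b, 1], np.roll(x[b, 1], s))
        np.testing.assert_array_equal(ys[b], np.roll(y[b], s))


def test_augmentation_improves_shift_robustness():
    """Trained with circular-shift augmentation, the CNN's error changes less
    when inputs and targets are rotated together by 5 samples."""
    cohort, _ = generate_cohort(make_noise_free_config(n_patients=16))
    train, _ = _split_triplets(cohort)
    hp = {"conv_channels": (8, 8, 8), "kernel_sizes": (7, 5, 3), "fc_sizes": (128,), "epochs": 60}
    x1, x2, y = triplets_to_arrays(train)
    x1s, x2s, ys = (np.roll(a, 5, axis=1) for a in (x1, x2, y))
    deltas = {}
    for label, shift_max in (("aug", 5), ("noaug", 0)):
        res = RNFLForecastModel(train, method="cnn",
                                hyperparams={**hp, "shift_max": shift_max}).fit(seed=4)
        base = compute_metrics(res.predict_batch(x1, x2), y).mae_um
        rotated = compute_metrics(res.predict_batch(x1s, x2s), ys).mae_um
        assert base < 6.0  # both runs must actually have learned the task
        deltas[label] = abs(rotated - base)
    assert deltas["aug"] < deltas["noaug"]


# -- persistence -------------------------------------------------------------

@pytest.mark.parametrize("method,hp", [("lr", None), ("cnn", TINY_CNN)])
def test_save_load_round_trip(tmp_path, method, hp):
    from rnflcast import RNFLForecastResults

    cohort, _ = generate_cohort(make_noise_free_config(n_patients=8))
    train, test = _split_triplets(cohort)
    res = RNFLForecastModel(train, method=method, hyperparams=hp).fit(seed=0)
    ref = res.predict_triplets(test)
    res.save(tmp_path / method)
    loaded = RNFLForecastResults.load(tmp_path / method)
    np.testing.assert_allclose(loaded.predict_triplets(test), ref, atol=1e-10)
    assert loaded.manifest["method"] == method


def test_summary_mentions_method_and_counts(small_preprocessed):
    train = build_training_triplets(small_preprocessed[:6])
    res = RNFLForecastModel(train, method="lr").fit(seed=2)
    text = res.summary()
    assert "lr" in text
    assert str(len(train)) in text
    assert "vector768" in text
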