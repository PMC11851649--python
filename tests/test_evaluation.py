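"""Metrics, clustered bootstrap, permutation comparisons, stratified report
and figure rendering."""

import numpy as np
import pytest

from rnflcast import (
    bootstrap_ci,
    build_test_triplets,
    compare,
    compute_metrics,
    generate_cohort,
    make_split,
    preprocess_cohort,
    render_figures,
    severity_label,
    stratified_report,
    triplets_to_arrays,
)
from rnflcast import CohortConfig
from oracles import metrics_loop_oracle


# -- metrics -----------------------------------------------------------------

def test_perfect_prediction():
    y = np.random.default_rng(0).uniform(30, 200, (5, 768))
    m = compute_metrics(y, y)
    assert m.mae_um == 0.0
    assert m.mre_percent == 0.0
    assert m.r2 == 1.0


def test_constant_offset_gives_offset_mae():
    y = np.random.default_rng(1).uniform(30, 200, (4, 768))
    m = compute_metrics(y + 5.0, y)
    assert m.mae_um == pytest.approx(5.0, abs=1e-12)


def test_metrics_match_loop_oracle(rng):
    y = rng.uniform(5, 250, (8, 50))
    pred = y + rng.normal(0, 10, y.shape)
    m = compute_metrics(pred, y)
    mae, mre, r2 = metrics_loop_oracle(pred, y)
    assert m.mae_um == pytest.approx(mae, abs=1e-9)
    assert m.mre_percent == pytest.approx(mre, abs=1e-9)
    assert m.r2 == pytest.approx(r2, abs=1e-9)


def test_metrics_invariant_to_row_order(rng):
    y = rng.uniform(30, 200, (10, 7))
    pred = y + rng.normal(0, 3, y.shape)
    perm = rng.permutation(10)
    a = compute_metrics(pred, y)
    b = compute_metrics(pred[perm], y[perm])
    assert a.mae_um == pytest.approx(b.mae_um, abs=1e-12)
    assert a.r2 == pytest.approx(b.r2, abs=1e-12)


def test_r2_invariant_under_joint_translation(rng):
    """Pooled R2 recentres SStot about the grand mean, so shifting both
    predictions and targets by a constant leaves it unchanged."""
    y = rng.uniform(30, 200, (6, 20))
    pred = y + rng.normal(0, 5, y.shape)
    a = compute_metrics(pred, y)
    b = compute_metrics(pred + 40.0, y + 40.0)
    assert b.r2 == pytest.approx(a.r2, abs=1e-12)
    assert b.mae_um == pytest.approx(a.mae_um, abs=1e-12)


def test_near_zero_targets_excluded_from_mre_only():
    y = np.full((1, 4), 100.0)
    y[0, 0] = 0.5  # below the 1 um denominator floor
    pred = y + 1.0
    m = compute_metrics(pred, y)
    assert m.n_mre_excluded == 1
    assert m.mre_percent == pytest.approx(1.0, abs=1e-9)
    assert m.mae_um == pytest.approx(1.0, abs=1e-12)


def test_metrics_reject_bad_shapes():
    with pytest.raises(ValueError):
        compute_metrics(np.ones((2, 3)), np.ones((3, 2)))
    with pytest.raises(ValueError):
        compute_metrics(np.empty((0, 7)), np.empty((0, 7)))


# -- bootstrap ---------------------------------------------------------------

def _mae_fn(pred, y):
    return compute_metrics(pred, y).mae_um


def test_bootstrap_zero_width_when_errors_identical():
    y = np.full((6, 10), 100.0)
    pred = y + 2.0
    pids = ["a", "a", "b", "b", "c", "c"]
    lo, hi = bootstrap_ci(_mae_fn, pred, y, pids, n_boot=200, seed=0)
    assert lo == hi == pytest.approx(2.0)


def test_bootstrap_deterministic_and_contains_point(rng):
    y = rng.uniform(50, 150, (40, 10))
    pred = y + rng.normal(0, 4, y.shape)
    pids = [f"p{i // 2}" for i in range(40)]
    point = _mae_fn(pred, y)
    a = bootstrap_ci(_mae_fn, pred, y, pids, n_boot=500, seed=42)
    b = bootstrap_ci(_mae_fn, pred, y, pids, n_boot=500, seed=42)
    assert a == b
    assert a[0] <= point <= a[1]


def test_bootstrap_rejects_single_patient():
    y = np.ones((3, 5))
    with pytest.raises(ValueError, match="resample"):
        bootstrap_ci(_mae_fn, y, y, ["p0", "p0", "p0"], n_boot=10, seed=0)


# -- permutation comparisons -------------------------------------------------

def test_identical_errors_give_p_one():
    errs = np.array([3.0, 4.0, 5.0, 6.0])
    pids = ["a", "a", "b", "b"]
    assert compare(errs, errs, pids, paired=True, n_perm=500, seed=0) == 1.0


def test_uniform_difference_detected(rng):
    b = rng.uniform(2, 6, 100)
    a = b + 5.0
    pids = [f"p{i // 2}" for i in range(100)]
    p = compare(a, b, pids, paired=True, n_perm=10_000, seed=1)
    assert p < 0.05


def test_compare_deterministic(rng):
    b = rng.uniform(2, 6, 30)
    a = b + rng.normal(0, 1, 30)
    pids = [f"p{i}" for i in range(30)]
    p1 = compare(a, b, pids, paired=True, n_perm=2000, seed=9)
    p2 = compare(a, b, pids, paired=True, n_perm=2000, seed=9)
    assert p1 == p2


def test_unpaired_group_comparison_detects_shift(rng):
    a = rng.uniform(2, 4, 60) + 5.0
    b = rng.uniform(2, 4, 60)
    pids_a = [f"a{i // 2}" for i in range(60)]
    pids_b = [f"b{i // 2}" for i in range(60)]
    p = compare(a, b, pids_a, pids_b, paired=False, n_perm=2000, seed=2)
    assert p < 0.05


# -- severity ----------------------------------------------------------------

@pytest.mark.parametrize("md,expected", [
    (-7.2, "moderate_advanced"),
    (-3.0, "mild"),
    (-6.0, "moderate_advanced"),  # threshold itself is moderate-to-advanced
    (-5.999, "mild"),
])
def test_severity_dichotomy(md, expected):
    assert severity_label(md) == expected


# -- stratified report & figures ---------------------------------------------

@pytest.fixture(scope="module")
def eval_setup():
    cohort, _ = generate_cohort(CohortConfig(n_patients=30, seed=17))
    pre = preprocess_cohort(cohort)
    split = make_split(pre, 0.6, seed=0)
    test = build_test_triplets(split.select(pre, "test"), seed=0)
    _, x2, y = triplets_to_arrays(test)
    preds = {"carry_forward": x2.copy(), "offset": y + 2.0}
    return preds, y, test, pre


def test_stratified_report_layout(eval_setup):
    preds, y, test, pre = eval_setup
    rep = stratified_report(preds, y, test, pre, n_boot=50, n_perm=200, seed=0)
    dims = set(rep.cells["stratum_dim"])
    assert {"overall", "sex", "race", "diagnosis", "severity", "age"} <= dims
    overall = rep.cells[(rep.cells["stratum"] == "overall") & (rep.cells["model"] == "offset")]
    assert overall.iloc[0]["mae_um"] == pytest.approx(2.0)
    assert (rep.cells["n_triplets"] >= 0).all()
    pair = rep.comparisons[rep.comparisons["kind"] == "model_pair"]
    assert len(pair) == 1
    assert rep.n_comparisons == len(rep.comparisons)
    # CI brackets the point wherever both exist
    has_ci = rep.cells.dropna(subset=["mae_lo", "mae_hi", "mae_um"])
    assert ((has_ci["mae_lo"] <= has_ci["mae_um"] + 1e-9)
            & (has_ci["mae_um"] <= has_ci["mae_hi"] + 1e-9)).all()


def test_single_diagnosis_cohort_reports_empty_cells():
    cohort, _ = generate_cohort(CohortConfig(n_patients=12, seed=3,
                                             diagnosis_mix=(1.0, 0.0, 0.0)))
    pre = preprocess_cohort(cohort)
    test = build_test_triplets(pre, seed=0)
    _, x2, y = triplets_to_arrays(test)
    rep = stratified_report({"cf": x2}, y, test, pre, n_boot=0, n_perm=100, seed=0)
    glaucoma = rep.cells[(rep.cells["stratum"] == "glaucoma")]
    assert (glaucoma["n_triplets"] == 0).all()
    assert glaucoma["mae_um"].isna().all()
    sev = rep.comparisons[rep.comparisons["stratum_dim"] == "severity"]
    assert len(sev) == 0


def test_report_json_round_trip(tmp_path, eval_setup):
    import json

    preds, y, test, pre = eval_setup
    rep = stratified_report(preds, y, test, pre, n_boot=0, n_perm=0,
                            with_comparisons=False, seed=0)
    path = tmp_path / "report.json"
    rep.to_json(path)
    payload = json.loads(path.read_text())
    assert len(payload["cells"]) == len(rep.cells)


@pytest.mark.parametrize("target_mode", ["vector768", "sector7"])
def test_figures_written_and_byte_stable(tmp_path, eval_setup, target_mode):
    preds, y, test, pre = eval_setup
    if target_mode == "sector7":
        y = y[:, :7].copy()
        preds = {k: v[:, :7] for k, v in preds.items()}
    a = render_figures(preds, y, test, pre, tmp_path / "a", target_mode=target_mode)
    b = render_figures(preds, y, test, pre, tmp_path / "b", target_mode=target_mode)
    assert a and len(a) == len(b)
    for pa, pb in zip(a, b):
        assert pa.read_bytes() == pb.read_bytes()
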