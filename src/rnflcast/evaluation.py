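"""Evaluation: pooled error metrics, clustered bootstrap CIs, permutation
tests, stratified reporting and diagnostic figures.

Metric definitions (pooled over every element of every evaluated triplet):

* MAE  = mean |ŷ − y|, μm;
* MRE  = 100 × mean(|ŷ − y| / y), %, excluding elements with y < 1 μm
  (near-zero thickness makes the ratio explode; excluded counts reported);
* R²   = 1 − SSres / SStot with SStot about the grand mean of y.

Uncertainty respects the clustered design — triplets nest in eyes nest in
patients — by resampling and permuting at patient level:

* 95% CIs: nonparametric patient-level bootstrap, percentile interval,
  1000 resamples by default;
* model comparisons: two-sided sign-flip permutation of per-triplet MAE
  differences with all of a patient's triplets flipping together;
* subgroup comparisons: patient-level group-label permutation.

Strata follow the clinical reporting layout: overall, sex, the two largest
self-reported race groups, diagnosis, glaucoma severity by the 24-2 visual
field mean deviation dichotomy (mild: MD > −6.0 dB; moderate-to-advanced:
MD ≤ −6.0 dB) and, when ages are available, a median split on age.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .profiles import EyeSeries, SECTOR_NAMES
from .triplets import Triplet

MD_SEVERITY_THRESHOLD_DB = -6.0
MRE_MIN_DENOMINATOR_UM = 1.0


def severity_label(md_db: float) -> str:
    """Glaucoma severity dichotomy: mild iff MD > −6.0 dB."""
    return "mild" if md_db > MD_SEVERITY_THRESHOLD_DB else "moderate_advanced"


@dataclass(frozen=True)
class Metrics:
    mae_um: float
    mre_percent: float
    r2: float
    n_elements: int
    n_mre_excluded: int


def compute_metrics(predictions: np.ndarray, targets: np.ndarray) -> Metrics:
    """Pooled MAE/MRE/R² over all elements of all evaluated triplets."""
    pred = np.asarray(predictions, dtype=float)
    y = np.asarray(targets, dtype=float)
    if pred.size == 0:
        raise ValueError("cannot compute metrics on an empty evaluation set")
    if pred.shape != y.shape:
        raise ValueError(f"shape mismatch: predictions {pred.shape} vs targets {y.shape}")
    abs_err = np.abs(pred - y)
    mae = float(abs_err.mean())
    denom_ok = y >= MRE_MIN_DENOMINATOR_UM
    n_excluded = int((~denom_ok).sum())
    mre = float(100.0 * (abs_err[denom_ok] / y[denom_ok]).mean()) if denom_ok.any() else float("nan")
    ss_res = float(((pred - y) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else float("-inf"))
    return Metrics(mae_um=mae, mre_percent=mre, r2=float(r2), n_elements=int(y.size), n_mre_excluded=n_excluded)


def bootstrap_ci(
    metric_fn: Callable[[np.ndarray, np.ndarray], float],
    predictions: np.ndarray,
    targets: np.ndarray,
    patient_ids: Sequence[str],
    n_boot: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile 95% CI from a patient-level bootstrap.

    Patients are resampled with replacement; a resample keeps every triplet
    of every drawn patient (drawn twice -> included twice). Deterministic
    given the seed. Requires at least two distinct patients.
    """
    pred = np.asarray(predictions, dtype=float)
    y = np.asarray(targets, dtype=float)
    pids = np.asarray(patient_ids)
    if pred.shape[0] != len(pids):
        raise ValueError("patient_ids must have one entry per evaluated triplet")
    unique = np.unique(pids)
    if len(unique) < 2:
        raise ValueError("cannot resample patients: need at least 2 distinct patients")
    rows_by_patient = {p: np.nonzero(pids == p)[0] for p in unique}
    rng = np.random.default_rng(seed)
    stats = np.empty(n_boot)
    for b in range(n_boot):
        draw = rng.choice(len(unique), size=len(unique), replace=True)
        rows = np.concatenate([rows_by_patient[unique[i]] for i in draw])
        stats[b] = metric_fn(pred[rows], y[rows])
    return float(np.percentile(stats, 2.5)), float(np.percentile(stats, 97.5))


def compare(
    errors_a: np.ndarray,
    errors_b: np.ndarray,
    patient_ids_a: Sequence[str],
    patient_ids_b: Sequence[str] | None = None,
    paired: bool = True,
    n_perm: int = 10_000,
    seed: int = 0,
) -> float:
    """Two-sided permutation p-value for a difference in mean error.

    Paired (model A vs model B on the same triplets): sign-flip permutation
    of per-triplet differences, flipping all of a patient's triplets as one
    block. Unpaired (subgroup A vs subgroup B): patient-level group-label
    permutation. The p-value counts permuted statistics with |T| >= |T_obs|
    (plus the identity permutation), so identical populations give p = 1.0.
    """
    a = np.asarray(errors_a, dtype=float)
    b = np.asarray(errors_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("cannot compare empty error sets")
    rng = np.random.default_rng(seed)
    if paired:
        if a.shape != b.shape:
            raise ValueError("paired comparison requires matching error arrays")
        pids = np.asarray(patient_ids_a)
        diffs = a - b
        unique, inv = np.unique(pids, return_inverse=True)
        patient_sums = np.bincount(inv, weights=diffs, minlength=len(unique))
        t_obs = diffs.mean()
        signs = rng.choice((-1.0, 1.0), size=(n_perm, len(unique)))
        t_perm = (signs @ patient_sums) / diffs.size
        n_ge = int((np.abs(t_perm) >= abs(t_obs) - 1e-12).sum())
        return (1 + n_ge) / (1 + n_perm)
    # unpaired: permute patient labels between the groups
    pids_a = np.asarray(patient_ids_a)
    pids_b = np.asarray(patient_ids_b if patient_ids_b is not None else [])
    if len(pids_b) != b.size:
        raise ValueError("unpaired comparison requires patient ids for both groups")
    errors = np.concatenate([a, b])
    pids = np.concatenate([pids_a, pids_b])
    unique, inv = np.unique(pids, return_inverse=True)
    sums = np.bincount(inv, weights=errors, minlength=len(unique))
    counts = np.bincount(inv, minlength=len(unique)).astype(float)
    in_a = np.isin(unique, np.unique(pids_a))
    if in_a.all() or not in_a.any():
        raise ValueError("both groups must contain at least one patient")
    n_a_patients = int(in_a.sum())

    def stat(mask: np.ndarray) -> float:
        ca, cb = counts[mask].sum(), counts[~mask].sum()
        if ca == 0 or cb == 0:
            return 0.0
        return sums[mask].sum() / ca - sums[~mask].sum() / cb

    t_obs = stat(in_a)
    count_ge = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(unique))
        mask = np.zeros(len(unique), dtype=bool)
        mask[perm[:n_a_patients]] = True
        if abs(stat(mask)) >= abs(t_obs) - 1e-12:
            count_ge += 1
    return (1 + count_ge) / (1 + n_perm)


@dataclass
class EvalReport:
    """Stratified evaluation cells plus comparison p-values."""

    cells: pd.DataFrame
    comparisons: pd.DataFrame
    n_comparisons: int = 0
    meta: dict = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "meta": self.meta,
            "n_comparisons": self.n_comparisons,
            "cells": self.cells.to_dict(orient="records"),
            "comparisons": self.comparisons.to_dict(orient="records"),
        }
        text = json.dumps(payload, indent=2, default=float)
        if path is not None:
            Path(path).write_text(text)
        return text

    def write_csv(self, cells_path: str | Path, comparisons_path: str | Path) -> None:
        self.cells.to_csv(cells_path, index=False)
        self.comparisons.to_csv(comparisons_path, index=False)


def _triplet_metadata(triplets: Sequence[Triplet], cohort: Sequence[EyeSeries]) -> pd.DataFrame:
    eyes = {e.eye_id: e for e in cohort}
    rows = []
    for t in triplets:
        e = eyes[t.eye_id]
        rows.append(
            {
                "patient_id": t.patient_id,
                "eye_id": t.eye_id,
                "sex": e.sex,
                "race": e.race,
                "diagnosis": e.diagnosis,
                "md_baseline": e.md_baseline,
                "age_baseline": e.age_baseline,
                "severity": severity_label(e.md_baseline) if e.diagnosis == "glaucoma" else "",
            }
        )
    return pd.DataFrame(rows)


def _strata(meta: pd.DataFrame) -> list[tuple[str, str, np.ndarray]]:
    """(dimension, level, row mask) for every reporting cell."""
    out: list[tuple[str, str, np.ndarray]] = [("overall", "overall", np.ones(len(meta), dtype=bool))]
    for sex in ("female", "male"):
        out.append(("sex", sex, (meta["sex"] == sex).to_numpy()))
    top_races = (
        meta.drop_duplicates("patient_id")["race"].value_counts().index[:2].tolist()
    )
    for race in top_races:
        out.append(("race", race, (meta["race"] == race).to_numpy()))
    for dx in ("normal", "suspect", "glaucoma"):
        out.append(("diagnosis", dx, (meta["diagnosis"] == dx).to_numpy()))
    glaucoma = (meta["diagnosis"] == "glaucoma").to_numpy()
    for sev in ("mild", "moderate_advanced"):
        out.append(("severity", sev, glaucoma & (meta["severity"] == sev).to_numpy()))
    ages = meta["age_baseline"]
    if ages.notna().all() and len(meta):
        med = float(meta.drop_duplicates("patient_id")["age_baseline"].median())
        out.append(("age", "below_median", (ages < med).to_numpy()))
        out.append(("age", "at_or_above_median", (ages >= med).to_numpy()))
    return out


def stratified_report(
    predictions_by_model: dict[str, np.ndarray],
    targets: np.ndarray,
    triplets: Sequence[Triplet],
    cohort: Sequence[EyeSeries],
    target_mode: str = "vector768",
    n_boot: int = 1000,
    n_perm: int = 10_000,
    seed: int = 0,
    with_comparisons: bool = True,
) -> EvalReport:
    """Per-model, per-stratum metrics with CIs plus comparison p-values.

    Empty strata are reported with n = 0 and null metrics. Model pairs are
    compared overall via paired sign-flip permutation; within each two-level
    stratum dimension each model's errors are compared across the levels via
    label permutation. No multiple-testing correction is applied; the total
    number of comparisons is reported.
    """
    meta = _triplet_metadata(triplets, cohort)
    y = np.asarray(targets, dtype=float)
    pids_all = meta["patient_id"].to_numpy()
    cells = []
    per_triplet_mae = {}
    for name, pred in predictions_by_model.items():
        pred = np.asarray(pred, dtype=float)
        per_triplet_mae[name] = np.abs(pred - y).mean(axis=1)
        for dim, level, mask in _strata(meta):
            n = int(mask.sum())
            cell = {
                "model": name, "target_mode": target_mode, "stratum_dim": dim,
                "stratum": level, "n_triplets": n,
                "n_patients": int(meta.loc[mask, "patient_id"].nunique()),
            }
            if n == 0:
                cell.update({k: None for k in (
                    "mae_um", "mae_lo", "mae_hi", "mre_percent", "mre_lo", "mre_hi",
                    "r2", "r2_lo", "r2_hi", "n_mre_excluded")})
            else:
                m = compute_metrics(pred[mask], y[mask])
                cell.update({
                    "mae_um": m.mae_um, "mre_percent": m.mre_percent, "r2": m.r2,
                    "n_mre_excluded": m.n_mre_excluded,
                })
                if cell["n_patients"] >= 2 and n_boot > 0:
                    pids = pids_all[mask]
                    for metric, fn in (
                        ("mae", lambda p, t: compute_metrics(p, t).mae_um),
                        ("mre", lambda p, t: compute_metrics(p, t).mre_percent),
                        ("r2", lambda p, t: compute_metrics(p, t).r2),
                    ):
                        lo, hi = bootstrap_ci(fn, pred[mask], y[mask], pids, n_boot=n_boot, seed=seed)
                        cell[f"{metric}_lo"], cell[f"{metric}_hi"] = lo, hi
                else:
                    cell.update({k: None for k in ("mae_lo", "mae_hi", "mre_lo", "mre_hi", "r2_lo", "r2_hi")})
            cells.append(cell)

    comparisons = []
    if with_comparisons:
        names = list(predictions_by_model)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                p = compare(per_triplet_mae[a], per_triplet_mae[b], pids_all,
                            paired=True, n_perm=n_perm, seed=seed)
                comparisons.append({
                    "kind": "model_pair", "model": f"{a} vs {b}", "stratum_dim": "overall",
                    "levels": "", "p_value": p,
                })
        two_level_dims = {}
        for dim, level, mask in _strata(meta):
            if dim in ("overall", "diagnosis"):
                continue
            two_level_dims.setdefault(dim, []).append((level, mask))
        for name in names:
            errs = per_triplet_mae[name]
            for dim, levels in two_level_dims.items():
                if len(levels) != 2:
                    continue
                (la, ma), (lb, mb) = levels
                if ma.sum() == 0 or mb.sum() == 0:
                    continue
                if meta.loc[ma, "patient_id"].nunique() < 1 or meta.loc[mb, "patient_id"].nunique() < 1:
                    continue
                try:
                    p = compare(errs[ma], errs[mb], pids_all[ma], pids_all[mb],
                                paired=False, n_perm=n_perm, seed=seed)
                except ValueError:
                    continue
                comparisons.append({
                    "kind": "subgroup", "model": name, "stratum_dim": dim,
                    "levels": f"{la} vs {lb}", "p_value": p,
                })
    cells_frame = pd.DataFrame(cells)
    comp_frame = pd.DataFrame(comparisons, columns=["kind", "model", "stratum_dim", "levels", "p_value"])
    return EvalReport(
        cells=cells_frame,
        comparisons=comp_frame,
        n_comparisons=len(comp_frame),
        meta={"target_mode": target_mode, "n_boot": n_boot, "n_perm": n_perm, "seed": seed},
    )


def render_figures(
    predictions_by_model: dict[str, np.ndarray],
    targets: np.ndarray,
    triplets: Sequence[Triplet],
    cohort: Sequence[EyeSeries],
    outdir: str | Path,
    target_mode: str = "vector768",
) -> list[Path]:
    """Write overlay curves (per diagnosis) and per-sector scatterplots.

    vector768 mode: one overlay figure per diagnosis showing the true
    768-point profile of the first test triplet of that diagnosis with every
    model's prediction. sector7 mode: per-model scatterplots of true vs
    predicted sector averages with the identity line.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = _triplet_metadata(triplets, cohort)
    y = np.asarray(targets, dtype=float)
    written: list[Path] = []
    if target_mode == "vector768":
        for dx in ("normal", "suspect", "glaucoma"):
            rows = np.nonzero((meta["diagnosis"] == dx).to_numpy())[0]
            if len(rows) == 0:
                continue
            r = rows[0]
            fig, ax = plt.subplots(figsize=(8, 4))
            ax.plot(y[r], color="black", lw=1.5, label="true")
            for name, pred in predictions_by_model.items():
                ax.plot(np.asarray(pred)[r], lw=1.0, alpha=0.8, label=name)
            ax.set_xlabel("circle position (TSNIT index)")
            ax.set_ylabel("RNFL thickness (μm)")
            ax.set_title(f"true vs predicted profile — {dx}")
            ax.legend(fontsize=8)
            path = outdir / f"overlay_{dx}.png"
            fig.savefig(path, dpi=110, metadata={"Software": "rnflcast"})
            plt.close(fig)
            written.append(path)
    else:
        for name, pred in predictions_by_model.items():
            pred = np.asarray(pred)
            fig, axes = plt.subplots(2, 4, figsize=(13, 6))
            for i, sector in enumerate(SECTOR_NAMES):
                ax = axes.flat[i]
                ax.scatter(y[:, i], pred[:, i], s=6, alpha=0.5)
                lims = [min(y[:, i].min(), pred[:, i].min()), max(y[:, i].max(), pred[:, i].max())]
                ax.plot(lims, lims, color="gray", lw=0.8)
                ax.set_title(sector.upper())
                ax.set_xlabel("true (μm)")
                ax.set_ylabel("predicted (μm)")
            axes.flat[-1].axis("off")
            fig.suptitle(f"true vs predicted sector averages — {name}")
            fig.tight_layout()
            path = outdir / f"scatter_sectors_{name}.png"
            fig.savefig(path, dpi=110, metadata={"Software": "rnflcast"})
            plt.close(fig)
            written.append(path)
    return written
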