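"""Synthetic longitudinal RNFL cohort generator.

The clinical cohorts this pipeline was designed around are not publicly
available, so this module generates cohorts with the statistical structure
the pipeline assumes, plus the noiseless ground truth that real data never
offers:

* semi-annual visits with jitter, occasional repeated scans per visit;
* a double-hump TSNIT baseline shape (thin temporally/nasally, thick at the
  superior and inferior poles) with between-eye variability;
* diagnosis-dependent progressive thinning — a global linear rate per eye
  plus, for a fraction of glaucoma eyes, a focal wedge arc that thins faster
  — floored at a configurable RNFL floor below which thinning is no longer
  measurable;
* along-ring correlated measurement noise, missing-sample artifacts and
  implausible >300 μm spikes;
* demographics (sex, race, age) and 24-2 visual-field mean deviation
  metadata so stratified evaluation has something to stratify on.

Defaults are package choices anchored to published cross-sectional summary
statistics of comparable cohorts (baseline sector means, ~1.7 eyes/patient,
~4 scans/eye, 54% female, 55% White / 33% Black, mean age ~69); progression
rates have no published anchor in that source and use values typical of the
glaucoma progression literature (healthy ≈ −0.3 μm/yr, glaucoma ≈ −1.5
μm/yr global). Everything is overridable via :class:`CohortConfig`.

Determinism: one global seed drives per-patient/per-eye child streams via
``SeedSequence`` spawn keys, so enlarging ``n_patients`` never reshuffles
the eyes already generated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .profiles import N_SAMPLES, EyeSeries, RNFLProfile, VisitScan, sector_means, preprocess_profile

DAYS_PER_YEAR = 365.25


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort. All thicknesses in μm, times in days."""

    n_patients: int = 100
    prob_two_eyes: float = 0.74
    diagnosis_mix: tuple[float, float, float] = (0.24, 0.32, 0.44)  # normal, suspect, glaucoma
    visit_interval_mean_days: float = 183.0
    visit_interval_jitter_days: float = 25.0
    n_visits_range: tuple[int, int] = (3, 6)
    prob_extra_scan_per_visit: float = 0.15
    prob_bad_quality: float = 0.02

    # TSNIT shape: baseline + two Gaussian humps at the superior/inferior poles
    temporal_baseline_um: float = 60.0
    hump_amplitude_um: float = 80.0
    hump_width_samples: float = 55.0
    hump_centers: tuple[int, int] = (192, 576)  # superior, inferior pole indices
    amplitude_factor_by_diagnosis: dict = field(
        default_factory=lambda: {"normal": 1.0, "suspect": 0.82, "glaucoma": 0.82}
    )

    # between-eye variability
    baseline_sd_um: float = 4.0
    amplitude_sd_um: float = 8.0
    center_jitter_samples: float = 10.0

    # progression model
    slope_mean_by_diagnosis: dict = field(
        default_factory=lambda: {"normal": -0.3, "suspect": -0.6, "glaucoma": -1.5}
    )  # μm/year, global
    slope_sd_um_yr: float = 0.25
    wedge_probability: float = 0.5  # glaucoma eyes only
    wedge_width_samples: tuple[int, int] = (40, 90)
    wedge_extra_slope_um_yr: float = -2.0
    floor_thickness_um: float = 50.0

    # measurement model: total noise sd = noise_scale_um, with a fraction of
    # the variance white (independent per sample) and the rest correlated
    # along the ring — adjacent A-scans share error, but each sample also
    # carries its own segmentation/speckle jitter
    noise_scale_um: float = 3.0
    noise_correlation_samples: float = 8.0
    noise_white_fraction: float = 0.3
    missing_rate: float = 0.002
    spike_rate: float = 0.0005
    spike_range_um: tuple[float, float] = (305.0, 400.0)

    # demographics / visual field metadata
    prob_female: float = 0.54
    race_mix: dict = field(
        default_factory=lambda: {"white": 0.55, "black": 0.33, "asian": 0.10, "other": 0.02}
    )
    age_mean_years: float = 68.8
    age_sd_years: float = 8.0
    md_baseline_by_diagnosis: dict = field(
        default_factory=lambda: {"normal": (-0.5, 1.0), "suspect": (-1.5, 1.5), "glaucoma": (-4.5, 4.0)}
    )  # (mean, sd) in dB
    md_slope_db_per_um: float = 0.15  # couples MD trajectory to global RNFL slope

    seed: int = 0

    def validate(self) -> None:
        errs = []
        if self.n_patients < 1:
            errs.append("n_patients must be >= 1")
        if not math.isclose(sum(self.diagnosis_mix), 1.0, abs_tol=1e-9):
            errs.append("diagnosis_mix must sum to 1")
        if not math.isclose(sum(self.race_mix.values()), 1.0, abs_tol=1e-9):
            errs.append("race_mix must sum to 1")
        for name in ("prob_two_eyes", "prob_extra_scan_per_visit", "prob_bad_quality",
                     "wedge_probability", "prob_female", "missing_rate", "spike_rate",
                     "noise_white_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                errs.append(f"{name} must be in [0, 1], got {v}")
        for name in ("noise_scale_um", "noise_correlation_samples", "visit_interval_jitter_days",
                     "baseline_sd_um", "amplitude_sd_um", "center_jitter_samples", "slope_sd_um_yr"):
            if getattr(self, name) < 0:
                errs.append(f"{name} must be >= 0")
        if not self.floor_thickness_um < self.temporal_baseline_um:
            errs.append("floor_thickness_um must be below temporal_baseline_um")
        if self.n_visits_range[0] < 1 or self.n_visits_range[0] > self.n_visits_range[1]:
            errs.append("n_visits_range must be (lo, hi) with 1 <= lo <= hi")
        if errs:
            raise ValueError("invalid CohortConfig: " + "; ".join(errs))

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        for key in ("diagnosis_mix", "n_visits_range", "hump_centers", "wedge_width_samples", "spike_range_um"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        if "md_baseline_by_diagnosis" in d:
            d["md_baseline_by_diagnosis"] = {k: tuple(v) for k, v in d["md_baseline_by_diagnosis"].items()}
        return cls(**d)


@dataclass
class EyeTruth:
    """Per-eye generative parameters plus the noiseless profile at each visit."""

    base_profile: np.ndarray  # μm, before any progression
    global_slope_um_yr: float
    wedge_center: int | None
    wedge_width: int | None
    wedge_extra_slope_um_yr: float
    noiseless: dict[int, np.ndarray] = field(default_factory=dict)  # visit_time -> profile


@dataclass
class GroundTruth:
    """Noiseless truth aligned 1:1 with the emitted scans, keyed by eye."""

    eyes: dict[str, EyeTruth] = field(default_factory=dict)

    def profile(self, eye_id: str, visit_time: int) -> np.ndarray:
        return self.eyes[eye_id].noiseless[visit_time]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        arrays = []
        for eye_id, et in self.eyes.items():
            for t, prof in sorted(et.noiseless.items()):
                rows.append({"eye_id": eye_id, "visit_time_days": t,
                             "global_slope_um_yr": et.global_slope_um_yr,
                             "wedge_center": et.wedge_center if et.wedge_center is not None else -1,
                             "wedge_width": et.wedge_width if et.wedge_width is not None else 0,
                             "wedge_extra_slope_um_yr": et.wedge_extra_slope_um_yr})
                arrays.append(prof)
        frame = pd.DataFrame(rows)
        vals = pd.DataFrame(np.asarray(arrays), columns=[f"v{i}" for i in range(N_SAMPLES)], index=frame.index)
        return pd.concat([frame, vals], axis=1)

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def _smooth_circular_noise(rng: np.random.Generator, scale: float, corr_len: float, n: int) -> np.ndarray:
    """White noise smoothed with a circular Gaussian kernel, rescaled to sd `scale`."""
    white = rng.standard_normal(n)
    if scale == 0.0:
        return np.zeros(n)
    if corr_len <= 0:
        return scale * white
    k = np.arange(n)
    d = np.minimum(k, n - k).astype(float)
    kernel = np.exp(-0.5 * (d / corr_len) ** 2)
    kernel /= np.linalg.norm(kernel)  # unit L2 => smoothed sd == input sd
    smoothed = np.real(np.fft.ifft(np.fft.fft(white) * np.fft.fft(kernel)))
    return scale * smoothed


def _truth_profile(et: EyeTruth, t_days: int, floor: float) -> np.ndarray:
    """Noiseless profile at time t: linear pointwise decline, floored.

    The floor never raises a baseline that already sits below it, so truth is
    monotonically non-increasing in time whenever all rates are <= 0.
    """
    rate = np.full(N_SAMPLES, et.global_slope_um_yr)
    if et.wedge_center is not None:
        idx = (np.arange(N_SAMPLES) - et.wedge_center) % N_SAMPLES
        in_wedge = np.minimum(idx, N_SAMPLES - idx) <= et.wedge_width / 2
        rate[in_wedge] += et.wedge_extra_slope_um_yr
    declined = et.base_profile + rate * (t_days / DAYS_PER_YEAR)
    eff_floor = np.minimum(et.base_profile, floor)
    return np.maximum(declined, eff_floor)


def _draw_categorical(rng: np.random.Generator, table: dict) -> str:
    names = list(table.keys())
    probs = np.array([table[n] for n in names], dtype=float)
    return names[rng.choice(len(names), p=probs / probs.sum())]


def generate_cohort(config: CohortConfig) -> tuple[list[EyeSeries], GroundTruth]:
    """Generate a longitudinal cohort plus its noiseless ground truth.

    Deterministic given ``config.seed``; observed profiles are raw (missing
    samples and >300 μm spikes included) and must be run through
    :func:`rnflcast.profiles.preprocess_cohort` before triplet building.
    """
    config.validate()

    def child_rng(*key: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=key))

    cohort: list[EyeSeries] = []
    truth = GroundTruth()
    diag_names = ("normal", "suspect", "glaucoma")

    for p in range(config.n_patients):
        prng = child_rng(p)
        patient_id = f"P{p:04d}"
        sex = "female" if prng.random() < config.prob_female else "male"
        race = _draw_categorical(prng, config.race_mix)
        age = float(prng.normal(config.age_mean_years, config.age_sd_years))
        n_eyes = 2 if prng.random() < config.prob_two_eyes else 1
        first_lat = "OD" if prng.random() < 0.5 else "OS"
        for e in range(n_eyes):
            erng = child_rng(p, e + 1)
            laterality = first_lat if e == 0 else ("OS" if first_lat == "OD" else "OD")
            eye_id = f"{patient_id}-{laterality}"
            diagnosis = diag_names[erng.choice(3, p=np.asarray(config.diagnosis_mix))]

            # baseline TSNIT shape
            amp_factor = config.amplitude_factor_by_diagnosis[diagnosis]
            base = np.full(N_SAMPLES, config.temporal_baseline_um + erng.normal(0, config.baseline_sd_um))
            idx = np.arange(N_SAMPLES)
            for center in config.hump_centers:
                c = center + erng.normal(0, config.center_jitter_samples)
                amp = amp_factor * config.hump_amplitude_um + erng.normal(0, config.amplitude_sd_um)
                d = np.minimum(np.abs(idx - c), N_SAMPLES - np.abs(idx - c))
                base += max(amp, 0.0) * np.exp(-0.5 * (d / config.hump_width_samples) ** 2)

            slope = erng.normal(config.slope_mean_by_diagnosis[diagnosis], config.slope_sd_um_yr)
            wedge_center = wedge_width = None
            if diagnosis == "glaucoma" and erng.random() < config.wedge_probability:
                wedge_center = int(erng.choice(config.hump_centers) + erng.integers(-40, 41))
                wedge_width = int(erng.integers(config.wedge_width_samples[0], config.wedge_width_samples[1] + 1))
            et = EyeTruth(
                base_profile=base,
                global_slope_um_yr=float(slope),
                wedge_center=wedge_center,
                wedge_width=wedge_width,
                wedge_extra_slope_um_yr=config.wedge_extra_slope_um_yr if wedge_center is not None else 0.0,
            )

            md_mean, md_sd = config.md_baseline_by_diagnosis[diagnosis]
            md0 = float(erng.normal(md_mean, md_sd))
            if diagnosis == "normal":
                md0 = min(md0, 1.5)  # healthy fields don't show deep defects

            n_visits = int(erng.integers(config.n_visits_range[0], config.n_visits_range[1] + 1))
            t = 0
            visit_times = []
            for v in range(n_visits):
                visit_times.append(t)
                gap = erng.normal(config.visit_interval_mean_days, config.visit_interval_jitter_days)
                t += int(max(30.0, round(gap)))

            eye = EyeSeries(
                eye_id=eye_id, patient_id=patient_id, laterality=laterality,
                diagnosis=diagnosis, md_baseline=md0, sex=sex, race=race,
                scans=[], age_baseline=age,
            )
            for t_v in visit_times:
                noiseless = _truth_profile(et, t_v, config.floor_thickness_um)
                et.noiseless[t_v] = noiseless
                n_scans = 1 + (1 if erng.random() < config.prob_extra_scan_per_visit else 0)
                for s in range(n_scans):
                    wf = config.noise_white_fraction
                    corr_sd = config.noise_scale_um * np.sqrt(1.0 - wf)
                    white_sd = config.noise_scale_um * np.sqrt(wf)
                    obs = noiseless + _smooth_circular_noise(
                        erng, corr_sd, config.noise_correlation_samples, N_SAMPLES
                    ) + white_sd * erng.standard_normal(N_SAMPLES)
                    np.maximum(obs, 0.0, out=obs)
                    spikes = erng.random(N_SAMPLES) < config.spike_rate
                    obs[spikes] = erng.uniform(*config.spike_range_um, size=int(spikes.sum()))
                    missing = erng.random(N_SAMPLES) < config.missing_rate
                    obs[missing] = np.nan
                    eye.scans.append(
                        VisitScan(
                            patient_id=patient_id, eye_id=eye_id, laterality=laterality,
                            visit_time=t_v, scan_index_within_visit=s,
                            profile=RNFLProfile(values=obs, missing_mask=missing),
                            quality_ok=bool(erng.random() >= config.prob_bad_quality),
                        )
                    )
            eye.sort_scans()
            cohort.append(eye)
            truth.eyes[eye_id] = et
    return cohort, truth


def summarize_cohort(cohort: list[EyeSeries]) -> dict:
    """Cohort descriptors in the layout of a clinical baseline table.

    Counts, diagnosis/severity/sex/race proportions, and first-visit sector
    means with normal-approximation 95% CIs across eyes. Empty strata yield
    zero counts, never errors.
    """
    if not cohort:
        raise ValueError("cannot summarize an empty cohort")
    patients = {e.patient_id for e in cohort}
    n_scans = sum(len(e.scans) for e in cohort)
    diag_counts = {d: sum(1 for e in cohort if e.diagnosis == d) for d in ("normal", "suspect", "glaucoma")}
    glaucoma = [e for e in cohort if e.diagnosis == "glaucoma"]
    severity = {
        "mild": sum(1 for e in glaucoma if e.md_baseline > -6.0),
        "moderate_advanced": sum(1 for e in glaucoma if e.md_baseline <= -6.0),
    }
    by_patient = {}
    for e in cohort:
        by_patient.setdefault(e.patient_id, e)
    sex_counts = {s: sum(1 for e in by_patient.values() if e.sex == s) for s in ("female", "male")}
    race_counts: dict[str, int] = {}
    for e in by_patient.values():
        race_counts[e.race] = race_counts.get(e.race, 0) + 1

    sector_rows = []
    for e in cohort:
        if not e.scans:
            continue
        first = e.scans[0]
        prof = first.profile if first.profile.is_preprocessed else preprocess_profile(first.profile)
        sector_rows.append(sector_means(prof).as_array())
    baseline = {}
    if sector_rows:
        arr = np.asarray(sector_rows)
        mean = arr.mean(axis=0)
        se = arr.std(axis=0, ddof=1) / np.sqrt(len(arr)) if len(arr) > 1 else np.zeros(7)
        for i, name in enumerate(("g", "t", "ts", "ti", "n", "ns", "ni")):
            baseline[name] = {
                "mean_um": float(mean[i]),
                "ci95": (float(mean[i] - 1.96 * se[i]), float(mean[i] + 1.96 * se[i])),
            }
    return {
        "n_patients": len(patients),
        "n_eyes": len(cohort),
        "n_images": n_scans,
        "diagnosis_counts": diag_counts,
        "severity_counts": severity,
        "sex_counts": sex_counts,
        "race_counts": race_counts,
        "baseline_sector_means": baseline,
    }
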