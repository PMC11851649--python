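"""On-disk formats: profile CSV, cohort metadata CSV, JSON cohorts, manifests.

Profile CSV: one row per scan with columns
``patient_id, eye_id, laterality, visit_time_days, scan_index, quality_ok,
v0..v767`` — an empty cell among v0..v767 marks a missing sample.

Metadata CSV: one row per eye with columns
``patient_id, eye_id, diagnosis, md_baseline_db, sex, race, age_baseline_years``.

All indices are 0-based, matching the in-memory model.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .profiles import N_SAMPLES, EyeSeries, RNFLProfile, VisitScan

VALUE_COLS = [f"v{i}" for i in range(N_SAMPLES)]
SCAN_META_COLS = ["patient_id", "eye_id", "laterality", "visit_time_days", "scan_index", "quality_ok"]
EYE_META_COLS = ["patient_id", "eye_id", "diagnosis", "md_baseline_db", "sex", "race", "age_baseline_years"]


def cohort_to_frames(cohort: list[EyeSeries]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flatten a cohort into (profiles frame, metadata frame)."""
    rows = []
    values = []
    meta_rows = []
    for eye in cohort:
        meta_rows.append(
            {
                "patient_id": eye.patient_id,
                "eye_id": eye.eye_id,
                "diagnosis": eye.diagnosis,
                "md_baseline_db": eye.md_baseline,
                "sex": eye.sex,
                "race": eye.race,
                "age_baseline_years": eye.age_baseline,
            }
        )
        for scan in eye.scans:
            rows.append(
                {
                    "patient_id": scan.patient_id,
                    "eye_id": scan.eye_id,
                    "laterality": scan.laterality,
                    "visit_time_days": scan.visit_time,
                    "scan_index": scan.scan_index_within_visit,
                    "quality_ok": scan.quality_ok,
                }
            )
            vals = scan.profile.values.copy()
            vals[scan.profile.missing_mask] = np.nan
            values.append(vals)
    profiles = pd.DataFrame(rows, columns=SCAN_META_COLS)
    if values:
        profiles = pd.concat(
            [profiles, pd.DataFrame(np.asarray(values), columns=VALUE_COLS, index=profiles.index)],
            axis=1,
        )
    else:
        profiles = profiles.reindex(columns=SCAN_META_COLS + VALUE_COLS)
    meta = pd.DataFrame(meta_rows, columns=EYE_META_COLS)
    return profiles, meta


def frames_to_cohort(profiles: pd.DataFrame, meta: pd.DataFrame) -> list[EyeSeries]:
    """Rebuild EyeSeries objects from the two frames."""
    eyes: dict[str, EyeSeries] = {}
    for _, row in meta.iterrows():
        age = row.get("age_baseline_years")
        eyes[row["eye_id"]] = EyeSeries(
            eye_id=row["eye_id"],
            patient_id=row["patient_id"],
            laterality="OD",  # refined from scan rows below
            diagnosis=row["diagnosis"],
            md_baseline=float(row["md_baseline_db"]),
            sex=row["sex"],
            race=row["race"],
            scans=[],
            age_baseline=None if age is None or pd.isna(age) else float(age),
        )
    value_block = profiles[VALUE_COLS].to_numpy(dtype=float)
    for pos, (_, row) in enumerate(profiles.iterrows()):
        eye = eyes[row["eye_id"]]
        vals = value_block[pos]
        scan = VisitScan(
            patient_id=row["patient_id"],
            eye_id=row["eye_id"],
            laterality=row["laterality"],
            visit_time=int(row["visit_time_days"]),
            scan_index_within_visit=int(row["scan_index"]),
            profile=RNFLProfile(values=vals),
            quality_ok=bool(row["quality_ok"]),
        )
        eye.laterality = scan.laterality
        eye.scans.append(scan)
    out = list(eyes.values())
    for eye in out:
        eye.sort_scans()
    return out


def write_cohort_csv(cohort: list[EyeSeries], profiles_path: str | Path, meta_path: str | Path) -> None:
    profiles, meta = cohort_to_frames(cohort)
    profiles.to_csv(profiles_path, index=False)
    meta.to_csv(meta_path, index=False)


def read_cohort_csv(profiles_path: str | Path, meta_path: str | Path) -> list[EyeSeries]:
    profiles = pd.read_csv(profiles_path)
    meta = pd.read_csv(meta_path)
    return frames_to_cohort(profiles, meta)


def cohort_to_json(cohort: list[EyeSeries]) -> list[dict]:
    """JSON-serializable cohort: a list of EyeSeries dicts with the CSV field names."""
    out = []
    for eye in cohort:
        out.append(
            {
                "eye_id": eye.eye_id,
                "patient_id": eye.patient_id,
                "laterality": eye.laterality,
                "diagnosis": eye.diagnosis,
                "md_baseline_db": eye.md_baseline,
                "sex": eye.sex,
                "race": eye.race,
                "age_baseline_years": eye.age_baseline,
                "scans": [
                    {
                        "visit_time_days": s.visit_time,
                        "scan_index": s.scan_index_within_visit,
                        "quality_ok": s.quality_ok,
                        "values": [None if m else v for v, m in zip(s.profile.values.tolist(), s.profile.missing_mask.tolist())],
                    }
                    for s in eye.scans
                ],
            }
        )
    return out


def json_to_cohort(data: list[dict]) -> list[EyeSeries]:
    cohort = []
    for d in data:
        eye = EyeSeries(
            eye_id=d["eye_id"],
            patient_id=d["patient_id"],
            laterality=d["laterality"],
            diagnosis=d["diagnosis"],
            md_baseline=float(d["md_baseline_db"]),
            sex=d["sex"],
            race=d["race"],
            scans=[],
            age_baseline=d.get("age_baseline_years"),
        )
        for s in d["scans"]:
            vals = np.array([np.nan if v is None else v for v in s["values"]], dtype=float)
            eye.scans.append(
                VisitScan(
                    patient_id=eye.patient_id,
                    eye_id=eye.eye_id,
                    laterality=eye.laterality,
                    visit_time=int(s["visit_time_days"]),
                    scan_index_within_visit=int(s["scan_index"]),
                    profile=RNFLProfile(values=vals),
                    quality_ok=bool(s["quality_ok"]),
                )
            )
        eye.sort_scans()
        cohort.append(eye)
    return cohort


def write_cohort_json(cohort: list[EyeSeries], path: str | Path) -> None:
    Path(path).write_text(json.dumps(cohort_to_json(cohort)))


def read_cohort_json(path: str | Path) -> list[EyeSeries]:
    return json_to_cohort(json.loads(Path(path).read_text()))
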