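"""Leakage-free triplet construction and patient-level data partitioning.

The supervised unit of the pipeline is the *triplet*: two input visits and
one later target visit from the same eye, with each consecutive inter-visit
gap inside a configurable window (default 183–548 days, ~6–18 months,
inclusive). Training uses every gap-valid ordered scan combination — when a
visit holds multiple scans, all scan permutations are enumerated to enlarge
the training set. Testing first retains a single randomly chosen scan per
visit and then enforces that the map (input1, input2) -> target is a
function: if one retained input pair admits several gap-valid targets, the
earliest target is kept and later ones are dropped.

Partitioning is strictly at patient level — both eyes of a patient travel
together — so no participant can contribute to both the training and the
test side.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .profiles import EyeSeries, VisitScan

logger = logging.getLogger(__name__)

GAP_WINDOW_DAYS = (183, 548)
"""Default inclusive bounds on each consecutive inter-visit gap (≈6–18 months)."""


@dataclass(frozen=True)
class Triplet:
    """Two input scans plus one target scan from a single eye."""

    input1: VisitScan
    input2: VisitScan
    target: VisitScan

    def __post_init__(self) -> None:
        if not (self.input1.eye_id == self.input2.eye_id == self.target.eye_id):
            raise ValueError("all three scans of a triplet must come from the same eye")
        if not (self.input1.visit_time < self.input2.visit_time < self.target.visit_time):
            raise ValueError("triplet visits must be strictly increasing in time")

    @property
    def eye_id(self) -> str:
        return self.input1.eye_id

    @property
    def patient_id(self) -> str:
        return self.input1.patient_id

    @property
    def gap12_days(self) -> int:
        return self.input2.visit_time - self.input1.visit_time

    @property
    def gap23_days(self) -> int:
        return self.target.visit_time - self.input2.visit_time


@dataclass
class SplitAssignment:
    """patient_id -> partition ('train_val' or 'test')."""

    assignment: dict[str, str]

    def partition_of(self, patient_id: str) -> str:
        return self.assignment[patient_id]

    def patients(self, partition: str) -> set[str]:
        return {p for p, part in self.assignment.items() if part == partition}

    def select(self, cohort: list[EyeSeries], partition: str) -> list[EyeSeries]:
        keep = self.patients(partition)
        return [e for e in cohort if e.patient_id in keep]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.assignment.items()), columns=["patient_id", "partition"]
        )


def make_split(cohort: list[EyeSeries], train_fraction: float = 0.8, seed: int = 0) -> SplitAssignment:
    """Partition patients into train_val and test sets.

    ``round(train_fraction * n)`` patients (half-up rounding) go to
    train_val; assignment is deterministic given the seed and operates on
    sorted patient ids, so eye order in the cohort is irrelevant.
    """
    patients = sorted({e.patient_id for e in cohort})
    n = len(patients)
    if n < 2:
        raise ValueError("need at least 2 patients to form a train/test split")
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be strictly between 0 and 1")
    n_train = int(np.floor(train_fraction * n + 0.5))
    n_train = min(max(n_train, 1), n - 1)  # both partitions non-empty
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    assignment = {}
    for rank, idx in enumerate(order):
        assignment[patients[idx]] = "train_val" if rank < n_train else "test"
    return SplitAssignment(assignment)


def split_validation_patients(
    train_val: SplitAssignment, val_fraction: float = 0.1, seed: int = 0
) -> tuple[set[str], set[str]]:
    """Carve a patient-level validation subset out of the train_val partition."""
    patients = sorted(train_val.patients("train_val"))
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(patients))
    n_val = int(np.floor(val_fraction * len(patients) + 0.5))
    val = {patients[i] for i in order[:n_val]}
    return set(patients) - val, val


def _usable_scans(eye: EyeSeries) -> dict[int, list[VisitScan]]:
    """Good-quality scans grouped by visit time."""
    by_visit: dict[int, list[VisitScan]] = {}
    for s in eye.scans:
        if s.quality_ok:
            by_visit.setdefault(s.visit_time, []).append(s)
    return by_visit


def _gap_valid_visit_triples(times: list[int], window: tuple[int, int]) -> list[tuple[int, int, int]]:
    lo, hi = window
    out = []
    for i, t1 in enumerate(times):
        for j in range(i + 1, len(times)):
            t2 = times[j]
            if not lo <= t2 - t1 <= hi:
                continue
            for k in range(j + 1, len(times)):
                t3 = times[k]
                if lo <= t3 - t2 <= hi:
                    out.append((t1, t2, t3))
    return out


def build_training_triplets(
    cohort: list[EyeSeries], gap_window_days: tuple[int, int] = GAP_WINDOW_DAYS
) -> list[Triplet]:
    """All gap-valid ordered triples within each eye, over all scan permutations.

    Eyes never mix; scans flagged quality_ok=False are excluded first.
    """
    triplets: list[Triplet] = []
    for eye in cohort:
        by_visit = _usable_scans(eye)
        times = sorted(by_visit)
        for t1, t2, t3 in _gap_valid_visit_triples(times, gap_window_days):
            for s1 in by_visit[t1]:
                for s2 in by_visit[t2]:
                    for s3 in by_visit[t3]:
                        triplets.append(Triplet(input1=s1, input2=s2, target=s3))
    return triplets


def build_test_triplets(
    cohort: list[EyeSeries],
    seed: int = 0,
    gap_window_days: tuple[int, int] = GAP_WINDOW_DAYS,
) -> list[Triplet]:
    """Unique test triplets: one retained scan per visit, no conflicting targets.

    Per (eye, visit) one scan is kept by a seeded draw; triples are then
    enumerated on the retained scans only. If one (input1, input2) pair still
    admits multiple targets, the earliest target is kept and the rest are
    dropped (logged), so the emitted input-pair -> target map is a function.
    """
    rng = np.random.default_rng(seed)
    triplets: list[Triplet] = []
    for eye in sorted(cohort, key=lambda e: e.eye_id):
        by_visit = _usable_scans(eye)
        retained = {t: scans[int(rng.integers(len(scans)))] for t, scans in sorted(by_visit.items())}
        times = sorted(retained)
        seen_pairs: dict[tuple, Triplet] = {}
        for t1, t2, t3 in _gap_valid_visit_triples(times, gap_window_days):
            key = (retained[t1].ref, retained[t2].ref)
            cand = Triplet(input1=retained[t1], input2=retained[t2], target=retained[t3])
            if key in seen_pairs:
                logger.debug(
                    "dropping conflicting test triplet for eye %s: pair %s already targets t=%d",
                    eye.eye_id, key, seen_pairs[key].target.visit_time,
                )
                continue
            seen_pairs[key] = cand
        triplets.extend(seen_pairs.values())
    return triplets


def triplets_to_frame(triplets: list[Triplet], partition: str = "") -> pd.DataFrame:
    """Triplet manifest: scan references, gaps and partition label."""
    rows = []
    for t in triplets:
        rows.append(
            {
                "eye_id": t.eye_id,
                "patient_id": t.patient_id,
                "input1_visit_time_days": t.input1.visit_time,
                "input1_scan_index": t.input1.scan_index_within_visit,
                "input2_visit_time_days": t.input2.visit_time,
                "input2_scan_index": t.input2.scan_index_within_visit,
                "target_visit_time_days": t.target.visit_time,
                "target_scan_index": t.target.scan_index_within_visit,
                "gap12_days": t.gap12_days,
                "gap23_days": t.gap23_days,
                "partition": partition,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "eye_id", "patient_id",
            "input1_visit_time_days", "input1_scan_index",
            "input2_visit_time_days", "input2_scan_index",
            "target_visit_time_days", "target_scan_index",
            "gap12_days", "gap23_days", "partition",
        ],
    )


def frame_to_triplets(frame: pd.DataFrame, cohort: list[EyeSeries]) -> list[Triplet]:
    """Resolve a triplet manifest back against cohort scans."""
    index: dict[tuple, VisitScan] = {}
    for eye in cohort:
        for s in eye.scans:
            index[(s.eye_id, s.visit_time, s.scan_index_within_visit)] = s
    out = []
    for _, r in frame.iterrows():
        out.append(
            Triplet(
                input1=index[(r["eye_id"], int(r["input1_visit_time_days"]), int(r["input1_scan_index"]))],
                input2=index[(r["eye_id"], int(r["input2_visit_time_days"]), int(r["input2_scan_index"]))],
                target=index[(r["eye_id"], int(r["target_visit_time_days"]), int(r["target_scan_index"]))],
            )
        )
    return out
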