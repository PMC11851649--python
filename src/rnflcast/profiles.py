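"""Domain types and preprocessing for circumpapillary RNFL thickness profiles.

A Spectralis-style optic-nerve-head circle scan yields 768 equally spaced
retinal nerve fiber layer (RNFL) thickness samples (in micrometers) around
the optic nerve head. Profiles are stored in TSNIT order: index 0 sits at
the temporal anchor and indices increase superiorly, through nasal, inferior
and back to temporal. This module provides:

* :class:`RNFLProfile`, :class:`VisitScan`, :class:`EyeSeries`,
  :class:`SectorAverages` — the in-memory data model;
* :func:`preprocess_profile` — repair of missing/invalid samples by circular
  linear interpolation plus truncation of implausible values at 300 μm;
* :func:`sector_means` — reduction of a 768-point profile to the seven
  global/sectoral averages (G, T, TS, TI, N, NS, NI);
* :func:`mirror_to_reference_orientation` — maps left-eye (OS) profiles into
  the right-eye (OD) coordinate frame so both lateralities share one TSNIT
  axis.

Angular convention
------------------
One sample covers 360/768 degrees. With the temporal anchor at index 0:

========  ===========================  ==================  =====
Sector    Degrees (centered layout)    Index range         Size
========  ===========================  ==================  =====
T         315–45   (90° about 0°)      672..767, 0..95     192
TS        45–90                        96..191             96
NS        90–135                       192..287            96
N         135–225  (90° about 180°)    288..479            192
NI        225–270                      480..575            96
TI        270–315                      576..671            96
========  ===========================  ==================  =====

All boundaries fall on exact integer indices (45° × 768/360 = 96), so the
six sectors partition 0..767 with no rounding.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

N_SAMPLES = 768
"""Number of thickness samples on one circle scan."""

MAX_THICKNESS_UM = 300.0
"""Upper truncation bound for physically plausible RNFL thickness."""

#: Contiguous (mod-768) index ranges of the six anatomical sectors.
#: Each entry is a tuple of (start, stop) half-open segments whose union is
#: the sector; only T wraps across the 0/767 seam.
SECTOR_SEGMENTS: dict[str, tuple[tuple[int, int], ...]] = {
    "t": ((672, 768), (0, 96)),
    "ts": ((96, 192),),
    "ns": ((192, 288),),
    "n": ((288, 480),),
    "ni": ((480, 576),),
    "ti": ((576, 672),),
}

SECTOR_NAMES = ("g", "t", "ts", "ti", "n", "ns", "ni")
"""Reporting order: global first, then temporal/nasal sectors."""


class UnrepairableProfileError(ValueError):
    """Raised when a profile has no valid sample to interpolate from."""


def sector_indices(sector: str) -> np.ndarray:
    """Return the sample indices belonging to ``sector`` (one of t, ts, ns, n, ni, ti)."""
    segs = SECTOR_SEGMENTS[sector]
    return np.concatenate([np.arange(a, b) for a, b in segs])


@dataclass(frozen=True)
class RNFLProfile:
    """One circle scan's 768 RNFL thickness samples in μm, TSNIT order.

    ``values`` may contain NaN where ``missing_mask`` is True; after
    :func:`preprocess_profile` every value is finite, within [0, 300] μm and
    the mask is all-False.
    """

    values: np.ndarray
    missing_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != (N_SAMPLES,):
            raise ValueError(f"profile must have exactly {N_SAMPLES} samples, got shape {values.shape}")
        if self.missing_mask is None:
            mask = ~np.isfinite(values)
        else:
            mask = np.asarray(self.missing_mask, dtype=bool)
            if mask.shape != (N_SAMPLES,):
                raise ValueError("missing_mask must match the 768-sample profile")
            mask = mask | ~np.isfinite(values)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "missing_mask", mask)

    @property
    def is_preprocessed(self) -> bool:
        v = self.values
        return (
            not self.missing_mask.any()
            and bool(np.isfinite(v).all())
            and bool((v >= 0).all())
            and bool((v <= MAX_THICKNESS_UM).all())
        )


@dataclass(frozen=True)
class VisitScan:
    """One OCT circle scan of one eye at one visit."""

    patient_id: str
    eye_id: str
    laterality: str  # "OD" or "OS"
    visit_time: int  # days since the eye's first visit
    scan_index_within_visit: int
    profile: RNFLProfile
    quality_ok: bool = True

    def __post_init__(self) -> None:
        if self.laterality not in ("OD", "OS"):
            raise ValueError(f"laterality must be OD or OS, got {self.laterality!r}")
        if self.visit_time < 0:
            raise ValueError("visit_time must be >= 0")

    @property
    def ref(self) -> tuple[int, int]:
        """(visit_time_days, scan_index) — the scan's identity within its eye."""
        return (self.visit_time, self.scan_index_within_visit)


@dataclass
class EyeSeries:
    """Time-ordered scans of one eye plus the metadata evaluation stratifies on."""

    eye_id: str
    patient_id: str
    laterality: str
    diagnosis: str  # normal | suspect | glaucoma
    md_baseline: float  # 24-2 visual field mean deviation, dB
    sex: str  # female | male
    race: str
    scans: list[VisitScan] = field(default_factory=list)
    age_baseline: float | None = None  # years at first visit

    def __post_init__(self) -> None:
        if self.diagnosis not in ("normal", "suspect", "glaucoma"):
            raise ValueError(f"unknown diagnosis {self.diagnosis!r}")
        self.sort_scans()

    def sort_scans(self) -> None:
        self.scans.sort(key=lambda s: (s.visit_time, s.scan_index_within_visit))

    @property
    def visit_times(self) -> list[int]:
        return sorted({s.visit_time for s in self.scans})


@dataclass(frozen=True)
class SectorAverages:
    """Global plus six sectoral RNFL thickness averages, μm."""

    g: float
    t: float
    ts: float
    ti: float
    n: float
    ns: float
    ni: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in SECTOR_NAMES], dtype=float)

    @classmethod
    def from_array(cls, arr: Sequence[float]) -> "SectorAverages":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (7,):
            raise ValueError("expected 7 sector values (g, t, ts, ti, n, ns, ni)")
        return cls(**dict(zip(SECTOR_NAMES, map(float, arr))))


def preprocess_profile(raw: RNFLProfile) -> RNFLProfile:
    """Repair and truncate a raw profile.

    Invalid samples (flagged missing, non-finite, or negative) are filled by
    linear interpolation between the nearest valid samples on each side,
    circularly across the 0/767 seam — the ring has no ends, so a missing run
    touching index 0 borrows from index 767's side. After filling, values
    above 300 μm are truncated to exactly 300 μm (inclusive bound). Valid
    in-range samples are never altered, so the operation is idempotent.

    Raises
    ------
    UnrepairableProfileError
        If every sample is missing/invalid — such scans mirror segmentation
        failures that cannot be corrected and must be excluded upstream.
    """
    values = raw.values.copy()
    invalid = raw.missing_mask | ~np.isfinite(values) | (values < 0)
    if invalid.all():
        raise UnrepairableProfileError("unrepairable profile: all 768 samples missing or invalid")
    if invalid.any():
        valid_idx = np.nonzero(~invalid)[0]
        fill_idx = np.nonzero(invalid)[0]
        values[fill_idx] = np.interp(
            fill_idx, valid_idx, values[valid_idx], period=N_SAMPLES
        )
    np.minimum(values, MAX_THICKNESS_UM, out=values)
    return RNFLProfile(values=values, missing_mask=np.zeros(N_SAMPLES, dtype=bool))


def sector_means(profile: RNFLProfile) -> SectorAverages:
    """Reduce a preprocessed profile to the 7 global/sectoral averages.

    ``g`` is the arithmetic mean of all 768 samples; each sector is the mean
    over its index range in the table above. The six sectors partition the
    ring, so the size-weighted mean of the sector values reproduces ``g``.
    """
    if not profile.is_preprocessed:
        raise ValueError("sector_means requires a preprocessed profile (no missing samples)")
    v = profile.values
    means = {name: float(v[sector_indices(name)].mean()) for name in SECTOR_SEGMENTS}
    return SectorAverages(g=float(v.mean()), **means)


def mirror_to_reference_orientation(profile: RNFLProfile, laterality: str) -> RNFLProfile:
    """Map a profile into the reference (OD) TSNIT frame.

    OD profiles pass through unchanged. OS profiles are index-reversed about
    the temporal anchor (index 0 stays fixed; sample i moves to 768 - i mod
    768), which swaps the superior/inferior traversal direction so that both
    eyes' superior sectors occupy the same indices. The map is an involution.
    """
    if laterality == "OD":
        return profile
    if laterality != "OS":
        raise ValueError(f"laterality must be OD or OS, got {laterality!r}")
    idx = (-np.arange(N_SAMPLES)) % N_SAMPLES
    return RNFLProfile(values=profile.values[idx], missing_mask=profile.missing_mask[idx])


def iter_scans(cohort: Iterable[EyeSeries]) -> Iterable[VisitScan]:
    for eye in cohort:
        yield from eye.scans


def preprocess_cohort(cohort: list[EyeSeries], mirror: bool = True) -> list[EyeSeries]:
    """Preprocess every scan in a cohort; optionally mirror OS eyes to the OD frame.

    Scans whose profile is unrepairable are dropped and flagged by setting
    nothing — they simply disappear from the returned series (mirroring the
    exclusion of uncorrectable segmentation failures from analysis).
    """
    out: list[EyeSeries] = []
    for eye in cohort:
        new_scans = []
        for scan in eye.scans:
            try:
                prof = preprocess_profile(scan.profile)
            except UnrepairableProfileError:
                continue
            if mirror:
                prof = mirror_to_reference_orientation(prof, scan.laterality)
            new_scans.append(replace(scan, profile=prof))
        out.append(
            EyeSeries(
                eye_id=eye.eye_id,
                patient_id=eye.patient_id,
                laterality=eye.laterality,
                diagnosis=eye.diagnosis,
                md_baseline=eye.md_baseline,
                sex=eye.sex,
                race=eye.race,
                scans=new_scans,
                age_baseline=eye.age_baseline,
            )
        )
    return out
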