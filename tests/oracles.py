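"""Independent reference implementations used to check the package.

These deliberately use plain loops / itertools rather than the package's
own vectorized code paths.
"""

import itertools

import numpy as np

from rnflcast.profiles import SECTOR_SEGMENTS
from rnflcast.triplets import GAP_WINDOW_DAYS


def circular_fill_oracle(values, missing):
    """Brute-force circular linear interpolation between nearest valid samples."""
    n = len(values)
    out = np.array(values, dtype=float)
    for i in range(n):
        if not missing[i]:
            continue
        left_off = next(d for d in range(1, n) if not missing[(i - d) % n])
        right_off = next(d for d in range(1, n) if not missing[(i + d) % n])
        lv = values[(i - left_off) % n]
        rv = values[(i + right_off) % n]
        span = left_off + right_off
        out[i] = lv + (rv - lv) * left_off / span
    return out


def sector_means_oracle(values):
    """Element-loop means over the documented index sets."""
    out = {}
    for name, segs in SECTOR_SEGMENTS.items():
        total, count = 0.0, 0
        for a, b in segs:
            for i in range(a, b):
                total += values[i]
                count += 1
        out[name] = total / count
    out["g"] = sum(values) / len(values)
    return out


def brute_force_triples(times, window=GAP_WINDOW_DAYS):
    """Independent enumeration of gap-valid ordered visit triples."""
    lo, hi = window
    return [
        (a, b, c)
        for a, b, c in itertools.combinations(sorted(times), 3)
        if lo <= b - a <= hi and lo <= c - b <= hi
    ]


def training_triplet_count_oracle(eye, window=GAP_WINDOW_DAYS):
    """Exhaustive count of gap-valid scan triples for one eye (good scans only)."""
    by_visit = {}
    for s in eye.scans:
        if s.quality_ok:
            by_visit.setdefault(s.visit_time, []).append(s)
    count = 0
    for t1, t2, t3 in brute_force_triples(sorted(by_visit), window):
        count += len(by_visit[t1]) * len(by_visit[t2]) * len(by_visit[t3])
    return count


def metrics_loop_oracle(pred, y, mre_floor=1.0):
    """Element-by-element reference for pooled MAE / MRE / R2."""
    abs_sum, rel_sum, rel_n, ss_res, n = 0.0, 0.0, 0, 0.0, 0
    flat_y = [v for row in y for v in row]
    mean_y = sum(flat_y) / len(flat_y)
    ss_tot = sum((v - mean_y) ** 2 for v in flat_y)
    for prow, yrow in zip(pred, y):
        for p, t in zip(prow, yrow):
            abs_sum += abs(p - t)
            ss_res += (p - t) ** 2
            n += 1
            if t >= mre_floor:
                rel_sum += abs(p - t) / t
                rel_n += 1
    return abs_sum / n, 100.0 * rel_sum / rel_n, 1.0 - ss_res / ss_tot
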