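"""Independent brute-force oracles used to cross-check the package.

These deliberately avoid the library calls used by the implementation:
local maxima come from an exhaustive scan, prominence from a contour
search over separating minima, width from an explicit half-prominence
crossing walk, and the distance rule from a greedy re-application of its
definition.
"""

from __future__ import annotations

import numpy as np


def brute_local_maxima(x: np.ndarray) -> list[int]:
    return [i for i in range(1, len(x) - 1) if x[i] > x[i - 1] and x[i] > x[i + 1]]


def brute_prominence(x: np.ndarray, i: int) -> tuple[float, int, int]:
    """Prominence plus the left/right base indices (minima positions)."""
    higher_left = [j for j in range(i) if x[j] > x[i]]
    lo = (max(higher_left) + 1) if higher_left else 0
    left_seg = x[lo : i + 1]
    left_min = float(left_seg.min())
    left_base = lo + int(np.argmin(left_seg))

    higher_right = [j for j in range(i + 1, len(x)) if x[j] > x[i]]
    hi = (min(higher_right) - 1) if higher_right else len(x) - 1
    right_seg = x[i : hi + 1]
    right_min = float(right_seg.min())
    right_base = i + int(np.argmin(right_seg))

    return float(x[i]) - max(left_min, right_min), left_base, right_base


def brute_width_at_half_prominence(x: np.ndarray, i: int) -> float:
    """Width in samples at the half-prominence evaluation height."""
    prom, left_base, right_base = brute_prominence(x, i)
    ref = float(x[i]) - 0.5 * prom

    k = i
    while k > left_base and x[k - 1] > ref:
        k -= 1
    if k == left_base or x[k - 1] == ref:
        left_ip = float(k) if x[k] <= ref else float(left_base)
        if k > left_base and x[k - 1] == ref:
            left_ip = float(k - 1)
    else:
        left_ip = (k - 1) + (ref - x[k - 1]) / (x[k] - x[k - 1])
    if x[left_base] > ref:  # cannot happen for true prominence, guard anyway
        left_ip = float(left_base)

    k = i
    while k < right_base and x[k + 1] > ref:
        k += 1
    if k == right_base:
        right_ip = float(right_base)
    elif x[k + 1] == ref:
        right_ip = float(k + 1)
    else:
        right_ip = (k + 1) - (ref - x[k + 1]) / (x[k] - x[k + 1])

    return right_ip - left_ip


def brute_detect(x: np.ndarray, params, sample_rate: float = 1000.0) -> list[int]:
    """Exhaustive re-application of every filter plus the distance rule."""
    ms_per_sample = 1000.0 / sample_rate
    survivors = []
    for i in brute_local_maxima(x):
        h = float(x[i])
        if not (params.min_height <= h <= params.max_height):
            continue
        prom, _, _ = brute_prominence(x, i)
        if prom < params.min_prominence:
            continue
        if brute_width_at_half_prominence(x, i) * ms_per_sample < params.min_width_ms:
            continue
        survivors.append(i)

    min_dist = params.min_distance_ms / ms_per_sample
    order = sorted(survivors, key=lambda i: (-x[i], i))
    kept: list[int] = []
    for i in order:
        if all(abs(i - k) >= min_dist for k in kept):
            kept.append(i)
    return sorted(kept)


def numeric_profile_area(profile, n_grid: int = 65536) -> float:
    """Midpoint-rule numeric integration of the circular step profile."""
    edges = np.cumsum([0.0] + [s.fraction for s in profile.segments])
    values = np.array([s.value for s in profile.segments])
    mid = (np.arange(n_grid) + 0.5) / n_grid
    seg_idx = np.clip(np.searchsorted(edges, mid, side="right") - 1, 0, values.size - 1)
    return float(values[seg_idx].mean())
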