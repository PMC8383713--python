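"""Candidate burst detection on the integrated MSNA channel.

A plain geometric detector: every local maximum is measured for
topographic prominence and width at half prominence, filtered on raw
height, prominence, and width, and thinned with a refractory distance
rule that keeps the higher of any two close peaks.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING, Sequence

import numpy as np
from scipy import signal as sps

if TYPE_CHECKING:  # pragma: no cover
    from .core_io import Recording


@dataclass
class PeakDetectionParams:
    """Geometric filters applied to candidate peaks.

    Defaults: 0.05 V prominence, 100 ms width, 250 ms distance, height
    within [0.05, 0.8] V.
    """

    min_prominence: float = 0.05
    min_width_ms: float = 100.0
    min_distance_ms: float = 250.0
    min_height: float = 0.05
    max_height: float = 0.8

    def __post_init__(self) -> None:
        for name in ("min_prominence", "min_width_ms", "min_distance_ms", "min_height", "max_height"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.min_height >= self.max_height:
            raise ValueError("min_height must be < max_height")


@dataclass
class CandidatePeak:
    """A detected local prominence in the MSNA channel."""

    index: int
    time: float
    height: float
    prominence: float
    width_ms: float
    left_ms: float = float("nan")
    right_ms: float = float("nan")


@dataclass
class SignalWindow:
    """Fixed-length excerpt centered on a peak; ``padded`` marks
    zero-filled out-of-range samples."""

    values: np.ndarray
    padded: bool


def compute_prominence(signal: Sequence[float], index: int) -> float:
    """Topographic prominence of the local maximum at ``index``.

    Height above the higher of the two lowest points separating the peak
    from higher terrain (or from the signal edge on either side).
    """
    x = np.asarray(signal, dtype=float)
    if index <= 0 or index >= x.size - 1:
        raise ValueError(f"index {index} is not an interior sample")
    if not (x[index] > x[index - 1] and x[index] > x[index + 1]):
        raise ValueError(f"index {index} is not a local maximum")
    prom = sps.peak_prominences(x, [index])[0][0]
    return float(prom)


def detect_candidate_peaks(
    msna: Sequence[float],
    params: PeakDetectionParams | None = None,
    sample_rate: float = 1000.0,
) -> list[CandidatePeak]:
    """Find all candidate burst peaks passing every geometric filter.

    Filters are applied per peak (height bounds, minimum prominence,
    minimum width at half prominence); survivors closer than the minimum
    distance are thinned, keeping the higher peak (the earlier one on
    exact ties).  Returned sorted by time.
    """
    params = params or PeakDetectionParams()
    x = np.asarray(msna, dtype=float)
    if x.size < 3:
        return []

    idx, _ = sps.find_peaks(x)
    if idx.size == 0:
        return []
    proms, left_bases, right_bases = sps.peak_prominences(x, idx)
    widths, _, left_ips, right_ips = sps.peak_widths(
        x, idx, rel_height=0.5, prominence_data=(proms, left_bases, right_bases)
    )
    ms_per_sample = 1000.0 / sample_rate
    widths_ms = widths * ms_per_sample

    heights = x[idx]
    keep = (
        (heights >= params.min_height)
        & (heights <= params.max_height)
        & (proms >= params.min_prominence)
        & (widths_ms >= params.min_width_ms)
    )
    idx, proms, widths_ms = idx[keep], proms[keep], widths_ms[keep]
    left_ips, right_ips = left_ips[keep], right_ips[keep]
    heights = heights[keep]
    if idx.size == 0:
        return []

    # refractory thinning: greedily keep by descending height, earlier on ties
    min_dist = params.min_distance_ms / ms_per_sample
    order = np.lexsort((idx, -heights))
    kept: list[int] = []
    selected = np.zeros(idx.size, dtype=bool)
    for j in order:
        if all(abs(int(idx[j]) - int(idx[k])) >= min_dist for k in kept):
            kept.append(j)
            selected[j] = True

    out = []
    for j in np.flatnonzero(selected):
        out.append(
            CandidatePeak(
                index=int(idx[j]),
                time=float(idx[j]) / sample_rate,
                height=float(heights[j]),
                prominence=float(proms[j]),
                width_ms=float(widths_ms[j]),
                left_ms=float(left_ips[j]) * ms_per_sample,
                right_ms=float(right_ips[j]) * ms_per_sample,
            )
        )
    out.sort(key=lambda p: p.index)
    return out


def extract_window(
    recording: "Recording", peak: CandidatePeak, half_width_ms: float
) -> SignalWindow:
    """Cut a ``2*half_width_ms + 1`` sample MSNA excerpt centered on the peak.

    Out-of-range samples are zero-padded and the window flagged.
    """
    if half_width_ms <= 0:
        raise ValueError("half_width_ms must be positive")
    half = int(round(half_width_ms * recording.sample_rate / 1000.0))
    n = recording.msna.size
    length = 2 * half + 1
    values = np.zeros(length, dtype=float)
    lo = peak.index - half
    hi = peak.index + half + 1
    src_lo, src_hi = max(lo, 0), min(hi, n)
    values[src_lo - lo : src_hi - lo] = recording.msna[src_lo:src_hi]
    return SignalWindow(values=values, padded=(lo < 0 or hi > n))


def extract_input_vector(
    recording: "Recording", peak: CandidatePeak, input_len: int
) -> SignalWindow:
    """Peak-centered excerpt of exactly ``input_len`` samples.

    Odd lengths are symmetric (half width ``(input_len - 1) / 2``); even
    lengths take the symmetric window of ``input_len + 1`` samples and
    trim the final one, so a 1000-sample request stays peak-centered.
    """
    if input_len < 1:
        raise ValueError("input_len must be >= 1")
    half = (input_len - 1) // 2 if input_len % 2 == 1 else input_len // 2
    win = extract_window(recording, peak, half * 1000.0 / recording.sample_rate)
    return SignalWindow(values=win.values[:input_len], padded=win.padded)


def write_peaks_bed(peaks: Sequence[CandidatePeak], path: str | Path) -> None:
    """Export peaks as a BED-like 3-column text: half-prominence start/end
    (ms) and height."""
    with open(path, "w") as fh:
        fh.write("start_ms\tend_ms\theight_v\n")
        for p in peaks:
            fh.write(f"{p.left_ms:.3f}\t{p.right_ms:.3f}\t{p.height:.6f}\n")
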