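"""Spectral signal-quality index and its likelihood model.

The quality marker of a candidate peak is the median of the absolute
values of the unnormalized forward discrete Fourier transform (full
two-sided spectrum, DC included) of the raw MSNA excerpt around it.
Quiet, burst-bearing signal yields low medians; broadband electrode
search noise yields distinctly higher ones.  The marker is turned into a
[0, 1] likelihood with a max-normalized Gaussian centered on the value
typical of valid signal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, NamedTuple, Sequence

import numpy as np
from scipy import stats

if TYPE_CHECKING:  # pragma: no cover
    from .core_io import Recording
    from .peak_detection import CandidatePeak


@dataclass
class QualityModel:
    """Gaussian likelihood model for the spectral quality index.

    ``center`` and ``sd`` are amplifier-gain dependent and recalibratable
    from labeled excerpts; ``noise_reference`` is informational only (the
    level typical of pure electrode-search noise).
    """

    center: float = 0.57
    sd: float = 0.3
    window_s: float = 60.0
    noise_reference: float = 1.5

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("sd must be strictly positive")
        if self.window_s <= 0:
            raise ValueError("window_s must be strictly positive")

    @classmethod
    def calibrated(
        cls,
        valid_medians: Sequence[float],
        sd: float | None = None,
        window_s: float = 60.0,
    ) -> "QualityModel":
        """Recalibrate the model on spectral medians of excerpts rated
        as valid signal: center = median of the sample, sd scaled
        proportionally to the default center/sd ratio unless given."""
        m = np.asarray(valid_medians, dtype=float)
        if m.size == 0:
            raise ValueError("valid_medians must be non-empty")
        center = float(np.median(m))
        if sd is None:
            sd = max(center * (0.3 / 0.57), 1e-12)
        return cls(center=center, sd=sd, window_s=window_s)


class PeakQuality(NamedTuple):
    median: float
    truncated: bool


class QualityGroupComparison(NamedTuple):
    u_statistic: float
    p_value: float
    median_valid: float
    median_invalid: float


def spectral_median(window: Sequence[float]) -> float:
    """Median of the two-sided DFT magnitude spectrum of a raw excerpt."""
    x = np.asarray(window, dtype=float)
    if x.size < 2:
        raise ValueError("window must contain at least 2 samples")
    return float(np.median(np.abs(np.fft.fft(x))))


def quality_index_for_peaks(
    recording: "Recording",
    peaks: Sequence["CandidatePeak"],
    model: QualityModel | None = None,
) -> list[PeakQuality]:
    """Spectral median of the raw MSNA window ``peak_time ± window_s/2``
    for each peak; boundary windows are truncated and flagged."""
    model = model or QualityModel()
    half = int(round(model.window_s / 2.0 * recording.sample_rate))
    n = recording.msna.size
    out = []
    for p in peaks:
        lo, hi = p.index - half, p.index + half
        truncated = lo < 0 or hi > n
        lo, hi = max(lo, 0), min(hi, n)
        out.append(PeakQuality(spectral_median(recording.msna[lo:hi]), truncated))
    return out


def quality_likelihood(median: float, model: QualityModel | None = None) -> float:
    """Max-normalized Gaussian likelihood of a spectral median, in (0, 1]."""
    model = model or QualityModel()
    if median < 0:
        raise ValueError("median must be >= 0")
    z = (median - model.center) / model.sd
    return float(np.exp(-0.5 * z * z))


def compare_quality_groups(
    valid_medians: Sequence[float], invalid_medians: Sequence[float]
) -> QualityGroupComparison:
    """Two-sided Mann-Whitney U test between valid and invalid excerpt
    medians; U is reported for the valid group."""
    v = np.asarray(valid_medians, dtype=float)
    i = np.asarray(invalid_medians, dtype=float)
    if v.size == 0 or i.size == 0:
        raise ValueError("both groups must be non-empty")
    res = stats.mannwhitneyu(v, i, alternative="two-sided")
    return QualityGroupComparison(
        u_statistic=float(res.statistic),
        p_value=float(res.pvalue),
        median_valid=float(np.median(v)),
        median_invalid=float(np.median(i)),
    )
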