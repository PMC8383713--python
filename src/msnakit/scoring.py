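"""Composite validity score and standard MSNA summary statistics.

Per-peak evidence (spectral quality, three network outputs, cardiac
timing) is laid out on a circle, each dimension occupying a configured
angular fraction; the composite score is the area under this step curve
normalized by the full circle, i.e. a weighted mean in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, NamedTuple, Sequence

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .core_io import PeakAnnotation


@dataclass
class ProfileWeights:
    """Angular fractions of the circular evidence profile.

    The quality index occupies half the circle by default; timing and
    the three network blocks split the other half into equal quarters.
    """

    w_quality: float = 0.5
    w_timing: float = 0.125
    w_nn: tuple[float, float, float] = (0.125, 0.125, 0.125)

    def __post_init__(self) -> None:
        self.w_nn = tuple(float(w) for w in self.w_nn)
        if len(self.w_nn) != 3:
            raise ValueError("w_nn must hold three fractions")
        weights = (self.w_quality, self.w_timing, *self.w_nn)
        if any(w < 0 for w in weights):
            raise ValueError("all weights must be >= 0")
        if abs(sum(weights) - 1.0) > 1e-9:
            raise ValueError(f"weights must sum to 1, got {sum(weights)}")


class ProfileSegment(NamedTuple):
    fraction: float
    value: float
    component: str


@dataclass
class ComponentProfile:
    """Ordered step segments covering the full circle."""

    segments: list[ProfileSegment]

    def __post_init__(self) -> None:
        total = sum(s.fraction for s in self.segments)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"segment fractions must sum to 1, got {total}")
        for s in self.segments:
            if not -1e-12 <= s.value <= 1.0 + 1e-12:
                raise ValueError(f"segment value {s.value} outside [0, 1]")


def assemble_profile(
    annotation: "PeakAnnotation", weights: ProfileWeights | None = None
) -> ComponentProfile:
    """Lay the annotation out on the circle.

    Fixed order: quality, then per network a block subdivided into equal
    thirds (continuous positive likelihood flanking the binary outcome),
    then timing.
    """
    weights = weights or ProfileWeights()
    segments = [ProfileSegment(weights.w_quality, annotation.quality_likelihood, "quality")]
    for i in range(3):
        w3 = weights.w_nn[i] / 3.0
        p = annotation.nn_prob[i]
        segments += [
            ProfileSegment(w3, p, f"nn{i + 1}_prob"),
            ProfileSegment(w3, float(annotation.nn_label[i]), f"nn{i + 1}_label"),
            ProfileSegment(w3, p, f"nn{i + 1}_prob"),
        ]
    segments.append(ProfileSegment(weights.w_timing, annotation.timing_likelihood, "timing"))
    return ComponentProfile(segments)


def composite_score(profile: ComponentProfile) -> float:
    """Normalized area under the circular step profile, in [0, 1]."""
    return float(sum(s.fraction * s.value for s in profile.segments))


def composite_from_components(
    quality_likelihood: float,
    timing_likelihood: float,
    nn_prob: Sequence[float],
    nn_label: Sequence[int],
    weights: ProfileWeights | None = None,
) -> float:
    """Closed-form composite: quality and timing weighted directly, each
    network block contributing ``(2 * p_pos + label) / 3`` of its weight."""
    weights = weights or ProfileWeights()
    score = weights.w_quality * quality_likelihood + weights.w_timing * timing_likelihood
    for w, p, l in zip(weights.w_nn, nn_prob, nn_label):
        score += w * (2.0 * p + l) / 3.0
    return float(score)


def burst_frequency(n_bursts: int, duration_min: float) -> float:
    """Bursts per minute."""
    if n_bursts < 0:
        raise ValueError("n_bursts must be >= 0")
    if duration_min <= 0:
        raise ValueError("duration_min must be strictly positive")
    return n_bursts / duration_min


def burst_incidence(n_bursts: int, n_heartbeats: int) -> float:
    """Bursts per 100 heartbeats."""
    if n_bursts < 0:
        raise ValueError("n_bursts must be >= 0")
    if n_heartbeats <= 0:
        raise ValueError("n_heartbeats must be strictly positive")
    return 100.0 * n_bursts / n_heartbeats


def total_msna(frequency: float, mean_height: float) -> float:
    """Product of burst frequency and mean burst height."""
    if frequency < 0 or mean_height < 0:
        raise ValueError("inputs must be >= 0")
    return frequency * mean_height


def select_valid_bursts(
    annotations: Sequence["PeakAnnotation"], threshold: float = 0.5
) -> list["PeakAnnotation"]:
    """Annotations whose composite strictly exceeds the threshold, order
    preserved."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    return [a for a in annotations if a.composite > threshold]


def plot_profile(profile: ComponentProfile, path: str) -> None:  # pragma: no cover
    """Optional circular rendering of a profile (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    theta = []
    r = []
    start = 0.0
    for s in profile.segments:
        seg_theta = np.linspace(start, start + s.fraction, 32) * 2.0 * np.pi
        theta.extend(seg_theta)
        r.extend([s.value] * seg_theta.size)
        start += s.fraction
    fig = plt.figure(figsize=(4, 4))
    ax = fig.add_subplot(projection="polar")
    ax.plot(theta, r)
    ax.fill(theta, r, alpha=0.3)
    ax.set_ylim(0, 1.05)
    ax.set_title(f"composite = {composite_score(profile):.3f}")
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)
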