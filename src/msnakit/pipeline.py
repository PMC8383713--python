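"""End-to-end analysis: detection, scoring, and summary statistics."""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .classifier import DenseNet, predict_window
from .core_io import AnalysisConfig, PeakAnnotation, Recording
from .peak_detection import detect_candidate_peaks, extract_input_vector
from .quality import quality_index_for_peaks, quality_likelihood
from .scoring import (
    burst_frequency,
    burst_incidence,
    composite_from_components,
    select_valid_bursts,
    total_msna,
)
from .timing import detect_r_waves, timing_likelihood


def annotate_recording(
    recording: Recording,
    config: AnalysisConfig | None = None,
    models: Sequence[DenseNet] = (),
    height_cm: float | None = None,
) -> list[PeakAnnotation]:
    """Detect candidate peaks and attach every per-peak evidence value.

    ``models`` holds up to three trained classifiers; if fewer are given
    the last one fills the remaining slots, and with none at all the
    network outputs are neutral (probability 0.5).  Height falls back to
    the recording metadata, then to the timing-model default.
    """
    config = config or AnalysisConfig()
    if height_cm is None:
        height_cm = recording.subject_height_cm

    peaks = detect_candidate_peaks(recording.msna, config.peak_params, recording.sample_rate)
    if not peaks:
        return []
    if recording.ecg is None:
        raise ValueError("recording has no ECG channel; timing model requires one")
    r_times = detect_r_waves(recording.ecg, recording.sample_rate)
    if r_times.size == 0:
        raise ValueError("no R-waves detected in the ECG channel")

    qualities = quality_index_for_peaks(recording, peaks, config.quality_model)

    slot_models: list[DenseNet | None] = list(models[:3])
    while len(slot_models) < 3:
        slot_models.append(slot_models[-1] if slot_models else None)

    annotations = []
    for peak, q in zip(peaks, qualities):
        nn_prob, nn_label = [], []
        for model in slot_models:
            if model is None:
                p_pos, label = 0.5, 1
            else:
                window = extract_input_vector(recording, peak, model.input_len)
                _, p_pos, label = predict_window(model, window.values)
            nn_prob.append(p_pos)
            nn_label.append(label)
        t_like = timing_likelihood(peak.time, r_times, height_cm, config.timing_model)
        q_like = quality_likelihood(q.median, config.quality_model)
        composite = composite_from_components(
            q_like, t_like, nn_prob, nn_label, config.profile_weights
        )
        annotations.append(
            PeakAnnotation(
                peak_time=peak.time,
                peak_height=peak.height,
                nn_prob=tuple(nn_prob),
                nn_label=tuple(nn_label),
                timing_likelihood=t_like,
                quality_median=q.median,
                quality_likelihood=q_like,
                composite=composite,
            )
        )
    return annotations


def summarize_annotations(
    annotations: Sequence[PeakAnnotation],
    duration_min: float,
    n_heartbeats: int | None = None,
    threshold: float = 0.5,
) -> dict:
    """Standard MSNA summary from an annotation list."""
    valid = select_valid_bursts(annotations, threshold)
    freq = burst_frequency(len(valid), duration_min)
    summary = {
        "n_peaks": len(annotations),
        "n_valid": len(valid),
        "threshold": threshold,
        "bursts_per_min": freq,
        "total_msna": total_msna(freq, float(np.mean([a.peak_height for a in valid])) if valid else 0.0),
    }
    if n_heartbeats is not None:
        summary["bursts_per_100_hb"] = burst_incidence(len(valid), n_heartbeats)
    return summary


def analyze_recording(
    recording: Recording,
    config: AnalysisConfig | None = None,
    models: Sequence[DenseNet] = (),
    height_cm: float | None = None,
    threshold: float = 0.5,
) -> tuple[list[PeakAnnotation], dict]:
    """Annotate a recording and compute the summary in one call."""
    annotations = annotate_recording(recording, config, models, height_cm)
    n_heartbeats = None
    if recording.ecg is not None:
        n_heartbeats = int(detect_r_waves(recording.ecg, recording.sample_rate).size)
    summary = summarize_annotations(
        annotations, recording.duration_s / 60.0, n_heartbeats, threshold
    )
    return annotations, summary
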