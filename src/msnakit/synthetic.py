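"""Seeded simulator of structured ECG / blood-pressure / MSNA recordings.

The simulator does not aim at biophysical realism; it reproduces the
statistical structure the analysis relies on: R-wave spike trains with
jittered RR intervals, a pressure wave whose diastolic nadir sits at a
fixed offset after the R-wave with the systolic upstroke shortly after,
burst-shaped MSNA bumps at a height-dependent latency after a random
subset of heartbeats, and optional electrode-search epochs of broadband
noise with bursts suppressed.  All randomness flows from one seed
through named `SeedSequence` substreams.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.ndimage import uniform_filter1d

from .classifier import LabeledWindowSet
from .core_io import Recording
from .peak_detection import CandidatePeak, PeakDetectionParams, detect_candidate_peaks, extract_input_vector
from .timing import TimingModel, expected_latency

#: Asymmetric burst morphology: slower decay than rise.
BURST_RISE_SD_MS = 100.0
BURST_DECAY_SD_MS = 180.0

_STREAMS = ("rr", "burst_occurrence", "burst_height", "burst_jitter", "baseline", "search", "windows")


def _rngs(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(s) for name, s in zip(_STREAMS, children)}


@dataclass
class SyntheticConfig:
    duration_s: float = 60.0
    rr_mean_ms: float = 1000.0
    rr_jitter_ms: float = 30.0
    burst_prob: float = 0.4
    burst_height_min_v: float = 0.1
    burst_height_max_v: float = 0.8
    burst_width_ms: float = 500.0
    latency_ms: float | None = None  # default: TimingModel latency at 175 cm
    timing_jitter_ms: float = 50.0
    ecg_to_diastole_ms: float = 180.0
    diastole_to_systole_ms: float = 120.0
    baseline_noise_v: float = 0.02
    search_noise_v: float = 0.3
    noise_epochs: list[tuple[float, float]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be strictly positive")
        if self.rr_mean_ms <= 0:
            raise ValueError("rr_mean_ms must be strictly positive")
        if not 0.0 <= self.burst_prob <= 1.0:
            raise ValueError("burst_prob must lie in [0, 1]")
        if not 0.05 <= self.burst_height_min_v <= self.burst_height_max_v <= 0.8:
            raise ValueError("burst heights must satisfy 0.05 <= min <= max <= 0.8")
        if self.diastole_to_systole_ms > 150:
            raise ValueError("diastole_to_systole_ms must be <= 150 (nadir follow rule)")
        if self.latency_ms is None:
            self.latency_ms = expected_latency(None, TimingModel())
        for lo, hi in self.noise_epochs:
            if not 0 <= lo < hi <= self.duration_s:
                raise ValueError(f"invalid noise epoch ({lo}, {hi})")


@dataclass
class GroundTruth:
    """Simulator-emitted truth enabling oracle tests."""

    r_times: np.ndarray
    bp_nadir_times: np.ndarray
    burst_times: np.ndarray
    burst_heights: np.ndarray
    noise_epochs: list[tuple[float, float]]
    duration_s: float

    def __post_init__(self) -> None:
        self.r_times = np.asarray(self.r_times, dtype=float)
        self.bp_nadir_times = np.asarray(self.bp_nadir_times, dtype=float)
        self.burst_times = np.asarray(self.burst_times, dtype=float)
        self.burst_heights = np.asarray(self.burst_heights, dtype=float)

    def valid_duration_s(self) -> float:
        return self.duration_s - sum(hi - lo for lo, hi in self.noise_epochs)

    def in_noise_epoch(self, t: float) -> bool:
        return any(lo <= t < hi for lo, hi in self.noise_epochs)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "r_times": self.r_times.tolist(),
                    "bp_nadir_times": self.bp_nadir_times.tolist(),
                    "burst_times": self.burst_times.tolist(),
                    "burst_heights": self.burst_heights.tolist(),
                    "noise_epochs": [list(e) for e in self.noise_epochs],
                    "duration_s": self.duration_s,
                },
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            r_times=np.array(d["r_times"]),
            bp_nadir_times=np.array(d["bp_nadir_times"]),
            burst_times=np.array(d["burst_times"]),
            burst_heights=np.array(d["burst_heights"]),
            noise_epochs=[tuple(e) for e in d["noise_epochs"]],
            duration_s=float(d["duration_s"]),
        )


#: Time scale of electrode-search noise features, matching the ~100 ms
#: analog integration of the neurogram.
INTEGRATION_MS = 100
#: Time scale of quiet-baseline amplifier noise (broader band, so its
#: wiggles stay far below the 100 ms width filter).
BASELINE_NOISE_MS = 20


def integrated_noise(
    rng: np.random.Generator,
    n: int,
    sd: float,
    sample_rate: float = 1000.0,
    window_ms: float = INTEGRATION_MS,
) -> np.ndarray:
    """Broadband noise smoothed to a given feature time scale.

    White noise is passed through a moving average of ``window_ms`` and
    rescaled to the requested standard deviation, so noise features
    carry the time scale of real integrated neurogram activity.
    """
    width = max(1, int(round(window_ms * sample_rate / 1000.0)))
    x = uniform_filter1d(rng.normal(0.0, 1.0, n), size=width, mode="nearest")
    s = x.std()
    return x * (sd / s) if s > 0 else x


def burst_template(
    height: float,
    rise_sd_ms: float = BURST_RISE_SD_MS,
    decay_sd_ms: float = BURST_DECAY_SD_MS,
    sample_rate: float = 1000.0,
) -> tuple[np.ndarray, int]:
    """Asymmetric Gaussian burst bump.

    Returns the sampled bump (support +-4 sd each side) and the index of
    its apex within the returned array.
    """
    left = int(round(4 * rise_sd_ms * sample_rate / 1000.0))
    right = int(round(4 * decay_sd_ms * sample_rate / 1000.0))
    dt_ms = np.arange(-left, right + 1) * 1000.0 / sample_rate
    sd = np.where(dt_ms < 0, rise_sd_ms, decay_sd_ms)
    return height * np.exp(-0.5 * (dt_ms / sd) ** 2), left


def _bp_wave(
    n: int,
    nadir_idx: np.ndarray,
    systole_offset: int,
    low: float = 75.0,
    high: float = 120.0,
) -> np.ndarray:
    """Piecewise-cosine pressure wave: nadir exactly at each nadir index,
    systolic peak ``systole_offset`` samples later."""
    bp = np.full(n, (low + high) / 2.0)

    def fill(lo: int, hi: int, v0: float, v1: float) -> None:
        lo_c, hi_c = max(lo, 0), min(hi, n)
        if hi_c <= lo_c or hi <= lo:
            return
        s = np.arange(lo_c, hi_c)
        phase = (s - lo) / (hi - lo)
        bp[lo_c:hi_c] = v0 + (v1 - v0) * 0.5 * (1.0 - np.cos(np.pi * phase))

    if nadir_idx.size == 0:
        return bp
    # leading decay into the first nadir
    fill(0, nadir_idx[0], high, low)
    for i, nd in enumerate(nadir_idx):
        peak = nd + systole_offset
        fill(nd, peak, low, high)
        nxt = nadir_idx[i + 1] if i + 1 < nadir_idx.size else n
        fill(peak, nxt, high, low)
    bp[min(nadir_idx[-1] + systole_offset, n - 1):] = np.clip(
        bp[min(nadir_idx[-1] + systole_offset, n - 1):], low, high
    )
    return bp


def simulate_recording(config: SyntheticConfig | None = None) -> tuple[Recording, GroundTruth]:
    """Simulate an aligned 1 kHz ECG/BP/MSNA recording with ground truth.

    Identical seeds give bit-identical output.
    """
    config = config or SyntheticConfig()
    fs = 1000.0
    n = int(round(config.duration_s * fs))
    rngs = _rngs(config.seed)

    # R-wave train with jittered RR intervals
    r_list = []
    t = 0.5
    while t < config.duration_s - 0.05:
        r_list.append(t)
        rr = config.rr_mean_ms + rngs["rr"].normal(0.0, config.rr_jitter_ms)
        t += max(rr, 200.0) / 1000.0
    r_idx = np.round(np.array(r_list) * fs).astype(int)
    r_idx = r_idx[(r_idx >= 0) & (r_idx < n)]
    r_times = r_idx / fs

    # ECG: 10 ms triangular R spikes of unit amplitude
    ecg = np.zeros(n)
    half_spike = 5
    tri = 1.0 - np.abs(np.arange(-half_spike, half_spike + 1)) / (half_spike + 1)
    for i in r_idx:
        lo, hi = i - half_spike, i + half_spike + 1
        lo_c, hi_c = max(lo, 0), min(hi, n)
        ecg[lo_c:hi_c] = np.maximum(ecg[lo_c:hi_c], tri[lo_c - lo : hi_c - lo])

    # BP: nadir at R + ecg_to_diastole, systolic peak diastole_to_systole later
    nadir_offset = int(round(config.ecg_to_diastole_ms * fs / 1000.0))
    systole_offset = int(round(config.diastole_to_systole_ms * fs / 1000.0))
    nadir_idx = r_idx + nadir_offset
    nadir_idx = nadir_idx[(nadir_idx > 0) & (nadir_idx < n - systole_offset - 1)]
    bp = _bp_wave(n, nadir_idx, systole_offset)
    bp_nadir_times = nadir_idx / fs

    # MSNA: quiet baseline noise + cardiac-locked burst bumps
    msna = integrated_noise(rngs["baseline"], n, config.baseline_noise_v, fs, BASELINE_NOISE_MS)
    burst_times, burst_heights = [], []
    occur = rngs["burst_occurrence"].random(r_idx.size)
    for k, r in enumerate(r_times):
        if occur[k] >= config.burst_prob:
            continue
        jitter = rngs["burst_jitter"].normal(0.0, config.timing_jitter_ms)
        # bursts are locked to the diastolic nadir, latency downstream of it
        delay_ms = config.ecg_to_diastole_ms + config.latency_ms + jitter
        apex = int(round((r + delay_ms / 1000.0) * fs))
        if not 0 <= apex < n:
            continue
        t_apex = apex / fs
        if any(lo <= t_apex < hi for lo, hi in config.noise_epochs):
            continue  # bursts suppressed while the electrode is searching
        height = rngs["burst_height"].uniform(config.burst_height_min_v, config.burst_height_max_v)
        bump, bump_apex = burst_template(height, sample_rate=fs)
        lo = apex - bump_apex
        hi = lo + bump.size
        lo_c, hi_c = max(lo, 0), min(hi, n)
        msna[lo_c:hi_c] += bump[lo_c - lo : hi_c - lo]
        burst_times.append(t_apex)
        burst_heights.append(height)

    for lo, hi in config.noise_epochs:
        i0, i1 = int(round(lo * fs)), int(round(hi * fs))
        msna[i0:i1] = integrated_noise(rngs["search"], i1 - i0, config.search_noise_v, fs)

    recording = Recording(
        time=np.arange(n) / fs,
        msna=msna,
        ecg=ecg,
        bp=bp,
        sample_rate=fs,
        subject_id=f"synthetic-{config.seed}",
    )
    truth = GroundTruth(
        r_times=r_times,
        bp_nadir_times=bp_nadir_times,
        burst_times=np.array(burst_times),
        burst_heights=np.array(burst_heights),
        noise_epochs=list(config.noise_epochs),
        duration_s=config.duration_s,
    )
    return recording, truth


def simulate_labeled_windows(
    n: int,
    input_len: int = 1000,
    separation: float = 4.0,
    seed: int = 0,
    noise_sd: float = 0.1,
) -> LabeledWindowSet:
    """Balanced labeled window set for classifier training.

    Positives are noise plus a burst bump whose apex sits at the window
    center sample and whose height is ``separation * noise_sd`` (with
    20 % spread); negatives are pure noise of the same amplitude, so at
    ``separation = 0`` the classes are indistinguishable.
    """
    if n < 4 or n % 2 != 0:
        raise ValueError("n must be even and >= 4")
    rng = _rngs(seed)["windows"]
    half = n // 2
    windows = np.stack([integrated_noise(rng, input_len, noise_sd) for _ in range(n)])
    labels = np.zeros(n, dtype=int)
    labels[:half] = 1
    center = input_len // 2
    for i in range(half):
        height = separation * noise_sd * rng.uniform(0.8, 1.2)
        bump, bump_apex = burst_template(height)
        lo = center - bump_apex
        hi = lo + bump.size
        lo_c, hi_c = max(lo, 0), min(hi, input_len)
        windows[i, lo_c:hi_c] += bump[lo_c - lo : hi_c - lo]
    perm = rng.permutation(n)
    provenance = [f"synthetic-{seed}-{'pos' if labels[i] else 'neg'}-{i}" for i in perm]
    return LabeledWindowSet(windows[perm], labels[perm], provenance)


def labeled_windows_from_recording(
    recording: Recording,
    truth: GroundTruth,
    input_len: int = 1000,
    seed: int = 0,
    params: PeakDetectionParams | None = None,
) -> LabeledWindowSet:
    """Labeled windows drawn from a simulated recording itself.

    Positives are windows centered on ground-truth burst apices;
    negatives are candidate peaks detected inside electrode-search noise
    epochs (balanced to the positive count by seeded subsampling).
    """
    rng = _rngs(seed)["windows"]
    fs = recording.sample_rate

    pos_windows = []
    for t in truth.burst_times:
        peak = CandidatePeak(index=int(round(t * fs)), time=t, height=0.0, prominence=0.0, width_ms=0.0)
        pos_windows.append(extract_input_vector(recording, peak, input_len).values)

    all_peaks = detect_candidate_peaks(recording.msna, params, fs)
    neg_peaks = [p for p in all_peaks if truth.in_noise_epoch(p.time)]
    neg_windows = [extract_input_vector(recording, p, input_len).values for p in neg_peaks]
    if not pos_windows or not neg_windows:
        raise ValueError("recording must yield both burst and noise-epoch windows")

    n_per_class = min(len(pos_windows), len(neg_windows))
    pos_sel = rng.choice(len(pos_windows), n_per_class, replace=False)
    neg_sel = rng.choice(len(neg_windows), n_per_class, replace=False)
    windows = np.vstack([np.array(pos_windows)[pos_sel], np.array(neg_windows)[neg_sel]])
    labels = np.concatenate([np.ones(n_per_class, dtype=int), np.zeros(n_per_class, dtype=int)])
    perm = rng.permutation(labels.size)
    return LabeledWindowSet(windows[perm], labels[perm], [recording.subject_id] * labels.size)
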