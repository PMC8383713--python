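"""Domain types, recording reader, annotation table I/O, and configuration.

Recordings are delimited-text exports of laboratory acquisition systems:
one header line, one numeric column per channel, nominally sampled at
1000 points per second.  Inputs at other rates are linearly resampled to
the 1 kHz analysis grid on ingestion.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .peak_detection import PeakDetectionParams
from .quality import QualityModel
from .scoring import ProfileWeights
from .timing import TimingModel

TARGET_SAMPLE_RATE = 1000.0

DEFAULT_COLUMN_MAP = {"time": "time", "msna": "msna", "ecg": "ecg", "bp": "bp"}

#: Fixed column order of the annotation CSV.
ANNOTATION_COLUMNS = [
    "peak_time_s",
    "peak_height_v",
    "nn1_prob",
    "nn2_prob",
    "nn3_prob",
    "nn1_label",
    "nn2_label",
    "nn3_label",
    "timing_likelihood",
    "quality_median",
    "quality_likelihood",
    "composite",
]


class FormatError(ValueError):
    """A required column is missing or the file layout is not usable."""


class ParseError(ValueError):
    """A mapped column contains a non-numeric cell."""


class EmptyInputError(ValueError):
    """The input file contains no data rows."""


class ConfigError(ValueError):
    """A configuration file is malformed or contains invalid values."""


@dataclass
class Recording:
    """Aligned multi-channel recording on a uniform 1 kHz time grid.

    Parameters
    ----------
    time :
        Sample times in seconds, strictly increasing with step
        ``1 / sample_rate``.
    msna :
        Integrated MSNA neurogram in volts (required).
    ecg :
        ECG channel in arbitrary units, or ``None``.
    bp :
        Continuous arterial pressure in mmHg, or ``None``.
    """

    time: np.ndarray
    msna: np.ndarray
    ecg: np.ndarray | None = None
    bp: np.ndarray | None = None
    sample_rate: float = TARGET_SAMPLE_RATE
    subject_height_cm: float | None = None
    subject_id: str = ""
    resampled: bool = False

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.msna = np.asarray(self.msna, dtype=float)
        if self.time.ndim != 1 or self.time.size < 1:
            raise ValueError("time must be a 1-D array with at least one sample")
        for name in ("ecg", "bp"):
            ch = getattr(self, name)
            if ch is not None:
                setattr(self, name, np.asarray(ch, dtype=float))
        n = self.time.size
        for name in ("msna", "ecg", "bp"):
            ch = getattr(self, name)
            if ch is not None and ch.shape != (n,):
                raise ValueError(f"channel {name!r} length {ch.shape} != time length {n}")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if n > 1:
            dt = np.diff(self.time)
            if np.any(dt <= 0):
                raise ValueError("time must be strictly increasing")
            if not np.allclose(dt, 1.0 / self.sample_rate, rtol=1e-6, atol=1e-6):
                raise ValueError("time grid is not uniform at the stated sample rate")
        if self.subject_height_cm is not None and self.subject_height_cm <= 0:
            raise ValueError("subject_height_cm must be positive")

    @property
    def n_samples(self) -> int:
        return self.time.size

    @property
    def duration_s(self) -> float:
        return self.time.size / self.sample_rate


@dataclass
class PeakAnnotation:
    """Per-candidate evidence bundle produced by the analysis pipeline."""

    peak_time: float
    peak_height: float
    nn_prob: tuple[float, float, float]
    nn_label: tuple[int, int, int]
    timing_likelihood: float
    quality_median: float
    quality_likelihood: float
    composite: float

    def __post_init__(self) -> None:
        self.nn_prob = tuple(float(p) for p in self.nn_prob)
        self.nn_label = tuple(int(l) for l in self.nn_label)
        if len(self.nn_prob) != 3 or len(self.nn_label) != 3:
            raise ValueError("nn_prob and nn_label must each hold three values")
        for p, l in zip(self.nn_prob, self.nn_label):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"nn_prob {p} outside [0, 1]")
            if l != int(p >= 0.5):
                raise ValueError("nn_label must be 1 exactly when nn_prob >= 0.5")
        for name in ("timing_likelihood", "quality_likelihood", "composite"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} {v} outside [0, 1]")
        if self.quality_median < 0:
            raise ValueError("quality_median must be >= 0")


def _read_table(path: str | Path) -> pd.DataFrame:
    import csv

    try:
        df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise EmptyInputError(f"{path}: empty input file") from exc
    except csv.Error:
        # sniffing failed (e.g. single column, odd spacing): retry as whitespace
        try:
            df = pd.read_csv(path, sep=r"\s+", engine="python", dtype=str)
        except pd.errors.EmptyDataError as exc:
            raise EmptyInputError(f"{path}: empty input file") from exc
    if df.shape[1] == 1 and df.columns[0].count(" ") > 0:
        # csv.Sniffer missed a space-delimited layout
        df = pd.read_csv(path, sep=r"\s+", engine="python", dtype=str)
    if df.shape[0] == 0:
        raise EmptyInputError(f"{path}: no data rows")
    return df


def _numeric_column(df: pd.DataFrame, column: str, path: str | Path) -> np.ndarray:
    raw = df[column]
    values = pd.to_numeric(raw, errors="coerce")
    bad = values.isna() & raw.notna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ParseError(
            f"{path}: non-numeric value {raw.iloc[row]!r} in column {column!r} at data row {row}"
        )
    if values.isna().any():
        row = int(np.flatnonzero(values.isna().to_numpy())[0])
        raise ParseError(f"{path}: missing value in column {column!r} at data row {row}")
    return values.to_numpy(dtype=float)


def _resample_linear(t_old: np.ndarray, y: np.ndarray, t_new: np.ndarray) -> np.ndarray:
    """Linear interpolation with linear extrapolation at the edges."""
    out = np.interp(t_new, t_old, y)
    if t_old.size >= 2:
        right = t_new > t_old[-1]
        if right.any():
            slope = (y[-1] - y[-2]) / (t_old[-1] - t_old[-2])
            out[right] = y[-1] + slope * (t_new[right] - t_old[-1])
        left = t_new < t_old[0]
        if left.any():
            slope = (y[1] - y[0]) / (t_old[1] - t_old[0])
            out[left] = y[0] + slope * (t_new[left] - t_old[0])
    return out


def read_recording(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    subject_height_cm: float | None = None,
    subject_id: str = "",
) -> Recording:
    """Read a delimited-text recording and align it on the 1 kHz grid.

    ``column_map`` maps channel names (``time``, ``msna``, ``ecg``, ``bp``)
    to column headers in the file; channels whose mapped column is absent
    are left out, except ``msna`` which is required.  Input sampled at a
    rate other than 1000 Hz is linearly resampled and the result flagged.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    df = _read_table(path)
    if cmap["msna"] not in df.columns:
        raise FormatError(
            f"{path}: required MSNA column {cmap['msna']!r} not found "
            f"(columns: {list(df.columns)})"
        )

    channels: dict[str, np.ndarray | None] = {}
    for name in ("msna", "ecg", "bp"):
        col = cmap.get(name)
        channels[name] = _numeric_column(df, col, path) if col in df.columns else None

    n = channels["msna"].size  # type: ignore[union-attr]
    if cmap.get("time") in df.columns:
        t = _numeric_column(df, cmap["time"], path)
    else:
        t = np.arange(n) / TARGET_SAMPLE_RATE

    resampled = False
    if n > 1:
        dt = float(np.median(np.diff(t)))
        if dt <= 0:
            raise ParseError(f"{path}: time column is not increasing")
        if abs(dt - 1.0 / TARGET_SAMPLE_RATE) > 1e-9:
            n_new = int(round(n * dt * TARGET_SAMPLE_RATE))
            t_new = t[0] + np.arange(n_new) / TARGET_SAMPLE_RATE
            for name, ch in channels.items():
                if ch is not None:
                    channels[name] = _resample_linear(t, ch, t_new)
            t = t_new
            resampled = True
        else:
            # snap to an exact uniform grid to absorb text round-off
            t = t[0] + np.arange(n) / TARGET_SAMPLE_RATE

    return Recording(
        time=t,
        msna=channels["msna"],
        ecg=channels["ecg"],
        bp=channels["bp"],
        sample_rate=TARGET_SAMPLE_RATE,
        subject_height_cm=subject_height_cm,
        subject_id=subject_id,
        resampled=resampled,
    )


def write_recording(recording: Recording, path: str | Path) -> None:
    """Write a recording as a tab-delimited text file readable by
    :func:`read_recording`."""
    data = {"time": recording.time, "msna": recording.msna}
    if recording.ecg is not None:
        data["ecg"] = recording.ecg
    if recording.bp is not None:
        data["bp"] = recording.bp
    pd.DataFrame(data).to_csv(path, sep="\t", index=False, float_format="%.6f")


def write_annotation_table(annotations: Sequence[PeakAnnotation], path: str | Path) -> None:
    """Write one CSV row per annotated peak, floats at six decimals."""
    rows = []
    for a in annotations:
        rows.append(
            {
                "peak_time_s": a.peak_time,
                "peak_height_v": a.peak_height,
                "nn1_prob": a.nn_prob[0],
                "nn2_prob": a.nn_prob[1],
                "nn3_prob": a.nn_prob[2],
                "nn1_label": a.nn_label[0],
                "nn2_label": a.nn_label[1],
                "nn3_label": a.nn_label[2],
                "timing_likelihood": a.timing_likelihood,
                "quality_median": a.quality_median,
                "quality_likelihood": a.quality_likelihood,
                "composite": a.composite,
            }
        )
    df = pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)
    df.to_csv(path, index=False, float_format="%.6f")


def read_annotation_table(path: str | Path) -> list[PeakAnnotation]:
    df = pd.read_csv(path)
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing annotation columns {missing}")
    out = []
    for _, r in df.iterrows():
        out.append(
            PeakAnnotation(
                peak_time=float(r["peak_time_s"]),
                peak_height=float(r["peak_height_v"]),
                nn_prob=(float(r["nn1_prob"]), float(r["nn2_prob"]), float(r["nn3_prob"])),
                nn_label=(int(r["nn1_label"]), int(r["nn2_label"]), int(r["nn3_label"])),
                timing_likelihood=float(r["timing_likelihood"]),
                quality_median=float(r["quality_median"]),
                quality_likelihood=float(r["quality_likelihood"]),
                composite=float(r["composite"]),
            )
        )
    return out


@dataclass
class AnalysisConfig:
    """Bundle of all tunable analysis parameters.

    Every nested block validates its own invariants on construction, so a
    successfully loaded config is usable as-is.
    """

    peak_params: PeakDetectionParams = field(default_factory=PeakDetectionParams)
    quality_model: QualityModel = field(default_factory=QualityModel)
    timing_model: TimingModel = field(default_factory=TimingModel)
    profile_weights: ProfileWeights = field(default_factory=ProfileWeights)
    classifier_paths: list[str] = field(default_factory=list)

    _SECTIONS = {
        "peak_params": PeakDetectionParams,
        "quality_model": QualityModel,
        "timing_model": TimingModel,
        "profile_weights": ProfileWeights,
    }

    @classmethod
    def from_dict(cls, data: Mapping | None) -> "AnalysisConfig":
        data = dict(data or {})
        kwargs: dict = {}
        unknown = set(data) - set(cls._SECTIONS) - {"classifier_paths"}
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for section, typ in cls._SECTIONS.items():
            block = data.get(section, {})
            if not isinstance(block, Mapping):
                raise ConfigError(f"{section}: expected a mapping")
            valid_fields = {f.name for f in dataclasses.fields(typ)}
            bad = set(block) - valid_fields
            if bad:
                raise ConfigError(f"{section}: unknown keys {sorted(bad)}")
            try:
                kwargs[section] = typ(**block)
            except ValueError as exc:
                raise ConfigError(f"{section}: {exc}") from exc
        paths = data.get("classifier_paths", [])
        if not isinstance(paths, (list, tuple)):
            raise ConfigError("classifier_paths: expected a list")
        kwargs["classifier_paths"] = [str(p) for p in paths]
        return cls(**kwargs)

    def to_dict(self) -> dict:
        out: dict = {}
        for section, _ in self._SECTIONS.items():
            block = dataclasses.asdict(getattr(self, section))
            # dataclasses.asdict keeps tuples; YAML/JSON round-trip as lists
            out[section] = {
                k: (list(v) if isinstance(v, tuple) else v) for k, v in block.items()
            }
        out["classifier_paths"] = list(self.classifier_paths)
        return out


def load_config(path: str | Path) -> AnalysisConfig:
    """Load an :class:`AnalysisConfig` from a YAML (or JSON) file.

    Unspecified fields take the package defaults; unknown keys are an
    error so typos cannot silently fall back to defaults.
    """
    text = Path(path).read_text()
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: {exc}") from exc
    if data is None:
        data = {}
    if not isinstance(data, Mapping):
        raise ConfigError(f"{path}: top level must be a mapping")
    return AnalysisConfig.from_dict(data)


def save_config(config: AnalysisConfig, path: str | Path) -> None:
    p = Path(path)
    if p.suffix.lower() == ".json":
        p.write_text(json.dumps(config.to_dict(), indent=2))
    else:
        p.write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))
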