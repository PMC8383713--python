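import numpy as np
import pytest
import yaml

from msnakit import (
    AnalysisConfig,
    PeakAnnotation,
    Recording,
    load_config,
    read_annotation_table,
    read_recording,
    save_config,
    write_annotation_table,
    write_recording,
)
from msnakit.core_io import ConfigError, EmptyInputError, FormatError, ParseError
from msnakit.timing import expected_latency


def _write(path, text):
    path.write_text(text)
    return path


class TestReadRecording:
    def test_three_column_ingestion(self, tmp_path):
        n = 5000
        t = np.arange(n) / 1000.0
        lines = ["time\tmsna\tecg"]
        lines += [f"{ti:.6f}\t{0.1:.6f}\t{0.0:.6f}" for ti in t]
        p = _write(tmp_path / "rec.txt", "\n".join(lines) + "\n")
        rec = read_recording(p)
        assert rec.n_samples == 5000
        assert rec.bp is None
        assert rec.ecg is not None
        assert not rec.resampled

    def test_comma_delimited(self, tmp_path):
        p = _write(tmp_path / "rec.csv", "time,msna\n0.000,0.1\n0.001,0.2\n0.002,0.3\n")
        rec = read_recording(p)
        assert rec.n_samples == 3
        np.testing.assert_allclose(rec.msna, [0.1, 0.2, 0.3])

    def test_resample_500hz_ramp(self, tmp_path):
        # linear-interpolation oracle: a ramp resamples to the same ramp
        n = 5000  # 10 s at 500 Hz
        t = np.arange(n) / 500.0
        ramp = 0.01 * t
        lines = ["time\tmsna"] + [f"{ti:.8f}\t{v:.10f}" for ti, v in zip(t, ramp)]
        p = _write(tmp_path / "rec.txt", "\n".join(lines) + "\n")
        rec = read_recording(p)
        assert rec.resampled
        assert rec.n_samples == 10000
        assert rec.sample_rate == 1000.0
        np.testing.assert_allclose(rec.msna, 0.01 * rec.time, atol=1e-7)

    def test_missing_msna_column(self, tmp_path):
        p = _write(tmp_path / "rec.txt", "time\tecg\n0.0\t1.0\n")
        with pytest.raises(FormatError):
            read_recording(p)

    def test_non_numeric_cell_reports_row(self, tmp_path):
        p = _write(tmp_path / "rec.txt", "time\tmsna\n0.000\t0.1\n0.001\toops\n")
        with pytest.raises(ParseError, match="row 1"):
            read_recording(p)

    def test_empty_file(self, tmp_path):
        p = _write(tmp_path / "rec.txt", "")
        with pytest.raises(EmptyInputError):
            read_recording(p)

    def test_header_only_file(self, tmp_path):
        p = _write(tmp_path / "rec.txt", "time\tmsna\n")
        with pytest.raises(EmptyInputError):
            read_recording(p)

    def test_column_map_override(self, tmp_path):
        p = _write(tmp_path / "rec.txt", "t,neurogram\n0.000,0.5\n0.001,0.6\n")
        rec = read_recording(p, column_map={"time": "t", "msna": "neurogram"})
        np.testing.assert_allclose(rec.msna, [0.5, 0.6])

    def test_round_trip_recording(self, tmp_path, default_recording):
        rec, _ = default_recording
        p = tmp_path / "rt.txt"
        write_recording(rec, p)
        back = read_recording(p)
        np.testing.assert_allclose(back.msna, rec.msna, atol=1e-6)
        np.testing.assert_allclose(back.ecg, rec.ecg, atol=1e-6)
        np.testing.assert_allclose(back.bp, rec.bp, atol=1e-6)
        assert not back.resampled  # 1000 Hz input is passed through

    def test_recording_invariants(self):
        with pytest.raises(ValueError):
            Recording(time=np.array([0.0, 0.001]), msna=np.array([0.0]))
        with pytest.raises(ValueError):
            Recording(time=np.array([0.0, 0.002]), msna=np.zeros(2), sample_rate=1000.0)


class TestAnnotationTable:
    @staticmethod
    def _annotation(t=1.0, composite=0.7):
        return PeakAnnotation(
            peak_time=t,
            peak_height=0.3,
            nn_prob=(0.9, 0.2, 0.6),
            nn_label=(1, 0, 1),
            timing_likelihood=0.8,
            quality_median=0.55,
            quality_likelihood=0.95,
            composite=composite,
        )

    def test_row_count(self, tmp_path):
        p = tmp_path / "ann.csv"
        write_annotation_table([self._annotation(1.0), self._annotation(2.0)], p)
        assert len(p.read_text().strip().splitlines()) == 3

    def test_empty_list_header_only(self, tmp_path):
        p = tmp_path / "ann.csv"
        write_annotation_table([], p)
        assert len(p.read_text().strip().splitlines()) == 1

    def test_round_trip_within_tolerance(self, tmp_path):
        p = tmp_path / "ann.csv"
        anns = [self._annotation(1.234567891, 0.654321987)]
        write_annotation_table(anns, p)
        back = read_annotation_table(p)
        assert len(back) == 1
        assert abs(back[0].peak_time - anns[0].peak_time) < 1e-6
        assert abs(back[0].composite - anns[0].composite) < 1e-6
        assert back[0].nn_label == anns[0].nn_label

    def test_label_probability_consistency_enforced(self):
        with pytest.raises(ValueError):
            PeakAnnotation(
                peak_time=0.0,
                peak_height=0.1,
                nn_prob=(0.9, 0.2, 0.6),
                nn_label=(0, 0, 1),  # contradicts nn_prob[0] >= 0.5
                timing_likelihood=0.5,
                quality_median=0.5,
                quality_likelihood=0.5,
                composite=0.5,
            )

    def test_bounded_fields_enforced(self):
        with pytest.raises(ValueError):
            PeakAnnotation(
                peak_time=0.0,
                peak_height=0.1,
                nn_prob=(0.9, 0.2, 0.6),
                nn_label=(1, 0, 1),
                timing_likelihood=1.5,
                quality_median=0.5,
                quality_likelihood=0.5,
                composite=0.5,
            )


class TestConfig:
    def test_empty_config_gives_defaults(self, tmp_path):
        p = _write(tmp_path / "cfg.yaml", "")
        cfg = load_config(p)
        assert cfg.peak_params.min_prominence == 0.05
        assert cfg.peak_params.min_width_ms == 100.0
        assert cfg.timing_model.sd_ms == 200.0
        assert cfg.quality_model.center == 0.57
        assert cfg.profile_weights.w_quality == 0.5

    def test_negative_sd_rejected(self, tmp_path):
        p = _write(tmp_path / "cfg.yaml", yaml.safe_dump({"timing_model": {"sd_ms": -5}}))
        with pytest.raises(ConfigError, match="sd_ms"):
            load_config(p)

    def test_height_override_propagates(self, tmp_path):
        p = _write(
            tmp_path / "cfg.yaml",
            yaml.safe_dump({"timing_model": {"default_height_cm": 180}}),
        )
        cfg = load_config(p)
        assert expected_latency(None, cfg.timing_model) == pytest.approx(
            -118.75 + 8.25 * 180
        )

    def test_unknown_key_rejected(self, tmp_path):
        p = _write(tmp_path / "cfg.yaml", yaml.safe_dump({"peak_paramz": {}}))
        with pytest.raises(ConfigError, match="peak_paramz"):
            load_config(p)

    def test_unknown_nested_key_rejected(self, tmp_path):
        p = _write(tmp_path / "cfg.yaml", yaml.safe_dump({"peak_params": {"min_prom": 1}}))
        with pytest.raises(ConfigError):
            load_config(p)

    def test_round_trip_yaml_and_json(self, tmp_path):
        cfg = AnalysisConfig.from_dict({"timing_model": {"sd_ms": 150.0}})
        for name in ("cfg.yaml", "cfg.json"):
            p = tmp_path / name
            save_config(cfg, p)
            back = load_config(p)
            assert back.timing_model.sd_ms == 150.0
            assert back.to_dict() == cfg.to_dict()

    def test_default_object_validates(self):
        AnalysisConfig()  # all nested invariants hold
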