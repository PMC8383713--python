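# msnakit

Automated analysis of muscle sympathetic nerve activity (MSNA) recordings
from microneurography. The package detects candidate bursts in the
integrated neurogram and scores each candidate on three independent axes —
burst shape (dense neural-network classifiers), cardiac-cycle timing
(Gaussian likelihood locked to the diastolic pressure nadir), and spectral
signal quality (median of the DFT magnitude over a 60 s window) — and
integrates them into a single 0–1 composite validity score laid out on a
circular evidence profile. A seeded physiological simulator makes every
stage testable without any real data.

## Modules

| Module | Purpose |
| --- | --- |
| `msnakit.core_io` | Domain types (`Recording`, `PeakAnnotation`, `AnalysisConfig`), delimited-text recording reader with 1 kHz resampling, annotation CSV writer, YAML/JSON config |
| `msnakit.peak_detection` | Prominence/width/height/distance candidate-peak detector and window extraction |
| `msnakit.quality` | Spectral quality index (DFT magnitude median), Gaussian quality likelihood, group comparison (Mann–Whitney U) |
| `msnakit.timing` | R-wave and diastolic-nadir detection, ECG→diastole offset estimation with artifact filters, height-adjusted burst-latency model, timing likelihood |
| `msnakit.classifier` | Dense (5 hidden ReLU layers + dropout + softmax) burst-shape classifiers, `dtct1`/`dtct2`/`dtct3` presets, adamax training harness with repeated reshuffled runs, NumPy implementation |
| `msnakit.scoring` | Circular evidence profile, composite score, burst frequency / incidence / total MSNA, threshold selection |
| `msnakit.synthetic` | Seeded ECG/BP/MSNA simulator with ground truth, labeled-window generators |
| `msnakit.pipeline` | End-to-end annotate / summarize glue |

## CLI

```bash
# simulate a recording plus ground-truth sidecar
msnakit simulate --duration 300 --seed 1 --out rec.txt --ground-truth truth.json

# train a classifier on a labeled window CSV (columns w0..w999 + label)
msnakit train --dataset windows.csv --preset dtct2 --reps 100 --seed 1 --out model_dir

# annotate every candidate peak and summarize
msnakit analyze --input rec.txt --height-cm 180 --model model_dir/model \
    --out annotations.csv --summary summary.json

# recompute summaries from an annotation table at another threshold
msnakit summarize --annotations annotations.csv --duration-min 5 --threshold 0.6
```

`analyze` accepts up to three `--model` options (one per classifier slot);
with fewer, the last model fills the remaining slots, and with none the
network outputs are neutral (0.5).

The quality model center/sd are amplifier-gain dependent; recalibrate them
on excerpts rated as valid signal via `QualityModel.calibrated(medians)`
or a config file:

```yaml
quality_model:
  center: 0.57
  sd: 0.3
timing_model:
  default_height_cm: 175
```

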