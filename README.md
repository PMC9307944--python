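# hrvsuite

Segment-wise heart rate variability (HRV) analysis: from raw R-peak times
through artifact correction and fixed-duration windowing to a
124-metric-per-segment table, higher-order fluctuation statistics of the
metrics themselves, and sleep-stage correlation analysis. Synthetic data
generators with known ground truth make every stage testable offline.

## What it computes

Per 5-minute segment (window length configurable), one row with 124 named
metric columns plus a quality-control segment duration and the SubjectID:

| family | columns | examples |
| --- | --- | --- |
| time domain | 24 | RMSSD, SDNN, pNN50, TINN, HTI, SDANN/SDNNI at 1/2/5 min |
| frequency domain | 9 | ULF/VLF/LF/HF/VHF powers, LF/HF, LFn, HFn, LnHF |
| recurrence quantification | 13 | RecurrenceRate, Determinism, Laminarity, TrappingTime |
| Poincare geometry | 7 | SD1, SD2, S, CSI, CVI |
| fragmentation | 4 | PIP, IALS, PSS, PAS |
| heart-rate asymmetry | 16 | GI, SI, AI, PI, C1d/C1a, SD2d/SD2a, Cd/Ca |
| complexity | 33 | SampEn, FuzzEn, multiscale entropies, fractal dimensions, optimal time delay |
| DFA / MFDFA | 18 | DFA_alpha1/2 and singularity-spectrum summaries per range |

The fuzzy-entropy/cApEn pathway uses a segment-specific optimal embedding
delay (first significant local minimum of average mutual information); the
classical entropy columns use delay 1.

A second layer summarizes each metric's across-segment time series
(mean, coefficient of variation, quartile coefficient of dispersion,
binned Shannon entropy), with an optional experimental Gaussian-HMM state
model. A sleep module parses `[id]_labeled_sleep.txt` stage files
(wake=0, N1=1, N2=2, N3=3, REM=5), accumulates per-stage durations, and
Spearman-correlates metric summaries with stage durations across subjects.

## CLI

```bash
# batch run from a YAML config
hrvsuite run --config cfg.yaml

# write a synthetic peak-index CSV fixture
hrvsuite simulate --out peaks.csv --duration 600 --seed 3 \
    --modulation 0.25 15

# correlate per-subject metric summaries with sleep-stage durations
hrvsuite sleep-correlate --summaries summaries.csv \
    --labels-dir labels/ --out correlations.csv
```

Example config:

```yaml
streams:
  - name: f           # output files: fmetrics.csv, higher_fmetrics.csv, ...
    paths: [raw/f1.csv, raw/f2.csv]
    interval_min: 0.33   # fetal plausibility bounds, seconds
    interval_max: 0.75
  - name: m
    paths: [raw/m1.csv, raw/m2.csv]
    interval_min: 0.4    # adult/maternal bounds
    interval_max: 1.5
sampling_rate: 1000
window_minutes: 5
output_dir: analysis
```

Input kinds per stream: `peaks_csv` (one column of sample indices),
`rri_csv`, `bpm_csv` (converted to pseudo-RRI = 60000/bpm with a warning),
or `peaks_mat` (named MAT variable + row index). With two streams the file
lists must pair up one-to-one; mismatched counts raise an explicit error.
Outputs are deterministic CSVs (12 significant digits); artifact
corrections are logged per subject with index, class and before/after
values.

## Library use

```python
from hrvsuite.signal_core import PeakSeries, trim_trailing_zeros, \
    correct_artifacts, peaks_to_rri
from hrvsuite.pipeline import compute_hrv_segmentwise

peaks = trim_trailing_zeros(PeakSeries(times, sampling_rate=1000))
peaks, report = correct_artifacts(peaks, interval_min=0.4, interval_max=1.5)
table = compute_hrv_segmentwise(peaks, peaks_to_rri(peaks), "subject01")
```
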