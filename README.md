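# tfspindle

Time-frequency characterization and detection of sleep-spindle
(sigma-band, 10–16 Hz) activity in single-channel sleep EEG.

Transient oscillatory bursts appear as salient local maxima in the
multitaper spectrogram. This package extracts those peaks with a
two-step prominence algorithm (a *frequency step* that finds the most
prominent spectral peak per time column, then a *time step* that finds
temporal peaks of the prominence trace), separates events from noise
with an exact, deterministic two-class 1-D k-means on log prominences,
and compares the result with a re-implementation of the classic
wavelet-threshold spindle detector. A statistics layer provides
event-based confusion matrices (asymmetric TP counting, no minimal
overlap), intersection-over-union overlap percentages, paired t-tests
on property medians, bin-wise modified-z signed-rank tests,
trough-aligned aggregate event spectrograms, and night-to-night rate
stability with robust regression and a permutation test on the
difference of Pearson correlations. A synthetic sleep-EEG generator
with exact ground truth makes the whole pipeline testable offline.

## Layout

| module | contents |
| --- | --- |
| `tfspindle.io` | `Recording`, `Hypnogram`, event tables; minimal EDF codec, text hypnograms, CSV events, YAML config |
| `tfspindle.multitaper` | multitaper spectrogram (1-s windows, 0.05-s step, TW=2, 3 DPSS tapers, NFFT ≥ 1024, constant detrend) |
| `tfspindle.artifact` | iterative amplitude-z-score artifact detection (35 Hz high-frequency and 2 Hz broadband passes) |
| `tfspindle.peaks` | two-step prominence extraction → `TFPeak` (prominence, duration, central frequency, bandwidth) |
| `tfspindle.sigma` | candidate filtering (≥ 0.3 s, ≥ 2 Hz), exact 1-D two-class k-means, unsupervised sigma-peak detection |
| `tfspindle.wavelet` | Morlet-bank magnitude statistic, 4.5× N2-mean thresholding, 0.3–3 s events, F1 threshold-grid optimization |
| `tfspindle.stats` | event selection, matching, F1, property/bin-wise tests, aggregate spectrograms, night stability |
| `tfspindle.synth` | synthetic recordings: pink-noise background, stage schedule, nested two-component sigma bursts, artifacts |
| `tfspindle.cli` | `tfspindle` command-line interface |

## CLI

```sh
tfspindle simulate --preset nested --seed 1 --minutes 30 --out fixture/
tfspindle artifacts fixture/synthetic.edf --out mask.csv
tfspindle spectrogram fixture/synthetic.edf --out spec.csv
tfspindle detect-tfsigma fixture/synthetic.edf --mask mask.csv --out tfsigma.csv
tfspindle detect-spindles fixture/synthetic.edf --hypnogram fixture/hypnogram.txt \
    --mask mask.csv --out spindles.csv
tfspindle optimize-threshold fixture/synthetic.edf --hypnogram fixture/hypnogram.txt \
    --reference fixture/ground_truth.csv --out curve.csv
tfspindle compare fixture/ground_truth.csv tfsigma.csv --fs 100 --out report.json
tfspindle stability rates.csv --method-a tfpeak_auto --method-b spindle_auto --out stab.json
```

Each detector also writes a JSON report next to its CSV (candidate
counts, cluster threshold/means, or the N2 mean statistic and absolute
threshold). Pipeline parameters can be supplied via `--config
params.yaml` with one section per module (`spectrogram`, `artifact`,
`tfsigma`, `wavelet`).

## Conventions

- Event intervals are half-open `[start_s, end_s)` seconds from the
  recording start; sample `i` covers `[i/fs, (i+1)/fs)`.
- Spectrogram timestamps are window centers; PSD is one-sided, linear
  µV²/Hz; dB is always `10·log10`.
- Peak prominence is computed on dB power; duration and bandwidth are
  full widths at half prominence.
- The two-class k-means is solved exactly by contiguous-split
  enumeration — the whole sigma-detection path is deterministic.
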