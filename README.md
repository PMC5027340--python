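# epimap

Analysis toolkit for epicardial multielectrode array (MEA) mapping and
longitudinal cohort endpoints, built around a fully synthetic data path so
every stage is testable offline:

* **`epimap.synthetic`** — electrode-grid geometry (default 16×8, 2.7 mm
  pitch, 128 channels), exact planar/focal ground-truth wavefronts,
  unipolar electrogram synthesis (25 kHz, optional 12-bit quantization,
  pacing at 120 bpm, stimulus artifact at the upper-left bipolar
  stimulation corner), and synthetic longitudinal cohorts (treated n = 9
  vs control n = 7 by default).
* **`epimap.features`** — activation detection (most negative discrete
  derivative of the intrinsic deflection), repolarization detection (most
  positive derivative in a window relative to activation), and activation
  recovery intervals (ARI = repolarization − activation).
* **`epimap.conduction`** — per-triangle conduction vectors via plane fits
  of activation times, wave propagation velocity (WPV) summary, phase maps
  (largest neighbor activation-time difference per site), and the
  conduction heterogeneity index CHI = (P95 − P5)/P50.
* **`epimap.stats`** — group summaries (mean ± SD), percent changes,
  pooled-variance Student's t-tests (paired and unpaired; Welch behind a
  flag), MAP trajectory/plateau characterization, and a full endpoint
  report with 0.05/0.01/0.001 star coding.
* **`epimap.io` / `epimap.cli` / `epimap.pipeline`** — file formats
  (geometry CSV, recording container with a text header and a binary or
  CSV matrix), a deterministic end-to-end pipeline with full provenance,
  and a CLI.

Units throughout: coordinates in mm, times in ms, speeds in m/s
(mm/ms ≡ m/s); channels 0-based, row-major.

## CLI

```sh
epimap run -o out/                 # full pipeline from a seed, no inputs
epimap run -c config.yaml --seed 7 -o out/
epimap simulate-recording --rows 16 --cols 8 --speed-mps 0.9 -o rec.egm
epimap activation-map -i rec.egm -o activation.csv
epimap conduction -i rec.egm -o cond      # cond_triangles.csv, cond_summary.json
epimap chi -i rec.egm -o chi
epimap ari -i rec.egm -o ari
epimap simulate-cohort --seed 1 -o cohort.csv
epimap endpoints -i cohort.csv -o report
```

Exit codes: 0 success, 2 usage/config error, 3 data/format error,
4 analysis error (e.g. no valid conduction triangle). Logs go to stderr;
every machine output embeds the effective config and seed, and reruns
with the same (config, seed) are byte-identical.

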