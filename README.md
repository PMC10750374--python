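# mstate-ri

EEG residual-inhibition analysis toolkit: a tested re-implementation of a
resting-state EEG pipeline for a two-group (TMNMT vs Placebo), three-condition
(stimuli-pre / -ing / -post) tinnitus study, exercised end to end on a
synthetic-EEG study generator with known ground truth.

The pipeline comprises:

- **synthetic** — multichannel EEG generator: semi-Markov microstate label
  sequences (geometric dwell times), topographic templates rendered under a
  rectified-sinusoid GFP envelope with per-run random polarity, white sensor
  noise, band-limited oscillations, subject-level clinical scores, and
  per-group × condition effect injection (band-power dB offsets, state
  duration multipliers). Every recording carries its ground-truth run table.
- **io_preprocess** — TSV recording I/O and the deterministic preprocessing
  chain: resampling to 512 Hz, zero-phase FIR band-pass 0.5–100 Hz with
  50/100 Hz notches, average reference, 2-s epochs with ±100 µV rejection,
  plus the 2–20 Hz band-pass used by the microstate stage.
- **spectral** — Welch PSD (Hamming window, segments never crossing epoch
  boundaries) and the nine-band summary (delta … gamma2) in dB.
- **microstate** — GFP, GFP-peak extraction, polarity-invariant AAHC
  (atomize-and-agglomerate) and modified k-means clustering, KL/CV model
  selection, subject → subgroup → grand two-level templates with class
  alignment, back-fitting by maximal spatial correlation with
  nearest-neighbour label interpolation, duration/occurrence/coverage
  metrics and row-normalized transition probabilities.
- **stats** — independent/paired t-tests (raw data or printed summaries),
  Pearson χ², balanced mixed-design (split-plot) ANOVA, simple effects,
  Benjamini–Hochberg FDR, and metric–score Pearson correlation.
- **pipeline / cli** — config-driven orchestration with per-stage logging,
  deterministic seeding, TSV artifacts and a JSON run report.

Recordings are plain TSV matrices (`# fs_hz=<rate>` header, one labelled
channel row per line); no EDF backend is built in.

## CLI

```sh
mstate-ri run --config demo_study.yaml --out out/demo --seed 1
mstate-ri report --out out/demo
```

Stage-wise execution over on-disk artifacts:

```sh
mstate-ri simulate   --config demo_study.yaml --out out/study --seed 1
mstate-ri preprocess --in out/study --config demo_study.yaml --out out/pre
mstate-ri spectral   --in out/pre   --config demo_study.yaml --out out/tables
mstate-ri microstate --in out/pre   --config demo_study.yaml --out out/tables
mstate-ri stats      --in out/tables --config demo_study.yaml --out out/tables
```

`run` produces `psd_bands.tsv`, `metrics.tsv`, `transitions.tsv`,
`stats_report.tsv`, `templates_grand.tsv` and `report.json`; identical
config + seed reproduce byte-identical tables. See `demo_study.yaml` for
the annotated configuration schema, including how to inject effects such as
`duration_multipliers: {"TMNMT:post": {"1": 0.8}}`.

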