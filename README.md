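# smfishq

Quantification of single-molecule RNA FISH combined with immunofluorescence
(smFISH-IF) in budding yeast.

In an smFISH experiment each mRNA is tiled by tens of short singly-labelled
oligo probes and appears as one diffraction-limited spot in a 3D widefield
stack; the absolute number of transcripts per cell can then be counted, and
the brightness of the intra-nuclear transcription site (TS), expressed in
units of the single-molecule intensity, counts the nascent transcripts being
made at the gene. Combined with an anti-tubulin immunofluorescence channel,
each cell can also be placed in the cell cycle (G1/S/G2/M), so expression
can be resolved by phase — the natural readout for a periodically expressed
cyclin transcript.

`smfishq` implements that workflow end to end for people who build or
validate such pipelines:

- **spot detection** — difference-of-Gaussian bandpass, 3D local-maximum
  pre-detection, and per-spot fitting of a voxel-integrated tri-axial
  Gaussian `I(v) = B + Q·gx·gy·gz` with two-pass neighbour subtraction for
  crowded cells; acceptance filtering by parameter bounds;
- **single-molecule reference** — the averaged molecule image and the
  reference intensity `Q_ref` (median per-spot integrated intensity);
- **nascent counting** — TS = intra-nuclear spot with `Q ≥ 1.5·Q_ref`;
  nascent count = `max(1, round(Q_ts/Q_ref))`;
- **per-cell quantification** — point-in-polygon spot assignment, IF
  integrated intensity (maximal projection excluding the slide bottom),
  morphology features and an ordered decision-list phase scorer;
- **cohort reporting** — expressing-cell mean with percentile-bootstrap 95%
  CI, nascent mean ± SD, frequency distributions;
- **QC** — z-drift detection by spot tracklets (flags stacks drifting
  ≥0.5 px/plane), DIC-to-fluorescence registration;
- **synthetic scenes** — a generator that renders ground-truth multichannel
  stacks (FISH, IF, DAPI, DIC proxy) with probe-binding brightness
  statistics, camera noise and the classic acquisition artifacts, so every
  stage above is tested against known truth.

File formats: multi-page grayscale TIFF stacks, block-structured outline
text files, key=value detection-settings files, and CSV for scoring,
spots, TS and per-cell tables.

## Worked example

Simulate two positions, run the whole pipeline, and summarize:

```
$ printf 'seed=9\nn_positions=2\nout_dir=runout\n' > cfg.ini
$ smfishq run --config cfg.ini
pos_00: 41 spots, 2 TS, Q_ref=6990
pos_01: 9 spots, 0 TS, Q_ref=6814
{"n_cells": 24, "n_expressing": 6, "n_ts": 2,
 "mean_expressing": 11.67, "ci95_expressing": [7.83, 16.17],
 "mean_nascent": 5.5, "sd_nascent": 3.54}
```

Reading the numbers: 24 cells were outlined across the two fields; 6
contained at least one transcript (expression is confined to G1 here), with
a mean of 11.7 mRNAs per expressing cell and a wide bootstrap CI because
n = 6; `Q_ref ≈ 6900` ADU·voxel is the single-mRNA reference each field
derived from its own accepted spots (48 probes × 80% binding × 180 ADU
≈ 6912 expected); two transcription sites were called, carrying 5.5 ± 3.5
nascent transcripts. Per-position spot tables, per-cell CSV, TS CSV and the
summary JSON are written under `runout/`.

The same stages are available individually (`smfishq simulate / qc /
detect / average / ts / cells / report`) and as library functions
(`smfishq.detect_spots`, `smfishq.find_ts`, `smfishq.analyze_position`, …).

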