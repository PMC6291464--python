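# plinet

Phase-lag-index (PLI) EEG functional connectivity, weighted undirected
network topology, and a nonparametric statistics battery — driven by a
synthetic-cohort generator that plants band-specific phase coupling at
analytically known strength, so every stage of the analysis is verifiable
without real EEG.

## What it does

- **simulate** — multichannel EEG-like recordings (default 59-channel
  extended 10–20 montage, 500 Hz) with planted pairwise coupling whose
  expected PLI has a closed form (`E[PLI] = |2q − 1|`, `q = (1 + target)/2`
  under a mixture-of-two-lags model); n-back trial schedules with exact
  match counts (default 3 × 40 trials, 39 matches); behavioral outcomes
  (truncated-normal accuracy, log-normal reaction times) for a young/senior
  cohort.
- **preprocess** — 3.5-s epochs at stimulus onsets (consecutive
  pseudo-epochs for rest), ±60 µV amplitude rejection, zero-phase FIR
  band-pass into theta/alpha/beta/gamma, edge trimming to 2.5-s segments.
- **connectivity** — Hilbert-transform instantaneous phases, PLI
  (`|⟨sign sin Δφ⟩|`, `sign(0) = 0`) for every channel pair per segment,
  entrywise condition averages.
- **network** — fully connected weighted undirected network straight from
  the PLI matrix (no threshold); Onnela weighted clustering, characteristic
  path length with edge length `1/w`, and the small-world coefficient
  `SW = (C/C_rand)/(L/L_rand)` against weight-shuffled surrogates.
- **stats** — rank-based partial correlation with covariate control,
  Friedman test with studentized-range (Nemenyi) post-hoc + paired Wilcoxon,
  Mann–Whitney U, and Benjamini–Hochberg FDR over node-level families.
- **io** — minimal self-contained EDF and BrainVision readers/writers, TSV
  channel×sample matrices, HDF5 bundles.

## CLI

Each stage reads/writes files in a run directory, so stages are
independently re-runnable:

```sh
plinet run-all --out demo_run --seed 7            # full pipeline, defaults
plinet simulate --config cfg.yaml --out demo_run  # or stage by stage
plinet preprocess --out demo_run
plinet connectivity --out demo_run
plinet network --out demo_run
plinet stats --out demo_run
```

Configuration is YAML (see `plinet.pipeline.PipelineConfig` for keys and
defaults: bands, sampling rate, epoch/trim lengths, artifact threshold,
surrogate count, clustering denominator, partial-correlation method, FDR q,
cohort recipe). Outputs: `cohort.tsv`, `recordings.h5`, `segments.h5`,
per-subject PLI matrices (`pli/*.tsv`, `pli.h5`), a tidy `metrics.tsv`,
`stats.tsv`, and a `manifest.json` with config hash and artifact checksums
(re-running with the same config and seed reproduces checksums exactly).

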