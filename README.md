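# lamcsd

Analysis toolkit for visually evoked laminar current-source-density (CSD)
patterns and population spiking, plus a desk-scale laminar forward model.

The package implements, end to end:

- **Synthetic flash experiments** (`lamcsd.synthetic`): cohorts of surrogate
  animals with QC exclusion flags, Neuropixels-like laminar LFP (20 µm pitch
  over ~860 µm) built from canonical sink/source components with per-animal
  jitter, trial noise with a ~20 ms-period gamma oscillation,
  inhomogeneous-Poisson population spike trains with bimodal waveform
  durations, and LGN/LM spike-train input pools.
- **LFP preprocessing** (`lamcsd.preprocess`): zero-phase 5th-order
  Butterworth low-pass at 500 Hz, spatial downsampling to 40 µm pitch, trial
  averaging, baseline subtraction, and bilinear interpolation onto the
  common 30 × 100 depth-time analysis grid.
- **Delta-iCSD** (`lamcsd.icsd`): the disc-source forward operator
  (configurable radius: 400 µm "model" / 800 µm "experiment" context) and
  the direct inverse, with forward/inverse round trips exact to solver
  tolerance.
- **Wasserstein pattern comparison** (`lamcsd.csd_metrics`,
  `lamcsd.transport`): sinks and sources normalized to unit mass
  separately, compared by an exact first Wasserstein distance under the
  grid-index Euclidean ground metric, and summed into a total pattern
  distance. The exact transport solve is a numba network-simplex
  (`lamcsd._network_simplex`) plus a Kantorovich–Rubinstein shared-mass
  cancellation that is mathematically exact for W1. Cohort machinery
  produces pairwise distance matrices, normalized distances, and
  inter-trial vs inter-animal KS comparisons.
- **Canonical pattern** (`lamcsd.canonical`): PCA over the stacked
  per-animal patterns (N × 3000); PC 1 is the canonical pattern, with the
  plain cohort mean as the alternative.
- **Spike metrics** (`lamcsd.spike_metrics`): RS/FS classification by
  trough-to-peak duration (0.4 ms cortex / 0.3 ms LGN cutoffs), 1 ms-binned
  Gaussian-smoothed population rates, KS similarity (1 − KS statistic),
  Pearson rate correlations, leave-one-out cohort comparison with a
  10-cell minimum, Tukey-boxplot outlier assessment, and per-unit feature
  moments.
- **Laminar model** (`lamcsd.laminar_model`): a threshold-linear rate
  network with depth-resolved synapse placement and per-projection current
  bookkeeping (inward current at the placement kernel, equal return current
  at the soma), reproducing the weight-vs-placement dissociation and
  sink/source-origin ablations. Three presets: `original`, `intermediate`,
  `final` (feedback + L6 placement restriction).
- **Pipeline + CLI** (`lamcsd.pipeline`, `lamcsd.cli`): orchestration with
  YAML configuration, seeded determinism, HDF5/CSV/JSON artifacts and
  figure reports.

## CLI

```sh
lamcsd run --outdir out --seed 1              # full pipeline, default config
lamcsd generate --outdir out                  # individual stages:
lamcsd preprocess --outdir out                #   generate -> preprocess ->
lamcsd csd --outdir out                       #   csd -> canonical ->
lamcsd canonical --outdir out                 #   compare -> spikes ->
lamcsd compare --outdir out                   #   simulate -> evaluate ->
lamcsd spikes --outdir out                    #   report
lamcsd simulate --outdir out
lamcsd evaluate --outdir out
lamcsd report --outdir out
```

All stages accept `--config my.yaml` (overlaying
`src/lamcsd/defaults.yaml`, which holds every analysis constant exactly
once) and `--seed N`.

## Notes

- The deposited datasets the analyses were designed around are *not*
  required: the synthetic module stands in for them, and an ingest adapter
  for real recordings is a documented extension point
  (`LaminarRecording` + the spike-table CSV schema in `lamcsd.core`).
- Patterns are stored as HDF5 (`/values`, `/depth_axis`, `/time_axis`),
  recordings as HDF5 (`/lfp`, `/depths`, `/fs`, `/trial_onsets`), spike
  tables and manifests as CSV, summaries as JSON.
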