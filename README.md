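# epifish

Joint analysis of local field potential (LFP) recordings and 2-photon
Ca²⁺ imaging in larval zebrafish: unbiased detection and quantification
of epileptiform activity, localization of LFP sources by pixelwise
cross-correlation, and identification of the neuronal populations that
fire during vs. before epileptiform bursts.

## What it does

- **`lfp_power`** — 30–95 Hz band-pass, sliding log₁₀ RMS power
  (250 ms window, 50 ms step) and its decomposition into a Gaussian
  Main Mode and a high-power Secondary Mode by an iterative trimmed fit;
  reports the MM mean and ΔSM-MM.
- **`calcium_dff`** — dark subtraction, 2×2 binning, per-pixel ΔF/F₀
  against the global temporal-mean baseline, Pearson second-skewness
  maps, and statistical binarization (per-pixel trimmed-Gaussian
  threshold, 3-frame persistence, 2-neighbor spatial support).
- **`cluster3d`** — spatiotemporal Ca²⁺ domains as connected components
  in (x, y, t); volume / duration / max surface / origin metrics and
  region classification (>300-voxel rule) against an anatomical atlas.
- **`coupling`** — log-RMS power interpolated at frame mean times;
  pixelwise lag-summed cross-correlation maps, trace correlograms,
  lag-half-width estimation, window-restricted (interictal/ictal) maps.
- **`neurons`** — donut-template soma detection, circular-ROI trace
  extraction, PCA of unit-SD traces, selection of the epileptiform (Ep,
  max zero-lag correlation with power) and pre-epileptiform (pre-Ep,
  positive peak at the negative lag closest to zero) components,
  normalized-loading maps, rostro-caudal profiles, and registered
  collective maps.
- **`motion`** — frame-wise larva displacement from the median
  silhouette centroid.
- **`synthetic`** — fully seeded paired recordings with ground truth:
  planted high-frequency bursts with a calibrated log-power excess,
  low-frequency movement artifacts, contiguous Ca²⁺ domains inside
  atlas regions, and Ep / pre-Ep / silent neuron cohorts with a
  configurable lead time; condition presets (WT, PTZ, MO, MO+VPA).
- **`io_formats` / `config` / `cli`** — TIFF stacks, delimited-text
  traces and tables, HDF5 result containers, a validated parameter
  object, and an end-to-end command line.

## CLI

```sh
# echo the effective configuration (all protocol defaults)
epifish config

# LFP power statistics of one trace (text file, one value per line)
epifish lfp trace.txt --out results/

# full joint pipeline on a paired recording
epifish joint trace.txt movie.tif --atlas atlas.tif --out results/

# write the four synthetic condition fixtures plus ground truth
epifish demo --seed 0 --out fixtures/
```

Parameters come from a YAML config (`--config`), mirroring
`epifish.config.PipelineConfig`; unknown keys are rejected. Exit codes:
0 ok, 2 validation error, 3 data error.

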