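# nanoftir

Simulation, reconstruction and multivariate analysis of broadband
hyperspectral near-field infrared (nano-FTIR) phase images.

The package models the full measurement chain of hyperspectral nano-FTIR
imaging with a tunable bandwidth-limited laser continuum:

1. **scene** — synthetic organic samples (a three-polymer blend and a hair
   cross-section with melanin granules) as label maps with per-label
   composition rules over Lorentzian-oscillator component spectra, with
   exact ground-truth phase cubes.
2. **interferometry** — one-sided asymmetric-Michelson interferograms per
   laser band (three ~350 cm⁻¹ bands tiling ~1,000–1,900 cm⁻¹), FFT
   reconstruction of complex spectra, and the analytic path-drift/phase
   relation Δφ = 360·ν·δ.
3. **acquisition** — raster scans (lines parallel to y) with stage drift,
   per-line reference pixels for normalization, the block-of-*m*-lines
   repositioning protocol with topography cross-correlation, and
   acquisition-time accounting.
4. **stitching** — per-pixel constant phase-offset correction in the
   spectral overlap regions, linear-ramp weight functions forming a
   partition of unity, weighted summation, and two-anchor linear baseline
   correction.
5. **mva** — Euclidean distance maps, composite colour maps, D-value
   ((1 − Pearson r)·1000) / Ward hierarchical clustering, cluster
   statistics, and non-negative linear-superposition (unmixing) testing.
6. **io / config / cli** — HDF5 cube container, CSV/PNG export, one
   serializable run configuration, command-line interface.

## CLI

```sh
# full pipeline (simulate -> reconstruct -> stitch -> baseline) into one HDF5
nanoftir pipeline --config run.yaml --seed 0 --out run.h5

# individual stages
nanoftir simulate   --config run.yaml --out bands.h5 --store-raw
nanoftir reconstruct --config run.yaml --input bands.h5 --out rec.h5
nanoftir stitch     --config run.yaml --input bands.h5 --out hyper.h5
nanoftir analyze hca --input run.h5 --out analysis/ --k 5 --exclude-rows 2
nanoftir export     --input run.h5 --pixel 10 20 --out spectrum.csv
```

A config file is YAML or JSON with the fields of
`nanoftir.config.RunConfig`; missing fields take the documented defaults
(62×82 px blend scene, bands centred at 1,175/1,450/1,725 cm⁻¹ with
350 cm⁻¹ bandwidth, m = 2 repositioning, baseline anchors 1,030 and
1,870 cm⁻¹). Every run logs the resolved config hash and seed; all
randomness flows from the single seed, so reruns are bit-identical.

## Library quick start

```python
from nanoftir.config import RunConfig
from nanoftir.pipeline import run_pipeline
from nanoftir.mva import hca

result = run_pipeline(RunConfig(seed=0))
hyper = result.hypercube                      # stitched phase cube (deg)
clusters = hca(hyper, n_clusters=5)           # Ward/D-value segmentation
truth = result.scene.truth_labels             # ground truth for scoring
```

## File layout

One HDF5 container per run: `/truth/{labels,phase,frequency}`,
`/band_<k>/{phase,amplitude,frequency,support,topo_blocks}`,
`/raw/band_<k>/{interferograms,positions}` (optional),
`/hyper/{phase,frequency,x,y,provenance/*}`, `/analysis/labels`.
Phase is stored in degrees, frequencies in cm⁻¹, lengths in nm; every
group carries `schema_version` and unit attributes.
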