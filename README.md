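# cardiomics

Quantitative analysis of in-vitro cardiomyocyte differentiation from
three kinds of label-free / fluorescence data, with seeded synthetic-data
generators so the whole pipeline is verifiable without any downloads:

- **FLIM / TCSPC** — per-pixel biexponential decay fitting
  (`I(t) = a1 e^{-t/tau1} + a2 e^{-t/tau2}`, `a1 + a2 = 100 %`),
  mean lifetime `tau_m = (a1 tau1 + a2 tau2)/100`, the
  fluorescence-lifetime redox ratio **FLIRR = NADH a2 / FAD a1**
  (bound-NAD(P)H over bound-FAD fraction, a glycolysis-vs-oxidative
  index), short-lifetime lipofuscin granule counting, ROI histograms and
  Cohen's d.
- **Morphometry** — mitochondrial segmentation with area, Crofton
  perimeter, form factor `P^2/(4 pi A)`, aspect ratio and skeleton branch
  counts; the 30 %-coverage Ki67 nuclear positivity rule; gamma-H2AX
  focus counting (Laplacian-of-Gaussian); CellROX-style per-cell MFI and
  foci-per-mean-ROS normalisation.
- **Chemometrics** — GC-MS feature-table filtering (65 % missingness,
  30 % QC RSD), median normalisation + square-root transform +
  autoscaling, PCA, PLS-DA with VIP scores and cross-validated R²/Q²,
  t-tests with Benjamini-Hochberg FDR, the three-way significance rule
  (FDR < 0.05 & p < 0.05 & VIP > 1), and hypergeometric pathway
  over-representation (lenient p < 0.1).

The package is a library first: import it from Python, or start from the
narrative scripts in `examples/`. A thin `cardiomics` CLI wraps the
workflow module for shell use.

## Worked example

`examples/flim_redox_pipeline.py` simulates NADH and FAD TCSPC cubes for
cells whose ground-truth bound fractions match differentiated
cardiomyocytes (a2 = 28.4 %, a1 = 68.2 %), fits every cytoplasm pixel
after 5x5 binning, and prints:

```
simulated (48, 48, 256) cubes, ~240 photons/pixel in cells
fitted NADH a2: 28.5 +/- 1.8 % (truth 28.4 %)
cell 1: FLIRR = 0.421
cell 2: FLIRR = 0.430
mean per-cell FLIRR = 0.425 (expected 28.4/68.2 = 0.416)
```

The fitted bound fraction lands on the planted truth within the pixel
noise, and the per-cell FLIRR recovers the ratio of the planted
fractions; values above ~0.4 indicate predominantly oxidative metabolism,
lower values a more glycolytic state. The other examples cover granule
counting and effect sizes (`granules_and_effect_sizes.py`), morphometry
on rendered scenes (`morphometry_scene.py`), and the full metabolomics
chain with a planted-pathway enrichment (`metabolomics_chemometrics.py`).

Equivalent shell usage:

```bash
cardiomics synth-flim --out demo --n-cells 2 --a1 71.6 --seed 1
cardiomics fit-flim --cube demo/cube.tif --out demo/maps
cardiomics synth-table --out table.csv --n-features 109
cardiomics chemometrics --table table.csv --out chem
```

## Layout

```
src/cardiomics/
  flim_synth.py     TCSPC scene + cube simulator (truth records, TIFF+JSON I/O)
  flim_fit.py       spatial binning, variable-projection biexponential fitter
  flim_metrics.py   ROI stats, Cohen's d, FLIRR, granule counting
  image_synth.py    nuclei/Ki67, foci, mitochondria, ROS scene generators
  morphometry.py    segmentation, shape metrics, Ki67 rule, focus counting, MFI
  metabo_synth.py   GC-MS-like feature tables with planted effects, toy pathways
  chemometrics.py   filtering, normalisation, PCA/PLS-DA+VIP, FDR, ORA
  workflow.py       config-driven arm runner + results bundles
  cli.py            thin click CLI over the above
```

See `docs/methods.md` for the models, parameter defaults and the
validation strategy.
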