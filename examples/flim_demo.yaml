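# Demo configuration for `cardiomics run --config examples/flim_demo.yaml`:
# simulates a small NADH/FAD scene at the differentiated-cell ground truth,
# fits both channels and writes the FLIRR map + per-cell CSV to out_dir.
arm: flim
seed: 1
out_dir: results/flim_demo
params:
  frame_shape: [48, 48]
  n_cells: 2
  cell_radius: 10.0
  photons_per_pixel: 240
  bin_size: 5
  nadh: {a1: 71.6, a2: 28.4, tau1: 0.4, tau2: 2.5}
  fad: {a1: 68.2, a2: 31.8, tau1: 0.35, tau2: 2.8}
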