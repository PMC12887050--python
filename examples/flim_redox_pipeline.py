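"""FLIM redox pipeline: simulate TCSPC cubes, fit decays, compute FLIRR.

Builds synthetic NADH and FAD channels for cells whose ground-truth bound
fractions match differentiated cardiomyocytes (a2 = 28.4 %, a1 = 68.2 %),
fits the biexponential model per pixel after 5x5 binning, and reports the
per-cell fluorescence-lifetime redox ratio.  FLIRR ~ 0.42 marks a
predominantly oxidative metabolism; lower values are more glycolytic.
"""

import numpy as np

from cardiomics.flim_fit import FitConfig, fit_cube
from cardiomics.flim_metrics import compute_flirr, roi_stats
from cardiomics.flim_synth import (
    AcquisitionSpec,
    BiexpTruth,
    SceneLayout,
    make_scene,
    simulate_cube,
)

spec = AcquisitionSpec(frame_shape=(48, 48))
nadh_truth = BiexpTruth(a1=71.6, a2=28.4, tau1=0.4, tau2=2.5)  # free/bound NAD(P)H
fad_truth = BiexpTruth(a1=68.2, a2=31.8, tau1=0.35, tau2=2.8)  # bound/free FAD

layout = dict(n_cells=2, granule_rate=0.0, cell_radius=10.0)
scene_n = make_scene(SceneLayout(group_params={"cm": nadh_truth}, **layout), spec, seed=1)
scene_f = make_scene(SceneLayout(group_params={"cm": fad_truth}, **layout), spec, seed=1)

cube_n = simulate_cube(scene_n, spec, photons_per_pixel=240, seed=2, channel="NADH")
cube_f = simulate_cube(scene_f, spec, photons_per_pixel=240, seed=3, channel="FAD")
print(f"simulated {cube_n.counts.shape} cubes, "
      f"~{cube_n.total_counts[scene_n.cell_masks > 0].mean():.0f} photons/pixel in cells")

config = FitConfig(bin_size=5)  # 5x5 sliding sum -> ~6000 photons per fitted pixel
maps_n = fit_cube(cube_n, scene_n.cytoplasm_masks, config)
maps_f = fit_cube(cube_f, scene_f.cytoplasm_masks, config)

a2_stats = roi_stats(maps_n.a2, scene_n.cytoplasm_masks, parameter="NADH a2")
print(f"fitted NADH a2: {a2_stats.mean:.1f} +/- {a2_stats.sd:.1f} % (truth 28.4 %)")

flirr = compute_flirr(maps_n, maps_f, scene_n.cytoplasm_masks)
for cell, value in flirr.per_cell.items():
    print(f"cell {cell}: FLIRR = {value:.3f}")
mean_flirr = np.nanmean(list(flirr.per_cell.values()))
print(f"mean per-cell FLIRR = {mean_flirr:.3f} (expected 28.4/68.2 = 0.416)")
print("FLIRR > ~0.4 indicates oxidative phosphorylation dominates over glycolysis.")
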