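"""Short-lifetime granule counting and Cohen's d from group summaries.

Plants lipofuscin-like granules (disks whose mean lifetime is half the
cytoplasm value) at two different per-cell rates, counts them back from
the tau_m truth maps, and computes standardised effect sizes from printed
group summary statistics.
"""

from cardiomics.flim_metrics import GroupStats, cohens_d, detect_granules
from cardiomics.flim_synth import AcquisitionSpec, SceneLayout, make_scene

spec = AcquisitionSpec(frame_shape=(120, 120))
for group, rate, seed in [("differentiated", 1.21, 5), ("undifferentiated", 0.19, 6)]:
    layout = SceneLayout(n_cells=16, granule_rate=rate, cell_radius=10)
    scene = make_scene(layout, spec, seed)
    gset = detect_granules(
        scene.tau_m,
        scene.cell_masks,
        threshold=0.75 * layout.group_params["cells"].tau_m,
        min_area=3,
    )
    total = sum(gset.per_cell_counts.values())
    print(f"{group}: planted rate {rate}/cell -> counted {total / 16:.2f}/cell "
          f"({total} granules in 16 cells)")

# effect sizes from published-style Mean +/- SD summaries
d_fad = cohens_d(
    GroupStats.from_summary("CM", 76.4, 6.0, 23),
    GroupStats.from_summary("CMB", 68.2, 6.0, 27),
)
d_tau = cohens_d(
    GroupStats.from_summary("CM", 1.16, 0.17, 14),
    GroupStats.from_summary("CMB", 0.89, 0.14, 21),
)
print(f"Cohen's d, bound-FAD fraction 76.4+/-6.0 (n=23) vs 68.2+/-6.0 (n=27): {d_fad:.2f}")
print(f"Cohen's d, mean lifetime 1.16+/-0.17 ns (n=14) vs 0.89+/-0.14 ns (n=21): {d_tau:.2f}")
print("d ~ 0.2/0.5/0.8 are conventionally small/medium/large separations.")
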