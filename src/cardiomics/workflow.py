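"""Configuration-driven orchestration of the three analysis arms.

``run`` takes a validated :class:`RunConfig` and executes one arm end to
end — generate (or load) inputs, fit/measure, and write a results bundle:
CSV tables, TIFF maps, a JSON summary and a manifest recording the seed
and configuration hash.  ``report`` renders a bundle as human-readable
text.  The CLI in :mod:`cardiomics.cli` is a thin wrapper over these two
functions.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .flim_synth import (
    AcquisitionSpec,
    BiexpTruth,
    SceneLayout,
    ValidationError,
    make_scene,
    simulate_cube,
)
from .flim_fit import FitConfig, fit_cube
from .flim_metrics import compute_flirr, detect_granules, group_stats, cohens_d, roi_stats
from .image_synth import MitoShapeSpec, synth_mitochondria, synth_nuclei_ki67, synth_foci
from .morphometry import count_foci, ki67_fraction, mito_metrics, segment_mitochondria
from .metabo_synth import EffectSpec, synth_table, toy_pathways
from . import chemometrics as chem

__all__ = ["RunConfig", "run", "report"]

_ARMS = ("flim", "morphometry", "metabolomics")


@dataclass
class RunConfig:
    """One arm of the study pipeline.

    ``params`` holds the arm-specific block (see the example configs under
    ``examples/``); unknown arms or malformed blocks fail validation with
    a message naming the offending field.
    """

    arm: str
    seed: int = 0
    out_dir: str = "results"
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.arm not in _ARMS:
            raise ValidationError(f"arm must be one of {_ARMS}, got {self.arm!r}")
        if not isinstance(self.seed, int):
            raise ValidationError("seed must be an integer")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ValidationError("config file must contain a mapping")
        unknown = set(data) - {"arm", "seed", "out_dir", "params"}
        if unknown:
            raise ValidationError(f"unknown config fields: {sorted(unknown)}")
        if "arm" not in data:
            raise ValidationError("config is missing required field 'arm'")
        return cls(**data)


def _manifest(config: RunConfig) -> dict:
    blob = json.dumps(asdict(config), sort_keys=True).encode()
    return {
        "config": asdict(config),
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "seed": config.seed,
        "version": __version__,
    }


def _run_flim(config: RunConfig, out: Path) -> dict:
    p = config.params
    spec = AcquisitionSpec(frame_shape=tuple(p.get("frame_shape", (64, 64))))
    nadh = BiexpTruth(**p.get("nadh", {"a1": 71.6, "a2": 28.4, "tau1": 0.4, "tau2": 2.5}))
    fad = BiexpTruth(**p.get("fad", {"a1": 68.2, "a2": 31.8, "tau1": 0.35, "tau2": 2.8}))
    layout_n = SceneLayout(
        n_cells=p.get("n_cells", 4),
        group_params={"cells": nadh},
        granule_rate=p.get("granule_rate", 0.0),
        cell_radius=p.get("cell_radius", 10.0),
    )
    layout_f = SceneLayout(
        n_cells=layout_n.n_cells,
        group_params={"cells": fad},
        granule_rate=0.0,
        cell_radius=layout_n.cell_radius,
    )
    photons = p.get("photons_per_pixel", 200)
    fit_cfg = FitConfig(bin_size=p.get("bin_size", 5))

    scene_n = make_scene(layout_n, spec, config.seed)
    scene_f = make_scene(layout_f, spec, config.seed)  # same geometry, FAD truth
    cube_n = simulate_cube(scene_n, spec, photons, config.seed + 1, channel="NADH")
    cube_f = simulate_cube(scene_f, spec, photons, config.seed + 2, channel="FAD")

    maps_n = fit_cube(cube_n, scene_n.cytoplasm_masks, fit_cfg)
    maps_f = fit_cube(cube_f, scene_f.cytoplasm_masks, fit_cfg)
    flirr = compute_flirr(maps_n, maps_f, scene_n.cytoplasm_masks)
    tifffile.imwrite(out / "flirr_map.tif", flirr.flirr_map.astype(np.float32))
    per_cell = pd.DataFrame(
        {"cell": list(flirr.per_cell), "flirr": list(flirr.per_cell.values())}
    )
    per_cell.to_csv(out / "flirr_per_cell.csv", index=False)

    gran = detect_granules(
        maps_n.tau_m, scene_n.cell_masks, threshold=p.get("granule_threshold", None)
    ) if p.get("detect_granules", False) else None

    summary = {
        "mean_flirr": float(np.nanmean(list(flirr.per_cell.values()))),
        "n_cells": len(flirr.per_cell),
        "n_valid_pixels": int(maps_n.valid.sum()),
    }
    if gran is not None:
        summary["granules_per_cell"] = {str(k): v for k, v in gran.per_cell_counts.items()}
    return summary


def _run_morphometry(config: RunConfig, out: Path) -> dict:
    p = config.params
    summary: dict = {}

    specs = [MitoShapeSpec(**s) for s in p.get(
        "mitochondria", [{"area": 300, "aspect_ratio": 2.0}, {"area": 150, "aspect_ratio": 1.0}]
    )]
    img, labels, _truth = synth_mitochondria(specs, config.seed)
    seg = segment_mitochondria(img)
    mm = mito_metrics(seg)
    pd.DataFrame(
        {
            "label": mm.labels,
            "area": mm.area,
            "perimeter": mm.perimeter,
            "form_factor": mm.form_factor,
            "aspect_ratio": mm.aspect_ratio,
            "branch_count": mm.branch_count,
        }
    ).to_csv(out / "mito_metrics.csv", index=False)
    summary["n_mitochondria"] = int(len(mm.labels))

    coverages = p.get("ki67_coverages", [0.0, 0.2, 0.5, 0.9])
    _dna, ki67, nlabels, _t = synth_nuclei_ki67(len(coverages), coverages, config.seed)
    calls, frac = ki67_fraction(nlabels, ki67)
    pd.DataFrame(
        {"nucleus": [c.nucleus_id for c in calls],
         "coverage": [c.coverage for c in calls],
         "positive": [c.positive for c in calls]}
    ).to_csv(out / "ki67_calls.csv", index=False)
    summary["ki67_positive_fraction"] = frac

    foci_counts = p.get("foci_counts", [0, 3, 7])
    focus_img, flabels, _t = synth_foci(foci_counts, config.seed)
    counted = count_foci(focus_img, flabels)
    pd.DataFrame(
        {"nucleus": list(counted), "foci": list(counted.values())}
    ).to_csv(out / "foci_counts.csv", index=False)
    summary["total_foci"] = int(sum(counted.values()))
    return summary


def _run_metabolomics(config: RunConfig, out: Path) -> dict:
    p = config.params
    n_features = p.get("n_features", 120)
    effects = {int(k): float(v) for k, v in p.get("log2_effects", {"0": 3.0, "1": -3.0}).items()}
    table, _truth = synth_table(
        n_features,
        groups=tuple(p.get("groups", ("day0", "day10"))),
        effect=EffectSpec(log2_effects=effects),
        seed=config.seed,
    )
    filtered, rep = chem.filter_features(table)
    imputed = chem.impute_half_min(filtered)
    norm = chem.normalize(imputed)
    model = chem.plsda(norm.table)
    cv = chem.cross_validate(norm.table)
    uni = chem.univariate(
        norm.table, fc_table=norm.stages.get("median_norm", imputed), vip=model.vip
    )
    uni.table.to_csv(out / "univariate.csv")
    model.vip.sort_values(ascending=False).to_csv(out / "vip.csv")

    sig = uni.table.index[uni.table["significant"]].tolist()
    library = toy_pathways(
        p.get("n_pathways", 10), p.get("pathway_size", 8), filtered.feature_meta.index,
        seed=config.seed,
    )
    summary = {
        "features_input": rep.n_input,
        "features_kept": rep.n_kept,
        "r2": cv.r2,
        "q2": cv.q2,
        "n_significant": len(sig),
    }
    if sig:
        enr = chem.ora_enrichment(sig, library, filtered.feature_meta.index)
        enr.table.to_csv(out / "enrichment.csv")
        summary["n_enriched_pathways"] = int(enr.table["enriched"].sum()) if len(enr.table) else 0
    else:
        summary["n_enriched_pathways"] = 0
    return summary


def run(config: RunConfig) -> Path:
    """Execute one arm and write its results bundle; returns the bundle dir."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    runner = {
        "flim": _run_flim,
        "morphometry": _run_morphometry,
        "metabolomics": _run_metabolomics,
    }[config.arm]
    summary = runner(config, out)
    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    (out / "manifest.json").write_text(json.dumps(_manifest(config), indent=1, sort_keys=True))
    return out


def report(bundle_dir: str | Path) -> str:
    """Render a results bundle as a plain-text summary."""
    bundle_dir = Path(bundle_dir)
    lines = [f"Results bundle: {bundle_dir}"]
    manifest_path = bundle_dir / "manifest.json"
    if manifest_path.exists():
        manifest = json.loads(manifest_path.read_text())
        lines.append(f"  arm={manifest['config']['arm']} seed={manifest['seed']} "
                     f"version={manifest['version']}")
    else:
        lines.append("  WARNING: manifest.json missing")
    summary_path = bundle_dir / "summary.json"
    if summary_path.exists():
        summary = json.loads(summary_path.read_text())
        for k, v in summary.items():
            lines.append(f"  {k}: {v}")
    else:
        lines.append("  WARNING: summary.json missing")
    for csv in sorted(bundle_dir.glob("*.csv")):
        df = pd.read_csv(csv)
        lines.append(f"\n== {csv.name} ({len(df)} rows) ==")
        lines.append(df.head(10).to_string(index=False))
        if len(df) == 0:
            lines.append("  (none)")
    return "\n".join(lines)
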