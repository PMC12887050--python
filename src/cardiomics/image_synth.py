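"""Seeded synthetic fluorescence scenes with morphometric ground truth.

Generators for the image-based readouts: nuclei with a controlled Ki67
coverage fraction, punctate nuclear foci (gamma-H2AX-like Gaussian spots),
filamentous or elliptical mitochondria with controlled area, aspect ratio
and branch structure, and cells with known mean ROS-probe intensity.
Images are single-plane 16-bit, row-major with origin at the top-left;
masks are label images with 0 = background.  Every generator is
deterministic for a fixed seed and returns a truth record that can be
serialised to JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import skimage.draw as draw
import skimage.morphology as morph

from .flim_synth import ValidationError

__all__ = [
    "MorphoSceneTruth",
    "MitoShapeSpec",
    "synth_nuclei_ki67",
    "synth_foci",
    "synth_mitochondria",
    "synth_ros_cells",
]

FOREGROUND = 3000  # 16-bit intensity used for rendered structures


@dataclass
class MorphoSceneTruth:
    """Ground truth emitted by the 2-D scene generators (JSON-serialisable)."""

    seed: int
    nuclei_coverage: dict[int, float] = field(default_factory=dict)
    foci_per_nucleus: dict[int, int] = field(default_factory=dict)
    foci_positions: list[tuple[int, float, float]] = field(default_factory=list)
    mito_objects: list[dict] = field(default_factory=list)
    ros_per_cell: dict[int, float] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = asdict(self)
        payload["nuclei_coverage"] = {str(k): v for k, v in self.nuclei_coverage.items()}
        payload["foci_per_nucleus"] = {str(k): v for k, v in self.foci_per_nucleus.items()}
        payload["ros_per_cell"] = {str(k): v for k, v in self.ros_per_cell.items()}
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "MorphoSceneTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            seed=d["seed"],
            nuclei_coverage={int(k): v for k, v in d["nuclei_coverage"].items()},
            foci_per_nucleus={int(k): v for k, v in d["foci_per_nucleus"].items()},
            foci_positions=[tuple(x) for x in d["foci_positions"]],
            mito_objects=d["mito_objects"],
            ros_per_cell={int(k): v for k, v in d["ros_per_cell"].items()},
        )


def _grid_centers(
    n: int, shape: tuple[int, int], radius: float, rng: np.random.Generator
) -> list[tuple[float, float]]:
    rows, cols = shape
    n_side = int(np.ceil(np.sqrt(n)))
    pr, pc = rows / n_side, cols / n_side
    if min(pr, pc) < 2 * radius + 2:
        raise ValidationError(f"cannot pack {n} objects of radius {radius} into {shape}")
    centers = []
    for k in rng.permutation(n_side * n_side)[:n]:
        i, j = divmod(int(k), n_side)
        jit = min(pr, pc) / 2 - radius - 1
        centers.append(
            ((i + 0.5) * pr + rng.uniform(-jit, jit), (j + 0.5) * pc + rng.uniform(-jit, jit))
        )
    return centers


def _place_nuclei(
    n: int, shape: tuple[int, int], radius: float, rng: np.random.Generator
) -> np.ndarray:
    labels = np.zeros(shape, dtype=np.uint16)
    for lbl, (cr, cc) in enumerate(_grid_centers(n, shape, radius, rng), start=1):
        rr, cc2 = draw.disk((cr, cc), radius, shape=shape)
        labels[rr, cc2] = lbl
    return labels


def synth_nuclei_ki67(
    n_nuclei: int,
    coverages,
    seed: int,
    shape: tuple[int, int] = (256, 256),
    nucleus_radius: float = 12.0,
    noise: bool = False,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, MorphoSceneTruth]:
    """DNA-stain and Ki67 channels with per-nucleus coverage control.

    For each nucleus the Ki67-positive region is a compact blob occupying
    the requested fraction of the nucleus area to within rasterisation
    error.  Returns (dna_channel, ki67_channel, nuclei_labels, truth).
    """
    coverages = list(coverages)
    if len(coverages) != n_nuclei:
        raise ValidationError("one coverage per nucleus required")
    if any(c < 0 or c > 1 for c in coverages):
        raise ValidationError("coverages must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    labels = _place_nuclei(n_nuclei, shape, nucleus_radius, rng)

    dna = np.zeros(shape, dtype=np.uint16)
    ki67 = np.zeros(shape, dtype=np.uint16)
    dna[labels > 0] = FOREGROUND
    truth = MorphoSceneTruth(seed=seed)
    for lbl in range(1, n_nuclei + 1):
        sel = labels == lbl
        area = int(sel.sum())
        n_pos = int(round(coverages[lbl - 1] * area))
        if n_pos > 0:
            rr, cc = np.nonzero(sel)
            # grow the positive blob from a random point inside the nucleus
            k = rng.integers(len(rr))
            d2 = (rr - rr[k]) ** 2 + (cc - cc[k]) ** 2
            order = np.argsort(d2, kind="stable")[:n_pos]
            ki67[rr[order], cc[order]] = FOREGROUND
        truth.nuclei_coverage[lbl] = n_pos / area
    if noise:
        dna = rng.poisson(dna.astype(float) / 10).astype(np.uint16) * 10
        ki67 = rng.poisson(ki67.astype(float) / 10).astype(np.uint16) * 10
    return dna, ki67, labels, truth


def synth_foci(
    counts_per_nucleus,
    seed: int,
    spot_sigma: float = 2.0,
    min_separation: float | None = None,
    shape: tuple[int, int] = (256, 256),
    nucleus_radius: float = 18.0,
    amplitude: float = FOREGROUND,
    noise: bool = False,
) -> tuple[np.ndarray, np.ndarray, MorphoSceneTruth]:
    """Gaussian focus channel with planted per-nucleus counts.

    Foci are isotropic Gaussian spots of width ``spot_sigma`` placed inside
    each nucleus with a minimum pairwise separation (default 4 sigma).
    Returns (focus_channel, nuclei_labels, truth).
    """
    counts = [int(c) for c in counts_per_nucleus]
    if any(c < 0 for c in counts):
        raise ValidationError("focus counts must be >= 0")
    if min_separation is None:
        min_separation = 4.0 * spot_sigma
    rng = np.random.default_rng(seed)
    labels = _place_nuclei(len(counts), shape, nucleus_radius, rng)

    img = np.zeros(shape, dtype=float)
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    truth = MorphoSceneTruth(seed=seed)
    for lbl, n_foci in enumerate(counts, start=1):
        truth.foci_per_nucleus[lbl] = n_foci
        if n_foci == 0:
            continue
        rr, cc = np.nonzero(labels == lbl)
        cy, cx = rr.mean(), cc.mean()
        margin = 2.0 * spot_sigma
        placed: list[tuple[float, float]] = []
        for _ in range(n_foci):
            for _attempt in range(500):
                ang = rng.uniform(0, 2 * np.pi)
                rad = rng.uniform(0, nucleus_radius - margin)
                p = (cy + rad * np.sin(ang), cx + rad * np.cos(ang))
                if all(np.hypot(p[0] - q[0], p[1] - q[1]) >= min_separation for q in placed):
                    placed.append(p)
                    break
            else:
                raise ValidationError(
                    f"cannot place {n_foci} foci at separation {min_separation} "
                    f"in a nucleus of radius {nucleus_radius}"
                )
        for p in placed:
            img += amplitude * np.exp(
                -((yy - p[0]) ** 2 + (xx - p[1]) ** 2) / (2 * spot_sigma**2)
            )
            truth.foci_positions.append((lbl, float(p[0]), float(p[1])))
    if noise:
        img = rng.poisson(np.clip(img, 0, None) / 10) * 10.0
    return np.clip(img, 0, 65535).astype(np.uint16), labels, truth


@dataclass(frozen=True)
class MitoShapeSpec:
    """Requested shape of one mitochondrion.

    ``branches`` follows the skeleton-analysis convention branch_count =
    junction points + 1: an unbranched filament or ellipse has
    ``branches = 1``; each additional branch adds one side arm at a
    distinct junction.
    """

    area: float
    aspect_ratio: float = 1.0
    branches: int = 1

    def __post_init__(self) -> None:
        if self.area <= 0:
            raise ValidationError("area must be positive")
        if self.aspect_ratio < 1:
            raise ValidationError("aspect_ratio must be >= 1")
        if self.branches < 1:
            raise ValidationError("branches must be >= 1")


def _render_ellipse(spec: MitoShapeSpec, center, shape) -> np.ndarray:
    b = np.sqrt(spec.area / (np.pi * spec.aspect_ratio))
    a = spec.aspect_ratio * b
    rr, cc = draw.ellipse(center[0], center[1], b, a, shape=shape)
    m = np.zeros(shape, dtype=bool)
    m[rr, cc] = True
    return m


def _render_filament(
    spec: MitoShapeSpec, center, shape, rng: np.random.Generator
) -> np.ndarray:
    """Dilated polyline with (branches - 1) side arms; area matched by iteration."""
    half_w = 2  # filament half-thickness in px
    n_side = spec.branches - 1
    # initial total skeleton length from the strip-area approximation
    length = max(spec.area / (2 * half_w + 1), 8.0)
    for _ in range(4):
        m = np.zeros(shape, dtype=bool)
        main_len = length / (1 + 0.5 * n_side)
        r0, c0 = center[0], center[1] - main_len / 2
        r1, c1 = center[0], center[1] + main_len / 2
        rr, cc = draw.line(int(r0), int(c0), int(r1), int(c1))
        m[np.clip(rr, 0, shape[0] - 1), np.clip(cc, 0, shape[1] - 1)] = True
        arm_len = 0.5 * main_len
        for k in range(n_side):
            # junctions spread along the main axis, arms alternate up/down
            fr = (k + 1) / (n_side + 1)
            jc = int(c0 + fr * (c1 - c0))
            sign = 1 if k % 2 == 0 else -1
            rr, cc = draw.line(
                int(center[0]), jc, int(center[0] + sign * arm_len), jc
            )
            m[np.clip(rr, 0, shape[0] - 1), np.clip(cc, 0, shape[1] - 1)] = True
        m = morph.dilation(m, morph.disk(half_w))
        got = m.sum()
        if abs(got - spec.area) / spec.area < 0.04:
            break
        length *= spec.area / got
    return m


def synth_mitochondria(
    shape_specs,
    seed: int,
    shape: tuple[int, int] = (256, 256),
    noise: bool = False,
) -> tuple[np.ndarray, np.ndarray, MorphoSceneTruth]:
    """Render mitochondria with requested area / aspect ratio / branches.

    Unbranched objects are ellipses; branched ones are skeleton-grown
    filaments of fixed thickness.  Returns (channel, labels, truth).
    """
    specs = [s if isinstance(s, MitoShapeSpec) else MitoShapeSpec(**s) for s in shape_specs]
    rng = np.random.default_rng(seed)
    max_extent = max(np.sqrt(s.area * s.aspect_ratio / np.pi) * 2 + 4 for s in specs)
    centers = _grid_centers(len(specs), shape, max_extent / 2, rng)

    labels = np.zeros(shape, dtype=np.uint16)
    truth = MorphoSceneTruth(seed=seed)
    for lbl, (spec_i, center) in enumerate(zip(specs, centers), start=1):
        if spec_i.branches == 1:
            m = _render_ellipse(spec_i, center, shape)
        else:
            m = _render_filament(spec_i, center, shape, rng)
        m &= labels == 0
        labels[m] = lbl
        truth.mito_objects.append(
            {
                "label": lbl,
                "requested": asdict(spec_i),
                "rendered_area": int(m.sum()),
            }
        )
    img = np.where(labels > 0, FOREGROUND, 0).astype(np.uint16)
    if noise:
        img = (rng.poisson(img.astype(float) / 10) * 10).astype(np.uint16)
    return img, labels, truth


def synth_ros_cells(
    per_cell_means,
    seed: int,
    shape: tuple[int, int] = (256, 256),
    cell_radius: float = 20.0,
    noise: bool = False,
) -> tuple[np.ndarray, np.ndarray, MorphoSceneTruth]:
    """Cells rendered as disks of constant, known mean ROS intensity."""
    means = [float(v) for v in per_cell_means]
    if any(v < 0 for v in means):
        raise ValidationError("intensities must be >= 0")
    rng = np.random.default_rng(seed)
    labels = _place_nuclei(len(means), shape, cell_radius, rng)
    img = np.zeros(shape, dtype=float)
    truth = MorphoSceneTruth(seed=seed)
    for lbl, v in enumerate(means, start=1):
        img[labels == lbl] = v
        truth.ros_per_cell[lbl] = v
    if noise:
        img = rng.poisson(np.clip(img, 0, None))
    return img.astype(np.uint16), labels, truth
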