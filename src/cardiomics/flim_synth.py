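"""Synthetic TCSPC decay cubes with known biexponential ground truth.

Time-correlated single photon counting (TCSPC) builds, for every image
pixel, a histogram of photon arrival times within one laser repetition
period.  For autofluorescence imaging of NAD(P)H and FAD the decay in each
pixel is well described by a two-component exponential

    I(t) = a1 * exp(-t / tau1) + a2 * exp(-t / tau2),

where ``a1 + a2 = 100 %`` are the fractional pre-exponential amplitudes of
the short- and long-lifetime species.  This module renders whole scenes of
cells with per-pixel ground-truth parameters, simulates photon shot noise,
and optionally plants short-lifetime lipofuscin-like granules, so that
every downstream fitting and measurement stage can be validated against a
known truth.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import tifffile

__all__ = [
    "AcquisitionSpec",
    "BiexpTruth",
    "GranuleTruth",
    "SceneLayout",
    "SceneTruth",
    "DecayCube",
    "decay_shape",
    "make_scene",
    "simulate_cube",
    "write_cube",
    "read_cube",
    "write_scene_truth",
    "read_scene_truth",
]


class ValidationError(ValueError):
    """Raised when a domain object violates its invariants."""


@dataclass(frozen=True)
class AcquisitionSpec:
    """TCSPC acquisition geometry.

    Defaults correspond to a pulsed laser at 80 MHz repetition rate
    (12.5 ns period) with the period divided into 256 timing bins.
    ``irf_fwhm`` is the FWHM of a Gaussian instrument response; 0 means an
    ideal delta IRF.
    """

    n_time_bins: int = 256
    bin_width: float = 12.5 / 256  # ns
    laser_period: float = 12.5  # ns (80 MHz)
    irf_fwhm: float = 0.0  # ns
    frame_shape: tuple[int, int] = (64, 64)

    def __post_init__(self) -> None:
        if self.n_time_bins <= 0:
            raise ValidationError("n_time_bins must be positive")
        if self.bin_width <= 0:
            raise ValidationError("bin_width must be positive")
        if self.laser_period <= 0:
            raise ValidationError("laser_period must be positive")
        if self.irf_fwhm < 0:
            raise ValidationError("irf_fwhm must be >= 0")
        if self.n_time_bins * self.bin_width > self.laser_period * (1 + 1e-9):
            raise ValidationError(
                "n_time_bins * bin_width exceeds laser_period: the measurement "
                "window cannot be longer than one repetition period"
            )
        if any(s <= 0 for s in self.frame_shape):
            raise ValidationError("frame_shape dimensions must be positive")

    @property
    def bin_edges(self) -> np.ndarray:
        return np.arange(self.n_time_bins + 1) * self.bin_width

    @property
    def bin_centers(self) -> np.ndarray:
        return (np.arange(self.n_time_bins) + 0.5) * self.bin_width


@dataclass(frozen=True)
class BiexpTruth:
    """Ground-truth biexponential parameters for one pixel population.

    Amplitudes are percentages of the total pre-exponential amplitude
    (``a1 + a2 = 100``); lifetimes are in ns with ``tau1 < tau2`` except in
    the mono-exponential limit ``a2 = 0`` where ``tau2`` is ignored.
    """

    a1: float
    a2: float
    tau1: float
    tau2: float

    def __post_init__(self) -> None:
        if not np.isclose(self.a1 + self.a2, 100.0, atol=1e-6):
            raise ValidationError(f"a1 + a2 must equal 100 %, got {self.a1 + self.a2}")
        if self.a1 < 0 or self.a2 < 0:
            raise ValidationError("amplitude fractions must be non-negative")
        if self.tau1 <= 0 or self.tau2 <= 0:
            raise ValidationError("lifetimes must be positive")
        if self.a2 > 0 and self.tau1 >= self.tau2:
            raise ValidationError(f"tau1 must be < tau2, got tau1={self.tau1}, tau2={self.tau2}")

    @property
    def tau_m(self) -> float:
        """Amplitude-weighted mean lifetime (ns): tau_m = a1*tau1 + a2*tau2."""
        return (self.a1 * self.tau1 + self.a2 * self.tau2) / 100.0

    def scaled_to_tau_m(self, target_tau_m: float) -> "BiexpTruth":
        """Return parameters with both lifetimes rescaled to hit a target tau_m."""
        s = target_tau_m / self.tau_m
        return BiexpTruth(self.a1, self.a2, self.tau1 * s, self.tau2 * s)


@dataclass(frozen=True)
class GranuleTruth:
    cell_label: int
    centroid: tuple[float, float]
    radius: float
    params: BiexpTruth


@dataclass
class SceneLayout:
    """Cell layout for a synthetic FLIM scene.

    ``group_params`` maps group name -> BiexpTruth; cells are assigned to
    groups round-robin.  ``granule_rate`` is the Poisson mean number of
    short-lifetime granules per cell.  Granule lifetimes default to the
    cell's parameters rescaled so that tau_m is halved (lipofuscin granules
    appear markedly shorter-lived than the surrounding cytoplasm; no
    canonical value exists, so the contrast is configurable).
    """

    n_cells: int = 4
    group_params: dict[str, BiexpTruth] = field(
        default_factory=lambda: {"cells": BiexpTruth(70.0, 30.0, 0.5, 2.5)}
    )
    granule_rate: float = 0.0
    granule_radius: float = 2.0
    granule_tau_m_factor: float = 0.5
    cell_radius: float = 10.0
    nucleus_radius_frac: float = 0.35


@dataclass
class SceneTruth:
    """Per-pixel ground truth for one synthetic scene.

    ``cell_masks`` labels whole cells (0 = background); ``cytoplasm_masks``
    labels the cytoplasmic annulus of each cell with the same label.
    ``a1/a2/tau1/tau2`` are per-pixel parameter images (NaN outside cells).
    """

    a1: np.ndarray
    a2: np.ndarray
    tau1: np.ndarray
    tau2: np.ndarray
    cell_masks: np.ndarray
    cytoplasm_masks: np.ndarray
    cell_groups: dict[int, str]
    granules: list[GranuleTruth]
    seed: int

    @property
    def tau_m(self) -> np.ndarray:
        return (self.a1 * self.tau1 + self.a2 * self.tau2) / 100.0

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SceneTruth):
            return NotImplemented
        return (
            all(
                np.array_equal(getattr(self, f), getattr(other, f), equal_nan=True)
                for f in ("a1", "a2", "tau1", "tau2", "cell_masks", "cytoplasm_masks")
            )
            and self.cell_groups == other.cell_groups
            and self.granules == other.granules
            and self.seed == other.seed
        )


@dataclass
class DecayCube:
    """A (rows, cols, n_time_bins) stack of per-pixel photon-count histograms."""

    counts: np.ndarray
    spec: AcquisitionSpec
    channel: str = "broad"

    def __post_init__(self) -> None:
        expected = (*self.spec.frame_shape, self.spec.n_time_bins)
        if self.counts.shape != expected:
            raise ValidationError(
                f"counts shape {self.counts.shape} inconsistent with spec {expected}"
            )
        if np.any(self.counts < 0):
            raise ValidationError("photon counts must be non-negative")

    @property
    def total_counts(self) -> np.ndarray:
        """Per-pixel photon totals (intensity image)."""
        return self.counts.sum(axis=-1)


def _wrapped_exp_bin_integrals(tau: float, spec: AcquisitionSpec) -> np.ndarray:
    """Integral of the periodically wrapped exponential over each timing bin.

    With repetition period T, the steady-state decay observed in [0, T) is
    sum_k exp(-(t + kT)/tau) = exp(-t/tau) / (1 - exp(-T/tau)); integrating
    over a bin [t0, t1) gives tau * (e^{-t0/tau} - e^{-t1/tau}) / (1 - e^{-T/tau}).
    """
    edges = np.arange(spec.n_time_bins + 1) * spec.bin_width
    e = np.exp(-edges / tau)
    return tau * (e[:-1] - e[1:]) / (1.0 - np.exp(-spec.laser_period / tau))


def _irf_kernel(spec: AcquisitionSpec) -> np.ndarray | None:
    if spec.irf_fwhm <= 0:
        return None
    sigma = spec.irf_fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    n = spec.n_time_bins
    # periodic Gaussian centred on bin 0
    t = (np.arange(n) + 0.5) * spec.bin_width
    period = spec.laser_period
    k = np.zeros(n)
    for shift in (-period, 0.0, period):
        k += np.exp(-0.5 * ((t + shift) / sigma) ** 2)
    return k / k.sum()


def decay_shape(params: BiexpTruth, spec: AcquisitionSpec) -> np.ndarray:
    """Expected per-bin photon fractions for a biexponential decay.

    Includes periodic wrap-around of incomplete decays and, when
    ``spec.irf_fwhm > 0``, circular convolution with a Gaussian IRF.
    Returns a probability vector over the ``n_time_bins`` bins.
    """
    p = params.a1 * _wrapped_exp_bin_integrals(params.tau1, spec)
    if params.a2 > 0:
        p = p + params.a2 * _wrapped_exp_bin_integrals(params.tau2, spec)
    kernel = _irf_kernel(spec)
    if kernel is not None:
        p = np.real(np.fft.ifft(np.fft.fft(p) * np.fft.fft(kernel)))
        p = np.clip(p, 0.0, None)
    return p / p.sum()


def _place_cells(
    n_cells: int, frame_shape: tuple[int, int], radius: float, rng: np.random.Generator
) -> list[tuple[float, float]]:
    """Jittered-grid placement of non-overlapping circular cells."""
    rows, cols = frame_shape
    n_side = int(np.ceil(np.sqrt(n_cells)))
    pitch_r, pitch_c = rows / n_side, cols / n_side
    if min(pitch_r, pitch_c) < 2 * radius + 1:
        raise ValidationError(
            f"cannot place {n_cells} cells of radius {radius} in frame {frame_shape}"
        )
    centers = []
    order = rng.permutation(n_side * n_side)[:n_cells]
    for k in order:
        i, j = divmod(int(k), n_side)
        jit = (min(pitch_r, pitch_c) / 2 - radius - 0.5)
        cr = (i + 0.5) * pitch_r + rng.uniform(-jit, jit)
        cc = (j + 0.5) * pitch_c + rng.uniform(-jit, jit)
        centers.append((cr, cc))
    return centers


def make_scene(layout: SceneLayout, spec: AcquisitionSpec, seed: int) -> SceneTruth:
    """Build a labelled scene of cells with per-pixel biexponential truth.

    Cells are circles with a central nucleus; the cytoplasm is the annulus
    between nucleus and cell boundary.  Granules are planted as small disks
    inside the cytoplasm whose truth is replaced by a short-tau_m parameter
    set.  Deterministic for a fixed seed.
    """
    if layout.n_cells <= 0:
        raise ValidationError("n_cells must be positive")
    if layout.granule_rate < 0:
        raise ValidationError("granule_rate must be >= 0")
    for name, p in layout.group_params.items():
        if p.a2 > 0 and p.tau2 >= spec.laser_period:
            raise ValidationError(f"group {name!r}: tau2 must be below the laser period")

    rng = np.random.default_rng(seed)
    rows, cols = spec.frame_shape
    rr, cc = np.mgrid[0:rows, 0:cols]

    a1 = np.full((rows, cols), np.nan)
    a2 = np.full((rows, cols), np.nan)
    tau1 = np.full((rows, cols), np.nan)
    tau2 = np.full((rows, cols), np.nan)
    cell_masks = np.zeros((rows, cols), dtype=np.uint16)
    cyto_masks = np.zeros((rows, cols), dtype=np.uint16)

    centers = _place_cells(layout.n_cells, (rows, cols), layout.cell_radius, rng)
    group_names = list(layout.group_params)
    cell_groups: dict[int, str] = {}
    granules: list[GranuleTruth] = []

    for idx, (cr, cc0) in enumerate(centers):
        label = idx + 1
        group = group_names[idx % len(group_names)]
        params = layout.group_params[group]
        cell_groups[label] = group

        d2 = (rr - cr) ** 2 + (cc - cc0) ** 2
        cell = d2 <= layout.cell_radius**2
        nucleus = d2 <= (layout.nucleus_radius_frac * layout.cell_radius) ** 2
        cell_masks[cell] = label
        cyto_masks[cell & ~nucleus] = label

        a1[cell] = params.a1
        a2[cell] = params.a2
        tau1[cell] = params.tau1
        tau2[cell] = params.tau2

        n_gran = rng.poisson(layout.granule_rate)
        g_params = params.scaled_to_tau_m(params.tau_m * layout.granule_tau_m_factor)
        for _ in range(n_gran):
            # rejection-sample a granule centre inside the cytoplasm annulus
            r_hi = layout.cell_radius - layout.granule_radius
            r_lo = layout.nucleus_radius_frac * layout.cell_radius + layout.granule_radius
            if r_lo >= r_hi:  # cell too small for the annulus; allow anywhere inside
                r_lo = 0.0
            for _attempt in range(200):
                ang = rng.uniform(0, 2 * np.pi)
                rad = rng.uniform(r_lo, max(r_hi, 0.0))
                gr, gc = cr + rad * np.sin(ang), cc0 + rad * np.cos(ang)
                gd2 = (rr - gr) ** 2 + (cc - gc) ** 2
                disk = gd2 <= layout.granule_radius**2
                if np.all(cell_masks[disk] == label):
                    a1[disk] = g_params.a1
                    a2[disk] = g_params.a2
                    tau1[disk] = g_params.tau1
                    tau2[disk] = g_params.tau2
                    granules.append(GranuleTruth(label, (gr, gc), layout.granule_radius, g_params))
                    break
            else:
                warnings.warn(f"could not place a granule in cell {label}; skipped")

    return SceneTruth(a1, a2, tau1, tau2, cell_masks, cyto_masks, cell_groups, granules, seed)


def simulate_cube(
    truth: SceneTruth,
    spec: AcquisitionSpec,
    photons_per_pixel: float,
    seed: int,
    channel: str = "broad",
    noise: bool = True,
    dark_rate: float = 0.0,
) -> DecayCube:
    """Forward-simulate a TCSPC cube from per-pixel ground truth.

    Each in-cell pixel's expected histogram is its biexponential shape
    (wrapped at the laser period, optionally IRF-convolved) scaled to
    ``photons_per_pixel``; counts are independent Poisson draws per bin.
    ``noise=False`` returns the expected values (useful as a noiseless
    oracle).  ``dark_rate`` adds a uniform background expectation
    (counts per pixel over the whole window) everywhere.
    """
    if photons_per_pixel <= 0:
        raise ValidationError("photons_per_pixel must be positive")
    if truth.cell_masks.shape != spec.frame_shape:
        raise ValidationError(
            f"truth frame {truth.cell_masks.shape} does not match spec {spec.frame_shape}"
        )

    rows, cols = spec.frame_shape
    expected = np.zeros((rows, cols, spec.n_time_bins))
    in_cell = truth.cell_masks > 0

    # pixels sharing a parameter tuple share one decay shape
    params_stack = np.stack([truth.a1, truth.a2, truth.tau1, truth.tau2], axis=-1)
    flat = params_stack[in_cell]
    uniq, inverse = np.unique(flat, axis=0, return_inverse=True)
    shapes = np.empty((len(uniq), spec.n_time_bins))
    for i, (ua1, ua2, ut1, ut2) in enumerate(uniq):
        shapes[i] = decay_shape(BiexpTruth(ua1, ua2, ut1, ut2), spec)
    expected[in_cell] = shapes[inverse] * photons_per_pixel

    if dark_rate > 0:
        expected += dark_rate / spec.n_time_bins

    if noise:
        rng = np.random.default_rng(seed)
        counts = rng.poisson(expected).astype(np.int64)
    else:
        counts = expected
    return DecayCube(counts=counts, spec=spec, channel=channel)


# ---------------------------------------------------------------------------
# I/O: cubes as multi-page TIFF + JSON sidecar; truth as TIFF labels + JSON


def write_cube(cube: DecayCube, tiff_path: str | Path) -> None:
    """Write a cube as a multi-page TIFF (one page per time bin) + JSON sidecar."""
    tiff_path = Path(tiff_path)
    pages = np.moveaxis(np.asarray(cube.counts), -1, 0)
    tifffile.imwrite(tiff_path, pages.astype(np.float64 if pages.dtype.kind == "f" else np.uint32))
    sidecar = {
        "channel": cube.channel,
        "spec": {
            "n_time_bins": cube.spec.n_time_bins,
            "bin_width": cube.spec.bin_width,
            "laser_period": cube.spec.laser_period,
            "irf_fwhm": cube.spec.irf_fwhm,
            "frame_shape": list(cube.spec.frame_shape),
        },
    }
    tiff_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_cube(tiff_path: str | Path) -> DecayCube:
    tiff_path = Path(tiff_path)
    pages = tifffile.imread(tiff_path)
    meta = json.loads(tiff_path.with_suffix(".json").read_text())
    s = meta["spec"]
    spec = AcquisitionSpec(
        n_time_bins=s["n_time_bins"],
        bin_width=s["bin_width"],
        laser_period=s["laser_period"],
        irf_fwhm=s["irf_fwhm"],
        frame_shape=tuple(s["frame_shape"]),
    )
    counts = np.moveaxis(pages, 0, -1)
    if counts.dtype.kind != "f":
        counts = counts.astype(np.int64)
    return DecayCube(counts=counts, spec=spec, channel=meta["channel"])


def write_scene_truth(truth: SceneTruth, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(directory / "cell_masks.tif", truth.cell_masks.astype(np.uint16))
    tifffile.imwrite(directory / "cytoplasm_masks.tif", truth.cytoplasm_masks.astype(np.uint16))
    for name in ("a1", "a2", "tau1", "tau2"):
        tifffile.imwrite(directory / f"{name}.tif", getattr(truth, name).astype(np.float64))
    payload = {
        "seed": truth.seed,
        "cell_groups": {str(k): v for k, v in truth.cell_groups.items()},
        "granules": [
            {
                "cell_label": g.cell_label,
                "centroid": list(g.centroid),
                "radius": g.radius,
                "params": asdict(g.params),
            }
            for g in truth.granules
        ],
    }
    (directory / "truth.json").write_text(json.dumps(payload, indent=1))


def read_scene_truth(directory: str | Path) -> SceneTruth:
    directory = Path(directory)
    payload = json.loads((directory / "truth.json").read_text())
    return SceneTruth(
        a1=tifffile.imread(directory / "a1.tif"),
        a2=tifffile.imread(directory / "a2.tif"),
        tau1=tifffile.imread(directory / "tau1.tif"),
        tau2=tifffile.imread(directory / "tau2.tif"),
        cell_masks=tifffile.imread(directory / "cell_masks.tif"),
        cytoplasm_masks=tifffile.imread(directory / "cytoplasm_masks.tif"),
        cell_groups={int(k): v for k, v in payload["cell_groups"].items()},
        granules=[
            GranuleTruth(
                g["cell_label"], tuple(g["centroid"]), g["radius"], BiexpTruth(**g["params"])
            )
            for g in payload["granules"]
        ],
        seed=payload["seed"],
    )
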