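"""Readouts derived from fitted FLIM parameter maps.

Covers the quantities used to compare undifferentiated cardiomyoblasts
with differentiated cardiomyocytes: cytoplasm-ROI histograms of fitted
parameters with mean and population SD, Cohen's d between groups, the
fluorescence-lifetime redox ratio FLIRR = NADH a2 / FAD a1 (per pixel,
summarised per cell), and counting of short-lifetime lipofuscin-like
granules in the tau_m map.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi
from skimage.filters import threshold_otsu

from .flim_fit import ParamMaps
from .flim_synth import ValidationError

__all__ = [
    "RoiStats",
    "GroupStats",
    "FlirrResult",
    "Granule",
    "GranuleSet",
    "roi_stats",
    "group_stats",
    "cohens_d",
    "compute_flirr",
    "detect_granules",
]


@dataclass
class RoiStats:
    """Pixel statistics of one parameter inside one ROI.

    ``sd`` is the population standard deviation (divisor N), matching the
    convention used for pixel histograms; the histogram covers all pixels.
    """

    roi_id: int
    parameter: str
    values: np.ndarray
    mean: float
    sd: float
    hist_counts: np.ndarray
    hist_edges: np.ndarray


@dataclass
class GroupStats:
    """Across-cell summary for one experimental group (sample SD, n-1)."""

    group: str
    per_cell_means: np.ndarray
    mean: float
    sd: float
    n: int

    @classmethod
    def from_values(cls, group: str, per_cell_means) -> "GroupStats":
        v = np.asarray(per_cell_means, dtype=float)
        return cls(group, v, float(v.mean()), float(v.std(ddof=1)) if len(v) > 1 else 0.0, len(v))

    @classmethod
    def from_summary(cls, group: str, mean: float, sd: float, n: int) -> "GroupStats":
        """Build from printed summary statistics (no raw values retained)."""
        return cls(group, np.array([]), float(mean), float(sd), int(n))


@dataclass
class FlirrResult:
    flirr_map: np.ndarray
    per_cell: dict[int, float]
    nadh_channel: str
    fad_channel: str
    mode: str


@dataclass
class Granule:
    cell_label: int
    centroid: tuple[float, float]
    area: int
    mean_tau_m: float


@dataclass
class GranuleSet:
    granules: list[Granule]
    per_cell_counts: dict[int, int]
    threshold: float
    min_area: int


def roi_stats(
    values_map: np.ndarray,
    mask: np.ndarray,
    parameter: str = "",
    roi_id: int = 0,
    bins: int = 32,
) -> RoiStats:
    """Mean, population SD and histogram of a parameter map inside a mask.

    Only finite (valid) pixels contribute; an ROI with no valid pixels is
    an error.
    """
    mask = np.asarray(mask) > 0
    vals = np.asarray(values_map)[mask]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValidationError(f"ROI {roi_id} contains no valid pixels")
    mean = float(vals.mean())
    sd = float(np.sqrt(np.mean((vals - mean) ** 2)))  # population formula, /N
    counts, edges = np.histogram(vals, bins=bins)
    return RoiStats(roi_id, parameter, vals, mean, sd, counts, edges)


def group_stats(group: str, per_cell_means) -> GroupStats:
    return GroupStats.from_values(group, per_cell_means)


def cohens_d(g1: GroupStats, g2: GroupStats, pooling: str = "weighted") -> float:
    """Standardised mean difference (mean1 - mean2) / pooled SD.

    ``pooling`` selects the pooled-SD convention: "weighted" uses the
    (n-1)-weighted pooled variance; "unweighted" averages the two
    variances.  Returns NaN when the pooled SD is zero.
    """
    if g1.n < 2 or g2.n < 2:
        raise ValidationError("Cohen's d needs n >= 2 in both groups")
    if pooling == "weighted":
        pooled_var = ((g1.n - 1) * g1.sd**2 + (g2.n - 1) * g2.sd**2) / (g1.n + g2.n - 2)
    elif pooling == "unweighted":
        pooled_var = (g1.sd**2 + g2.sd**2) / 2.0
    else:
        raise ValidationError(f"unknown pooling {pooling!r}")
    if pooled_var <= 0:
        return float("nan")
    return (g1.mean - g2.mean) / float(np.sqrt(pooled_var))


def compute_flirr(
    nadh: ParamMaps,
    fad: ParamMaps,
    cytoplasm_masks: np.ndarray,
    mode: str = "pixel_mean",
) -> FlirrResult:
    """Fluorescence-lifetime redox ratio map and per-cell means.

    FLIRR = bound-NAD(P)H fraction / bound-FAD fraction = NADH a2 / FAD a1,
    computed per pixel where both fits are valid.  The per-cell value is
    the mean of the per-pixel ratios over the cell's cytoplasm
    (``mode="pixel_mean"``) or the ratio of the two ROI means
    (``mode="ratio_of_means"``).
    """
    if nadh.a2.shape != fad.a1.shape:
        raise ValidationError("NADH and FAD maps must be co-registered (same shape)")
    if mode not in ("pixel_mean", "ratio_of_means"):
        raise ValidationError(f"unknown FLIRR mode {mode!r}")
    masks = np.asarray(cytoplasm_masks)
    if masks.shape != nadh.a2.shape:
        raise ValidationError("cytoplasm masks shape mismatch")

    with np.errstate(divide="ignore", invalid="ignore"):
        flirr = nadh.a2 / fad.a1
    flirr[~np.isfinite(flirr)] = np.nan
    flirr[np.asarray(fad.a1) == 0] = np.nan

    per_cell: dict[int, float] = {}
    for label in np.unique(masks[masks > 0]):
        sel = masks == label
        if mode == "pixel_mean":
            vals = flirr[sel]
            vals = vals[np.isfinite(vals)]
            per_cell[int(label)] = float(vals.mean()) if vals.size else float("nan")
        else:
            a2v = nadh.a2[sel]
            a1v = fad.a1[sel]
            ok = np.isfinite(a2v) & np.isfinite(a1v) & (a1v > 0)
            per_cell[int(label)] = (
                float(a2v[ok].mean() / a1v[ok].mean()) if ok.any() else float("nan")
            )
    return FlirrResult(flirr, per_cell, nadh.channel, fad.channel, mode)


def detect_granules(
    tau_m_map: np.ndarray,
    cell_masks: np.ndarray,
    threshold: float | None = None,
    min_area: int = 4,
) -> GranuleSet:
    """Count short-lifetime granules per cell in a tau_m map.

    Granules are connected components of in-cell pixels with
    ``tau_m < threshold`` and area >= ``min_area``; each is assigned to the
    cell whose mask contains its centroid.  When ``threshold`` is None an
    Otsu split of the pooled in-cell tau_m histogram is used (sensible only
    when the distribution is bimodal).
    """
    cell_masks = np.asarray(cell_masks)
    tau_m_map = np.asarray(tau_m_map, dtype=float)
    in_cell = (cell_masks > 0) & np.isfinite(tau_m_map)
    if not in_cell.any():
        raise ValidationError("no valid in-cell tau_m pixels")
    pooled = tau_m_map[in_cell]
    if threshold is None:
        threshold = float(threshold_otsu(pooled))
    if threshold > float(np.median(pooled)):
        warnings.warn(
            f"granule threshold {threshold:.3g} exceeds the ROI median tau_m "
            f"({np.median(pooled):.3g}); likely misconfigured"
        )

    short = in_cell & (tau_m_map < threshold)
    labels, n = ndi.label(short)
    granules: list[Granule] = []
    counts = {int(lbl): 0 for lbl in np.unique(cell_masks[cell_masks > 0])}
    if n:
        objects = ndi.find_objects(labels)
        for i, sl in enumerate(objects, start=1):
            comp = labels[sl] == i
            area = int(comp.sum())
            if area < min_area:
                continue
            rr, cc = np.nonzero(comp)
            cy = float(rr.mean() + sl[0].start)
            cx = float(cc.mean() + sl[1].start)
            cell = int(cell_masks[int(round(cy)), int(round(cx))])
            if cell == 0:
                continue
            granules.append(
                Granule(cell, (cy, cx), area, float(tau_m_map[sl][comp].mean()))
            )
            counts[cell] = counts.get(cell, 0) + 1
    return GranuleSet(granules, counts, float(threshold), int(min_area))
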