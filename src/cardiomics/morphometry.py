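"""Fluorescence-image morphometry.

Measurements used to characterise differentiating cardiomyocytes:
mitochondrial segmentation and per-object shape metrics (area, perimeter,
form factor, aspect ratio, skeleton branch count), the 30 %-coverage Ki67
nuclear positivity rule, gamma-H2AX focus counting by
Laplacian-of-Gaussian blob detection, per-cell mean fluorescence intensity
(MFI) of a ROS probe, and normalisation of focus counts by each group's
mean ROS level.

Form factor is implemented as the inverse of circularity,
FF = perimeter^2 / (4 pi area), so a circle scores 1 and elongated objects
score above 1.  Perimeters use the Crofton estimator, which is far closer
to the true contour length of rasterised shapes than a pixel-edge count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu, threshold_local
from skimage.measure import label as cc_label, regionprops
from skimage.morphology import remove_small_objects, skeletonize

from .flim_synth import ValidationError

__all__ = [
    "MitoMetrics",
    "NucleusCall",
    "FociPerRos",
    "segment_mitochondria",
    "mito_metrics",
    "ki67_fraction",
    "count_foci",
    "mfi",
    "foci_per_ros",
]


@dataclass
class MitoMetrics:
    """Per-object mitochondrial shape metrics and per-cell counts."""

    labels: np.ndarray  # object labels present
    area: np.ndarray  # px^2
    perimeter: np.ndarray  # px (Crofton)
    form_factor: np.ndarray
    aspect_ratio: np.ndarray
    branch_count: np.ndarray
    per_cell_counts: dict[int, int]


@dataclass
class NucleusCall:
    nucleus_id: int
    coverage: float
    positive: bool


@dataclass
class FociPerRos:
    group: str
    foci_counts: np.ndarray
    group_mean_ros: float
    normalized: np.ndarray


def segment_mitochondria(
    image: np.ndarray,
    threshold: str | float = "otsu",
    min_size: int = 4,
    block_size: int = 51,
) -> np.ndarray:
    """Threshold, size-filter and label a mitochondrial channel.

    ``threshold`` may be "otsu" (global), "adaptive" (local mean over
    ``block_size``) or a numeric value.  Objects below ``min_size`` pixels
    are discarded.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValidationError("expected a single-channel 2-D image")
    if image.max() == image.min():
        warnings.warn("image has no contrast: returning empty label map")
        return np.zeros(image.shape, dtype=np.int32)
    if threshold == "otsu":
        fg = image > threshold_otsu(image)
    elif threshold == "adaptive":
        fg = image > threshold_local(image, block_size=block_size)
    else:
        fg = image > float(threshold)
    fg = remove_small_objects(fg, max_size=min_size - 1)  # drop area < min_size
    if not fg.any():
        warnings.warn("no foreground after size filtering")
    return cc_label(fg, connectivity=2).astype(np.int32)


def _branch_count(mask: np.ndarray) -> int:
    """Skeleton branch count = junction clusters + 1.

    A straight or curved unbranched object counts 1; each distinct
    junction along the skeleton adds one branch.
    """
    skel = skeletonize(mask)
    if skel.sum() == 0:
        return 1
    neighbours = ndi.convolve(skel.astype(np.uint8), np.ones((3, 3), np.uint8), mode="constant")
    # neighbours counts the centre pixel too; degree >= 3 marks a junction
    junction = skel & (neighbours - 1 >= 3)
    _, n_clusters = ndi.label(junction, structure=np.ones((3, 3)))
    return int(n_clusters) + 1


def mito_metrics(label_map: np.ndarray, cell_masks: np.ndarray | None = None) -> MitoMetrics:
    """Shape metrics per labelled object and object counts per cell.

    FF = perimeter^2 / (4 pi area); AR = major / minor axis length from
    image moments.  Degenerate objects (minor axis ~ 0 or area < 2 px)
    carry NaN metrics.  Cell assignment uses the object centroid.
    """
    label_map = np.asarray(label_map)
    props = regionprops(label_map)
    n = len(props)
    labels = np.array([p.label for p in props], dtype=int)
    area = np.array([p.area for p in props], dtype=float)
    perim = np.array([p.perimeter_crofton for p in props], dtype=float)
    ff = np.full(n, np.nan)
    ar = np.full(n, np.nan)
    branches = np.zeros(n, dtype=float)
    for i, p in enumerate(props):
        if p.area < 2:
            branches[i] = np.nan
            continue
        if area[i] > 0 and perim[i] > 0:
            ff[i] = perim[i] ** 2 / (4 * np.pi * area[i])
        if p.axis_minor_length > 1e-6:
            ar[i] = p.axis_major_length / p.axis_minor_length
        branches[i] = _branch_count(label_map == p.label)

    per_cell: dict[int, int] = {}
    if cell_masks is not None:
        cell_masks = np.asarray(cell_masks)
        per_cell = {int(lbl): 0 for lbl in np.unique(cell_masks[cell_masks > 0])}
        for p in props:
            r, c = (int(round(x)) for x in p.centroid)
            cell = int(cell_masks[r, c])
            if cell == 0:
                # boundary-straddling object: assign to majority-overlap cell
                overlap = cell_masks[label_map == p.label]
                overlap = overlap[overlap > 0]
                if overlap.size == 0:
                    continue
                vals, cnts = np.unique(overlap, return_counts=True)
                cell = int(vals[np.argmax(cnts)])
            per_cell[cell] = per_cell.get(cell, 0) + 1
    return MitoMetrics(labels, area, perim, ff, ar, branches, per_cell)


def ki67_fraction(
    nuclei_labels: np.ndarray,
    ki67_channel: np.ndarray,
    threshold: str | float = "otsu",
    coverage_cutoff: float = 0.30,
) -> tuple[list[NucleusCall], float]:
    """Classify nuclei as Ki67-positive by fractional coverage.

    A nucleus is positive when Ki67-above-threshold pixels cover at least
    ``coverage_cutoff`` of its area (the 30 % rule by default).  Returns
    the per-nucleus calls and the positive fraction over all nuclei.
    """
    nuclei_labels = np.asarray(nuclei_labels)
    ki67_channel = np.asarray(ki67_channel, dtype=float)
    if nuclei_labels.shape != ki67_channel.shape:
        raise ValidationError("nuclei and Ki67 channels must be co-registered")
    ids = np.unique(nuclei_labels[nuclei_labels > 0])
    if ids.size == 0:
        raise ValidationError("no nuclei in the label image")
    if threshold == "otsu":
        if ki67_channel.max() == ki67_channel.min():
            positive_px = np.zeros(ki67_channel.shape, dtype=bool)
        else:
            positive_px = ki67_channel > threshold_otsu(ki67_channel)
    else:
        positive_px = ki67_channel > float(threshold)

    calls = []
    for lbl in ids:
        sel = nuclei_labels == lbl
        cov = float(positive_px[sel].sum() / sel.sum())
        calls.append(NucleusCall(int(lbl), cov, cov >= coverage_cutoff))
    frac = sum(c.positive for c in calls) / len(calls)
    return calls, float(frac)


def count_foci(
    focus_channel: np.ndarray,
    nuclei_labels: np.ndarray,
    log_sigma: float = 2.0,
    prominence: float = 0.2,
) -> dict[int, int]:
    """Count punctate foci per nucleus with a Laplacian-of-Gaussian detector.

    Local maxima of the LoG response above ``prominence`` times the global
    response maximum, at least ``2 * log_sigma`` apart, are counted as
    foci; spots closer than about 2 sigma merge into one detection.
    """
    focus_channel = np.asarray(focus_channel, dtype=float)
    nuclei_labels = np.asarray(nuclei_labels)
    if focus_channel.shape != nuclei_labels.shape:
        raise ValidationError("focus channel and nuclei labels must be co-registered")
    counts = {int(lbl): 0 for lbl in np.unique(nuclei_labels[nuclei_labels > 0])}
    if focus_channel.max() <= 0:
        return counts
    response = -ndi.gaussian_laplace(focus_channel, sigma=log_sigma)
    response = np.clip(response, 0, None)
    if response.max() <= 0:
        return counts
    peaks = peak_local_max(
        response,
        min_distance=max(int(round(2 * log_sigma)), 1),
        threshold_abs=prominence * response.max(),
        exclude_border=False,
    )
    for r, c in peaks:
        lbl = int(nuclei_labels[r, c])
        if lbl > 0:
            counts[lbl] += 1
    return counts


def mfi(image: np.ndarray, masks: np.ndarray) -> dict[int, float]:
    """Per-cell mean fluorescence intensity over labelled masks."""
    image = np.asarray(image, dtype=float)
    masks = np.asarray(masks)
    if image.shape != masks.shape:
        raise ValidationError("image and masks must have the same shape")
    ids = np.unique(masks[masks > 0])
    if ids.size == 0:
        raise ValidationError("empty mask: no cells to measure")
    return {int(lbl): float(image[masks == lbl].mean()) for lbl in ids}


def foci_per_ros(foci_counts, group_mean_ros: float, group: str = "") -> FociPerRos:
    """Normalise per-cell focus counts by the group's mean ROS intensity."""
    counts = np.asarray(list(foci_counts), dtype=float)
    if group_mean_ros <= 0:
        raise ValidationError("group mean ROS must be positive")
    return FociPerRos(group, counts, float(group_mean_ros), counts / group_mean_ros)
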