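"""Nuclear segmentation from transmission images and per-nucleus L_d statistics.

Nuclei appear as dark compact regions in bright-field transmission images of
isolated cells.  The pipeline is: polarity normalization -> maximum-entropy
(Kapur) histogram thresholding -> morphological cleanup (hole fill, 1-px
opening) -> watershed splitting of touching nuclei seeded from distance-
transform maxima -> area gating in um^2.  Per-nucleus statistics are then
read off a co-registered disorder-strength map; a "cellular" mean over the
nucleus plus a perinuclear annulus is available for compartment comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.measure import regionprops
from skimage.morphology import disk
from skimage.segmentation import watershed

from .spectral_core import LdMap

__all__ = [
    "LabelMask",
    "NucleusRegion",
    "SegmentationParams",
    "max_entropy_threshold",
    "watershed_split",
    "segment_nuclei",
    "region_ld_stats",
]


@dataclass
class LabelMask:
    """Integer nucleus labels: 0 = background, 1..K = nuclei."""

    labels: np.ndarray
    pixel_size_um: float | None = None

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.ndim != 2:
            raise ValueError("label mask must be 2-D")
        if not np.issubdtype(lab.dtype, np.integer):
            if not np.all(lab == np.round(lab)):
                raise ValueError("labels must be integers")
            lab = lab.astype(np.int64)
        if lab.size and lab.min() < 0:
            raise ValueError("labels must be non-negative")
        self.labels = lab.astype(np.int64, copy=False)

    @property
    def n_labels(self) -> int:
        return int(self.labels.max()) if self.labels.size else 0


@dataclass(frozen=True)
class NucleusRegion:
    """Geometry and L_d statistics of one segmented nucleus."""

    label: int
    area_px: int
    area_um2: float
    centroid: tuple[float, float]
    mean_ld: float
    pixel_count_used: int
    cellular_mean_ld: float | None = None


@dataclass(frozen=True)
class SegmentationParams:
    """Tunables of the nuclear segmentation pipeline.

    Area gates are generous bounds for buccal/columnar nuclei; ``dark_nuclei``
    is the polarity of transmission images (nuclei absorb/scatter more than
    the surround).
    """

    histogram_bins: int = 256
    min_area_um2: float = 20.0
    max_area_um2: float = 500.0
    polarity: str = "dark_nuclei"
    watershed_seed_min_distance_px: int = 5

    def __post_init__(self) -> None:
        if self.histogram_bins < 8:
            raise ValueError("histogram_bins must be >= 8")
        if not (0 < self.min_area_um2 < self.max_area_um2):
            raise ValueError("require 0 < min_area_um2 < max_area_um2")
        if self.polarity not in ("dark_nuclei", "bright_nuclei"):
            raise ValueError(f"unknown polarity {self.polarity!r}")
        if self.watershed_seed_min_distance_px < 1:
            raise ValueError("watershed_seed_min_distance_px must be >= 1")


def max_entropy_threshold(image: np.ndarray, bins: int = 256) -> float:
    """Kapur maximum-entropy threshold of a grey-level image.

    The image histogram (``bins`` equal-width bins over [min, max]) is split
    at every interior bin edge; the returned threshold is the edge maximizing
    the sum of Shannon entropies of the normalized background and foreground
    histograms.  Ties break to the lowest qualifying edge.  Foreground is
    ``image >= threshold``.
    """
    img = np.asarray(image, dtype=float)
    if not np.all(np.isfinite(img)):
        raise ValueError("image must be finite")
    lo, hi = float(img.min()), float(img.max())
    if lo == hi:
        raise ValueError("constant image: no threshold exists")
    hist, edges = np.histogram(img, bins=bins, range=(lo, hi))
    p = hist / hist.sum()
    # cumulative mass and cumulative p*ln(p) (0*ln 0 := 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    omega = np.cumsum(p)
    cum_plogp = np.cumsum(plogp)
    total_plogp = cum_plogp[-1]

    best_idx, best_crit = None, -np.inf
    for t in range(1, bins):  # background bins [0, t), foreground [t, bins)
        w_b = omega[t - 1]
        w_f = 1.0 - w_b
        if w_b <= 0.0 or w_f <= 0.0:
            continue
        h_b = np.log(w_b) - cum_plogp[t - 1] / w_b
        h_f = np.log(w_f) - (total_plogp - cum_plogp[t - 1]) / w_f
        crit = h_b + h_f
        if crit > best_crit:
            best_crit, best_idx = crit, t
    if best_idx is None:
        raise ValueError("degenerate histogram: no admissible threshold")
    return float(edges[best_idx])


def watershed_split(binary: np.ndarray, min_seed_distance_px: int = 5) -> LabelMask:
    """Split a binary foreground mask into labels along distance-transform ridges.

    Seeds are local maxima of the (lightly smoothed) Euclidean distance
    transform separated by at least ``min_seed_distance_px``; every foreground
    pixel receives exactly one label.  Disjoint components that need no
    splitting come out as plain connected components.
    """
    mask = np.asarray(binary, dtype=bool)
    if not mask.any():
        raise ValueError("binary mask is empty")
    dist = ndi.distance_transform_edt(mask)
    comp, _ = ndi.label(mask)
    smooth = ndi.gaussian_filter(dist, sigma=1.0)
    coords = peak_local_max(
        smooth,
        min_distance=min_seed_distance_px,
        labels=comp,
        exclude_border=False,
    )
    markers = np.zeros(mask.shape, dtype=np.int32)
    for i, (r, c) in enumerate(coords, start=1):
        markers[r, c] = i
    labels = watershed(-dist, markers, mask=mask)
    return LabelMask(labels)


def _relabel_raster(labels: np.ndarray) -> np.ndarray:
    """Renumber labels 1..K in raster order of their centroids."""
    props = regionprops(labels)
    order = sorted(props, key=lambda p: (p.centroid[0], p.centroid[1]))
    out = np.zeros_like(labels)
    for new, prop in enumerate(order, start=1):
        out[labels == prop.label] = new
    return out


def segment_nuclei(
    transmission: np.ndarray,
    params: SegmentationParams = SegmentationParams(),
    pixel_size_um: float = 1.0,
) -> LabelMask:
    """Detect nuclei in a transmission image.

    Pipeline: polarity normalization -> Kapur threshold -> hole fill and 1-px
    opening -> distance-transform watershed -> [min_area, max_area] um^2 gate
    -> labels renumbered 1..K in raster order of centroids.  Zero surviving
    regions yields an empty mask with a warning, not an error.
    """
    img = np.asarray(transmission, dtype=float)
    if img.ndim != 2:
        raise ValueError("transmission image must be 2-D")
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be positive")
    feature = img.max() - img if params.polarity == "dark_nuclei" else img

    def _empty(reason: str) -> LabelMask:
        warnings.warn(f"segment_nuclei: no nuclei found ({reason})", stacklevel=2)
        return LabelMask(np.zeros(img.shape, dtype=np.int64), pixel_size_um)

    try:
        thr = max_entropy_threshold(feature, params.histogram_bins)
    except ValueError:
        return _empty("constant image")
    binary = feature >= thr
    binary = ndi.binary_fill_holes(binary)
    binary = ndi.binary_opening(binary, structure=disk(1))
    if not binary.any():
        return _empty("empty after cleanup")
    split = watershed_split(binary, params.watershed_seed_min_distance_px)
    # area gate in physical units
    px_area = pixel_size_um**2
    labels = split.labels.copy()
    for prop in regionprops(labels):
        area_um2 = prop.area * px_area
        if not (params.min_area_um2 <= area_um2 <= params.max_area_um2):
            labels[labels == prop.label] = 0
    if not labels.any():
        return _empty("all regions outside area gate")
    return LabelMask(_relabel_raster(labels), pixel_size_um)


def region_ld_stats(
    ld: LdMap,
    mask: LabelMask,
    annulus_width_px: int | None = None,
) -> list[NucleusRegion]:
    """Per-nucleus mean L_d (and optional cellular mean) for every label.

    When ``annulus_width_px`` is given, the cellular mean is taken over the
    nucleus united with a perinuclear annulus of that width, excluding pixels
    belonging to any other nucleus.
    """
    if ld.values.shape != mask.labels.shape:
        raise ValueError(
            f"L_d map shape {ld.values.shape} != label mask shape {mask.labels.shape}"
        )
    px_area = (mask.pixel_size_um**2) if mask.pixel_size_um else float("nan")
    any_nucleus = mask.labels > 0
    out: list[NucleusRegion] = []
    for prop in regionprops(mask.labels, intensity_image=ld.values):
        cellular = None
        if annulus_width_px is not None:
            region = mask.labels == prop.label
            dilated = ndi.binary_dilation(region, disk(annulus_width_px))
            cell = region | (dilated & ~any_nucleus)
            cellular = float(ld.values[cell].mean())
        out.append(
            NucleusRegion(
                label=int(prop.label),
                area_px=int(prop.area),
                area_um2=float(prop.area * px_area),
                centroid=(float(prop.centroid[0]), float(prop.centroid[1])),
                mean_ld=float(prop.intensity_mean),
                pixel_count_used=int(prop.area),
                cellular_mean_ld=cellular,
            )
        )
    return out
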