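"""Nuclear segmentation and derived measurement regions.

Implements the measurement geometry used for KTR quantification: a
cytoplasmic ring from 2 um to at most 10 um outside the nuclear mask (pixels
within 10 um of *another* nucleus excluded, optionally restricted to pixels
distinguishable from background), and a whole-cell region reaching up to
50 um from the nucleus while never overlapping a neighboring cell (nearest-
nucleus partition).  Distances are Euclidean on the pixel grid, measured to
the nearest nucleus pixel.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.measure import regionprops
from skimage.segmentation import watershed

__all__ = [
    "PixelCalibration",
    "SegmentationConfig",
    "RegionSet",
    "correct_illumination",
    "segment_nuclei",
    "cytoplasmic_ring",
    "whole_cell_regions",
    "build_regions",
    "background_threshold",
]


class BiasError(ValueError):
    """Raised for invalid illumination-bias surfaces."""


@dataclass(frozen=True)
class PixelCalibration:
    um_per_px: float = 0.65

    def __post_init__(self) -> None:
        if self.um_per_px <= 0:
            raise ValueError("um_per_px must be positive")

    def to_px(self, um: float) -> float:
        return um / self.um_per_px


@dataclass(frozen=True)
class SegmentationConfig:
    """Geometry constants (um) and thresholds for region construction."""

    ring_inner_um: float = 2.0
    ring_outer_um: float = 10.0
    neighbor_exclusion_um: float = 10.0
    wholecell_reach_um: float = 50.0
    min_nucleus_area_um2: float = 30.0
    background_floor: float | None = None
    fish_kernel_radius_um: float = 4.0
    fixed_threshold: float | None = None

    def __post_init__(self) -> None:
        if not self.ring_inner_um < self.ring_outer_um:
            raise ValueError("ring_inner_um must be < ring_outer_um")

    def replace(self, **kwargs) -> "SegmentationConfig":
        return replace(self, **kwargs)


@dataclass
class RegionSet:
    """Per-cell measurement regions stored as label images.

    ``nuclei``, ``rings`` and ``wholecell`` are integer label images where
    label ``k > 0`` marks cell ``k``; rings are pairwise disjoint and disjoint
    from every nucleus, whole-cell regions are pairwise disjoint and contain
    their nucleus.  ``centroids`` maps label -> (y, x) nucleus centroid in
    pixels.
    """

    nuclei: np.ndarray
    rings: np.ndarray | None
    wholecell: np.ndarray | None
    centroids: dict[int, tuple[float, float]]
    calibration: PixelCalibration

    @property
    def labels(self) -> np.ndarray:
        return np.unique(self.nuclei[self.nuclei > 0])


def correct_illumination(image: np.ndarray, bias: np.ndarray | None = None) -> np.ndarray:
    """Divide out a multiplicative illumination surface, preserving the mean.

    With ``bias`` given, it is normalized to unit mean and divided out.
    Otherwise a quadratic surface is fitted by least squares to per-block
    background quantiles (10th percentile on a coarse grid) and divided out.
    """
    img = np.asarray(image, float)
    if not np.isfinite(img).all():
        raise ValueError("image must be finite-valued")
    if bias is not None:
        bias = np.asarray(bias, float)
        if bias.shape != img.shape:
            raise BiasError("bias shape must match image")
        if bias.min() <= 0:
            raise BiasError("bias must be strictly positive")
        surf = bias / bias.mean()
    else:
        surf = _fit_background_surface(img)
    out = img / surf
    return out * (img.mean() / out.mean())


def _fit_background_surface(img: np.ndarray, grid: int = 8, q: float = 10.0) -> np.ndarray:
    h, w = img.shape
    ys = np.linspace(0, h, grid + 1).astype(int)
    xs = np.linspace(0, w, grid + 1).astype(int)
    cy, cx, val = [], [], []
    for i in range(grid):
        for j in range(grid):
            block = img[ys[i] : ys[i + 1], xs[j] : xs[j + 1]]
            if block.size == 0:
                continue
            cy.append((ys[i] + ys[i + 1]) / 2.0)
            cx.append((xs[j] + xs[j + 1]) / 2.0)
            val.append(np.percentile(block, q))
    cy = 2.0 * np.asarray(cy) / h - 1.0
    cx = 2.0 * np.asarray(cx) / w - 1.0
    A = np.column_stack([np.ones_like(cx), cx, cy, cx * cx, cx * cy, cy * cy])
    coef, *_ = np.linalg.lstsq(A, np.asarray(val), rcond=None)
    y = np.linspace(-1, 1, h)[:, None]
    x = np.linspace(-1, 1, w)[None, :]
    surf = (
        coef[0] + coef[1] * x + coef[2] * y
        + coef[3] * x * x + coef[4] * x * y + coef[5] * y * y
    )
    surf = np.clip(surf, surf[surf > 0].min() if (surf > 0).any() else 1.0, None)
    return surf / surf.mean()


def segment_nuclei(
    nuclear_channel: np.ndarray,
    cfg: SegmentationConfig | None = None,
    cal: PixelCalibration | None = None,
) -> np.ndarray:
    """Threshold-based nuclear segmentation with watershed splitting.

    Global histogram threshold (inter-class variance maximization, or
    ``cfg.fixed_threshold``), hole filling, marker-based watershed to split
    touching nuclei, and removal of components below ``min_nucleus_area_um2``.
    Labels are renumbered in raster order of their centroids.  A blank image
    yields an all-zero mask.
    """
    cfg = cfg or SegmentationConfig()
    cal = cal or PixelCalibration()
    img = np.asarray(nuclear_channel, float)
    if cfg.fixed_threshold is not None:
        thr = cfg.fixed_threshold
    else:
        if np.ptp(img) == 0:
            return np.zeros(img.shape, np.int32)
        thr = threshold_otsu(img, nbins=256)
    fg = ndi.binary_fill_holes(img > thr)
    if not fg.any():
        return np.zeros(img.shape, np.int32)

    min_area_px = cfg.min_nucleus_area_um2 / cal.um_per_px**2
    # Watershed on the distance transform splits touching nuclei; markers are
    # maxima separated by at least a nuclear radius.
    dist = ndi.distance_transform_edt(fg)
    min_sep = max(int(round(np.sqrt(min_area_px / np.pi))), 3)
    maxfilt = ndi.maximum_filter(dist, size=2 * min_sep + 1)
    peaks = fg & (dist == maxfilt) & (dist > 1.0)
    markers, _ = ndi.label(peaks)
    # Collapse plateau markers: merge peaks closer than min_sep.
    if markers.max() > 1:
        markers, _ = ndi.label(ndi.binary_dilation(peaks, iterations=min_sep // 2 or 1))
        markers[~fg] = 0
    labels = watershed(-dist, markers, mask=fg) if markers.max() > 0 else ndi.label(fg)[0]

    # Drop small components, then renumber by centroid raster order.
    out = np.zeros(img.shape, np.int32)
    props = [p for p in regionprops(labels) if p.area >= min_area_px]
    props.sort(key=lambda p: (p.centroid[0], p.centroid[1]))
    for new, p in enumerate(props, start=1):
        out[labels == p.label] = new
    return out


def _per_label_distances(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Distance (px) from every pixel to each nucleus, stacked per label."""
    labels = np.unique(mask[mask > 0])
    dists = np.empty((len(labels),) + mask.shape, float)
    for i, lab in enumerate(labels):
        dists[i] = ndi.distance_transform_edt(mask != lab)
    return labels, dists


def background_threshold(image: np.ndarray, bg_pixels: np.ndarray) -> float:
    """Background floor: median + 2 * MAD of the supplied background pixels."""
    med = np.median(bg_pixels)
    mad = np.median(np.abs(bg_pixels - med))
    return float(med + 2.0 * mad)


def cytoplasmic_ring(
    mask: np.ndarray,
    cfg: SegmentationConfig | None = None,
    cal: PixelCalibration | None = None,
    intensity: np.ndarray | None = None,
) -> np.ndarray:
    """Cytoplasmic ring label image.

    ``ring(k)`` = pixels at Euclidean distance in [ring_inner, ring_outer] um
    from nucleus k, farther than ``neighbor_exclusion_um`` from every other
    nucleus, outside all nuclei; when ``intensity`` is supplied, pixels
    indistinguishable from background (below ``cfg.background_floor``, or
    background median + 2 MAD if unset) are excluded as well.
    """
    cfg = cfg or SegmentationConfig()
    cal = cal or PixelCalibration()
    mask = np.asarray(mask)
    out = np.zeros(mask.shape, np.int32)
    if not (mask > 0).any():
        return out
    labels, dists = _per_label_distances(mask)
    inner = cal.to_px(cfg.ring_inner_um)
    outer = cal.to_px(cfg.ring_outer_um)
    excl = cal.to_px(cfg.neighbor_exclusion_um)

    keep = np.ones(mask.shape, bool)
    if intensity is not None:
        intensity = np.asarray(intensity, float)
        floor = cfg.background_floor
        if floor is None:
            far = dists.min(axis=0) > outer
            floor = background_threshold(intensity, intensity[far]) if far.any() else -np.inf
        keep = intensity >= floor

    for i, lab in enumerate(labels):
        ring = (dists[i] >= inner) & (dists[i] <= outer) & (mask == 0) & keep
        for j in range(len(labels)):
            if j != i:
                ring &= dists[j] > excl
        out[ring] = lab
    return out


def whole_cell_regions(
    mask: np.ndarray,
    cfg: SegmentationConfig | None = None,
    cal: PixelCalibration | None = None,
) -> np.ndarray:
    """Whole-cell label image: nearest-nucleus partition within 50 um.

    ``wholecell(k)`` = pixels within ``wholecell_reach_um`` of nucleus k for
    which k is the nearest nucleus (ties broken toward the lower label),
    together with nucleus k itself.
    """
    cfg = cfg or SegmentationConfig()
    cal = cal or PixelCalibration()
    mask = np.asarray(mask)
    out = np.zeros(mask.shape, np.int32)
    if not (mask > 0).any():
        return out
    labels, dists = _per_label_distances(mask)
    reach = cal.to_px(cfg.wholecell_reach_um)
    nearest = np.argmin(dists, axis=0)  # argmin takes the first (lowest label) on ties
    dmin = np.take_along_axis(dists, nearest[None], axis=0)[0]
    within = dmin <= reach
    out[within] = labels[nearest[within]]
    out[mask > 0] = mask[mask > 0]
    return out


def build_regions(
    nuclear_channel: np.ndarray,
    cfg: SegmentationConfig | None = None,
    cal: PixelCalibration | None = None,
    intensity: np.ndarray | None = None,
    nuclei: np.ndarray | None = None,
) -> RegionSet:
    """Segment (or accept) nuclei and build ring + whole-cell regions."""
    cfg = cfg or SegmentationConfig()
    cal = cal or PixelCalibration()
    if nuclei is None:
        nuclei = segment_nuclei(nuclear_channel, cfg, cal)
    rings = cytoplasmic_ring(nuclei, cfg, cal, intensity=intensity)
    whole = whole_cell_regions(nuclei, cfg, cal)
    centroids = {
        int(p.label): (float(p.centroid[0]), float(p.centroid[1]))
        for p in regionprops(nuclei)
    }
    return RegionSet(
        nuclei=nuclei, rings=rings, wholecell=whole, centroids=centroids, calibration=cal
    )
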