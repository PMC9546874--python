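"""Per-cell reporter quantification from images and measurement regions.

KTR activity is the background-subtracted cytoplasmic-ring mean over the
nuclear mean.  The raw CDK4/6 reporter additionally reads a fraction of CDK2
activity; that cross-talk coefficient is estimated by ordinary least squares
on inhibitor-treated calibration pairs and subtracted:

    CDK4/6 activity = CDK4/6 reporter activity - rho * CDK2 reporter activity

FISH puncta are isolated by a white top-hat with a circular kernel and an
absolute intensity threshold; per cell both the puncta-pixel count inside the
whole-cell region and the connected-component count are reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy import stats
from skimage.morphology import disk, white_tophat

from .segmentation import PixelCalibration, RegionSet, SegmentationConfig

__all__ = [
    "Measurement",
    "CrosstalkModel",
    "measure_regions",
    "ktr_activity",
    "estimate_crosstalk",
    "correct_cdk46",
    "degron_level",
    "fish_puncta_per_cell",
]


class ActivityError(ValueError):
    """Raised when a KTR ratio is undefined (non-positive nuclear mean)."""


class SingularFitError(ValueError):
    """Raised when the calibration regression design is degenerate."""


@dataclass(frozen=True)
class CrosstalkModel:
    """Linear cross-talk of the CDK2 reporter into the CDK4/6 reporter.

    ``rho`` is the OLS slope of the CDK4/6 reporter signal on the CDK2
    reporter signal under full CDK4/6 inhibition.  The intercept is reported
    for diagnostics but never subtracted: the correction removes only the
    proportional term.
    """

    rho: float
    intercept: float = 0.0
    n_points: int = 0
    residual_sd: float = 0.0

    def correct(self, r46, r2):
        return correct_cdk46(r46, r2, self)


# Measurement rows are plain DataFrame records; this alias documents the schema.
Measurement = pd.DataFrame


def _region_mean(img: np.ndarray, label_img: np.ndarray, label: int) -> float:
    sel = label_img == label
    if not sel.any():
        return np.nan
    return float(img[sel].mean())


def measure_regions(
    images: dict[str, np.ndarray],
    regions: RegionSet,
    channels: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Background-subtracted nuclear and ring means per cell and channel.

    Background is the median over pixels belonging to no whole-cell region;
    means are floored at zero after subtraction.  Cells whose ring was fully
    excluded get ``ring_mean = NaN`` and ``flag_missing_ring = True``.
    """
    channels = channels or tuple(images)
    rows = []
    bg_sel = regions.wholecell == 0 if regions.wholecell is not None else regions.nuclei == 0
    for ch in channels:
        img = np.asarray(images[ch], float)
        bg = float(np.median(img[bg_sel])) if bg_sel.any() else 0.0
        for lab in regions.labels:
            nuc = _region_mean(img, regions.nuclei, lab)
            ring = (
                _region_mean(img, regions.rings, lab)
                if regions.rings is not None
                else np.nan
            )
            rows.append(
                {
                    "cell_id": int(lab),
                    "channel": ch,
                    "nuc_mean": max(nuc - bg, 0.0) if np.isfinite(nuc) else np.nan,
                    "ring_mean": max(ring - bg, 0.0) if np.isfinite(ring) else np.nan,
                    "bg": bg,
                    "flag_missing_ring": not np.isfinite(ring),
                }
            )
    df = pd.DataFrame(rows)
    df["activity"] = np.where(
        (df["nuc_mean"] > 0) & np.isfinite(df["ring_mean"]),
        df["ring_mean"] / df["nuc_mean"],
        np.nan,
    )
    return df


def ktr_activity(nuc_mean: float, ring_mean: float) -> float:
    """Cytoplasm/nucleus translocation ratio (the KTR activity readout)."""
    if not nuc_mean > 0:
        raise ActivityError(f"nuclear mean must be positive, got {nuc_mean}")
    return float(ring_mean) / float(nuc_mean)


def estimate_crosstalk(pairs: pd.DataFrame) -> CrosstalkModel:
    """OLS regression of the CDK4/6 reporter on the CDK2 reporter.

    ``pairs`` must contain columns ``r46_obs`` and ``r2_obs`` measured under
    full CDK4/6 inhibition, so the slope is the cross-talk coefficient.
    """
    x = np.asarray(pairs["r2_obs"], float)
    y = np.asarray(pairs["r46_obs"], float)
    if len(x) < 2:
        raise SingularFitError("need at least 2 calibration pairs")
    if np.ptp(x) == 0:
        raise SingularFitError("all CDK2 reporter values identical; slope undefined")
    fit = stats.linregress(x, y)
    resid = y - (fit.intercept + fit.slope * x)
    sd = float(np.sqrt(resid @ resid / max(len(x) - 2, 1)))
    return CrosstalkModel(
        rho=float(fit.slope),
        intercept=float(fit.intercept),
        n_points=len(x),
        residual_sd=sd,
    )


def correct_cdk46(r46, r2, model: CrosstalkModel | float):
    """Remove the CDK2 cross-talk component from the raw CDK4/6 activity.

    Accepts scalars or arrays; no clipping is applied, so corrected values
    may be negative.
    """
    rho = model.rho if isinstance(model, CrosstalkModel) else float(model)
    return np.asarray(r46, float) - rho * np.asarray(r2, float)


def degron_level(images: dict[str, np.ndarray], regions: RegionSet,
                 channel: str = "degron") -> pd.DataFrame:
    """Background-subtracted mean nuclear degron intensity per cell."""
    img = np.asarray(images[channel], float)
    bg_sel = regions.wholecell == 0 if regions.wholecell is not None else regions.nuclei == 0
    bg = float(np.median(img[bg_sel])) if bg_sel.any() else 0.0
    rows = [
        {"cell_id": int(lab), "degron": max(_region_mean(img, regions.nuclei, lab) - bg, 0.0)}
        for lab in regions.labels
    ]
    return pd.DataFrame(rows)


def fish_puncta_per_cell(
    fish_image: np.ndarray,
    regions: RegionSet,
    cfg: SegmentationConfig | None = None,
    threshold: float | None = None,
) -> pd.DataFrame:
    """Top-hat spot segmentation and per-cell puncta quantification.

    White top-hat with a circular kernel of ``cfg.fish_kernel_radius_um``
    (removes any constant or slowly varying background), thresholded at an
    absolute intensity; default threshold is background median + 5 MAD of the
    top-hat image.  Per cell, reports the number of puncta-mask pixels inside
    the whole-cell region (the RNA puncta parameter) and the number of
    connected components.
    """
    cfg = cfg or SegmentationConfig()
    cal = regions.calibration
    img = np.asarray(fish_image, float)
    radius = int(round(cal.to_px(cfg.fish_kernel_radius_um)))
    if 2 * radius + 1 > min(img.shape):
        raise ValueError("top-hat kernel larger than image")
    top = white_tophat(img, footprint=disk(radius))
    if threshold is None:
        med = float(np.median(top))
        mad = float(np.median(np.abs(top - med)))
        threshold = med + 5.0 * mad
    puncta = top > threshold
    comp, _ = ndi.label(puncta)
    rows = []
    whole = regions.wholecell if regions.wholecell is not None else regions.nuclei
    for lab in regions.labels:
        sel = whole == lab
        n_px = int(np.count_nonzero(puncta & sel))
        n_comp = len(np.unique(comp[puncta & sel]))
        rows.append({"cell_id": int(lab), "puncta_px": n_px, "puncta_count": n_comp})
    return pd.DataFrame(rows)
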