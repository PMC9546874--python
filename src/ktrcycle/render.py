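"""Virtual microscopy: render simulated cohorts into multichannel image stacks.

Cells are drawn as a nuclear disk surrounded by a cytoplasmic annulus.  For a
kinase translocation reporter the per-cell reporter amount is fixed and split
between nucleus and cytoplasm so that the rendered cytoplasm-mean /
nucleus-mean ratio equals the reporter activity; the degron channel scales
nuclear intensity with the degron level.  A multiplicative quadratic
illumination surface and Poisson + Gaussian camera noise can be applied, and
ground-truth label masks are returned for every frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import ImagingParams
from .simulate import TraceSet

__all__ = ["Movie", "render_movie", "render_fish_field", "render_spots", "bias_surface"]


class PlacementError(RuntimeError):
    """Raised when the requested cells cannot be placed in the field."""


@dataclass
class Movie:
    """Rendered stack: per-channel (T, H, W) arrays plus ground truth.

    ``channels`` holds float32 stacks keyed by ``nuclear, cdk4, cdk2,
    degron``; ``nuclei_masks`` / ``cyto_masks`` are uint16 label stacks where
    label ``cell_id + 1`` marks cell ``cell_id``; ``positions`` lists the true
    nucleus center per (cell_id, frame) in pixel coordinates (row ``y``,
    column ``x``).
    """

    channels: dict[str, np.ndarray]
    nuclei_masks: np.ndarray
    cyto_masks: np.ndarray
    positions: pd.DataFrame
    imaging: ImagingParams

    @property
    def n_frames(self) -> int:
        return self.nuclei_masks.shape[0]


def bias_surface(shape: tuple[int, int], coeffs) -> np.ndarray:
    """Quadratic multiplicative illumination surface, normalized to unit mean.

    ``coeffs`` = (c0, cx, cy, cxx, cxy, cyy) over coordinates normalized to
    [-1, 1] in each axis.
    """
    h, w = shape
    y = np.linspace(-1.0, 1.0, h)[:, None]
    x = np.linspace(-1.0, 1.0, w)[None, :]
    c0, cx, cy, cxx, cxy, cyy = coeffs
    s = c0 + cx * x + cy * y + cxx * x * x + cxy * x * y + cyy * y * y
    if s.min() <= 0:
        raise ValueError("bias surface must be strictly positive")
    return s / s.mean()


def _place_cells(n: int, imaging: ImagingParams, rng: np.random.Generator) -> np.ndarray:
    """Jittered-grid initial nucleus centers; cytoplasm disks stay disjoint."""
    h, w = imaging.field_shape
    r_cyto = imaging.cyto_radius_um / imaging.pixel_size_um
    spacing = 2.0 * r_cyto + 4.0
    margin = r_cyto + 2.0
    nx = int((w - 2 * margin) // spacing) + 1
    ny = int((h - 2 * margin) // spacing) + 1
    if nx < 1 or ny < 1 or n > nx * ny:
        raise PlacementError(
            f"cannot place {n} cells in a {h}x{w} field at "
            f"{imaging.cyto_radius_um} um cytoplasm radius"
        )
    idx = rng.permutation(nx * ny)[:n]
    gy, gx = np.divmod(idx, nx)
    jitter = rng.uniform(-1.5, 1.5, (n, 2))
    pos = np.stack(
        [margin + gy * spacing + jitter[:, 0], margin + gx * spacing + jitter[:, 1]],
        axis=1,
    )
    return pos


def _camera(img: np.ndarray, imaging: ImagingParams, rng: np.random.Generator) -> np.ndarray:
    shot = rng.poisson(np.clip(img * imaging.gain, 0, None)) / imaging.gain
    return (shot + rng.normal(0.0, imaging.read_noise, img.shape)).astype(np.float32)


def render_movie(traces: TraceSet, imaging: ImagingParams, noise: bool = True) -> Movie:
    """Render a simulated cohort into a 4-channel time-lapse stack.

    The two KTR channels render the *observed* reporter signal, i.e. the
    CDK4/6 channel includes the cross-talk component, so the downstream
    segmentation -> ring measurement -> ratio -> cross-talk-correction
    pipeline can be validated end to end against ``a2_true`` / ``a46_true``.
    """
    imaging_rng = np.random.default_rng(imaging.seed)
    h, w = imaging.field_shape
    params = traces.params
    rho = params.crosstalk_rho if params is not None else 0.0

    cell_ids, t, a46 = traces.matrix("a46_true")
    _, _, a2 = traces.matrix("a2_true")
    _, _, deg = traces.matrix("degron_obs")
    n_cells, n_frames = a46.shape
    ratio46 = a46 + rho * a2
    ratio2 = a2
    deg = np.clip(deg, 0.0, None)

    pos0 = _place_cells(n_cells, imaging, imaging_rng)
    step_px = imaging.jitter_um / imaging.pixel_size_um
    steps = imaging_rng.normal(0.0, step_px, (n_frames - 1, n_cells, 2)) if n_frames > 1 else np.zeros((0, n_cells, 2))
    pos = np.empty((n_frames, n_cells, 2))
    pos[0] = pos0
    r_cyto = imaging.cyto_radius_um / imaging.pixel_size_um
    for k in range(1, n_frames):
        pos[k] = pos[k - 1] + steps[k - 1]
        np.clip(pos[k, :, 0], r_cyto + 1, h - r_cyto - 2, out=pos[k, :, 0])
        np.clip(pos[k, :, 1], r_cyto + 1, w - r_cyto - 2, out=pos[k, :, 1])

    r_nuc = imaging.nucleus_radius_um / imaging.pixel_size_um
    bias = (
        bias_surface((h, w), imaging.bias_coeffs)
        if imaging.bias_coeffs is not None
        else None
    )

    yy, xx = np.mgrid[0:h, 0:w]
    channels = {
        name: np.empty((n_frames, h, w), np.float32)
        for name in ("nuclear", "cdk4", "cdk2", "degron")
    }
    nuc_masks = np.zeros((n_frames, h, w), np.uint16)
    cyt_masks = np.zeros((n_frames, h, w), np.uint16)

    for k in range(n_frames):
        imgs = {name: np.full((h, w), imaging.background, float) for name in channels}
        for i in range(n_cells):
            cy, cx = pos[k, i]
            y0, y1 = int(max(0, cy - r_cyto - 2)), int(min(h, cy + r_cyto + 3))
            x0, x1 = int(max(0, cx - r_cyto - 2)), int(min(w, cx + r_cyto + 3))
            d2 = (yy[y0:y1, x0:x1] - cy) ** 2 + (xx[y0:y1, x0:x1] - cx) ** 2
            nuc = d2 <= r_nuc**2
            cyt = (d2 <= r_cyto**2) & ~nuc
            a_n, a_c = max(int(nuc.sum()), 1), max(int(cyt.sum()), 1)
            nuc_masks[k, y0:y1, x0:x1][nuc] = i + 1
            cyt_masks[k, y0:y1, x0:x1][cyt] = i + 1
            imgs["nuclear"][y0:y1, x0:x1][nuc] += imaging.nuclear_amp
            for name, ratio in (("cdk4", ratio46[i, k]), ("cdk2", ratio2[i, k])):
                r = max(float(ratio), 0.0)
                nuc_mean = imaging.reporter_total / (a_n + r * a_c)
                imgs[name][y0:y1, x0:x1][nuc] += nuc_mean
                imgs[name][y0:y1, x0:x1][cyt] += r * nuc_mean
            imgs["degron"][y0:y1, x0:x1][nuc] += imaging.degron_amp * deg[i, k]
        for name in channels:
            img = imgs[name]
            if bias is not None:
                img = img * bias
            channels[name][k] = (
                _camera(img, imaging, imaging_rng) if noise else img.astype(np.float32)
            )

    positions = pd.DataFrame(
        {
            "cell_id": np.tile(cell_ids, n_frames),
            "frame": np.repeat(np.arange(n_frames), n_cells),
            "y": pos[:, :, 0].ravel(),
            "x": pos[:, :, 1].ravel(),
        }
    )
    return Movie(
        channels=channels,
        nuclei_masks=nuc_masks,
        cyto_masks=cyt_masks,
        positions=positions,
        imaging=imaging,
    )


def render_spots(
    shape: tuple[int, int],
    centers: np.ndarray,
    sigma_px: float = 2.0,
    amplitude: float = 400.0,
    background: float = 100.0,
) -> np.ndarray:
    """Render Gaussian puncta of fixed peak amplitude at ``centers`` (y, x)."""
    h, w = shape
    img = np.full((h, w), background, float)
    if len(centers) == 0:
        return img
    yy, xx = np.mgrid[0:h, 0:w]
    reach = int(np.ceil(4 * sigma_px))
    for cy, cx in np.asarray(centers, float):
        y0, y1 = int(max(0, cy - reach)), int(min(h, cy + reach + 1))
        x0, x1 = int(max(0, cx - reach)), int(min(w, cx + reach + 1))
        d2 = (yy[y0:y1, x0:x1] - cy) ** 2 + (xx[y0:y1, x0:x1] - cx) ** 2
        img[y0:y1, x0:x1] += amplitude * np.exp(-d2 / (2 * sigma_px**2))
    return img


def render_fish_field(
    mrna_true: np.ndarray,
    wholecell_labels: np.ndarray,
    imaging: ImagingParams,
    noise: bool = True,
    sigma_px: float = 2.0,
    amplitude: float = 400.0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Render an RNA FISH field: one Gaussian punctum per transcript.

    ``mrna_true[i]`` transcripts are placed uniformly at random inside the
    region labeled ``i + 1`` in ``wholecell_labels``.  Returns the image and a
    truth table of puncta centers (``cell_id, y, x``).
    """
    rng = np.random.default_rng(imaging.seed)
    counts = np.asarray(mrna_true, int)
    if (counts < 0).any():
        raise ValueError("mrna counts must be non-negative")
    rows = []
    for i, c in enumerate(counts):
        if c == 0:
            continue
        ys, xs = np.nonzero(wholecell_labels == i + 1)
        if len(ys) == 0:
            raise ValueError(f"no whole-cell region for cell {i}")
        pick = rng.integers(0, len(ys), c)
        sub = rng.uniform(-0.5, 0.5, (c, 2))
        for j, p in enumerate(pick):
            rows.append((i, ys[p] + sub[j, 0], xs[p] + sub[j, 1]))
    centers = pd.DataFrame(rows, columns=["cell_id", "y", "x"])
    img = render_spots(
        wholecell_labels.shape,
        centers[["y", "x"]].to_numpy() if len(rows) else np.empty((0, 2)),
        sigma_px=sigma_px,
        amplitude=amplitude,
        background=imaging.background,
    )
    if noise:
        img = _camera(img, imaging, rng)
    return np.asarray(img, float), centers
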