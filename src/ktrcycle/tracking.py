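"""Frame-to-frame linking, gap bridging, and live-to-fixed cell mapping.

Linking between consecutive frames is a gated optimal linear assignment
minimizing total squared displacement; leaving a detection unmatched costs
the squared gate distance, so distant pairs are never forced together.  Gap
bridging joins track ends to later track starts (gap <= ``max_gap`` frames)
with a single global assignment over all end/start pairs, which re-evaluates
links disturbed by appearing or disappearing neighbors as part of one
optimization.  Tracks whose nuclear mass changes abruptly are flagged, never
silently re-identified.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from skimage.measure import regionprops

from .segmentation import PixelCalibration

__all__ = [
    "TrackingConfig",
    "detections_from_masks",
    "link_frames",
    "build_tracks",
    "map_fixed_to_live",
]


@dataclass(frozen=True)
class TrackingConfig:
    """Gates for linking (um, frames, relative mass change)."""

    max_step_um: float = 15.0
    max_gap: int = 2
    mass_tolerance: float = 0.3
    fixed_map_radius_um: float = 15.0

    def __post_init__(self) -> None:
        if min(self.max_step_um, self.max_gap, self.mass_tolerance,
               self.fixed_map_radius_um) <= 0:
            raise ValueError("all tracking gates must be positive")


def detections_from_masks(
    masks: np.ndarray, images: np.ndarray | None = None
) -> pd.DataFrame:
    """Per-frame detections (centroid, mass) from a (T, H, W) label stack.

    ``mass`` is total intensity within the label when ``images`` is given,
    otherwise the pixel area.
    """
    rows = []
    for f in range(masks.shape[0]):
        img = images[f] if images is not None else None
        for p in regionprops(masks[f], intensity_image=img):
            mass = float(p.image_intensity.sum()) if img is not None else float(p.area)
            rows.append(
                {"frame": f, "label": int(p.label), "y": p.centroid[0],
                 "x": p.centroid[1], "mass": mass}
            )
    return pd.DataFrame(rows)


def _gated_assignment(
    pos_a: np.ndarray, pos_b: np.ndarray, gate_px: float,
    cost: np.ndarray | None = None,
) -> list[tuple[int, int]]:
    """Optimal one-to-one matching with per-item opt-out at cost ``gate_px**2``.

    Returns matched (i, j) index pairs.  The augmented square formulation
    lets any detection stay unmatched, so the result minimizes total squared
    displacement plus the gate penalty for every unmatched item.
    """
    n, m = len(pos_a), len(pos_b)
    if n == 0 or m == 0:
        return []
    if cost is None:
        d2 = ((pos_a[:, None, :] - pos_b[None, :, :]) ** 2).sum(axis=2)
    else:
        d2 = cost
    gate2 = gate_px**2
    big = 1e12
    full = np.full((n + m, n + m), 0.0)
    full[:n, :m] = np.where(d2 <= gate2, d2, big)
    full[:n, m:] = big
    full[n:, :m] = big
    np.fill_diagonal(full[:n, m:], gate2)
    np.fill_diagonal(full[n:, :m], gate2)
    rows, cols = linear_sum_assignment(full)
    return [
        (int(r), int(c))
        for r, c in zip(rows, cols)
        if r < n and c < m and d2[r, c] <= gate2
    ]


def link_frames(
    dets_t: pd.DataFrame,
    dets_t1: pd.DataFrame,
    cfg: TrackingConfig | None = None,
    cal: PixelCalibration | None = None,
) -> list[tuple[int, int]]:
    """Match detections of two consecutive frames.

    Returns positional (row) index pairs into the two tables; detections left
    out of the matching become track ends / starts.
    """
    cfg = cfg or TrackingConfig()
    cal = cal or PixelCalibration()
    pa = dets_t[["y", "x"]].to_numpy(float)
    pb = dets_t1[["y", "x"]].to_numpy(float)
    return _gated_assignment(pa, pb, cal.to_px(cfg.max_step_um))


def build_tracks(
    detections: pd.DataFrame,
    cfg: TrackingConfig | None = None,
    cal: PixelCalibration | None = None,
) -> pd.DataFrame:
    """Link all frames into tracks, bridge short gaps, flag mass anomalies.

    Returns a long table ``(track_id, frame, label, y, x, mass, bridged,
    mass_flag)``.  ``bridged`` marks detections joined across a gap;
    ``mass_flag`` marks tracks with a relative nuclear-mass change beyond
    ``mass_tolerance`` between consecutive detections (e.g. transient merges
    or divisions) — they are kept but never silently trusted.
    """
    cfg = cfg or TrackingConfig()
    cal = cal or PixelCalibration()
    dets = detections.sort_values(["frame", "y", "x"], kind="mergesort").reset_index(drop=True)
    frames = np.sort(dets["frame"].unique())
    step_px = cal.to_px(cfg.max_step_um)

    # Frame-by-frame optimal linking into gapless segments.
    seg_of_det = -np.ones(len(dets), int)
    n_seg = 0
    prev_idx = dets.index[dets["frame"] == frames[0]].to_numpy()
    for i in prev_idx:
        seg_of_det[i] = n_seg
        n_seg += 1
    for fa, fb in zip(frames[:-1], frames[1:]):
        cur_idx = dets.index[dets["frame"] == fb].to_numpy()
        if fb - fa == 1:
            a = dets.loc[prev_idx, ["y", "x"]].to_numpy(float)
            b = dets.loc[cur_idx, ["y", "x"]].to_numpy(float)
            pairs = _gated_assignment(a, b, step_px)
        else:
            pairs = []
        matched_b = set()
        for ia, ib in pairs:
            seg_of_det[cur_idx[ib]] = seg_of_det[prev_idx[ia]]
            matched_b.add(ib)
        for ib, i in enumerate(cur_idx):
            if ib not in matched_b:
                seg_of_det[i] = n_seg
                n_seg += 1
        prev_idx = cur_idx

    dets["segment"] = seg_of_det
    seg_groups = dets.groupby("segment")
    seg_first = seg_groups["frame"].min()
    seg_last = seg_groups["frame"].max()

    # Global gap bridging: one assignment over all (end, start) candidates.
    ends = seg_last.index.to_numpy()
    starts = seg_first.index.to_numpy()
    end_rows = dets.loc[seg_groups["frame"].idxmax()]
    start_rows = dets.loc[seg_groups["frame"].idxmin()]
    ne, ns = len(ends), len(starts)
    cost = np.full((ne, ns), np.inf)
    for i, se in enumerate(ends):
        for j, ss in enumerate(starts):
            if se == ss:
                continue
            g = seg_first[ss] - seg_last[se]
            if not 1 <= g <= cfg.max_gap:
                continue
            er, sr = end_rows.iloc[i], start_rows.iloc[j]
            d2 = (er["y"] - sr["y"]) ** 2 + (er["x"] - sr["x"]) ** 2
            if d2 > (g * step_px) ** 2:
                continue
            ref = max(abs(er["mass"]), 1e-12)
            if abs(sr["mass"] - er["mass"]) / ref > cfg.mass_tolerance:
                continue
            cost[i, j] = d2
    gate2 = (cfg.max_gap * step_px) ** 2
    bridges = _gated_assignment(
        np.zeros((ne, 2)), np.zeros((ns, 2)), np.sqrt(gate2),
        cost=np.where(np.isfinite(cost), cost, 1e12),
    )

    # Merge bridged segments (chains resolve via union toward the earliest).
    parent = {int(s): int(s) for s in ends}

    def find(s: int) -> int:
        while parent[s] != s:
            parent[s] = parent[parent[s]]
            s = parent[s]
        return s

    bridged_segments = set()
    for i, j in bridges:
        se, ss = int(ends[i]), int(starts[j])
        parent[find(ss)] = find(se)
        bridged_segments.add(ss)

    root = {s: find(s) for s in parent}
    track_ids = {}
    order = sorted(set(root.values()), key=lambda s: (seg_first[s], s))
    for tid, s in enumerate(order):
        track_ids[s] = tid
    dets["track_id"] = [track_ids[root[int(s)]] for s in dets["segment"]]
    first_frame_of_seg = dets.groupby("segment")["frame"].transform("min")
    dets["bridged"] = dets["segment"].isin(bridged_segments) & (
        dets["frame"] == first_frame_of_seg
    )

    # Mass-change flag per track.
    dets = dets.sort_values(["track_id", "frame"]).reset_index(drop=True)
    flags = {}
    for tid, g in dets.groupby("track_id"):
        m = g["mass"].to_numpy(float)
        rel = np.abs(np.diff(m)) / np.maximum(np.abs(m[:-1]), 1e-12)
        flags[tid] = bool((rel > cfg.mass_tolerance).any())
    dets["mass_flag"] = dets["track_id"].map(flags)
    return dets[["track_id", "frame", "label", "y", "x", "mass", "bridged", "mass_flag"]]


def map_fixed_to_live(
    last_frame_dets: pd.DataFrame,
    fixed_dets: pd.DataFrame,
    cfg: TrackingConfig | None = None,
    cal: PixelCalibration | None = None,
) -> pd.DataFrame:
    """Correspondence between the final live-cell frame and the fixed image.

    Optimal assignment gated at ``fixed_map_radius_um``; every fixed-cell
    detection appears in the output, unmatched ones with ``live_index = -1``.
    """
    cfg = cfg or TrackingConfig()
    cal = cal or PixelCalibration()
    pa = last_frame_dets[["y", "x"]].to_numpy(float)
    pb = fixed_dets[["y", "x"]].to_numpy(float)
    pairs = _gated_assignment(pa, pb, cal.to_px(cfg.fixed_map_radius_um))
    live_for_fixed = {j: i for i, j in pairs}
    rows = []
    for j in range(len(fixed_dets)):
        i = live_for_fixed.get(j, -1)
        d = (
            float(np.hypot(*(pa[i] - pb[j]))) if i >= 0 else np.nan
        )
        rows.append({"fixed_index": j, "live_index": i, "distance_px": d,
                     "mapped": i >= 0})
    return pd.DataFrame(rows)
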