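"""Shared fixtures: calibrated parameters, small cohorts, and an end-to-end
movie-analysis helper used by rendering and tracking tests."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import ktrcycle as kc


@pytest.fixture(scope="session")
def calib():
    """The packaged study-condition calibration."""
    return kc.paper_calibration()


@pytest.fixture(scope="session")
def cohort(calib):
    """Default 2000-cell cohort at the 14-h horizon (seed 1)."""
    return kc.simulate_population(calib, n_cells=2000, seed=1)


@pytest.fixture(scope="session")
def inhibition_cohort(calib):
    """CDK4/6 inhibition at 11 h, horizon extended past the fate windows."""
    pert = kc.PerturbationSpec(mode="rapid_inhibitor", t_treat=11.0)
    return kc.simulate_population(
        calib.replace(horizon=22.0), pert, n_cells=1000, seed=3
    )


@pytest.fixture(scope="session")
def noiseless_active(calib):
    """Noise-free, all-activating small cohort for exact checks."""
    p = calib.replace(p_active=1.0, noise_sd=0.0)
    return kc.simulate_population(p, n_cells=50, seed=5)


def label_to_cell(regions: kc.RegionSet, positions: pd.DataFrame, frame: int) -> dict:
    """Map segmentation labels to simulated cell ids via nearest true center."""
    posk = positions[positions["frame"] == frame]
    py = posk["y"].to_numpy()
    px = posk["x"].to_numpy()
    cid = posk["cell_id"].to_numpy()
    out = {}
    for lab, (cy, cx) in regions.centroids.items():
        d = (py - cy) ** 2 + (px - cx) ** 2
        out[int(lab)] = int(cid[np.argmin(d)])
    return out


def analyze_movie(movie: kc.Movie, traces: kc.TraceSet, frames=None):
    """Run segmentation -> regions -> measurement -> correction on a movie.

    Returns a long DataFrame (cell_id, frame, cdk2_activity, cdk4_corrected)
    of pipeline-recovered activities keyed by the simulated cell ids.
    """
    cal = kc.PixelCalibration(movie.imaging.pixel_size_um)
    cfg = kc.SegmentationConfig()
    rho = traces.params.crosstalk_rho if traces.params is not None else 0.35
    frames = range(movie.n_frames) if frames is None else frames
    rows = []
    for k in frames:
        nuc = kc.segment_nuclei(movie.channels["nuclear"][k], cfg, cal)
        regs = kc.build_regions(
            None, cfg, cal, intensity=movie.channels["cdk2"][k], nuclei=nuc
        )
        meas = kc.measure_regions(
            {"cdk2": movie.channels["cdk2"][k], "cdk4": movie.channels["cdk4"][k]},
            regs,
        )
        mapping = label_to_cell(regs, movie.positions, k)
        wide = meas.pivot(index="cell_id", columns="channel", values="activity")
        for lab, row in wide.iterrows():
            if int(lab) not in mapping:
                continue
            r2 = row.get("cdk2", np.nan)
            r46 = row.get("cdk4", np.nan)
            rows.append(
                {
                    "cell_id": mapping[int(lab)],
                    "frame": k,
                    "cdk2_activity": r2,
                    "cdk4_corrected": float(kc.correct_cdk46(r46, r2, rho))
                    if np.isfinite(r46) and np.isfinite(r2)
                    else np.nan,
                }
            )
    return pd.DataFrame(rows)
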