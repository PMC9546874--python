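"""Synthetic single-cell cohorts from a phenomenological commitment circuit.

The generator produces per-cell, per-frame reporter traces with linked ground
truth so that every downstream stage (quantification, tracking, event calling,
population statistics) can be validated without real microscopy data.

Circuit (per cell, substepped Euler integration sampled on the frame grid):

* CDK4/6 activity ``A46`` rises as ``a46_max * (1 - exp(-(t - onset)/rise_tau))``
  after a cell-specific onset drawn uniformly from
  ``[onset_min, onset_min + onset_scale]``;
  a perturbation switches production off (immediately for inhibitor/DNA-damage
  modes, after a uniform per-cell lag for mitogen withdrawal), after which
  activity decays exponentially.
* Rb is inactive while ``A46 >= theta_rb`` OR the running maximum of CDK2
  activity has ever reached ``theta_commit`` (the CDK2-Rb positive-feedback
  latch: commitment is irreversible).
* The E2F driver ``E`` integrates constant production while Rb is inactive,
  with first-order decay.
* CDK2 activity ``A2`` integrates ``cdk2_rate * E`` while Rb is inactive and
  relaxes first-order toward the quiescent baseline; when Rb re-activates
  (CDK4/6 lost before commitment) production ceases and activity decays back
  toward baseline.
* The APC/C(Cdh1) degron rises linearly once ``A2`` crosses ``theta_apc``.

Observed reporter values add cross-talk (the CDK4/6 reporter reads a fraction
``crosstalk_rho`` of CDK2 activity) and Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import CircuitParams, ImagingParams, ParameterError, PerturbationSpec

__all__ = [
    "TraceSet",
    "simulate_population",
    "simulate_calibration_pairs",
    "simulate_cell_cycle_snapshot",
    "CDK2_ON_LEVEL",
]

# Operational CDK2-activation level on the reporter scale, matching the
# selection gate used for perturbation analyses.  Ground-truth CDK2-on times
# are the first crossing of this level that is *sustained* for
# CDK2_ON_SUSTAIN_H hours: transient grazing (in particular a crossing in
# the last samples before fixation) does not count as activation.
CDK2_ON_LEVEL = 0.6
CDK2_ON_SUSTAIN_H = 0.4


@dataclass
class TraceSet:
    """A simulated (or measured) cohort of single-cell reporter traces.

    Attributes
    ----------
    frames
        Long-format table keyed by ``(cell_id, frame)`` with columns
        ``t, a46_true, a2_true, e2f_true, r46_obs, r2_obs, degron_obs``.
    cells
        Per-cell ground truth: ``is_active46, onset46_true, onset2_true,
        committed, apc_off_true, outcome_true, mrna_true``.
    params, pert, seed
        Generating parameters and seed (``None`` for measured data).
    """

    frames: pd.DataFrame
    cells: pd.DataFrame
    params: CircuitParams | None = None
    pert: PerturbationSpec | None = None
    seed: int | None = None

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def times(self) -> np.ndarray:
        return np.sort(self.frames["t"].unique())

    def matrix(self, column: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Pivot one frames column to a dense (cells x frames) array.

        Returns ``(cell_ids, times, values)``; missing entries are NaN.
        """
        wide = self.frames.pivot(index="cell_id", columns="frame", values=column)
        wide = wide.sort_index()
        t = (
            self.frames[["frame", "t"]]
            .drop_duplicates("frame")
            .sort_values("frame")["t"]
            .to_numpy()
        )
        return wide.index.to_numpy(), t, wide.to_numpy(float)

    def to_csv(self, traces_path, cells_path) -> None:
        self.frames.to_csv(traces_path, index=False)
        self.cells.to_csv(cells_path, index=False)


def simulate_population(
    params: CircuitParams,
    pert: PerturbationSpec | None = None,
    n_cells: int = 100,
    seed: int = 0,
    cdk2_on_level: float = CDK2_ON_LEVEL,
) -> TraceSet:
    """Simulate a cohort of ``n_cells`` cells under ``params`` and ``pert``.

    Identical arguments (including ``seed``) produce identical output.

    Raises
    ------
    ParameterError
        If ``n_cells`` < 1.
    """
    if n_cells < 1:
        raise ParameterError("n_cells must be >= 1")
    pert = pert or PerturbationSpec(mode="none")
    if pert.mode != "none" and not 0 <= pert.t_treat <= params.horizon:
        raise ParameterError("t_treat must lie within [0, horizon]")

    rng = np.random.default_rng(seed)
    n_frames = params.n_frames
    t = np.arange(n_frames) * params.dt

    # Activation onsets are spread uniformly across a bounded window
    # [onset_min, onset_min + onset_scale]: every activating cell switches
    # CDK4/6 on within the experiment, as in a stimulation time course.
    active = rng.random(n_cells) < params.p_active
    onset = params.onset_min + rng.uniform(0.0, params.onset_scale, n_cells)
    onset = np.where(active, onset, np.inf)

    # Time at which CDK4/6 production switches off (inf = never).
    if pert.mode == "none":
        t_off = np.full(n_cells, np.inf)
    elif pert.mode in ("rapid_inhibitor", "ncs_pulse"):
        t_off = np.full(n_cells, pert.t_treat)
    else:  # mitogen_withdrawal
        lo, hi = pert.withdrawal_delay_range
        t_off = pert.t_treat + rng.uniform(lo, hi, n_cells)

    # CDK4/6 activity: closed form rise, exponential decay after shut-off.
    # Shut-off times are capped just beyond the horizon so that "never" (inf)
    # stays on the rise branch without producing inf - inf.
    t_off_eff = np.minimum(t_off, params.horizon + params.dt)
    a46_at_off = params.a46_max * -np.expm1(
        -np.clip(t_off_eff - onset, 0.0, None) / max(params.rise_tau, 1e-12)
    )

    def a46_at(times: np.ndarray) -> np.ndarray:
        tt = times if times.ndim == 2 else times[None, :]
        rise = params.a46_max * -np.expm1(
            -np.clip(tt - onset[:, None], 0.0, None) / max(params.rise_tau, 1e-12)
        )
        dec = a46_at_off[:, None] * np.exp(
            -np.clip(tt - t_off_eff[:, None], 0.0, None) / pert.fast_decay_tau
        )
        out = np.where(tt < t_off_eff[:, None], rise, dec)
        out[~active] = 0.0
        return out

    a46 = a46_at(t)

    # Euler integration (substepped for accuracy at treatment switches) of the
    # E2F driver and CDK2 activity with the commitment latch.  CDK2 production
    # requires Rb to be inactive: losing CDK4/6 before commitment re-activates
    # Rb and CDK2 activity relaxes back to baseline, so the fate boundary sits
    # at theta_commit itself.
    n_sub = 4
    h = params.dt / n_sub
    e2f = np.zeros((n_cells, n_frames))
    a2 = np.full((n_cells, n_frames), params.a2_baseline)
    committed = np.zeros(n_cells, bool)
    e_cur = np.zeros(n_cells)
    a_cur = np.full(n_cells, params.a2_baseline)
    for k in range(n_frames - 1):
        for s in range(n_sub):
            committed |= a_cur >= params.theta_commit
            a46_s = a46_at(np.full((1,), t[k] + s * h))[:, 0]
            rb_inactive = (a46_s >= params.theta_rb) | committed
            e_next = e_cur + h * (params.e2f_rate * rb_inactive - params.e2f_decay * e_cur)
            a_cur = a_cur + h * (
                params.cdk2_rate * e_cur * rb_inactive
                - params.cdk2_decay * (a_cur - params.a2_baseline)
            )
            e_cur = e_next
        e2f[:, k + 1] = e_cur
        a2[:, k + 1] = a_cur
    committed |= a_cur >= params.theta_commit

    # APC/C degron: linear rise after first crossing of theta_apc.
    above_apc = a2 >= params.theta_apc
    has_apc = above_apc.any(axis=1)
    apc_idx = np.where(has_apc, above_apc.argmax(axis=1), 0)
    t_apc = np.where(has_apc, t[apc_idx], np.inf)
    degron = params.degron_rate * np.clip(t[None, :] - t_apc[:, None], 0.0, None)

    # Observation model: cross-talk plus Gaussian noise.
    noise = rng.normal(0.0, 1.0, (3, n_cells, n_frames)) * params.noise_sd
    r46 = a46 + params.crosstalk_rho * a2 + noise[0]
    r2 = a2 + noise[1]
    deg_obs = degron + noise[2]

    # Ground-truth event times and labels.  CDK2-on must be sustained for
    # CDK2_ON_SUSTAIN_H so that it is a real activation, observable at
    # fixation, rather than a grazing of the level in the final samples.
    sustain = int(round(CDK2_ON_SUSTAIN_H / params.dt)) + 1
    above2 = a2 >= cdk2_on_level
    run2 = np.ones((n_cells, max(n_frames - sustain + 1, 1)), bool)
    for k in range(min(sustain, n_frames)):
        run2 &= above2[:, k : k + run2.shape[1]]
    has2 = run2.any(axis=1)
    onset2 = np.where(has2, t[run2.argmax(axis=1)], np.nan)
    t_ref = pert.t_treat if pert.mode != "none" else params.horizon
    committed_at_treat = (a2[:, t <= t_ref] >= params.theta_commit).any(axis=1)
    outcome = np.where(~active, "quiescent", np.where(committed, "inc", "low"))

    e2f_end = e2f[:, -1]
    mrna = rng.poisson(2.0 + 6.0 * np.clip(e2f_end, 0.0, None))

    cells = pd.DataFrame(
        {
            "cell_id": np.arange(n_cells),
            "is_active46": active,
            "onset46_true": np.where(active, onset, np.nan),
            "onset2_true": onset2,
            "committed": committed_at_treat,
            "apc_off_true": np.where(has_apc, t_apc, np.nan),
            "outcome_true": outcome,
            "mrna_true": mrna,
        }
    )

    cell_ids = np.repeat(np.arange(n_cells), n_frames)
    frame_ids = np.tile(np.arange(n_frames), n_cells)
    frames = pd.DataFrame(
        {
            "cell_id": cell_ids,
            "frame": frame_ids,
            "t": np.tile(t, n_cells),
            "a46_true": a46.ravel(),
            "a2_true": a2.ravel(),
            "e2f_true": e2f.ravel(),
            "r46_obs": r46.ravel(),
            "r2_obs": r2.ravel(),
            "degron_obs": deg_obs.ravel(),
        }
    )
    return TraceSet(frames=frames, cells=cells, params=params, pert=pert, seed=seed)


def simulate_calibration_pairs(
    rho: float,
    n: int,
    a2_range: tuple[float, float] = (0.0, 2.0),
    noise_sd: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Paired reporter observations under full CDK4/6 inhibition.

    With CDK4/6 fully inhibited the CDK4/6 reporter reads only the cross-talk
    component ``rho * A2``; regressing ``r46_obs`` on ``r2_obs`` therefore
    recovers ``rho``.  Returns a table with columns ``r46_obs, r2_obs``.
    """
    if n < 2:
        raise ParameterError("need at least 2 calibration pairs")
    if not 0.0 <= rho < 1.0:
        raise ParameterError("rho must be in [0, 1)")
    rng = np.random.default_rng(seed)
    a2 = rng.uniform(a2_range[0], a2_range[1], n)
    r46 = rho * a2 + rng.normal(0.0, noise_sd, n)
    r2 = a2 + rng.normal(0.0, noise_sd, n)
    return pd.DataFrame({"r46_obs": r46, "r2_obs": r2})


def simulate_cell_cycle_snapshot(
    n: int,
    fractions: tuple[float, float, float] = (0.6, 0.25, 0.15),
    seed: int = 0,
) -> pd.DataFrame:
    """Fixed-cell DNA content (Hoechst) and EdU incorporation snapshot.

    Emulates the standard cell-cycle gating scatter: a 2N Hoechst band
    (G0/G1, EdU-negative), an EdU-positive S population with intermediate
    DNA content, and a 4N band (G2/M, EdU-negative).  ``fractions`` are the
    (G0/G1, S, G2/M) phase probabilities.  Returns columns
    ``hoechst, edu, phase_true``.
    """
    if n < 1:
        raise ParameterError("n must be >= 1")
    fr = np.asarray(fractions, float)
    if fr.min() < 0 or abs(fr.sum() - 1.0) > 1e-9:
        raise ParameterError("fractions must be non-negative and sum to 1")
    rng = np.random.default_rng(seed)
    phase = rng.choice(["G0/G1", "S", "G2/M"], size=n, p=fr)
    hoechst = np.empty(n)
    edu = np.empty(n)
    g1, s, g2 = phase == "G0/G1", phase == "S", phase == "G2/M"
    hoechst[g1] = rng.normal(1.0, 0.07, g1.sum())
    hoechst[s] = rng.uniform(1.1, 1.9, s.sum())
    hoechst[g2] = rng.normal(2.0, 0.12, g2.sum())
    edu[g1] = rng.normal(0.1, 0.03, g1.sum())
    edu[s] = rng.normal(1.0, 0.15, s.sum())
    edu[g2] = rng.normal(0.12, 0.04, g2.sum())
    return pd.DataFrame({"hoechst": hoechst, "edu": edu, "phase_true": phase})
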