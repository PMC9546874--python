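"""Event calling on single-cell traces and commitment-boundary estimation.

Onsets are called with a threshold-plus-persistence rule: the first frame at
which activity stays at or above the threshold for ``w`` consecutive frames.
Cells are classed CDK4/6-high (activated) or CDK4/6-low (quiescent) by the
presence of a CDK4/6 onset on the cross-talk-corrected activity.  After a
perturbation at ``t_treat``, proliferative fate is classified from CDK2
activity in two post-treatment windows among cells that had already activated
CDK2 (activity >= 0.6) at treatment time; the CDK2 level at which the
probability of continued cell-cycle entry crosses 50% (logistic regression)
is the operational commitment boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .quantify import CrosstalkModel, correct_cdk46
from .simulate import TraceSet

__all__ = [
    "EventConfig",
    "BoundaryEstimate",
    "detect_onset",
    "call_events",
    "classify_fate",
    "align_and_summarize",
    "estimate_commitment_boundary",
    "inactivation_delay",
    "inactivation_delays",
]


class EventConfigError(ValueError):
    pass


@dataclass(frozen=True)
class EventConfig:
    """Thresholds and windows for event calling and fate classification.

    ``theta46_on`` applies to cross-talk-corrected CDK4/6 activity,
    ``theta2_on`` to CDK2 activity (matching the 0.6 selection gate),
    ``theta_degron`` to the APC/C degron signal.  ``window1``/``window2``
    are (start, end) offsets in hours after treatment used for the
    two-window fate call.
    """

    theta46_on: float = 0.3
    theta2_on: float = 0.6
    persistence_w: int = 3
    theta_off: float = 0.3
    theta_degron: float = 0.1
    select_gate: float = 0.6
    window1: tuple[float, float] = (0.0, 2.0)
    window2: tuple[float, float] = (6.0, 10.0)
    inc_cutoff: float = 0.8
    low_cutoff: float = 0.5

    def __post_init__(self) -> None:
        if self.persistence_w < 1:
            raise EventConfigError("persistence_w must be >= 1")
        if not self.window1[1] <= self.window2[0]:
            raise EventConfigError("window1 must precede window2")
        for name in ("theta46_on", "theta2_on", "theta_off", "theta_degron",
                     "select_gate"):
            if getattr(self, name) < 0:
                raise EventConfigError(f"{name} must be non-negative")


def _first_run_starts(above: np.ndarray, w: int) -> np.ndarray:
    """Per row: first index starting a run of >= w consecutive True; -1 if none."""
    above = np.asarray(above, bool)
    if above.ndim == 1:
        above = above[None, :]
    n, f = above.shape
    if w > f:
        raise EventConfigError("persistence window longer than trace")
    run = np.ones((n, f - w + 1), bool)
    for k in range(w):
        run &= above[:, k : k + f - w + 1]
    has = run.any(axis=1)
    idx = np.where(has, run.argmax(axis=1), -1)
    return idx


def detect_onset(
    values: np.ndarray, times: np.ndarray, theta: float, w: int = 3
) -> float | None:
    """First time at which ``values >= theta`` for ``w`` consecutive frames."""
    values = np.asarray(values, float)
    times = np.asarray(times, float)
    idx = _first_run_starts(np.nan_to_num(values, nan=-np.inf) >= theta, w)[0]
    return None if idx < 0 else float(times[idx])


def _corrected46(traces: TraceSet, crosstalk) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    ids, t, r46 = traces.matrix("r46_obs")
    _, _, r2 = traces.matrix("r2_obs")
    if crosstalk is None:
        rho = traces.params.crosstalk_rho if traces.params is not None else 0.35
    elif isinstance(crosstalk, CrosstalkModel):
        rho = crosstalk.rho
    else:
        rho = float(crosstalk)
    return ids, t, correct_cdk46(r46, r2, rho)


def call_events(
    traces: TraceSet,
    cfg: EventConfig | None = None,
    crosstalk: CrosstalkModel | float | None = None,
    t_treat: float | None = None,
) -> pd.DataFrame:
    """Per-cell onset times and CDK4/6-high/low classification.

    Onset detection runs on cross-talk-corrected CDK4/6 activity, raw CDK2
    activity, and the degron signal.  ``crosstalk`` defaults to the
    generative coefficient attached to the traces (or 0.35).  Returns a table
    with ``onset46, onset2, apc_off`` (NaN = no event), ``class46`` and,
    when ``t_treat`` is given, ``cdk2_at_treatment``.
    """
    cfg = cfg or EventConfig()
    ids, t, corr46 = _corrected46(traces, crosstalk)
    _, _, r2 = traces.matrix("r2_obs")
    _, _, deg = traces.matrix("degron_obs")
    w = cfg.persistence_w

    i46 = _first_run_starts(corr46 >= cfg.theta46_on, w)
    i2 = _first_run_starts(r2 >= cfg.theta2_on, w)
    ideg = _first_run_starts(deg >= cfg.theta_degron, w)
    onset46 = np.where(i46 >= 0, t[np.clip(i46, 0, None)], np.nan)
    onset2 = np.where(i2 >= 0, t[np.clip(i2, 0, None)], np.nan)
    apc_off = np.where(ideg >= 0, t[np.clip(ideg, 0, None)], np.nan)

    table = pd.DataFrame(
        {
            "cell_id": ids,
            "onset46": onset46,
            "onset2": onset2,
            "apc_off": apc_off,
            "class46": np.where(i46 >= 0, "high", "low"),
        }
    )
    if t_treat is not None:
        k = int(np.argmin(np.abs(t - t_treat)))
        table["cdk2_at_treatment"] = r2[:, k]
    return table


def classify_fate(
    traces: TraceSet,
    t_treat: float,
    cfg: EventConfig | None = None,
) -> pd.DataFrame:
    """Two-window proliferative-fate call after a perturbation.

    Only cells with CDK2 activity >= ``select_gate`` at treatment are
    classified.  ``inc`` (continued cell-cycle entry): mean CDK2 over
    ``window2`` >= ``inc_cutoff`` and not below the ``window1`` mean;
    ``low`` (reversal to quiescence): mean over ``window2`` <= ``low_cutoff``;
    anything else is ``unclassified``.  Returns ``cell_id,
    cdk2_at_treatment, selected, fate``.
    """
    cfg = cfg or EventConfig()
    ids, t, r2 = traces.matrix("r2_obs")
    if t_treat + cfg.window2[1] > t[-1] + 1e-9:
        raise EventConfigError("window2 extends beyond the end of the traces")
    k = int(np.argmin(np.abs(t - t_treat)))
    at_treat = r2[:, k]
    w1 = (t >= t_treat + cfg.window1[0]) & (t <= t_treat + cfg.window1[1])
    w2 = (t >= t_treat + cfg.window2[0]) & (t <= t_treat + cfg.window2[1])
    m1 = np.nanmean(r2[:, w1], axis=1)
    m2 = np.nanmean(r2[:, w2], axis=1)
    selected = at_treat >= cfg.select_gate
    fate = np.full(len(ids), "unclassified", object)
    fate[(m2 >= cfg.inc_cutoff) & (m2 >= m1)] = "inc"
    fate[m2 <= cfg.low_cutoff] = "low"
    fate[~selected] = "excluded"
    return pd.DataFrame(
        {
            "cell_id": ids,
            "cdk2_at_treatment": at_treat,
            "selected": selected,
            "fate": fate,
        }
    )


def align_and_summarize(
    traces: TraceSet,
    event_times: pd.Series | dict,
    channel: str = "r2_obs",
) -> pd.DataFrame:
    """Average traces aligned to a per-cell event time.

    ``event_times`` maps cell_id -> event time (h); cells with no event
    (NaN) are skipped.  Each trace is shifted so its event sits at offset 0
    (event times are rounded to the frame grid) and averaged per offset.
    Returns ``offset, mean, ci_halfwidth, n`` with a t-based two-sided 95%
    confidence interval of the mean.
    """
    ids, t, vals = traces.matrix(channel)
    dt = float(np.median(np.diff(t))) if len(t) > 1 else 1.0
    ev = pd.Series(event_times)
    buckets: dict[int, list[float]] = {}
    for i, cid in enumerate(ids):
        e = ev.get(cid, np.nan)
        if not np.isfinite(e):
            continue
        shift = int(round(e / dt))
        for k in range(len(t)):
            buckets.setdefault(k - shift, []).append(vals[i, k])
    rows = []
    for off in sorted(buckets):
        v = np.asarray(buckets[off], float)
        v = v[np.isfinite(v)]
        n = len(v)
        if n == 0:
            continue
        mean = v.mean()
        if n > 1:
            hw = stats.t.ppf(0.975, n - 1) * v.std(ddof=1) / np.sqrt(n)
        else:
            hw = np.nan
        rows.append(
            {"offset": round(off * dt, 9), "mean": mean, "ci_halfwidth": hw, "n": n}
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class BoundaryEstimate:
    """Logistic 50% point of continued cell-cycle entry vs CDK2 at treatment."""

    boundary: float
    ci_low: float
    ci_high: float
    n: int
    separated: bool


def _logit_boundary(x: np.ndarray, y: np.ndarray) -> float:
    X = sm.add_constant(x)
    with np.errstate(all="ignore"):
        res = sm.Logit(y, X).fit(disp=0, maxiter=200)
    b0, b1 = res.params
    if b1 == 0:
        raise np.linalg.LinAlgError("flat logistic fit")
    return float(-b0 / b1)


def estimate_commitment_boundary(
    cdk2_at_treatment: np.ndarray,
    fate: np.ndarray,
    n_boot: int = 1000,
    seed: int = 0,
) -> BoundaryEstimate:
    """CDK2 activity at which P(continued entry) = 0.5, with bootstrap CI.

    ``fate`` entries equal to ``"inc"`` (or truthy 1) count as continued
    entry; ``unclassified``/``excluded`` cells must be removed beforehand.
    Complete separation is reported as the midpoint between the class
    extremes with ``separated=True``.
    """
    x = np.asarray(cdk2_at_treatment, float)
    f = np.asarray(fate)
    y = (f == "inc").astype(int) if f.dtype.kind in "OUS" else f.astype(int)
    ok = np.isfinite(x)
    x, y = x[ok], y[ok]
    if y.min() == y.max():
        raise ValueError("both fates must be represented")

    separated = x[y == 0].max() < x[y == 1].min()
    if separated:
        mid = 0.5 * (x[y == 0].max() + x[y == 1].min())
        return BoundaryEstimate(
            boundary=float(mid),
            ci_low=float(x[y == 0].max()),
            ci_high=float(x[y == 1].min()),
            n=len(x),
            separated=True,
        )

    boundary = _logit_boundary(x, y)
    rng = np.random.default_rng(seed)
    boots = []
    for _ in range(n_boot):
        idx = rng.integers(0, len(x), len(x))
        xb, yb = x[idx], y[idx]
        if yb.min() == yb.max():
            continue
        if xb[yb == 0].max() < xb[yb == 1].min():
            boots.append(0.5 * (xb[yb == 0].max() + xb[yb == 1].min()))
            continue
        try:
            boots.append(_logit_boundary(xb, yb))
        except (np.linalg.LinAlgError, ValueError):
            continue
    if boots:
        lo, hi = np.percentile(boots, [2.5, 97.5])
    else:
        lo = hi = boundary
    return BoundaryEstimate(
        boundary=float(boundary), ci_low=float(lo), ci_high=float(hi),
        n=len(x), separated=False,
    )


def inactivation_delay(
    values: np.ndarray,
    times: np.ndarray,
    t_treat: float,
    theta_off: float = 0.3,
    w: int = 3,
) -> float | None:
    """Hours from treatment to sustained loss of activity (None if never).

    The first time at or after ``t_treat`` with activity below ``theta_off``
    for ``w`` consecutive frames, minus ``t_treat``.
    """
    values = np.asarray(values, float)
    times = np.asarray(times, float)
    sel = times >= t_treat - 1e-9
    idx = _first_run_starts(values[sel] < theta_off, w)[0]
    return None if idx < 0 else float(times[sel][idx] - t_treat)


def inactivation_delays(
    traces: TraceSet,
    t_treat: float,
    cfg: EventConfig | None = None,
    crosstalk: CrosstalkModel | float | None = None,
) -> pd.Series:
    """Per-cell CDK4/6 inactivation delays for cells active at treatment.

    Runs on cross-talk-corrected CDK4/6 activity; cells below ``theta_off``
    at treatment are skipped, cells that never inactivate get NaN.
    """
    cfg = cfg or EventConfig()
    ids, t, corr46 = _corrected46(traces, crosstalk)
    k = int(np.argmin(np.abs(t - t_treat)))
    out = {}
    for i, cid in enumerate(ids):
        if corr46[i, k] < cfg.theta_off:
            continue
        d = inactivation_delay(corr46[i], t, t_treat, cfg.theta_off, cfg.persistence_w)
        out[cid] = np.nan if d is None else d
    return pd.Series(out, name="delay", dtype=float)
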