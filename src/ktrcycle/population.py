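"""Fixed-cell population analysis: thresholds, time courses, activity maps,
cell-cycle phase gating, and significance testing.

Population fractions (active CDK4/6, active CDK2, inactive APC/C, p-Rb) are
computed against per-channel thresholds — fitted by inter-class-variance
maximization, by the equal-likelihood crossing of a two-component normal
mixture, or set manually — and their time courses are summarized with a
four-parameter sigmoid fit.  Two-dimensional CDK4/6 x CDK2 "activity maps"
bin cells on both activities and color-code a per-bin statistic.  Group
comparisons use Welch's unequal-variance two-sample t-test, the test used
throughout for condition contrasts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from skimage.filters import threshold_otsu
from sklearn.mixture import GaussianMixture

__all__ = [
    "ThresholdModel",
    "SigmoidFit",
    "ActivityMap",
    "fit_threshold",
    "fraction_positive_timecourse",
    "fit_sigmoid",
    "activity_map",
    "gate_phases",
    "welch_ttest",
]


@dataclass(frozen=True)
class ThresholdModel:
    channel: str
    threshold: float
    method: str
    means: tuple[float, float] | None = None
    sds: tuple[float, float] | None = None
    weights: tuple[float, float] | None = None
    flagged: bool = False


@dataclass(frozen=True)
class SigmoidFit:
    """4-parameter logistic: lower + (upper-lower)/(1+exp(-slope*(t-t50)))."""

    lower: float
    upper: float
    t50: float
    slope: float
    rss: float
    degenerate: bool = False

    def predict(self, t):
        t = np.asarray(t, float)
        return self.lower + (self.upper - self.lower) / (
            1.0 + np.exp(-self.slope * (t - self.t50))
        )


@dataclass
class ActivityMap:
    """2D-binned grid over two activities with a per-bin statistic.

    ``statistic`` is the percentage positive (binary marker) or mean value
    (numeric marker) per bin; bins with fewer than ``min_n`` cells are NaN
    in ``statistic`` (the ``counts`` grid is always full).
    """

    x_edges: np.ndarray
    y_edges: np.ndarray
    counts: np.ndarray
    statistic: np.ndarray
    min_n: int
    kind: str


def _gmm2_crossing(x: np.ndarray) -> ThresholdModel | None:
    q25, q75 = np.percentile(x, [25, 75])
    gm = GaussianMixture(
        n_components=2,
        means_init=[[q25], [q75]],
        random_state=0,
        n_init=1,
    ).fit(x[:, None])
    mu = gm.means_.ravel()
    sd = np.sqrt(gm.covariances_.ravel())
    w = gm.weights_.ravel()
    order = np.argsort(mu)
    mu, sd, w = mu[order], sd[order], w[order]
    if mu[1] - mu[0] < 1e-6 * max(np.ptp(x), 1e-12):
        return None
    # Equal-likelihood crossing between the two component means.
    grid = np.linspace(mu[0], mu[1], 2001)
    diff = w[0] * stats.norm.pdf(grid, mu[0], sd[0]) - w[1] * stats.norm.pdf(
        grid, mu[1], sd[1]
    )
    sign = np.sign(diff)
    flips = np.nonzero(np.diff(sign))[0]
    if len(flips) == 0:
        return None
    thr = float(grid[flips[0]])
    return ThresholdModel(
        channel="", threshold=thr, method="gmm2",
        means=(float(mu[0]), float(mu[1])),
        sds=(float(sd[0]), float(sd[1])),
        weights=(float(w[0]), float(w[1])),
    )


def fit_threshold(
    values: np.ndarray, method: str = "otsu",
    channel: str = "", manual: float | None = None,
) -> ThresholdModel:
    """Classification threshold for one channel.

    ``otsu``: inter-class-variance maximization on a 256-bin histogram.
    ``gmm2``: equal-likelihood crossing of a 2-component normal mixture
    (initialized at the 25th/75th percentiles); degenerate mixtures fall
    back to otsu with ``flagged=True``.  ``manual`` passes the given value
    through.
    """
    x = np.asarray(values, float)
    x = x[np.isfinite(x)]
    if method == "manual":
        if manual is None:
            raise ValueError("manual method requires a threshold value")
        return ThresholdModel(channel=channel, threshold=float(manual), method="manual")
    if len(x) < 10:
        raise ValueError("need at least 10 values to fit a threshold")
    if np.ptp(x) == 0:
        raise ValueError("all values identical; no threshold exists")
    if method == "otsu":
        return ThresholdModel(
            channel=channel, threshold=float(threshold_otsu(x, nbins=256)),
            method="otsu",
        )
    if method == "gmm2":
        model = _gmm2_crossing(x)
        if model is None:
            return ThresholdModel(
                channel=channel, threshold=float(threshold_otsu(x, nbins=256)),
                method="otsu", flagged=True,
            )
        return ThresholdModel(
            channel=channel, threshold=model.threshold, method="gmm2",
            means=model.means, sds=model.sds, weights=model.weights,
        )
    raise ValueError(f"unknown method {method!r}")


def fraction_positive_timecourse(
    samples: dict[float, np.ndarray],
    model: ThresholdModel,
    polarity: str = "above",
) -> pd.DataFrame:
    """Percentage of cells beyond the threshold at each timepoint.

    ``polarity='above'`` counts values >= threshold (active-type channels);
    ``'below'`` counts values <= threshold (e.g. classifying low signal as
    positive).  Empty timepoints are omitted with a warning.
    """
    if polarity not in ("above", "below"):
        raise ValueError("polarity must be 'above' or 'below'")
    rows = []
    for t in sorted(samples):
        v = np.asarray(samples[t], float)
        v = v[np.isfinite(v)]
        if len(v) == 0:
            warnings.warn(f"timepoint {t} has no cells; omitted")
            continue
        pos = v >= model.threshold if polarity == "above" else v <= model.threshold
        rows.append({"t": t, "percent": 100.0 * pos.mean(), "n": len(v)})
    return pd.DataFrame(rows)


def fit_sigmoid(t: np.ndarray, p: np.ndarray) -> SigmoidFit:
    """Least-squares 4-parameter sigmoid fit with multi-start on t50.

    Deterministic: starts span the observed time range; the best residual
    sum of squares wins.  A flat response is returned flagged degenerate.
    """
    t = np.asarray(t, float)
    p = np.asarray(p, float)
    if len(t) < 4:
        raise ValueError("need at least 4 points for a sigmoid fit")
    span = max(np.ptp(p), 1e-12)
    if np.ptp(p) < 1e-9:
        return SigmoidFit(
            lower=float(p.mean()), upper=float(p.mean()),
            t50=float(np.median(t)), slope=0.0, rss=0.0, degenerate=True,
        )

    def model(params, tt):
        lo, hi, t50, k = params
        return lo + (hi - lo) / (1.0 + np.exp(-np.clip(k * (tt - t50), -500, 500)))

    def resid(params):
        return model(params, t) - p

    best = None
    t_starts = np.linspace(t.min(), t.max(), 7)
    k0 = 4.0 / max(np.ptp(t) / 4.0, 1e-6)
    for t50_0 in t_starts:
        x0 = [p.min(), p.max(), t50_0, k0]
        try:
            sol = optimize.least_squares(resid, x0, method="lm", max_nfev=5000)
        except Exception:
            continue
        rss = float(2 * sol.cost)
        if best is None or rss < best[0]:
            best = (rss, sol.x)
    if best is None:
        raise RuntimeError("sigmoid fit failed to converge from all starts")
    rss, (lo, hi, t50, k) = best
    if k < 0:  # canonicalize to a rising parameterization
        lo, hi, k = hi, lo, -k
    degenerate = bool(abs(hi - lo) < 1e-3 * span)
    return SigmoidFit(
        lower=float(lo), upper=float(hi), t50=float(t50), slope=float(k),
        rss=rss, degenerate=degenerate,
    )


def activity_map(
    x: np.ndarray,
    y: np.ndarray,
    marker: np.ndarray,
    bins: int | tuple = 30,
    extent: tuple[float, float, float, float] = (0.0, 2.5, 0.0, 2.5),
    min_n: int = 5,
    kind: str = "auto",
) -> ActivityMap:
    """2D-binned activity map of a marker over (CDK4/6, CDK2) activity.

    Binary markers are summarized as percentage positive per bin, numeric
    markers as the mean; ``kind='auto'`` treats {0,1}-valued markers as
    binary.  Bins with fewer than ``min_n`` cells are masked (NaN).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    m = np.asarray(marker, float)
    if not (len(x) == len(y) == len(m)):
        raise ValueError("x, y, marker must have equal length")
    if kind == "auto":
        vals = np.unique(m[np.isfinite(m)])
        kind = "binary" if np.isin(vals, (0.0, 1.0)).all() else "numeric"
    x_edges = np.linspace(extent[0], extent[1], (bins if np.isscalar(bins) else bins[0]) + 1)
    y_edges = np.linspace(extent[2], extent[3], (bins if np.isscalar(bins) else bins[1]) + 1)
    if len(x) == 0:
        counts = np.zeros((len(x_edges) - 1, len(y_edges) - 1))
        return ActivityMap(x_edges, y_edges, counts, np.full_like(counts, np.nan),
                           min_n, kind)
    counts, _, _ = np.histogram2d(x, y, bins=(x_edges, y_edges))
    sums, _, _ = np.histogram2d(x, y, bins=(x_edges, y_edges), weights=m)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = sums / counts
    stat = 100.0 * mean if kind == "binary" else mean
    stat = np.where(counts >= min_n, stat, np.nan)
    return ActivityMap(x_edges, y_edges, counts, stat, min_n, kind)


def gate_phases(
    hoechst: np.ndarray,
    edu: np.ndarray,
    edu_threshold: float | None = None,
    hoechst_bands: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Cell-cycle phase gating from DNA content and EdU incorporation.

    S phase: EdU above threshold.  Among EdU-negative cells, DNA content is
    split into the 2N (G0/G1) and 4N (G2/M) bands by a two-component normal
    mixture (or by the manual ``hoechst_bands`` = (2N center, 4N center)).
    Returns ``hoechst, edu, phase``.
    """
    h = np.asarray(hoechst, float)
    e = np.asarray(edu, float)
    if len(h) != len(e):
        raise ValueError("hoechst and edu must have equal length")
    if len(h) == 0:
        return pd.DataFrame({"hoechst": h, "edu": e, "phase": np.array([], object)})
    if edu_threshold is None:
        edu_threshold = fit_threshold(e, "gmm2").threshold if np.ptp(e) > 0 else np.inf
    s_mask = e >= edu_threshold
    neg = ~s_mask
    if hoechst_bands is None:
        hn = h[neg]
        if len(hn) >= 10 and np.ptp(hn) > 0:
            model = _gmm2_crossing(hn)
            if model is not None:
                c2n, c4n = model.means
            else:
                c2n, c4n = np.median(hn), np.median(hn) * 2
        else:
            c2n, c4n = (np.median(h[neg]) if neg.any() else 1.0), np.inf
    else:
        c2n, c4n = hoechst_bands
    split = 0.5 * (c2n + c4n)
    phase = np.where(s_mask, "S", np.where(h < split, "G0/G1", "G2/M"))
    return pd.DataFrame({"hoechst": h, "edu": e, "phase": phase})


def welch_ttest(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float]:
    """Welch's unequal-variance two-sided t-test.

    Returns (t, Satterthwaite df, p).  Two zero-variance samples with equal
    means return (0, n_a + n_b - 2, 1) by convention.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ValueError("each sample needs at least 2 observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            warnings.warn("both samples constant and equal; p = 1 by convention")
            return 0.0, float(na + nb - 2), 1.0
        return (np.inf if a.mean() > b.mean() else -np.inf), float(na + nb - 2), 0.0
    se2 = va / na + vb / nb
    tstat = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * stats.t.sf(abs(tstat), df)
    return float(tstat), float(df), float(p)
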