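"""Snapshot-based ("spatial") Granger causality.

Interactions between an extracellular field and the neural activity that
generates it are effectively instantaneous, so classical time-lagged
Granger causality does not apply. Instead, each time point is treated as a
snapshot — a spatial profile over the electrode positions — and the causal
question is asked over space: does knowing the source profile at preceding
locations improve the prediction of the target profile at the next
location, beyond the target's own spatial history? The patch orientation
(which edge counts as the "beginning") is a nuisance choice; the default is
left-to-right, with a both-orientations mode that averages the two.

The strength is the generalized-variance log-ratio
``F = ln(RSS_restricted / RSS_full)`` of nested least-squares spatial
autoregressions, tested with the nested-model F statistic with
``(p, n_obs - 2p - 1)`` degrees of freedom (designs include an intercept).
Temporal stability of the per-snapshot strengths is summarized by the
coefficient of variation in percent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "SnapshotSeries",
    "GCResult",
    "select_order",
    "gc_strength",
    "gc_significance",
    "gc_over_time",
    "coefficient_of_variation",
    "window_axis_correlation",
]


@dataclass(frozen=True)
class SnapshotSeries:
    """Stack of spatial profiles, one per time point."""

    values: np.ndarray  # n_snapshots x n_points
    label: str = "activity"  # {"field", "activity"} or free-form
    area: str = ""

    def __post_init__(self) -> None:
        v = np.atleast_2d(np.asarray(self.values, dtype=float))
        if not np.all(np.isfinite(v)):
            raise ValueError("snapshot values must be finite")
        object.__setattr__(self, "values", v)

    @property
    def n_snapshots(self) -> int:
        return self.values.shape[0]

    @property
    def n_points(self) -> int:
        return self.values.shape[1]


def _lag_matrix(x: np.ndarray, p: int) -> np.ndarray:
    """Columns x[t-1], ..., x[t-p] for rows t = p..n-1."""
    return np.column_stack([x[p - k : len(x) - k] for k in range(1, p + 1)])


def _rss(y: np.ndarray, X: np.ndarray) -> float:
    coef, res, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise np.linalg.LinAlgError("rank-deficient spatial regression design")
    r = y - X @ coef
    return float(r @ r)


def _nested_rss(target: np.ndarray, source: np.ndarray, p: int) -> tuple[float, float, int]:
    """(RSS_restricted, RSS_full, n_obs) of the spatial lag regressions."""
    target = np.asarray(target, dtype=float).ravel()
    source = np.asarray(source, dtype=float).ravel()
    if target.size != source.size:
        raise ValueError("series must share the spatial grid")
    if p < 1:
        raise ValueError("lag order must be >= 1")
    n_obs = target.size - p
    if n_obs <= 2 * p + 1:
        raise ValueError(f"too few spatial observations ({n_obs}) for order {p}")
    y = target[p:]
    ones = np.ones((n_obs, 1))
    Xr = np.hstack([ones, _lag_matrix(target, p)])
    Xf = np.hstack([Xr, _lag_matrix(source, p)])
    return _rss(y, Xr), _rss(y, Xf), n_obs


def gc_strength(
    target: np.ndarray, source: np.ndarray, p: int = 1, orientation: str = "forward"
) -> float:
    """Spatial GC strength ln(RSS_restricted / RSS_full) of source -> target.

    ``orientation``: 'forward' (default left-to-right spatial ordering),
    'backward', or 'both' (mean of the two orientations).
    """
    if orientation == "both":
        return 0.5 * (
            gc_strength(target, source, p, "forward")
            + gc_strength(target, source, p, "backward")
        )
    t = np.asarray(target, dtype=float).ravel()
    s = np.asarray(source, dtype=float).ravel()
    if orientation == "backward":
        t, s = t[::-1], s[::-1]
    elif orientation != "forward":
        raise ValueError(f"unknown orientation {orientation!r}")
    rss_r, rss_f, _ = _nested_rss(t, s, p)
    if rss_f <= 0:
        return np.inf
    return max(float(np.log(rss_r / rss_f)), 0.0)


def gc_significance(strength: float, n_obs: int, p: int) -> float:
    """p-value of the nested-regression F test for a spatial GC strength.

    F = (exp(strength) - 1) * (n_obs - 2p - 1) / p with (p, n_obs - 2p - 1)
    degrees of freedom.
    """
    df2 = n_obs - 2 * p - 1
    if df2 <= 0:
        raise ValueError("insufficient observations for the F test")
    if np.isinf(strength):
        return 0.0
    f_stat = (np.exp(strength) - 1.0) * df2 / p
    return float(stats.f.sf(f_stat, p, df2))


@dataclass
class GCResult:
    """Per-snapshot directed GC strengths with F-test significance."""

    strengths: np.ndarray
    pvalues: np.ndarray
    direction: tuple[str, str]  # (source label, target label)
    order_p: int
    alpha: float = 0.05

    @property
    def significance_mask(self) -> np.ndarray:
        return self.pvalues < self.alpha

    @property
    def cv_percent(self) -> float:
        return coefficient_of_variation(self.strengths)

    def summary(self) -> dict:
        return {
            "direction": "->".join(self.direction),
            "order_p": self.order_p,
            "mean_strength": float(np.mean(self.strengths)),
            "cv_percent": float(self.cv_percent),
            "fraction_significant": float(np.mean(self.significance_mask)),
        }


def gc_over_time(
    field: SnapshotSeries,
    activity: SnapshotSeries,
    p: int = 1,
    alpha: float = 0.05,
    orientation: str = "forward",
) -> tuple[GCResult, GCResult]:
    """Per-snapshot spatial GC in both directions.

    Returns (field -> activity, activity -> field) results with matched
    snapshot indexing.
    """
    if field.n_snapshots != activity.n_snapshots or field.n_points != activity.n_points:
        raise ValueError("snapshot series must have matching shapes")
    n_obs = field.n_points - p

    def one_direction(src: SnapshotSeries, tgt: SnapshotSeries) -> GCResult:
        strengths = np.empty(tgt.n_snapshots)
        pvals = np.empty(tgt.n_snapshots)
        for i in range(tgt.n_snapshots):
            strengths[i] = gc_strength(tgt.values[i], src.values[i], p, orientation)
            pvals[i] = gc_significance(strengths[i], n_obs, p)
        return GCResult(strengths, pvals, (src.label, tgt.label), p, alpha)

    return one_direction(field, activity), one_direction(activity, field)


def select_order(
    a: np.ndarray, b: np.ndarray, max_order: int, criterion: str = "BIC"
) -> int:
    """Spatial VAR lag order minimizing an information criterion or CV error.

    The bivariate spatial autoregression is fitted with coefficients pooled
    over snapshots; AIC/BIC use the Gaussian log-likelihood based on the
    log-determinant of the pooled residual covariance, CV uses
    split-half prediction error across snapshots.
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    if a.shape != b.shape:
        raise ValueError("series must have matching shapes")
    n_points = a.shape[1]
    if max_order < 1 or max_order >= n_points / 3:
        raise ValueError("max_order must be >= 1 and < n_points / 3")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("degenerate (constant) series")
    criterion = criterion.upper()
    if criterion not in {"AIC", "BIC", "CV"}:
        raise ValueError(f"unknown criterion {criterion!r}")

    def pooled_design(rows_a, rows_b, p):
        Ys, Xs = [], []
        for xa, xb in zip(rows_a, rows_b):
            n_obs = n_points - p
            ones = np.ones((n_obs, 1))
            X = np.hstack([ones, _lag_matrix(xa, p), _lag_matrix(xb, p)])
            Y = np.column_stack([xa[p:], xb[p:]])
            Ys.append(Y)
            Xs.append(X)
        return np.vstack(Ys), np.vstack(Xs)

    scores = []
    for p in range(1, max_order + 1):
        if criterion == "CV":
            half = a.shape[0] // 2
            if half == 0:
                raise ValueError("CV criterion needs >= 2 snapshots")
            err = 0.0
            for tr, te in (((slice(0, half)), slice(half, None)),
                           ((slice(half, None)), slice(0, half))):
                Ytr, Xtr = pooled_design(a[tr], b[tr], p)
                Yte, Xte = pooled_design(a[te], b[te], p)
                coef, *_ = np.linalg.lstsq(Xtr, Ytr, rcond=None)
                r = Yte - Xte @ coef
                err += float(np.sum(r**2))
            scores.append(err)
        else:
            Y, X = pooled_design(a, b, p)
            coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
            R = Y - X @ coef
            n = Y.shape[0]
            sigma = (R.T @ R) / n
            sign, logdet = np.linalg.slogdet(sigma + 1e-300 * np.eye(2))
            k = 2 * X.shape[1]
            penalty = 2.0 * k if criterion == "AIC" else k * np.log(n)
            scores.append(n * logdet + penalty)
    return int(np.argmin(scores)) + 1


def coefficient_of_variation(values: np.ndarray) -> float:
    """100 * sample standard deviation / mean; errors on zero mean."""
    v = np.asarray(values, dtype=float).ravel()
    m = v.mean()
    if m == 0:
        raise ValueError("coefficient of variation undefined for zero mean")
    sd = v.std(ddof=1) if v.size > 1 else 0.0
    return float(100.0 * sd / m)


def window_axis_correlation(
    mask: np.ndarray, axes: list[np.ndarray], alpha: float = 0.05
) -> list[dict]:
    """Correlate a significance time-mask with principal-axis magnitudes.

    ``mask`` is a 0/1 series over time (e.g. snapshots with significant
    field GC); each axis H_j (channels x time) is collapsed to a time
    course by the mean absolute value over channels. Returns one record per
    axis with the Pearson correlation, its two-sided p-value, and whether
    it clears ``alpha`` (non-significant entries are reported as such
    rather than dropped).
    """
    m = np.asarray(mask, dtype=float).ravel()
    if np.ptp(m) == 0:
        raise ValueError("mask is constant: correlation undefined (zero variance)")
    out = []
    for j, H in enumerate(axes):
        H = np.asarray(H, dtype=float)
        course = np.mean(np.abs(H), axis=0) if H.ndim == 2 else np.abs(H)
        if course.size != m.size:
            raise ValueError("axis time course length must match mask length")
        r, pval = stats.pearsonr(m, course)
        out.append(
            {"axis": j, "correlation": float(r), "pvalue": float(pval),
             "significant": bool(pval < alpha)}
        )
    return out
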