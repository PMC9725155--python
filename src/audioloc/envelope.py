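"""Head-distance-vs-error structure: envelope regressions, the 5%
quadrant-partition frontier, and the quartile-split divergence comparison.

The scatter of head distance ``h`` (m) against unsigned error ``eps`` (deg)
is *triangular*: large head movement co-occurs only with small error.  Three
summaries quantify it:

* **Binned envelope fits** — per 1-degree error bin, an upper confidence
  bound ``mean(h) + k_sd * SD(h)`` (k_sd = 1.96 for the 95% level, 3.0 for
  99.7%); the bounds are then fitted with a line ``h ~ m*eps + q`` and with
  a logarithmic model ``h ~ A*log(max + 1 - eps) + B`` where ``max`` is the
  largest unsigned error (natural log; base only rescales A).
* **Quadrant-partition curve** — the frontier of corners (eps0, h0) whose
  closed upper-right quadrants {eps >= eps0, h >= h0} each contain a fixed
  fraction (default 5%) of the data.
* **Quartile split** — head divergence statistics for trials above vs below
  the third quartile of head distance: high-movement trials cluster around
  zero divergence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import AnalysisError, ValidationError
from .metrics import bin_by_degree
from .stats import RegressionFit, ols_fit

__all__ = [
    "BinnedBounds",
    "LogFit",
    "EnvelopeFit",
    "QuadrantCurve",
    "QuartileSplit",
    "bin_upper_bounds",
    "fit_linear_envelope",
    "fit_log_envelope",
    "fit_envelope",
    "quadrant_curve",
    "quadrant_emptiness",
    "quartile_split_divergence",
]


@dataclass(frozen=True)
class BinnedBounds:
    """Per-error-bin upper confidence bounds of head distance."""

    bin_centers: np.ndarray  # degrees, ascending
    upper_bounds: np.ndarray  # meters
    k_sd: float
    excluded_bins: tuple[float, ...]  # centers dropped for having < 2 points


@dataclass(frozen=True)
class LogFit:
    """Logarithmic envelope h ~ A*log(max + 1 - eps) + B."""

    A: float
    B: float
    r_squared: float
    max_error: float
    n_points: int


@dataclass(frozen=True)
class EnvelopeFit:
    """One confidence level's binned bounds with both regression models."""

    level_label: str
    k_sd: float
    bounds: BinnedBounds
    linear: RegressionFit
    log: LogFit


@dataclass(frozen=True)
class QuadrantCurve:
    """Frontier of closed upper-right quadrants each holding k data points."""

    fraction: float
    k: int
    n_total: int
    eps0: np.ndarray  # degrees, ascending
    h0: np.ndarray  # meters, non-increasing

    @property
    def points(self) -> list[tuple[float, float]]:
        return list(zip(self.eps0.tolist(), self.h0.tolist()))


def bin_upper_bounds(
    eps: np.ndarray,
    h: np.ndarray,
    k_sd: float,
    bin_width: float = 1.0,
) -> BinnedBounds:
    """Upper bound ``mean + k_sd * sample SD`` of h per unsigned-error bin.

    Bins with fewer than two points cannot yield a sample SD and are
    excluded (reported in ``excluded_bins``).  Raises
    :class:`AnalysisError` if no bin has >= 2 points.
    """
    eps = np.asarray(eps, dtype=float)
    h = np.asarray(h, dtype=float)
    if eps.size == 0 or eps.size != h.size:
        raise ValidationError("eps and h must be equal-length, non-empty")
    groups: dict[float, list[float]] = {}
    binned = bin_by_degree(eps, width=bin_width)
    # bin_by_degree partitions values; re-derive membership for h by index
    centers_of = np.floor((eps + bin_width / 2.0) / bin_width) * bin_width
    for c in sorted(binned):
        groups[c] = h[centers_of == c]
    centers, bounds, excluded = [], [], []
    for c, hv in groups.items():
        if len(hv) < 2:
            excluded.append(c)
            continue
        centers.append(c)
        bounds.append(float(np.mean(hv) + k_sd * np.std(hv, ddof=1)))
    if not centers:
        raise AnalysisError("all error bins have < 2 points; no bounds computable")
    return BinnedBounds(
        bin_centers=np.asarray(centers),
        upper_bounds=np.asarray(bounds),
        k_sd=float(k_sd),
        excluded_bins=tuple(excluded),
    )


def fit_linear_envelope(bin_centers, upper_bounds) -> RegressionFit:
    """Unweighted OLS of the binned upper bounds on the bin centers."""
    return ols_fit(np.asarray(bin_centers, float), np.asarray(upper_bounds, float))


def fit_log_envelope(bin_centers, upper_bounds, max_error: float) -> LogFit:
    """OLS of the bounds on ``log(max_error + 1 - eps)`` (natural log).

    Every bin center must be <= ``max_error`` so the log argument stays
    positive (eps = max gives predictor log(1) = 0, still defined).
    """
    centers = np.asarray(bin_centers, dtype=float)
    bounds = np.asarray(upper_bounds, dtype=float)
    if np.any(centers > max_error):
        raise ValidationError(
            f"bin center {centers.max()} exceeds max_error {max_error}: "
            "log argument would be non-positive"
        )
    x = np.log(max_error + 1.0 - centers)
    fit = ols_fit(x, bounds)
    return LogFit(
        A=fit.slope,
        B=fit.intercept,
        r_squared=fit.r_squared,
        max_error=float(max_error),
        n_points=fit.n_points,
    )


def fit_envelope(
    eps,
    h,
    level_label: str,
    k_sd: float,
    bin_width: float = 1.0,
    max_error: float | None = None,
) -> EnvelopeFit:
    """Convenience wrapper: bin, then fit both the linear and log models."""
    eps = np.asarray(eps, dtype=float)
    h = np.asarray(h, dtype=float)
    bounds = bin_upper_bounds(eps, h, k_sd=k_sd, bin_width=bin_width)
    if max_error is None:
        max_error = float(eps.max())
    return EnvelopeFit(
        level_label=level_label,
        k_sd=float(k_sd),
        bounds=bounds,
        linear=fit_linear_envelope(bounds.bin_centers, bounds.upper_bounds),
        log=fit_log_envelope(bounds.bin_centers, bounds.upper_bounds, max_error),
    )


def quadrant_curve(eps, h, fraction: float = 0.05) -> QuadrantCurve:
    """Sweep candidate corners over sorted unique eps values; at each corner
    eps0 the height h0 is the k-th largest h among points with eps >= eps0,
    so the closed quadrant {eps >= eps0, h >= h0} holds exactly k points
    when h values are distinct (with ties: the smallest count >= k).

    k = round(fraction * N), at least 1.  The curve terminates once fewer
    than k points remain to the right; h0 is non-increasing in eps0.
    """
    eps = np.asarray(eps, dtype=float)
    h = np.asarray(h, dtype=float)
    n = eps.size
    if n == 0 or n != h.size:
        raise ValidationError("eps and h must be equal-length, non-empty")
    k = int(round(fraction * n))
    if k < 1:
        raise ValidationError(
            f"fraction {fraction} of N={n} points rounds below one point"
        )
    order = np.argsort(eps, kind="stable")
    eps_sorted = eps[order]
    h_sorted = h[order]
    uniques = np.unique(eps_sorted)
    eps0_list, h0_list = [], []
    for e0 in uniques:
        start = int(np.searchsorted(eps_sorted, e0, side="left"))
        tail = h_sorted[start:]
        if tail.size < k:
            break
        # k-th largest of the tail
        h0 = float(np.partition(tail, tail.size - k)[tail.size - k])
        eps0_list.append(float(e0))
        h0_list.append(h0)
    return QuadrantCurve(
        fraction=float(fraction),
        k=k,
        n_total=n,
        eps0=np.asarray(eps0_list),
        h0=np.asarray(h0_list),
    )


def _frontier_height(frontier, eps: np.ndarray) -> np.ndarray:
    """Evaluate a frontier (QuadrantCurve step function, RegressionFit line,
    LogFit curve, or callable) at each eps."""
    if isinstance(frontier, QuadrantCurve):
        # right-continuous step: height of the corner at the largest eps0 <= eps
        idx = np.searchsorted(frontier.eps0, eps, side="right") - 1
        out = np.full(eps.shape, np.inf)
        valid = idx >= 0
        out[valid] = frontier.h0[idx[valid]]
        return out
    if isinstance(frontier, RegressionFit):
        return frontier.slope * eps + frontier.intercept
    if isinstance(frontier, LogFit):
        return frontier.A * np.log(frontier.max_error + 1.0 - eps) + frontier.B
    if callable(frontier):
        return np.asarray([frontier(e) for e in eps], dtype=float)
    raise ValidationError(f"unsupported frontier type {type(frontier).__name__}")


def quadrant_emptiness(eps, h, frontier) -> float:
    """Fraction of points strictly above the given frontier — the
    sufficiency diagnostic (large movement with large error should be rare)."""
    eps = np.asarray(eps, dtype=float)
    h = np.asarray(h, dtype=float)
    if eps.size == 0:
        return 0.0
    heights = _frontier_height(frontier, eps)
    return float(np.mean(h > heights))


@dataclass(frozen=True)
class QuartileSplit:
    """Divergence statistics above vs at-or-below Q3 of head distance."""

    q3: float  # meters
    n_above: int
    n_below: int
    mean_above: float
    mean_below: float
    sd_above: float
    sd_below: float
    mean_shift_pct: float  # how much closer to zero the above-Q3 mean is
    sd_reduction_pct: float


def quartile_split_divergence(head_distance, divergence) -> QuartileSplit:
    """Split trials at the third quartile of head distance (linear-interpolated
    percentile) and compare head-divergence location and spread.

    ``mean_shift_pct = 100 * (|mean_below| - |mean_above|) / |mean_below|``
    and ``sd_reduction_pct = 100 * (sd_below - sd_above) / sd_below``; both
    positive when high-movement trials are tighter around zero divergence.
    """
    h = np.asarray(head_distance, dtype=float)
    d = np.asarray(divergence, dtype=float)
    if h.size != d.size or h.size < 8:
        raise ValidationError("need >= 8 paired trials")
    q3 = float(np.percentile(h, 75))
    above = d[h > q3]
    below = d[h <= q3]
    if above.size == 0 or below.size == 0:
        raise AnalysisError("degenerate split: one side of Q3 is empty")
    mean_above = float(above.mean())
    mean_below = float(below.mean())
    sd_above = float(above.std(ddof=1)) if above.size > 1 else 0.0
    sd_below = float(below.std(ddof=1)) if below.size > 1 else 0.0
    mean_shift = (
        100.0 * (abs(mean_below) - abs(mean_above)) / abs(mean_below)
        if mean_below != 0.0
        else 0.0
    )
    sd_reduction = (
        100.0 * (sd_below - sd_above) / sd_below if sd_below != 0.0 else 0.0
    )
    return QuartileSplit(
        q3=q3,
        n_above=int(above.size),
        n_below=int(below.size),
        mean_above=mean_above,
        mean_below=mean_below,
        sd_above=sd_above,
        sd_below=sd_below,
        mean_shift_pct=mean_shift,
        sd_reduction_pct=sd_reduction,
    )
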