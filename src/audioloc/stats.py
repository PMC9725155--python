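"""The inferential battery: Levene, (Welch) ANOVA, Welch's t, Spearman,
Bonferroni, post-hoc power, plus the eccentricity and per-participant
correlation analyses.

All tests are two-tailed.  Levene's test uses mean centering by default
(the classical Levene; pass ``center='median'`` for Brown-Forsythe).
Bonferroni family sizes are declared explicitly by the caller — the
adjusted p is ``min(1, m * p)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sps

from .exceptions import AnalysisError, ValidationError
from .metrics import TrialMetrics, metrics_to_frame

__all__ = [
    "StatResult",
    "RegressionFit",
    "levene_test",
    "anova_f",
    "welch_anova",
    "welch_t",
    "spearman",
    "bonferroni",
    "posthoc_power",
    "eccentricity_regression",
    "per_participant_spearman",
    "ParticipantCorrelation",
]


@dataclass(frozen=True)
class StatResult:
    """Outcome of one hypothesis test."""

    test: str  # levene | anova_f | welch_anova | welch_t | spearman
    statistic: float
    dof: tuple[float, ...]
    p_value: float
    p_adjusted: float | None = None
    power: float | None = None


@dataclass(frozen=True)
class RegressionFit:
    """Ordinary least-squares line: slope m, intercept q, coefficient r^2."""

    slope: float
    intercept: float
    r_squared: float
    n_points: int


def _check_samples(samples: Sequence[np.ndarray], min_size: int = 2) -> list[np.ndarray]:
    if len(samples) < 2:
        raise ValidationError("need at least two samples")
    arrays = [np.asarray(s, dtype=float) for s in samples]
    for i, a in enumerate(arrays):
        if a.size < min_size:
            raise ValidationError(f"sample {i} has {a.size} values; need >= {min_size}")
    return arrays


def levene_test(samples: Sequence[Sequence[float]], center: str = "mean") -> StatResult:
    """Levene's homogeneity-of-variance test (W statistic, F reference).

    Identical samples give W = 0, p = 1.
    """
    arrays = _check_samples(samples)
    w, p = sps.levene(*arrays, center=center)
    k = len(arrays)
    n = sum(a.size for a in arrays)
    if not np.isfinite(w):  # all spread measures zero -> no variance anywhere
        w, p = 0.0, 1.0
    return StatResult("levene", float(w), (float(k - 1), float(n - k)), float(p))


def anova_f(samples: Sequence[Sequence[float]]) -> StatResult:
    """Classical one-way ANOVA F-test (assumes equal variances)."""
    arrays = _check_samples(samples)
    f, p = sps.f_oneway(*arrays)
    k = len(arrays)
    n = sum(a.size for a in arrays)
    if not np.isfinite(f):
        f, p = 0.0, 1.0
    return StatResult("anova_f", float(f), (float(k - 1), float(n - k)), float(p))


def welch_anova(samples: Sequence[Sequence[float]]) -> StatResult:
    """One-way Welch ANOVA (heteroscedasticity-robust); for two groups the
    F statistic equals Welch's t squared."""
    arrays = _check_samples(samples)
    df = pd.DataFrame(
        {
            "y": np.concatenate(arrays),
            "g": np.repeat(np.arange(len(arrays)), [a.size for a in arrays]),
        }
    )
    res = pg.welch_anova(data=df, dv="y", between="g")
    f = float(res.at[0, "F"])
    p_col = "p_unc" if "p_unc" in res.columns else "p-unc"
    p = float(res.at[0, p_col])
    if not np.isfinite(f):
        f, p = 0.0, 1.0
    return StatResult(
        "welch_anova", f, (float(res.at[0, "ddof1"]), float(res.at[0, "ddof2"])), p
    )


def welch_t(sample_a: Sequence[float], sample_b: Sequence[float]) -> StatResult:
    """Welch's two-sample t-test with Welch-Satterthwaite degrees of freedom."""
    a, b = _check_samples([sample_a, sample_b])
    res = sps.ttest_ind(a, b, equal_var=False)
    t, p, dof = float(res.statistic), float(res.pvalue), float(res.df)
    if not np.isfinite(t):
        t, p = 0.0, 1.0
    return StatResult("welch_t", t, (dof,), p)


def spearman(x: Sequence[float], y: Sequence[float]) -> StatResult:
    """Spearman rank correlation (ties average-ranked), two-tailed p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValidationError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 3:
        raise ValidationError("need at least 3 pairs")
    rho, p = sps.spearmanr(x, y)
    return StatResult("spearman", float(rho), (float(x.size - 2),), float(p))


def bonferroni(p_values: Sequence[float], m: int) -> list[float]:
    """Bonferroni adjustment with an explicitly declared family size ``m``:
    each adjusted p is ``min(1, m * p)``."""
    p_values = list(p_values)
    if m < len(p_values):
        raise ValidationError(
            f"family size m={m} smaller than the {len(p_values)} comparisons"
        )
    return [min(1.0, m * float(p)) for p in p_values]


def posthoc_power(
    result: StatResult,
    sizes: Sequence[int],
    effect: float,
    alpha: float = 0.05,
) -> float:
    """Post-hoc power from the noncentral t/F distribution.

    For a two-sample design (``welch_t`` / two-group ANOVA), ``effect`` is
    Cohen's d and the noncentrality is ``d * sqrt(n1*n2/(n1+n2))``.  For a
    one-way design, ``effect`` is Cohen's f and the noncentrality is
    ``f^2 * N``.  At zero effect the power equals ``alpha`` by construction.
    """
    sizes = [int(n) for n in sizes]
    if result.test == "welch_t" or (result.test in ("anova_f", "welch_anova") and len(sizes) == 2):
        if len(sizes) != 2:
            raise NotImplementedError("two-sample power needs exactly two sizes")
        n1, n2 = sizes
        dof = result.dof[-1] if result.test != "welch_t" else result.dof[0]
        ncp = abs(effect) * np.sqrt(n1 * n2 / (n1 + n2))
        t_crit = sps.t.ppf(1 - alpha / 2, dof)
        power = (1 - sps.nct.cdf(t_crit, dof, ncp)) + sps.nct.cdf(-t_crit, dof, ncp)
        return float(power)
    if result.test in ("anova_f", "welch_anova"):
        k = len(sizes)
        n = sum(sizes)
        df1, df2 = result.dof
        ncp = effect**2 * n
        f_crit = sps.f.ppf(1 - alpha, df1, df2)
        return float(1 - sps.ncf.cdf(f_crit, df1, df2, ncp))
    raise NotImplementedError(f"power not implemented for test {result.test!r}")


def with_power(result: StatResult, sizes: Sequence[int], effect: float, alpha: float = 0.05) -> StatResult:
    """Return a copy of ``result`` with its post-hoc power filled in."""
    return replace(result, power=posthoc_power(result, sizes, effect, alpha=alpha))


def ols_fit(x: Sequence[float], y: Sequence[float]) -> RegressionFit:
    """Unweighted OLS line with the zero-variance convention r^2 = 0."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValidationError("need at least 3 points for a regression")
    if np.ptp(y) == 0.0:
        return RegressionFit(0.0, float(y[0]), 0.0, int(x.size))
    res = sps.linregress(x, y)
    return RegressionFit(
        float(res.slope), float(res.intercept), float(res.rvalue**2), int(x.size)
    )


def eccentricity_regression(
    metrics: Sequence[TrialMetrics],
    measure: str,
    condition: str,
    exclude_outliers: bool = True,
) -> RegressionFit:
    """OLS of per-target-location means of ``measure`` against target azimuth.

    The regression is fitted ON THE MEANS (one point per azimuth, up to 13),
    not on raw trials.  Requires data at >= 3 distinct locations.
    """
    df = metrics_to_frame(list(metrics))
    df = df[df["condition"] == condition]
    if exclude_outliers:
        df = df[~df["is_outlier"]]
    if measure not in df.columns:
        raise ValidationError(f"unknown measure {measure!r}")
    means = df.groupby("target_az")[measure].mean()
    if len(means) < 3:
        raise ValidationError(
            f"only {len(means)} target locations with data; need >= 3"
        )
    return ols_fit(means.index.to_numpy(), means.to_numpy())


@dataclass(frozen=True)
class ParticipantCorrelation:
    """Per-participant divergence-vs-signed-error association."""

    participant_id: str
    rho: float
    p_value: float
    significant: bool
    n: int
    mean_signed_error: float
    mean_unsigned_error: float


def per_participant_spearman(
    metrics: Sequence[TrialMetrics],
    alpha: float = 0.05,
    exclude_outliers: bool = True,
) -> list[ParticipantCorrelation]:
    """Spearman of head divergence vs signed error, one result per participant.

    Participants with fewer than 3 usable trials are skipped.  Results are
    sorted by rho ascending, matching the usual presentation of
    per-individual correlation profiles.
    """
    df = metrics_to_frame(list(metrics))
    if exclude_outliers:
        df = df[~df["is_outlier"]]
    out = []
    for pid, g in df.groupby("participant_id"):
        if len(g) < 3:
            continue
        res = spearman(g["head_divergence"].to_numpy(), g["signed_error"].to_numpy())
        out.append(
            ParticipantCorrelation(
                participant_id=str(pid),
                rho=res.statistic,
                p_value=res.p_value,
                significant=res.p_value < alpha,
                n=len(g),
                mean_signed_error=float(g["signed_error"].mean()),
                mean_unsigned_error=float(g["unsigned_error"].mean()),
            )
        )
    out.sort(key=lambda r: r.rho)
    return out
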