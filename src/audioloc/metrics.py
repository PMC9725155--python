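"""Per-trial response measures and the 2-SD outlier filter.

Signed error follows the rightward-positive convention: it is
``pointed - target`` wrapped to (-180, 180], so a positive value means the
response fell to the right of the source.  Unsigned error (epsilon) is its
absolute value and is the accuracy measure; it is analyzed in 1-degree bins
because the pointer resolution is 1 degree.

Outliers are trials whose unsigned error exceeds mean + k*SD (default k=2,
sample SD) within a stratum.  Strata are per target location; by default
each condition is pooled separately across participants so the tighter R
errors are not mixed with the wider V errors.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from . import kinematics
from .io import HeadTrajectory, TrialRecord

__all__ = [
    "TrialMetrics",
    "GroupSummary",
    "signed_error",
    "unsigned_error",
    "compute_metrics",
    "flag_outliers",
    "summarize",
    "bin_by_degree",
    "metrics_to_frame",
]


@dataclass(frozen=True)
class TrialMetrics:
    """Derived measures for one trial."""

    trial_id: str
    participant_id: str
    group: str
    condition: str
    target_az: float
    signed_error: float
    unsigned_error: float
    latency: float
    head_divergence: float
    head_distance: float
    is_outlier: bool = False


@dataclass(frozen=True)
class GroupSummary:
    """Mean/SD of one measure within a (group, condition) cell."""

    group: str
    condition: str
    n: int
    mean: float
    sd: float


def signed_error(target_az: float, pointed_az: float) -> float:
    """Directed error ``pointed - target``, wrapped to (-180, 180] degrees.

    Positive values are rightward response shifts under the package's
    rightward-positive azimuth convention.
    """
    return kinematics.wrap_angle(float(pointed_az) - float(target_az))


def unsigned_error(signed: float) -> float:
    """Absolute localization error in degrees."""
    return abs(float(signed))


def compute_metrics(
    records: Sequence[TrialRecord],
    trajectories: Mapping[str, HeadTrajectory],
) -> list[TrialMetrics]:
    """Join trial records with their trajectories and derive all measures.

    Raises :class:`ValidationError` naming the trial if its trajectory is
    missing.  Outlier flags are left False; run :func:`flag_outliers` next.
    """
    out: list[TrialMetrics] = []
    for rec in records:
        traj = trajectories.get(rec.trajectory_ref)
        if traj is None:
            raise ValidationError(
                f"trial {rec.trial_id}: no trajectory with id {rec.trajectory_ref!r}"
            )
        s_err = signed_error(rec.target_az, rec.pointed_az)
        yaw_hit = kinematics.yaw_at_hit(traj, rec.t_hit)
        out.append(
            TrialMetrics(
                trial_id=rec.trial_id,
                participant_id=rec.participant_id,
                group=rec.group,
                condition=rec.condition,
                target_az=rec.target_az,
                signed_error=s_err,
                unsigned_error=unsigned_error(s_err),
                latency=rec.t_hit - rec.t_onset,
                head_divergence=kinematics.head_divergence(rec.target_az, yaw_hit),
                head_distance=kinematics.head_distance(traj, rec.t_onset, rec.t_hit),
            )
        )
    return out


def metrics_to_frame(metrics: Sequence[TrialMetrics]) -> pd.DataFrame:
    from .io import METRICS_COLUMNS  # local import to avoid cycle at module load

    return pd.DataFrame([vars(m) for m in metrics], columns=METRICS_COLUMNS)


def _stratum_key(m: TrialMetrics, strata: str):
    if strata == "per_condition":
        return (m.target_az, m.condition)
    if strata == "fully_pooled":
        return (m.target_az,)
    if strata == "per_participant":
        return (m.target_az, m.condition, m.participant_id)
    raise ValidationError(f"unknown outlier strata {strata!r}")


def flag_outliers(
    metrics: Sequence[TrialMetrics],
    k: float = 2.0,
    strata: str = "per_condition",
) -> list[TrialMetrics]:
    """Flag trials with unsigned error strictly above mean + k*SD per stratum.

    A single pass: the threshold is computed once from all trials in the
    stratum (sample SD, ddof=1) and flags are set without deleting records —
    exclusion is the caller's choice.  Strata with fewer than two trials get
    a warning and no flags.
    """
    groups: dict = defaultdict(list)
    for i, m in enumerate(metrics):
        groups[_stratum_key(m, strata)].append(i)
    flagged = np.zeros(len(metrics), dtype=bool)
    for key, idx in groups.items():
        if len(idx) < 2:
            warnings.warn(
                f"outlier stratum {key} has {len(idx)} trial(s); no flags set",
                stacklevel=2,
            )
            continue
        errs = np.array([metrics[i].unsigned_error for i in idx])
        threshold = errs.mean() + k * errs.std(ddof=1)
        for i in idx:
            if metrics[i].unsigned_error > threshold:
                flagged[i] = True
    return [
        replace(m, is_outlier=bool(f)) if bool(f) != m.is_outlier else m
        for m, f in zip(metrics, flagged)
    ]


def summarize(
    metrics: Sequence[TrialMetrics],
    measure: str,
    by: Sequence[str] = ("group", "condition"),
    exclude_outliers: bool = True,
) -> list[GroupSummary]:
    """Mean and sample SD of ``measure`` per grouping cell.

    Cells with a single trial report sd = 0 with a warning.  Outliers are
    excluded by default.
    """
    if not metrics:
        raise ValidationError("no metrics to summarize")
    if measure not in vars(metrics[0]):
        raise ValidationError(f"unknown measure {measure!r}")
    df = metrics_to_frame(list(metrics))
    if exclude_outliers:
        df = df[~df["is_outlier"]]
    out: list[GroupSummary] = []
    for key, g in df.groupby(list(by), sort=True):
        key = key if isinstance(key, tuple) else (key,)
        cell = dict(zip(by, key))
        vals = g[measure].to_numpy(dtype=float)
        if len(vals) == 1:
            warnings.warn(
                f"cell {cell} has a single trial; reporting sd=0", stacklevel=2
            )
            sd = 0.0
        else:
            sd = float(vals.std(ddof=1))
        out.append(
            GroupSummary(
                group=str(cell.get("group", "")),
                condition=str(cell.get("condition", "")),
                n=len(vals),
                mean=float(vals.mean()),
                sd=sd,
            )
        )
    return out


def bin_by_degree(
    values: Iterable[float], width: float = 1.0
) -> dict[float, list[float]]:
    """Partition values into half-open bins [c - w/2, c + w/2) centered on
    integer multiples of ``width``.

    Every value lands in exactly one bin; empty input yields an empty map.
    """
    if width <= 0:
        raise ValidationError("bin width must be positive")
    bins: dict[float, list[float]] = defaultdict(list)
    for v in values:
        center = float(np.floor((float(v) + width / 2.0) / width)) * width
        bins[center].append(float(v))
    return dict(bins)
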