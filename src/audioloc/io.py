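"""Trial-log and trajectory I/O, plus the study-wide configuration object.

Conventions used throughout the package
---------------------------------------
* Coordinate frame: right-handed, ``y`` up, the listener sits at the origin
  facing ``-z`` at trial start.  Azimuth is measured in the horizontal
  (``x``-``z``) plane, 0 deg straight ahead, **positive to the listener's
  right**, range (-180, 180].
* Quaternions are stored scalar-first ``(w, x, y, z)`` and must be unit norm.
* Timestamps are seconds from session start, as floats.
* All delimited files are comma-separated UTF-8 with a header row;
  trajectories are long-format keyed by ``trial_id``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .exceptions import FormatError, ValidationError

GROUPS = ("G_R", "G_V")
CONDITIONS = ("R", "V")

#: The 13 loudspeaker azimuths: -90 deg ... +90 deg in 15 deg steps.
DEFAULT_AZIMUTHS: tuple[float, ...] = tuple(float(a) for a in range(-90, 91, 15))

TRIAL_COLUMNS = (
    "trial_id",
    "participant_id",
    "group",
    "condition",
    "target_az",
    "pointed_az",
    "t_onset",
    "t_hit",
    "trajectory_ref",
)

TRAJECTORY_COLUMNS = ("trial_id", "t", "x", "y", "z", "qw", "qx", "qy", "qz")

#: Quaternion norms within this distance of 1 are renormalized; beyond, rejected.
QUAT_NORM_TOL = 1e-3


@dataclass(frozen=True)
class TrialRecord:
    """One localization trial: who, what condition, target, response, timing."""

    trial_id: str
    participant_id: str
    group: str
    condition: str
    target_az: float
    pointed_az: int
    t_onset: float
    t_hit: float
    trajectory_ref: str

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValidationError(f"unknown group {self.group!r}, expected one of {GROUPS}")
        if self.condition not in CONDITIONS:
            raise ValidationError(
                f"unknown condition {self.condition!r}, expected one of {CONDITIONS}"
            )
        if self.t_hit <= self.t_onset:
            raise ValidationError(
                f"trial {self.trial_id}: t_hit ({self.t_hit}) must exceed t_onset ({self.t_onset})"
            )

    @property
    def latency(self) -> float:
        return self.t_hit - self.t_onset


@dataclass
class HeadTrajectory:
    """Timestamped head pose samples for one trial.

    ``t`` is shape ``(n,)``, ``pos`` is ``(n, 3)`` meters, ``quat`` is
    ``(n, 4)`` scalar-first unit quaternions.
    """

    t: np.ndarray
    pos: np.ndarray
    quat: np.ndarray
    nominal_rate: float = 10.0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.pos = np.asarray(self.pos, dtype=float).reshape(-1, 3)
        self.quat = np.asarray(self.quat, dtype=float).reshape(-1, 4)
        if not (len(self.t) == len(self.pos) == len(self.quat)):
            raise ValidationError("trajectory arrays must have equal lengths")
        if len(self.t) > 1 and not np.all(np.diff(self.t) > 0):
            raise ValidationError("trajectory timestamps must be strictly increasing")
        if len(self.quat):
            norms = np.linalg.norm(self.quat, axis=1)
            bad = np.abs(norms - 1.0) > QUAT_NORM_TOL
            if bad.any():
                i = int(np.argmax(bad))
                raise ValidationError(
                    f"quaternion at sample {i} has norm {norms[i]:.6f}, "
                    f"beyond the {QUAT_NORM_TOL} renormalization tolerance"
                )
            self.quat = self.quat / norms[:, None]

    def __len__(self) -> int:
        return len(self.t)


@dataclass
class StudyConfig:
    """Analysis parameters shared across the pipeline.

    ``envelope_levels`` maps a display label to the SD multiplier used for
    the binned upper confidence bound: 1.96 for the two-sided 95% normal
    interval, 3.0 for 99.7% ("three SDs above the mean").
    """

    azimuth_set: tuple[float, ...] = DEFAULT_AZIMUTHS
    reps_per_target: int = 5
    bin_width: float = 1.0
    outlier_k: float = 2.0
    outlier_strata: str = "per_condition"  # per_condition | fully_pooled | per_participant
    envelope_levels: tuple[tuple[str, float], ...] = (("95", 1.96), ("99.7", 3.0))
    quadrant_fraction: float = 0.05
    alpha: float = 0.05
    #: Bonferroni family size; None means "size of each emitted comparison
    #: family" (recorded per row in the stats table)
    bonferroni_m: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.azimuth_set = tuple(float(a) for a in self.azimuth_set)
        self.envelope_levels = tuple((str(k), float(v)) for k, v in self.envelope_levels)
        if self.bin_width <= 0:
            raise ValidationError("bin_width must be positive")
        if self.outlier_k <= 0:
            raise ValidationError("outlier_k must be positive")
        if not 0 < self.quadrant_fraction < 1:
            raise ValidationError("quadrant_fraction must lie in (0, 1)")
        if self.outlier_strata not in ("per_condition", "fully_pooled", "per_participant"):
            raise ValidationError(f"unknown outlier_strata {self.outlier_strata!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        if "envelope_levels" in raw:
            raw["envelope_levels"] = tuple(
                (str(k), float(v)) for k, v in dict(raw["envelope_levels"]).items()
            )
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["azimuth_set"] = list(self.azimuth_set)
        d["envelope_levels"] = [list(kv) for kv in self.envelope_levels]
        return d

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _require_columns(df: pd.DataFrame, required: Sequence[str], path: str | Path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")


def read_trial_log(
    path: str | Path,
    azimuth_set: Iterable[float] = DEFAULT_AZIMUTHS,
) -> list[TrialRecord]:
    """Read a trial-log CSV into validated :class:`TrialRecord` objects.

    Row order is preserved.  Target azimuths are checked against
    ``azimuth_set`` and ``t_hit > t_onset`` is enforced, with the offending
    1-based data-row number in the error message.
    """
    df = pd.read_csv(path)
    _require_columns(df, TRIAL_COLUMNS, path)
    grid = {float(a) for a in azimuth_set}
    records: list[TrialRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        target = float(row.target_az)
        if target not in grid:
            raise ValidationError(
                f"{path}: row {i}: target_az {target} not in the azimuth grid"
            )
        if float(row.t_hit) <= float(row.t_onset):
            raise ValidationError(
                f"{path}: row {i}: t_hit ({row.t_hit}) must exceed t_onset ({row.t_onset})"
            )
        records.append(
            TrialRecord(
                trial_id=str(row.trial_id),
                participant_id=str(row.participant_id),
                group=str(row.group),
                condition=str(row.condition),
                target_az=target,
                pointed_az=int(row.pointed_az),
                t_onset=float(row.t_onset),
                t_hit=float(row.t_hit),
                trajectory_ref=str(row.trajectory_ref),
            )
        )
    return records


def write_trial_log(records: Sequence[TrialRecord], path: str | Path) -> Path:
    """Write trial records as CSV (inverse of :func:`read_trial_log`)."""
    df = pd.DataFrame([dataclasses.asdict(r) for r in records], columns=TRIAL_COLUMNS)
    df.to_csv(path, index=False)
    return Path(path)


def read_trajectories(path: str | Path) -> dict[str, HeadTrajectory]:
    """Read a long-format trajectory CSV into a map ``trial_id -> HeadTrajectory``.

    Samples are grouped by ``trial_id`` and sorted by ``t``.  Quaternions
    whose norm deviates from 1 by at most 1e-3 are renormalized; larger
    deviations raise :class:`ValidationError`, as do duplicated timestamps
    within a trial.
    """
    df = pd.read_csv(path)
    _require_columns(df, TRAJECTORY_COLUMNS, path)
    out: dict[str, HeadTrajectory] = {}
    for trial_id, g in df.groupby("trial_id", sort=False):
        g = g.sort_values("t", kind="stable")
        try:
            out[str(trial_id)] = HeadTrajectory(
                t=g["t"].to_numpy(),
                pos=g[["x", "y", "z"]].to_numpy(),
                quat=g[["qw", "qx", "qy", "qz"]].to_numpy(),
            )
        except ValidationError as err:
            raise ValidationError(f"{path}: trial {trial_id}: {err}") from err
    return out


def write_trajectories(trajectories: Mapping[str, HeadTrajectory], path: str | Path) -> Path:
    """Write trajectories in long format (inverse of :func:`read_trajectories`)."""
    frames = []
    for trial_id, traj in trajectories.items():
        frames.append(
            pd.DataFrame(
                {
                    "trial_id": trial_id,
                    "t": traj.t,
                    "x": traj.pos[:, 0],
                    "y": traj.pos[:, 1],
                    "z": traj.pos[:, 2],
                    "qw": traj.quat[:, 0],
                    "qx": traj.quat[:, 1],
                    "qy": traj.quat[:, 2],
                    "qz": traj.quat[:, 3],
                }
            )
        )
    df = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=TRAJECTORY_COLUMNS)
    )
    df.to_csv(path, index=False, float_format="%.12g")
    return Path(path)


METRICS_COLUMNS = (
    "trial_id",
    "participant_id",
    "group",
    "condition",
    "target_az",
    "signed_error",
    "unsigned_error",
    "latency",
    "head_divergence",
    "head_distance",
    "is_outlier",
)


def write_metrics_table(metrics, path: str | Path) -> Path:
    """Write per-trial metrics as CSV; outlier flags become a 0/1 column.

    Accepts a list of :class:`~audioloc.metrics.TrialMetrics` or a DataFrame
    with the same columns.  Round-trips with :func:`read_metrics_table` at
    1e-9 numeric tolerance.
    """
    if isinstance(metrics, pd.DataFrame):
        df = metrics.copy()
    else:
        df = pd.DataFrame([dataclasses.asdict(m) for m in metrics], columns=METRICS_COLUMNS)
    if "is_outlier" in df.columns and len(df):
        df["is_outlier"] = df["is_outlier"].astype(int)
    df.to_csv(path, index=False, float_format="%.12g", columns=list(METRICS_COLUMNS))
    return Path(path)


def read_metrics_table(path: str | Path) -> pd.DataFrame:
    """Read a metrics CSV back into a DataFrame with boolean outlier flags."""
    df = pd.read_csv(path)
    _require_columns(df, METRICS_COLUMNS, path)
    df["is_outlier"] = df["is_outlier"].astype(bool)
    for col in ("trial_id", "participant_id", "group", "condition"):
        df[col] = df[col].astype(str)
    return df
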