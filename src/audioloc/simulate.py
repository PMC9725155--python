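"""Synthetic localization sessions with the statistical structure of a
frontal-hemifield VR pointing study.

The generator emulates, per trial: a rightward response bias of ~1-2.5 deg
depending on group and condition, an eccentricity undershoot (responses
compressed toward the midline by a fixed proportion of the target azimuth),
lognormal response latencies, and a two-strategy head-movement mixture:

* **static** trials (probability ``1 - p_dynamic``): the head orients only
  loosely toward the target (final divergence SD ~21 deg), rotates about
  its own axis, and translates only by small smoothed postural sway;
* **dynamic** trials: an active search — the head sweeps an arc on a neck
  pivot of ~9 cm with a decaying scanning oscillation, ends tightly on
  target (divergence SD ~8 deg), and the response error is small.

Because only dynamic trials combine large head path length with small
error, the pooled (error, head-distance) scatter is triangular: large
movement co-occurs only with accurate responses, while accurate responses
also arise without movement — movement is sufficient, not necessary.

All randomness flows through one ``numpy.random.Generator`` seeded from
``SimConfig.seed``, so a fixed seed gives bitwise-identical output.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .exceptions import ValidationError
from .io import (
    DEFAULT_AZIMUTHS,
    HeadTrajectory,
    TrialRecord,
    write_trajectories,
    write_trial_log,
)

__all__ = ["SimConfig", "generate_trial", "generate_dataset", "write_fixture"]


@dataclass
class SimConfig:
    """Parameters of the synthetic behavioral model.

    Defaults reproduce the study conditions: 37 participants split 17/20
    into the R-first and V-first order groups, 13 targets from -90 to
    +90 deg in 15 deg steps, 5 repetitions per target per condition
    (65 trials per condition, 4810 trials in total), 10 Hz head tracking.
    """

    n_participants: int = 37
    n_group_r: int | None = None  # R-first group size; default 17/37 of n
    azimuths: tuple[float, ...] = DEFAULT_AZIMUTHS
    reps: int = 5
    #: mean signed error (deg) per (group, condition); rightward positive
    rightward_bias: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: {
            ("G_R", "R"): 1.9,
            ("G_R", "V"): 2.5,
            ("G_V", "R"): 1.7,
            ("G_V", "V"): 0.6,
        }
    )
    #: proportional compression of responses toward the midline
    undershoot_slope: float = 0.03
    #: response noise SD (deg) per condition for static trials
    base_error_sd: Mapping[str, float] = field(
        default_factory=lambda: {"R": 2.8, "V": 4.9}
    )
    #: probability of an active head search; scalar or per-condition map
    p_dynamic: float | Mapping[str, float] = 0.3
    dynamic_error_sd: float = 1.5
    divergence_sd_static: float = 21.0
    divergence_sd_dynamic: float = 8.0
    pivot_radius: float = 0.09  # m, neck-pivot translation arm
    jitter_sd: float = 0.002  # m, SD of smoothed postural sway per axis
    search_amplitude: float = 30.0  # deg, max scanning oscillation amplitude
    #: (mu_log, sigma_log) of the lognormal latency per condition;
    #: defaults give mean latencies ~3.2 s (R) and ~4.0 s (V)
    latency_lognormal: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"R": (1.102, 0.35), "V": (1.325, 0.35)}
    )
    sample_rate: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.azimuths = tuple(float(a) for a in self.azimuths)
        if self.n_participants < 1 or self.reps < 1:
            raise ValidationError("n_participants and reps must be positive")
        if any(abs(a) > 90 for a in self.azimuths):
            raise ValidationError("azimuths must lie in the frontal hemifield")
        for p in self._p_dynamic_map().values():
            if not 0 <= p <= 1:
                raise ValidationError("p_dynamic must be a probability")
        for sd in (
            self.dynamic_error_sd,
            self.divergence_sd_static,
            self.divergence_sd_dynamic,
            self.jitter_sd,
        ):
            if sd < 0:
                raise ValidationError("noise SDs must be non-negative")
        if self.n_group_r is None:
            self.n_group_r = int(round(self.n_participants * 17 / 37))
        if not 0 <= self.n_group_r <= self.n_participants:
            raise ValidationError("n_group_r out of range")

    def _p_dynamic_map(self) -> dict[str, float]:
        if isinstance(self.p_dynamic, Mapping):
            return {c: float(self.p_dynamic[c]) for c in ("R", "V")}
        return {"R": float(self.p_dynamic), "V": float(self.p_dynamic)}

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["azimuths"] = list(self.azimuths)
        d["rightward_bias"] = {f"{g},{c}": v for (g, c), v in self.rightward_bias.items()}
        d["p_dynamic"] = (
            dict(self.p_dynamic) if isinstance(self.p_dynamic, Mapping) else self.p_dynamic
        )
        d["base_error_sd"] = dict(self.base_error_sd)
        d["latency_lognormal"] = {k: list(v) for k, v in self.latency_lognormal.items()}
        return d


def _yaw_to_quat(yaw_deg: np.ndarray) -> np.ndarray:
    """Scalar-first quaternions for pure yaw rotations (rightward positive).

    A rightward yaw is a negative right-hand rotation about the +y axis.
    """
    half = np.radians(-np.asarray(yaw_deg)) / 2.0
    q = np.zeros((len(half), 4))
    q[:, 0] = np.cos(half)
    q[:, 2] = np.sin(half)
    return q


def _smoothed_sway(n: int, sd: float, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Low-frequency positional sway: white noise moving-averaged over ~0.5 s,
    scaled so the per-axis marginal SD equals ``sd``."""
    if sd == 0 or n == 0:
        return np.zeros((n, 3))
    w = max(1, int(round(0.5 * rate)))
    white = rng.normal(0.0, sd * np.sqrt(w), size=(n + w - 1, 3))
    kernel = np.ones(w) / w
    return np.column_stack(
        [np.convolve(white[:, i], kernel, mode="valid") for i in range(3)]
    )


def generate_trial(
    cfg: SimConfig,
    participant_id: str,
    group: str,
    condition: str,
    target_az: float,
    t_onset: float,
    trial_id: str,
    rng: np.random.Generator,
) -> tuple[TrialRecord, HeadTrajectory, dict]:
    """Simulate one trial; returns the record, its trajectory, and the
    ground-truth draws (strategy, divergence, latency, ...) for recovery
    tests."""
    dynamic = bool(rng.random() < cfg._p_dynamic_map()[condition])
    mu_log, sd_log = cfg.latency_lognormal[condition]
    latency = float(np.clip(rng.lognormal(mu_log, sd_log), 0.5, 20.0))

    div_sd = cfg.divergence_sd_dynamic if dynamic else cfg.divergence_sd_static
    divergence = float(rng.normal(0.0, div_sd))
    final_yaw = target_az - divergence

    dt = 1.0 / cfg.sample_rate
    t_rel = np.arange(0.0, latency, dt)
    if latency - t_rel[-1] > 1e-9:
        t_rel = np.append(t_rel, latency)

    tau = float(rng.uniform(0.3, 1.0))
    approach = (1.0 - np.exp(-t_rel / tau)) / (1.0 - np.exp(-latency / tau))
    yaw = final_yaw * approach
    if dynamic and cfg.search_amplitude > 0:
        amp = float(rng.uniform(0.0, cfg.search_amplitude))
        freq = float(rng.uniform(0.3, 0.8))
        phase = float(rng.uniform(0.0, 2.0 * np.pi))
        yaw = yaw + amp * np.sin(2 * np.pi * freq * t_rel + phase) * (1.0 - t_rel / latency)

    if dynamic and cfg.pivot_radius > 0:
        # head sweeps an arc about a vertical neck axis; origin at trial start
        phi = np.radians(yaw)
        pos = cfg.pivot_radius * np.column_stack(
            [np.sin(phi), np.zeros_like(phi), 1.0 - np.cos(phi)]
        )
        pos[:, 2] *= -1.0  # arc bulges forward (toward -z)
    else:
        pos = np.zeros((len(t_rel), 3))
    pos = pos + _smoothed_sway(len(t_rel), cfg.jitter_sd, cfg.sample_rate, rng)
    pos = pos - pos[0]  # trial starts at the origin

    err_sd = cfg.dynamic_error_sd if dynamic else cfg.base_error_sd[condition]
    bias = float(cfg.rightward_bias[(group, condition)])
    pointed = (
        target_az * (1.0 - cfg.undershoot_slope) + bias + float(rng.normal(0.0, err_sd))
    )
    pointed_az = int(np.clip(np.rint(pointed), -179, 180))

    record = TrialRecord(
        trial_id=trial_id,
        participant_id=participant_id,
        group=group,
        condition=condition,
        target_az=float(target_az),
        pointed_az=pointed_az,
        t_onset=t_onset,
        t_hit=t_onset + latency,
        trajectory_ref=trial_id,
    )
    traj = HeadTrajectory(
        t=t_onset + t_rel, pos=pos, quat=_yaw_to_quat(yaw), nominal_rate=cfg.sample_rate
    )
    truth = {
        "trial_id": trial_id,
        "dynamic": dynamic,
        "divergence": divergence,
        "latency": latency,
        "tau": tau,
        "error_sd": float(err_sd),
        "bias": bias,
    }
    return record, traj, truth


def generate_dataset(
    cfg: SimConfig,
) -> tuple[list[TrialRecord], dict[str, HeadTrajectory], dict]:
    """Simulate a full study: every participant completes one randomly
    balanced block of ``len(azimuths) * reps`` trials per condition, in the
    order dictated by their group (G_R: R then V; G_V: V then R).

    Returns the trial records, the trajectory map, and a truth record with
    the configuration and all per-trial generating draws.
    """
    rng = np.random.default_rng(cfg.seed)
    groups = ["G_R"] * cfg.n_group_r + ["G_V"] * (cfg.n_participants - cfg.n_group_r)
    rng.shuffle(groups)

    records: list[TrialRecord] = []
    trajectories: dict[str, HeadTrajectory] = {}
    truths: list[dict] = []
    width = max(2, len(str(cfg.n_participants)))
    for p_index, group in enumerate(groups):
        pid = f"P{p_index + 1:0{width}d}"
        order = ("R", "V") if group == "G_R" else ("V", "R")
        t_cursor = 0.0
        for condition in order:
            targets = np.repeat(cfg.azimuths, cfg.reps).astype(float)
            rng.shuffle(targets)
            for j, target in enumerate(targets):
                trial_id = f"{pid}_{condition}_{j + 1:03d}"
                rec, traj, truth = generate_trial(
                    cfg, pid, group, condition, float(target), t_cursor, trial_id, rng
                )
                records.append(rec)
                trajectories[trial_id] = traj
                truths.append(truth)
                t_cursor = rec.t_hit + 1.0  # one second of silence between trials
    truth_record = {"config": cfg.to_dict(), "trials": truths}
    return records, trajectories, truth_record


def write_fixture(cfg: SimConfig, outdir: str | Path) -> dict[str, Path]:
    """Serialize a generated dataset as trials.csv + trajectories.csv +
    truth.json under ``outdir``; round-trips through the readers."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records, trajectories, truth = generate_dataset(cfg)
    paths = {
        "trials": write_trial_log(records, outdir / "trials.csv"),
        "trajectories": write_trajectories(trajectories, outdir / "trajectories.csv"),
        "truth": outdir / "truth.json",
    }
    with open(paths["truth"], "w", encoding="utf-8") as fh:
        json.dump(truth, fh, indent=1)
    return paths
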