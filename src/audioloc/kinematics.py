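"""Head-movement measures derived from tracking trajectories.

Two quantities summarize head behavior during a trial:

* **head divergence** — the circular difference between the target azimuth
  and the head's horizontal orientation (yaw) at the moment of response;
  0 deg means the head points exactly at the source.
* **head distance** — the cumulative translational path length of the head
  (meters) between stimulus onset and response, the dynamism measure.

Yaw is extracted by rotating the frame's forward unit vector (0, 0, -1) by
the orientation quaternion and projecting onto the horizontal plane, rather
than by Euler decomposition, which avoids Euler-order ambiguity.  Positive
yaw is to the listener's right.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation

from .exceptions import DegenerateOrientationError, ValidationError
from .io import HeadTrajectory

FORWARD = np.array([0.0, 0.0, -1.0])

_HORIZONTAL_EPS = 1e-9


def wrap_angle(angle_deg: float) -> float:
    """Wrap an angle in degrees into the interval (-180, 180]."""
    wrapped = (float(angle_deg) + 180.0) % 360.0 - 180.0
    if wrapped == -180.0:
        wrapped = 180.0
    return wrapped


def quaternion_to_yaw(quat: np.ndarray) -> float:
    """Yaw (degrees, rightward positive) of a scalar-first unit quaternion.

    The forward vector is rotated by ``quat`` and projected onto the x-z
    plane; the signed angle from straight ahead is returned.  If the head
    points (numerically) straight up or down the projection vanishes and a
    :class:`DegenerateOrientationError` is raised — callers may carry the
    last valid yaw forward.
    """
    q = np.asarray(quat, dtype=float)
    if q.shape != (4,):
        raise ValidationError(f"expected a 4-vector quaternion, got shape {q.shape}")
    norm = np.linalg.norm(q)
    if abs(norm - 1.0) > 1e-6:
        raise ValidationError(f"quaternion norm {norm:.8f} is not unit within 1e-6")
    v = Rotation.from_quat(q, scalar_first=True).apply(FORWARD)
    horiz = np.hypot(v[0], v[2])
    if horiz < _HORIZONTAL_EPS:
        raise DegenerateOrientationError(
            "orientation has no horizontal component (gaze straight up/down)"
        )
    # atan2(x, -z): 0 when facing -z, positive toward +x (the listener's right)
    return float(np.degrees(np.arctan2(v[0], -v[2])))


def yaw_from_quaternions(quat: np.ndarray) -> np.ndarray:
    """Vectorized yaw for an ``(n, 4)`` scalar-first quaternion array.

    Degenerate samples (no horizontal projection) get the previous valid
    yaw carried forward; a degenerate first sample raises.
    """
    q = np.asarray(quat, dtype=float).reshape(-1, 4)
    v = Rotation.from_quat(q, scalar_first=True).apply(FORWARD)
    v = v.reshape(-1, 3)
    horiz = np.hypot(v[:, 0], v[:, 2])
    yaw = np.degrees(np.arctan2(v[:, 0], -v[:, 2]))
    bad = horiz < _HORIZONTAL_EPS
    if bad.any():
        if bad[0]:
            raise DegenerateOrientationError("first sample has no horizontal component")
        for i in np.flatnonzero(bad):
            yaw[i] = yaw[i - 1]
    return yaw


def head_divergence(target_az: float, yaw_at_hit_deg: float) -> float:
    """Circular difference ``target - yaw`` wrapped into (-180, 180] degrees."""
    if not (np.isfinite(target_az) and np.isfinite(yaw_at_hit_deg)):
        raise ValidationError("angles must be finite")
    return wrap_angle(float(target_az) - float(yaw_at_hit_deg))


def yaw_at_hit(traj: HeadTrajectory, t_hit: float) -> float:
    """Yaw of the sample nearest in time to ``t_hit`` (ties to the earlier).

    ``t_hit`` must lie within the sampled span padded by one nominal sample
    period on each side; interpolation is deliberately avoided at ~10 Hz.
    """
    if len(traj) == 0:
        raise ValidationError("empty trajectory")
    pad = 1.0 / traj.nominal_rate
    if not (traj.t[0] - pad <= t_hit <= traj.t[-1] + pad):
        raise ValidationError(
            f"t_hit {t_hit} outside trajectory span [{traj.t[0]}, {traj.t[-1]}] "
            f"padded by {pad}"
        )
    dt = np.abs(traj.t - t_hit)
    idx = int(np.argmin(dt))  # argmin takes the first minimum: ties -> earlier sample
    return quaternion_to_yaw(traj.quat[idx])


def head_distance(traj: HeadTrajectory, t_onset: float, t_hit: float) -> float:
    """Cumulative Euclidean path length (m) over samples in [t_onset, t_hit].

    Returns 0 if fewer than two samples fall in the window.  No smoothing is
    applied before summation; pass ``min_displacement`` > 0 to ignore
    segment steps below a jitter threshold.
    """
    return _path_length(traj, t_onset, t_hit, min_displacement=0.0)


def _path_length(
    traj: HeadTrajectory, t_onset: float, t_hit: float, min_displacement: float = 0.0
) -> float:
    if len(traj) == 0:
        raise ValidationError("empty trajectory")
    if t_onset >= t_hit:
        raise ValidationError("t_onset must precede t_hit")
    mask = (traj.t >= t_onset) & (traj.t <= t_hit)
    pos = traj.pos[mask]
    if len(pos) < 2:
        return 0.0
    steps = np.linalg.norm(np.diff(pos, axis=0), axis=1)
    if min_displacement > 0:
        steps = steps[steps >= min_displacement]
    return float(steps.sum())


def head_distance_thresholded(
    traj: HeadTrajectory, t_onset: float, t_hit: float, min_displacement: float
) -> float:
    """Path length ignoring per-sample steps smaller than ``min_displacement`` m."""
    return _path_length(traj, t_onset, t_hit, min_displacement=min_displacement)
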