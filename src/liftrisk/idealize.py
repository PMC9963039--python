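"""Idealized wearable-sensor channels.

Converts laboratory-style 3D signals into the channels a trunk IMU and a pair
of pressure insoles would ideally report: 9 trunk channels (3 orientation
angles, 3 gravity-free linear accelerations, 3 angular velocities, global
frame, intrinsic X-Y-Z angle convention in degrees) and 6 under-foot channels
(per foot: 1 foot-normal force, anteroposterior and mediolateral centre of
pressure in the foot frame).

No sensor noise, bias or drift is modelled: the channels are idealized by
design, so results quantify what the *signals* can support rather than what
any particular sensor product achieves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .generator import FORCE_CHANNELS, TRUNK_CHANNELS, LiftTrial  # noqa: F401

_UNIT_TOL = 1e-9


@dataclass
class FootPose:
    """A foot's coordinate frame in the global frame.

    ``long_axis`` points along the foot (anteroposterior, toward the toes),
    ``normal`` is perpendicular to the sole (upward for a flat foot).  The
    mediolateral axis completes a right-handed frame as ``normal x long_axis``.
    """

    origin: np.ndarray
    long_axis: np.ndarray
    normal: np.ndarray

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.long_axis = np.asarray(self.long_axis, dtype=float)
        self.normal = np.asarray(self.normal, dtype=float)
        if abs(np.linalg.norm(self.long_axis) - 1.0) > _UNIT_TOL:
            raise ValueError("foot long_axis must be unit-norm")
        if abs(np.linalg.norm(self.normal) - 1.0) > _UNIT_TOL:
            raise ValueError("foot normal must be unit-norm")
        if abs(float(self.long_axis @ self.normal)) > _UNIT_TOL:
            raise ValueError("foot normal must be orthogonal to the long axis")

    @property
    def ml_axis(self) -> np.ndarray:
        return np.cross(self.normal, self.long_axis)


#: a flat, forward-pointing foot: the pose of every synthetic trial
FLAT_FOOT = FootPose(
    origin=np.zeros(3), long_axis=np.array([1.0, 0, 0]), normal=np.array([0, 0, 1.0])
)


def project_grf_to_foot_normal(grf_3d: np.ndarray, pose: FootPose) -> float | np.ndarray:
    """Project a 3D ground reaction force onto the foot-normal direction.

    Returns the compressive support component (positive = pushing up along
    the normal); shear along the sole is discarded, so the result never
    exceeds the 3D force magnitude.
    """
    grf = np.asarray(grf_3d, dtype=float)
    return grf @ pose.normal


def transform_cop_to_foot_frame(
    cop_global: np.ndarray, pose: FootPose
) -> tuple[float, float] | tuple[np.ndarray, np.ndarray]:
    """Express a global centre of pressure in the foot frame as (AP, ML)."""
    rel = np.asarray(cop_global, dtype=float) - pose.origin
    ap = rel @ pose.long_axis
    ml = rel @ pose.ml_axis
    return ap, ml


def cop_foot_to_global(ap, ml, pose: FootPose) -> np.ndarray:
    """Inverse of :func:`transform_cop_to_foot_frame` (in the sole plane)."""
    return pose.origin + np.multiply.outer(ap, pose.long_axis) + np.multiply.outer(
        ml, pose.ml_axis
    )


def differentiate(y: np.ndarray, time: np.ndarray) -> np.ndarray:
    """Central-difference derivative with one-sided endpoint stencils.

    Requires a uniform time base; raises otherwise.
    """
    time = np.asarray(time, dtype=float)
    if len(time) < 2:
        raise ValueError("need at least 2 samples to differentiate")
    dt = np.diff(time)
    if not np.allclose(dt, dt[0], rtol=1e-9, atol=1e-12):
        raise ValueError("non-uniform time base: differentiation requires uniform sampling")
    return np.gradient(np.asarray(y, dtype=float), time[1] - time[0], axis=0)


def extract_trunk_channels(
    time: np.ndarray,
    angles_deg: np.ndarray,
    lin_acc: np.ndarray | None = None,
    ang_vel_degs: np.ndarray | None = None,
) -> pd.DataFrame:
    """Assemble the 9 idealized trunk channels in canonical order.

    ``angles_deg`` is (n, 3): flexion, lateral bend, axial twist.  Angular
    velocities are differentiated from the angles when not supplied; linear
    accelerations default to zero when not supplied (orientation-only input).
    """
    angles = np.atleast_2d(np.asarray(angles_deg, dtype=float))
    if angles.shape[1] != 3:
        raise ValueError("angles_deg must have 3 columns (flexion, lateral, axial)")
    if ang_vel_degs is None:
        ang_vel = differentiate(angles, time)
    else:
        ang_vel = np.atleast_2d(np.asarray(ang_vel_degs, dtype=float))
    acc = (
        np.zeros_like(angles)
        if lin_acc is None
        else np.atleast_2d(np.asarray(lin_acc, dtype=float))
    )
    if not (len(angles) == len(ang_vel) == len(acc) == len(time)):
        raise ValueError("all channel blocks must share the time base")
    data = np.hstack([angles, acc, ang_vel])
    return pd.DataFrame(data, columns=TRUNK_CHANNELS)


def trial_force_block(trial: LiftTrial) -> pd.DataFrame:
    """The 6 under-foot channels of a trial, in canonical order."""
    return pd.DataFrame(
        {
            "foot_force_left_n": trial.foot_force_left,
            "foot_force_right_n": trial.foot_force_right,
            "cop_ap_left_m": trial.cop_ap_left,
            "cop_ml_left_m": trial.cop_ml_left,
            "cop_ap_right_m": trial.cop_ap_right,
            "cop_ml_right_m": trial.cop_ml_right,
        }
    )
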