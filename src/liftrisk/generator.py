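"""Synthetic sagittal-plane lifting-trial generator.

Produces seeded lifting trials with laboratory-style ground truth: a
time-series lumbar extension moment about a fixed L5/S1 pivot, per-foot
vertical ground forces and centres of pressure, and idealized trunk-sensor
channels (orientation angles, gravity-free linear accelerations, angular
velocities).

The model is a single rigid head-arms-trunk (HAT) segment rotating about a
fixed pivot.  A lift is: quiet stand, minimum-jerk flexion to a shelf-height-
dependent peak angle, a grasp dwell (the box is acquired at the dwell
midpoint), minimum-jerk extension back upright with the box, and a final
stand holding the box.  The key statistical structure is that box mass is
observable in the force channels (weight support) but never enters the trunk
kinematics: a person's movement is identical whether the box holds 5 or
23 kg.

All randomness (postural jitter, sensor jitter, foot-force asymmetry, COP
noise) is keyed on ``(seed, participant, shelf height, repetition)`` so that
two tasks differing only in box mass produce identical kinematic channels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import AnthroRanges, ConfigurationError, SimConfig


@dataclass
class AnthroProfile:
    """Participant anthropometry and HAT inertial parameters.

    The HAT segment is modelled as a rectangular prism of height
    ``hat_prism_height`` and depth ``hat_prism_depth``; its moment of inertia
    about its own centre of mass is ``m_HAT (h^2 + d^2) / 12`` and about the
    L5/S1 pivot ``I_com + m_HAT hat_com_distance^2``.
    """

    participant_id: int
    body_mass: float          # kg
    stature: float            # m
    hat_mass_fraction: float = 0.678
    hat_com_distance: float = 0.0   # m, pivot -> HAT COM; 0 -> scaled from stature
    hat_prism_height: float = 0.0   # m; 0 -> scaled from stature
    hat_prism_depth: float = 0.20   # m
    style_speed_factor: float = 1.0
    style_flexion_offset: float = 0.0  # deg

    def __post_init__(self) -> None:
        if self.body_mass <= 0:
            raise ValueError("body_mass must be > 0")
        if self.stature <= 0:
            raise ValueError("stature must be > 0")
        if not 0 < self.hat_mass_fraction < 1:
            raise ValueError("hat_mass_fraction must lie in (0, 1)")
        if self.hat_com_distance == 0.0:
            self.hat_com_distance = 0.17 * self.stature
        if self.hat_prism_height == 0.0:
            self.hat_prism_height = (0.6 / 1.75) * self.stature
        if self.hat_com_distance <= 0:
            raise ValueError("hat_com_distance must be > 0")

    @property
    def hat_mass(self) -> float:
        return self.hat_mass_fraction * self.body_mass

    @property
    def inertia_com(self) -> float:
        h, d = self.hat_prism_height, self.hat_prism_depth
        return self.hat_mass * (h * h + d * d) / 12.0

    @property
    def inertia_pivot(self) -> float:
        return self.inertia_com + self.hat_mass * self.hat_com_distance**2


@dataclass
class LiftTaskSpec:
    """One symmetric lifting task: a box mass and a lift-origin shelf height."""

    task_id: int
    box_mass: float       # kg
    origin_height: float  # cm above ground
    repetitions: int = 1

    def __post_init__(self) -> None:
        if self.box_mass < 0:
            raise ValueError("box_mass must be >= 0")
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")


#: canonical channel ordering used by every downstream consumer
TRUNK_CHANNELS = [
    "trunk_angle_flexion_deg",
    "trunk_angle_lateral_deg",
    "trunk_angle_axial_deg",
    "trunk_lin_acc_x_ms2",
    "trunk_lin_acc_y_ms2",
    "trunk_lin_acc_z_ms2",
    "trunk_ang_vel_flexion_degs",
    "trunk_ang_vel_lateral_degs",
    "trunk_ang_vel_axial_degs",
]
FORCE_CHANNELS = [
    "foot_force_left_n",
    "foot_force_right_n",
    "cop_ap_left_m",
    "cop_ml_left_m",
    "cop_ap_right_m",
    "cop_ml_right_m",
]
TARGET_CHANNEL = "lumbar_moment_truth_nm"


@dataclass
class LiftTrial:
    """Per-lift time series plus task metadata.

    Channel arrays all share ``time`` as their base.  ``hold_mask`` is True
    while the box is in the hands.  Private sagittal-truth arrays (COM
    acceleration, angular acceleration) support quasi-static audits without
    re-differentiating noisy channels.
    """

    participant_id: int
    task_id: int
    repetition_index: int
    box_mass: float
    origin_height: float
    box_at_hands_flag: bool
    sample_rate: float
    time: np.ndarray
    trunk_angles: np.ndarray     # (n, 3) deg: flexion, lateral, axial
    trunk_lin_acc: np.ndarray    # (n, 3) m/s^2, gravity-free, global x/y/z
    trunk_ang_vel: np.ndarray    # (n, 3) deg/s
    foot_force_left: np.ndarray  # N, foot-normal
    foot_force_right: np.ndarray
    cop_ap_left: np.ndarray      # m, foot frame
    cop_ml_left: np.ndarray
    cop_ap_right: np.ndarray
    cop_ml_right: np.ndarray
    lumbar_moment_truth: np.ndarray  # Nm, extension about L5/S1
    hold_mask: np.ndarray            # bool
    lift_window: np.ndarray = None   # bool; held grasp dwell (peak-extraction window)
    com_acc: np.ndarray = field(repr=False, default=None)    # (n, 2) HAT COM (x, z) m/s^2
    alpha_rads2: np.ndarray = field(repr=False, default=None)

    @property
    def trial_id(self) -> str:
        return f"P{self.participant_id:02d}_T{self.task_id:03d}_R{self.repetition_index}"

    @property
    def n_samples(self) -> int:
        return len(self.time)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({"time_s": self.time})
        for i, name in enumerate(TRUNK_CHANNELS[:3]):
            df[name] = self.trunk_angles[:, i]
        for i, name in enumerate(TRUNK_CHANNELS[3:6]):
            df[name] = self.trunk_lin_acc[:, i]
        for i, name in enumerate(TRUNK_CHANNELS[6:9]):
            df[name] = self.trunk_ang_vel[:, i]
        df["foot_force_left_n"] = self.foot_force_left
        df["foot_force_right_n"] = self.foot_force_right
        df["cop_ap_left_m"] = self.cop_ap_left
        df["cop_ml_left_m"] = self.cop_ml_left
        df["cop_ap_right_m"] = self.cop_ap_right
        df["cop_ml_right_m"] = self.cop_ml_right
        df[TARGET_CHANNEL] = self.lumbar_moment_truth
        df["hold_mask"] = self.hold_mask.astype(int)
        if self.lift_window is not None:
            df["lift_window"] = self.lift_window.astype(int)
        return df


def sample_participants(
    n: int, anthro_ranges: AnthroRanges | None = None, seed: int = 0
) -> list[AnthroProfile]:
    """Draw ``n`` participant profiles uniformly from the configured ranges."""
    if n < 2:
        raise ConfigurationError(
            "at least 2 participants are required: leave-one-participant-out "
            "cross-validation cannot run with a single participant"
        )
    ranges = anthro_ranges or AnthroRanges()
    rng = np.random.default_rng(seed)
    profiles = []
    for pid in range(n):
        mass = rng.uniform(*ranges.body_mass_kg)
        stature = rng.uniform(*ranges.stature_m)
        speed = rng.uniform(*ranges.style_speed_range)
        offset = rng.uniform(*ranges.style_flexion_offset_deg)
        profiles.append(
            AnthroProfile(
                participant_id=pid,
                body_mass=mass,
                stature=stature,
                hat_mass_fraction=ranges.hat_mass_fraction,
                hat_com_distance=ranges.hat_com_distance_factor * stature,
                hat_prism_height=ranges.hat_prism_height_factor * stature,
                hat_prism_depth=ranges.hat_prism_depth_m,
                style_speed_factor=speed,
                style_flexion_offset=offset,
            )
        )
    return profiles


def build_task_grid(
    mass_range: tuple[float, float] = (5.0, 23.0),
    height_range: tuple[float, float] = (40.0, 160.0),
    n_masses: int = 5,
    n_heights: int = 10,
    repetitions: int = 1,
) -> list[LiftTaskSpec]:
    """Evenly spaced task grid covering both ranges inclusive of endpoints.

    A count of 1 collapses that axis to the range midpoint.  The default
    5 x 10 grid yields the 50 distinct task conditions of the study design.
    """
    if n_masses < 1 or n_heights < 1 or repetitions < 1:
        raise ConfigurationError("grid counts and repetitions must be >= 1")
    for lo, hi, n, name in (
        (*mass_range, n_masses, "mass_range"),
        (*height_range, n_heights, "height_range"),
    ):
        if lo > hi or (lo == hi and n > 1):
            raise ConfigurationError(f"{name} is empty or degenerate: ({lo}, {hi})")
    masses = (
        np.array([(mass_range[0] + mass_range[1]) / 2.0])
        if n_masses == 1
        else np.linspace(*mass_range, n_masses)
    )
    heights = (
        np.array([(height_range[0] + height_range[1]) / 2.0])
        if n_heights == 1
        else np.linspace(*height_range, n_heights)
    )
    tasks = []
    tid = 0
    for m in masses:
        for h in heights:
            tasks.append(
                LiftTaskSpec(
                    task_id=tid,
                    box_mass=float(m),
                    origin_height=float(h),
                    repetitions=repetitions,
                )
            )
            tid += 1
    return tasks


def _min_jerk(tau: np.ndarray, duration: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Minimum-jerk unit trajectory s(tau) on [0, 1] with time derivatives."""
    s = 10 * tau**3 - 15 * tau**4 + 6 * tau**5
    sd = (30 * tau**2 - 60 * tau**3 + 30 * tau**4) / duration
    sdd = (60 * tau - 180 * tau**2 + 120 * tau**3) / duration**2
    return s, sd, sdd


def _smooth_noise(
    rng: np.random.Generator, t: np.ndarray, sd: float, n_components: int = 4
) -> tuple[np.ndarray, np.ndarray]:
    """Band-limited sensor jitter as a sum of sinusoids, with exact derivative."""
    y = np.zeros_like(t)
    yd = np.zeros_like(t)
    if sd <= 0:
        return y, yd
    amp = sd * math.sqrt(2.0 / n_components)
    for _ in range(n_components):
        f = rng.uniform(0.3, 1.5)
        phase = rng.uniform(0, 2 * np.pi)
        w = 2 * np.pi * f
        y += amp * np.sin(w * t + phase)
        yd += amp * w * np.cos(w * t + phase)
    return y, yd


def _trial_rng(seed: int, profile: AnthroProfile, task: LiftTaskSpec, repetition: int):
    # keyed on shelf height (deci-cm), not task_id: technique responds to the
    # shelf, never to the (unknown-beforehand) box mass
    key = [int(seed), int(profile.participant_id), int(round(task.origin_height * 10)), int(repetition)]
    return np.random.default_rng(key)


def peak_flexion_angle(
    profile: AnthroProfile, task: LiftTaskSpec, sim: SimConfig, jitter: float = 0.0
) -> float:
    """Shelf-height -> peak trunk flexion mapping (linear), with style offset."""
    h0, h1 = sim.flexion_map_heights_cm
    a0, a1 = sim.flexion_map_angles_deg
    base = a0 + (a1 - a0) * (task.origin_height - h0) / (h1 - h0)
    theta = base + profile.style_flexion_offset + jitter
    if not 0.0 < theta <= 135.0:
        raise ConfigurationError(
            f"peak flexion mapping out of (0, 135] deg: got {theta:.1f} deg for "
            f"origin height {task.origin_height} cm"
        )
    # postural ceiling: trunk flexion beyond ~horizontal is not physiological,
    # and capping keeps peak moment monotone in shelf height under style offsets
    return min(theta, sim.peak_flexion_cap_deg)


def simulate_lift(
    profile: AnthroProfile,
    task: LiftTaskSpec,
    sim: SimConfig | None = None,
    seed: int = 0,
    repetition: int = 0,
) -> LiftTrial:
    """Simulate one lift and return the full trial time series.

    Ground-truth lumbar moment is computed by planar Newton-Euler about the
    fixed L5/S1 pivot::

        M(t) = I a(t) + m_HAT g x(t) + m_HAT (-x_dd(t)) z(t)  [+ box terms]

    with I the HAT inertia about the pivot and (x, z) the HAT-COM position
    relative to the pivot.  In default mode the box is co-located with the
    HAT COM; in box-at-hands mode it sits ``hand_offset_m`` anterior along the
    trunk.  Total vertical ground force follows Newton's second law for the
    supported masses, and the combined centre of pressure is placed so the
    ground wrench reproduces the truth moment (it reduces to the quasi-static
    whole-body COM projection at low acceleration).
    """
    sim = sim or SimConfig()
    fs = sim.sample_rate_hz
    if fs <= 0:
        raise ConfigurationError("sample_rate_hz must be > 0")
    g = sim.gravity_ms2
    rng = _trial_rng(seed, profile, task, repetition)

    jitter = rng.uniform(-sim.trial_flexion_jitter_deg, sim.trial_flexion_jitter_deg)
    theta_peak = peak_flexion_angle(profile, task, sim, jitter)

    scale = 1.0 / profile.style_speed_factor
    durations = [
        sim.stand_duration_s,
        sim.descent_duration_s * scale,
        sim.dwell_duration_s * scale,
        sim.ascent_duration_s * scale,
        sim.end_duration_s,
    ]
    counts = [int(round(d * fs)) for d in durations]
    if any(d <= 0 for d in durations) or any(c < 2 for c in counts):
        raise ConfigurationError(
            "phase durations incompatible with sampling rate: every phase needs "
            f"a positive duration spanning >= 2 samples (got {counts} samples at {fs} Hz)"
        )
    n = sum(counts) + 1
    t = np.arange(n) / fs
    edges = np.cumsum([0] + counts)  # sample indices of phase boundaries

    theta = np.zeros(n)   # rad
    theta_d = np.zeros(n)
    theta_dd = np.zeros(n)
    th_pk = math.radians(theta_peak)

    # descent
    seg = slice(edges[1], edges[2] + 1)
    dur = t[edges[2]] - t[edges[1]]
    tau = (t[seg] - t[edges[1]]) / dur
    s, sd, sdd = _min_jerk(tau, dur)
    theta[seg], theta_d[seg], theta_dd[seg] = th_pk * s, th_pk * sd, th_pk * sdd
    # dwell
    theta[edges[2] : edges[3] + 1] = th_pk
    theta_d[edges[2] : edges[3] + 1] = 0.0
    theta_dd[edges[2] : edges[3] + 1] = 0.0
    # ascent
    seg = slice(edges[3], edges[4] + 1)
    dur = t[edges[4]] - t[edges[3]]
    tau = (t[seg] - t[edges[3]]) / dur
    s, sd, sdd = _min_jerk(tau, dur)
    theta[seg], theta_d[seg], theta_dd[seg] = th_pk * (1 - s), -th_pk * sd, -th_pk * sdd
    # final stand
    theta[edges[4] :] = 0.0
    theta_d[edges[4] :] = 0.0
    theta_dd[edges[4] :] = 0.0

    grasp_index = edges[2] + counts[2] // 2  # dwell midpoint
    hold = np.zeros(n, dtype=bool)
    hold[grasp_index:] = True
    # peak-extraction window: the held portion of the grasp dwell, i.e. the
    # deepest-flexion posture with the box in hand.  Per-lift peaks are
    # searched here: load moment is the moment created by the held object, so
    # samples without the box (or upright samples, where a regressor trained
    # only above the moment threshold extrapolates) are not candidates.
    lift_window = np.zeros(n, dtype=bool)
    lift_window[grasp_index : edges[3] + 1] = True

    m_hat = profile.hat_mass
    r = profile.hat_com_distance
    inertia = profile.inertia_pivot

    sin_t, cos_t = np.sin(theta), np.cos(theta)
    x_hat = r * sin_t
    z_hat = r * cos_t
    xdd_hat = r * (theta_dd * cos_t - theta_d**2 * sin_t)
    zdd_hat = -r * (theta_dd * sin_t + theta_d**2 * cos_t)

    if sim.box_at_hands:
        radius_box = math.hypot(r, sim.hand_offset_m)
        phase_box = math.atan2(sim.hand_offset_m, r)
    else:
        radius_box, phase_box = r, 0.0
    tb = theta + phase_box
    sin_b, cos_b = np.sin(tb), np.cos(tb)
    x_box = radius_box * sin_b
    z_box = radius_box * cos_b
    xdd_box = radius_box * (theta_dd * cos_b - theta_d**2 * sin_b)
    zdd_box = -radius_box * (theta_dd * sin_b + theta_d**2 * cos_b)

    m_box = task.box_mass
    moment = (
        inertia * theta_dd
        + m_hat * g * x_hat
        + m_hat * (-xdd_hat) * z_hat
        + hold * (m_box * g * x_box + m_box * (-xdd_box) * z_box)
    )

    f_total = profile.body_mass * g + m_hat * zdd_hat + hold * m_box * (g + zdd_box)
    x_cop = moment / f_total  # ground-wrench moment balance about the pivot axis

    split = float(np.clip(0.5 + rng.normal(0.0, sim.force_split_sd), 0.35, 0.65))
    f_left = split * f_total
    f_right = (1.0 - split) * f_total

    cop_noise = sim.cop_noise_m
    cop_ap_left = x_cop + rng.normal(0.0, cop_noise, n) if cop_noise > 0 else x_cop.copy()
    cop_ap_right = x_cop + rng.normal(0.0, cop_noise, n) if cop_noise > 0 else x_cop.copy()
    cop_ml_left = rng.normal(0.0, cop_noise, n) if cop_noise > 0 else np.zeros(n)
    cop_ml_right = rng.normal(0.0, cop_noise, n) if cop_noise > 0 else np.zeros(n)

    # idealized trunk sensor at a configurable fraction of trunk length
    rho = sim.sensor_fraction_of_trunk * profile.hat_prism_height
    acc_x = rho * (theta_dd * cos_t - theta_d**2 * sin_t)
    acc_z = -rho * (theta_dd * sin_t + theta_d**2 * cos_t)

    lat_angle, lat_vel = _smooth_noise(rng, t, sim.angle_noise_deg)
    ax_angle, ax_vel = _smooth_noise(rng, t, sim.angle_noise_deg)
    acc_y, _ = _smooth_noise(rng, t, sim.lin_acc_noise_ms2)

    trunk_angles = np.column_stack([np.degrees(theta), lat_angle, ax_angle])
    trunk_lin_acc = np.column_stack([acc_x, acc_y, acc_z])
    trunk_ang_vel = np.column_stack([np.degrees(theta_d), lat_vel, ax_vel])

    return LiftTrial(
        participant_id=profile.participant_id,
        task_id=task.task_id,
        repetition_index=repetition,
        box_mass=m_box,
        origin_height=task.origin_height,
        box_at_hands_flag=sim.box_at_hands,
        sample_rate=fs,
        time=t,
        trunk_angles=trunk_angles,
        trunk_lin_acc=trunk_lin_acc,
        trunk_ang_vel=trunk_ang_vel,
        foot_force_left=f_left,
        foot_force_right=f_right,
        cop_ap_left=cop_ap_left,
        cop_ml_left=cop_ml_left,
        cop_ap_right=cop_ap_right,
        cop_ml_right=cop_ml_right,
        lumbar_moment_truth=moment,
        hold_mask=hold,
        lift_window=lift_window,
        com_acc=np.column_stack([xdd_hat, zdd_hat]),
        alpha_rads2=theta_dd.copy(),
    )


def quasi_static_mask(
    trial: LiftTrial, a_tol: float = 0.05, alpha_tol: float = 0.05
) -> np.ndarray:
    """Samples where sagittal COM acceleration and angular acceleration are ~0."""
    a_mag = np.hypot(trial.com_acc[:, 0], trial.com_acc[:, 1])
    return (a_mag < a_tol) & (np.abs(trial.alpha_rads2) < alpha_tol)


def supported_weight(trial: LiftTrial, body_mass: float, g: float = 9.81) -> np.ndarray:
    """Weight the ground must support at each sample: body plus held box."""
    return (body_mass + trial.hold_mask * trial.box_mass) * g


def bottom_up_lumbar_moment(trial: LiftTrial) -> np.ndarray:
    """Recompute the lumbar moment from ground forces and foot geometry.

    Bottom-up route: combine the per-foot normal forces and centres of
    pressure into a resultant ground wrench and take its moment about the
    pivot axis (in this stance the lower-body COM lies on the pivot vertical,
    so its weight contributes no moment).  Independent of the Newton-Euler
    truth channel; agreement between the two is a generator audit.
    """
    f_tot = trial.foot_force_left + trial.foot_force_right
    x_comb = (
        trial.foot_force_left * trial.cop_ap_left
        + trial.foot_force_right * trial.cop_ap_right
    ) / f_tot
    return f_tot * x_comb


def generate_dataset(
    profiles: list[AnthroProfile],
    tasks: list[LiftTaskSpec],
    sim: SimConfig | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
    write_trials: bool = False,
) -> tuple[list[LiftTrial], pd.DataFrame]:
    """One trial per (participant, task, repetition), plus a manifest table.

    With ``out_dir`` set the manifest (and, optionally, one CSV per trial) is
    written to disk; outputs are byte-identical across runs for a fixed seed.
    """
    sim = sim or SimConfig()
    trials: list[LiftTrial] = []
    rows = []
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
        if write_trials:
            (out_path / "trials").mkdir(exist_ok=True)
    for profile in profiles:
        for task in tasks:
            for rep in range(task.repetitions):
                trial = simulate_lift(profile, task, sim, seed=seed, repetition=rep)
                trials.append(trial)
                fname = ""
                if out_path is not None and write_trials:
                    fname = f"trials/{trial.trial_id}.csv"
                    try:
                        trial.to_dataframe().to_csv(
                            out_path / fname, index=False, float_format="%.9g"
                        )
                    except OSError as exc:
                        raise OSError(f"failed writing trial file {out_path / fname}: {exc}")
                rows.append(
                    {
                        "trial_id": trial.trial_id,
                        "participant_id": trial.participant_id,
                        "task_id": trial.task_id,
                        "repetition": rep,
                        "box_mass_kg": trial.box_mass,
                        "origin_height_cm": trial.origin_height,
                        "n_samples": trial.n_samples,
                        "file": fname,
                    }
                )
    manifest = pd.DataFrame(rows)
    if out_path is not None:
        try:
            manifest.to_csv(out_path / "manifest.csv", index=False, float_format="%.9g")
        except OSError as exc:
            raise OSError(f"failed writing manifest to {out_path / 'manifest.csv'}: {exc}")
    return trials, manifest
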