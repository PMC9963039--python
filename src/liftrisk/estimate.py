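"""Lumbar-moment estimation from idealized wearable channels.

Gradient-boosted decision-tree regressors map per-sample sensor channels to
the time-series lumbar extension moment, under two signal conditions:

* ``trunk`` -- the 9 trunk-IMU channels;
* ``trunk_force`` -- trunk plus the 6 under-foot channels (15 total).

Models are evaluated with leave-one-participant-out cross-validation: each
participant's trials are predicted by a model trained exclusively on the
other participants, so no within-person information leaks into the held-out
predictions.  Training keeps only samples whose target exceeds a 100 Nm
threshold, prioritising accuracy at the high moments that drive
fatigue-failure damage; prediction always runs on full, unfiltered trials.

Features are instantaneous per-sample channel values (no windows or lags).
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import HistGradientBoostingRegressor

from . import lifft
from .config import EstimatorConfig
from .generator import FORCE_CHANNELS, TARGET_CHANNEL, TRUNK_CHANNELS, AnthroProfile, LiftTrial
from .idealize import differentiate

CONDITIONS = ("trunk", "trunk_force")
KEY_COLUMNS = ["participant_id", "trial_id", "sample_index"]


class SchemaError(ValueError):
    """A trial table does not match the expected channel schema."""


def condition_channels(condition: str) -> list[str]:
    if condition == "trunk":
        return list(TRUNK_CHANNELS)
    if condition == "trunk_force":
        return list(TRUNK_CHANNELS) + list(FORCE_CHANNELS)
    raise ValueError(f"unknown condition {condition!r}; expected one of {CONDITIONS}")


def build_features(trials: list[LiftTrial], condition: str) -> pd.DataFrame:
    """Pool trials into a per-sample feature table for one signal condition.

    Columns: the condition's channels, the ground-truth target, and grouping
    keys tracing every row back to (participant, trial, sample).
    """
    channels = condition_channels(condition)
    frames = []
    for trial in trials:
        df = trial.to_dataframe()
        missing = [c for c in channels + [TARGET_CHANNEL] if c not in df.columns]
        if missing:
            raise SchemaError(f"trial {trial.trial_id} is missing channel(s): {missing}")
        block = df[channels + [TARGET_CHANNEL]].copy()
        block["participant_id"] = trial.participant_id
        block["trial_id"] = trial.trial_id
        block["sample_index"] = np.arange(len(df))
        frames.append(block)
    if not frames:
        raise ValueError("no trials supplied")
    table = pd.concat(frames, ignore_index=True)
    if table[channels + [TARGET_CHANNEL]].isna().any().any():
        raise SchemaError("feature table contains missing values")
    return table


def filter_training_samples(
    table: pd.DataFrame, threshold: float = 100.0
) -> pd.DataFrame:
    """Keep only rows whose target strictly exceeds ``threshold`` (Nm).

    Applied to training data only; raises if nothing survives (usually a
    threshold/configuration mismatch).
    """
    if TARGET_CHANNEL not in table.columns:
        raise SchemaError(f"table has no target column {TARGET_CHANNEL!r}")
    kept = table[table[TARGET_CHANNEL] > threshold]
    if kept.empty:
        raise ValueError(
            f"no training samples exceed the {threshold} Nm threshold; check that "
            "the threshold matches the scale of the generated moments"
        )
    return kept


def train_estimator(
    table: pd.DataFrame,
    config: EstimatorConfig | None = None,
    seed: int = 0,
    condition: str | None = None,
) -> HistGradientBoostingRegressor:
    """Fit a gradient-boosted decision-tree regressor on a feature table.

    100 boosting stages by default; training is seeded and deterministic.
    The feature ordering is the canonical channel ordering, inferred from the
    table when ``condition`` is not given.
    """
    config = config or EstimatorConfig()
    if condition is None:
        condition = "trunk_force" if FORCE_CHANNELS[0] in table.columns else "trunk"
    channels = condition_channels(condition)
    if table.empty:
        raise ValueError("empty training table")
    model = HistGradientBoostingRegressor(
        max_iter=config.n_stages,
        learning_rate=config.learning_rate,
        max_depth=config.max_depth,
        early_stopping=False,
        random_state=seed,
    )
    model.fit(table[channels].to_numpy(), table[TARGET_CHANNEL].to_numpy())
    return model


def save_model(model, path: str | Path, config_hash: str = "", seed: int = 0) -> None:
    """Serialize a fitted model with a JSON sidecar recording provenance."""
    path = Path(path)
    joblib.dump(model, path)
    sidecar = {"config_hash": config_hash, "seed": seed, "format": "joblib"}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def load_model(path: str | Path):
    return joblib.load(path)


def lopo_cross_validate(
    trials: list[LiftTrial],
    condition: str,
    config: EstimatorConfig | None = None,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Held-out lumbar-moment predictions for every trial.

    For each participant, a model trained on all *other* participants'
    threshold-filtered samples predicts the participant's full trials (no
    filter at prediction time).  Returns ``{trial_id: predicted series}``
    with exactly one prediction per trial.
    """
    config = config or EstimatorConfig()
    participants = sorted({t.participant_id for t in trials})
    if len(participants) < 2:
        raise ValueError("leave-one-participant-out needs at least 2 participants")
    by_participant: dict[int, list[LiftTrial]] = {p: [] for p in participants}
    for t in trials:
        by_participant[t.participant_id].append(t)
    for p, ts in by_participant.items():
        if not ts:
            raise ValueError(f"participant {p} has no trials")

    table = build_features(trials, condition)
    channels = condition_channels(condition)
    predictions: dict[str, np.ndarray] = {}
    for held_out in participants:
        train = filter_training_samples(
            table[table["participant_id"] != held_out], config.training_threshold_nm
        )
        model = train_estimator(train, config, seed=seed, condition=condition)
        for trial in by_participant[held_out]:
            df = trial.to_dataframe()
            predictions[trial.trial_id] = model.predict(df[channels].to_numpy())
    return predictions


def peak_of_series(
    series: np.ndarray, window: np.ndarray | None = None
) -> tuple[float, int]:
    """Maximum of a moment series and its sample index (first max on ties).

    ``window`` restricts the search to the lift event (descent through
    ascent); quiet-standing samples are excluded because a regressor trained
    only above the moment threshold extrapolates there, and a spurious
    standing-phase maximum would be converted with a near-zero horizontal
    distance.  Without a window the full series is searched.
    """
    series = np.asarray(series, dtype=float)
    if series.size == 0:
        raise ValueError("empty moment series")
    if window is None:
        idx = int(np.argmax(series))
    else:
        window = np.asarray(window, dtype=bool)
        if window.shape != series.shape or not window.any():
            raise ValueError("lift window must be a non-empty mask over the series")
        candidates = np.flatnonzero(window)
        idx = int(candidates[np.argmax(series[candidates])])
    return float(series[idx]), idx


def extract_peaks(
    trials: list[LiftTrial], predictions: dict[str, dict[str, np.ndarray]]
) -> pd.DataFrame:
    """Per-trial peak lumbar moments for the lab truth and each condition.

    ``predictions`` maps condition name -> {trial_id: predicted series}.
    Also records the peak sample index per column (needed for the
    lumbar-to-load conversion) and trial metadata.
    """
    rows = []
    for trial in trials:
        window = trial.lift_window
        peak_lab, idx_lab = peak_of_series(trial.lumbar_moment_truth, window)
        row = {
            "participant_id": trial.participant_id,
            "trial_id": trial.trial_id,
            "box_mass": trial.box_mass,
            "peak_bend_angle": float(np.max(trial.trunk_angles[:, 0])),
            "peak_lumbar_lab": peak_lab,
            "_idx_lab": idx_lab,
        }
        for cond, pred in predictions.items():
            if trial.trial_id not in pred:
                raise ValueError(f"no {cond} prediction for trial {trial.trial_id}")
            val, idx = peak_of_series(pred[trial.trial_id], window)
            suffix = "trunkforce" if cond == "trunk_force" else cond
            row[f"peak_lumbar_{suffix}"] = val
            row[f"_idx_{suffix}"] = idx
        rows.append(row)
    return pd.DataFrame(rows)


def _conversion_at_sample(
    trial: LiftTrial, profile: AnthroProfile, m_lumbar: float, idx: int, g: float
) -> float:
    """Apply the lumbar-to-load conversion at one peak sample of a trial.

    ``a`` and ``alpha`` are taken from the idealized trunk channels (vertical
    linear acceleration; differentiated sagittal angular velocity), and ``L``
    is the horizontal projection of the pivot-to-HAT-COM distance at the
    trial's flexion angle -- all sagittal components.
    """
    a_vert = float(trial.trunk_lin_acc[idx, 2])
    ang_vel_rad = np.radians(trial.trunk_ang_vel[:, 0])
    alpha = float(differentiate(ang_vel_rad, trial.time)[idx])
    theta = math.radians(float(trial.trunk_angles[idx, 0]))
    horiz = profile.hat_com_distance * math.sin(theta)
    return lifft.lumbar_to_load_moment(
        lifft.MomentConversionInputs(
            m_lumbar_peak=m_lumbar,
            a_at_peak=a_vert,
            alpha_at_peak=alpha,
            horizontal_distance=horiz,
            m_hat=profile.hat_mass,
            m_box=trial.box_mass,
            inertia=profile.inertia_pivot,
            g=g,
        )
    )


LOOKUP_COLUMNS = [
    "participant_id",
    "trial_id",
    "peak_lumbar_lab",
    "peak_lumbar_trunk",
    "peak_lumbar_trunkforce",
    "peak_load_lab",
    "peak_load_trunk",
    "peak_load_trunkforce",
    "box_mass",
    "peak_bend_angle",
]


def build_lookup(
    trials: list[LiftTrial],
    profiles: list[AnthroProfile],
    predictions: dict[str, dict[str, np.ndarray]],
    g: float = 9.81,
) -> pd.DataFrame:
    """Per-participant, per-lift peak-moment lookup table.

    One row per recorded lift with peak lumbar and peak load moments for the
    lab truth and each wearable condition, plus the box mass and peak bend
    angle used by the workday simulation.
    """
    peaks = extract_peaks(trials, predictions)
    by_id = {t.trial_id: t for t in trials}
    prof_by_id = {p.participant_id: p for p in profiles}
    suffixes = ["lab"] + [
        "trunkforce" if c == "trunk_force" else c for c in predictions
    ]
    for suffix in suffixes:
        loads = []
        for _, row in peaks.iterrows():
            trial = by_id[row["trial_id"]]
            profile = prof_by_id[row["participant_id"]]
            loads.append(
                _conversion_at_sample(
                    trial,
                    profile,
                    float(row[f"peak_lumbar_{suffix}"]),
                    int(row[f"_idx_{suffix}"]),
                    g,
                )
            )
        peaks[f"peak_load_{suffix}"] = loads
    cols = [c for c in LOOKUP_COLUMNS if c in peaks.columns]
    return peaks[cols]
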