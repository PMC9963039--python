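"""Monte-Carlo simulation of material-handling workdays.

A simulated workday draws a lift count uniformly from a configured integer
range (800-2000 by default) and samples that many lifts uniformly, with
replacement, from a participant's peak-moment lookup table.  The *same* lift
sequence feeds all three conditions (lab truth, trunk, trunk+force), so
condition differences isolate estimator error from sampling noise.  Damage
accumulates per condition via the fatigue-failure law and maps to
low-back-disorder risk through the logistic model.

A "lift-counter" baseline is included: it knows only the number of lifts and
charges every lift a constant nominal load moment (75 Nm by default), the
kind of estimate a bend-counting IMU algorithm could produce.

Per-day random substreams are derived from ``(seed, participant, day)`` so
results are independent of execution order and stable under parallel runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import lifft
from .config import WorkdayConfig

logger = logging.getLogger(__name__)

CONDITION_SUFFIXES = ("lab", "trunk", "trunkforce")


@dataclass
class WorkdayResult:
    """One simulated workday for one participant."""

    participant_id: int
    day_index: int
    n_lifts: int
    sampled_lift_rows: np.ndarray  # positional row indices into the lookup
    damage: dict[str, float]       # condition suffix -> cumulative damage D
    risk: dict[str, float]         # condition suffix -> risk R in [0, 1)
    risk_liftcounter: float
    mean_bend_angle: float

    def to_row(self) -> dict:
        row = {
            "participant_id": self.participant_id,
            "day_index": self.day_index,
            "n_lifts": self.n_lifts,
            "mean_bend_angle": self.mean_bend_angle,
            "risk_liftcounter": self.risk_liftcounter,
        }
        for cond in self.damage:
            row[f"damage_{cond}"] = self.damage[cond]
            row[f"risk_{cond}"] = self.risk[cond]
        return row


def moment_column(condition: str, moment_type: str = "load") -> str:
    """Lookup column holding the per-lift peak moment for a condition."""
    prefix = "peak_load" if moment_type == "load" else "peak_lumbar"
    return f"{prefix}_{condition}"


def lift_counter_baseline(
    n_lifts: int,
    nominal_load_moment: float = 75.0,
    grouping: str = lifft.EXPONENT_INCLUSIVE,
) -> float:
    """Risk from lift count alone, charging each lift a nominal load moment."""
    if n_lifts < 0:
        raise ValueError("n_lifts must be >= 0")
    damage = n_lifts * lifft.per_lift_damage(nominal_load_moment, grouping)
    return lifft.lbd_risk(damage).risk


def simulate_workday(
    lookup: pd.DataFrame,
    rng: np.random.Generator,
    config: WorkdayConfig | None = None,
    day_index: int = 0,
    grouping: str = lifft.EXPONENT_INCLUSIVE,
) -> WorkdayResult:
    """Simulate one workday from one participant's lookup table."""
    config = config or WorkdayConfig()
    if lookup.empty:
        raise ValueError("empty lookup table: cannot sample lifts")
    pid = int(lookup["participant_id"].iloc[0])
    n_lifts = int(rng.integers(config.min_lifts, config.max_lifts + 1))
    rows = rng.integers(0, len(lookup), size=n_lifts)

    damage: dict[str, float] = {}
    risk: dict[str, float] = {}
    for cond in CONDITION_SUFFIXES:
        col = moment_column(cond, config.moment_type)
        if col not in lookup.columns:
            raise ValueError(f"lookup table is missing column {col!r}")
        moments = lookup[col].to_numpy()[rows]
        acc = lifft.cumulative_damage(moments, grouping)
        damage[cond] = acc.damage
        risk[cond] = lifft.lbd_risk(acc.damage).risk

    mean_bend = float(lookup["peak_bend_angle"].to_numpy()[rows].mean())
    return WorkdayResult(
        participant_id=pid,
        day_index=day_index,
        n_lifts=n_lifts,
        sampled_lift_rows=rows,
        damage=damage,
        risk=risk,
        risk_liftcounter=lift_counter_baseline(
            n_lifts, config.nominal_load_moment_nm, grouping
        ),
        mean_bend_angle=mean_bend,
    )


def run_simulation(
    lookup: pd.DataFrame,
    n_days: int = 1000,
    seed: int = 0,
    config: WorkdayConfig | None = None,
    grouping: str = lifft.EXPONENT_INCLUSIVE,
) -> pd.DataFrame:
    """Simulate ``n_days`` workdays for every participant in the lookup.

    Returns one row per (participant, day); total rows =
    participants x n_days.  Reproducible from the seed: each day uses an
    independent substream keyed on (seed, participant, day).
    """
    participants = sorted(lookup["participant_id"].unique())
    if not participants:
        raise ValueError("lookup table has no participants")
    cfg = config or WorkdayConfig()
    rows = []
    for pid in participants:
        sub = lookup[lookup["participant_id"] == pid].reset_index(drop=True)
        # clamp negative load moments once per participant (not per simulated
        # day), logging the count; negative "load" is meaningless to the
        # fatigue model and arises only from estimator error
        sub = sub.copy()
        for cond in CONDITION_SUFFIXES:
            col = moment_column(cond, cfg.moment_type)
            if col in sub.columns:
                n_neg = int((sub[col] < 0).sum())
                if n_neg:
                    logger.warning(
                        "participant %s: clamping %d negative %s moments to 0",
                        pid, n_neg, col,
                    )
                    sub[col] = sub[col].clip(lower=0.0)
        for day in range(n_days):
            rng = np.random.default_rng([int(seed), int(pid), int(day)])
            result = simulate_workday(sub, rng, config, day_index=day, grouping=grouping)
            rows.append(result.to_row())
    return pd.DataFrame(rows)
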