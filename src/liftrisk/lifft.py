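"""Fatigue-failure low-back-disorder risk model (LiFFT) and moment conversion.

Two pieces of biomechanics-to-ergonomics plumbing live here:

1. Conversion of a peak *lumbar* extension moment (everything acting about
   L5/S1: trunk weight, inertia, and the load) into the peak *load* moment
   (the contribution of the lifted object alone), by subtracting the linear
   and rotational trunk terms::

       M_load = M_lumbar - [m_HAT (a + g) L + m_box a L] - I alpha

   where ``L`` is the horizontal pivot-to-HAT-COM distance at the peak
   sample, ``a`` the vertical trunk acceleration and ``alpha`` the trunk
   angular acceleration at that sample.

2. The cumulative-damage and risk equations.  Each lift's peak load moment
   ``M_i`` (Nm) inflicts a damage fraction, summed over a workday::

       D = (1/902416) * sum_i exp(0.038 M_i + 0.32)

   and damage maps to the probability of being in a high-risk job through a
   logistic model calibrated on epidemiological surveillance data::

       Y = 1.72 + log10(D),    R = e^Y / (1 + e^Y)

   The flattened printed form of the damage equation is ambiguous about the
   0.32 constant; the default grouping keeps it inside the exponent (a
   per-cycle damage intercept, consistent with fatigue-failure damage laws),
   and the alternative reading -- ``(exp(0.038 M_i) + 0.32)/902416`` -- is
   available as ``grouping="additive_constant"`` for comparison.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

logger = logging.getLogger(__name__)

DAMAGE_DENOMINATOR = 902416.0
DAMAGE_SLOPE = 0.038      # per Nm
DAMAGE_INTERCEPT = 0.32
RISK_INTERCEPT = 1.72

EXPONENT_INCLUSIVE = "exponent_inclusive"
ADDITIVE_CONSTANT = "additive_constant"


@dataclass
class MomentConversionInputs:
    """Everything needed to strip trunk terms from a peak lumbar moment."""

    m_lumbar_peak: float   # Nm
    a_at_peak: float       # m/s^2, vertical trunk acceleration (gravity-free)
    alpha_at_peak: float   # rad/s^2
    horizontal_distance: float  # m, pivot -> HAT COM, horizontal, at the peak
    m_hat: float           # kg
    m_box: float           # kg
    inertia: float         # kg m^2, HAT about the pivot
    g: float = 9.81

    def __post_init__(self) -> None:
        if self.horizontal_distance < 0:
            raise ValueError("horizontal_distance must be >= 0")
        if self.m_hat <= 0:
            raise ValueError("m_hat must be > 0")
        if self.m_box < 0:
            raise ValueError("m_box must be >= 0")
        if self.inertia <= 0:
            raise ValueError("inertia must be > 0")


def lumbar_to_load_moment(inputs: MomentConversionInputs) -> float:
    """Peak load moment (Nm) from a peak lumbar moment.

    May be negative when the lumbar estimate is noisy; clamping is the
    caller's decision (the damage accumulator clamps, with a logged count).
    """
    m_linear = (
        inputs.m_hat * (inputs.a_at_peak + inputs.g) * inputs.horizontal_distance
        + inputs.m_box * inputs.a_at_peak * inputs.horizontal_distance
    )
    m_rotation = inputs.inertia * inputs.alpha_at_peak
    return inputs.m_lumbar_peak - m_linear - m_rotation


def per_lift_damage(m_load, grouping: str = EXPONENT_INCLUSIVE):
    """Damage fraction inflicted by a single lift of peak load moment ``m_load`` (Nm).

    Strictly positive, strictly increasing and convex in the load moment.
    Vectorized over array input.
    """
    m = np.asarray(m_load, dtype=float)
    if not np.all(np.isfinite(m)):
        raise ValueError("load moment must be finite")
    if grouping == EXPONENT_INCLUSIVE:
        d = np.exp(DAMAGE_SLOPE * m + DAMAGE_INTERCEPT) / DAMAGE_DENOMINATOR
    elif grouping == ADDITIVE_CONSTANT:
        d = (np.exp(DAMAGE_SLOPE * m) + DAMAGE_INTERCEPT) / DAMAGE_DENOMINATOR
    else:
        raise ValueError(f"unknown damage grouping {grouping!r}")
    return d if np.ndim(m_load) else float(d)


@dataclass
class DamageAccumulator:
    """Cumulative damage over a sequence of lifts (additive across lifts)."""

    per_lift: np.ndarray = field(default_factory=lambda: np.empty(0))
    grouping: str = EXPONENT_INCLUSIVE

    @property
    def damage(self) -> float:
        return float(np.sum(self.per_lift))

    @property
    def n_lifts(self) -> int:
        return len(self.per_lift)


def cumulative_damage(
    m_loads,
    grouping: str = EXPONENT_INCLUSIVE,
    clamp_negative: bool = True,
) -> DamageAccumulator:
    """Accumulate damage over a workday's peak load moments.

    Negative load moments (possible under estimator error) are physically
    meaningless to the fatigue model and are clamped to zero before the
    damage computation; the clamped count is logged.  An empty sequence
    yields zero damage.
    """
    m = np.asarray(m_loads, dtype=float)
    if m.size == 0:
        return DamageAccumulator(np.empty(0), grouping)
    if clamp_negative:
        n_neg = int(np.sum(m < 0))
        if n_neg:
            logger.warning("clamping %d negative load moments to 0 before damage", n_neg)
            m = np.maximum(m, 0.0)
    return DamageAccumulator(per_lift_damage(m, grouping), grouping)


@dataclass
class RiskResult:
    """Cumulative damage with its logit and probability of high-risk-job membership."""

    damage: float
    logit: float
    risk: float


def lbd_risk(damage: float) -> RiskResult:
    """Low-back-disorder risk from cumulative damage.

    ``damage = 0`` (an empty workday) returns the exact limit ``R = 0``
    rather than an error; otherwise ``R`` is strictly increasing in damage
    and confined to (0, 1).
    """
    if damage < 0:
        raise ValueError("cumulative damage must be >= 0")
    if damage == 0:
        return RiskResult(0.0, -math.inf, 0.0)
    y = RISK_INTERCEPT + math.log10(damage)
    return RiskResult(float(damage), y, float(expit(y)))


def risk_from_loads(m_loads, grouping: str = EXPONENT_INCLUSIVE) -> RiskResult:
    """Convenience: peak load moments -> cumulative damage -> risk."""
    return lbd_risk(cumulative_damage(m_loads, grouping).damage)
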