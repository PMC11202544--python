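"""Discounting, stage utilities, lifetime QALYs and Weibull survival tools.

A participant's quality-adjusted lifetime is assembled from a pre-diagnosis
period at the no-cancer utility (the lead time), a post-diagnosis period at
the stage-decremented utility, and — for long-term survivors — reversion to
the baseline utility once the stage decrement expires.  All time streams are
discounted with a continuous-time kernel that leaves the first year
undiscounted.

The Weibull helpers (`fit_weibull_to_km`, `calibrate_to_survival`,
`apply_hazard_ratio`, `weibull_mean`) reproduce the survival-extrapolation
pipeline behind the stage life expectancies: fit a parametric model to
digitised Kaplan–Meier points, recalibrate its scale to an observed
five-year survival, and shift it by a treatment hazard ratio under
proportional hazards.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import gamma as _gamma_fn

from .parameters import ModelInputs
from .tree import OutcomeClass, PathwayCell

__all__ = [
    "DiscountSpec",
    "discounted_years",
    "discount_amount",
    "stage_utility",
    "life_expectancy_for",
    "qaly_for_cell",
    "WeibullModel",
    "KMPoint",
    "weibull_mean",
    "fit_weibull_to_km",
    "calibrate_to_survival",
    "apply_hazard_ratio",
]


@dataclass(frozen=True)
class DiscountSpec:
    """Annual discount rate with an initial discount-free window (years)."""

    rate: float = 0.035
    free_years: float = 1.0

    def __post_init__(self) -> None:
        if self.rate < 0 or self.free_years < 0:
            raise ValueError("rate and free_years must be >= 0")


def discounted_years(duration, start, spec: DiscountSpec):
    """Discounted year-equivalents of a period of ``duration`` years
    beginning ``start`` years after time zero.

    The weight is 1 inside the discount-free window and
    ``(1+rate)^-(t - free_years)`` beyond it; the integral is evaluated in
    closed form (no quadrature).  Accepts scalars or broadcastable arrays;
    ``duration`` may be ``inf``.
    """
    duration = np.asarray(duration, dtype=float)
    start = np.asarray(start, dtype=float)
    if np.any(duration < 0) or np.any(start < 0):
        raise ValueError("duration and start must be >= 0")
    if spec.rate == 0.0:
        out = duration + 0.0 * start
        return float(out) if out.ndim == 0 else out
    free = spec.free_years
    end = start + duration
    undisc = np.clip(np.minimum(end, free) - np.minimum(start, free), 0.0, None)
    ln = math.log1p(spec.rate)
    a = np.maximum(start, free)
    b = np.maximum(end, free)
    disc = (np.exp(-ln * (a - free)) - np.exp(-ln * (b - free))) / ln
    out = undisc + disc
    return float(out) if out.ndim == 0 else out


def discount_amount(amount, time, spec: DiscountSpec):
    """Present value of a lump sum occurring at ``time`` years."""
    time = np.asarray(time, dtype=float)
    if np.any(time < 0):
        raise ValueError("time must be >= 0")
    if spec.rate == 0.0:
        w = np.ones_like(time)
    else:
        ln = math.log1p(spec.rate)
        w = np.exp(-ln * np.clip(time - spec.free_years, 0.0, None))
    out = np.asarray(amount, dtype=float) * w
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# utilities and life expectancy


def stage_utility(outcome: OutcomeClass, mi: ModelInputs):
    """Post-diagnosis health utility for an outcome class, clamped to [0, 1].

    No-cancer outcomes carry the baseline utility; cancer outcomes subtract
    the cancer decrement plus the stage-specific additional decrement.
    """
    if outcome in (OutcomeClass.NOLC, OutcomeClass.NOLC_FP):
        u = mi.u_nolc
    elif outcome is OutcomeClass.ES_DETECTED:
        u = mi.u_nolc - mi.u_dec_lc - mi.u_dec_es
    else:
        u = mi.u_nolc - mi.u_dec_lc - mi.u_dec_ls
    return np.clip(u, 0.0, 1.0)


def life_expectancy_for(outcome: OutcomeClass, mi: ModelInputs):
    """Mean years from diagnosis for a cancer outcome class.

    Early detections average stages I and II; late detections (during or
    after screening) average the immunotherapy-era stage III/IV figures;
    never-treated cases average the pre-immunotherapy figures.
    """
    if outcome is OutcomeClass.ES_DETECTED:
        return 0.5 * (mi.le_stage_i + mi.le_stage_ii)
    if outcome in (OutcomeClass.LS_DETECTED, OutcomeClass.LS_LATE_TREATED):
        return 0.5 * (mi.le_stage_iii_immuno + mi.le_stage_iv_immuno)
    if outcome is OutcomeClass.LS_NEVER_TREATED:
        return 0.5 * (mi.le_stage_iii_prior + mi.le_stage_iv_prior)
    raise ValueError(f"no life expectancy for outcome {outcome}")


def qaly_for_cell(cell: PathwayCell, mi: ModelInputs, disc: DiscountSpec):
    """Discounted QALYs per person in a pathway cell.

    No-cancer outcomes pass through the calibrated baseline lifetime QALY.
    Cancer outcomes live the lead time at the baseline utility, then the
    stage life expectancy at the stage utility; survivors past
    ``utility_decrement_years`` after diagnosis revert to baseline utility
    (set that parameter to ``inf`` for lifetime decrements).
    """
    if cell.outcome in (OutcomeClass.NOLC, OutcomeClass.NOLC_FP):
        return mi.baseline_disc_qaly_nolc
    if cell.diagnosis_time is None:
        raise ValueError(f"cell {cell.pathway}/{cell.outcome} has no diagnosis time")
    dx = cell.diagnosis_time
    le = life_expectancy_for(cell.outcome, mi)
    u_pre = np.clip(mi.u_nolc, 0.0, 1.0)
    u_post = stage_utility(cell.outcome, mi)
    cap = mi.utility_decrement_years
    q = u_pre * discounted_years(dx, 0.0, disc)
    q = q + u_post * discounted_years(np.minimum(le, cap), dx, disc)
    tail = np.maximum(le - cap, 0.0)
    if np.any(np.asarray(tail) > 0.0):
        q = q + u_pre * discounted_years(tail, dx + cap, disc)
    return q


# ---------------------------------------------------------------------------
# Weibull survival machinery


@dataclass(frozen=True)
class WeibullModel:
    """Weibull survival model, S(t) = exp(-(t/scale)^shape)."""

    shape: float
    scale: float

    def __post_init__(self) -> None:
        if self.shape <= 0 or self.scale <= 0:
            raise ValueError("shape and scale must be > 0")

    def survival(self, t):
        return np.exp(-np.power(np.asarray(t, dtype=float) / self.scale, self.shape))


@dataclass(frozen=True)
class KMPoint:
    """One point of a (possibly digitised) Kaplan–Meier curve."""

    time: float
    survival: float


def weibull_mean(m: WeibullModel) -> float:
    """Mean survival, scale * Gamma(1 + 1/shape)."""
    return m.scale * float(_gamma_fn(1.0 + 1.0 / m.shape))


def fit_weibull_to_km(points: Sequence[KMPoint]) -> WeibullModel:
    """Least-squares Weibull fit on the linearised survival curve.

    Uses ``log(-log S) = shape*log t - shape*log scale`` over points with
    survival strictly inside (0, 1) and positive time.
    """
    t = np.array([p.time for p in points], dtype=float)
    s = np.array([p.survival for p in points], dtype=float)
    keep = (t > 0) & (s > 0) & (s < 1)
    t, s = t[keep], s[keep]
    if t.size < 2:
        raise ValueError("need at least two points with survival in (0, 1)")
    x = np.log(t)
    if np.allclose(x, x[0]):
        raise ValueError("degenerate points: all at the same time")
    y = np.log(-np.log(s))
    shape, intercept = np.polyfit(x, y, 1)
    if shape <= 0:
        raise ValueError("fitted shape is not positive; survival not decreasing")
    return WeibullModel(float(shape), float(math.exp(-intercept / shape)))


def calibrate_to_survival(
    m: WeibullModel, horizon: float, target_survival: float
) -> WeibullModel:
    """Rescale so that S(horizon) equals the target exactly, keeping shape."""
    if not (0.0 < target_survival < 1.0):
        raise ValueError("target survival must be in (0, 1)")
    if horizon <= 0:
        raise ValueError("horizon must be > 0")
    scale = horizon / (-math.log(target_survival)) ** (1.0 / m.shape)
    return WeibullModel(m.shape, scale)


def apply_hazard_ratio(m: WeibullModel, hr: float) -> WeibullModel:
    """Proportional-hazards shift: shape preserved, scale * hr^(-1/shape)."""
    if hr <= 0:
        raise ValueError("hazard ratio must be > 0")
    return WeibullModel(m.shape, m.scale * hr ** (-1.0 / m.shape))
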