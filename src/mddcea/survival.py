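"""Probability/rate conversions and relapse-hazard machinery.

Monthly cycle probabilities are derived from annual probabilities on the
constant-rate scale, relative risks act on the log-survival (rate) scale so
results stay inside [0, 1], and relapse from remission follows a Weibull
relapse-free survival curve whose clock restarts at each new remission entry.
"""

from __future__ import annotations

import math

import numpy as np

from .parameters import RelapseSpec, ValidationError
from .synthetic_data import SurvivalPoint

__all__ = [
    "annual_to_monthly_prob",
    "monthly_to_annual_prob",
    "apply_rr_to_prob",
    "weibull_survival",
    "monthly_relapse_prob",
    "fit_weibull",
]


def annual_to_monthly_prob(p_annual: float) -> float:
    """Convert an annual event probability to a 1-month cycle probability.

    Constant-rate conversion: ``1 - (1 - p)**(1/12)``.
    """
    if not (0.0 <= p_annual <= 1.0):
        raise ValidationError(f"annual probability must be in [0, 1]; got {p_annual!r}")
    return 1.0 - (1.0 - p_annual) ** (1.0 / 12.0)


def monthly_to_annual_prob(p_monthly: float) -> float:
    """Exact inverse of :func:`annual_to_monthly_prob`."""
    if not (0.0 <= p_monthly <= 1.0):
        raise ValidationError(f"monthly probability must be in [0, 1]; got {p_monthly!r}")
    return 1.0 - (1.0 - p_monthly) ** 12.0


def apply_rr_to_prob(p: float, rr: float) -> float:
    """Apply a relative risk to a cycle probability on the rate scale.

    ``1 - (1 - p)**rr`` — equals ``p * rr`` to first order in ``p`` but stays
    in [0, 1] for any ``rr > 0``.
    """
    if not (0.0 <= p <= 1.0):
        raise ValidationError(f"probability must be in [0, 1]; got {p!r}")
    if not rr > 0:
        raise ValidationError(f"relative risk must be > 0; got {rr!r}")
    return 1.0 - (1.0 - p) ** rr


def weibull_survival(t: float, shape: float, scale: float) -> float:
    """S(t) = exp(-(t/scale)^shape)."""
    if t < 0:
        raise ValidationError(f"time must be >= 0; got {t!r}")
    return math.exp(-((t / scale) ** shape))


def monthly_relapse_prob(
    cycle_in_remission: int, spec: RelapseSpec, base: RelapseSpec | None = None
) -> float:
    """Probability of relapsing during the next month of remission.

    ``cycle_in_remission`` counts completed months since entering remission
    (0 for the first remission month).  For a Weibull spec this is the
    conditional probability ``1 - S(t+1)/S(t)``; for a relative-risk spec the
    base (placebo) curve's conditional probability is adjusted on the rate
    scale.  The clock is the caller's: it restarts at each remission entry.
    """
    if cycle_in_remission < 0:
        raise ValidationError(f"cycle_in_remission must be >= 0; got {cycle_in_remission!r}")
    spec.validate(prefix="relapse")
    if spec.mode == "weibull":
        t = float(cycle_in_remission)
        s_now = weibull_survival(t, spec.weibull_shape, spec.weibull_scale)
        s_next = weibull_survival(t + 1.0, spec.weibull_shape, spec.weibull_scale)
        return min(1.0, max(0.0, 1.0 - s_next / s_now))
    if base is None or base.mode != "weibull":
        raise ValidationError("rr_vs_placebo relapse requires a weibull base (placebo) spec")
    p_base = monthly_relapse_prob(cycle_in_remission, base)
    return apply_rr_to_prob(p_base, spec.rr)


def fit_weibull(points: list[SurvivalPoint]) -> tuple[RelapseSpec, float]:
    """Least-squares Weibull fit to relapse-free survival points.

    Fits the linearised form ``ln(-ln S) = shape·ln t - shape·ln scale`` by
    ordinary least squares over the points with ``t > 0`` and ``0 < S < 1``.
    Returns the fitted spec together with the residual sum of squares on the
    linearised scale.
    """
    usable = [p for p in points if p.time > 0 and 0.0 < p.survival < 1.0]
    if len(usable) < 2:
        raise ValidationError("weibull fit needs at least 2 points with t > 0 and 0 < S < 1")
    x = np.log([p.time for p in usable])
    y = np.log(-np.log([p.survival for p in usable]))
    slope, intercept = np.polyfit(x, y, 1)
    if not slope > 0:
        raise ValidationError(f"fitted weibull shape is not positive ({slope!r}); survival must decrease with time")
    shape = float(slope)
    scale = float(math.exp(-intercept / slope))
    rss = float(np.sum((y - (slope * x + intercept)) ** 2))
    return RelapseSpec.weibull(shape, scale), rss
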