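"""Second-order Monte Carlo (probabilistic sensitivity analysis).

Every scalar model parameter receives a sampling distribution chosen by its
nature — beta for quantities bounded on [0, 1] (probabilities, utilities),
lognormal for positive-scale quantities (costs, relative risks, survival
parameters) — with parameters set by method of moments from the point
estimate and a standard deviation equal to 10% of the mean where no
published spread exists.  Each Monte Carlo iteration draws one joint
parameter set, rebuilds the configuration, runs every arm, and records the
incremental cost and QALYs of the reference arm against each comparator.
The draws feed dominance proportions, percentile bootstrap intervals and
cost-effectiveness acceptability curves (CEACs).
"""

from __future__ import annotations

import copy
import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .economics import incremental_analysis, summarize_arm
from .markov_engine import run_cohort
from .parameters import (
    ModelConfig,
    ValidationError,
    ValidationWarning,
    iter_numeric_params,
    set_param,
)

__all__ = [
    "ParamDistribution",
    "PsaResult",
    "CeacCurve",
    "assign_distributions",
    "moment_match",
    "sample_distribution",
    "run_psa",
    "ceac",
    "bootstrap_summary",
]

logger = logging.getLogger(__name__)

DEFAULT_SD_RULE = 0.10


@dataclass
class ParamDistribution:
    """Sampling distribution for one config parameter."""

    path: str
    family: str  # 'beta' | 'lognormal' | 'fixed'
    mean: float
    sd: float

    def __post_init__(self):
        if self.family not in ("beta", "lognormal", "fixed"):
            raise ValidationError(f"{self.path}: unknown family {self.family!r}")
        if self.sd < 0:
            raise ValidationError(f"{self.path}: sd must be >= 0")
        if self.sd == 0:
            self.family = "fixed"
        if self.family == "beta" and not (0.0 < self.mean < 1.0):
            raise ValidationError(f"{self.path}: beta mean must be in (0, 1); got {self.mean!r}")
        if self.family == "lognormal" and not self.mean > 0:
            raise ValidationError(f"{self.path}: lognormal mean must be > 0; got {self.mean!r}")


def assign_distributions(config: ModelConfig, sd_rule: float = DEFAULT_SD_RULE) -> list[ParamDistribution]:
    """Choose a distribution for every scalar parameter of the config.

    Probabilities and utilities become beta, positive-scale quantities
    (costs, relative risks, Weibull parameters) lognormal; parameters at a
    degenerate mean (0, 1, or 0 cost) are held fixed.  ``sd_rule`` sets the
    standard deviation as a fraction of the mean.
    """
    dists = []
    for path, value, kind in iter_numeric_params(config):
        if kind in ("probability", "utility"):
            family = "fixed" if value in (0.0, 1.0) else "beta"
        else:  # cost, rr, positive
            family = "fixed" if value == 0.0 else "lognormal"
        dists.append(ParamDistribution(path=path, family=family, mean=value, sd=sd_rule * value))
    return dists


def moment_match(family: str, mean: float, sd: float) -> dict[str, float]:
    """Method-of-moments parameters for ``family`` at the requested moments.

    beta: alpha = m(m(1-m)/s^2 - 1), beta = (1-m)(m(1-m)/s^2 - 1), feasible
    only when s^2 < m(1-m).  lognormal: sigma^2 = ln(1 + s^2/m^2),
    mu = ln m - sigma^2/2.
    """
    if sd == 0 or family == "fixed":
        return {"value": mean}
    if family == "beta":
        var = sd * sd
        limit = mean * (1.0 - mean)
        if var >= limit:
            raise ValidationError(
                f"beta moments infeasible: sd^2={var!r} must be < mean(1-mean)={limit!r}"
            )
        nu = limit / var - 1.0
        return {"alpha": mean * nu, "beta": (1.0 - mean) * nu}
    if family == "lognormal":
        if not mean > 0:
            raise ValidationError("lognormal mean must be > 0")
        sigma2 = math.log(1.0 + (sd * sd) / (mean * mean))
        return {"mu": math.log(mean) - sigma2 / 2.0, "sigma": math.sqrt(sigma2)}
    raise ValidationError(f"unknown family {family!r}")


def sample_distribution(dist: ParamDistribution, rng: np.random.Generator) -> float:
    params = moment_match(dist.family, dist.mean, dist.sd)
    if dist.family == "fixed" or dist.sd == 0:
        return dist.mean
    if dist.family == "beta":
        return float(rng.beta(params["alpha"], params["beta"]))
    return float(rng.lognormal(params["mu"], params["sigma"]))


@dataclass
class PsaResult:
    """Monte Carlo draws of pairwise increments versus each comparator.

    ``delta_cost`` and ``delta_qalys`` are (n_iterations x n_comparators)
    arrays of reference-minus-comparator increments; ``arm_costs`` and
    ``arm_qalys`` store the per-arm discounted totals behind them.
    """

    reference: str
    comparators: list[str]
    delta_cost: np.ndarray
    delta_qalys: np.ndarray
    arm_names: list[str]
    arm_costs: np.ndarray
    arm_qalys: np.ndarray
    seed: int
    n_iterations: int
    n_redraws: int = 0

    def comparator_index(self, comparator: str) -> int:
        try:
            return self.comparators.index(comparator)
        except ValueError:
            raise ValidationError(
                f"unknown comparator {comparator!r}; valid: {self.comparators}"
            ) from None


def _draw_config(
    base: ModelConfig, dists: list[ParamDistribution], rng: np.random.Generator
) -> tuple[ModelConfig, int]:
    """Draw one feasible config; redraw wholesale on validation failure."""
    redraws = 0
    while True:
        candidate = copy.deepcopy(base)
        for dist in dists:
            set_param(candidate, dist.path, sample_distribution(dist, rng))
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ValidationWarning)
                candidate.validate()
            return candidate, redraws
        except ValidationError:
            redraws += 1
            if redraws > 1000:
                raise


def run_psa(
    config: ModelConfig,
    n: int = 1000,
    seed: int = 0,
    sd_rule: float = DEFAULT_SD_RULE,
    reference: str | None = None,
    distributions: list[ParamDistribution] | None = None,
) -> PsaResult:
    """Second-order Monte Carlo over ``n`` joint parameter draws.

    One parameter set is drawn per iteration and shared across all arms, so
    common inputs (utilities, state costs) move together and do not inject
    spurious incremental noise.
    """
    if n < 1:
        raise ValidationError(f"n must be >= 1; got {n!r}")
    if distributions is None:
        distributions = assign_distributions(config, sd_rule=sd_rule)
    ref_name = reference if reference is not None else config.treatments[0].name
    config.treatment(ref_name)  # existence check
    arm_names = [t.name for t in config.treatments]
    comparators = [name for name in arm_names if name != ref_name]
    rng = np.random.default_rng(seed)

    arm_costs = np.zeros((n, len(arm_names)))
    arm_qalys = np.zeros((n, len(arm_names)))
    total_redraws = 0
    for it in range(n):
        drawn, redraws = _draw_config(config, distributions, rng)
        total_redraws += redraws
        for j, t in enumerate(drawn.treatments):
            res = summarize_arm(run_cohort(t, drawn), t, drawn)
            arm_costs[it, j] = res.total_cost
            arm_qalys[it, j] = res.total_qalys
    if total_redraws > 0.01 * n:
        logger.warning("PSA redraw rate %.1f%% exceeds 1%%", 100.0 * total_redraws / n)

    ref_idx = arm_names.index(ref_name)
    comp_idx = [arm_names.index(c) for c in comparators]
    delta_cost = arm_costs[:, [ref_idx]] - arm_costs[:, comp_idx]
    delta_qalys = arm_qalys[:, [ref_idx]] - arm_qalys[:, comp_idx]
    return PsaResult(
        reference=ref_name,
        comparators=comparators,
        delta_cost=delta_cost,
        delta_qalys=delta_qalys,
        arm_names=arm_names,
        arm_costs=arm_costs,
        arm_qalys=arm_qalys,
        seed=seed,
        n_iterations=n,
        n_redraws=total_redraws,
    )


@dataclass
class CeacCurve:
    """Acceptability curve: P(NMB >= 0) over a willingness-to-pay grid."""

    comparator: str
    wtp: np.ndarray
    probability: np.ndarray
    probability_dominant: float


def ceac(result: PsaResult, comparator: str, wtp_grid) -> CeacCurve:
    """Cost-effectiveness acceptability curve against one comparator."""
    wtp = np.asarray(list(wtp_grid), dtype=float)
    if wtp.size == 0:
        raise ValidationError("wtp_grid must not be empty")
    if np.any(np.diff(wtp) <= 0):
        raise ValidationError("wtp_grid must be strictly increasing")
    j = result.comparator_index(comparator)
    dc = result.delta_cost[:, j]
    dq = result.delta_qalys[:, j]
    prob = np.array([np.mean(w * dq - dc >= 0) for w in wtp])
    dominant = float(np.mean((dc < 0) & (dq > 0)))
    return CeacCurve(comparator=comparator, wtp=wtp, probability=prob, probability_dominant=dominant)


def bootstrap_summary(
    result: PsaResult, n_boot: int = 1000, seed: int = 0, ci: float = 0.95
) -> dict[str, dict[str, float]]:
    """Percentile bootstrap intervals for mean increments per comparator."""
    if n_boot < 1:
        raise ValidationError(f"n_boot must be >= 1; got {n_boot!r}")
    rng = np.random.default_rng(seed)
    n = result.n_iterations
    lo_q, hi_q = 100 * (1 - ci) / 2, 100 * (1 + ci) / 2
    out: dict[str, dict[str, float]] = {}
    idx = rng.integers(0, n, size=(n_boot, n))
    for j, comp in enumerate(result.comparators):
        dc = result.delta_cost[:, j]
        dq = result.delta_qalys[:, j]
        boot_dc = dc[idx].mean(axis=1)
        boot_dq = dq[idx].mean(axis=1)
        out[comp] = {
            "mean_delta_cost": float(dc.mean()),
            "delta_cost_lo": float(np.percentile(boot_dc, lo_q)),
            "delta_cost_hi": float(np.percentile(boot_dc, hi_q)),
            "mean_delta_qalys": float(dq.mean()),
            "delta_qalys_lo": float(np.percentile(boot_dq, lo_q)),
            "delta_qalys_hi": float(np.percentile(boot_dq, hi_q)),
        }
    return out
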