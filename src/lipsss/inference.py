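"""Prior-augmented least-squares cost and point estimation.

The cost is

    C(theta) = 1/2 sum_i ((m_sim_i - m_exp_i) / sigma_i)^2 + sum_j prior(theta_j)

with lognormal priors on the auxiliary parameters t_trans and the ratio
j_exch/j_tca, and a uniform([0,1]) + half-normal tail prior on p_anap.  The
primary parameters j_tca and p_dil carry no prior.  exp(-C) is the
(unnormalized) posterior sampled by the MCMC module.

Point estimation is three-phase: a coarse grid scan of the 5-dimensional
parameter space (the cost basin is shallow and multimodal), Nelder-Mead
simplex refinement from the best grid point, then posterior sampling.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit

from .model import (
    DEFAULT_T_SAMPLE,
    ODESystem,
    build_system,
    simulate_fast,
)
from .network import (
    ConfigError,
    LabelSchedule,
    ModelParameters,
    NetworkConfig,
    PARAM_ORDER,
    default_config,
)
from .nmr import MULTIPLETS_BY_NAME, NMRSample, compile_multiplet

__all__ = [
    "PriorSpec",
    "CostBreakdown",
    "CostEvaluator",
    "sigma_from_factor",
    "lognormal_prior_cost",
    "panap_constants",
    "panap_prior_cost",
    "prior_costs",
    "default_priors",
    "total_cost",
    "default_grid",
    "grid_optimize",
    "simplex_refine",
    "params_to_z",
    "z_to_params",
]

#: reference values from the cardiac labeling literature
TTRANS_PRIOR_REF = 0.202      # min
TTRANS_PRIOR_SIGMA = 0.336    # log-space SD, = sigma_from_factor(1.96) to 3 dp
RATIO_PRIOR_REF = 1.0         # j_exch / j_tca
PANAP_HALF_SIGMA = 0.3        # half-normal SD of the p_anap tail above 1


def sigma_from_factor(f: float) -> float:
    """Log-space prior SD such that the central 95% region spans
    [theta*/f, theta*.f]:  (ln(theta*f) - ln(theta/f)) / 4 = ln(f)/2."""
    if not f > 1:
        raise ValueError(f"factor must be > 1, got {f}")
    return math.log(f) / 2.0


@dataclass(frozen=True)
class PriorSpec:
    """Prior on one auxiliary quantity.

    ``target`` is a parameter name or ``"jexch_jtca_ratio"``; ``family`` is
    ``"lognormal"`` or ``"uniform_halfnormal"`` (the p_anap prior).  ``scale``
    is a global width multiplier (2.0 reproduces the doubled-prior
    sensitivity re-analysis).
    """

    target: str
    family: str
    ref: float = 1.0
    sigma: float = 1.0
    scale: float = 1.0

    def __post_init__(self):
        if self.family not in ("lognormal", "uniform_halfnormal"):
            raise ConfigError(f"unknown prior family {self.family!r}")
        if self.family == "lognormal" and not self.ref > 0:
            raise ConfigError("lognormal prior needs ref > 0")
        if not self.sigma > 0 or not self.scale > 0:
            raise ConfigError("prior sigma and scale must be > 0")

    @property
    def effective_sigma(self) -> float:
        return self.sigma * self.scale

    def value_of(self, params: ModelParameters) -> float:
        if self.target == "jexch_jtca_ratio":
            if params.j_tca <= 0:
                raise ValueError("ratio prior needs j_tca > 0")
            return params.j_exch / params.j_tca
        return getattr(params, self.target)

    def cost(self, params: ModelParameters) -> float:
        theta = self.value_of(params)
        if self.family == "lognormal":
            return lognormal_prior_cost(theta, self.ref, self.effective_sigma)
        return panap_prior_cost(theta, self.effective_sigma)


def default_priors(scale: float = 1.0) -> tuple[PriorSpec, ...]:
    """t_trans ~ lognormal(0.202, 0.336); j_exch/j_tca ~ lognormal(1,
    ln(15)/2); p_anap ~ uniform[0,1] + half-normal(sd 0.3) tail."""
    return (
        PriorSpec("t_trans", "lognormal", TTRANS_PRIOR_REF, TTRANS_PRIOR_SIGMA, scale),
        PriorSpec("jexch_jtca_ratio", "lognormal", RATIO_PRIOR_REF,
                  sigma_from_factor(15.0), scale),
        PriorSpec("p_anap", "uniform_halfnormal", 1.0, PANAP_HALF_SIGMA, scale),
    )


def lognormal_prior_cost(theta: float, ref: float, sigma: float) -> float:
    """1/2 ((ln theta - ln ref)/sigma)^2 (no normalization constant)."""
    if not theta > 0:
        raise ValueError(f"lognormal prior needs theta > 0, got {theta}")
    return 0.5 * ((math.log(theta) - math.log(ref)) / sigma) ** 2


def panap_constants(sigma: float = PANAP_HALF_SIGMA) -> tuple[float, float]:
    """Constants (c1, c2) of the p_anap prior density: uniform height c1 on
    [0, 1] continued by c2 * Normal(1, sigma) above 1.  Continuity at 1 and a
    unit total integral give c2 = 1/(0.5 + 1/sqrt(2 pi sigma^2)) and
    c1 = 1 - c2/2."""
    peak = 1.0 / (sigma * math.sqrt(2.0 * math.pi))
    c2 = 1.0 / (0.5 + peak)
    c1 = 1.0 - 0.5 * c2
    return c1, c2


def panap_prior_cost(p: float, sigma: float = PANAP_HALF_SIGMA) -> float:
    """-log of the p_anap prior density (constant -ln c1 on [0, 1])."""
    if p < 0:
        raise ValueError(f"p_anap prior needs p >= 0, got {p}")
    c1, c2 = panap_constants(sigma)
    if p <= 1.0:
        return -math.log(c1)
    z = (p - 1.0) / sigma
    log_norm = math.log(c2) - math.log(sigma * math.sqrt(2.0 * math.pi))
    return -(log_norm - 0.5 * z * z)


def prior_costs(params: ModelParameters,
                priors: Sequence[PriorSpec]) -> dict[str, float]:
    return {sp.target: sp.cost(params) for sp in priors}


@dataclass(frozen=True)
class CostBreakdown:
    """Total cost plus the per-multiplet data terms and per-prior terms."""

    total: float
    data_terms: Mapping[str, float]
    prior_terms: Mapping[str, float]

    @property
    def data_total(self) -> float:
        return sum(self.data_terms.values())

    @property
    def prior_total(self) -> float:
        return sum(self.prior_terms.values())


class CostEvaluator:
    """Cost of one sample as a function of the five parameters.

    Compiles the network once per sample (the glutamate concentration is a
    per-sample measurement) and uses the fully compiled integration path, so
    a single evaluation costs a few milliseconds.
    """

    def __init__(
        self,
        sample: NMRSample,
        config: NetworkConfig | None = None,
        priors: Sequence[PriorSpec] | None = None,
        t_sample: float = DEFAULT_T_SAMPLE,
        observed_pool: str = "glutamate",
        rtol: float = 1e-6,
        atol: float = 1e-9,
    ):
        self.sample = sample
        self.config = config or default_config()
        self.priors = tuple(default_priors() if priors is None else priors)
        self.t_sample = t_sample
        self.rtol, self.atol = rtol, atol
        self.system: ODESystem = build_system(
            self.config.pools, self.config.transitions,
            concentration_overrides={observed_pool: sample.glutamate_conc})
        self.schedule: LabelSchedule = self.config.schedule
        self._pool_slice = self.system.pool_slice(observed_pool)
        self.names = tuple(sample.multiplets)
        if not self.names:
            raise ConfigError(f"sample {sample.sample_id!r} has no multiplets")
        try:
            defs = [MULTIPLETS_BY_NAME[n] for n in self.names]
        except KeyError as exc:
            raise ConfigError(f"unknown multiplet {exc.args[0]!r}") from None
        self._idx = [compile_multiplet(d) for d in defs]
        self._m_exp = sample.intensity_array()
        self._sigma = sample.sigma_array()
        self.n_evaluations = 0

    def m_sim(self, params: ModelParameters) -> np.ndarray:
        y = simulate_fast(params, self.system, self.schedule, self.t_sample,
                          rtol=self.rtol, atol=self.atol)
        glu = y[self._pool_slice]
        return np.array([glu[ix].sum() for ix in self._idx])

    def data_cost(self, params: ModelParameters) -> float:
        r = (self.m_sim(params) - self._m_exp) / self._sigma
        return 0.5 * float(r @ r)

    def __call__(self, params: ModelParameters) -> float:
        self.n_evaluations += 1
        c = self.data_cost(params)
        for sp in self.priors:
            c += sp.cost(params)
        return c

    def breakdown(self, params: ModelParameters) -> CostBreakdown:
        r = (self.m_sim(params) - self._m_exp) / self._sigma
        data_terms = {n: 0.5 * float(v * v) for n, v in zip(self.names, r)}
        prior_terms = prior_costs(params, self.priors)
        total = sum(data_terms.values()) + sum(prior_terms.values())
        return CostBreakdown(total, data_terms, prior_terms)


def total_cost(
    params: ModelParameters,
    sample: NMRSample,
    priors: Sequence[PriorSpec] | None = None,
    config: NetworkConfig | None = None,
    t_sample: float = DEFAULT_T_SAMPLE,
) -> CostBreakdown:
    """One-shot cost breakdown (convenience wrapper over CostEvaluator)."""
    return CostEvaluator(sample, config, priors, t_sample).breakdown(params)


# ---------------------------------------------------------------------------
# optimization / sampling coordinates
# ---------------------------------------------------------------------------
# z = (ln j_tca, ln j_exch, ln t_trans, logit p_dil, p_anap).  The log and
# logit coordinates are the model's natural parameters: the auxiliary priors
# are Gaussian over the *logarithms* (their dropped normalization constant
# is that of the log-space Gaussian), so the posterior density is taken over
# these coordinates directly and exp(z) reports the parameter values.
# p_anap stays on the raw axis because its uniform + half-normal prior is a
# normalized density over p_anap itself.  Positivity and the [0, 1] bound of
# p_dil are enforced by the coordinates, not by clipping.

def params_to_z(params: ModelParameters) -> np.ndarray:
    v = params.as_array()
    if np.any(v[[0, 1, 2]] <= 0) or not 0 < v[3] < 1:
        raise ValueError(
            "sampling coordinates require strictly positive fluxes and"
            " p_dil in (0, 1)")
    return np.array([math.log(v[0]), math.log(v[1]), math.log(v[2]),
                     math.log(v[3] / (1.0 - v[3])), v[4]])


def z_to_params(z: Sequence[float]) -> ModelParameters:
    z = np.asarray(z, dtype=float)
    p_dil = float(expit(z[3]))
    return ModelParameters(math.exp(z[0]), math.exp(z[1]), math.exp(z[2]),
                           p_dil, float(z[4]))


# ---------------------------------------------------------------------------
# grid + simplex optimization
# ---------------------------------------------------------------------------

def default_grid(
    midpoints: Mapping[str, float] | None = None,
    n_positive: int = 7,
    span: float = 30.0,
    n_dil: int = 5,
) -> dict[str, np.ndarray]:
    """Log-spaced grid over the positive parameters (factor ``span`` around
    physiologic midpoints), linear for p_dil."""
    mid = {"j_tca": 6.0, "j_exch": 6.0, "t_trans": TTRANS_PRIOR_REF,
           "p_anap": 0.25}
    mid.update(midpoints or {})
    half = math.sqrt(span)
    grid = {
        k: np.geomspace(mid[k] / half, mid[k] * half, n_positive)
        for k in ("j_tca", "j_exch", "t_trans", "p_anap")
    }
    grid["p_dil"] = np.linspace(0.05, 0.95, n_dil)
    return {k: grid[k] for k in PARAM_ORDER}


def grid_optimize(
    cost_fn: Callable[[ModelParameters], float],
    grid: Mapping[str, Sequence[float]],
) -> tuple[ModelParameters, float]:
    """Exhaustive scan; ties break to the lexicographically first grid index."""
    axes = []
    for k in PARAM_ORDER:
        vals = np.asarray(grid.get(k, ()), dtype=float)
        if vals.size == 0:
            raise ConfigError(f"empty grid for parameter {k!r}")
        axes.append(vals)
    best, best_cost = None, math.inf
    for combo in itertools.product(*axes):
        p = ModelParameters(*combo)
        c = cost_fn(p)
        if c < best_cost:
            best, best_cost = p, c
    return best, best_cost


def simplex_refine(
    cost_fn: Callable[[ModelParameters], float],
    start: ModelParameters,
    fatol: float = 1e-8,
    max_evaluations: int = 5000,
) -> tuple[ModelParameters, float]:
    """Nelder-Mead refinement in transformed coordinates.

    Guaranteed no worse than the start (the incumbent is kept if the
    optimizer cannot improve it)."""
    z0 = params_to_z(start)
    c0 = cost_fn(start)
    if not math.isfinite(c0):
        raise ValueError(f"non-finite cost at start: {c0}")

    def f(z):
        try:
            return cost_fn(z_to_params(z))
        except (OverflowError, FloatingPointError, ValueError):
            return math.inf  # e.g. a negative p_anap excursion of the simplex

    res = minimize(f, z0, method="Nelder-Mead",
                   options={"fatol": fatol, "xatol": 1e-8,
                            "maxfev": max_evaluations})
    if math.isfinite(res.fun) and res.fun < c0:
        return z_to_params(res.x), float(res.fun)
    return start, c0
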