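"""Adaptive Metropolis-Hastings sampling of the posterior
Pr(theta | D) proportional to exp(-C(theta)).

The random walk runs in the sampling coordinates (log fluxes and time
constant, logit dilution, raw anaplerotic ratio - the spaces the priors are
densities over), with a diagonal Gaussian proposal whose per-coordinate
scales are adapted in batches during burn-in (targeting an acceptance
fraction between 0.2 and 0.5) and frozen afterwards, so the kept chain is a
valid fixed-kernel MH sample.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .inference import params_to_z, z_to_params
from .network import ModelParameters, PARAM_ORDER

__all__ = [
    "EnsembleResult",
    "QualityFlag",
    "adaptive_metropolis",
    "sample_posterior",
    "integrated_autocorr_time",
    "summarize_ensemble",
    "quality_filter",
]

DEFAULT_N_DRAWS = 35_000
DEFAULT_SD_THRESHOLD = 10.0   # umol/(min*gdw), ensemble SD of j_tca
DEFAULT_TAU_THRESHOLD = 500.0  # draws; above this the trace deserves a look
PRIMARY_PARAMETERS = ("j_tca", "p_dil")

# Generous physiologic box in the transformed coordinates.  Only samples
# whose data carry (almost) no flux information ever reach these walls: for
# them the j_tca direction has no stationary distribution (no prior on the
# primary parameters), the walk would drift indefinitely, and the ensemble
# SD correctly explodes past the quality threshold either way.
DEFAULT_Z_BOUNDS = (
    np.array([math.log(1e-4), math.log(1e-4), math.log(1e-4), -30.0, 0.0]),
    np.array([math.log(1e4), math.log(1e4), math.log(1e3), 30.0, 1e3]),
)


def adaptive_metropolis(
    log_density: Callable[[np.ndarray], tuple[float, float]],
    z0: np.ndarray,
    n_draws: int,
    seed: int,
    n_burn: int | None = None,
    init_scales: float | Sequence[float] = 0.1,
    batch: int = 100,
    accept_band: tuple[float, float] = (0.2, 0.5),
    sample_mask: Sequence[bool] | None = None,
    bounds: tuple[np.ndarray, np.ndarray] | None = None,
) -> dict:
    """Generic adaptive random-walk MH in R^d.

    ``log_density(z)`` returns ``(log density, aux)``; the aux value (here:
    the cost) is stored alongside each kept draw.  Coordinates where
    ``sample_mask`` is False are held fixed.  Proposals outside ``bounds``
    (lo, hi) are rejected.  Scale adaptation is diminishing and stops at
    burn-in end.
    """
    z = np.asarray(z0, dtype=float).copy()
    d = z.shape[0]
    if n_burn is None:
        n_burn = max(1, int(0.1 * n_draws))
    rng = np.random.default_rng(seed)
    scales = np.broadcast_to(np.asarray(init_scales, dtype=float), (d,)).copy()
    mask = np.ones(d, dtype=bool) if sample_mask is None else \
        np.asarray(sample_mask, dtype=bool)
    ld, aux = log_density(z)
    if not math.isfinite(ld):
        raise ValueError(f"non-finite log density at start: {ld}")
    chain = np.empty((n_draws, d))
    aux_out = np.empty(n_draws)
    n_acc = 0
    batch_acc = 0
    batch_no = 0
    floor = 1e-6
    for it in range(n_burn + n_draws):
        step = rng.standard_normal(d) * scales
        step[~mask] = 0.0
        z_prop = z + step
        if bounds is not None and (np.any(z_prop < bounds[0])
                                   or np.any(z_prop > bounds[1])):
            ld_prop = -math.inf
            aux_prop = math.inf
        else:
            ld_prop, aux_prop = log_density(z_prop)
        if math.log(rng.random()) < ld_prop - ld:
            z, ld, aux = z_prop, ld_prop, aux_prop
            n_acc += 1
            batch_acc += 1
        if it < n_burn and (it + 1) % batch == 0:
            batch_no += 1
            frac = batch_acc / batch
            delta = min(0.25, 1.0 / math.sqrt(batch_no))
            if frac < accept_band[0]:
                scales[mask] *= math.exp(-delta)
            elif frac > accept_band[1]:
                scales[mask] *= math.exp(delta)
            if np.all(scales[mask] < floor):
                scales[mask] = floor  # step-size floor; avoid a dead chain
            batch_acc = 0
        if it >= n_burn:
            chain[it - n_burn] = z
            aux_out[it - n_burn] = aux
    return {
        "chain": chain,
        "aux": aux_out,
        "acceptance_rate": n_acc / (n_burn + n_draws),
        "scales": scales,
        "n_burn": n_burn,
    }


@dataclass(frozen=True)
class QualityFlag:
    passed: bool
    reason: str
    flags: tuple[str, ...] = ()


@dataclass
class EnsembleResult:
    """MCMC ensemble for one sample: the kept chain (original parameter
    space), per-draw costs, the best fit seen anywhere (including the
    optimization phase), and diagnostics."""

    param_names: tuple[str, ...]
    chain: np.ndarray            # (n_draws, 5), original parameter space
    costs: np.ndarray
    best_params: ModelParameters
    best_cost: float
    acceptance_rate: float
    tau: dict[str, float]
    n_burn: int
    seed: int
    quality: QualityFlag | None = None

    def column(self, name: str) -> np.ndarray:
        return self.chain[:, self.param_names.index(name)]

    def sd(self, name: str) -> float:
        return float(np.std(self.column(name), ddof=1))


def sample_posterior(
    cost_fn: Callable[[ModelParameters], float],
    start: ModelParameters,
    n_draws: int = DEFAULT_N_DRAWS,
    seed: int = 0,
    n_burn: int | None = None,
    init_scales: float | Sequence[float] = 0.1,
    sample_mask: Sequence[bool] | None = None,
    quality_sd_threshold: float = DEFAULT_SD_THRESHOLD,
    tau_threshold: float = DEFAULT_TAU_THRESHOLD,
) -> EnsembleResult:
    """Sample exp(-C(theta)) starting from the (simplex-refined) best fit.

    ``sample_mask`` lets prior-recovery runs hold the unconstrained primary
    parameters fixed (their posterior is improper without a data term).
    Reproducible given ``seed``.
    """
    best = {"cost": math.inf, "params": None}

    def log_density(z):
        try:
            p = z_to_params(z)
        except (OverflowError, ValueError):
            return -math.inf, math.inf
        c = cost_fn(p)
        if c < best["cost"]:
            best["cost"], best["params"] = c, p
        # Pr(theta|D) ratio = e^{-C(theta')} / e^{-C(theta)}; the log/logit
        # coordinates are the natural parameters (see inference module)
        return -c, c

    out = adaptive_metropolis(
        log_density, params_to_z(start), n_draws, seed, n_burn=n_burn,
        init_scales=init_scales, sample_mask=sample_mask,
        bounds=DEFAULT_Z_BOUNDS)
    chain_z = out["chain"]
    chain = np.column_stack([
        np.exp(chain_z[:, 0]), np.exp(chain_z[:, 1]), np.exp(chain_z[:, 2]),
        1.0 / (1.0 + np.exp(-chain_z[:, 3])), chain_z[:, 4],
    ])
    tau = {name: integrated_autocorr_time(chain[:, i])
           for i, name in enumerate(PARAM_ORDER)}
    result = EnsembleResult(
        param_names=PARAM_ORDER, chain=chain, costs=out["aux"],
        best_params=best["params"], best_cost=best["cost"],
        acceptance_rate=out["acceptance_rate"], tau=tau,
        n_burn=out["n_burn"], seed=seed)
    result.quality = quality_filter(result, quality_sd_threshold, tau_threshold)
    return result


def integrated_autocorr_time(x: Sequence[float]) -> float:
    """Integrated autocorrelation time (draws) via Geyer's initial positive
    sequence estimator; 1.0 for white noise.  A constant chain has no
    defined autocorrelation time and returns the sentinel ``inf``."""
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    if n < 100:
        raise ValueError(f"need a chain of length >= 100, got {n}")
    x = x - x.mean()
    var = float(x @ x) / n
    if var == 0.0 or not math.isfinite(var):
        return math.inf
    nfft = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(f * np.conjugate(f), nfft)[:n] / n
    rho = acov / acov[0]
    tau = -1.0  # pair sums count rho_0 twice
    prev = math.inf
    for m in range(n // 2):
        g = rho[2 * m] + (rho[2 * m + 1] if 2 * m + 1 < n else 0.0)
        if g <= 0.0:
            break
        g = min(g, prev)  # enforce monotonicity (initial convex refinement)
        tau += 2.0 * g
        prev = g
    return max(tau, 1.0)


def _histogram_mode(x: np.ndarray) -> float:
    if np.ptp(x) == 0.0:
        return float(x[0])
    try:
        counts, edges = np.histogram(x, bins="fd")
    except ValueError:
        counts, edges = np.histogram(x, bins="auto")
    if counts.size == 0:
        return float(np.median(x))
    i = int(np.argmax(counts))
    return float(0.5 * (edges[i] + edges[i + 1]))


def summarize_ensemble(result: EnsembleResult) -> pd.DataFrame:
    """Per-parameter mean, SD, median, histogram mode (Freedman-Diaconis
    bins), autocorrelation time and the best-fit point estimate."""
    if result.chain.shape[0] == 0:
        raise ValueError("empty chain")
    rows = {}
    for i, name in enumerate(result.param_names):
        col = result.chain[:, i]
        rows[name] = {
            "mean": float(col.mean()),
            "sd": float(np.std(col, ddof=1)) if col.size > 1 else 0.0,
            "median": float(np.median(col)),
            "mode": _histogram_mode(col),
            "best_fit": getattr(result.best_params, name),
            "tau": result.tau[name],
        }
    return pd.DataFrame(rows).T.loc[list(result.param_names)]


def quality_filter(
    result: EnsembleResult,
    threshold: float = DEFAULT_SD_THRESHOLD,
    tau_threshold: float = DEFAULT_TAU_THRESHOLD,
) -> QualityFlag:
    """Exclude a sample iff the ensemble SD of j_tca *exceeds* the threshold
    (boundary value passes).  High autocorrelation in a primary parameter is
    flagged for trace inspection but does not by itself reject."""
    sd = result.sd("j_tca")
    flags = []
    if any(result.tau[p] > tau_threshold for p in PRIMARY_PARAMETERS):
        flags.append("high_autocorrelation")
    if sd > threshold:
        return QualityFlag(
            False,
            f"ensemble SD(J_TCA) = {sd:.3g} exceeds {threshold:g} umol/(min*gdw)",
            tuple(flags))
    return QualityFlag(True, f"ensemble SD(J_TCA) = {sd:.3g} within threshold",
                       tuple(flags))
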