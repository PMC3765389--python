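"""Synthetic NMR samples and a stochastic oracle for the labeling model.

``generate_sample`` applies the measurement model used for method
validation: simulate multiplet intensities at known fluxes, add Gaussian
noise of stated SD, and zero-assign intensities below the detection
threshold (keeping their SD, as in the real spectra).

``stochastic_oracle`` is an independent check on the ODE model: it tracks a
discrete population of molecules through the same atom maps with
exponential event times.  Pool sizes stay fixed (each inflow event
overwrites a uniformly chosen molecule of the target pool), which
reproduces the fraction-space balance equations in expectation for a
flux-balanced network.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from . import _kernels
from .model import DEFAULT_T_SAMPLE, acetyl_coa_target, build_system, simulate, _segments
from .network import (
    ModelParameters,
    NetworkConfig,
    ROLE_ANAPLEROSIS_IN,
    ROLE_ANAPLEROSIS_OUT,
    ROLE_EXCHANGE,
    ROLE_INPUT,
    ROLE_TCA,
    default_config,
)
from .nmr import (
    MultipletMeasurement,
    NMRSample,
    multiplet_intensities,
)

__all__ = [
    "NoiseModel",
    "GroupSpec",
    "generate_sample",
    "generate_cohort",
    "default_groups",
    "stochastic_oracle",
]


@dataclass(frozen=True)
class NoiseModel:
    """Per-multiplet noise: sigma = max(cv * intensity, floor); measured
    intensities below ``threshold`` are zero-assigned (detected = False).

    The defaults (5% relative noise with a small absolute floor, no
    detection cutoff) are fixture choices for recovery studies, not
    measured spectrometer properties.
    """

    cv: float = 0.05
    floor: float = 0.003
    threshold: float = 0.0
    seed: int | None = None

    def __post_init__(self):
        if self.cv < 0 or self.floor < 0 or self.threshold < 0:
            raise ValueError("noise parameters must be >= 0")
        if self.cv == 0 and self.floor == 0:
            raise ValueError("need a positive cv or floor (sigma must be > 0)")


def generate_sample(
    true_params: ModelParameters,
    config: NetworkConfig | None = None,
    noise: NoiseModel = NoiseModel(),
    *,
    sample_id: str = "S1",
    heart_id: str = "H1",
    group: str = "synthetic",
    glutamate_conc: float = 20.0,
    dry_weight_g: float = 0.1,
    t_sample: float = DEFAULT_T_SAMPLE,
    multiplet_names: Sequence[str] | None = None,
    rng: np.random.Generator | None = None,
) -> NMRSample:
    """Simulate one sample's multiplets at known fluxes and corrupt them."""
    cfg = config or default_config()
    if rng is None:
        rng = np.random.default_rng(noise.seed)
    system = build_system(cfg.pools, cfg.transitions,
                          concentration_overrides={"glutamate": glutamate_conc})
    vec = simulate(true_params, system, cfg.schedule, t_sample)
    m_sim = multiplet_intensities(vec["glutamate"])
    if multiplet_names is not None:
        m_sim = {k: m_sim[k] for k in multiplet_names}
    measurements = {}
    for name, m in m_sim.items():
        sigma = max(noise.cv * m, noise.floor)
        if sigma > 0:
            m_exp = m + rng.normal(0.0, sigma)
        else:  # noiseless limit (cv = 0 would need floor > 0; kept for clarity)
            m_exp = m
        if m_exp < noise.threshold:
            measurements[name] = MultipletMeasurement(0.0, sigma, detected=False)
        else:
            measurements[name] = MultipletMeasurement(float(m_exp), sigma)
    return NMRSample(sample_id, heart_id, group, dry_weight_g,
                     glutamate_conc, measurements)


@dataclass(frozen=True)
class GroupSpec:
    """One experimental group of the synthetic cohort.

    Mean parameters vary lognormally between hearts (``cv_between``) and
    again between samples within a heart (``cv_within``); p_dil varies on
    the logit scale with comparable spread.  These are fixture values that
    loosely emulate a control/stress design, not measured group statistics.
    """

    name: str
    params: ModelParameters
    n_hearts: int = 6
    samples_per_heart: int = 9
    cv_between: float = 0.15
    cv_within: float = 0.08
    glutamate_conc: float = 20.0
    glutamate_cv: float = 0.15
    dry_weight_g: float = 0.1
    dry_weight_cv: float = 0.25


def default_groups() -> tuple[GroupSpec, ...]:
    """Six groups emulating the control / stenosis / inotropic-stress design
    (group sizes as in the porcine study; flux levels are fixture values)."""
    def gp(name, j_tca, p_dil, n_hearts):
        return GroupSpec(name, ModelParameters(j_tca, j_tca, 0.202, p_dil, 0.2),
                         n_hearts=n_hearts)
    return (
        gp("control", 7.0, 0.25, 7),
        gp("mild_stenosis", 4.1, 0.40, 7),
        gp("moderate_stenosis", 3.0, 0.50, 6),
        gp("dobutamine", 11.2, 0.55, 6),
        gp("adenosine", 7.0, 0.30, 4),
        gp("stenosis_adenosine", 3.5, 0.45, 8),
    )


def _lognormal_around(rng, mean, cv):
    if cv <= 0:
        return mean
    s = np.sqrt(np.log1p(cv * cv))
    return float(mean * np.exp(rng.normal(-0.5 * s * s, s)))


def _jitter_params(rng, p: ModelParameters, cv: float) -> ModelParameters:
    if cv <= 0:
        return p
    logit = np.log(p.p_dil / (1.0 - p.p_dil)) + rng.normal(0.0, 2.0 * cv)
    return ModelParameters(
        _lognormal_around(rng, p.j_tca, cv),
        _lognormal_around(rng, p.j_exch, cv),
        _lognormal_around(rng, p.t_trans, cv),
        float(1.0 / (1.0 + np.exp(-logit))),
        _lognormal_around(rng, p.p_anap, cv),
    )


def generate_cohort(
    groups: Sequence[GroupSpec] | None = None,
    seed: int = 0,
    config: NetworkConfig | None = None,
    noise: NoiseModel = NoiseModel(),
    measurements: bool = True,
) -> tuple[list[NMRSample], pd.DataFrame]:
    """Draw a cohort of hearts and samples with known ground truth.

    Returns ``(samples, truth)``; ``truth`` has one row per sample with the
    true parameters and true MVO2.  With ``measurements=False`` only the
    (cheap) ground-truth table is produced, e.g. for design checks.
    """
    groups = default_groups() if groups is None else tuple(groups)
    rng = np.random.default_rng(seed)
    samples: list[NMRSample] = []
    rows = []
    for g in groups:
        for h in range(g.n_hearts):
            heart_id = f"{g.name}-H{h + 1}"
            heart_params = _jitter_params(rng, g.params, g.cv_between)
            for s in range(g.samples_per_heart):
                sid = f"{heart_id}-S{s + 1}"
                p = _jitter_params(rng, heart_params, g.cv_within)
                conc = _lognormal_around(rng, g.glutamate_conc, g.glutamate_cv)
                dw = _lognormal_around(rng, g.dry_weight_g, g.dry_weight_cv)
                rows.append({
                    "sample_id": sid, "heart_id": heart_id, "group": g.name,
                    "dry_weight_g": dw, "glutamate_umol_per_gdw": conc,
                    **{k: getattr(p, k) for k in
                       ("j_tca", "j_exch", "t_trans", "p_dil", "p_anap")},
                    "mvo2_true": (2.0 + p.p_dil) * p.j_tca,
                })
                if measurements:
                    samples.append(generate_sample(
                        p, config, noise, sample_id=sid, heart_id=heart_id,
                        group=g.name, glutamate_conc=conc, dry_weight_g=dw,
                        rng=rng))
    return samples, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# stochastic molecule-tracking oracle
# ---------------------------------------------------------------------------

def stochastic_oracle(
    params: ModelParameters,
    config: NetworkConfig | None = None,
    n_molecules: int = 100_000,
    t_sample: float = DEFAULT_T_SAMPLE,
    seed: int = 0,
    relax_pool: str = "acetyl_coa",
    observed_pool: str = "glutamate",
    glutamate_conc: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Discrete-event molecule tracking through the atom maps.

    ``n_molecules`` are distributed over the dynamic pools in proportion to
    their concentrations; transitions fire as Poisson events with rates
    flux * weight * N_target / C_target.  Returns the glutamate positional
    enrichments (C1..C5) and their binomial standard errors.
    """
    cfg = config or default_config()
    overrides = {"glutamate": glutamate_conc} if glutamate_conc else None
    pools = []
    for p in cfg.pools:
        if not p.dynamic:
            continue
        if overrides and p.name in overrides:
            p = replace(p, concentration=overrides[p.name])
        pools.append(p)
    names = [p.name for p in pools]
    conc = np.array([p.concentration for p in pools])
    # Allocation affects only the Monte Carlo error, never the expectation.
    # Upstream pools get equal shares and the observed pool a smaller one:
    # otherwise the few molecules of fast-turnover pools are common
    # ancestors of much of the observed pool and the true error of its
    # enrichments exceeds the nominal binomial estimate.
    w = np.ones(len(pools))
    w[names.index(observed_pool)] = 0.25
    n_pool = np.maximum(20, np.round(n_molecules * w / w.sum())).astype(np.int64)
    pool_off = np.concatenate(([0], np.cumsum(n_pool)))[:-1]
    pool_idx = {n: i for i, n in enumerate(names)}
    mol = np.zeros(int(n_pool.sum()), dtype=np.uint8)
    n_carbons = {p.name: p.n_carbons for p in cfg.pools}
    dynamic = {p.name for p in pools}

    def role_flux(role):
        return {
            ROLE_TCA: params.j_tca,
            ROLE_EXCHANGE: params.j_exch,
            ROLE_ANAPLEROSIS_IN: params.p_anap * params.j_tca,
            ROLE_ANAPLEROSIS_OUT: params.p_anap * params.j_tca,
        }[role]

    def map_bits(tr, src_pool, bits):
        out = 0
        for (sp, sc), (tp, tc) in tr.atom_map:
            if sp == src_pool and tp not in ("CO2", "EFFLUX"):
                if bits >> (sc - 1) & 1:
                    out |= 1 << (tc - 1)
        return out

    ev_kind, ev_rate, ev_s1, ev_s2, ev_tgt, ev_n1, tab_off = [], [], [], [], [], [], []
    tables: list[int] = []
    for tr in cfg.transitions:
        if tr.role == ROLE_INPUT or not tr.targets:
            continue
        g = tr.targets[0]
        if g not in dynamic:
            continue
        gi = pool_idx[g]
        rate = role_flux(tr.role) * tr.weight * n_pool[gi] / conc[gi]
        if rate <= 0:
            continue
        dyn_src = [s for s in tr.sources if s in dynamic]
        tab_off.append(len(tables))
        if len(dyn_src) == 2:
            s1, s2 = dyn_src
            n1 = n_carbons[s1]
            # joint table indexed i1 + (i2 << n1)
            table = [0] * (1 << (n1 + n_carbons[s2]))
            for i2 in range(1 << n_carbons[s2]):
                h2 = map_bits(tr, s2, i2)
                for i1 in range(1 << n1):
                    table[i1 + (i2 << n1)] = map_bits(tr, s1, i1) | h2
            tables.extend(table)
            ev_kind.append(_kernels.EV_CONDENSE)
            ev_s1.append(pool_idx[s1]); ev_s2.append(pool_idx[s2]); ev_n1.append(n1)
        elif len(dyn_src) == 1:
            s = dyn_src[0]
            tables.extend(map_bits(tr, s, i) for i in range(1 << n_carbons[s]))
            ev_kind.append(_kernels.EV_SINGLE)
            ev_s1.append(pool_idx[s]); ev_s2.append(-1); ev_n1.append(0)
        else:  # forcing (unlabeled) source
            tables.append(0)
            ev_kind.append(_kernels.EV_FORCING)
            ev_s1.append(-1); ev_s2.append(-1); ev_n1.append(0)
        ev_rate.append(rate)
        ev_tgt.append(gi)
    # acetyl-CoA refresh event
    ri = pool_idx[relax_pool]
    ev_kind.append(_kernels.EV_REFRESH)
    ev_rate.append(n_pool[ri] / params.t_trans)
    ev_s1.append(-1); ev_s2.append(-1); ev_tgt.append(ri); ev_n1.append(0)
    tab_off.append(len(tables))

    ev_kind = np.array(ev_kind, dtype=np.int8)
    ev_rate = np.array(ev_rate)
    ev_s1 = np.array(ev_s1, dtype=np.int64)
    ev_s2 = np.array(ev_s2, dtype=np.int64)
    ev_tgt = np.array(ev_tgt, dtype=np.int64)
    ev_n1 = np.array(ev_n1, dtype=np.int64)
    tab_off = np.array(tab_off, dtype=np.int64)
    tab = np.array(tables, dtype=np.uint8)

    rng = np.random.default_rng(seed)
    for (a, e) in _segments(cfg.schedule, t_sample):
        comp = acetyl_coa_target(0.5 * (a + e), cfg.schedule, params.p_dil)
        refresh_cum = np.cumsum(comp)
        mol = _kernels.run_events(
            mol, pool_off, n_pool, ev_kind, ev_rate, ev_s1, ev_s2, ev_tgt,
            ev_n1, tab, tab_off, refresh_cum, a, e,
            int(rng.integers(0, 2**31 - 1)))

    oi = pool_idx[observed_pool]
    obs = mol[pool_off[oi]:pool_off[oi] + n_pool[oi]]
    nc = n_carbons[observed_pool]
    enrich = np.array([np.mean(obs >> c & 1) for c in range(nc)], dtype=float)
    se = np.sqrt(np.maximum(enrich * (1 - enrich), 1.0 / n_pool[oi]) / n_pool[oi])
    return enrich, se
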