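"""Independent oracles used by the test suite.

These deliberately re-derive quantities from the network *configuration*
by direct enumeration, sharing no code with the compiled implementation
paths they check.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

from lipsss.network import ACETYL_ISOTOPOMER, ROLE_INPUT

_SINKS = ("CO2", "EFFLUX")


def role_flux(role, params):
    return {
        "TCA": params.j_tca,
        "EXCHANGE": params.j_exch,
        "ANAPLEROSIS_IN": params.p_anap * params.j_tca,
        "ANAPLEROSIS_OUT": params.p_anap * params.j_tca,
    }[role]


def acetyl_target(t, schedule, p_dil):
    tgt = np.zeros(4)
    tgt[0] = p_dil
    for species, frac in schedule.composition_at(t).items():
        tgt[ACETYL_ISOTOPOMER[species]] += (1 - p_dil) * frac
    return tgt


def brute_force_rhs(state, t, params, cfg, relax_pool="acetyl_coa"):
    """Flux-by-flux recomputation of the balance equations by enumerating
    every transition's joint source isotopomer distribution."""
    pools = {p.name: p for p in cfg.pools}
    dynamic = [p for p in cfg.pools if p.dynamic]
    deriv = {p.name: np.zeros(1 << p.n_carbons) for p in dynamic}
    # relaxation of the entry pool
    x_relax = state[relax_pool]
    deriv[relax_pool] += (acetyl_target(t, cfg.schedule, params.p_dil)
                          - x_relax) / params.t_trans
    for tr in cfg.transitions:
        if tr.role == ROLE_INPUT:
            continue
        F = role_flux(tr.role, params) * tr.weight
        if F == 0.0:
            continue
        # proportional removal from consumed dynamic sources
        for s in tr.sources:
            if pools[s].dynamic and s != relax_pool:
                deriv[s] -= F / pools[s].concentration * state[s]
        if not tr.targets:
            continue
        g = tr.targets[0]
        # joint enumeration over all source isotopomer combinations
        axes = []
        for s in tr.sources:
            if pools[s].dynamic:
                axes.append([(s, i, state[s][i])
                             for i in range(1 << pools[s].n_carbons)])
            else:  # forcing pools are unlabeled
                axes.append([(s, 0, 1.0)])
        for combo in itertools.product(*axes):
            prob = 1.0
            tbits = 0
            for (s, iso, w) in combo:
                prob *= w
                for (sp, sc), (tp, tc) in tr.atom_map:
                    if sp == s and tp == g and (iso >> (sc - 1) & 1):
                        tbits |= 1 << (tc - 1)
            if prob != 0.0:
                deriv[g][tbits] += F / pools[g].concentration * prob
    return deriv


def positional_steady_state(cfg, params, relax_pool="acetyl_coa"):
    """Steady-state positional enrichments by a linear solve over
    (pool, carbon) sites, with the entry pool pinned at its asymptotic
    composition.  Valid for a constant-composition schedule."""
    pools = {p.name: p for p in cfg.pools}
    tgt = acetyl_target(0.0, cfg.schedule, params.p_dil)
    relax_enrich = {
        c: sum(tgt[i] for i in range(4) if i >> (c - 1) & 1)
        for c in (1, 2)
    }
    sites = [(p.name, c) for p in cfg.pools
             if p.dynamic and p.name != relax_pool
             for c in range(1, p.n_carbons + 1)]
    index = {s: i for i, s in enumerate(sites)}
    A = np.zeros((len(sites), len(sites)))
    rhs = np.zeros(len(sites))
    outflux = {s: 0.0 for s in index}
    for tr in cfg.transitions:
        if tr.role == ROLE_INPUT:
            continue
        F = role_flux(tr.role, params) * tr.weight
        if F == 0.0:
            continue
        for (sp, sc), (tp, tc) in tr.atom_map:
            if tp in _SINKS or not pools[tp].dynamic:
                continue
            if tp == relax_pool:
                continue
            row = index[(tp, tc)]
            if sp == relax_pool:
                rhs[row] -= F * relax_enrich[sc]
            elif pools[sp].dynamic:
                A[row, index[(sp, sc)]] += F
            # forcing sources are unlabeled: contribute 0
        # track outflux per source site (label leaving with any destination)
        for s in tr.sources:
            if pools[s].dynamic and s != relax_pool:
                for c in range(1, pools[s].n_carbons + 1):
                    outflux[(s, c)] += F
    for site, i in index.items():
        A[i, i] -= outflux[site]
    e = np.linalg.solve(A, rhs)
    out = {}
    for (p, c), i in index.items():
        out.setdefault(p, {})[c] = e[i]
    return out


def eq1_cost(m_sim, m_exp, sigma, params, ttrans_ref=0.202, ttrans_sd=0.336,
             ratio_sd=math.log(15) / 2, panap_sd=0.3):
    """Direct transcription of the prior-augmented least-squares cost."""
    c = 0.0
    for ms, me, sd in zip(m_sim, m_exp, sigma):
        c += 0.5 * ((ms - me) / sd) ** 2
    c += 0.5 * ((math.log(params.t_trans) - math.log(ttrans_ref)) / ttrans_sd) ** 2
    c += 0.5 * (math.log(params.j_exch / params.j_tca) / ratio_sd) ** 2
    peak = 1.0 / (panap_sd * math.sqrt(2 * math.pi))
    c2 = 1.0 / (0.5 + peak)
    c1 = 1.0 - 0.5 * c2
    if params.p_anap <= 1.0:
        c += -math.log(c1)
    else:
        c += -math.log(c2 * peak
                       * math.exp(-0.5 * ((params.p_anap - 1) / panap_sd) ** 2))
    return c
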