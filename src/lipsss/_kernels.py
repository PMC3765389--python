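"""numba-compiled hot loops: ODE right-hand side/Jacobian and the
stochastic molecule-tracking event loop."""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def rhs(x, M, b, cs1, cs2, ct, ck):
    """d/dt of the isotopomer-fraction state.

    ``M`` carries all terms linear in the state, ``b`` the constant inflows
    (anaplerotic unlabeled inflow, acetyl-CoA relaxation target), and the
    ``c*`` arrays the bilinear condensation pairs (citrate synthase):
    d[ct[m]] += ck[m] * x[cs1[m]] * x[cs2[m]].
    """
    d = M.dot(x) + b
    for m in range(cs1.shape[0]):
        d[ct[m]] += ck[m] * x[cs1[m]] * x[cs2[m]]
    return d


@njit(cache=True)
def jac(x, M, cs1, cs2, ct, ck):
    J = M.copy()
    for m in range(cs1.shape[0]):
        J[ct[m], cs1[m]] += ck[m] * x[cs2[m]]
        J[ct[m], cs2[m]] += ck[m] * x[cs1[m]]
    return J


# event kinds for the stochastic oracle
EV_SINGLE = 0      # map a random source molecule, replace a random target molecule
EV_CONDENSE = 1    # combine random molecules of two source pools
EV_FORCING = 2     # replace a random target molecule with a fixed pattern
EV_REFRESH = 3     # redraw a random relax-pool molecule from the target composition


@njit(cache=True)
def run_events(mol, pool_off, pool_n,
               ev_kind, ev_rate, ev_src1, ev_src2, ev_tgt,
               ev_n1, tab, tab_off,
               refresh_cum, t0, t1, seed):
    """Advance the molecule population from t0 to t1.

    mol : uint8 array of per-molecule isotopomer bit patterns, all pools
          concatenated; pool_off/pool_n give each pool's slice.
    Events fire as a merged Poisson process with constant per-event rates;
    each event samples source molecules uniformly (without removal - the
    sources' own replacement events account for turnover) and overwrites a
    uniformly chosen target molecule, which keeps pool sizes fixed and
    reproduces the fraction-space balance equations in expectation.
    refresh_cum : cumulative probabilities over the 4 acetyl-CoA isotopomers
          for EV_REFRESH draws (phase- and p_dil-dependent).
    """
    np.random.seed(seed)
    n_ev = ev_rate.shape[0]
    total = 0.0
    for e in range(n_ev):
        total += ev_rate[e]
    cum = np.empty(n_ev)
    acc = 0.0
    for e in range(n_ev):
        acc += ev_rate[e]
        cum[e] = acc
    t = t0
    while True:
        t += -np.log(np.random.random()) / total
        if t >= t1:
            break
        r = np.random.random() * total
        e = np.searchsorted(cum, r)
        if e >= n_ev:
            e = n_ev - 1
        kind = ev_kind[e]
        tgt = ev_tgt[e]
        jt = pool_off[tgt] + int(np.random.random() * pool_n[tgt])
        if kind == EV_SINGLE:
            s = ev_src1[e]
            i = pool_off[s] + int(np.random.random() * pool_n[s])
            mol[jt] = tab[tab_off[e] + mol[i]]
        elif kind == EV_CONDENSE:
            s1 = ev_src1[e]
            s2 = ev_src2[e]
            i1 = pool_off[s1] + int(np.random.random() * pool_n[s1])
            i2 = pool_off[s2] + int(np.random.random() * pool_n[s2])
            idx = int(mol[i1]) + (int(mol[i2]) << ev_n1[e])
            mol[jt] = tab[tab_off[e] + idx]
        elif kind == EV_FORCING:
            mol[jt] = tab[tab_off[e]]
        else:  # EV_REFRESH
            u = np.random.random()
            iso = 0
            while refresh_cum[iso] < u and iso < 3:
                iso += 1
            mol[jt] = iso
    return mol


@njit(cache=True)
def _rhs_csr(y, data, indices, indptr, b, cs1, cs2, ct, ck, out):
    n = y.shape[0]
    for i in range(n):
        acc = b[i]
        for k in range(indptr[i], indptr[i + 1]):
            acc += data[k] * y[indices[k]]
        out[i] = acc
    for m in range(cs1.shape[0]):
        out[ct[m]] += ck[m] * y[cs1[m]] * y[cs2[m]]


@njit(cache=True)
def rk_phase(y, data, indices, indptr, b, cs1, cs2, ct, ck,
             t0, t1, rtol, atol, hmax, max_steps):
    """Adaptive Cash-Karp RK5(4) over one infusion phase.

    The step is additionally capped at ``hmax`` (a stability bound derived
    from the fastest pool turnover rate), so the explicit method stays
    stable on the mildly stiff balance system while the embedded error
    estimate governs accuracy.  Returns (y, 0) on success, (y, 1) on
    step-size underflow, (y, 2) if max_steps is exceeded.
    """
    n = y.shape[0]
    k1 = np.empty(n); k2 = np.empty(n); k3 = np.empty(n)
    k4 = np.empty(n); k5 = np.empty(n); k6 = np.empty(n)
    yt = np.empty(n)
    t = t0
    h = min(hmax, (t1 - t0) * 0.1)
    steps = 0
    while t1 - t > 1e-10:
        if h > t1 - t:
            h = t1 - t
        _rhs_csr(y, data, indices, indptr, b, cs1, cs2, ct, ck, k1)
        for i in range(n):
            yt[i] = y[i] + h * 0.2 * k1[i]
        _rhs_csr(yt, data, indices, indptr, b, cs1, cs2, ct, ck, k2)
        for i in range(n):
            yt[i] = y[i] + h * (0.075 * k1[i] + 0.225 * k2[i])
        _rhs_csr(yt, data, indices, indptr, b, cs1, cs2, ct, ck, k3)
        for i in range(n):
            yt[i] = y[i] + h * (0.3 * k1[i] - 0.9 * k2[i] + 1.2 * k3[i])
        _rhs_csr(yt, data, indices, indptr, b, cs1, cs2, ct, ck, k4)
        for i in range(n):
            yt[i] = y[i] + h * ((-11.0 / 54.0) * k1[i] + 2.5 * k2[i]
                                + (-70.0 / 27.0) * k3[i] + (35.0 / 27.0) * k4[i])
        _rhs_csr(yt, data, indices, indptr, b, cs1, cs2, ct, ck, k5)
        for i in range(n):
            yt[i] = y[i] + h * ((1631.0 / 55296.0) * k1[i] + (175.0 / 512.0) * k2[i]
                                + (575.0 / 13824.0) * k3[i]
                                + (44275.0 / 110592.0) * k4[i]
                                + (253.0 / 4096.0) * k5[i])
        _rhs_csr(yt, data, indices, indptr, b, cs1, cs2, ct, ck, k6)
        errn = 0.0
        for i in range(n):
            y5 = y[i] + h * ((37.0 / 378.0) * k1[i] + (250.0 / 621.0) * k3[i]
                             + (125.0 / 594.0) * k4[i] + (512.0 / 1771.0) * k6[i])
            y4 = y[i] + h * ((2825.0 / 27648.0) * k1[i] + (18575.0 / 48384.0) * k3[i]
                             + (13525.0 / 55296.0) * k4[i] + (277.0 / 14336.0) * k5[i]
                             + 0.25 * k6[i])
            sc = atol + rtol * abs(y[i])
            e = (y5 - y4) / sc
            errn += e * e
            yt[i] = y5
        errn = np.sqrt(errn / n)
        if errn <= 1.0:
            t += h
            for i in range(n):
                y[i] = yt[i]
            fac = 5.0 if errn == 0.0 else min(5.0, max(0.2, 0.9 * errn ** -0.2))
            h = min(h * fac, hmax)
        else:
            h *= max(0.2, 0.9 * errn ** -0.25)
        if h < 1e-12:
            return y, 1
        steps += 1
        if steps > max_steps:
            return y, 2
    return y, 0
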