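"""Low-level stochastic simulation kernels.

The Gillespie loops for the transcriptional network and for the 500-site
regulatory region dominate the cost of a colony simulation (tens of millions
of site-transition events per colony), so they are written as plain-numpy
functions and compiled with numba.  All kernels are also valid pure Python
and remain importable (slowly) if numba is unavailable.

Random numbers inside the kernels come from numba's per-thread legacy
MT19937 stream, seeded explicitly per call; callers derive those seeds from
``numpy.random.Generator`` streams so that every trajectory is reproducible
from a single root seed.

Species index order used throughout: R=0, T=1, G=2, P=3, X=4, N=5.
Site state codes: C=0, I=1, O=2.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit
except ImportError:  # pragma: no cover - numba is a declared dependency
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(func):
            return func

        return wrap


#: species order for all 6-vectors
R_, T_, G_, P_, X_, N_ = 0, 1, 2, 3, 4, 5

# epigenetic channel table: (source, target) with C=0, I=1, O=2.
# channels 0-3 are the input-coupled ("direct") ones, 4-8 the mediated ones.
_EPI_SRC = np.array([2, 1, 0, 1, 2, 1, 1, 0, 1], dtype=np.int64)
_EPI_TGT = np.array([1, 0, 1, 2, 1, 0, 2, 1, 0], dtype=np.int64)


@njit(cache=True)
def grn_production_rates(s, p, kd):
    """Shea-Ackers production rates (h^-1) for the six species.

    ``s`` may hold integer molecule counts (SSA) or real concentrations
    (ODE mode).  ``p`` is the length-16 regulation parameter vector and
    ``kd`` the per-gene multiplicative knockdown factors.
    """
    R = s[0]
    T = s[1]
    G = s[2]
    P = s[3]
    N = s[5]
    out = np.empty(6)
    out[0] = kd[0] * (p[0] * R + p[1] * N) / (1.0 + p[0] * R + p[1] * N)
    out[1] = kd[1] * (p[2] * T + p[3] * G + p[4] * N / (p[5] + P)) / (
        1.0 + p[2] * T + p[3] * G + p[4] * N + p[6] * P
    )
    out[2] = kd[2] * (p[7] * T + p[8] * N / (p[9] + P)) / (
        1.0 + p[7] * T + p[8] * N + p[10] * P
    )
    out[3] = kd[3] * (p[11] * P) / (1.0 + p[11] * P + p[12] * R * G * T)
    out[4] = kd[4] * 1.0 / (1.0 + p[13] * T + p[14] * G)
    out[5] = kd[5] * p[15] / (1.0 + N)
    return out


@njit(cache=True)
def grn_degradation_rates(s, gamma):
    """First-order decay rates gamma_i * count; Notch has no decay channel."""
    out = np.empty(6)
    for i in range(5):
        out[i] = gamma[i] * s[i]
    out[5] = 0.0
    return out


@njit(cache=True)
def grn_ssa(s0, t0, t1, p, gamma, kd0, kd1, t_switch, seed):
    """Exact SSA for the six-species network over [t0, t1].

    ``kd0`` applies while t < t_switch, ``kd1`` afterwards (used for delayed
    knockdowns; pass t_switch = inf for none).  Returns the event record
    (times, states) with the initial state first; the state is piecewise
    constant between events and holds up to t1.
    """
    np.random.seed(seed)
    s = s0.astype(np.float64)
    cap = 256
    times = np.empty(cap)
    states = np.empty((cap, 6), dtype=np.int64)
    times[0] = t0
    for i in range(6):
        states[0, i] = s0[i]
    n = 1
    t = t0
    while t < t1:
        if t < t_switch:
            kd = kd0
        else:
            kd = kd1
        prod = grn_production_rates(s, p, kd)
        deg = grn_degradation_rates(s, gamma)
        tot = prod.sum() + deg.sum()
        bound = t1
        if t < t_switch and t_switch < t1:
            bound = t_switch
        if tot <= 0.0:
            t = bound
            continue
        dt = np.random.exponential(1.0 / tot)
        if t + dt > bound:
            # no event before the boundary; memorylessness lets us restart
            t = bound
            continue
        t = t + dt
        u = np.random.random() * tot
        idx = -1
        sign = 1
        acc = 0.0
        for i in range(6):
            acc += prod[i]
            if u < acc:
                idx = i
                break
        if idx < 0:
            for i in range(6):
                acc += deg[i]
                if u < acc:
                    idx = i
                    sign = -1
                    break
        if idx < 0:
            # floating-point edge at u ~= tot; skip (measure zero)
            continue
        s[idx] += sign
        if n == cap:
            cap2 = cap * 2
            nt = np.empty(cap2)
            ns = np.empty((cap2, 6), dtype=np.int64)
            nt[:cap] = times
            ns[:cap] = states
            times = nt
            states = ns
            cap = cap2
        times[n] = t
        for i in range(6):
            states[n, i] = np.int64(s[i])
        n += 1
    return times[:n], states[:n]


@njit(cache=True)
def epi_channel_rates(c, i_, o, S, X, R, N, k1, k2, k3, al, be, gm, de, ep):
    """Propensities of the nine site-transition channels (h^-1).

    Order: [O->I direct, I->C direct, C->I direct, I->O direct,
    O->I med. C, I->C med. C, I->O med. O, C->I med. O, I->C med. I].

    Each channel's attempt rate (k1*X, k2*N + k3*R, or a mediated-rate
    constant) is multiplied by the probability that a uniformly chosen site
    matches the channel's source state (count/S), and for mediated channels
    also by the probability that a second uniformly chosen site matches the
    mediator state.  This aggregates the rejection scheme exactly: sites are
    exchangeable, so only the acceptance probabilities matter.
    """
    r = np.empty(9)
    opening = k2 * N + k3 * R
    r[0] = k1 * X * o / S
    r[1] = k1 * X * i_ / S
    r[2] = opening * c / S
    r[3] = opening * i_ / S
    r[4] = al * (o / S) * (c / S)
    r[5] = be * (i_ / S) * (c / S)
    r[6] = gm * (i_ / S) * (o / S)
    r[7] = de * (c / S) * (o / S)
    r[8] = ep * (i_ / S) * (i_ / S)
    return r


@njit(cache=True)
def epi_ssa(c0, i0, o0, S, gt, gX, gR, gN, t0, t1,
            k1, k2, k3, al, be, gm, de, ep, seed, record):
    """SSA for the regulatory region driven by a piecewise-constant input.

    ``gt`` holds the input change-point times (ascending), ``gX/gR/gN`` the
    X, Runx1 and Notch counts on each segment.  At every input change the
    waiting-time draw is restarted with updated propensities, which is exact
    for piecewise-constant hazards.  Returns (times, states, C, I, O); the
    event record has length 1 when ``record`` is false.
    """
    np.random.seed(seed)
    c = c0
    i_ = i0
    o = o0
    m = len(gt)
    j = 0
    while j + 1 < m and gt[j + 1] <= t0:
        j += 1
    cap = 256
    times = np.empty(cap)
    states = np.empty((cap, 3), dtype=np.int64)
    times[0] = t0
    states[0, 0] = c
    states[0, 1] = i_
    states[0, 2] = o
    n = 1
    t = t0
    while t < t1:
        X = gX[j]
        R = gR[j]
        N = gN[j]
        rates = epi_channel_rates(float(c), float(i_), float(o), float(S),
                                  X, R, N, k1, k2, k3, al, be, gm, de, ep)
        tot = rates.sum()
        nb = t1
        if j + 1 < m and gt[j + 1] < t1:
            nb = gt[j + 1]
        if tot <= 0.0:
            t = nb
            if nb >= t1:
                break
            j += 1
            continue
        dt = np.random.exponential(1.0 / tot)
        if t + dt > nb:
            t = nb
            if nb >= t1:
                break
            j += 1
            continue
        t = t + dt
        u = np.random.random() * tot
        idx = -1
        acc = 0.0
        for k in range(9):
            acc += rates[k]
            if u < acc:
                idx = k
                break
        if idx < 0:
            continue
        src = _EPI_SRC[idx]
        tgt = _EPI_TGT[idx]
        if src == 0:
            c -= 1
        elif src == 1:
            i_ -= 1
        else:
            o -= 1
        if tgt == 0:
            c += 1
        elif tgt == 1:
            i_ += 1
        else:
            o += 1
        if record:
            if n == cap:
                cap2 = cap * 2
                nt = np.empty(cap2)
                ns = np.empty((cap2, 3), dtype=np.int64)
                nt[:cap] = times
                ns[:cap] = states
                times = nt
                states = ns
                cap = cap2
            times[n] = t
            states[n, 0] = c
            states[n, 1] = i_
            states[n, 2] = o
            n += 1
    return times[:n], states[:n], c, i_, o
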