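"""Numba kernels for diffusion simulation and binned kernel density evaluation.

The simulator uses an Euler scheme with a Brownian-bridge absorption
correction: after each full step that stays inside (0, a), the exact
probability that the bridge between the two endpoints crossed a boundary in
between is applied. This keeps coarse step sizes (up to ~10 ms) accurate;
the oracle-equivalence tests pin this down against the series solution.
"""

import math

import numpy as np
from numba import njit

_U64 = np.uint64
_MUL = _U64(0x2545F4914F6CDD1D)
_SM1 = _U64(0x9E3779B97F4A7C15)
_SM2 = _U64(0xBF58476D1CE4E5B9)
_SM3 = _U64(0x94D049BB133111EB)
_INV53 = 1.0 / 9007199254740992.0  # 2^-53
_TWO_PI = 2.0 * math.pi


@njit(cache=True, fastmath=True, inline="always")
def _mix_seed(seed):
    """splitmix64 finalizer: spreads a small integer over 64 bits."""
    x = _U64(seed) + _SM1
    x = (x ^ (x >> _U64(30))) * _SM2
    x = (x ^ (x >> _U64(27))) * _SM3
    return x ^ (x >> _U64(31))


@njit(cache=True, fastmath=True, inline="always")
def _next_u64(state):
    """xorshift64* step; returns (new_state, value)."""
    x = state
    x ^= x >> _U64(12)
    x ^= x << _U64(25)
    x ^= x >> _U64(27)
    return x, x * _MUL


@njit(cache=True, fastmath=True)
def simulate_cell_kernel(v_mean, s_d, a, z, s_z, s, dt, max_time, n, seed):
    """Simulate n first passages; returns (decision times, upper flags).

    Unabsorbed trials (decision time would exceed max_time) get time = inf.
    Uses an inlined xorshift64* generator with Box-Muller normals; seeded
    independently of numpy's global state.
    """
    st = _mix_seed(seed)
    if st == _U64(0):
        st = _SM1
    rts = np.empty(n)
    upper = np.zeros(n, dtype=np.int8)
    sq = s * np.sqrt(dt)
    max_steps = int(max_time / dt) + 1
    two_inv_s2dt = 2.0 / (s * s * dt)
    # beyond this product of boundary distances the bridge crossing
    # probability is < exp(-22) ~ 3e-10 and can be skipped
    skip = 22.0 / two_inv_s2dt
    spare = 0.0
    have_spare = False
    for i in range(n):
        # trial drift and start point
        if s_d == 0.0:
            v = v_mean
        else:
            st, r1 = _next_u64(st)
            st, r2 = _next_u64(st)
            u1 = ((r1 >> _U64(11)) + _U64(1)) * _INV53
            u2 = (r2 >> _U64(11)) * _INV53
            mag = math.sqrt(-2.0 * math.log(u1))
            v = v_mean + s_d * (mag * math.cos(_TWO_PI * u2))
            spare = mag * math.sin(_TWO_PI * u2)
            have_spare = True
        if s_z == 0.0:
            x = z
        else:
            st, r1 = _next_u64(st)
            x = z + s_z * ((r1 >> _U64(11)) * _INV53 - 0.5)
        t = np.inf
        up = 0
        vdt = v * dt
        for step in range(1, max_steps + 1):
            if have_spare:
                g = spare
                have_spare = False
            else:
                st, r1 = _next_u64(st)
                st, r2 = _next_u64(st)
                u1 = ((r1 >> _U64(11)) + _U64(1)) * _INV53
                u2 = (r2 >> _U64(11)) * _INV53
                mag = math.sqrt(-2.0 * math.log(u1))
                g = mag * math.cos(_TWO_PI * u2)
                spare = mag * math.sin(_TWO_PI * u2)
                have_spare = True
            xn = x + vdt + sq * g
            if xn >= a:
                t = (step - 0.5) * dt
                up = 1
                break
            if xn <= 0.0:
                t = (step - 0.5) * dt
                up = 0
                break
            # Brownian-bridge crossing probabilities within the step
            qu = (a - x) * (a - xn)
            ql = x * xn
            if qu < skip or ql < skip:
                p_up = math.exp(-qu * two_inv_s2dt) if qu < skip else 0.0
                p_lo = math.exp(-ql * two_inv_s2dt) if ql < skip else 0.0
                st, r1 = _next_u64(st)
                u = (r1 >> _U64(11)) * _INV53
                if u < p_up:
                    t = (step - 0.5) * dt
                    up = 1
                    break
                elif u < p_up + p_lo:
                    t = (step - 0.5) * dt
                    up = 0
                    break
            x = xn
        rts[i] = t
        upper[i] = up
    return rts, upper


@njit(cache=True)
def binned_kde_logpdf(obs, centers, counts, h, weight, n_total, floor):
    """Log of (weight * Gaussian-KDE density) at each obs, from binned sample.

    ``centers``/``counts`` form a histogram of the synthetic sample (bin
    width much smaller than h); the KDE is evaluated against bin centers.
    Density is floored at ``floor`` before the log.
    """
    out = np.empty(obs.shape[0])
    norm = weight / (n_total * h * np.sqrt(2.0 * np.pi))
    nb = centers.shape[0]
    for i in range(obs.shape[0]):
        acc = 0.0
        x = obs[i]
        for b in range(nb):
            c = counts[b]
            if c > 0.0:
                u = (x - centers[b]) / h
                if u < 8.0 and u > -8.0:
                    acc += c * np.exp(-0.5 * u * u)
        d = norm * acc
        if d < floor:
            d = floor
        out[i] = np.log(d)
    return out


@njit(cache=True)
def pda_cell_loglik(obs_rt, obs_upper, v_mean, s_d, a, z, s_z, s, t_nd,
                    dt, max_decision_time, n_syn, seed, floor, n_bins):
    """PDA log-likelihood of one design cell's observed (choice, RT) data.

    Simulates n_syn trials, drops timeouts, builds one defective density per
    response option (binned Gaussian KDE with Silverman bandwidth, mixture
    weight = option's choice proportion among non-timeouts) and sums the log
    density over observations.
    """
    rts, upper = simulate_cell_kernel(v_mean, s_d, a, z, s_z, s, dt,
                                      max_decision_time, n_syn, seed)
    total = 0.0
    n_ok = 0
    for i in range(n_syn):
        if np.isfinite(rts[i]):
            n_ok += 1
    if n_ok < 2:
        return np.log(floor) * obs_rt.shape[0]
    loglik = 0.0
    for opt in range(2):  # 0 lower, 1 upper
        n_obs_opt = 0
        for j in range(obs_rt.shape[0]):
            if obs_upper[j] == opt:
                n_obs_opt += 1
        n_opt = 0
        for i in range(n_syn):
            if np.isfinite(rts[i]) and upper[i] == opt:
                n_opt += 1
        if n_obs_opt == 0:
            continue
        if n_opt < 2:
            loglik += np.log(floor) * n_obs_opt
            continue
        samp = np.empty(n_opt)
        k = 0
        for i in range(n_syn):
            if np.isfinite(rts[i]) and upper[i] == opt:
                samp[k] = rts[i] + t_nd
                k += 1
        # Silverman: 0.9 * min(SD, IQR/1.34) * n^(-1/5)
        m = samp.mean()
        sd = np.sqrt(((samp - m) ** 2).sum() / (n_opt - 1))
        ss = np.sort(samp)
        q1 = ss[int(0.25 * (n_opt - 1))]
        q3 = ss[int(0.75 * (n_opt - 1))]
        spread = min(sd, (q3 - q1) / 1.34)
        h = 0.9 * spread * n_opt ** (-0.2)
        if h < 1e-4:
            h = 1e-4
        lo = ss[0] - 1e-9
        hi = ss[-1] + 1e-9
        width = (hi - lo) / n_bins
        counts = np.zeros(n_bins)
        centers = np.empty(n_bins)
        for b in range(n_bins):
            centers[b] = lo + (b + 0.5) * width
        for i in range(n_opt):
            b = int((samp[i] - lo) / width)
            if b >= n_bins:
                b = n_bins - 1
            counts[b] += 1.0
        w = n_opt / n_ok
        obs_o = np.empty(n_obs_opt)
        k = 0
        for j in range(obs_rt.shape[0]):
            if obs_upper[j] == opt:
                obs_o[k] = obs_rt[j]
                k += 1
        lp = binned_kde_logpdf(obs_o, centers, counts, h, w, n_opt, floor)
        loglik += lp.sum()
    return loglik
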