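"""Numba kernels for the Wiener diffusion model.

Everything here operates on the decision-time axis (rt minus non-decision
time) with diffusion coefficient fixed at 1.  The defective first-passage
density uses the dual small-time / large-time series with an automatic
switch on scaled time; truncation error is bounded by ``ERR``.
"""

import math

import numpy as np
from numba import njit

ERR = 1e-7


@njit(cache=True)
def _fpt_lower_scaled(tau, w):
    """Density of absorption at the lower bound for unit separation, zero
    drift, relative start ``w``, at scaled time ``tau = t / a**2``."""
    if tau <= 0.0:
        return 0.0

    # number of terms needed by each series for truncation error < ERR
    if math.pi * tau * ERR < 1.0:
        kl = math.sqrt(-2.0 * math.log(math.pi * tau * ERR) / (math.pi**2 * tau))
        kl = max(kl, 1.0 / (math.pi * math.sqrt(tau)))
    else:
        kl = 1.0 / (math.pi * math.sqrt(tau))
    if 2.0 * math.sqrt(2.0 * math.pi * tau) * ERR < 1.0:
        ks = 2.0 + math.sqrt(-2.0 * tau * math.log(2.0 * math.sqrt(2.0 * math.pi * tau) * ERR))
        ks = max(ks, math.sqrt(tau) + 1.0)
    else:
        ks = 2.0

    p = 0.0
    if ks < kl:  # small-time expansion
        K = int(math.ceil(ks))
        for k in range(-((K - 1) // 2), ((K - 1) // 2) + 1):
            p += (w + 2.0 * k) * math.exp(-((w + 2.0 * k) ** 2) / (2.0 * tau))
        p /= math.sqrt(2.0 * math.pi * tau**3)
    else:  # large-time expansion
        K = int(math.ceil(kl))
        for k in range(1, K + 1):
            p += k * math.exp(-(k**2) * (math.pi**2) * tau / 2.0) * math.sin(k * math.pi * w)
        p *= math.pi
    return p


@njit(cache=True)
def wfpt_pdf(t_dec, v, a, z, upper):
    """Defective FPT density at decision time ``t_dec`` for the named bound.

    ``z`` is the relative starting point; ``upper=True`` evaluates the
    upper (veracity-promoting) bound via the mirror identity.
    """
    if t_dec <= 0.0:
        return 0.0
    if upper:
        v = -v
        w = 1.0 - z
    else:
        w = z
    tau = t_dec / (a * a)
    f = _fpt_lower_scaled(tau, w)
    if f <= 0.0:
        return 0.0
    return f / (a * a) * math.exp(-v * a * w - v * v * t_dec / 2.0)


@njit(cache=True)
def wfpt_logpdf(t_dec, v, a, z, upper):
    if t_dec <= 0.0:
        return -np.inf
    if upper:
        v = -v
        w = 1.0 - z
    else:
        w = z
    tau = t_dec / (a * a)
    f = _fpt_lower_scaled(tau, w)
    if f <= 0.0:
        return -np.inf
    return math.log(f) - 2.0 * math.log(a) - v * a * w - v * v * t_dec / 2.0


@njit(cache=True)
def subject_logliks(rt, upper, subj_idx, n_subj, v, a, z, t0):
    """Per-subject summed log likelihood over a veracity-coded trial table.

    rt, upper, subj_idx are trial-length arrays; v, a, z, t0 are
    subject-length arrays.  Trials with rt <= t0 contribute -inf.
    """
    out = np.zeros(n_subj)
    for i in range(rt.shape[0]):
        s = subj_idx[i]
        ll = wfpt_logpdf(rt[i] - t0[s], v[s], a[s], z[s], upper[i])
        out[s] += ll
    return out


@njit(cache=True)
def simulate_trials(v, a, z, t0, n, dt, seed):
    """Euler scheme with Brownian-bridge absorption correction.

    Returns (rt, upper) arrays of length ``n``.  The bridge correction
    removes the leading-order discretisation bias in both the absorbed
    fraction and the passage-time law.
    """
    np.random.seed(seed)
    rts = np.empty(n)
    ups = np.empty(n, dtype=np.bool_)
    sq = math.sqrt(dt)
    for i in range(n):
        x = z * a
        t = 0.0
        while True:
            x_new = x + v * dt + sq * np.random.normal()
            t += dt
            if x_new >= a:
                ups[i] = True
                break
            if x_new <= 0.0:
                ups[i] = False
                break
            # bridge crossing probabilities within the step
            p_up = math.exp(-2.0 * (a - x) * (a - x_new) / dt)
            if np.random.random() < p_up:
                ups[i] = True
                break
            p_lo = math.exp(-2.0 * x * x_new / dt)
            if np.random.random() < p_lo:
                ups[i] = False
                break
            x = x_new
        rts[i] = t0 + t
    return rts, ups
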