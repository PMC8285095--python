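"""Numba-compiled batch log-likelihood kernel for the PVL variants."""

import math

import numpy as np
from numba import njit


@njit(cache=True)
def loglik_batch(params, deck_idx, net_scaled, delta_rule, trial_dependent):
    """Per-subject PVL log-likelihoods.

    params      : (n, 4) float64 — retention, consistency, attn_losses,
                  attn_magnitude
    deck_idx    : (n, T) int64 — chosen deck 0..3 per trial
    net_scaled  : (n, T) float64 — net outcome per trial, already scaled
    delta_rule  : True for delta learning, False for decay
    trial_dependent : True for theta=(t/10)**c, False for theta=3**c-1
    """
    n, T = deck_idx.shape
    out = np.empty(n)
    for i in range(n):
        A = params[i, 0]
        c = params[i, 1]
        lam = params[i, 2]
        alpha = params[i, 3]
        E = np.zeros(4)
        theta = 0.0
        if not trial_dependent:
            theta = 3.0**c - 1.0
        ll = 0.0
        for t in range(T):
            if trial_dependent:
                theta = ((t + 1) / 10.0) ** c
            m = E[0]
            for j in range(1, 4):
                if E[j] > m:
                    m = E[j]
            s = 0.0
            for j in range(4):
                s += math.exp(theta * (E[j] - m))
            d = deck_idx[i, t]
            ll += theta * (E[d] - m) - math.log(s)
            x = net_scaled[i, t]
            if x == 0.0:
                u = 0.0
            elif x > 0.0:
                u = x**alpha
            else:
                u = -lam * (-x) ** alpha
            if delta_rule:
                E[d] += A * (u - E[d])
            else:
                for j in range(4):
                    E[j] *= 1.0 - A
                E[d] += u
        out[i] = ll
    return out
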