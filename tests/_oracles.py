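"""Independent brute-force oracles used only by the test suite.

Each oracle is written from the defining formulas with plain loops, kept
deliberately separate from the package's code paths.
"""

import math

import numpy as np


def pvl_loglik_loop(params, deck_idx, net_scaled, learning_rule, choice_rule):
    """Naive per-trial log-likelihood for one subject.

    params: (A, c, lam, alpha); deck_idx: ints 0..3; net_scaled: floats.
    """
    A, c, lam, alpha = params
    E = [0.0, 0.0, 0.0, 0.0]
    ll = 0.0
    for t, (d, x) in enumerate(zip(deck_idx, net_scaled), start=1):
        if choice_rule == "trial_dependent":
            theta = (t / 10.0) ** c
        else:
            theta = 3.0**c - 1.0
        m = max(E)
        denom = sum(math.exp(theta * (e - m)) for e in E)
        ll += theta * (E[d] - m) - math.log(denom)
        if x == 0:
            u = 0.0
        elif x > 0:
            u = x**alpha
        else:
            u = -lam * (-x) ** alpha
        if learning_rule == "delta":
            E[d] = E[d] + A * (u - E[d])
        else:
            E = [e * (1.0 - A) for e in E]
            E[d] = E[d] + u
    return ll


def rhat_textbook(chains):
    """Potential scale reduction from the between/within decomposition."""
    chains = np.asarray(chains, dtype=float)
    m, n = chains.shape
    chain_means = [float(np.mean(c)) for c in chains]
    grand = sum(chain_means) / m
    B = n / (m - 1) * sum((cm - grand) ** 2 for cm in chain_means)
    W = sum(float(np.sum((c - cm) ** 2)) / (n - 1) for c, cm in zip(chains, chain_means)) / m
    var_hat = (n - 1) / n * W + B / n
    return math.sqrt(var_hat / W)


def _nw_spectral_zero(x, lag):
    x = np.asarray(x, dtype=float)
    n = len(x)
    xc = x - x.mean()
    s = float(xc @ xc) / n
    for k in range(1, lag + 1):
        g = float(xc[k:] @ xc[:-k]) / n
        s += 2.0 * (1.0 - k / (lag + 1)) * g
    return max(s, 0.0)


def geweke_textbook(chain, first=0.1, last=0.5):
    x = np.asarray(chain, dtype=float)
    n1 = int(len(x) * first)
    n2 = int(len(x) * last)
    a, b = x[:n1], x[-n2:]
    la = max(1, int(n1**0.5 / 2))
    lb = max(1, int(n2**0.5 / 2))
    va = _nw_spectral_zero(a, la) / n1
    vb = _nw_spectral_zero(b, lb) / n2
    return (a.mean() - b.mean()) / math.sqrt(va + vb)


def two_step_index_oracle(harm, maps):
    """Spreadsheet-style two-step standardization for the health-risk index."""
    harm = [float(v) for v in harm]
    maps = [float(v) for v in maps]
    n = len(harm)

    def zscores(vals):
        mu = sum(vals) / n
        sd = math.sqrt(sum((v - mu) ** 2 for v in vals) / n)
        return [(v - mu) / sd for v in vals]

    zh, zm = zscores(harm), zscores(maps)
    avg = [(a + b) / 2.0 for a, b in zip(zh, zm)]
    return zscores(avg)
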