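"""MCMC convergence diagnostics: Gelman-Rubin R-hat and Geweke z-score."""

from __future__ import annotations

import numpy as np


class DegenerateChainError(ValueError):
    """Raised when a diagnostic is undefined (e.g. constant chains)."""


def gelman_rubin(chains: np.ndarray) -> float:
    """Potential scale reduction factor R-hat for one scalar parameter.

    ``chains`` is (n_chains, n_draws). Uses the classic between/within
    decomposition: W is the mean within-chain variance, B/n the variance of
    chain means, Vhat = (n-1)/n * W + B/n, R-hat = sqrt(Vhat / W). Constant
    chains make W zero, which is flagged rather than reported as 1.
    """
    x = np.asarray(chains, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need >= 2 chains of equal length >= 2")
    m, n = x.shape
    w = x.var(axis=1, ddof=1).mean()
    if w == 0:
        raise DegenerateChainError("zero within-chain variance; R-hat undefined")
    b_over_n = x.mean(axis=1).var(ddof=1)
    vhat = (n - 1) / n * w + b_over_n
    return float(np.sqrt(vhat / w))


def _spectral_density_zero(x: np.ndarray) -> float:
    """S(0) estimate via Bartlett-windowed autocovariances (Newey-West)."""
    n = len(x)
    x = x - x.mean()
    lag = max(1, int(n**0.5 / 2))
    gamma0 = float(x @ x) / n
    s = gamma0
    for k in range(1, lag + 1):
        gamma_k = float(x[k:] @ x[:-k]) / n
        s += 2.0 * (1.0 - k / (lag + 1)) * gamma_k
    return max(s, 0.0)


def geweke(
    chain: np.ndarray, first_fraction: float = 0.1, last_fraction: float = 0.5
) -> float:
    """Geweke stationarity z-score for a single chain.

    Compares the mean of the first ``first_fraction`` of draws with the
    mean of the last ``last_fraction``, with variances of the means
    estimated from the spectral density at frequency zero within each
    window. |z| > ~2-3 indicates non-stationarity.
    """
    x = np.asarray(chain, dtype=float).ravel()
    n1 = int(len(x) * first_fraction)
    n2 = int(len(x) * last_fraction)
    if n1 < 10 or n2 < 10:
        raise ValueError("chain too short for the requested window fractions")
    a, b = x[:n1], x[-n2:]
    if np.ptp(x) == 0:
        raise DegenerateChainError("constant chain; Geweke undefined")
    va = _spectral_density_zero(a) / n1
    vb = _spectral_density_zero(b) / n2
    denom = np.sqrt(va + vb)
    if denom == 0:
        raise DegenerateChainError("zero spectral variance; Geweke undefined")
    return float((a.mean() - b.mean()) / denom)
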