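"""Bayesian linear regression with PVL posterior uncertainty propagation.

Outcomes are regressed on the four PVL decision parameters (optionally
plus age and gender) under improper uniform priors on the coefficients and
an Inverse-Gamma(3, 3) prior on the residual variance. Rather than fixing
the predictors at point estimates, each MCMC iteration draws one joint set
of all subjects' PVL parameters from the stored PVL posterior (preserving
cross-subject posterior correlation), rebuilds the design matrix, and then
draws the regression parameters conditional on it. The resulting
coefficient posteriors therefore carry the PVL estimation uncertainty.

The conditional regression draw is exact (normal for coefficients given
the variance, inverse-gamma for the variance given coefficients); a
Metropolis-Hastings alternative targeting the same conditionals is
available via ``method="mh"`` and agrees within Monte-Carlo error.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .diagnostics import gelman_rubin, geweke
from .hba import GroupPosterior
from .pvl import PARAM_NAMES

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RegressionSpec:
    """What to regress on what.

    Residual variance prior: Inverse-Gamma(shape=3, scale=3), which has
    mean 1.5 and variance 2.25; coefficient priors are improper uniform.
    """

    outcome: str = "outcome"
    covariates: tuple[str, ...] = ()  # e.g. ("age", "gender")
    standardize: bool = False
    var_shape: float = 3.0
    var_scale: float = 3.0


class PointMassDraws:
    """Degenerate PVL 'posterior': fixed per-subject parameters.

    Useful for design-fixed regressions and for checking that propagation
    collapses to ordinary Bayesian regression when there is no PVL
    uncertainty.
    """

    def __init__(self, params: pd.DataFrame):
        missing = [c for c in PARAM_NAMES if c not in params.columns]
        if missing:
            raise ValueError(f"params table missing columns {missing}")
        self.subject_ids = list(params.index)
        self._draws = params[list(PARAM_NAMES)].to_numpy(dtype=float)[None, :, :]

    def subject_draws_combined(self) -> np.ndarray:
        return self._draws


class SubjectDraws:
    """Minimal draw source: explicit (n_draws, n_subjects, 4) array."""

    def __init__(self, subject_ids: Sequence, draws: np.ndarray):
        draws = np.asarray(draws, dtype=float)
        if draws.ndim != 3 or draws.shape[2] != len(PARAM_NAMES):
            raise ValueError("draws must be (n_draws, n_subjects, 4)")
        if draws.shape[1] != len(subject_ids):
            raise ValueError("draws and subject_ids disagree on subject count")
        self.subject_ids = list(subject_ids)
        self._draws = draws

    def subject_draws_combined(self) -> np.ndarray:
        return self._draws


@dataclass
class RegressionPosterior:
    """Kept draws of regression coefficients and residual variance."""

    predictor_names: list[str]
    coef: np.ndarray  # (chains, kept, p)
    sigma2: np.ndarray  # (chains, kept)
    burn_in: int
    seed: int
    spec: RegressionSpec

    @property
    def chain_count(self) -> int:
        return self.coef.shape[0]

    def coef_combined(self) -> np.ndarray:
        c, k, p = self.coef.shape
        return self.coef.reshape(c * k, p)

    def rhat(self) -> dict[str, float]:
        return {
            name: gelman_rubin(self.coef[:, :, j])
            for j, name in enumerate(self.predictor_names)
        }

    def geweke_z(self) -> pd.DataFrame:
        rows = {}
        for j, name in enumerate(self.predictor_names):
            rows[name] = [geweke(self.coef[c, :, j]) for c in range(self.chain_count)]
        return pd.DataFrame(rows).T.rename(columns=lambda c: f"chain_{c}")

    def summary(self, level: float = 0.95) -> pd.DataFrame:
        flat = self.coef_combined()
        rows = []
        for j, name in enumerate(self.predictor_names):
            lo, hi = credible_interval(flat[:, j], level)
            rows.append(
                {
                    "predictor": name,
                    "mean": flat[:, j].mean(),
                    "se": flat[:, j].std(ddof=1),
                    "ci_lower": lo,
                    "ci_upper": hi,
                }
            )
        return pd.DataFrame(rows)


def credible_interval(draws: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    """Central credible interval: empirical quantiles with linear interpolation."""
    x = np.asarray(draws, dtype=float).ravel()
    if len(x) < 100:
        raise ValueError("need at least 100 draws for a credible interval")
    if not np.isfinite(x).all():
        raise ValueError("non-finite draws present")
    lo = (1.0 - level) / 2.0
    return tuple(np.quantile(x, [lo, 1.0 - lo], method="linear"))


def _align(
    pvl_posterior, outcomes: pd.DataFrame, spec: RegressionSpec
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    df = outcomes.set_index("subject_id") if "subject_id" in outcomes.columns else outcomes
    ids = [s for s in pvl_posterior.subject_ids if s in df.index]
    dropped_pvl = [s for s in pvl_posterior.subject_ids if s not in df.index]
    needed = [spec.outcome, *spec.covariates]
    sub = df.loc[ids, needed]
    ok = sub.notna().all(axis=1)
    if not ok.all():
        logger.info("dropping %d subjects with missing outcome/covariates", (~ok).sum())
    if dropped_pvl:
        logger.info("dropping %d subjects without outcome rows", len(dropped_pvl))
    ids = [s for s, keep in zip(ids, ok) if keep]
    sub = sub.loc[ids]
    y = sub[spec.outcome].to_numpy(dtype=float)
    if y.std() == 0:
        raise ValueError("outcome has zero variance")
    cov = sub[list(spec.covariates)].to_numpy(dtype=float) if spec.covariates else np.empty((len(ids), 0))
    draws = pvl_posterior.subject_draws_combined()
    keep_idx = [pvl_posterior.subject_ids.index(s) for s in ids]
    return y, cov, draws[:, keep_idx, :], ids


def _gibbs_step(rng, X, y, sigma2, a_post, b0):
    n, p = X.shape
    XtX = X.T @ X
    L = np.linalg.cholesky(XtX)
    beta_hat = np.linalg.solve(XtX, X.T @ y)
    z = rng.standard_normal(p)
    # beta | sigma2 ~ N(beta_hat, sigma2 * (X'X)^-1)
    beta = beta_hat + np.sqrt(sigma2) * np.linalg.solve(L.T, z)
    resid = y - X @ beta
    rss = resid @ resid
    sigma2 = (b0 + 0.5 * rss) / rng.gamma(a_post)
    return beta, sigma2


def _mh_step(rng, X, y, beta, sigma2, scale, a0, b0):
    n, p = X.shape

    def logpost(b, s2):
        r = y - X @ b
        return (
            -0.5 * n * np.log(s2)
            - 0.5 * (r @ r) / s2
            - (a0 + 1) * np.log(s2)
            - b0 / s2
        )

    XtX = X.T @ X
    cov_chol = np.linalg.cholesky(sigma2 * np.linalg.inv(XtX))
    prop = beta + scale * cov_chol @ rng.standard_normal(p)
    if np.log(rng.uniform()) < logpost(prop, sigma2) - logpost(beta, sigma2):
        beta = prop
    ls2_prop = np.log(sigma2) + 0.5 * rng.standard_normal()
    s2_prop = np.exp(ls2_prop)
    la = logpost(beta, s2_prop) - logpost(beta, sigma2) + ls2_prop - np.log(sigma2)
    if np.log(rng.uniform()) < la:
        sigma2 = s2_prop
    return beta, sigma2


def propagate_regression(
    pvl_posterior: GroupPosterior | PointMassDraws,
    outcomes: pd.DataFrame,
    spec: Optional[RegressionSpec] = None,
    chains: int = 4,
    iterations: int = 5000,
    burn_in: int = 1500,
    seed: int = 0,
    method: str = "gibbs",
) -> RegressionPosterior:
    """Regression of an outcome on PVL parameters with posterior propagation.

    Per iteration: (1) one joint draw of all subjects' PVL parameters is
    taken (uniformly over the stored posterior draws, independently per
    chain); (2) regression coefficients and residual variance are drawn
    conditional on that design matrix. The PVL index stream depends only on
    the run seed and the chain, so different ``RegressionSpec``s run under
    the same seed consume identical PVL parameter streams.
    """
    spec = spec or RegressionSpec()
    if chains < 2:
        raise ValueError("need at least 2 chains")
    if method not in ("gibbs", "mh"):
        raise ValueError("method must be 'gibbs' or 'mh'")
    y, cov, draws, ids = _align(pvl_posterior, outcomes, spec)
    n = len(y)
    names = ["intercept", *spec.covariates, *PARAM_NAMES]
    p = len(names)
    if n <= p + 2:
        raise ValueError(f"n={n} too small for {p} predictors (need n > p + 2)")
    n_draws = draws.shape[0]
    a0, b0 = spec.var_shape, spec.var_scale
    a_post = a0 + n / 2.0

    if spec.standardize:
        y = (y - y.mean()) / y.std(ddof=1)

    ss = np.random.SeedSequence(seed)
    kept = iterations
    coef_out = np.empty((chains, kept, p))
    s2_out = np.empty((chains, kept))
    for c in range(chains):
        # separate streams: PVL draw indices vs regression randomness, so the
        # same seed reuses identical PVL parameter streams across specs
        rng_idx = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(0, c)))
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(1, c)))
        sigma2 = float(
            stats.invgamma.rvs(a0, scale=b0, random_state=rng)
        )
        beta = np.zeros(p)
        for it in range(burn_in + kept):
            idx = int(rng_idx.integers(n_draws))
            X = np.column_stack([np.ones(n), cov, draws[idx]])
            if method == "gibbs":
                beta, sigma2 = _gibbs_step(rng, X, y, sigma2, a_post, b0)
            else:
                beta, sigma2 = _mh_step(rng, X, y, beta, sigma2, 0.6, a0, b0)
            if it >= burn_in:
                coef_out[c, it - burn_in] = beta
                s2_out[c, it - burn_in] = sigma2
    return RegressionPosterior(
        predictor_names=names,
        coef=coef_out,
        sigma2=s2_out,
        burn_in=burn_in,
        seed=seed,
        spec=spec,
    )


def covariate_screen(
    outcome: np.ndarray | pd.Series, demographics: pd.DataFrame, alpha: float = 0.10
) -> list[str]:
    """Demographics whose correlation with the outcome has p < ``alpha``.

    Pearson correlation throughout (for a binary demographic this is the
    point-biserial correlation). Constant columns are excluded with a
    warning.
    """
    y = np.asarray(outcome, dtype=float)
    if len(y) < 10:
        raise ValueError("need n >= 10 for the covariate screen")
    selected = []
    for col in demographics.columns:
        x = demographics[col].to_numpy(dtype=float)
        if np.std(x) == 0:
            warnings.warn(f"demographic {col!r} is constant; excluded from screen")
            continue
        r, pval = stats.pearsonr(x, y)
        if pval < alpha:
            selected.append(col)
    return selected


def correlation_screen(
    df: pd.DataFrame, outcome: str, predictors: Sequence[str], alpha: float = 0.05
) -> pd.DataFrame:
    """Zero-order Pearson correlations with a Bonferroni-corrected gate.

    The significance threshold is ``alpha / k`` for the ``k`` comparisons
    tested (thin exploratory utility, not a general frequentist toolbox).
    """
    k = len(predictors)
    rows = []
    for pred in predictors:
        sub = df[[outcome, pred]].dropna()
        r, pval = stats.pearsonr(sub[pred], sub[outcome])
        rows.append(
            {
                "predictor": pred,
                "r": r,
                "p": pval,
                "bonferroni_threshold": alpha / k,
                "significant": pval < alpha / k,
            }
        )
    return pd.DataFrame(rows)
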