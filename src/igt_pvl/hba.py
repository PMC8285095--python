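"""Hierarchical Bayesian estimation of PVL parameters and DIC model comparison.

The hierarchy: each subject's parameter vector is drawn from independent
normal distributions truncated to the parameter's admissible range; group
means carry uniform priors over that same range and group variances carry
Inverse-Gamma(shape=5, scale=1) priors. The posterior is explored with a
seeded adaptive random-walk Metropolis-within-Gibbs sampler: per-parameter
subject blocks (batch likelihood evaluations), then group mean and group
variance updates, with proposal scales adapted during burn-in only.

Model comparison uses the Deviance Information Criterion,
``DIC = Dbar + pD`` with ``pD = Dbar - D(theta_bar)``; smaller is better
among models fit to the same data.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .diagnostics import gelman_rubin
from .pvl import PARAM_NAMES, ChoiceSequence, ModelSpec, cohort_arrays, log_likelihood_cohort

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class HierarchicalPrior:
    """Group-level prior: uniform means over the ranges, IG variances."""

    var_shape: float = 5.0
    var_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.var_shape <= 0 or self.var_scale <= 0:
            raise ValueError("Inverse-Gamma shape and scale must be positive")

    @property
    def var_prior_mean(self) -> float:
        return self.var_scale / (self.var_shape - 1.0)


@dataclass(frozen=True)
class MCMCSettings:
    """Chain bookkeeping: kept iterations per chain after burn-in."""

    chains: int = 4
    kept_iterations: int = 2000
    burn_in: int = 1000

    @property
    def total_kept(self) -> int:
        return self.chains * self.kept_iterations

    @property
    def iterations_per_chain(self) -> int:
        return self.kept_iterations + self.burn_in

    @classmethod
    def published_scale(cls) -> "MCMCSettings":
        return cls(chains=4, kept_iterations=75_000, burn_in=25_000)

    @classmethod
    def desk_scale(cls) -> "MCMCSettings":
        return cls(chains=4, kept_iterations=2000, burn_in=1000)


def cohort_fingerprint(sequences: Sequence[ChoiceSequence]) -> str:
    """Stable digest of a cohort's identity and trial data."""
    h = hashlib.sha1()
    for s in sequences:
        h.update(str(s.subject_id).encode())
        h.update(s.deck_indices.tobytes())
        h.update(np.asarray(s.net, dtype=float).tobytes())
    return h.hexdigest()[:16]


@dataclass
class GroupPosterior:
    """Kept MCMC draws of the hierarchical PVL posterior for one variant."""

    model: ModelSpec
    subject_ids: list
    group_mean: np.ndarray  # (chains, kept, 4)
    group_var: np.ndarray  # (chains, kept, 4)
    subject: np.ndarray  # (chains, kept, n_subjects, 4)
    burn_in: int
    seed: int
    cohort_hash: str = ""

    @property
    def chain_count(self) -> int:
        return self.group_mean.shape[0]

    @property
    def kept_iterations(self) -> int:
        return self.group_mean.shape[1]

    @property
    def total_kept(self) -> int:
        return self.chain_count * self.kept_iterations

    @property
    def n_subjects(self) -> int:
        return self.subject.shape[2]

    @property
    def param_names(self) -> tuple:
        return PARAM_NAMES

    def subject_draws_combined(self) -> np.ndarray:
        """(total_kept, n_subjects, 4) — chains concatenated."""
        c, k, n, p = self.subject.shape
        return self.subject.reshape(c * k, n, p)

    def subject_posterior_means(self) -> pd.DataFrame:
        means = self.subject_draws_combined().mean(axis=0)
        return pd.DataFrame(means, columns=list(PARAM_NAMES), index=self.subject_ids)

    def group_rhat(self) -> dict[str, float]:
        return {
            name: gelman_rubin(self.group_mean[:, :, k])
            for k, name in enumerate(PARAM_NAMES)
        }

    def summary(self, level: float = 0.95) -> pd.DataFrame:
        """Group-mean posterior summary: median, IQR and central interval."""
        lo_q, hi_q = (1 - level) / 2, 1 - (1 - level) / 2
        rows = []
        flat = self.group_mean.reshape(-1, 4)
        for k, name in enumerate(PARAM_NAMES):
            d = flat[:, k]
            q25, q50, q75 = np.quantile(d, [0.25, 0.5, 0.75])
            rows.append(
                {
                    "parameter": name,
                    "mean": d.mean(),
                    "median": q50,
                    "iqr": q75 - q25,
                    "ci_lower": np.quantile(d, lo_q),
                    "ci_upper": np.quantile(d, hi_q),
                    "rhat": gelman_rubin(self.group_mean[:, :, k]),
                }
            )
        return pd.DataFrame(rows)


def _truncnorm_kernel(x, mu, sd):
    return -0.5 * ((x - mu) / sd) ** 2


def _log_z(mu, sd, lo, hi):
    z = ndtr((hi - mu) / sd) - ndtr((lo - mu) / sd)
    if z <= 0:
        return -np.inf
    return float(np.log(z))


def _run_chain(rng, deck_idx, net, spec, prior, kept, burn, record):
    n = deck_idx.shape[0]
    bounds = spec.param_bounds()
    lo, hi = bounds[:, 0], bounds[:, 1]
    width = hi - lo

    # initialization (jittered; re-drawn if the likelihood is non-finite)
    for attempt in range(10):
        mu = (lo + hi) / 2 + 0.1 * width * rng.uniform(-1, 1, size=4)
        s2 = prior.var_prior_mean * np.exp(0.2 * rng.standard_normal(4))
        subj = mu[None, :] + 0.05 * width[None, :] * rng.standard_normal((n, 4))
        subj = np.clip(subj, lo + 1e-6 * width, hi - 1e-6 * width)
        ll = log_likelihood_cohort(subj, deck_idx, net, spec)
        if np.isfinite(ll).all():
            break
    else:
        raise RuntimeError("could not initialize chain at a finite log-posterior")

    step_subj = 0.1 * width.copy()
    step_mu = 0.1 * width.copy()
    step_ls2 = np.full(4, 0.3)
    target = 0.44

    total = kept + burn
    out_mu = np.empty((kept, 4))
    out_s2 = np.empty((kept, 4))
    out_subj = np.empty((kept, n, 4)) if record else None

    for it in range(total):
        adapting = it < burn
        gamma = (it + 1) ** -0.6 if adapting else 0.0
        sd = np.sqrt(s2)
        for k in range(4):
            # --- subject-level update for parameter k
            prop = subj.copy()
            prop[:, k] = subj[:, k] + step_subj[k] * rng.standard_normal(n)
            in_bounds = (prop[:, k] >= lo[k]) & (prop[:, k] <= hi[k])
            ll_prop = log_likelihood_cohort(prop, deck_idx, net, spec)
            log_alpha = (
                ll_prop
                - ll
                + _truncnorm_kernel(prop[:, k], mu[k], sd[k])
                - _truncnorm_kernel(subj[:, k], mu[k], sd[k])
            )
            accept = in_bounds & (np.log(rng.uniform(size=n)) < log_alpha)
            subj[accept, k] = prop[accept, k]
            ll = np.where(accept, ll_prop, ll)
            if adapting:
                step_subj[k] *= np.exp(gamma * (accept.mean() - target))

            # --- group mean update (likelihood does not depend on mu)
            mu_prop = mu[k] + step_mu[k] * rng.standard_normal()
            if lo[k] <= mu_prop <= hi[k]:
                la = (
                    _truncnorm_kernel(subj[:, k], mu_prop, sd[k]).sum()
                    - _truncnorm_kernel(subj[:, k], mu[k], sd[k]).sum()
                    - n * _log_z(mu_prop, sd[k], lo[k], hi[k])
                    + n * _log_z(mu[k], sd[k], lo[k], hi[k])
                )
                acc = np.log(rng.uniform()) < la
            else:
                acc = False
            if acc:
                mu[k] = mu_prop
            if adapting:
                step_mu[k] *= np.exp(gamma * (float(acc) - target))

            # --- group variance update (random walk on log sigma^2)
            ls2_prop = np.log(s2[k]) + step_ls2[k] * rng.standard_normal()
            s2_prop = np.exp(ls2_prop)
            sd_prop = np.sqrt(s2_prop)
            la = (
                _truncnorm_kernel(subj[:, k], mu[k], sd_prop).sum()
                - n * np.log(sd_prop)
                - n * _log_z(mu[k], sd_prop, lo[k], hi[k])
                - _truncnorm_kernel(subj[:, k], mu[k], sd[k]).sum()
                + n * np.log(sd[k])
                + n * _log_z(mu[k], sd[k], lo[k], hi[k])
                # IG(shape, scale) prior and log-scale Jacobian
                + (-(prior.var_shape + 1) * ls2_prop - prior.var_scale / s2_prop)
                - (-(prior.var_shape + 1) * np.log(s2[k]) - prior.var_scale / s2[k])
                + (ls2_prop - np.log(s2[k]))
            )
            acc = np.log(rng.uniform()) < la
            if acc:
                s2[k] = s2_prop
                sd[k] = sd_prop
            if adapting:
                step_ls2[k] *= np.exp(gamma * (float(acc) - target))

        if it >= burn:
            j = it - burn
            out_mu[j] = mu
            out_s2[j] = s2
            if record:
                out_subj[j] = subj
    return out_mu, out_s2, out_subj


def sample_posterior(
    cohort: Sequence[ChoiceSequence],
    spec: ModelSpec,
    prior: Optional[HierarchicalPrior] = None,
    chains: int = 4,
    iterations: int = 2000,
    burn_in: int = 1000,
    seed: int = 0,
) -> GroupPosterior:
    """Draw from the hierarchical PVL posterior for one model variant.

    ``iterations`` is the number of kept draws per chain (after discarding
    ``burn_in``). The same seed reproduces the draws exactly.
    """
    cohort = list(cohort)
    if len(cohort) < 2:
        raise ValueError("need at least 2 subjects")
    if chains < 2:
        raise ValueError("need at least 2 chains")
    if iterations < 1 or burn_in < 0:
        raise ValueError("iterations must be >= 1 and burn_in >= 0")
    prior = prior or HierarchicalPrior()
    deck_idx, net = cohort_arrays(cohort)

    ss = np.random.SeedSequence(seed)
    chain_seeds = ss.spawn(chains)
    mus, s2s, subjs = [], [], []
    for cs in chain_seeds:
        rng = np.random.default_rng(cs)
        m, v, s = _run_chain(
            rng, deck_idx, net, spec, prior, iterations, burn_in, record=True
        )
        mus.append(m)
        s2s.append(v)
        subjs.append(s)
    return GroupPosterior(
        model=spec,
        subject_ids=[s.subject_id for s in cohort],
        group_mean=np.stack(mus),
        group_var=np.stack(s2s),
        subject=np.stack(subjs),
        burn_in=burn_in,
        seed=seed,
        cohort_hash=cohort_fingerprint(cohort),
    )


@dataclass
class DICResult:
    model: ModelSpec
    mean_deviance: float
    deviance_at_point: float
    effective_parameters: float
    dic: float
    cohort_hash: str
    excluded_draws: int = 0
    point_estimator: str = "per-subject posterior means of constrained parameters"


def dic(
    posterior: GroupPosterior,
    cohort: Sequence[ChoiceSequence],
    spec: Optional[ModelSpec] = None,
    max_draws: int = 4000,
) -> DICResult:
    """Deviance Information Criterion for one fitted variant.

    ``Dbar`` is the mean over posterior draws of -2 * total log-likelihood
    (draws thinned evenly to at most ``max_draws``); ``D(theta_bar)`` is
    the deviance at the per-subject posterior-mean parameters.
    """
    spec = spec or posterior.model
    cohort = list(cohort)
    if posterior.cohort_hash and posterior.cohort_hash != cohort_fingerprint(cohort):
        raise ValueError("posterior was not fitted on this cohort")
    deck_idx, net = cohort_arrays(cohort)
    draws = posterior.subject_draws_combined()
    if len(draws) > max_draws:
        idx = np.linspace(0, len(draws) - 1, max_draws).astype(int)
        draws = draws[idx]
    deviances = np.array(
        [-2.0 * log_likelihood_cohort(d, deck_idx, net, spec).sum() for d in draws]
    )
    finite = np.isfinite(deviances)
    excluded = int((~finite).sum())
    if excluded > 0.01 * len(deviances):
        raise RuntimeError(f"{excluded} of {len(deviances)} draws had infinite deviance")
    if excluded:
        logger.warning("excluded %d draws with infinite deviance", excluded)
    dbar = float(deviances[finite].mean())
    theta_bar = draws.mean(axis=0)
    d_point = float(-2.0 * log_likelihood_cohort(theta_bar, deck_idx, net, spec).sum())
    pd_eff = dbar - d_point
    return DICResult(
        model=spec,
        mean_deviance=dbar,
        deviance_at_point=d_point,
        effective_parameters=pd_eff,
        dic=dbar + pd_eff,
        cohort_hash=posterior.cohort_hash,
        excluded_draws=excluded,
    )


def compare_models(results: Sequence[DICResult]) -> pd.DataFrame:
    """Rank fitted variants by DIC (ascending); delta_dic is vs the best."""
    results = list(results)
    if not results:
        raise ValueError("no DIC results to compare")
    hashes = {r.cohort_hash for r in results}
    if len(hashes) > 1:
        raise ValueError("DIC comparison across different cohorts is invalid")
    rows = sorted(results, key=lambda r: r.dic)
    best = rows[0].dic
    return pd.DataFrame(
        {
            "model": [r.model.name for r in rows],
            "dic": [r.dic for r in rows],
            "delta_dic": [r.dic - best for r in rows],
            "mean_deviance": [r.mean_deviance for r in rows],
            "effective_parameters": [r.effective_parameters for r in rows],
        }
    )
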