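"""Construction of the health-risk outcome variables.

Three linked constructions for substance-using cohorts followed monthly:

* a *harm composite*: per month, each substance's published harm-to-self
  weight is multiplied by the days of use that month (per 28-day month)
  and summed over substances; monthly scores are averaged over the months
  observed in the first study year;
* a *MAP index*: of four risk behaviors (needle-sharing, unprotected sex,
  pipe-sharing, injection drug use), the count reported at least once in
  the year, 0-4;
* a *Health-risk Index*: the harm composite and MAP index are each
  z-scored within the cohort, averaged per subject, and the average is
  re-standardized so the index itself is an exact z-score.

Plus per-substance 0-3 frequency-of-use codes (non-users 0, users split
into tertiles) and an EM imputation routine for questionnaire items with
sparse missingness.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

#: Published harm-to-self weights per substance (unitless).
HARM_INDEX: dict[str, float] = {
    "tobacco": 37.3,
    "alcohol": 56.1,
    "crack_cocaine": 79.5,
    "cannabis": 25.3,
    "heroin": 73.0,
    "powder_cocaine": 42.4,
    "methadone_prescribed": 24.9,
    "methamphetamine": 68.8,
    "amphetamine": 40.8,
    "methadone_nonprescribed": 24.9,
    "ecstasy": 18.5,
    "lsd": 15.0,
    "ghb": 37.9,
    "ketamine": 28.9,
}

BEHAVIORS = ("needle_sharing", "unprotected_sex", "pipe_sharing", "injection_drug_use")


def monthly_harm_score(
    days_by_substance: Mapping[str, float],
    harm_indices: Mapping[str, float] = HARM_INDEX,
    month_length: float = 28.0,
) -> float:
    """Harm score for one month: sum of harm_index(s) * days(s).

    Days are normalized to a 28-day month rate if ``month_length``
    differs. Substances without a harm index are a hard error.
    """
    missing = [s for s in days_by_substance if s not in harm_indices]
    if missing:
        raise KeyError(f"no harm index for substances: {missing}")
    scale = 28.0 / month_length
    total = 0.0
    for s, d in days_by_substance.items():
        if not 0.0 <= d <= month_length:
            raise ValueError(f"days for {s} must lie in [0, {month_length}]")
        total += harm_indices[s] * d * scale
    return total


def harm_composite(monthly_scores: Sequence[float]) -> float:
    """Mean harm score over the months of data available."""
    scores = [s for s in monthly_scores if s is not None and np.isfinite(s)]
    if not scores:
        raise ValueError("no months of data; subject must be excluded")
    return float(np.mean(scores))


def map_index(behaviors_by_month: Iterable[Mapping[str, bool]]) -> int:
    """Count of the four behavior types reported at least once (0-4).

    Dichotomization: a behavior recurring in many months counts once.
    """
    months = list(behaviors_by_month)
    if not months:
        raise ValueError("behavior reports must cover at least one month")
    return int(sum(any(m.get(b, False) for m in months) for b in BEHAVIORS))


def health_risk_index(
    harm_composites: np.ndarray,
    map_indices: np.ndarray,
    method: str = "z_average_restandardized",
) -> np.ndarray:
    """Cohort-standardized combination of the two components.

    Default: z-score each component, average the two per subject, and
    re-standardize the average, guaranteeing the index is an exact z-score
    (mean 0, SD 1 within the cohort). ``method="raw_average"`` instead
    z-scores the plain average of the raw components.
    """
    h = np.asarray(harm_composites, dtype=float)
    m = np.asarray(map_indices, dtype=float)
    if len(h) != len(m):
        raise ValueError("component vectors must be the same length")
    if len(h) < 3:
        raise ValueError("need a cohort of at least 3 subjects")
    for name, v in (("harm composite", h), ("MAP index", m)):
        if v.std() == 0:
            raise ValueError(f"zero-variance component: {name}")

    def z(v):
        return (v - v.mean()) / v.std(ddof=0)

    if method == "z_average_restandardized":
        avg = (z(h) + z(m)) / 2.0
        return z(avg)
    if method == "raw_average":
        return z((h + m) / 2.0)
    raise ValueError(f"unknown method {method!r}")


def frequency_code(frequencies: np.ndarray) -> np.ndarray:
    """0-3 frequency-of-use codes for one substance across a cohort.

    Non-users (zero frequency) are coded 0. Users are rank-ordered: the
    bottom third get 1, the middle third 2, the top third 3. Tied
    frequencies all receive the code of the tertile containing their
    average rank, so equal frequencies never get different codes. With
    fewer than 3 users tertiles are undefined and all users are coded 2.
    """
    f = np.asarray(frequencies, dtype=float)
    if (f < 0).any():
        raise ValueError("frequencies must be non-negative")
    codes = np.zeros(len(f), dtype=int)
    users = f > 0
    n_users = int(users.sum())
    if n_users == 0:
        return codes
    if n_users < 3:
        codes[users] = 2
        return codes
    ranks = rankdata(f[users], method="average")
    codes[users] = np.ceil(ranks / (n_users / 3.0)).astype(int)
    return codes


def em_impute_items(
    items: np.ndarray | pd.DataFrame,
    max_missing_fraction: float = 0.05,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> np.ndarray | pd.DataFrame:
    """EM imputation of missing questionnaire items.

    Missing entries are replaced by their conditional expectations under a
    multivariate-normal working model whose mean and covariance are
    re-estimated each EM iteration (conditional covariances included in
    the M-step). Observed entries are never modified. Iteration stops when
    no imputed value changes by more than ``tol``.
    """
    is_frame = isinstance(items, pd.DataFrame)
    X = items.to_numpy(dtype=float) if is_frame else np.asarray(items, dtype=float).copy()
    X = X.copy()
    miss = np.isnan(X)
    if not miss.any():
        return items
    frac = miss.mean()
    if frac > max_missing_fraction:
        raise ValueError(
            f"missingness {frac:.1%} exceeds ceiling {max_missing_fraction:.1%}; "
            "consider listwise deletion"
        )
    complete_rows = (~miss).all(axis=1)
    if complete_rows.sum() < 10:
        raise ValueError("need at least 10 complete rows for the EM working model")

    n, p = X.shape
    col_means = np.nanmean(X, axis=0)
    Xf = np.where(miss, col_means, X)
    for _ in range(max_iter):
        mu = Xf.mean(axis=0)
        # expected scatter: add conditional covariance of missing blocks
        centered = Xf - mu
        S = centered.T @ centered
        cond_cov_sum = np.zeros((p, p))
        sigma = S / n
        new = Xf.copy()
        for i in range(n):
            mi = miss[i]
            if not mi.any():
                continue
            oi = ~mi
            s_oo = sigma[np.ix_(oi, oi)]
            s_mo = sigma[np.ix_(mi, oi)]
            s_mm = sigma[np.ix_(mi, mi)]
            sol = np.linalg.solve(s_oo, (Xf[i, oi] - mu[oi]))
            new[i, mi] = mu[mi] + s_mo @ sol
            cc = s_mm - s_mo @ np.linalg.solve(s_oo, s_mo.T)
            block = np.zeros((p, p))
            block[np.ix_(mi, mi)] = cc
            cond_cov_sum += block
        delta = np.abs(new[miss] - Xf[miss]).max()
        Xf = new
        if delta < tol:
            break
    out = np.where(miss, Xf, X)
    if is_frame:
        return pd.DataFrame(out, index=items.index, columns=items.columns)
    return out


def build_outcome_table(
    use_long: pd.DataFrame,
    behaviors_long: pd.DataFrame,
    harm_indices: Mapping[str, float] = HARM_INDEX,
    exclude_substances: Sequence[str] = (),
) -> pd.DataFrame:
    """Per-subject outcome table from long-format monthly records.

    ``use_long`` columns: subject_id, month, substance, days.
    ``behaviors_long`` columns: subject_id, month, behavior, occurred.
    Returns subject_id, harm_composite, map_index, health_risk_index and a
    0-3 frequency code per substance.
    """
    use = use_long[~use_long["substance"].isin(exclude_substances)]
    monthly = (
        use.assign(harm=lambda d: d.apply(
            lambda r: monthly_harm_score({r["substance"]: r["days"]}, harm_indices), axis=1
        ))
        .groupby(["subject_id", "month"])["harm"]
        .sum()
    )
    composites = monthly.groupby("subject_id").mean()

    def subject_map(grp: pd.DataFrame) -> int:
        months = [
            {str(r["behavior"]): bool(r["occurred"]) for _, r in g.iterrows()}
            for _, g in grp.groupby("month")
        ]
        return map_index(months)

    maps = behaviors_long.groupby("subject_id").apply(subject_map, include_groups=False)
    ids = sorted(set(composites.index) & set(maps.index))
    h = composites.loc[ids].to_numpy()
    m = maps.loc[ids].to_numpy()
    out = pd.DataFrame(
        {"subject_id": ids, "harm_composite": h, "map_index": m,
         "health_risk_index": health_risk_index(h, m)}
    )
    mean_days = use.groupby(["subject_id", "substance"])["days"].mean().unstack(fill_value=0.0)
    mean_days = mean_days.reindex(ids, fill_value=0.0)
    for s in mean_days.columns:
        out[f"code_{s}"] = frequency_code(mean_days[s].to_numpy())
    return out
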