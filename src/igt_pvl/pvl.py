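"""Prospect Valence Learning (PVL) model variants for the IGT.

Four variants arise from crossing two expectancy-learning rules with two
softmax sensitivity rules:

* utility of a net outcome x (prospect-theory shaped):
  ``u = x**alpha`` for gains, ``u = -lam * |x|**alpha`` for losses;
* delta learning: ``E_chosen += A * (u - E_chosen)`` (unchosen decks keep
  their expectancies); decay learning: all expectancies decay by ``(1-A)``
  then ``u`` is added to the chosen deck — in both rules larger retention A
  means faster updating / shorter memory of distant outcomes;
* trial-dependent sensitivity ``theta(t) = (t/10)**c`` (choice consistency
  changes over the task) or trial-independent ``theta = 3**c - 1``;
* softmax choice: ``P_j = exp(theta*E_j) / sum_k exp(theta*E_k)``.

Parameters (with their admissible ranges): retention A in [0,1],
consistency c in [-5,5] (trial-dependent) or [0,5] (trial-independent),
attention to losses lam in [0,5], attention to magnitude alpha in [0,1].

Net outcomes are scaled by ``OUTCOME_SCALE`` (1/100, i.e. hundreds of
points) before entering the utility function, for numerical stability of
the power transform.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .task import DECKS, ChoiceSequence, PayoffSchedule

OUTCOME_SCALE = 0.01  # net outcomes in hundreds of points

PARAM_NAMES = ("retention", "consistency", "attn_losses", "attn_magnitude")

LEARNING_RULES = ("delta", "decay")
CHOICE_RULES = ("trial_dependent", "trial_independent")


@dataclass(frozen=True)
class ModelSpec:
    """One of the four PVL variants."""

    learning_rule: str = "delta"
    choice_rule: str = "trial_dependent"

    def __post_init__(self) -> None:
        if self.learning_rule not in LEARNING_RULES:
            raise ValueError(f"learning_rule must be one of {LEARNING_RULES}")
        if self.choice_rule not in CHOICE_RULES:
            raise ValueError(f"choice_rule must be one of {CHOICE_RULES}")

    @property
    def name(self) -> str:
        lr = {"delta": "Delta", "decay": "Decay"}[self.learning_rule]
        cr = {"trial_dependent": "TD", "trial_independent": "TI"}[self.choice_rule]
        return f"PVL-{lr}-{cr}"

    @classmethod
    def from_name(cls, name: str) -> "ModelSpec":
        parts = name.lower().replace("pvl-", "").split("-")
        if len(parts) != 2:
            raise ValueError(f"cannot parse model name {name!r}")
        lr = {"delta": "delta", "decay": "decay"}[parts[0]]
        cr = {"td": "trial_dependent", "ti": "trial_independent"}[parts[1]]
        return cls(learning_rule=lr, choice_rule=cr)

    def param_bounds(self) -> np.ndarray:
        """(4, 2) array of closed [low, high] bounds in PARAM_NAMES order."""
        c_lo = -5.0 if self.choice_rule == "trial_dependent" else 0.0
        return np.array([[0.0, 1.0], [c_lo, 5.0], [0.0, 5.0], [0.0, 1.0]])


ALL_MODELS = tuple(
    ModelSpec(lr, cr) for lr in LEARNING_RULES for cr in CHOICE_RULES
)


@dataclass(frozen=True)
class PVLParams:
    """The four decision parameters of one subject."""

    retention: float
    consistency: float
    attn_losses: float
    attn_magnitude: float

    def validate(self, spec: ModelSpec) -> "PVLParams":
        bounds = spec.param_bounds()
        for name, (lo, hi) in zip(PARAM_NAMES, bounds):
            v = getattr(self, name)
            if not (lo <= v <= hi):
                raise ValueError(f"{name}={v} outside [{lo}, {hi}] for {spec.name}")
        return self

    def as_array(self) -> np.ndarray:
        return np.array([self.retention, self.consistency, self.attn_losses, self.attn_magnitude])

    @classmethod
    def from_array(cls, a) -> "PVLParams":
        return cls(*(float(v) for v in a))


def utility(x: float, alpha: float, lam: float) -> float:
    """Prospect-theory utility of a (scaled) net outcome."""
    if not math.isfinite(x):
        raise ValueError("net outcome must be finite")
    if x == 0:
        return 0.0  # continuity at 0 (0**0 would be 1)
    if x > 0:
        return x**alpha
    return -lam * (-x) ** alpha


def update_expectancies(
    E: np.ndarray, chosen_deck: int | str, u: float, A: float, rule: str
) -> np.ndarray:
    """One learning step; returns a new expectancy vector."""
    if isinstance(chosen_deck, str):
        try:
            chosen_deck = DECKS.index(chosen_deck)
        except ValueError:
            raise ValueError(f"unknown deck {chosen_deck!r}") from None
    if not 0 <= chosen_deck < 4:
        raise ValueError("chosen deck index out of range")
    E = np.array(E, dtype=float)
    if rule == "delta":
        E[chosen_deck] += A * (u - E[chosen_deck])
    elif rule == "decay":
        E *= 1.0 - A
        E[chosen_deck] += u
    else:
        raise ValueError(f"unknown learning rule {rule!r}")
    return E


def sensitivity(t: int, c: float, rule: str) -> float:
    """Softmax sensitivity theta at trial t (1-based)."""
    if t < 1:
        raise ValueError("trial index is 1-based")
    if rule == "trial_dependent":
        if not -5.0 <= c <= 5.0:
            raise ValueError("consistency outside [-5, 5] for trial-dependent rule")
        return (t / 10.0) ** c
    if rule == "trial_independent":
        if not 0.0 <= c <= 5.0:
            raise ValueError("consistency outside [0, 5] for trial-independent rule")
        return 3.0**c - 1.0
    raise ValueError(f"unknown choice rule {rule!r}")


def choice_probabilities(E: np.ndarray, theta: float) -> np.ndarray:
    """Softmax over deck expectancies (max-subtracted for overflow safety)."""
    if theta < 0:
        raise ValueError("theta must be non-negative")
    z = theta * np.asarray(E, dtype=float)
    z = z - z.max()
    w = np.exp(z)
    return w / w.sum()


def log_likelihood(
    params: PVLParams, seq: ChoiceSequence, spec: ModelSpec
) -> float:
    """Log-likelihood of one subject's choices under one PVL variant.

    Expectancies start at zero, so the first trial always contributes
    log(1/4); the choice probability at trial t uses expectancies updated
    through trial t-1.
    """
    params.validate(spec)
    from ._likelihood import loglik_batch

    ll = loglik_batch(
        params.as_array()[None, :],
        seq.deck_indices[None, :],
        (seq.net * OUTCOME_SCALE)[None, :],
        spec.learning_rule == "delta",
        spec.choice_rule == "trial_dependent",
    )
    return float(ll[0])


def log_likelihood_cohort(
    params_matrix: np.ndarray,
    deck_idx: np.ndarray,
    net_scaled: np.ndarray,
    spec: ModelSpec,
) -> np.ndarray:
    """Vectorised per-subject log-likelihoods.

    ``params_matrix`` is (n_subjects, 4) in PARAM_NAMES order; ``deck_idx``
    and ``net_scaled`` are (n_subjects, T) with outcomes already scaled.
    """
    from ._likelihood import loglik_batch

    return loglik_batch(
        np.ascontiguousarray(params_matrix, dtype=np.float64),
        np.ascontiguousarray(deck_idx, dtype=np.int64),
        np.ascontiguousarray(net_scaled, dtype=np.float64),
        spec.learning_rule == "delta",
        spec.choice_rule == "trial_dependent",
    )


def simulate_subject(
    params: PVLParams,
    spec: ModelSpec,
    schedule: PayoffSchedule,
    n_trials: int = 100,
    seed: int | np.random.Generator = 0,
    subject_id: str = "sim",
) -> ChoiceSequence:
    """Generate a choice sequence from the model's own choice probabilities."""
    params.validate(spec)
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    E = np.zeros(4)
    draw_counts = np.zeros(4, dtype=int)
    decks, gains, losses = [], [], []
    for t in range(1, n_trials + 1):
        theta = sensitivity(t, params.consistency, spec.choice_rule)
        p = choice_probabilities(E, theta)
        j = int(rng.choice(4, p=p))
        draw_counts[j] += 1
        gain, loss = schedule.draw(DECKS[j], draw_counts[j])
        u = utility((gain - loss) * OUTCOME_SCALE, params.attn_magnitude, params.attn_losses)
        E = update_expectancies(E, j, u, params.retention, spec.learning_rule)
        decks.append(DECKS[j])
        gains.append(gain)
        losses.append(loss)
    return ChoiceSequence(subject_id=subject_id, decks=np.array(decks), gains=gains, losses=losses)


def cohort_arrays(sequences: Iterable[ChoiceSequence]) -> tuple[np.ndarray, np.ndarray]:
    """Stack equal-length sequences into (deck_idx, net_scaled) matrices."""
    seqs = list(sequences)
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError("all sequences must have equal length")
    deck_idx = np.stack([s.deck_indices for s in seqs])
    net = np.stack([s.net for s in seqs]) * OUTCOME_SCALE
    return deck_idx, net
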