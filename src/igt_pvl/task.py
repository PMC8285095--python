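"""Iowa Gambling Task payoff environment and traditional performance scores.

The IGT presents four decks of cards. Decks A and B pay a large constant
gain (+100) but carry losses totalling 1250 points per 10-card cycle, so
their long-run net is -250 per 10 draws. Decks C and D pay +50 with losses
totalling 250 per cycle, netting +250 per 10 draws. "Advantageous"
performance means drawing predominantly from C and D.

Traditional scores summarise a choice sequence without any model:
proportion of advantageous picks (overall and in late-trial windows), the
per-deck choice proportions, the five-block learning curve, and the Net
score (advantageous minus disadvantageous picks).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DECKS = ("A", "B", "C", "D")
ADVANTAGEOUS = {"A": False, "B": False, "C": True, "D": True}


@dataclass(frozen=True)
class PayoffSchedule:
    """Cyclic per-deck payoff table.

    ``positions[deck]`` is an ordered list of ``(gain, loss)`` pairs; draws
    cycle through it. Losses are stored as non-negative magnitudes.
    """

    positions: dict[str, tuple[tuple[float, float], ...]]

    def __post_init__(self) -> None:
        for deck in DECKS:
            if deck not in self.positions:
                raise ValueError(f"schedule missing deck {deck!r}")
            for gain, loss in self.positions[deck]:
                if not gain > 0:
                    raise ValueError(f"deck {deck}: every position must have gain > 0")
                if loss < 0:
                    raise ValueError(f"deck {deck}: losses are non-negative magnitudes")

    def cycle_length(self, deck: str) -> int:
        return len(self.positions[self._check(deck)])

    def _check(self, deck: str) -> str:
        if deck not in self.positions:
            raise ValueError(f"unknown deck label {deck!r}")
        return deck

    def draw(self, deck: str, draw_count: int) -> tuple[float, float]:
        """Outcome of the ``draw_count``-th draw (1-based) from ``deck``."""
        if draw_count < 1:
            raise ValueError("draw_count is 1-based and must be >= 1")
        pos = self.positions[self._check(deck)]
        return pos[(draw_count - 1) % len(pos)]

    @classmethod
    def bechara(cls) -> "PayoffSchedule":
        """The canonical 10-card cyclic schedule.

        A: +100 each card, five losses (150, 300, 200, 250, 350) per cycle;
        B: +100 each card, a single 1250 loss;
        C: +50 each card, five losses of 50;
        D: +50 each card, a single 250 loss.
        """
        a_loss = {3: 150.0, 5: 300.0, 7: 200.0, 9: 250.0, 10: 350.0}
        c_loss = {3: 50.0, 5: 50.0, 7: 50.0, 9: 50.0, 10: 50.0}
        return cls(
            positions={
                "A": tuple((100.0, a_loss.get(i, 0.0)) for i in range(1, 11)),
                "B": tuple((100.0, 1250.0 if i == 9 else 0.0) for i in range(1, 11)),
                "C": tuple((50.0, c_loss.get(i, 0.0)) for i in range(1, 11)),
                "D": tuple((50.0, 250.0 if i == 10 else 0.0) for i in range(1, 11)),
            }
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"deck": d, "position": i + 1, "gain": g, "loss": l}
            for d in DECKS
            for i, (g, l) in enumerate(self.positions[d])
        ]
        return pd.DataFrame(rows)

    @classmethod
    def from_csv(cls, path) -> "PayoffSchedule":
        df = pd.read_csv(path)
        positions = {}
        for deck, grp in df.groupby("deck"):
            grp = grp.sort_values("position")
            positions[str(deck)] = tuple(
                (float(g), float(l)) for g, l in zip(grp["gain"], grp["loss"])
            )
        return cls(positions=positions)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def draw_card(schedule: PayoffSchedule, deck: str, draw_count: int) -> tuple[float, float]:
    """(gain, loss) for the ``draw_count``-th pick from ``deck`` (1-based, cyclic)."""
    return schedule.draw(deck, draw_count)


@dataclass
class ChoiceSequence:
    """One subject's ordered IGT trials."""

    subject_id: str
    decks: np.ndarray  # array of deck labels, dtype <U1
    gains: np.ndarray
    losses: np.ndarray

    def __post_init__(self) -> None:
        self.decks = np.asarray(self.decks, dtype="U1")
        self.gains = np.asarray(self.gains, dtype=float)
        self.losses = np.asarray(self.losses, dtype=float)
        if not (len(self.decks) == len(self.gains) == len(self.losses)):
            raise ValueError("decks, gains and losses must have equal length")
        bad = set(self.decks) - set(DECKS)
        if bad:
            raise ValueError(f"unknown deck labels {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.decks)

    @property
    def net(self) -> np.ndarray:
        return self.gains - self.losses

    @property
    def deck_indices(self) -> np.ndarray:
        """Decks as integers 0..3 (A..D)."""
        lut = {d: i for i, d in enumerate(DECKS)}
        return np.array([lut[d] for d in self.decks], dtype=np.int64)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": self.subject_id,
                "trial": np.arange(1, len(self) + 1),
                "deck": self.decks,
                "gain": self.gains,
                "loss": self.losses,
            }
        )


@dataclass
class TraditionalScores:
    prop_advantageous_total: float
    prop_advantageous_last60: Optional[float]  # trials 41-100
    prop_advantageous_21to100: Optional[float]  # trials 21-100
    net_score_total: float
    deck_proportions: np.ndarray  # A, B, C, D
    block_curve: np.ndarray  # proportion advantageous per 20-trial block


def traditional_scores(seq: ChoiceSequence, block_size: int = 20) -> TraditionalScores:
    """All conventional IGT summary scores for one subject.

    Late-trial windows are computed in both conventions (trials 41-100 and
    21-100); a window extending past the end of the sequence is reported as
    ``None`` rather than extrapolated. Trailing trials that do not fill a
    complete block are dropped from the block curve.
    """
    T = len(seq)
    if T == 0:
        raise ValueError("empty choice sequence")
    adv = np.array([ADVANTAGEOUS[d] for d in seq.decks], dtype=float)

    def window(lo: int, hi: int) -> Optional[float]:
        # 1-based inclusive trial window
        if T < hi:
            return None
        return float(adv[lo - 1 : hi].mean())

    p_total = float(adv.mean())
    n_blocks = T // block_size
    if n_blocks * block_size != T:
        logger.info(
            "sequence length %d not a multiple of %d; dropping final partial block",
            T,
            block_size,
        )
    curve = adv[: n_blocks * block_size].reshape(n_blocks, block_size).mean(axis=1)
    props = np.array([(seq.decks == d).mean() for d in DECKS])
    return TraditionalScores(
        prop_advantageous_total=p_total,
        prop_advantageous_last60=window(41, 100),
        prop_advantageous_21to100=window(21, 100),
        net_score_total=float(T * (2.0 * p_total - 1.0)),
        deck_proportions=props,
        block_curve=curve,
    )


def proportion_to_net(p: float, n_trials: int) -> float:
    """Convert a proportion-advantageous score to a Net score.

    Net = n_trials * (2p - 1): e.g. 80% advantageous over 100 trials is a
    Net score of +60.
    """
    if not (0.0 <= p <= 1.0):
        raise ValueError("proportion must lie in [0, 1]")
    return n_trials * (2.0 * p - 1.0)


def net_to_proportion(net: float, n_trials: int) -> float:
    """Inverse of :func:`proportion_to_net`."""
    return (net / n_trials + 1.0) / 2.0


def _orthogonal_poly_contrasts(k: int) -> np.ndarray:
    """Rows: linear, quadratic, cubic orthogonal contrasts over k levels."""
    x = np.arange(k, dtype=float)
    x = x - x.mean()
    # Gram-Schmidt on powers of the centred index; each power is also
    # centred so every contrast is orthogonal to the intercept
    basis = []
    for degree in range(1, 4):
        v = x**degree
        v = v - v.mean()
        for b in basis:
            v = v - (v @ b) / (b @ b) * b
        basis.append(v)
    return np.vstack(basis)


def block_trend_contrasts(block_curves: np.ndarray) -> dict[str, tuple[float, tuple[int, int]]]:
    """Repeated-measures polynomial trend tests over trial blocks.

    For each orthogonal contrast (linear, quadratic, cubic across the 5
    blocks) a per-subject contrast score is formed; the F statistic is the
    one-sample test that its mean is zero, with df (1, n-1). Subjects with
    any missing block are excluded (logged).
    """
    y = np.asarray(block_curves, dtype=float)
    if y.ndim != 2 or y.shape[1] < 4:
        raise ValueError("block_curves must be subjects x blocks with >= 4 blocks")
    keep = ~np.isnan(y).any(axis=1)
    if not keep.all():
        logger.info("excluding %d subjects with missing blocks", (~keep).sum())
    y = y[keep]
    n = y.shape[0]
    if n < 2:
        raise ValueError("need at least 2 complete subjects")
    contrasts = _orthogonal_poly_contrasts(y.shape[1])
    out = {}
    for name, c in zip(("linear", "quadratic", "cubic"), contrasts):
        scores = y @ c
        m = scores.mean()
        v = scores.var(ddof=1)
        # floating-point dust from the contrast arithmetic counts as zero
        tol = 1e-9 * (np.abs(y).max() + 1.0) * np.linalg.norm(c)
        if abs(m) < tol:
            m = 0.0
        if v < tol * tol:
            v = 0.0
        f = math.inf if v == 0 and m != 0 else (0.0 if v == 0 else n * m * m / v)
        out[name] = (float(f), (1, n - 1))
    return out
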