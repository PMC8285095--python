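"""Delimited-text readers and writers for the pipeline's tables."""

from __future__ import annotations

import json
from typing import Sequence

import numpy as np
import pandas as pd

from .pvl import PARAM_NAMES
from .task import ChoiceSequence


def save_trials(sequences: Sequence[ChoiceSequence], path) -> None:
    """Write trial records (subject_id, trial, deck, gain, loss) as CSV."""
    pd.concat([s.to_frame() for s in sequences], ignore_index=True).to_csv(path, index=False)


def load_trials(path) -> list[ChoiceSequence]:
    """Read trial CSV back into per-subject sequences (trial order kept)."""
    df = pd.read_csv(path)
    required = {"subject_id", "trial", "deck", "gain", "loss"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"trial file missing columns {sorted(missing)}")
    if (df["loss"] < 0).any():
        raise ValueError("losses must be stored as non-negative magnitudes")
    out = []
    for sid, grp in df.groupby("subject_id", sort=False):
        grp = grp.sort_values("trial")
        trials = grp["trial"].to_numpy()
        if not np.array_equal(trials, np.arange(1, len(trials) + 1)):
            raise ValueError(f"subject {sid}: trial indices must run 1..T")
        out.append(
            ChoiceSequence(
                subject_id=sid,
                decks=grp["deck"].to_numpy(),
                gains=grp["gain"].to_numpy(),
                losses=grp["loss"].to_numpy(),
            )
        )
    return out


def save_params(params: pd.DataFrame, path, model_name: str = "") -> None:
    df = params.reset_index()
    if model_name:
        df["model"] = model_name
    df.to_csv(path, index=False)


def load_params(path) -> pd.DataFrame:
    df = pd.read_csv(path).set_index("subject_id")
    missing = [c for c in PARAM_NAMES if c not in df.columns]
    if missing:
        raise ValueError(f"parameter file missing columns {missing}")
    return df


def save_posterior_summary(summary: pd.DataFrame, path) -> None:
    """Posterior summary table as JSON (medians, IQRs, central intervals)."""
    with open(path, "w") as fh:
        json.dump(summary.to_dict(orient="records"), fh, indent=2)
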