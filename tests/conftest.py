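import numpy as np
import pytest

from igt_pvl import ModelSpec, PayoffSchedule


@pytest.fixture(scope="session")
def schedule():
    return PayoffSchedule.bechara()


@pytest.fixture(scope="session")
def delta_td():
    return ModelSpec("delta", "trial_dependent")


def random_params(rng, spec):
    """Uniform draw inside the variant's parameter box."""
    bounds = spec.param_bounds()
    return rng.uniform(bounds[:, 0], bounds[:, 1])


def random_sequence_arrays(rng, schedule, n_trials=100):
    """Random deck choices with schedule-consistent outcomes (0-based decks)."""
    from igt_pvl.task import DECKS

    decks = rng.integers(0, 4, size=n_trials)
    counts = np.zeros(4, dtype=int)
    gains = np.empty(n_trials)
    losses = np.empty(n_trials)
    for t, d in enumerate(decks):
        counts[d] += 1
        gains[t], losses[t] = schedule.draw(DECKS[d], counts[d])
    return decks, gains, losses
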