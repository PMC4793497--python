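import numpy as np
import pytest

from medsurv import GroupedSurvivalData, SurvivalSample


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def toy_uncensored():
    """Four subjects, all events at times 1..4: S = (.75, .5, .25, 0)."""
    return SurvivalSample([1, 2, 3, 4], [1, 1, 1, 1], label="A")


@pytest.fixture
def toy_censored():
    """First observation censored: event times (2, 3), S = (.5, 0)."""
    return SurvivalSample([1, 2, 3], [0, 1, 1], label="C")


def random_sample(rng, n, censor_frac=0.3, label=None):
    """A random censored sample for property tests."""
    times = rng.exponential(5.0, n) + rng.uniform(0, 1, n)
    events = (rng.uniform(size=n) > censor_frac).astype(int)
    if events.sum() == 0:
        events[rng.integers(n)] = 1
    return SurvivalSample(times, events, label=label)


def random_grouped(rng, k=3, n_lo=15, n_hi=40):
    """Random grouped data with a defined pooled median (retry if not)."""
    from medsurv import DegenerateDataError, median_survival_test

    while True:
        data = GroupedSurvivalData(
            [
                random_sample(rng, int(rng.integers(n_lo, n_hi)), label=i)
                for i in range(k)
            ]
        )
        try:
            median_survival_test(data)
        except DegenerateDataError:
            continue
        return data
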