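import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from casesurv import SurvivalDataset

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_dataset(ids, times, events, n_features: int = 1, seed: int = 0):
    """Small survival dataset with random-normal covariates."""
    rng = np.random.default_rng(seed)
    n = len(ids)
    feats = pd.DataFrame(rng.standard_normal((n, n_features)),
                         columns=[f"x{j}" for j in range(n_features)])
    return SurvivalDataset(np.asarray(ids, dtype=str),
                           np.asarray(times, dtype=float),
                           np.asarray(events), feats)


def random_dataset(rng: np.random.Generator, max_n: int = 50,
                   max_time: float = 30.0) -> SurvivalDataset:
    n = int(rng.integers(1, max_n + 1))
    times = rng.uniform(0.0, max_time, size=n)
    events = rng.integers(0, 2, size=n)
    return make_dataset([f"r{i}" for i in range(n)], times, events,
                        seed=int(rng.integers(2**31)))


@pytest.fixture
def tiny_dataset():
    """Five subjects: events at 1 and 3, censored at 2, 4 and 5."""
    return make_dataset(["a", "b", "c", "d", "e"],
                        [1.0, 2.0, 3.0, 4.0, 5.0],
                        [1, 0, 1, 0, 0])


class ConstantScorer:
    """Classifier stub emitting one fixed raw score everywhere."""

    def __init__(self, value: float = 0.7):
        self.value = value

    def score(self, X):
        return np.full(len(X), self.value)
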