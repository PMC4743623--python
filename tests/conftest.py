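"""Shared fixtures and deterministic hypothesis settings for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

# All property tests run derandomized so the suite is fully reproducible.
settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


def make_small_fixture(seed: int, n=6, p=4, q=2, r=2, signal: float = 0.0):
    """A tiny random dataset (X binary, Y gaussian, optional planted signal)."""
    rng = np.random.default_rng(seed)
    X = (rng.random((n, p)) < 0.5).astype(float)
    # guard against constant / duplicate columns which make designs singular
    for j in range(p):
        while np.std(X[:, j]) == 0 or any(
            np.array_equal(X[:, j], X[:, i]) or np.array_equal(X[:, j], 1 - X[:, i])
            for i in range(j)
        ):
            X[:, j] = (rng.random(n) < 0.5).astype(float)
    stacks = 0.5 * rng.standard_normal((q, n, r))
    if signal:
        for k in range(q):
            stacks[k] += signal * X[:, k % p][:, None]
    return X, stacks


@pytest.fixture
def small_fixture():
    return make_small_fixture(0)
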