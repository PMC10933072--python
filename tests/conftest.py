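"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import math

import numpy as np
import pytest

from gaitmse import SensorLayout, speed_preset


def brute_force_sample_entropy(x, m, r):
    """Naive O(N^2) template-counting sample entropy, kept deliberately simple.

    Counts ordered pairs of templates (self-pairs excluded) whose Chebyshev
    distance is strictly below r, at lengths m and m+1, over the same number
    of templates (N - m), and returns -ln(A / B).  Pure Python loops; used
    only as an independent cross-check of the vectorized implementation.
    """
    x = list(map(float, x))
    n = len(x)
    n_templates = n - m

    def count(length):
        total = 0
        for i in range(n_templates):
            for j in range(n_templates):
                if i == j:
                    continue
                d = 0.0
                for k in range(length):
                    d = max(d, abs(x[i + k] - x[j + k]))
                if d < r:
                    total += 1
        return total

    b = count(m)
    a = count(m + 1)
    if a == 0 or b == 0:
        return float("nan")
    return -math.log(a / b)


@pytest.fixture(scope="session")
def layout():
    return SensorLayout.default()


@pytest.fixture(scope="session")
def presets():
    """The three study-speed generator configurations, small enough for tests."""
    return {s: speed_preset(s, n_cycles=60, seed=42 + s) for s in (2, 4, 6)}
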