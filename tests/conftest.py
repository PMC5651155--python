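"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import math

import numpy as np
import pytest

from spikegp import FitnessContext, GPConfig, SegmentationConfig


# ---------------------------------------------------------------------------
# independent direct-summation feature oracle (pure Python, no numpy paths)
# ---------------------------------------------------------------------------

def _median_py(values: list[float]) -> float:
    s = sorted(values)
    n = len(s)
    mid = n // 2
    return s[mid] if n % 2 else (s[mid - 1] + s[mid]) / 2.0


def oracle_features(values) -> list[float]:
    """X1..X8 by direct summation of the defining equations."""
    x = [float(v) for v in values]
    n = len(x)
    mu = sum(x) / n
    ss = sum((xi - mu) ** 2 for xi in x)
    sigma = math.sqrt(ss / (n - 1))
    s = sorted(x)
    lower = s[: n // 2]
    upper = s[(n + 1) // 2:]
    iqr = _median_py(upper) - _median_py(lower)
    if sigma == 0:
        kurt = skew = 0.0
    else:
        kurt = sum((xi - mu) ** 4 for xi in x) / ((n - 1) * sigma ** 4)
        skew = sum((xi - mu) ** 3 for xi in x) / ((n - 1) * sigma ** 3)
    return [max(x), min(x), mu, sigma, _median_py(x), iqr, kurt, skew]


def oracle_knn(ref_values, ref_labels, k: int, query: float) -> int:
    """Exhaustive sort-and-vote KNN with the stated tie rules."""
    order = sorted(range(len(ref_values)),
                   key=lambda i: (abs(query - ref_values[i]), i))
    neighbors = order[:k]
    votes = sum(ref_labels[i] for i in neighbors)
    if 2 * votes > k:
        return 1
    if 2 * votes < k:
        return 0
    return ref_labels[neighbors[0]]


def brute_force_windows(length: int, window: int, step: int) -> list[int]:
    """All start positions whose full window fits, by enumeration."""
    return [s for s in range(0, length + 1, step) if s + window <= length]


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def seg_cfg() -> SegmentationConfig:
    return SegmentationConfig()


def sigma_contrast_features(rng: np.random.Generator, n_per_class: int,
                            sigma_spike: float = 3.0,
                            n_samples: int = 100) -> tuple[np.ndarray, np.ndarray]:
    """Feature vectors of raw-noise windows whose classes differ only in
    their standard deviation (X4) — the separation the detector relies on.
    """
    from spikegp.preprocess import features_matrix

    spike = rng.standard_normal((n_per_class, n_samples)) * sigma_spike
    nonspike = rng.standard_normal((n_per_class, n_samples))
    feats = features_matrix(np.vstack([spike, nonspike]))
    labels = np.r_[np.ones(n_per_class, int), np.zeros(n_per_class, int)]
    return feats, labels


@pytest.fixture
def separable_ctx(rng) -> FitnessContext:
    """Balanced reference/validation groups separable through X4 only."""
    ref_f, ref_l = sigma_contrast_features(rng, 60)
    val_f, val_l = sigma_contrast_features(rng, 60)
    return FitnessContext(ref_f, ref_l, val_f, val_l, k=15)


@pytest.fixture
def quick_gp_config() -> GPConfig:
    return GPConfig(population_size=10, n_generations=8, rng_seed=3)
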