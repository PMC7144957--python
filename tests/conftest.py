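"""Shared fixtures and independent oracles used across the suite."""

from __future__ import annotations

import numpy as np
import pytest

from zipfnorm import ExpressionProfile


def brute_force_ranks(counts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rank of each distinct positive value by the definition itself.

    For every distinct positive z, counts how many observations are >= z
    with an explicit double loop.  Returns (values decreasing, ranks).
    """
    positive = [c for c in counts if c > 0]
    values = sorted(set(positive), reverse=True)
    ranks = []
    for z in values:
        r = 0
        for x in positive:
            if x >= z:
                r += 1
        ranks.append(r)
    return np.array(values, dtype=float), np.array(ranks)


def ols_two_var(y: np.ndarray, x1: np.ndarray, x2: np.ndarray) -> np.ndarray:
    """Closed-form OLS of y on (1, x1, x2) via the normal equations."""
    X = np.column_stack([np.ones_like(x1), x1, x2])
    return np.linalg.solve(X.T @ X, X.T @ y)


def ols_one_var(y: np.ndarray, x: np.ndarray) -> tuple[float, float]:
    """Closed-form simple OLS (intercept, slope) via the normal equations."""
    n = len(x)
    sx, sy, sxx, sxy = x.sum(), y.sum(), (x * x).sum(), (x * y).sum()
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    return intercept, slope


def pareto_sample(rng: np.random.Generator, kappa: float, x_min: float, size: int) -> np.ndarray:
    """Power-law sample with density ~ x**-kappa above x_min."""
    return x_min * (1.0 + rng.pareto(kappa - 1.0, size))


def zero_inflated_profile(
    rng: np.random.Generator,
    n_genes: int = 5000,
    zero_fraction: float = 0.5,
    kappa: float = 2.7,
    x_min: float = 10.0,
    sample_id: str = "p",
) -> ExpressionProfile:
    """Continuous zero-inflated power-law profile for tail-fit tests."""
    counts = np.zeros(n_genes)
    pos = rng.random(n_genes) >= zero_fraction
    counts[pos] = pareto_sample(rng, kappa, x_min, int(pos.sum()))
    return ExpressionProfile(sample_id, counts)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260926)
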