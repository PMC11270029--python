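"""Shared fixtures: small synthetic bundles generated at test time."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from heatspeech.meteo import BinScheme, add_weather_features
from heatspeech.panel import PanelDesign
from heatspeech.synthetic import SimConfig, simulate_panel


SMALL_SIM = dict(
    n_politicians=20,
    cities=("Arlen", "Bergsee", "Corvale", "Dunmere"),
    start="2010-01-01",
    end="2010-12-31",
    speeches_per_sitting_day=3.0,
    seed=42,
)


@pytest.fixture(scope="session")
def small_bundle():
    """~3k-speech panel with default injected effects; (speeches, weather, truth)."""
    return simulate_panel(SimConfig(**SMALL_SIM))


@pytest.fixture(scope="session")
def small_features(small_bundle):
    _, weather, _ = small_bundle
    return add_weather_features(weather, BinScheme.full_10bin())


def random_panel(rng: np.random.Generator, n: int | None = None):
    """A random small panel with 3 crossed FE dimensions and its components.

    Returns (PanelDesign, true_beta). Used for oracle-equivalence checks.
    """
    n = n or int(rng.integers(200, 800))
    k = int(rng.integers(2, 5))
    X = rng.normal(size=(n, k))
    l1, l2, l3 = rng.integers(5, 30), rng.integers(3, 12), rng.integers(2, 7)
    f1 = rng.integers(0, l1, n)
    f2 = rng.integers(0, l2, n)
    f3 = rng.integers(0, l3, n)
    beta = rng.normal(scale=2.0, size=k)
    y = (
        X @ beta
        + rng.normal(size=l1)[f1]
        + rng.normal(size=l2)[f2]
        + rng.normal(size=l3)[f3]
        + rng.normal(size=n)
    )
    clusters = rng.integers(0, max(int(n // 20), 2), n)
    design = PanelDesign(
        y=y,
        X=X,
        colnames=[f"x{i}" for i in range(k)],
        fe={"f1": f1, "f2": f2, "f3": f3},
        clusters=clusters,
    )
    return design, beta


def dense_dummy_ols(design: PanelDesign) -> np.ndarray:
    """Brute-force oracle: explicit dummy columns for every FE level."""
    blocks = [design.X]
    first = True
    for name, codes in design.fe_codes.items():
        levels = design.fe_levels[name]
        dummies = np.equal.outer(codes, np.arange(levels)).astype(float)
        if not first:
            dummies = dummies[:, 1:]  # avoid exact dummy-trap collinearity
        first = False
        blocks.append(dummies)
    D = np.column_stack(blocks)
    coef, *_ = np.linalg.lstsq(D, design.y, rcond=None)
    return coef[: design.X.shape[1]]
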