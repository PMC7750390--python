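"""Shared fixtures: a small synthetic herd reused across test modules."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from herdnet.geometry import BarnGeometry
from herdnet.proximity import ProximityProtocol
from herdnet.synthdata import SimConfig, inject_artifacts, simulate_herd


@pytest.fixture(scope="session")
def geometry() -> BarnGeometry:
    return BarnGeometry()


@pytest.fixture(scope="session")
def protocol() -> ProximityProtocol:
    return ProximityProtocol()


@pytest.fixture(scope="session")
def small_herd():
    """10 cows, 1 day, artifact-free noise-free planted trajectories + truth."""
    cfg = SimConfig(
        n_cows=10, n_days=1, seed=42, noise_cep50=0.0, stuck_rate=0.0, outlier_rate=0.0
    )
    positions, truth = simulate_herd(cfg)
    return cfg, positions, truth


@pytest.fixture(scope="session")
def noisy_herd():
    """8 cows, 1 day with default sensor noise, no discrete artifacts."""
    cfg = SimConfig(n_cows=8, n_days=1, seed=7, stuck_rate=0.0, outlier_rate=0.0)
    clean, truth = simulate_herd(cfg, include_truth=False)
    noisy, _ = inject_artifacts(clean, cfg)
    return cfg, clean, noisy, truth


def make_track(
    xs, ys=None, animal_id="a", day_index=0, t0=0.0, interval=10.0
) -> pd.DataFrame:
    """Hand-built single-animal position table."""
    xs = np.asarray(xs, dtype=float)
    ys = np.zeros_like(xs) if ys is None else np.asarray(ys, dtype=float)
    return pd.DataFrame(
        {
            "animal_id": animal_id,
            "day_index": day_index,
            "timestamp": t0 + np.arange(len(xs)) * interval,
            "x_m": xs,
            "y_m": ys,
        }
    )


def distance_series(dists, t0=0.0, interval=10.0) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "timestamp": t0 + np.arange(len(dists)) * interval,
            "distance": np.asarray(dists, dtype=float),
        }
    )
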