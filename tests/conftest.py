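"""Shared fixtures: small synthetic studies reused across the suite."""

from __future__ import annotations

import numpy as np
import pytest

import farmscape as fs


@pytest.fixture(scope="session")
def study73():
    """One simulated 73-site study: config, sites, coords, metrics table.

    Session-scoped because simulating 146 mosaics is the most expensive step
    in the suite and the table is read-only for every consumer.
    """
    sim = fs.SimConfig(seed=20260922, n_sites=73)
    sites = fs.simulate_sites(sim)
    coords = sites[["x", "y"]].to_numpy()
    metrics = fs.metrics_table(fs.simulate_landscapes(sim))
    return {"sim": sim, "sites": sites, "coords": coords, "metrics": metrics}


@pytest.fixture()
def rng():
    return np.random.default_rng(7)


def random_mosaic(rng, shape=(10, 10), codes=(1, 2, 6, 7), cell_size=50.0):
    """A random full-buffer categorical mosaic for oracle comparisons."""
    grid = rng.choice(codes, size=shape)
    return fs.LandscapeMosaic(grid, cell_size)
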