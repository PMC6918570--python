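"""Shared fixtures and hypothesis configuration."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from hictad import ContactMap
from hictad.matrix import distance_center

# deterministic, CI-friendly hypothesis defaults
settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def symmetric(values: np.ndarray) -> np.ndarray:
    return (values + values.T) / 2.0


def make_map(values, resolution=10_000, **kw) -> ContactMap:
    return ContactMap(np.asarray(values, dtype=float), resolution, **kw)


def random_centered_map(rng: np.random.Generator, n: int) -> ContactMap:
    raw = rng.gamma(2.0, 2.0, size=(n, n))
    return distance_center(make_map(symmetric(raw)))


def greedy_match(src, ref, tol=1) -> int:
    """Number of src elements matched one-to-one to ref within tol bins."""
    ref = sorted(ref)
    used = [False] * len(ref)
    cnt = 0
    for x in sorted(src):
        best, best_d = None, tol + 1
        for j, y in enumerate(ref):
            if used[j]:
                continue
            d = abs(x - y)
            if d < best_d:
                best, best_d = j, d
        if best is not None and best_d <= tol:
            used[best] = True
            cnt += 1
    return cnt


@pytest.fixture
def planted_map():
    """A small noiseless map fully tiled by two 2-level hierarchies.

    Full coverage matters: a large uncovered margin inflates the global
    sd of the insulation tracks and prunes the shallower sibling dips.
    """
    from hictad.simulate import PlantedInterval, SimulationSpec, simulate_map

    ivs = [
        PlantedInterval(0, 32, 2.0, 1),
        PlantedInterval(0, 15, 2.0, 2),
        PlantedInterval(15, 32, 2.0, 2),
        PlantedInterval(32, 60, 2.0, 1),
        PlantedInterval(32, 46, 2.0, 2),
        PlantedInterval(46, 60, 2.0, 2),
    ]
    spec = SimulationSpec(n_bins=60, intervals=ivs, noise="none")
    cmap, truth = simulate_map(spec)
    return cmap, truth
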