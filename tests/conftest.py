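"""Shared fixtures: parameter sets, small geometries, cached scenario runs."""

import numpy as np
import pytest
from hypothesis import settings

import granulesim as gs
from granulesim import engine

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def params():
    return gs.default_parameters()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def small_geometry(side=64.0, spacing=4.0, d_max=48.0):
    return gs.DomainGeometry(side=side, spacing=spacing,
                             max_granule_diameter=d_max)


@pytest.fixture
def small_params():
    p = gs.default_parameters()
    p.geometry = small_geometry()
    return p


# Reduced-scale scenario runs are the expensive shared resource of the
# suite; run each at most once per session and reuse the RunResult.
_RUN_CACHE: dict = {}


def cached_run(name: str, seed: int = 1, duration: float | None = None):
    key = (name, seed, duration)
    if key not in _RUN_CACHE:
        spec = engine.preset(name, seed=seed, reduced=True)
        if duration is not None:
            spec.duration = duration
            spec.events = [e for e in spec.events if e.time <= duration]
        _RUN_CACHE[key] = engine.run(spec)
    return _RUN_CACHE[key]
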