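"""Shared fixtures: small head models, grids and synthetic sessions.

Everything is generated programmatically at session scope so expensive
objects (lead fields, inverse operators) are built once per test run.
"""

from __future__ import annotations

import numpy as np
import pytest

from deepesi.forward import HeadModel, build_leadfield, build_source_space
from deepesi.inverse import build_laura_operator
from deepesi.simulate import SimulationConfig, default_head, simulate_session


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def sensors64():
    from deepesi.simulate import sensor_layout

    return sensor_layout(64, 92.0)


@pytest.fixture(scope="session")
def head64(sensors64):
    return HeadModel(sensor_positions=sensors64)


@pytest.fixture(scope="session")
def src300(head64):
    return build_source_space(head64, 300)


@pytest.fixture(scope="session")
def lead300(head64, src300):
    return build_leadfield(head64, src300)


@pytest.fixture(scope="session")
def op300(lead300, src300):
    """Depth-weighted operator matching the pipeline preset, small scale."""
    return build_laura_operator(lead300, src300, lam=1e-5, lam_relative=True,
                                depth_weight=2.0)


@pytest.fixture(scope="session")
def op300_plain(lead300, src300):
    """Local-autoregressive operator without depth weighting."""
    return build_laura_operator(lead300, src300, lam=1e-5, lam_relative=True,
                                depth_weight=0.0)


@pytest.fixture(scope="session")
def small_session():
    """Scaled synthetic session: 64 sensors, 250 Hz, 120 s."""
    cfg = SimulationConfig(sampling_rate=250.0, duration=120.0, n_sensors=64,
                           seed=42)
    head = default_head(64)
    scalp, ic, gt = simulate_session(cfg, head)
    return cfg, head, scalp, ic, gt
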