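import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_session():
    """A short two-zone session with one excited, one inhibited, one null cell."""
    from calzone.synthgen import CellSpec, SimConfig, ZoneSpec, simulate_behavior, simulate_traces

    cfg = SimConfig(
        session_duration=300.0,
        zones=(ZoneSpec("open", 10.0), ZoneSpec("closed", 10.0)),
        n_cells=3,
        cell_specs=(
            CellSpec(0.5, {"open": 1.0}),
            CellSpec(0.5, {"open": -0.5}),
            CellSpec(0.5, {}),
        ),
        transit_s=2.0,
        seed=42,
    )
    occ, events = simulate_behavior(cfg)
    traces, gt = simulate_traces(occ, cfg)
    return cfg, occ, events, traces, gt
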