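"""Shared synthetic-session fixtures.

Sessions are generated once per test run (session scope) and shared by the
unit and acceptance tests.  Sizes are chosen so the full suite stays
desk-scale: layer-structure analyses need the full 64-channel probe, while
state scoring and slow-wave detection are single-channel analyses and run
on 32-channel sessions.
"""

from __future__ import annotations

import numpy as np
import pytest

from laminarkit.synthetic import SimConfig, simulate_session, simulate_spike_network


@pytest.fixture(scope="session")
def wake_session():
    """600 s all-WAKE 64-channel session: the layer-recovery workload."""
    cfg = SimConfig(duration_s=600.0, seed=3, n_units=6, n_opto_pulses=0)
    rec, spikes, events, truth = simulate_session(cfg)
    return cfg, rec, spikes, events, truth


@pytest.fixture(scope="session")
def three_state_session():
    """30 min WAKE/NREM/REM session with every waking bout >= 7 min."""
    plan = (("WAKE", 480.0), ("NREM", 420.0), ("REM", 150.0),
            ("WAKE", 450.0), ("NREM", 300.0))
    cfg = SimConfig(duration_s=1800.0, seed=5, n_channels=32, n_units=16,
                    state_plan=plan, n_opto_pulses=150)
    rec, spikes, events, truth = simulate_session(cfg)
    return cfg, rec, spikes, events, truth


@pytest.fixture(scope="session")
def arousal_session():
    """Sleep with a planted 5 min arousal (below the 7 min waking rule)."""
    plan = (("WAKE", 480.0), ("NREM", 420.0), ("WAKE", 300.0), ("NREM", 420.0))
    cfg = SimConfig(duration_s=1620.0, seed=8, n_channels=32, n_units=12,
                    state_plan=plan, n_opto_pulses=0)
    rec, spikes, events, truth = simulate_session(cfg)
    return cfg, rec, spikes, events, truth


@pytest.fixture(scope="session")
def nrem_session():
    """600 s of pure non-REM with planted DOWN/UP alternation."""
    cfg = SimConfig(duration_s=600.0, seed=5, n_channels=32, n_units=20,
                    state_plan=(("NREM", 600.0),), n_opto_pulses=0)
    rec, spikes, events, truth = simulate_session(cfg)
    return cfg, rec, spikes, events, truth


@pytest.fixture(scope="session")
def nrem_30ms_session():
    """Non-REM session whose planted DOWN states all last 30 ms (below the
    40 ms acceptance floor of the detector)."""
    cfg = SimConfig(duration_s=300.0, seed=6, n_channels=32, n_units=20,
                    state_plan=(("NREM", 300.0),), n_opto_pulses=0,
                    down_dur_fixed_s=0.030)
    rec, spikes, events, truth = simulate_session(cfg)
    return cfg, rec, spikes, events, truth


@pytest.fixture(scope="session")
def nrem_down_active_session():
    """Non-REM session containing one planted DOWN-state-active unit."""
    cfg = SimConfig(duration_s=400.0, seed=12, n_channels=32, n_units=20,
                    state_plan=(("NREM", 400.0),), n_down_active=1,
                    n_opto_pulses=0)
    rec, spikes, events, truth = simulate_session(cfg)
    return cfg, rec, spikes, events, truth


#: planted monosynaptic network used by the connectivity tests:
#: three excitatory edges at each strength plus one inhibitory edge
NET_EDGES = [(0, 1, 0.05), (2, 3, 0.05), (4, 5, 0.05),
             (6, 7, 0.10), (8, 9, 0.10), (10, 11, 0.10),
             (12, 13, 0.20), (14, 15, 0.20), (16, 17, 0.20),
             (18, 19, -0.5)]


@pytest.fixture(scope="session")
def spike_network():
    """20-unit, 600 s Poisson network at 5 Hz with planted edges."""
    rates = np.full(20, 5.0)
    ds, true_edges = simulate_spike_network(rates, 600.0, NET_EDGES, seed=42)
    return ds, true_edges
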