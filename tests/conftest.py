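"""Shared fixtures and deterministic hypothesis configuration."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def default_config():
    from barostate import SimConfig

    return SimConfig(seed=7, duration_s=600.0)


def make_segments(truth, window_s=300.0):
    """Cut a simulated beat table into contiguous fixed-length segments."""
    b = truth.beats
    end = b["t_s"].iloc[-1]
    segs = []
    for s in np.arange(0.0, end, window_s):
        seg = b[(b["t_s"] >= s) & (b["t_s"] < s + window_s)].reset_index(drop=True)
        if len(seg) >= 3:
            segs.append(seg)
    return segs


@pytest.fixture
def all_on_truth():
    """Half-hour recording with the baroreflex permanently engaged."""
    from barostate import SimConfig, simulate

    cfg = SimConfig(
        seed=11, duration_s=1800.0, mean_dwell_on_s=1e9, mean_dwell_off_s=1e-6
    )
    return simulate(cfg)


@pytest.fixture
def line_beats():
    """Tiny beat table lying exactly on a line RR(t) = 0.2 + 0.002 t."""
    t = np.arange(0.0, 60.0, 0.2)
    return pd.DataFrame(
        {"t_s": t, "rr_s": 0.2 + 0.002 * t, "map_mmHg": np.full(t.size, 120.0)}
    )
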