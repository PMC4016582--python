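import numpy as np
import pandas as pd
import pytest

from divcontrol import SimConfig, simulate_mother_machine, extract_cycles
from divcontrol.presets import sim_preset


@pytest.fixture(scope="session")
def sizer_tracks():
    """Moderate mother-machine sizer dataset (~1.2e3 complete cycles)."""
    cfg = sim_preset("sizer-s1", seed=101, generations=24, n_channels=60)
    return cfg, simulate_mother_machine(cfg)


@pytest.fixture(scope="session")
def sizer_cycles(sizer_tracks):
    _, tracks = sizer_tracks
    return extract_cycles(tracks, generation_window=(4, 24))


@pytest.fixture(scope="session")
def timer_tracks():
    cfg = sim_preset("timer-s1", seed=102, generations=24, n_channels=60)
    return cfg, simulate_mother_machine(cfg)


@pytest.fixture(scope="session")
def timer_cycles(timer_tracks):
    _, tracks = timer_tracks
    return extract_cycles(tracks, generation_window=(4, 24))


@pytest.fixture()
def tiny_tree():
    """Hand-built 3-cell tree: one mother dividing symmetrically at t=10."""
    rows = []
    for k, t in enumerate(np.arange(0.0, 10.1, 2.0)):
        rows.append((1, None, t, 2.0 * np.exp(0.05 * t)))
    xd = 2.0 * np.exp(0.5)
    for cid in (2, 3):
        for k, t in enumerate(np.arange(10.0, 16.1, 2.0)):
            rows.append((cid, 1, t, 0.5 * xd * np.exp(0.05 * (t - 10.0))))
    df = pd.DataFrame(rows, columns=["cell_id", "parent_id", "time_min",
                                     "length_um"])
    df["parent_id"] = df["parent_id"].astype("Int64")
    return df
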