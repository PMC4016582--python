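import json

import numpy as np
import pandas as pd
import pytest

from divcontrol import (DensityGrid, EvalConfig, GrowthLaw, SolverConfig,
                        correlation_diagnostic, distance, evaluate_models,
                        robustness_scan)
from divcontrol.kde import make_grid
from divcontrol.presets import sim_preset, sizer_rate
from divcontrol.simulate import simulate_mother_machine


def gaussian2d(grid_a, grid_x, mu, sigma):
    A, X = np.meshgrid(grid_a, grid_x, indexing="ij")
    vals = np.exp(-((A - mu[0]) ** 2 + (X - mu[1]) ** 2) / (2 * sigma ** 2))
    return DensityGrid(("age", "size"), (grid_a, grid_x), vals).normalize()


def test_distance_identity_and_zero_density():
    g = make_grid(10.0, 64)
    f = DensityGrid(("size",), (g,), np.exp(-g)).normalize()
    assert distance(f, f).d == 0.0
    zero = DensityGrid(("size",), (g,), np.zeros_like(g))
    assert distance(f, zero).percent == pytest.approx(100.0)


def test_distance_requires_matching_grids():
    f = DensityGrid(("size",), (make_grid(10.0, 64),),
                    np.ones(64)).normalize()
    g = DensityGrid(("size",), (make_grid(12.0, 64),),
                    np.ones(64)).normalize()
    with pytest.raises(ValueError):
        distance(f, g)


@pytest.mark.parametrize("alpha,expect", [(0.9, 0.1569), (0.75, 0.4667)])
def test_distance_gaussian_calibration(alpha, expect):
    """Isotropic bivariate Gaussians with SD ratio alpha have
    D = sqrt(1 + 1/alpha^2 - 4/(1+alpha^2)) in closed form."""
    ga, gx = make_grid(40.0, 256, lower=-40.0), make_grid(40.0, 256,
                                                          lower=-40.0)
    f = gaussian2d(ga, gx, (0.0, 0.0), 4.0)
    g = gaussian2d(ga, gx, (0.0, 0.0), 4.0 * alpha)
    d = distance(f, g).d
    closed = np.sqrt(1 + 1 / alpha ** 2 - 4 / (1 + alpha ** 2))
    assert d == pytest.approx(closed, abs=1e-3)
    assert d == pytest.approx(expect, abs=1e-3)


def test_distance_monotone_under_mixing():
    g = make_grid(10.0, 64)
    f = DensityGrid(("size",), (g,), np.exp(-g)).normalize()
    h = DensityGrid(("size",), (g,),
                    np.exp(-0.5 * (g - 5) ** 2)).normalize()
    ds = [distance(f, DensityGrid(("size",), (g,),
                                  (1 - e) * f.values + e * h.values)).d
          for e in np.linspace(0, 1, 11)]
    assert all(np.diff(ds) > 0)


def test_correlation_deterministic_sizer_closed_form():
    """With x_d fixed, a_d = ln(x_d/x_b)/v is a monotone decreasing
    transform of birth size, so r equals corr(-ln x_b, x_b) < 0."""
    rng = np.random.default_rng(8)
    x_b = rng.lognormal(np.log(2.0), 0.1, 2000)
    a_d = np.log(4.0 / x_b) / 0.0274
    cyc = pd.DataFrame({"cell_id": np.arange(2000), "complete": True,
                        "birth_size_um": x_b, "division_age_min": a_d})
    r, p = correlation_diagnostic(cyc, n_perm=200, seed=1)
    ref = np.corrcoef(-np.log(x_b), x_b)[0, 1]
    assert r == pytest.approx(ref, abs=1e-12)
    assert r < 0 and p < 0.01


def test_correlation_constant_column_raises():
    cyc = pd.DataFrame({"cell_id": np.arange(100), "complete": True,
                        "birth_size_um": np.full(100, 2.0),
                        "division_age_min": np.linspace(20, 30, 100)})
    with pytest.raises(ValueError, match="constant"):
        correlation_diagnostic(cyc)


def test_evaluate_models_insufficient_cycles():
    cfg = sim_preset("sizer-s1", seed=13, generations=6, n_channels=10)
    tracks = simulate_mother_machine(cfg)
    with pytest.raises(ValueError, match="insufficient cycles"):
        evaluate_models(tracks, EvalConfig(topology="sparse_tree",
                                           min_cycles=100))


def test_evaluate_models_report_is_deterministic_and_serializable(tmp_path):
    cfg = sim_preset("sizer-s1", seed=14, generations=22, n_channels=60)
    tracks = simulate_mother_machine(cfg)
    ec = EvalConfig(topology="sparse_tree", generation_window=(4, 22),
                    n_perm=100, seed=14)
    r1 = evaluate_models(tracks, ec)
    r2 = evaluate_models(tracks, ec)
    assert r1.to_dict() == r2.to_dict()
    out = tmp_path / "report.json"
    r1.to_json(out)
    loaded = json.loads(out.read_text())
    assert set(loaded) >= {"d_age_pct", "d_size_pct", "correlation_r",
                           "preferred", "provenance"}
    assert loaded["preferred"] == "sizer"


def test_robustness_scan_zero_cv_and_validation():
    cfg = SolverConfig(x_max=12.0, n_size=128)
    law = GrowthLaw.exponential(0.0274)
    tab = robustness_scan(sizer_rate(), law, "growth_rate", [0.0, 0.1], cfg)
    assert tab.loc[0, "distance_pct"] == 0.0
    assert tab.loc[1, "distance_pct"] > 0.0
    with pytest.raises(ValueError):
        robustness_scan(sizer_rate(), law, "growth_rate", [0.3, 0.1], cfg)
    with pytest.raises(ValueError):
        robustness_scan(sizer_rate(), law, "sorcery", [0.1], cfg)
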