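import numpy as np
import pytest

from divcontrol import (DivisionRate, GrowthLaw, NoStableDistributionError,
                        SolverConfig, distance, solve_size_profile,
                        solve_stable, solve_with_growth_variability,
                        solve_with_septum_noise, rate_density_truncnorm,
                        septum_kernel_truncnorm)
from divcontrol.kde import DensityGrid
from divcontrol.presets import sizer_rate, timer_rate, growth_law_preset

V = 0.0274


@pytest.fixture(scope="module")
def sizer_profile():
    return solve_size_profile(sizer_rate(), GrowthLaw.exponential(V),
                              SolverConfig(x_max=12.0, n_size=128))


def test_positivity_mass_and_convergence_flags(sizer_profile):
    sol = sizer_profile
    assert sol.converged and sol.residual < 1e-8
    assert np.all(sol.density.values >= 0)
    assert sol.density.integral() == pytest.approx(1.0, abs=1e-6)
    assert sol.boundary_leak < 1e-6


def test_malthus_equals_growth_rate_for_pure_exponential():
    # fragmentation conserves biomass, so the population grows at rate v
    sol = solve_size_profile(sizer_rate(), GrowthLaw.exponential(V),
                             SolverConfig(x_max=12.0, n_size=256))
    assert abs(sol.malthus - V) / V < 0.01


def test_initialization_independence():
    cfg = SolverConfig(x_max=12.0, n_size=128)
    x = np.linspace(0, 12, 129)[:-1] + 12 / 256
    a_init = np.exp(-0.5 * ((x - 3) / 0.5) ** 2)
    b_init = np.where((x > 1) & (x < 9), 1.0, 1e-6)
    law = GrowthLaw.exponential(V)
    s1 = solve_size_profile(sizer_rate(), law, cfg, initial=a_init)
    s2 = solve_size_profile(sizer_rate(), law, cfg, initial=b_init)
    assert distance(s1.size_marginal, s2.size_marginal).d < 1e-3


def test_grid_refinement_first_order():
    law = GrowthLaw.exponential(V)
    c1 = SolverConfig(x_max=12.0, n_size=256)
    c2 = SolverConfig(x_max=12.0, n_size=512)
    s1 = solve_size_profile(sizer_rate(), law, c1)
    s2 = solve_size_profile(sizer_rate(), law, c2)
    assert abs(s2.malthus - s1.malthus) / s1.malthus < 0.005
    coarse = np.interp(s1.density.grids[0], s2.density.grids[0],
                       s2.density.values)
    ref = DensityGrid(("size",), (s1.density.grids[0],), coarse).normalize()
    assert distance(ref, s1.size_marginal).d < 0.02


def test_sparse_tree_malthus_is_zero():
    cfg = SolverConfig(x_max=12.0, n_size=256, topology="sparse_tree")
    sol = solve_size_profile(sizer_rate(), GrowthLaw.exponential(V), cfg)
    assert abs(sol.malthus) < 1e-4


def test_growth_variability_point_mass_reduces_to_plain(sizer_profile):
    cfg = SolverConfig(x_max=12.0, n_size=128)
    sol = solve_with_growth_variability(sizer_rate(), ("point", V),
                                        GrowthLaw.exponential(V), cfg)
    assert distance(sizer_profile.size_marginal, sol.size_marginal).d < 0.005


def test_septum_point_kernel_reduces_to_plain(sizer_profile):
    cfg = SolverConfig(x_max=12.0, n_size=128)
    sol = solve_with_septum_noise(sizer_rate(), ("point", 0.5),
                                  GrowthLaw.exponential(V), cfg)
    assert distance(sizer_profile.size_marginal, sol.size_marginal).d < 0.005


def test_septum_kernel_validation():
    cfg = SolverConfig(x_max=12.0, n_size=128)
    law = GrowthLaw.exponential(V)
    th = np.linspace(0.3, 0.9, 61)          # asymmetric about 1/2
    q = np.exp(-0.5 * ((th - 0.6) / 0.05) ** 2)
    with pytest.warns(UserWarning, match="asymmetric"):
        solve_with_septum_noise(sizer_rate(), (th, q), law, cfg)
    th2 = np.linspace(0.01, 0.99, 99)       # mass near 0 and 1
    with pytest.raises(ValueError, match="degenerate"):
        solve_with_septum_noise(sizer_rate(), (th2, np.ones_like(th2)),
                                law, cfg)


def test_two_dimensional_solution_matches_profile(sizer_profile):
    cfg = SolverConfig(a_max=60.0, x_max=12.0)
    sol = solve_stable("size", sizer_rate(), GrowthLaw.exponential(V), cfg)
    assert distance(sizer_profile.size_marginal, sol.size_marginal).d < 0.02
    assert sol.age_marginal.values[0] > sol.age_marginal.values[-1]


def test_timer_with_uncapped_exponential_growth_has_no_stable_state():
    """The theoretical failure of timer control under exponential growth:
    the iterate is stationary only because mass escapes the size domain."""
    cfg = SolverConfig(a_max=100.0, x_max=60.0, n_age=128, n_size=256,
                       max_iter=20_000)
    with pytest.raises(NoStableDistributionError):
        solve_stable("age", timer_rate(), GrowthLaw.exponential(V), cfg)


def test_model_index_mismatch_rejected():
    cfg = SolverConfig()
    with pytest.raises(ValueError):
        solve_stable("age", sizer_rate(), GrowthLaw.exponential(V), cfg)
    with pytest.raises(ValueError):
        solve_stable("size", timer_rate(), GrowthLaw.exponential(V), cfg)
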