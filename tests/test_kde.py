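import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from divcontrol import DensityGrid, kde1d, kde2d, make_grid
from divcontrol.kde import smooth_density


def test_two_point_sample_symmetric_with_wide_bandwidth():
    grid = make_grid(9.0, 256, lower=-5.0)   # covers the kernel tails
    d = kde1d([1.0, 3.0], grid=grid, bandwidth=1.0, reflect=False)
    assert d.integral() == pytest.approx(1.0, abs=1e-3)
    assert d.mean() == pytest.approx(2.0, abs=1e-3)


def test_exponential_sample_l1_accuracy():
    rng = np.random.default_rng(42)
    x = rng.exponential(1.0, 10_000)
    grid = make_grid(1.05 * x.max(), 256)
    d = kde1d(x, grid=grid)
    truth = np.exp(-grid)
    truth /= np.trapezoid(truth, grid)
    l1 = np.trapezoid(np.abs(d.values - truth), grid)
    assert l1 < 0.05


def test_degenerate_sample_raises():
    with pytest.raises(ValueError):
        kde1d(np.full(100, 2.0))
    with pytest.raises(ValueError):
        kde1d([1.0])


def test_kde2d_mode_location_and_normalization():
    rng = np.random.default_rng(7)
    a = 30.0 + rng.standard_normal(10_000)
    x = 4.0 + rng.standard_normal(10_000)
    d = kde2d(a, x, grid_a=make_grid(40.0), grid_x=make_grid(8.0))
    assert d.integral() == pytest.approx(1.0, abs=1e-3)
    i, j = np.unravel_index(np.argmax(d.values), d.values.shape)
    assert abs(d.grids[0][i] - 30.0) <= d.spacing(0)
    assert abs(d.grids[1][j] - 4.0) <= d.spacing(1)


def test_kde2d_duplication_invariance_with_fixed_bandwidth():
    rng = np.random.default_rng(3)
    a = rng.uniform(5, 25, 500)
    x = rng.uniform(1, 5, 500)
    kw = dict(grid_a=make_grid(30.0), grid_x=make_grid(6.0),
              bandwidths=(1.0, 0.3))
    d1 = kde2d(a, x, **kw)
    d2 = kde2d(np.tile(a, 2), np.tile(x, 2), **kw)
    assert np.allclose(d1.values, d2.values, atol=1e-12)


def test_kde2d_degenerate_cloud_raises():
    with pytest.raises(ValueError):
        kde2d(np.ones(50), np.arange(50.0))


def test_boxcar_kernel_removes_lattice_comb():
    rng = np.random.default_rng(11)
    x = np.round(rng.normal(25, 4, 50_000))   # 1-min lattice
    grid = make_grid(45.0, 256)
    comb = kde1d(x, grid=grid, bandwidth=0.35, reflect=False)
    smooth = kde1d(x, grid=grid, bandwidth=0.35, boxcar=1.0, reflect=False)
    truth = np.exp(-0.5 * ((grid - 25) / 4) ** 2)
    truth /= np.trapezoid(truth, grid)
    err = lambda d: np.max(np.abs(d.values - truth)[(grid > 15) & (grid < 35)])
    assert err(smooth) < 0.3 * err(comb)


def test_smooth_density_matches_kde_of_lattice_free_sample():
    # smoothing a point-mass density with bandwidth h equals the kernel
    rng = np.random.default_rng(5)
    grid = make_grid(10.0, 200)
    vals = np.zeros_like(grid)
    vals[100] = 1.0
    base = DensityGrid(("size",), (grid,), vals).normalize()
    sm = smooth_density(base, 0.4)
    ref = np.exp(-0.5 * ((grid - grid[100]) / 0.4) ** 2)
    ref /= np.trapezoid(ref, grid)
    assert np.max(np.abs(sm.values - ref)) < 0.02


def test_marginals_and_mean():
    grid_a, grid_x = make_grid(10.0, 64), make_grid(4.0, 32)
    vals = np.outer(np.exp(-grid_a), np.exp(-0.5 * (grid_x - 2) ** 2))
    d = DensityGrid(("age", "size"), (grid_a, grid_x), vals).normalize()
    assert d.marginal("size").integral() == pytest.approx(1.0, rel=1e-9)
    assert d.mean("size") == pytest.approx(2.0, abs=0.01)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.lists(st.floats(0.1, 50.0), min_size=5, max_size=200))
def test_kde1d_normalized_and_nonnegative(sample):
    sample = np.asarray(sample)
    if np.ptp(sample) == 0:
        return
    d = kde1d(sample, grid=make_grid(55.0, 128))
    assert np.all(d.values >= 0)
    assert d.integral() == pytest.approx(1.0, abs=1e-3)
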