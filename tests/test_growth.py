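import numpy as np
import pytest

from divcontrol import (SimConfig, GrowthLaw, extract_cycles,
                        fit_single_cell_growth, increment_curve,
                        noise_summary, fit_polynomial_cap,
                        simulate_mother_machine)
from divcontrol.presets import sim_preset, timer_rate


def test_exact_exponential_fit():
    t = np.arange(0, 28, 2.0)
    y = 2.0 * np.exp(0.0274 * t)
    res = fit_single_cell_growth(t, y)
    assert res.rate == pytest.approx(0.0274, abs=1e-12)
    assert res.r2_exponential == pytest.approx(1.0, abs=1e-10)
    assert res.r2_linear < 1.0


def test_exact_linear_fit():
    t = np.arange(0, 28, 2.0)
    res = fit_single_cell_growth(t, 2.0 + 0.07 * t)
    assert res.r2_linear == pytest.approx(1.0, abs=1e-10)
    assert res.r2_exponential < 1.0


def test_fit_input_validation():
    with pytest.raises(ValueError):
        fit_single_cell_growth([0, 1], [1.0, 2.0])
    with pytest.raises(ValueError):
        fit_single_cell_growth([0, 1, 2], [1.0, -2.0, 3.0])


def test_exponential_beats_linear_under_multiplicative_noise():
    """With 1% noise on exponentially growing cells, the exponential model
    wins the R^2 comparison in the median, as in real data."""
    rng = np.random.default_rng(17)
    t = np.arange(0, 26, 1.0)
    r2e, r2l = [], []
    for _ in range(1000):
        y = 2.0 * np.exp(0.0274 * t) * (1 + 0.01 * rng.standard_normal(t.size))
        res = fit_single_cell_growth(t, y)
        r2e.append(res.r2_exponential)
        r2l.append(res.r2_linear)
    assert np.median(r2e) > np.median(r2l)


def test_increment_curve_exponential_closed_form(sizer_tracks):
    """Noiseless exponential growth: mean increment = l*(e^{v dt}-1)."""
    cfg, _ = sizer_tracks
    clean = sim_preset("sizer-s1", seed=55, generations=24, n_channels=60,
                       rate_cv=0.0, septum_cv=0.0)
    tracks = simulate_mother_machine(clean)
    curve = increment_curve(tracks, bin_width=0.2)
    expect = np.exp(clean.mean_rate * clean.acquisition_dt) - 1.0
    assert curve.prop_slope == pytest.approx(expect, rel=0.02)
    assert abs(curve.intercept) < 0.01


def test_threshold_detection_on_capped_growth():
    """Growth frozen above 5.3 µm: detected x_max within one bin of 5.3."""
    cfg = SimConfig(control_law="timer", division_rate=timer_rate(),
                    growth_law=GrowthLaw.capped_constant(0.0274, 1.0, 5.3),
                    topology="sparse_tree", generations=54, n_channels=200,
                    acquisition_dt=1.0, seed=23, rate_cv=0.0,
                    initial_size=("lognormal", 2.8, 0.15))
    tracks = simulate_mother_machine(cfg)
    curve = increment_curve(tracks, bin_width=0.25, fit_range=(3.0, 4.5),
                            min_count=200)
    assert abs(curve.x_max - 5.3) <= 2 * 0.25


def test_increment_curve_degenerate_input_raises(tiny_tree):
    with pytest.raises(ValueError):
        increment_curve(tiny_tree.iloc[:2], bin_width=0.2,
                        fit_range=(10.0, 12.0))


def test_polynomial_cap_recovers_rate_curve(sizer_tracks):
    _, tracks = sizer_tracks
    curve = increment_curve(tracks, bin_width=0.2)
    coeffs = fit_polynomial_cap(curve)
    mid = 0.5 * (curve.fit_range[0] + curve.fit_range[1])
    assert np.polyval(coeffs, mid) == pytest.approx(0.0317 * mid, rel=0.05)


def test_noise_summary_recovers_generator_cvs(sizer_cycles):
    ns = noise_summary(sizer_cycles)
    assert 0.07 <= ns.rate_cv <= 0.09
    assert 0.035 <= ns.septum_cv <= 0.045
    assert ns.septum_density.mean() == pytest.approx(0.5, abs=0.01)


def test_noise_summary_septum_cv_zero_when_symmetric():
    cfg = sim_preset("sizer-s1", seed=77, generations=10, n_channels=30,
                     septum_cv=0.0)
    cyc = extract_cycles(simulate_mother_machine(cfg))
    ns = noise_summary(cyc)
    assert ns.septum_cv == pytest.approx(0.0, abs=1e-12)


def test_noise_summary_needs_enough_cycles(sizer_cycles):
    with pytest.raises(ValueError):
        noise_summary(sizer_cycles.iloc[:10])
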