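"""Binning, trimmed statistics, curve integration, hydrophilic degree."""

import numpy as np
import pandas as pd
import pytest

from deltacg.profiles import (
    Curve, GapError, ProfileCurve, bin_profile, hydrophilic_degree,
    integrate_force_to_potential, integrate_spring_to_force,
    potential_minimum,
)


def records_frame(r, v, component="f_s_all"):
    return pd.DataFrame({"r": np.asarray(r, float),
                         component: np.asarray(v, float)})


# -- binning ----------------------------------------------------------------


def test_identical_values_bin():
    recs = records_frame(np.full(40, 3.02), np.full(40, 1.7))
    curve = bin_profile(recs, "f_s_all", min_count=25)
    assert len(curve.centers) == 1
    assert curve.centers[0] == pytest.approx(3.0)
    for attr in ("mean", "p10", "p90"):
        assert getattr(curve, attr)[0] == pytest.approx(1.7)
    assert curve.std[0] == 0.0
    assert curve.count[0] == 40


def test_trimmed_mean_oracle_1_to_100():
    vals = np.arange(1.0, 101.0)
    recs = records_frame(np.full(100, 5.0), vals)
    curve = bin_profile(recs, "f_s_all", min_count=25)
    q5, q95 = np.percentile(vals, [5, 95])
    interior = vals[(vals >= q5) & (vals <= q95)]
    assert curve.mean[0] == pytest.approx(interior.mean())
    assert curve.std[0] == pytest.approx(interior.std())
    assert curve.p10[0] == pytest.approx(np.percentile(vals, 10))
    assert curve.p25[0] == pytest.approx(np.percentile(vals, 25))


def test_half_open_bin_convention():
    # r = 3.05 belongs to the bin centered at 3.1 ([3.05, 3.15)), not 3.0
    recs = records_frame(np.full(30, 3.05), np.ones(30))
    curve = bin_profile(recs, "f_s_all", min_count=25)
    assert curve.centers[0] == pytest.approx(3.1)
    recs = records_frame(np.full(30, 3.049999), np.ones(30))
    curve = bin_profile(recs, "f_s_all", min_count=25)
    assert curve.centers[0] == pytest.approx(3.0)


def test_percentile_ordering_and_masking():
    rng = np.random.default_rng(23)
    r = rng.uniform(3.0, 6.0, size=4000)
    v = rng.normal(size=4000)
    recs = records_frame(r, v)
    curve = bin_profile(recs, "f_s_all", min_count=25)
    sel = curve.mask
    assert np.all(curve.p10[sel] <= curve.p25[sel])
    assert np.all(curve.p25[sel] <= curve.p75[sel])
    assert np.all(curve.p75[sel] <= curve.p90[sel])
    assert np.all(curve.count[sel] >= 25)


def test_binning_permutation_invariance():
    rng = np.random.default_rng(29)
    r = rng.uniform(2.0, 8.0, size=500)
    v = rng.normal(size=500)
    recs = records_frame(r, v)
    perm = rng.permutation(500)
    shuffled = recs.iloc[perm].reset_index(drop=True)
    c0 = bin_profile(recs, "f_s_all", min_count=10)
    c1 = bin_profile(shuffled, "f_s_all", min_count=10)
    assert np.array_equal(c0.mean, c1.mean, equal_nan=True)
    assert np.array_equal(c0.count, c1.count)


def test_bin_profile_errors():
    with pytest.raises(ValueError):
        bin_profile(records_frame([], []), "f_s_all")
    with pytest.raises(KeyError):
        bin_profile(records_frame([3.0], [1.0]), "nope")
    with pytest.raises(ValueError):
        bin_profile(records_frame(np.full(5, 3.0), np.ones(5)), "f_s_all",
                    min_count=25)


# -- integration ------------------------------------------------------------


def grid_curve(x0=2.0, x1=12.0, y=None, fn=None):
    x = np.round(np.arange(x0, x1 + 1e-9, 0.1), 9)
    if fn is not None:
        y = fn(x)
    return Curve(x=x, y=np.asarray(y, float) if np.ndim(y) else
                 np.full_like(x, float(y)))


def test_zero_spring_curve_integrates_to_zero():
    fhat = integrate_spring_to_force(grid_curve(y=0.0))
    assert np.abs(fhat.y).max() == 0.0


def test_constant_spring_closed_form():
    c = 1.8
    fhat = integrate_spring_to_force(grid_curve(y=c))
    # hand integral: f0(x) = c (x - 2); g = -mean of f0 over [8, 12] = -c*8
    expect = c * (fhat.x - 2.0) - c * 8.0
    assert np.allclose(fhat.y, expect, atol=1e-9)


def test_coulomb_pair_integration_consistency():
    """Analytic +1e/-1e pair: integrating k recovers f up to the
    documented far-field offset g (f does not vanish by 12 A for a bare
    1/r^2 force, so f_hat differs from f by exactly -mean(f) over the
    zero window); the sign convention is pinned by requiring positive
    correlation between f_hat and f."""
    C = 332.0637
    x = np.round(np.arange(2.0, 12.0 + 1e-9, 0.1), 9)
    f = -C / x**2                 # attractive
    k = 2 * C / x**3              # df/dr
    fhat = integrate_spring_to_force(Curve(x=x, y=k), (8.0, 12.0))
    win = (x >= 8.0) & (x <= 12.0)
    expect = f - f[win].mean()
    sel = (x >= 3.0) & (x <= 10.0)
    scale = np.abs(f[sel]).max()
    assert np.abs(fhat.y[sel] - expect[sel]).max() < 0.02 * scale
    # the wrong sign would anti-correlate f_hat with f
    assert np.corrcoef(fhat.y[sel], f[sel])[0, 1] > 0.999


def test_gap_error_on_masked_holes():
    centers = np.array([3.0, 3.1, 3.2, 5.0, 5.1])
    n = len(centers)
    curve = ProfileCurve(centers=centers, mean=np.ones(n),
                         p10=np.ones(n), p25=np.ones(n), p75=np.ones(n),
                         p90=np.ones(n), std=np.zeros(n),
                         count=np.full(n, 30), mask=np.full(n, True))
    with pytest.raises(GapError):
        integrate_spring_to_force(curve)


def test_potential_minimum_of_known_force():
    # f(x) = -dU/dx with U = (x - 3.3)^2: argmin of integrated U at 3.3
    curve = grid_curve(fn=lambda x: -2.0 * (x - 3.3))
    U = integrate_force_to_potential(curve)
    assert potential_minimum(U, (2.0, 4.0)) == pytest.approx(3.3)
    with pytest.raises(ValueError):
        potential_minimum(U, (100.0, 101.0))


# -- hydrophilic degree -----------------------------------------------------


def test_positive_force_degree_zero():
    f = grid_curve(y=0.5)
    res = hydrophilic_degree(f, f)
    assert res.degree == 0.0
    assert res.classification == "hydrophobic"


def test_rectangle_area_degree():
    def fn(x):
        return np.where((x >= 3.0) & (x < 4.0), -1.0, 0.0)
    f = grid_curve(fn=fn)
    res = hydrophilic_degree(f, f)
    assert res.degree == pytest.approx(1.0, abs=1e-9)
    assert res.area_f == pytest.approx(res.area_fhat)
    assert res.classification == "hydrophilic"


def test_degree_is_average_of_areas():
    f = grid_curve(fn=lambda x: np.where(x < 4.0, -2.0, 0.0))
    fh = grid_curve(fn=lambda x: np.where(x < 4.0, -1.0, 0.0))
    res = hydrophilic_degree(f, fh)
    assert res.degree == pytest.approx(0.5 * (res.area_f + res.area_fhat))
    assert res.degree >= 0


def test_degree_monotone_in_force_depth():
    rng = np.random.default_rng(31)
    base = rng.normal(scale=0.5, size=101)
    x = np.round(np.arange(2.0, 12.0 + 1e-9, 0.1), 9)
    f0 = Curve(x=x, y=base)
    f1 = Curve(x=x, y=base - np.abs(rng.normal(size=101)))  # deeper
    d0 = hydrophilic_degree(f0, f0).degree
    d1 = hydrophilic_degree(f1, f1).degree
    assert d1 >= d0


def test_grid_mismatch_rejected():
    f = grid_curve(y=-1.0)
    g = grid_curve(x0=2.1, y=-1.0)
    with pytest.raises(ValueError):
        hydrophilic_degree(f, g)
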