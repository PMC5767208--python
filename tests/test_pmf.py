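"""WHAM, route combination and standard-state conversion."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mrfe.fixtures import AnalyticPMF, DEFAULT_WINDOW_CENTERS, make_umbrella_dataset
from mrfe.pmf import (
    ConnectivityError,
    PMFProfile,
    R_GAS_KJ,
    STANDARD_VOLUME_A3,
    StandardStateCal,
    UmbrellaWindow,
    combine_routes,
    fit_kw_cv,
    pmf_work,
    read_profile,
    read_window_series,
    standard_dg,
    standard_dg_integral,
    standard_volume_A3,
    wham,
    write_profile,
)

RT310 = R_GAS_KJ * 310.0


class TestStandardVolume:
    def test_first_principles_value_rounds_to_1661(self):
        v = standard_volume_A3()
        assert round(v) == 1661
        assert v == pytest.approx(1e27 / 6.02214076e23, rel=1e-12)


class TestWham:
    def test_unbiased_uniform_window_recovers_flat_profile(self):
        rng = np.random.default_rng(0)
        win = UmbrellaWindow(center=0.5, spring_k=0.0, samples=rng.uniform(0, 1, 20000))
        profile = wham([win], grid=np.linspace(0.05, 0.95, 19))
        _, w = profile.sampled()
        assert np.nanmax(np.abs(w)) < 0.3 * RT310

    def test_duplicated_window_gives_same_profile(self):
        rng = np.random.default_rng(1)
        win = UmbrellaWindow(center=0.5, spring_k=500.0, samples=rng.normal(0.5, 0.07, 5000))
        one = wham([win])
        two = wham([win, UmbrellaWindow(0.5, 500.0, win.samples.copy())])
        np.testing.assert_allclose(one.w, two.w, atol=1e-9)

    def test_double_well_oracle_recovery(self):
        pmf = AnalyticPMF(form="double-well", barrier=20.0)
        windows = make_umbrella_dataset(
            pmf, DEFAULT_WINDOW_CENTERS, spring_k=1000.0, n_per_window=2000, seed=1
        )
        profile = wham(windows)
        z, w = profile.sampled()
        diff = w - pmf(z)
        diff -= diff.mean()  # PMFs are defined up to an additive constant
        assert np.sqrt(np.mean(diff**2)) < 0.2 * RT310

    def test_window_order_is_irrelevant(self):
        pmf = AnalyticPMF(form="harmonic", curvature=50.0, z0=0.5)
        windows = make_umbrella_dataset(pmf, [0.2, 0.4, 0.6, 0.8], 800.0, 2000, seed=2)
        a = wham(windows)
        b = wham(list(reversed(windows)))
        np.testing.assert_allclose(a.w, b.w, atol=1e-9)

    def test_disconnected_windows_raise_connectivity_error(self):
        rng = np.random.default_rng(3)
        wins = [
            UmbrellaWindow(0.0, 5000.0, rng.normal(0.0, 0.02, 500)),
            UmbrellaWindow(3.0, 5000.0, rng.normal(3.0, 0.02, 500)),
        ]
        with pytest.raises(ConnectivityError):
            wham(wins)


class TestPmfWork:
    def test_flat_profile_has_zero_work(self):
        z = np.linspace(0, 3, 61)
        res = pmf_work(PMFProfile(z, np.zeros_like(z)))
        assert res.value == pytest.approx(0.0)
        assert res.plateaued

    def test_step_profile_work_equals_step_height(self):
        z = np.linspace(0, 3, 301)
        w = np.where(z < 1.0, 0.0, 50.0)
        res = pmf_work(PMFProfile(z, w), bound_region=(0.0, 0.5))
        assert res.value == pytest.approx(50.0)

    def test_double_well_matches_direct_evaluation(self):
        pmf = AnalyticPMF(form="double-well", barrier=25.0)
        z = np.linspace(0.0, 3.2, 321)
        w = pmf(z)
        res = pmf_work(PMFProfile(z, w), bound_region=(0.3, 0.5), plateau_frac=0.2)
        tail = z >= z[-1] - 0.2 * (z[-1] - z[0])
        bound = (z >= 0.3) & (z <= 0.5)
        assert res.value == pytest.approx(w[tail].max() - w[bound].mean(), rel=1e-12)

    def test_unplateaued_profile_is_flagged(self):
        z = np.linspace(0, 3, 61)
        res = pmf_work(PMFProfile(z, 40.0 * z))  # still climbing at the end
        assert not res.plateaued


class TestCombineRoutes:
    def test_arithmetic_mean(self):
        dw, sigma = combine_routes([10.0, 20.0], T=310.0)
        assert dw == pytest.approx(15.0)
        assert sigma == pytest.approx(np.std([10.0, 20.0], ddof=1))

    def test_methods_agree_on_identical_values(self):
        a, _ = combine_routes([42.0] * 4, method="arithmetic")
        j, _ = combine_routes([42.0] * 4, method="jarzynski")
        assert j == pytest.approx(a, abs=1e-10)

    def test_jensen_inequality_on_random_sets(self):
        rng = np.random.default_rng(6)
        for _ in range(100):
            dws = rng.uniform(5.0, 80.0, rng.integers(2, 8))
            arith, _ = combine_routes(dws, method="arithmetic")
            jarz, _ = combine_routes(dws, method="jarzynski")
            assert jarz <= arith + 1e-9
            if np.ptp(dws) > 1e-6:
                assert jarz < arith


class TestStandardDg:
    def test_neutral_calibration_returns_work(self):
        cal = StandardStateCal(k_w=1.0, c_v=0.0)
        assert standard_dg(12.5, cal) == pytest.approx(12.5)

    def test_cv_offset(self):
        cal = StandardStateCal(k_w=1.0, c_v=5.0)
        assert standard_dg(0.0, cal) == pytest.approx(-5.0)

    def test_kw_contributes_minus_rt_log(self):
        rt = R_GAS_KJ * 310.0
        assert rt == pytest.approx(2.577, abs=5e-4)  # RT at 310 K
        base = standard_dg(30.0, StandardStateCal(k_w=1.0), T=310.0)
        doubled = standard_dg(30.0, StandardStateCal(k_w=2.0), T=310.0)
        assert doubled - base == pytest.approx(-rt * np.log(2.0), rel=1e-12)

    def test_monotone_in_dw_and_kw(self):
        cal = StandardStateCal(k_w=1.0)
        assert standard_dg(10.0, cal) < standard_dg(11.0, cal)
        assert standard_dg(10.0, StandardStateCal(k_w=2.0)) < standard_dg(10.0, cal)


class TestStandardDgIntegral:
    def test_standard_volume_ratio_of_one_contributes_nothing(self):
        z = np.linspace(0, 1, 101)
        profile = PMFProfile(z, np.zeros_like(z))
        dg = standard_dg_integral(
            profile, (0.0, 1.0), v_unbound=STANDARD_VOLUME_A3, include_minus_one=False
        )
        assert dg == pytest.approx(0.0, abs=1e-12)

    def test_square_well_matches_closed_form(self):
        z = np.linspace(0, 2, 2001)
        w = np.where(z <= 0.5, 0.0, 200.0)  # effectively infinite wall
        profile = PMFProfile(z, w)
        dg = standard_dg_integral(
            profile, (0.0, 0.25), v_unbound=STANDARD_VOLUME_A3,
            include_minus_one=False, T=310.0,
        )
        # ∫ exp(-W/RT) dz ≈ well width 0.5; bound length 0.25
        assert dg == pytest.approx(-RT310 * np.log(0.5 / 0.25), abs=5e-3)

    def test_all_negative_integrand_rejected(self):
        z = np.linspace(0, 1, 11)
        profile = PMFProfile(z, np.full_like(z, 300.0))
        with pytest.raises(ValueError):
            standard_dg_integral(profile, (0, 0.5), v_unbound=1661.0, include_minus_one=True)


class TestFitStandardState:
    def test_consistent_references_recover_offset_exactly(self):
        cal_true = StandardStateCal(k_w=1.0, c_v=17.0)
        refs = [(dw, standard_dg(dw, cal_true)) for dw in (40.0, 60.0)]
        cal, residuals = fit_kw_cv(refs)
        assert cal.c_v == pytest.approx(17.0, rel=1e-12)
        np.testing.assert_allclose(residuals, 0.0, atol=1e-10)

    def test_gauge_choice_preserves_predictions(self):
        cal_true = StandardStateCal(k_w=1.0, c_v=10.0)
        refs = [(dw, standard_dg(dw, cal_true)) for dw in (30.0, 50.0, 70.0)]
        cal_a, _ = fit_kw_cv(refs, k_w=1.0)
        cal_b, _ = fit_kw_cv(refs, k_w=4.0)
        for dw in (35.0, 55.0):
            assert standard_dg(dw, cal_a) == pytest.approx(standard_dg(dw, cal_b), rel=1e-10)

    def test_duplicated_reference_leaves_fit_unchanged(self):
        refs = [(40.0, -20.0), (60.0, -10.0)]
        a, _ = fit_kw_cv(refs)
        b, _ = fit_kw_cv(refs + [refs[0]])
        # duplication shifts the least-squares mean; equal-offset refs do not
        consistent = [(40.0, 40.0 - 25.0), (60.0, 60.0 - 25.0)]
        c, _ = fit_kw_cv(consistent)
        d, _ = fit_kw_cv(consistent + [consistent[1]])
        assert c.c_v == pytest.approx(d.c_v, rel=1e-12)

    def test_accepts_profiles_as_references(self):
        z = np.linspace(0, 3, 301)
        profile = PMFProfile(z, np.where(z < 1, 0.0, 30.0))
        cal, _ = fit_kw_cv([(profile, 5.0), (profile, 5.0)], bound_region=(0.0, 0.5))
        assert cal.c_v == pytest.approx(25.0, rel=1e-9)


def test_profile_text_roundtrip():
    z = np.linspace(0, 1, 11)
    profile = PMFProfile(z, z**2)
    back = read_profile(write_profile(profile))
    np.testing.assert_allclose(back.z, profile.z, atol=1e-6)
    np.testing.assert_allclose(back.w, profile.w, atol=1e-6)


def test_window_series_reader_skips_headers():
    vals = read_window_series("# header\n@ xaxis\n0.0 0.12\n0.05 0.13\n")
    np.testing.assert_allclose(vals, [0.12, 0.13])


def test_build_ensemble_bundles_route_statistics():
    z = np.linspace(0, 3, 301)
    profiles = [
        PMFProfile(z, np.where(z < 1.0, 0.0, h)) for h in (48.0, 50.0, 52.0)
    ]
    from mrfe.pmf import build_ensemble

    ens = build_ensemble(profiles, bound_region=(0.0, 0.5))
    assert ens.dw_mean == pytest.approx(50.0)
    assert ens.dw_sigma == pytest.approx(np.std([48.0, 50.0, 52.0], ddof=1))
    np.testing.assert_allclose(ens.dw_values, [48.0, 50.0, 52.0])
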