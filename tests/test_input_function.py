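"""Input-function assembly, component fits and corrections."""

import dataclasses

import numpy as np
import pytest

from petkin import (
    BloodSampleSet,
    HillParams,
    assemble_whole_blood,
    build_input_function,
    correct_dispersion,
    fit_parent_fraction,
    fit_plasma_blood_ratio,
)
from petkin.errors import (
    DivisionError,
    InsufficientDataError,
    JoinError,
    ParameterError,
)
from petkin.input_function import apply_dispersion, ratio_curve

from .test_io import make_blood


class TestAssembleWholeBlood:
    def test_constant_data_gives_constant_curve(self):
        samples = make_blood(
            abss_blood_kbq_cc=np.full(301, 10.0),
            manual_blood_kbq_cc=np.full(6, 10.0),
        )
        curve = assemble_whole_blood(samples, 2760.0)
        np.testing.assert_allclose(curve, 10.0, rtol=1e-12)

    def test_abss_window_is_identity(self):
        samples = make_blood()
        curve = assemble_whole_blood(samples, 2760.0)
        np.testing.assert_array_equal(curve[:301], samples.abss_blood_kbq_cc)

    def test_manual_interpolation_tracks_monoexponential(self):
        # manual samples on a known exponential decay, joined at 300 s
        t_manual = np.arange(315.0, 2700.0, 180.0)
        true = lambda t: 8.0 * np.exp(-t / 1500.0)  # noqa: E731
        samples = make_blood(
            abss_blood_kbq_cc=true(np.arange(301.0)),
            manual_time_s=t_manual,
            manual_blood_kbq_cc=true(t_manual),
            manual_plasma_kbq_cc=true(t_manual) * 1.5,
        )
        curve = assemble_whole_blood(samples, 2760.0)
        mid = (t_manual[:-1] + t_manual[1:]) / 2.0
        got = curve[mid.astype(int)]
        assert np.max(np.abs(got - true(mid)) / true(mid)) < 0.01

    def test_large_gap_requires_flag(self):
        samples = make_blood(
            manual_time_s=np.array([500.0, 900.0, 1500.0, 2100.0, 2400.0, 2600.0])
        )
        with pytest.raises(JoinError, match="gap"):
            assemble_whole_blood(samples, 2760.0)
        curve = assemble_whole_blood(samples, 2760.0, allow_extrapolation=True)
        assert np.all(np.isfinite(curve))


class TestPlasmaBloodRatio:
    def test_constant_ratio(self):
        samples = make_blood(
            manual_blood_kbq_cc=np.full(6, 2.0),
            manual_plasma_kbq_cc=np.full(6, 3.2),
        )
        intercept, slope = fit_plasma_blood_ratio(samples)
        assert slope == pytest.approx(0.0, abs=1e-12)
        assert intercept == pytest.approx(1.6, abs=1e-12)

    def test_two_points_fit_exactly(self):
        samples = make_blood(
            manual_time_s=np.array([600.0, 3000.0]),
            manual_blood_kbq_cc=np.array([1.0, 1.0]),
            manual_plasma_kbq_cc=np.array([1.4, 1.8]),
        )
        intercept, slope = fit_plasma_blood_ratio(samples)
        assert intercept + slope * 600.0 == pytest.approx(1.4, abs=1e-12)
        assert intercept + slope * 3000.0 == pytest.approx(1.8, abs=1e-12)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(7)
        t = np.array([240.0, 600.0, 1200.0, 1800.0, 2400.0, 3000.0])
        ratio = 1.32 + 1.6e-4 * t + rng.normal(0, 0.02, 6)
        blood = rng.uniform(1.0, 4.0, 6)
        samples = make_blood(
            manual_time_s=t,
            manual_blood_kbq_cc=blood,
            manual_plasma_kbq_cc=ratio * blood,
        )
        intercept, slope = fit_plasma_blood_ratio(samples)
        # closed-form simple regression
        sxx = np.sum((t - t.mean()) ** 2)
        slope_o = np.sum((t - t.mean()) * (ratio - ratio.mean())) / sxx
        inter_o = ratio.mean() - slope_o * t.mean()
        assert slope == pytest.approx(slope_o, abs=1e-12)
        assert intercept == pytest.approx(inter_o, abs=1e-12)

    def test_zero_blood_sample_identified(self):
        samples = make_blood(
            manual_blood_kbq_cc=np.array([5.0, 0.0, 3.2, 2.5, 2.0, 1.4])
        )
        with pytest.raises(DivisionError, match="450"):
            fit_plasma_blood_ratio(samples)

    def test_ratio_curve_clipped_nonnegative(self):
        assert np.all(ratio_curve(0.1, -1e-3, np.arange(0, 1000.0)) >= 0.0)


class TestParentFraction:
    def test_zero_noise_recovery(self):
        truth = HillParams(alpha=0.35, beta=1.5, gamma=2.0e5)
        t = np.array([240.0, 600.0, 1200.0, 1800.0, 2400.0, 3000.0])
        samples = make_blood(
            parent_time_s=t, parent_fraction=truth.parent_fraction(t)
        )
        fit = fit_parent_fraction(samples)
        for name in ("alpha", "beta", "gamma"):
            assert getattr(fit, name) == pytest.approx(
                getattr(truth, name), rel=1e-6
            ), name

    def test_model_is_unity_at_time_zero(self):
        samples = make_blood()
        fit = fit_parent_fraction(samples)
        assert fit.parent_fraction(0.0) == pytest.approx(1.0, abs=1e-12)

    def test_end_of_scan_fraction_near_published_value(self, if_truth):
        # samples generated from the default truth, which is calibrated to
        # reach a parent fraction of about 0.70 at 60 min
        t = np.array([240.0, 600.0, 1200.0, 1800.0, 2400.0, 3000.0])
        samples = make_blood(
            parent_time_s=t, parent_fraction=if_truth.hill.parent_fraction(t)
        )
        fit = fit_parent_fraction(samples)
        assert fit.parent_fraction(3600.0) == pytest.approx(0.70, abs=0.015)

    def test_too_few_points(self):
        with pytest.raises(InsufficientDataError):
            fit_parent_fraction(
                make_blood(
                    parent_time_s=np.array([240.0, 600.0]),
                    parent_fraction=np.array([0.97, 0.9]),
                )
            )

    def test_monotone_non_increasing(self):
        hill = HillParams(0.4, 1.2, 5e4)
        pf = hill.parent_fraction(np.linspace(0, 4000, 400))
        assert np.all(np.diff(pf) <= 1e-15)


class TestDispersion:
    def test_tau_zero_is_identity(self):
        g = np.sin(np.linspace(0, 3, 100)) + 2.0
        np.testing.assert_array_equal(correct_dispersion(g, 0.0), g)

    @pytest.mark.parametrize("method,tol", [("exact", 1e-10), ("derivative", 0.02)])
    def test_convolve_then_correct_recovers(self, method, tol):
        t = np.arange(0.0, 600.0)
        g = np.where(t < 20, 0.0, (t - 20) * np.exp(-(t - 20) / 40.0))
        dispersed = apply_dispersion(g, 2.5)
        recovered = correct_dispersion(dispersed, 2.5, method=method)
        interior = slice(5, -5)
        rms = np.sqrt(np.mean((recovered[interior] - g[interior]) ** 2))
        assert rms / np.max(g) < tol

    def test_constant_curve_unchanged(self):
        g = np.full(200, 7.5)
        for tau in (0.5, 2.5, 10.0):
            np.testing.assert_allclose(correct_dispersion(g, tau), g, rtol=1e-9)
            np.testing.assert_allclose(
                correct_dispersion(g, tau, method="derivative"), g, rtol=1e-9
            )

    def test_negative_tau_rejected(self):
        with pytest.raises(ParameterError):
            correct_dispersion(np.ones(10), -1.0)


class TestBuildInputFunction:
    def make_trivial_samples(self):
        """pf == 1, plasma == blood, so the input equals the blood curve."""
        t_manual = np.array([315.0, 450.0, 630.0, 990.0, 1410.0, 2610.0])
        blood_vals = 8.0 * np.exp(-t_manual / 1500.0)
        return make_blood(
            abss_blood_kbq_cc=8.0 * np.exp(-np.arange(301.0) / 1500.0),
            manual_time_s=t_manual,
            manual_blood_kbq_cc=blood_vals,
            manual_plasma_kbq_cc=blood_vals,  # ratio == 1
            parent_time_s=np.array([240.0, 600.0, 1200.0, 1800.0, 2400.0]),
            parent_fraction=np.ones(5),
        )

    def test_identity_composition(self):
        samples = self.make_trivial_samples()
        aifn = build_input_function(samples, 2760.0, tau_s=0.0)
        blood = assemble_whole_blood(samples, 2760.0)
        np.testing.assert_allclose(aifn.plasma_parent_kbq_cc, blood, rtol=1e-12)

    def test_grid_invariant(self, blood):
        aifn = build_input_function(blood, 2760.0)
        assert aifn.time_s[0] == 0.0
        assert aifn.time_s[-1] == 2760.0
        np.testing.assert_array_equal(np.diff(aifn.time_s), 1.0)

    def test_parent_bounded_by_uncorrected_plasma(self, blood):
        aifn = build_input_function(blood, 2760.0)
        uncorrected = aifn.whole_blood_kbq_cc * ratio_curve(
            aifn.ratio_intercept, aifn.ratio_slope, aifn.time_s
        )
        assert np.all(aifn.plasma_parent_kbq_cc <= uncorrected + 1e-12)

    def test_reconstructs_generating_truth(self, aif, blood):
        rebuilt = build_input_function(blood, aif.end_s)
        truth = aif.plasma_parent_kbq_cc
        mask = truth > 0.01 * truth.max()
        rel = np.abs(rebuilt.plasma_parent_kbq_cc[mask] - truth[mask]) / truth[mask]
        assert np.max(rel) < 0.02

    def test_increasing_metabolism_never_raises_plasma(self):
        samples = make_blood()
        base = build_input_function(samples, 2760.0)
        blood_curve = base.whole_blood_kbq_cc * ratio_curve(
            base.ratio_intercept, base.ratio_slope, base.time_s
        )
        prev = None
        for alpha in (0.0, 0.2, 0.4, 0.8):
            hill = HillParams(alpha, base.hill.beta, base.hill.gamma)
            plasma = blood_curve * hill.parent_fraction(base.time_s)
            if prev is not None:
                assert np.all(plasma <= prev + 1e-12)
            prev = plasma

    def test_stage_labelled_errors(self):
        samples = make_blood(
            manual_blood_kbq_cc=np.array([5.0, 0.0, 3.2, 2.5, 2.0, 1.4])
        )
        with pytest.raises(DivisionError, match=r"\[plasma/blood ratio\]"):
            build_input_function(samples, 2760.0)
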