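"""Equidistant log-log resampling, background fitting, slope-free intercepts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nremspec import (
    PowerLawFit, Spectrum, evaluate_background, fit_background, fit_spectrum,
    loglog_grid_step, slope_free_pivot, to_equidistant_loglog,
)
from nremspec.powerlaw import ALT_INTERCEPT_ANCHORS


class TestEquidistantGrid:
    def test_smallest_step_sits_at_the_top_of_the_range(self):
        step = loglog_grid_step(2.0, 48.0)
        assert step == pytest.approx(np.log(48) - np.log(47.75))
        assert round(step, 4) == 0.0052

    def test_point_count_matches_brute_force_construction(self, make_spectrum):
        spec, _ = make_spectrum()
        ll = to_equidistant_loglog(spec)
        # oracle: walk from ln 2 in units of the step until ln 48 is passed
        n = 0
        x = np.log(2.0)
        while x <= np.log(48.0) + 1e-15:
            n += 1
            x += ll.step
        assert len(ll.lnf) == n
        assert len(ll.lnf) == int(np.floor((np.log(48) - np.log(2)) / ll.step)) + 1

    def test_interpolant_reproduces_source_knots(self, make_spectrum):
        spec, _ = make_spectrum(alpha=-2.1, lnC=3.0,
                                bumps=((13.0, 0.6, 0.5),))
        ll = to_equidistant_loglog(spec)
        f, p = spec.band(2.0, 48.0)
        assert np.allclose(ll.interpolant(np.log(f)), np.log(p), atol=1e-12)

    def test_nonpositive_power_identified(self, make_spectrum):
        spec, _ = make_spectrum()
        power = spec.power.copy()
        power[np.argmin(np.abs(spec.freqs - 30.0))] = 0.0
        bad = Spectrum(spec.freqs, power)
        with pytest.raises(ValueError, match="30.00 Hz"):
            to_equidistant_loglog(bad)


class TestFitBackground:
    @pytest.mark.parametrize("alpha,lnC", [(-1.0, 5.0), (-2.5, 5.0),
                                           (-4.0, -2.0), (-2.5, 0.0)])
    def test_exact_recovery_on_noiseless_model(self, make_spectrum, alpha, lnC):
        spec, _ = make_spectrum(alpha=alpha, lnC=lnC)
        fit = fit_spectrum(spec)
        assert fit.alpha == pytest.approx(alpha, abs=1e-9)
        assert fit.lnC0 == pytest.approx(lnC, abs=1e-9)
        assert fit.r2 == pytest.approx(1.0, abs=1e-9)

    def test_bump_inside_excluded_band_shields_the_fit(self, make_spectrum):
        clean, _ = make_spectrum(alpha=-2.5, lnC=5.0)
        bumped, _ = make_spectrum(alpha=-2.5, lnC=5.0,
                                  bumps=((12.0, 1.5, 0.8),))
        f_clean = fit_spectrum(clean)
        f_bump = fit_spectrum(bumped)
        assert abs(f_bump.alpha - f_clean.alpha) < 1e-9
        assert abs(f_bump.lnC0 - f_clean.lnC0) < 1e-9

    def test_noisy_fit_close_to_ols_theory(self, make_spectrum):
        spec, _ = make_spectrum(alpha=-2.5, lnC=5.0, noise_sd=0.05, seed=7)
        fit = fit_spectrum(spec)
        assert abs(fit.alpha + 2.5) < 0.01
        assert fit.r2 < 1.0

    def test_r2_decreases_with_noise(self, make_spectrum):
        r2s = []
        for sd in (0.0, 0.05, 0.2, 0.5):
            vals = [fit_spectrum(make_spectrum(noise_sd=sd, seed=s, bumps=())[0]).r2
                    for s in range(5)]
            r2s.append(np.mean(vals))
        assert all(a > b for a, b in zip(r2s, r2s[1:]))

    def test_too_few_points_outside_exclusion(self, make_spectrum):
        spec, _ = make_spectrum()
        ll = to_equidistant_loglog(spec)
        with pytest.raises(ValueError, match="outside the excluded band"):
            fit_background(ll, exclude=(1.0, 50.0))

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(alpha=st.floats(-4.0, -1.0), lnC=st.floats(-5.0, 10.0))
    def test_exact_recovery_property(self, alpha, lnC):
        freqs = 0.25 * np.arange(1, 193)
        power = np.exp(lnC + alpha * np.log(freqs))
        fit = fit_spectrum(Spectrum(freqs, power))
        assert abs(fit.alpha - alpha) < 1e-9
        assert abs(fit.lnC0 - lnC) < 1e-9


class TestIntercepts:
    def test_intercept_at_lnf_zero_and_arithmetic(self):
        fit = PowerLawFit(alpha=-2.0, lnC0=4.0, r2=1.0, alt_intercepts={})
        assert evaluate_background(fit, 0.0) == pytest.approx(4.0)
        assert evaluate_background(fit, 2.5) == pytest.approx(-1.0)

    def test_anchor_frequencies_are_the_published_ones(self):
        # ln f = 2.5 and 2.6 correspond to the 12.2 and 13.5 Hz anchors
        assert np.exp(2.5) == pytest.approx(12.2, abs=0.02)
        assert np.exp(2.6) == pytest.approx(13.5, abs=0.04)

    def test_alt_intercepts_follow_the_line_exactly(self, make_spectrum):
        fit = fit_spectrum(make_spectrum(alpha=-3.1, lnC=6.0)[0])
        anchors = sorted(fit.alt_intercepts)
        for x in anchors:
            assert fit.alt_intercepts[x] == fit.lnC0 + fit.alpha * x
        for x, y in zip(anchors, anchors[1:]):
            got = fit.alt_intercepts[x] - fit.alt_intercepts[y]
            assert got == pytest.approx(fit.alpha * (x - y), abs=1e-12)

    def test_gauge_shift_moves_only_the_intercept(self, make_spectrum):
        spec, _ = make_spectrum(alpha=-2.5, lnC=4.0)
        shifted = Spectrum(spec.freqs, spec.power * np.e)
        f0, f1 = fit_spectrum(spec), fit_spectrum(shifted)
        assert f1.alpha == pytest.approx(f0.alpha, abs=1e-9)
        assert f1.lnC0 == pytest.approx(f0.lnC0 + 1.0, abs=1e-9)


def _orthogonalize(u, alpha):
    """Remove the in-sample alpha component so corr(alpha, u) = 0 exactly."""
    a = alpha - alpha.mean()
    return u - a * np.dot(u - u.mean(), a) / np.dot(a, a)


def _cohort_fits(rng, n=60, pivot=2.5):
    """Subjects where lnC at the pivot anchor is independent of alpha."""
    alpha = rng.uniform(-3.5, -1.5, n)
    u = _orthogonalize(rng.normal(-1.5, 0.4, n), alpha)
    return [PowerLawFit(alpha=a, lnC0=ui - a * pivot, r2=0.99, alt_intercepts={})
            for a, ui in zip(alpha, u)]


class TestSlopeFreePivot:
    def test_planted_pivot_recovered_with_sign_profile(self, rng):
        report = slope_free_pivot(_cohort_fits(rng))
        assert report.pivot == 2.5
        assert report.r_alpha_lnC0 < 0
        for x in ALT_INTERCEPT_ANCHORS:
            if x < 2.5:
                assert report.correlations[x] < 0
            elif x > 2.5:
                assert report.correlations[x] > 0
        assert report.sign_change is not None
        assert report.sign_change[0] <= 2.5 <= report.sign_change[1]
        assert not report.flat_profile

    def test_structureless_cohort_flags_flat_profile(self, rng):
        # near-constant slopes against independent intercept noise leave
        # |r| tiny at every anchor
        alpha = -2.5 + 1e-3 * rng.normal(size=60)
        lnC0 = _orthogonalize(rng.normal(4.0, 1.0, 60), alpha)
        fits = [PowerLawFit(alpha=a, lnC0=c, r2=0.99, alt_intercepts={})
                for a, c in zip(alpha, lnC0)]
        report = slope_free_pivot(fits)
        assert report.flat_profile

    def test_constant_alpha_rejected(self):
        fits = [PowerLawFit(alpha=-2.5, lnC0=4.0, r2=1.0, alt_intercepts={})
                for _ in range(12)]
        with pytest.raises(ValueError, match="constant"):
            slope_free_pivot(fits)

    def test_too_few_subjects_rejected(self, rng):
        with pytest.raises(ValueError, match="at least 10"):
            slope_free_pivot(_cohort_fits(rng, n=5))
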