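"""Zone arithmetic and partial polynomial background fitting."""

import numpy as np
import pytest
from numpy.polynomial import Polynomial

import ramanclean as rc
from ramanclean.errors import (
    ContractError,
    EmptySelectionError,
    UnderdeterminedError,
    WindowError,
)
from ramanclean.synthetic import gaussian_peaks

COEF = np.array([2000.0, -800.0, 300.0, -120.0, 60.0, -25.0])


def true_poly(axis):
    return Polynomial(COEF, domain=(350.0, 1800.0))(axis)


class TestSelectChannels:
    def test_paper_zones_with_water_exclusion(self, axis):
        idx = rc.select_channels(axis, rc.DEFAULT_FIT_ZONES, rc.WATER_EXCLUDE_ZONES)
        selected = set(axis[idx])
        for w in (400, 450, 800, 1200, 1800):
            assert w in selected  # closed include boundaries
        for w in np.arange(1550, 1651, 2):
            assert w not in selected  # closed exclusion removes 1600-1650 too
        assert 1652 in selected
        # nothing outside the include zones
        assert selected <= set(
            w for w in axis if rc.DEFAULT_FIT_ZONES.contains([w])[0]
        )

    def test_channel_count_on_arithmetic_grid(self):
        axis = np.arange(400.0, 451.0, 2.0)
        idx = rc.select_channels(axis, rc.ZoneSet(((400.0, 450.0),)))
        assert idx.size == 26

    def test_full_cancellation_is_empty_selection_error(self, axis):
        zones = rc.ZoneSet(((400.0, 450.0),))
        with pytest.raises(EmptySelectionError):
            rc.select_channels(axis, zones, zones)


class TestZoneSet:
    def test_from_string_round_trip(self):
        zs = rc.ZoneSet.from_string("400-450,800-1200,1600-1800")
        assert zs == rc.DEFAULT_FIT_ZONES

    @pytest.mark.parametrize(
        "intervals",
        [((450.0, 400.0),), ((800.0, 1200.0), (400.0, 450.0)), ((400.0, 900.0), (800.0, 1200.0))],
    )
    def test_invalid_zonesets_rejected(self, intervals):
        with pytest.raises(ContractError):
            rc.ZoneSet(intervals)


class TestFit:
    def test_exact_recovery_of_degree5_member(self, axis):
        s = rc.Spectrum(axis, true_poly(axis))
        bl = rc.fit_partial_polynomial(s)
        win = (axis >= 400) & (axis <= 1700)
        err = np.max(np.abs(bl(axis[win]) - true_poly(axis[win])))
        assert err < 1e-8 * np.ptp(true_poly(axis))
        assert bl.degree == 5

    def test_constant_spectrum_fits_itself(self, axis):
        s = rc.Spectrum(axis, np.full(axis.size, 123.0))
        bl = rc.fit_partial_polynomial(s)
        assert bl.fit_rms < 1e-9
        np.testing.assert_allclose(bl(axis), 123.0)

    def test_peak_inside_fit_zone_hurts_more_than_outside(self, axis):
        base = true_poly(axis)
        inside = base + gaussian_peaks(axis, [(1000.0, 20.0, 800.0)])
        outside = base + gaussian_peaks(axis, [(600.0, 20.0, 800.0)])
        err_in = np.max(np.abs(rc.fit_partial_polynomial(rc.Spectrum(axis, inside))(axis) - base))
        err_out = np.max(np.abs(rc.fit_partial_polynomial(rc.Spectrum(axis, outside))(axis) - base))
        assert err_out < err_in

    def test_fit_blind_to_bumps_outside_zones(self, axis):
        base = true_poly(axis)
        bump = gaussian_peaks(axis, [(600.0, 25.0, 1e6), (1400.0, 40.0, 5e5)])
        idx = rc.select_channels(axis, rc.DEFAULT_FIT_ZONES, rc.WATER_EXCLUDE_ZONES)
        bump[idx] = 0.0  # supported strictly outside the fit channels
        b1 = rc.fit_partial_polynomial(rc.Spectrum(axis, base))
        b2 = rc.fit_partial_polynomial(rc.Spectrum(axis, base + bump))
        assert b1.coefficients == b2.coefficients  # fit never sees the bump

    def test_fit_is_linear_in_the_data(self, axis, rng):
        y1 = rng.normal(size=axis.size)
        y2 = rng.normal(size=axis.size)
        a, b = 2.5, -1.25
        f = lambda y: np.asarray(
            rc.fit_partial_polynomial(rc.Spectrum(axis, y)).coefficients
        )
        combo = f(a * y1 + b * y2)
        np.testing.assert_allclose(combo, a * f(y1) + b * f(y2), rtol=1e-8, atol=1e-10)

    def test_underdetermined_fit_rejected(self):
        axis = np.arange(400.0, 416.0, 2.0)
        s = rc.Spectrum(axis, np.ones(axis.size))
        zones = rc.ZoneSet(((400.0, 404.0),))  # 3 channels < degree+1
        with pytest.raises(UnderdeterminedError):
            rc.fit_partial_polynomial(s, zones, None, degree=5)

    def test_noise_consistency_small(self, axis):
        win = (axis >= 400) & (axis <= 1700)
        sigma = 20.0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            y = true_poly(axis) + rng.normal(0, sigma, axis.size)
            bl = rc.fit_partial_polynomial(rc.Spectrum(axis, y))
            rmse = np.sqrt(np.mean((bl(axis[win]) - true_poly(axis[win])) ** 2))
            assert rmse < 3 * sigma


class TestSubtract:
    def test_self_subtraction_is_zero(self, axis):
        s = rc.Spectrum(axis, true_poly(axis))
        bl = rc.fit_partial_polynomial(s)
        out = rc.subtract_baseline(s, bl)
        assert np.max(np.abs(out.intensities)) < 1e-8 * np.ptp(s.intensities)

    def test_output_restricted_to_window(self, axis):
        s = rc.Spectrum(axis, true_poly(axis))
        bl = rc.fit_partial_polynomial(s, window=(400.0, 1700.0))
        out = rc.subtract_baseline(s, bl)
        assert out.wavenumbers[0] == 400.0
        assert out.wavenumbers[-1] == 1700.0

    def test_disjoint_window_is_error(self, axis):
        s = rc.Spectrum(axis, true_poly(axis))
        bl = rc.fit_partial_polynomial(s, window=(2000.0, 2100.0))
        with pytest.raises(WindowError):
            rc.subtract_baseline(s, bl)

    def test_negative_residuals_are_preserved(self, axis, rng):
        y = true_poly(axis) + rng.normal(0, 20.0, axis.size)
        s = rc.Spectrum(axis, y)
        out = rc.subtract_baseline(s, rc.fit_partial_polynomial(s))
        assert (out.intensities < 0).any()  # no clipping before the top-hat
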