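"""External-standard and standard-additions calibration, interpolation
and uncertainty combination."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tubeqc.calibration import (
    CalibrationFit,
    CalibrationPoint,
    apply_dilution,
    combine_relative_uncertainties,
    estimate_concentration,
    fit_calibration,
    interpolate,
    repeatability,
    standard_additions,
)
from tubeqc.datasets import repeatability_table
from tubeqc.exceptions import DegenerateComputationError, InvalidInputError

from .oracles import ols_oracle


class TestFitCalibration:
    def test_collinear_points_give_exact_line(self):
        fit = fit_calibration(
            [CalibrationPoint(0, 0), CalibrationPoint(1, 0.2), CalibrationPoint(2, 0.4)]
        )
        assert fit.slope == pytest.approx(0.2, rel=1e-12)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)
        assert fit.residual_sd == pytest.approx(0.0, abs=1e-12)
        assert fit.r_squared == 1.0

    def test_rejects_fewer_than_three_points(self):
        with pytest.raises(InvalidInputError):
            fit_calibration([CalibrationPoint(1, 1), CalibrationPoint(3, 5)])

    def test_rejects_identical_concentrations(self):
        with pytest.raises(DegenerateComputationError):
            fit_calibration(
                [CalibrationPoint(1, 0.1), CalibrationPoint(1, 0.2), CalibrationPoint(1, 0.3)]
            )

    def test_six_point_design_matches_closed_form(self, six_point_design, six_point_fit):
        x = [p.concentration for p in six_point_design]
        y = [p.absorbance for p in six_point_design]
        slope, intercept, syx, slope_sd, intercept_sd = ols_oracle(x, y)
        assert six_point_fit.slope == pytest.approx(slope, rel=1e-12)
        assert six_point_fit.intercept == pytest.approx(intercept, rel=1e-9)
        assert six_point_fit.residual_sd == pytest.approx(syx, rel=1e-12)
        assert six_point_fit.slope_sd == pytest.approx(slope_sd, rel=1e-12)
        assert six_point_fit.intercept_sd == pytest.approx(intercept_sd, rel=1e-12)
        # frozen spot values from the independent evaluation
        assert six_point_fit.slope == pytest.approx(0.2027634, abs=5e-7)
        assert six_point_fit.residual_sd == pytest.approx(0.0017631, abs=5e-7)

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_random_designs_match_closed_form(self, seed):
        rng = np.random.default_rng(seed)
        x = np.sort(rng.uniform(0.1, 5.0, size=6))
        x += np.arange(6) * 1e-3  # guarantee distinct levels
        y = 0.2 * x + 0.01 + rng.normal(0, 0.005, size=6)
        fit = fit_calibration([CalibrationPoint(a, b) for a, b in zip(x, y)])
        slope, intercept, syx, slope_sd, intercept_sd = ols_oracle(x, y)
        assert fit.slope == pytest.approx(slope, rel=1e-10)
        assert fit.intercept == pytest.approx(intercept, rel=1e-8, abs=1e-12)
        assert fit.residual_sd == pytest.approx(syx, rel=1e-10)
        assert fit.slope_sd == pytest.approx(slope_sd, rel=1e-10)
        assert fit.intercept_sd == pytest.approx(intercept_sd, rel=1e-10)


class TestInterpolate:
    def test_centroid_maps_to_x_mean_with_minimal_sd(self, six_point_fit):
        est = interpolate(six_point_fit, six_point_fit.y_mean)
        assert est.value == pytest.approx(six_point_fit.x_mean, rel=1e-12)
        expected_sd = (six_point_fit.residual_sd / six_point_fit.slope) * math.sqrt(
            1 + 1 / six_point_fit.n_points
        )
        assert est.interp_sd == pytest.approx(expected_sd, rel=1e-12)

    @settings(max_examples=50, deadline=None)
    @given(st.floats(0.25, 4.0))
    def test_roundtrip_recovers_concentration(self, six_point_fit, x):
        y = six_point_fit.predict(x)
        assert interpolate(six_point_fit, y).value == pytest.approx(x, rel=1e-12)

    def test_sd_symmetric_about_centroid_and_increasing(self, six_point_fit):
        ybar = six_point_fit.y_mean
        sd0 = interpolate(six_point_fit, ybar).interp_sd
        for delta in (0.05, 0.1, 0.2):
            lo = interpolate(six_point_fit, ybar - delta).interp_sd
            hi = interpolate(six_point_fit, ybar + delta).interp_sd
            assert lo == pytest.approx(hi, rel=1e-12)
            assert lo > sd0
        sds = [
            interpolate(six_point_fit, ybar + d).interp_sd
            for d in np.linspace(0, 0.4, 9)
        ]
        assert all(a < b for a, b in zip(sds, sds[1:]))

    def test_six_point_example_frozen_values(self, six_point_fit):
        est = interpolate(six_point_fit, 0.300)
        # independently evaluated closed forms
        assert est.value == pytest.approx(1.4752059, abs=5e-7)
        assert est.interp_sd == pytest.approx(0.0094283, abs=5e-7)

    def test_historical_line_interpolation(self):
        # a reported dated line (a = 0.2032, b = 0.0002) applied to a
        # measured absorbance of 0.28716; the same-day raw calibration
        # printed 1.4118, direct arithmetic on the rounded line gives 1.4122
        fit = CalibrationFit(
            slope=0.2032, intercept=0.0002, slope_sd=0.0010, intercept_sd=0.0021,
            residual_sd=0.0032, r_squared=0.99991, n_points=6,
            x_mean=1.7916667, y_mean=0.3641667, sxx=11.052083,
        )
        assert interpolate(fit, 0.28716).value == pytest.approx(1.4122, abs=1e-4)

    def test_replicates_shrink_uncertainty(self, six_point_fit):
        one = interpolate(six_point_fit, 0.3, replicates=1)
        four = interpolate(six_point_fit, 0.3, replicates=4)
        assert four.interp_sd < one.interp_sd
        with pytest.raises(InvalidInputError):
            interpolate(six_point_fit, 0.3, replicates=0)

    def test_nonpositive_value_flagged_not_raised(self, six_point_fit):
        est = interpolate(six_point_fit, six_point_fit.intercept - 0.05)
        assert not est.quantifiable
        assert est.value < 0
        assert math.isnan(est.rel_interp_sd)

    def test_zero_slope_is_degenerate(self):
        fit = CalibrationFit(
            slope=0.0, intercept=0.1, slope_sd=0.0, intercept_sd=0.0,
            residual_sd=0.01, r_squared=0.0, n_points=6,
            x_mean=1.0, y_mean=0.1, sxx=1.0,
        )
        with pytest.raises(DegenerateComputationError):
            interpolate(fit, 0.2)


class TestUncertaintyCombination:
    @pytest.mark.parametrize(
        "components, expected",
        [
            ([0.01], 0.01),
            ([0.01, 0.0], 0.01),
            ([0.0054, 0.0087], math.sqrt(0.0054**2 + 0.0087**2)),  # 0.0102396...
        ],
    )
    def test_root_sum_of_squares(self, components, expected):
        assert combine_relative_uncertainties(components) == pytest.approx(
            expected, rel=1e-12
        )

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=6))
    def test_square_is_sum_of_squares_and_dominates_max(self, comps):
        combined = combine_relative_uncertainties(comps)
        assert combined**2 == pytest.approx(sum(c**2 for c in comps), rel=1e-12, abs=1e-15)
        assert combined >= max(comps) - 1e-15

    def test_empty_rejected(self):
        with pytest.raises(InvalidInputError):
            combine_relative_uncertainties([])


class TestDilutionAndChain:
    @pytest.mark.parametrize(
        "measured, factor, expected",
        [(1.4150, 10, 14.150), (2.5, 1, 2.5), (0.0, 10, 0.0)],
    )
    def test_apply_dilution(self, measured, factor, expected):
        assert apply_dilution(measured, factor) == pytest.approx(expected, abs=1e-12)

    def test_nonpositive_factor_rejected(self):
        with pytest.raises(InvalidInputError):
            apply_dilution(1.0, 0)

    def test_estimate_concentration_combines_dilution_uncertainty(self, six_point_fit):
        est = estimate_concentration(six_point_fit, 0.300, dilution_factor=10)
        base = interpolate(six_point_fit, 0.300)
        assert est.value == pytest.approx(10 * base.value, rel=1e-12)
        expected = est.value * math.sqrt(base.rel_interp_sd**2 + 0.0087**2)
        assert est.combined_sd == pytest.approx(expected, rel=1e-12)
        assert est.combined_sd > 10 * base.interp_sd * 0.99  # dilution adds, never removes


class TestStandardAdditions:
    def test_exact_line(self):
        assert standard_additions([(0, 0.30), (1, 0.50), (2, 0.70)]) == pytest.approx(
            1.5, rel=1e-12
        )

    def test_zero_intercept(self):
        assert standard_additions([(0, 0.0), (1, 0.2), (2, 0.4)]) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_noisy_points_match_intercept_oracle(self):
        rng = np.random.default_rng(7)
        added = np.array([0.0, 1.0, 2.0, 4.0])
        true_conc, slope = 1.25, 0.21
        absorb = slope * (added + true_conc) + rng.normal(0, 0.002, size=4)
        est = standard_additions(list(zip(added, absorb)))
        a, b, *_ = ols_oracle(added, absorb)
        assert est == pytest.approx(b / a, rel=1e-10)
        assert est == pytest.approx(true_conc, abs=0.1)

    def test_preconditions(self):
        with pytest.raises(InvalidInputError):
            standard_additions([(0, 0.1), (1, 0.2)])
        with pytest.raises(InvalidInputError):
            standard_additions([(1, 0.2), (2, 0.3), (3, 0.4)])  # no zero addition
        with pytest.raises(DegenerateComputationError):
            standard_additions([(0, 0.4), (1, 0.3), (2, 0.2)])  # negative slope


def test_repeatability_of_replicate_determinations():
    table = repeatability_table()
    mean, sd, rsd = repeatability(table["concentration_mmol_L"])
    assert round(mean, 4) == 1.4150
    assert round(sd, 4) == 0.0043
    assert rsd == pytest.approx(100 * sd / mean, rel=1e-12)
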