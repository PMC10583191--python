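"""Decline splines, averaged profiles, crossings and senescence parameters."""

import math

import numpy as np
import pytest

from phenoseason import senescence
from phenoseason import synthetic_data as synth
from phenoseason import trajectory
from phenoseason.errors import ProfileError
from phenoseason.senescence import (
    SenescenceProfile,
    SmoothingSpline,
    average_profile,
    crossing_date,
    extract_senescence_params,
    fit_decline_spline,
)

from conftest import closed_form_crossing

# Frozen predictions of R's stats::smooth.spline(spar=0.5, all.knots=TRUE)
# on the seeded sigmoid fixture below, evaluated at days 180, 192, ..., 348.
R_ORACLE_DAYS = np.arange(180.0, 349.0, 12.0)
R_ORACLE_PRED = np.array([
    18.707423, 18.265592, 17.654543, 16.705875, 15.265858, 13.232194,
    10.660423, 7.830524, 5.132422, 2.912570, 1.343876, 0.396179,
    -0.091258, -0.311388, -0.423226,
])


def sigmoid_fixture():
    rng = np.random.default_rng(7)
    days = np.arange(180, 358, 14, dtype=float)
    true = (1 + np.exp(0.08 * (days - 260.0))) ** -1.0 * 18.0
    return days, true * np.exp(rng.normal(0, 0.05, days.size))


class TestSmoothingSpline:
    def test_linear_data_reproduced_exactly(self):
        days = np.arange(200.0, 300.0, 10.0)
        sizes = 5.0 - 0.03 * (days - 200.0)
        spline = fit_decline_spline(days, sizes)
        assert np.allclose(spline(days), sizes, atol=1e-6)

    def test_matches_r_smooth_spline_at_spar_half(self):
        days, y = sigmoid_fixture()
        spline = SmoothingSpline(days, y, spar=0.5)
        got = spline(R_ORACLE_DAYS)
        assert np.max(np.abs(got - R_ORACLE_PRED)) < 0.01

    def test_large_spar_approaches_least_squares_line(self):
        days, y = sigmoid_fixture()
        spline = SmoothingSpline(days, y, spar=3.0)
        grid = np.linspace(days[0], days[-1], 60)
        line = np.polyval(np.polyfit(days, y, 1), grid)
        assert np.max(np.abs(spline(grid) - line)) < 1e-3
        assert np.max(np.abs(np.diff(spline(grid), 2))) < 1e-8

    def test_few_points_fall_back_to_linear_interpolation(self):
        with pytest.warns(UserWarning):
            f = fit_decline_spline([1.0, 2.0, 3.0], [3.0, 2.0, 1.0])
        assert f(1.5) == pytest.approx(2.5)

    def test_dense_noiseless_decline_reproduces_truth_at_crossings(
        self, noiseless_series
    ):
        truths, by_species = noiseless_series
        truth = truths[1]  # theta = 1
        shoot = by_species[truth.species_id][0]
        spline = fit_decline_spline(shoot.decline_days, shoot.decline_sizes)
        for q in (0.95, 0.5, 0.25):
            t_q = closed_form_crossing(truth, q)
            predicted = float(spline(t_q)) / truth.K_true
            assert predicted == pytest.approx(q, rel=0.01)


def linear_profile(start, stop, species_id="sp"):
    """Exact linear decline 1 -> 0 over [start, stop] as a profile."""
    grid = np.arange(float(start), float(stop) + 1)
    frac = (stop - grid) / (stop - start)
    crossings = {
        q: senescence._crossing(grid, frac, q, "last" if q == 0.95 else "first")
        for q in senescence.PROFILE_FRACTIONS
    }
    return SenescenceProfile(
        species_id=species_id,
        grid_days=grid,
        mean_fraction=frac,
        crossings=crossings,
        overwinters=crossings[0.25] is None,
    )


class _LineSpline:
    def __init__(self, start, stop, peak):
        self.domain = (float(start), float(stop))
        self.peak = peak
        self.start, self.stop = float(start), float(stop)

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        return self.peak * (self.stop - t) / (self.stop - self.start)


class TestAverageProfile:
    def test_single_individual_identity(self):
        profile = average_profile([_LineSpline(200, 300, 10.0)], [10.0])
        assert np.allclose(
            profile.mean_fraction, (300 - profile.grid_days) / 100.0
        )

    def test_normalization_invariance(self):
        a = average_profile(
            [_LineSpline(200, 300, 10.0), _LineSpline(200, 300, 20.0)],
            [10.0, 20.0],
        )
        b = average_profile([_LineSpline(200, 300, 10.0)], [10.0])
        assert np.allclose(a.mean_fraction, b.mean_fraction)

    def test_two_linear_declines_average_cross_midway(self):
        # 50 % at day 240 and 260 -> the averaged curve crosses at 250
        a = _LineSpline(190, 290, 8.0)   # 50 % at 240
        b = _LineSpline(210, 310, 8.0)   # 50 % at 260
        profile = average_profile([a, b], [8.0, 8.0])
        assert crossing_date(profile, 0.5) == pytest.approx(250.0, abs=0.2)

    def test_empty_input_rejected(self):
        with pytest.raises(ProfileError):
            average_profile([], [])


class TestCrossingDate:
    def test_linear_closed_forms(self):
        profile = linear_profile(200, 300)
        assert crossing_date(profile, 0.50, "first") == pytest.approx(250.0)
        assert crossing_date(profile, 0.95, "last") == pytest.approx(205.0)
        assert crossing_date(profile, 0.05, "first") == pytest.approx(295.0)

    def test_never_crossed_is_undefined_and_overwinters(self):
        grid = np.arange(200.0, 301.0)
        frac = 0.6 + 0.2 * (300 - grid) / 100.0  # stays in [0.6, 0.8]
        profile = SenescenceProfile("sp", grid, frac, {}, False)
        assert crossing_date(profile, 0.25, "first") is None
        full = average_profile(
            [_LineSpline(200, 400, 1.0)], [1.0]
        )  # domain truncated at 400 but grid spans it entirely
        assert full.crossings[0.25] is not None

    def test_non_monotone_profile_first_and_last_modes(self):
        # dips to 0.4, recovers to 0.8, then declines for good
        grid = np.arange(0.0, 101.0)
        frac = np.concatenate([
            np.linspace(1.0, 0.4, 26),   # days 0-25: dip
            np.linspace(0.4, 0.8, 25)[1:],  # days 26-49: recovery
            np.linspace(0.8, 0.0, 52)[1:],  # days 50-100: final decline
        ])
        profile = SenescenceProfile("sp", grid, frac, {}, False)
        first_half = crossing_date(profile, 0.5, "first")
        assert first_half < 25.0  # inside the dip
        last95 = crossing_date(profile, 0.95, "last")
        assert last95 < first_half  # before the dip
        # brute-force scan oracle
        below = grid[frac <= 0.5]
        assert first_half == pytest.approx(below[0], abs=1.0)

    def test_crossings_are_ordered(self):
        profile = linear_profile(210, 330)
        c = profile.crossings
        assert c[0.95] <= c[0.50] <= c[0.25] <= c[0.05]


class TestExtractParams:
    def test_linear_decline_pace_and_symmetric_shape(self):
        params = extract_senescence_params(linear_profile(200, 300))
        assert params.sen_date == pytest.approx(250.0)
        assert params.sen_pace == pytest.approx(1.0 / 90.0, rel=1e-6)
        assert params.C == pytest.approx(45.0)
        assert params.D == pytest.approx(45.0)
        assert params.sen_shape == pytest.approx(0.0, abs=1e-9)
        assert params.season_end == pytest.approx(275.0)

    def test_symmetric_richards_profile(self):
        # theta = 1, s = 0.1, m = 250: crossings are the closed forms
        grid = np.arange(180.0, 331.0)
        frac = (1 + np.exp(0.1 * (grid - 250.0))) ** -1.0
        crossings = {
            q: senescence._crossing(
                grid, frac, q, "last" if q == 0.95 else "first"
            )
            for q in senescence.PROFILE_FRACTIONS
        }
        profile = SenescenceProfile("sp", grid, frac, crossings, False)
        params = extract_senescence_params(profile)
        assert params.sen_date == pytest.approx(250.0, abs=0.1)
        assert params.sen_pace == pytest.approx(1.0 / 58.89, abs=2e-4)
        assert params.sen_shape == pytest.approx(0.0, abs=0.01)

    def test_time_shift_moves_dates_not_pace_or_shape(self):
        base = extract_senescence_params(linear_profile(200, 300))
        shifted = extract_senescence_params(linear_profile(210, 310))
        assert shifted.sen_date == base.sen_date + 10.0
        assert shifted.season_end == base.season_end + 10.0
        assert shifted.sen_pace == pytest.approx(base.sen_pace)
        assert shifted.sen_shape == pytest.approx(base.sen_shape)

    def test_profile_without_half_crossing_is_ineligible(self):
        grid = np.arange(200.0, 301.0)
        frac = np.full(grid.size, 0.8)
        profile = SenescenceProfile("sp", grid, frac, {}, True)
        with pytest.raises(ProfileError):
            extract_senescence_params(profile)

    def test_scale_invariance_of_species_parameters(self, small_noisy_dataset):
        _, measurements, _, _ = small_noisy_dataset
        series = trajectory.measurements_to_series(measurements)
        sid = series[0].species_id
        group = [s for s in series if s.species_id == sid]
        base = senescence.species_senescence(group)
        scaled = measurements.copy()
        for col in ("upper_width_cm", "lower_width_cm", "length_cm"):
            scaled[col] = scaled[col] * 3.7
        series2 = trajectory.measurements_to_series(scaled)
        group2 = [s for s in series2 if s.species_id == sid]
        other = senescence.species_senescence(group2)
        assert other.sen_date == pytest.approx(base.sen_date, abs=0.11)
        assert other.sen_pace == pytest.approx(base.sen_pace, rel=1e-3)
        assert other.sen_shape == pytest.approx(base.sen_shape, abs=1e-2)

    @pytest.mark.parametrize("index,theta", [(0, 0.3), (1, 1.0), (2, 3.0)])
    def test_shape_sign_matches_truth_across_theta(
        self, noiseless_series, index, theta
    ):
        truths, by_species = noiseless_series
        truth = truths[index]
        assert truth.theta_true == theta
        params = senescence.species_senescence(by_species[truth.species_id])
        t50 = closed_form_crossing(truth, 0.5)
        t95 = closed_form_crossing(truth, 0.95)
        t05 = closed_form_crossing(truth, 0.05)
        if t05 > max(s.days[-1] for s in by_species[truth.species_id]):
            assert params.sen_pace is None  # crossing beyond observation
            return
        true_shape = math.log((t05 - t50) / (t50 - t95))
        if abs(true_shape) > 0.05:
            assert math.copysign(1, params.sen_shape) == math.copysign(
                1, true_shape
            )
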