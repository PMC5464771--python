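"""Track analytics: speeds, excursion, arrest rule, cohort summaries."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tcellmech import (
    Track,
    classify_arrest,
    instantaneous_speeds,
    max_excursion,
    net_displacement,
    summarize_cohort,
    track_metrics,
)
from tcellmech.synth import TrackSimParams, simulate_tracks

from conftest import brute_force_max_excursion, make_track, random_track


class TestTrackValidation:
    def test_rejects_mismatched_lengths(self):
        with pytest.raises(ValueError, match="lengths differ"):
            Track("t", times=[0.0, 5.0], xs=[0.0], ys=[0.0, 1.0])

    def test_rejects_non_increasing_times(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            Track("t", times=[0.0, 5.0, 5.0], xs=[0.0] * 3, ys=[0.0] * 3)

    def test_irregular_interval_warns_but_accepts(self, caplog):
        with caplog.at_level("WARNING"):
            tr = Track("t", times=[0.0, 5.0, 12.0], xs=[0.0] * 3, ys=[0.0] * 3)
        assert tr.n_points == 3
        assert any("irregular frame interval" in r.message for r in caplog.records)


class TestInstantaneousSpeeds:
    @pytest.mark.parametrize(
        "points, expected",
        [
            ([(0, 0), (3, 4)], [60.0]),  # 5 µm step in 5 s
            ([(0, 0)] * 10, [0.0] * 9),  # stationary
            ([(0, 0), (1, 0), (1, 0)], [12.0, 0.0]),
        ],
    )
    def test_hand_computed_examples(self, points, expected):
        tr = make_track(points, dt=5.0)
        np.testing.assert_allclose(instantaneous_speeds(tr), expected)

    def test_single_point_track_errors(self):
        with pytest.raises(ValueError, match="too short"):
            instantaneous_speeds(make_track([(0, 0)]))

    def test_irregular_intervals_use_per_step_durations(self):
        tr = Track("t", times=[0.0, 5.0, 15.0], xs=[0.0, 1.0, 3.0], ys=[0.0, 0.0, 0.0])
        np.testing.assert_allclose(instantaneous_speeds(tr), [12.0, 12.0])


class TestMaxExcursion:
    @pytest.mark.parametrize(
        "points, expected",
        [
            ([(0, 0), (3, 4), (0, 0)], 5.0),  # return trip: not path length
            ([(0, 0)], 0.0),
            ([(0, 0), (2, 0), (7, 0), (4, 0)], 7.0),  # collinear, interior pair
        ],
    )
    def test_examples(self, points, expected):
        assert max_excursion(make_track(points)) == pytest.approx(expected)

    def test_matches_brute_force_oracle_on_random_tracks(self, rng):
        for _ in range(100):
            tr = random_track(rng)
            assert max_excursion(tr) == pytest.approx(brute_force_max_excursion(tr))

    def test_dominates_net_displacement(self, rng):
        for _ in range(50):
            tr = random_track(rng)
            assert max_excursion(tr) >= net_displacement(tr) - 1e-12

    def test_equals_net_displacement_for_straight_monotone_track(self):
        tr = make_track([(0, 0), (1, 1), (2, 2), (5, 5)])
        assert max_excursion(tr) == pytest.approx(net_displacement(tr))


@st.composite
def track_strategy(draw):
    n = draw(st.integers(min_value=2, max_value=20))
    coords = st.floats(min_value=-100, max_value=100, allow_nan=False)
    pts = draw(st.lists(st.tuples(coords, coords), min_size=n, max_size=n))
    return make_track(pts)


class TestMetricInvariances:
    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(track_strategy(), st.floats(-50, 50), st.floats(-50, 50), st.floats(0, 2 * math.pi))
    def test_rigid_motions_leave_metrics_unchanged(self, tr, dx, dy, angle):
        c, s = math.cos(angle), math.sin(angle)
        xs = c * tr.xs - s * tr.ys + dx
        ys = s * tr.xs + c * tr.ys + dy
        moved = Track(tr.track_id, tr.times, xs, ys)
        assert max_excursion(moved) == pytest.approx(max_excursion(tr), abs=1e-9)
        np.testing.assert_allclose(
            instantaneous_speeds(moved), instantaneous_speeds(tr), atol=1e-9
        )

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(track_strategy(), st.floats(0.1, 10))
    def test_scaling_positions_scales_metrics(self, tr, c):
        scaled = Track(tr.track_id, tr.times, c * tr.xs, c * tr.ys)
        assert max_excursion(scaled) == pytest.approx(c * max_excursion(tr), rel=1e-9)
        np.testing.assert_allclose(
            instantaneous_speeds(scaled), c * instantaneous_speeds(tr), rtol=1e-9
        )


class TestClassifyArrest:
    def test_strict_threshold_boundary(self):
        arrested = make_track([(0, 0)] * 60 + [(9.9, 0)], dt=5.0)  # duration 300 s
        migrating = make_track([(0, 0)] * 60 + [(10.0, 0)], dt=5.0)
        assert classify_arrest(arrested) is True
        assert classify_arrest(migrating) is False

    def test_short_track_threshold_scales_linearly(self):
        # 2.5-min track: threshold scales to 5 µm
        tr = make_track([(0, 0)] * 30 + [(4.9, 0)], dt=5.0)  # duration 150 s
        assert classify_arrest(tr) is True
        tr2 = make_track([(0, 0)] * 30 + [(5.0, 0)], dt=5.0)
        assert classify_arrest(tr2) is False

    def test_distance_rule_equals_rate_rule(self, rng):
        # 10 µm / 300 s is the same call as 2 µm/min on the same window
        for _ in range(50):
            tr = random_track(rng, scale=rng.uniform(1, 30))
            rate_threshold_um = 2.0 * (tr.duration / 60.0)
            rate_call = max_excursion(tr) < rate_threshold_um
            assert classify_arrest(tr, threshold_um=10.0, window_s=300.0) == rate_call

    def test_zero_duration_errors(self):
        with pytest.raises(ValueError, match="zero-duration"):
            classify_arrest(make_track([(0, 0)]))


class TestSummarizeCohort:
    def test_hand_computed_mixed_cohort(self):
        arrested = [
            make_track([(0, 0)] * 61, dt=5.0, track_id=f"a{i}") for i in range(3)
        ]
        pts = [(i * 1.0, 0.0) for i in range(61)]  # 1 µm per 5 s = 12 µm/min
        migrating = [make_track(pts, dt=5.0, track_id="m")]
        s = summarize_cohort(arrested + migrating)
        assert s.percent_arrested == pytest.approx(75.0)
        assert s.n_arrested == 3
        assert s.velocity_defined
        assert s.velocity_mean == pytest.approx(12.0)

    def test_all_arrested_flags_velocity_undefined(self):
        cohort = [make_track([(0, 0)] * 61, track_id=f"a{i}") for i in range(4)]
        s = summarize_cohort(cohort)
        assert s.percent_arrested == 100.0
        assert not s.velocity_defined
        assert math.isnan(s.velocity_mean)

    def test_empty_cohort_errors(self):
        with pytest.raises(ValueError, match="empty"):
            summarize_cohort([])

    def test_short_tracks_excluded_from_velocity_only(self):
        two_point = make_track([(0, 0), (20, 0)], dt=300.0, track_id="short")
        pts = [(i * 1.0, 0.0) for i in range(61)]
        s = summarize_cohort([two_point, make_track(pts, track_id="long")])
        assert s.n_tracks == 2  # short track still counted for arrest stats
        assert s.n_velocity_tracks == 1
        assert s.n_excluded_short == 1

    def test_synthetic_arrest_fraction_within_binomial_error(self):
        p = 0.3
        params = TrackSimParams(n_cells=200, frac_arrested=p, seed=7)
        s = summarize_cohort(simulate_tracks(params))
        se = 100.0 * math.sqrt(p * (1 - p) / 200)
        assert abs(s.percent_arrested - 100.0 * p) <= 3 * se

    def test_velocity_mean_recovers_generator_mean(self):
        params = TrackSimParams(
            n_cells=100, frac_arrested=0.0, migrating_speed_mean=15.5,
            migrating_speed_sd=4.0, seed=3,
        )
        s = summarize_cohort(simulate_tracks(params))
        assert abs(s.velocity_mean - 15.5) <= 3 * 0.4


def test_track_metrics_roundup():
    pts = [(i * 1.0, 0.0) for i in range(61)]
    m = track_metrics(make_track(pts, dt=5.0, track_id="m1"))
    assert m.track_id == "m1"
    assert m.duration_s == pytest.approx(300.0)
    assert m.mean_velocity_um_min == pytest.approx(12.0)
    assert m.max_excursion_um == pytest.approx(60.0)
    assert m.arrested is False
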