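"""I-VT event labeling, AOI counting, scan-path length, and trial filters."""

import numpy as np
import pandas as pd
import pytest
import shapely
from hypothesis import given, settings
from hypothesis import strategies as st
from shapely.geometry import Polygon

from gazefeit.events import (
    FIXATION,
    INVALID,
    SACCADE,
    DisplayGeometry,
    EventConfig,
    angular_velocity,
    classify_events_ivt,
    count_fixation_samples_in_aoi,
    count_saccades,
    cyclopean_points,
    filter_trials,
    scan_path_length,
)

GEOM = DisplayGeometry()


def _sep_normalized(angle_deg: float) -> float:
    """On-axis horizontal separation (normalized x units) subtending angle_deg."""
    sep_mm = 2.0 * GEOM.viewing_distance_mm * np.tan(np.radians(angle_deg) / 2.0)
    return sep_mm / GEOM.physical_width_mm


class TestCyclopean:
    @pytest.mark.parametrize(
        "left,right,lv,rv,expected",
        [
            ((0.4, 0.5), (0.6, 0.5), True, True, (0.5, 0.5)),
            ((0.2, 0.9), (0.7, 0.7), True, False, (0.2, 0.9)),
            ((0.2, 0.9), (0.7, 0.7), False, True, (0.7, 0.7)),
            ((0.2, 0.9), (0.7, 0.7), False, False, None),
        ],
    )
    def test_eye_combination(self, left, right, lv, rv, expected):
        df = pd.DataFrame(
            [{"lx": left[0], "ly": left[1], "rx": right[0], "ry": right[1], "lvalid": lv, "rvalid": rv}]
        )
        pt = cyclopean_points(df)[0]
        if expected is None:
            assert np.isnan(pt).all()
        else:
            assert pt == pytest.approx(expected)


class TestAngularVelocity:
    def test_identical_points_zero(self):
        assert angular_velocity((0.3, 0.3), (0.3, 0.3), 1 / 120) == 0.0

    def test_on_axis_separation_oracle(self):
        # 11.35 mm separation centered on-axis at 650 mm over one 120 Hz frame:
        # the subtended angle is 2*atan(5.675/650) ~ 1.0006 deg -> ~120 deg/s.
        dx = 11.35 / GEOM.physical_width_mm
        v = angular_velocity((0.5 - dx / 2, 0.5), (0.5 + dx / 2, 0.5), 1 / 120)
        expected = np.degrees(2 * np.arctan(5.675 / 650.0)) * 120
        assert v == pytest.approx(expected, rel=1e-9)
        assert v == pytest.approx(120.0, rel=2e-3)

    def test_velocity_scales_inversely_with_dt(self):
        dx = 11.35 / GEOM.physical_width_mm
        p, q = (0.5 - dx / 2, 0.5), (0.5 + dx / 2, 0.5)
        assert angular_velocity(p, q, 1 / 60) == pytest.approx(angular_velocity(p, q, 1 / 120) / 2)

    def test_symmetric_in_argument_order(self):
        assert angular_velocity((0.1, 0.2), (0.8, 0.9), 0.01) == pytest.approx(
            angular_velocity((0.8, 0.9), (0.1, 0.2), 0.01)
        )

    def test_nonpositive_dt_rejected(self):
        with pytest.raises(ValueError):
            angular_velocity((0.1, 0.2), (0.3, 0.4), 0.0)


class TestIVT:
    def test_stationary_sequence_all_fixation(self):
        pts = np.tile([0.5, 0.5], (50, 1))
        labels = classify_events_ivt(pts, np.arange(50) / 0.12)
        assert (labels == FIXATION).all()

    def test_velocity_at_threshold_is_fixation(self):
        # The rule is "exceeds": a velocity exactly equal to the threshold is
        # a fixation.  Set the threshold to the velocity the classifier itself
        # computes so the comparison is exact.
        dx = _sep_normalized(1.0)
        pts = np.array([[0.5 - dx / 2, 0.5], [0.5 + dx / 2, 0.5]])
        t = np.array([0.0, 1000.0 / 120.0])
        v = angular_velocity(pts[0], pts[1], 1 / 120)
        labels = classify_events_ivt(pts, t, EventConfig(velocity_threshold_deg_s=v))
        assert (labels == FIXATION).all()
        labels = classify_events_ivt(pts, t, EventConfig(velocity_threshold_deg_s=v * (1 - 1e-9)))
        assert labels[1] == SACCADE

    def test_single_step_jump_yields_one_saccade_run(self):
        # 5 deg instantaneous jump mid-trial: only the post-jump sample moves.
        dx = _sep_normalized(5.0)
        pts = np.vstack([np.tile([0.4, 0.5], (20, 1)), np.tile([0.4 + dx, 0.5], (20, 1))])
        labels = classify_events_ivt(pts, np.arange(40) / 0.12)
        assert count_saccades(labels) == 1
        assert labels[20] == SACCADE
        assert (labels[:20] == FIXATION).all() and (labels[21:] == FIXATION).all()

    def test_first_sample_inherits_successor_label(self):
        dx = _sep_normalized(5.0)
        pts = np.array([[0.2, 0.5], [0.2 + dx, 0.5], [0.2 + dx, 0.5]])
        labels = classify_events_ivt(pts, np.arange(3) / 0.12)
        assert labels[0] == SACCADE  # successor is a saccade

    def test_long_gap_breaks_velocity_chain(self):
        # Invalid gap of 100 ms (> 75 ms): the sample after the gap has no
        # usable predecessor and inherits from its own successor (fixation).
        dx = _sep_normalized(30.0)
        pts = np.array([[0.2, 0.5]] * 5 + [[np.nan, np.nan]] * 12 + [[0.2 + dx, 0.5]] * 5)
        labels = classify_events_ivt(pts, np.arange(22) / 0.12)
        assert (labels[5:17] == INVALID).all()
        assert labels[17] == FIXATION

    def test_label_partition(self):
        rng = np.random.default_rng(3)
        pts = rng.uniform(0, 1, (600, 2))
        pts[rng.random(600) < 0.2] = np.nan
        labels = classify_events_ivt(pts, np.arange(600) / 0.12)
        n_inv = int((labels == INVALID).sum())
        n_fix = int((labels == FIXATION).sum())
        n_sac = int((labels == SACCADE).sum())
        assert n_inv + n_fix + n_sac == 600
        assert n_inv == int(np.isnan(pts).any(axis=1).sum())

    def test_lower_threshold_never_decreases_saccade_samples(self):
        rng = np.random.default_rng(4)
        pts = np.cumsum(rng.normal(0, 0.01, (300, 2)), axis=0) % 1.0
        t = np.arange(300) / 0.12
        counts = [
            int((classify_events_ivt(pts, t, EventConfig(velocity_threshold_deg_s=thr)) == SACCADE).sum())
            for thr in (300.0, 100.0, 30.0, 10.0)
        ]
        assert counts == sorted(counts)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            classify_events_ivt(np.empty((0, 2)), np.empty(0))


class TestAOICounts:
    SQUARE = Polygon([(0.4, 0.4), (0.6, 0.4), (0.6, 0.6), (0.4, 0.6)])

    def test_no_points_inside(self):
        pts = np.tile([0.1, 0.1], (10, 1))
        labels = np.full(10, FIXATION)
        assert count_fixation_samples_in_aoi(labels, pts, self.SQUARE) == 0

    def test_all_fixation_inside(self):
        pts = np.tile([0.5, 0.5], (600, 1))
        labels = np.full(600, FIXATION)
        assert count_fixation_samples_in_aoi(labels, pts, self.SQUARE) == 600

    def test_brute_force_agreement_and_saccades_excluded(self):
        rng = np.random.default_rng(5)
        pts = rng.uniform(0.3, 0.7, (200, 2))
        labels = rng.choice([FIXATION, SACCADE, INVALID], size=200)
        pts[labels == INVALID] = np.nan
        expected = sum(
            1
            for lab, p in zip(labels, pts)
            if lab == FIXATION and self.SQUARE.covers(shapely.geometry.Point(p))
        )
        assert count_fixation_samples_in_aoi(labels, pts, self.SQUARE) == expected

    def test_boundary_point_counts_inside(self):
        pts = np.array([[0.4, 0.5]])  # on the left edge
        assert count_fixation_samples_in_aoi(np.array([FIXATION]), pts, self.SQUARE) == 1

    def test_vertex_order_invariance(self):
        rng = np.random.default_rng(6)
        pts = rng.uniform(0.2, 0.8, (100, 2))
        labels = np.full(100, FIXATION)
        reversed_sq = Polygon(list(self.SQUARE.exterior.coords[:-1])[::-1])
        assert count_fixation_samples_in_aoi(labels, pts, self.SQUARE) == count_fixation_samples_in_aoi(
            labels, pts, reversed_sq
        )


class TestScanPath:
    def test_stationary_gaze_zero(self):
        assert scan_path_length(np.tile([0.5, 0.5], (100, 1))) == 0.0

    def test_three_four_five_triangle(self):
        assert scan_path_length(np.array([[0.0, 0.0], [0.3, 0.4]])) == pytest.approx(0.5)

    def test_broken_trace_mean_over_valid_pairs(self):
        pts = np.array([[0.0, 0.0], [0.3, 0.4], [np.nan, np.nan], [0.1, 0.1], [0.1, 0.2]])
        assert scan_path_length(pts) == pytest.approx((0.5 + 0.1) / 2)

    def test_no_valid_pair_is_zero(self):
        pts = np.array([[0.1, 0.1], [np.nan, np.nan], [0.2, 0.2]])
        assert scan_path_length(pts) == 0.0

    @settings(max_examples=60, deadline=None)
    @given(st.data())
    def test_matches_brute_force_on_random_masked_traces(self, data):
        n = data.draw(st.integers(2, 40))
        rng = np.random.default_rng(data.draw(st.integers(0, 10**6)))
        pts = rng.uniform(0, 1, (n, 2))
        mask = rng.random(n) < 0.35
        pts[mask] = np.nan
        total, count = 0.0, 0
        for i in range(n - 1):
            if not (np.isnan(pts[i]).any() or np.isnan(pts[i + 1]).any()):
                total += float(np.hypot(*(pts[i + 1] - pts[i])))
                count += 1
        expected = total / count if count else 0.0
        assert scan_path_length(pts) == pytest.approx(expected, abs=1e-12)


class TestFilters:
    def _frame(self, scan, valid):
        return pd.DataFrame(
            [{"trial_id": "t", "scan_path_length": scan, "valid_fraction": valid}]
        )

    def test_low_validity_excluded(self):
        kept, log = filter_trials(self._frame(0.1, 0.35))
        assert kept.empty and log["exclusion_reason"].iloc[0] == "valid_fraction"

    def test_zero_scan_path_excluded(self):
        kept, log = filter_trials(self._frame(0.0, 1.0))
        assert kept.empty and log["exclusion_reason"].iloc[0] == "scan_path_zero"

    def test_moving_valid_trial_kept(self):
        kept, log = filter_trials(self._frame(0.05, 0.95))
        assert len(kept) == 1 and log.empty

    def test_validity_threshold_is_inclusive(self):
        kept, _ = filter_trials(self._frame(0.05, 0.40))
        assert len(kept) == 1
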