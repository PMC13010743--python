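"""Feature extraction: scan-path statistics, grating-viewing stability,
pursuit fidelity, and subject-level aggregation."""

import numpy as np
import pandas as pd
import pytest

from oculoscreen.events import FixationEvent
from oculoscreen.features import (
    FeatureConfig,
    aggregate_subject,
    grid_cell,
    task1_features,
    task2_features,
    task3_features,
    transition_entropy,
)
from oculoscreen.preprocess import ScreenGeometry

from conftest import make_segment

GEOM = ScreenGeometry()
FS = 30.0


def fixation_at(x, y, t0=0.0, dur=0.2, cell=None):
    return FixationEvent(
        start_idx=int(t0 * FS),
        end_idx=int((t0 + dur) * FS),
        t_start=t0,
        t_end=t0 + dur,
        duration_ms=dur * 1000,
        centroid=(x, y),
        rms_dispersion=0.1,
        cell=cell,
    )


def segment_from_fixations(fixations, jitter=0.0, seed=0):
    rng = np.random.default_rng(seed)
    parts = []
    for f in fixations:
        n = max(int(round(f.duration_ms / 1000 * FS)), 4)
        parts.append(np.asarray(f.centroid) + rng.normal(0, jitter, size=(n, 2)))
    return make_segment(np.vstack(parts), smooth=False)


class TestTransitionEntropy:
    def test_four_equiprobable_distinct_transitions(self):
        cells = [(0, 0), (1, 0), (2, 0), (3, 0), (4, 0)]
        assert transition_entropy(cells) == pytest.approx(2.0)

    def test_repeated_single_transition_zero_entropy(self):
        cells = [(0, 0), (0, 0), (0, 0), (0, 0)]
        assert transition_entropy(cells) == pytest.approx(0.0)

    def test_bounded_by_log2_of_transition_types(self):
        rng = np.random.default_rng(1)
        cells = [tuple(c) for c in rng.integers(0, 4, size=(30, 2))]
        pairs = set(zip(cells[:-1], cells[1:]))
        assert transition_entropy(cells) <= np.log2(len(pairs)) + 1e-12

    def test_invariant_to_uniform_translation_within_cells(self):
        # translate all fixations by less than a cell without crossing edges
        fx = [fixation_at(-15.0, -5.0), fixation_at(-8.0, 0.0), fixation_at(0.0, 5.0), fixation_at(8.0, 0.0)]
        cells_a = [grid_cell(f.centroid, GEOM) for f in fx]
        cells_b = [grid_cell((f.centroid[0] + 0.4, f.centroid[1] + 0.4), GEOM) for f in fx]
        assert transition_entropy(cells_a) == transition_entropy(cells_b)


class TestTask1:
    def test_single_fixation_has_missing_transition_features(self):
        fx = [fixation_at(0.0, 0.0)]
        seg = segment_from_fixations(fx)
        out = task1_features(seg, GEOM, fixations=fx)
        assert np.isnan(out["scanpath_entropy_bits"])
        assert out["regression_count"] == 0
        assert out["refixation_count"] == 0

    def test_regressions_counted_against_predominant_direction(self):
        # rightward scan of 6 fixations with exactly 2 leftward steps
        xs = [0.0, 3.0, 1.5, 4.5, 7.5, 6.0]
        fx = [fixation_at(x, 0.0, t0=0.25 * i) for i, x in enumerate(xs)]
        seg = segment_from_fixations(fx)
        out = task1_features(seg, GEOM, fixations=fx)
        assert out["regression_count"] == 2

    def test_saccade_amplitude_is_centroid_distance(self):
        fx = [fixation_at(0.0, 0.0), fixation_at(3.0, 4.0)]
        seg = segment_from_fixations(fx)
        out = task1_features(seg, GEOM, fixations=fx)
        assert out["saccade_amplitude_mean_deg"] == pytest.approx(5.0)

    def test_refixation_requires_nonadjacent_return(self):
        fx = [
            fixation_at(0.0, 0.0),
            fixation_at(5.0, 0.0),
            fixation_at(0.2, 0.0),  # within 1 deg of fixation 0, two steps back
        ]
        seg = segment_from_fixations(fx)
        out = task1_features(seg, GEOM, fixations=fx)
        assert out["refixation_count"] == 1

    def test_equiprobable_transitions_give_two_bits(self):
        # 5 fixations in distinct far-apart cells -> 4 distinct transitions
        fx = [
            fixation_at(-18.0, -8.0),
            fixation_at(-6.0, -8.0),
            fixation_at(6.0, -8.0),
            fixation_at(18.0, -8.0),
            fixation_at(18.0, 8.0),
        ]
        seg = segment_from_fixations(fx)
        out = task1_features(seg, GEOM, fixations=fx)
        assert out["scanpath_entropy_bits"] == pytest.approx(2.0)


class TestTask2:
    def test_pinned_gaze_has_zero_drift_and_hull(self):
        pos = np.zeros((60, 2))
        seg = make_segment(pos, task_id=2, smooth=False)
        out = task2_features(seg, GEOM, orientation_deg=30.0, stimulus_onset_s=0.0)
        assert out["directional_drift_deg"] == pytest.approx(0.0, abs=1e-9)
        assert out["hull_dispersion_deg2"] == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("orientation,expected", [(0.0, 0.5), (90.0, 0.0)])
    def test_drift_is_projection_on_orientation_axis(self, orientation, expected):
        pos = np.zeros((60, 2))
        pos[:, 0] = np.linspace(0, 0.5, 60)  # net displacement (0.5, 0)
        seg = make_segment(pos, task_id=2, smooth=False)
        out = task2_features(seg, GEOM, orientation_deg=orientation, stimulus_onset_s=0.0)
        assert out["directional_drift_deg"] == pytest.approx(expected, abs=1e-9)

    def test_hull_area_of_unit_square(self):
        # samples on the corners of a 1x1 deg square inside the ROI
        corners = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float) - 0.5
        pos = np.repeat(corners, 15, axis=0)
        seg = make_segment(pos, task_id=2, smooth=False)
        out = task2_features(seg, GEOM, orientation_deg=0.0, stimulus_onset_s=0.0)
        assert out["hull_dispersion_deg2"] == pytest.approx(1.0, abs=1e-9)

    def test_no_in_roi_fixation_means_missing_latency(self):
        pos = np.full((60, 2), [8.0, 0.0])  # parked far outside the 2 deg ROI
        seg = make_segment(pos, task_id=2, smooth=False)
        out = task2_features(seg, GEOM, orientation_deg=0.0, stimulus_onset_s=0.0)
        assert np.isnan(out["fixation_latency_ms"])


class TestTask3:
    def _target(self, n=600):
        t = np.arange(n) / FS
        pos = np.column_stack([15 * np.sin(2 * np.pi * 0.08 * t), 7.5 * np.sin(2 * np.pi * 0.16 * t)])
        vel = np.column_stack(
            [15 * 2 * np.pi * 0.08 * np.cos(2 * np.pi * 0.08 * t),
             7.5 * 2 * np.pi * 0.16 * np.cos(2 * np.pi * 0.16 * t)]
        )
        return pos, vel

    def test_perfect_tracking(self):
        pos, vel = self._target()
        seg = make_segment(pos, task_id=3)
        out = task3_features(seg, pos, vel, motion_onset_s=0.0)
        assert out["tracking_error_deg"] == pytest.approx(0.0, abs=0.02)
        assert out["pursuit_gain"] == pytest.approx(1.0, abs=0.01)

    def test_gain_recovers_scaling_factor(self):
        pos, vel = self._target()
        seg = make_segment(0.8 * pos, task_id=3)
        out = task3_features(seg, pos, vel, motion_onset_s=0.0)
        assert out["pursuit_gain"] == pytest.approx(0.8, abs=0.01)

    def test_stationary_gaze_zero_gain(self):
        pos, vel = self._target()
        seg = make_segment(np.zeros_like(pos), task_id=3)
        out = task3_features(seg, pos, vel, motion_onset_s=0.0)
        assert out["pursuit_gain"] == pytest.approx(0.0, abs=1e-9)

    def test_error_invariant_under_joint_translation(self):
        pos, vel = self._target()
        rng = np.random.default_rng(0)
        gaze = pos + rng.normal(0, 0.3, pos.shape)
        a = task3_features(make_segment(gaze, task_id=3), pos, vel, 0.0)
        b = task3_features(make_segment(gaze + 3.0, task_id=3), pos + 3.0, vel, 0.0)
        assert a["tracking_error_deg"] == pytest.approx(b["tracking_error_deg"], abs=1e-6)

    def test_misaligned_target_rejected(self):
        pos, vel = self._target()
        seg = make_segment(pos, task_id=3)
        with pytest.raises(ValueError):
            task3_features(seg, pos[:-1], vel[:-1], 0.0)


class TestAggregation:
    def _table(self, rows):
        from oculoscreen.features import ALL_FEATURES

        df = pd.DataFrame(rows)
        for col in ["orientation_deg", "contrast", *ALL_FEATURES]:
            if col not in df:
                df[col] = np.nan
        return df

    def test_identical_trials_aggregate_to_trial_value(self):
        rows = [
            {"subject_id": "a", "group": "control", "task_id": 3, "trial_id": i,
             "pursuit_gain": 0.9, "tracking_error_deg": 0.5,
             "catch_up_count": 4.0, "pursuit_onset_latency_ms": 150.0}
            for i in range(4)
        ]
        agg = aggregate_subject(self._table(rows))
        assert agg.loc[0, "pursuit_gain"] == pytest.approx(0.9)

    def test_median_robust_to_outlier_trial(self):
        rows = [
            {"subject_id": "a", "group": "control", "task_id": 3, "trial_id": i,
             "pursuit_gain": v} for i, v in enumerate([1.0, 2.0, 100.0])
        ]
        agg = aggregate_subject(self._table(rows))
        assert agg.loc[0, "pursuit_gain"] == pytest.approx(2.0)

    def test_orientation_then_average(self):
        # 2 orientations x 2 trials: median within orientation, mean across
        rows = []
        for ori, vals in [(0.0, [1.0, 3.0]), (90.0, [5.0, 7.0])]:
            for i, v in enumerate(vals):
                rows.append({"subject_id": "a", "group": "control", "task_id": 2,
                             "trial_id": len(rows), "orientation_deg": ori,
                             "directional_drift_deg": v})
        agg = aggregate_subject(self._table(rows))
        assert agg.loc[0, "directional_drift_deg"] == pytest.approx((2.0 + 6.0) / 2)

    def test_permutation_invariance_over_trial_order(self):
        rng = np.random.default_rng(2)
        rows = [
            {"subject_id": "a", "group": "control", "task_id": 1, "trial_id": i,
             "scanpath_entropy_bits": float(rng.uniform(1, 3))} for i in range(8)
        ]
        a = aggregate_subject(self._table(rows))
        b = aggregate_subject(self._table(rows[::-1]))
        assert a.loc[0, "scanpath_entropy_bits"] == pytest.approx(b.loc[0, "scanpath_entropy_bits"])

    def test_no_retained_trials_gives_missing_task_features(self):
        rows = [
            {"subject_id": "a", "group": "control", "task_id": 1, "trial_id": 0,
             "scanpath_entropy_bits": 2.0},
        ]
        agg = aggregate_subject(self._table(rows))
        assert np.isnan(agg.loc[0, "pursuit_gain"])
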