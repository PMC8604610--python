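import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mousegait.classify import ClassifiedFootfall, PawLabel
from mousegait.config import GaitConfig
from mousegait.detect import PawCluster
from mousegait.gait import (
    Step,
    cadence,
    paw_area_intensity,
    paw_position_table,
    paw_support,
    run_duration,
    segment_steps,
    stride_lengths,
    summarize_gait,
    swing_and_stance,
)


def footfall(frame, x=0.0, y=0.0, label=PawLabel.LEFT_FRONT, size=5, g=230):
    base = np.array([[0, 0], [-1, 0], [1, 0], [0, -1], [0, 1]])
    coords = base[:size] + np.array([round(x), round(y)])
    return ClassifiedFootfall(
        PawCluster(frame, coords, np.full(len(coords), g)), label
    )


def step(label, t_f, t_l, x=0.0, y=0.0):
    t_m = (t_f + t_l) // 2
    return Step(label, t_f, t_m, t_l, (x, y), tuple(range(t_f, t_l + 1)))


class TestSegmentation:
    def test_two_contact_phases(self):
        ff = [footfall(t) for t in list(range(10, 41)) + list(range(70, 101))]
        steps = segment_steps(ff, gap_tolerance=2)
        assert [(s.t_f, s.t_l) for s in steps] == [(10, 40), (70, 100)]

    def test_short_gap_is_bridged(self):
        ff = [footfall(t) for t in list(range(10, 21)) + list(range(22, 31))]
        steps = segment_steps(ff, gap_tolerance=2)
        assert [(s.t_f, s.t_l) for s in steps] == [(10, 30)]

    def test_single_detection(self):
        steps = segment_steps([footfall(5)], gap_tolerance=2)
        assert [(s.t_f, s.t_m, s.t_l) for s in steps] == [(5, 5, 5)]

    def test_mean_frame_snaps_to_member(self):
        # frames 0..4 and 10..14 bridged: midpoint 7 is absent, snaps to
        # the nearest member (tie -> earlier, so 4 vs 10: picks smaller gap)
        ff = [footfall(t) for t in [0, 1, 2, 3, 4, 10, 11, 12, 13, 14]]
        steps = segment_steps(ff, gap_tolerance=5)
        assert len(steps) == 1
        assert steps[0].t_m in steps[0].frames
        assert steps[0].t_m == 4  # |7-4| = 3 < |7-10| = 3 -> tie, earlier wins


class TestScalarFormulas:
    def test_run_duration_examples(self):
        assert run_duration([0, 60], 60) == 1.0
        assert run_duration([7], 60) == 0.0
        assert run_duration([30, 100, 330], 60) == 5.0

    def test_run_duration_requires_detections(self):
        with pytest.raises(ValueError):
            run_duration([], 60)

    def test_cadence_examples(self):
        assert cadence(10, 2.0) == 5.0
        assert cadence(0, 2.0) == 0.0
        assert cadence(7, 3.5) == 2.0
        assert math.isnan(cadence(3, 0.0))

    def test_stride_length_examples(self):
        s = [step(PawLabel.LEFT_FRONT, 0, 5, x=0), step(PawLabel.LEFT_FRONT, 20, 25, x=120)]
        values, avg = stride_lengths(s)
        assert values == [120.0] and avg == 120.0
        s345 = [step(PawLabel.LEFT_FRONT, 0, 5, x=0, y=0), step(PawLabel.LEFT_FRONT, 20, 25, x=3, y=4)]
        assert stride_lengths(s345)[0] == [5.0]

    def test_average_uses_actual_value_count(self):
        s = [
            step(PawLabel.LEFT_FRONT, 0, 5, x=0),
            step(PawLabel.LEFT_FRONT, 20, 25, x=100),
            step(PawLabel.LEFT_FRONT, 40, 45, x=220),
        ]
        values, avg = stride_lengths(s)
        assert values == [100.0, 120.0]
        assert avg == 110.0  # mean of the S-1 = 2 strides, not divided by S

    def test_fewer_than_two_steps_no_stride(self):
        values, avg = stride_lengths([step(PawLabel.LEFT_FRONT, 0, 5)])
        assert values == [] and math.isnan(avg)


class TestSwingStanceDutyCycle:
    def test_two_step_example(self):
        s = [step(PawLabel.LEFT_FRONT, 10, 40), step(PawLabel.LEFT_FRONT, 70, 100)]
        ss = swing_and_stance(s, 60)
        assert ss.stances_s == (0.5, 0.5)
        assert ss.swings_s == (0.5,)
        assert ss.duty_cycle == pytest.approx(2.0 / 3.0)

    def test_single_instant_step(self):
        ss = swing_and_stance([step(PawLabel.LEFT_FRONT, 5, 5)], 60)
        assert ss.stances_s == (0.0,)
        assert ss.swings_s == ()
        assert ss.duty_cycle == 1.0

    def test_stance_only_run(self):
        ss = swing_and_stance([step(PawLabel.LEFT_FRONT, 0, 59)], 60)
        assert ss.avg_stance_s == pytest.approx(59 / 60)
        assert ss.duty_cycle == 1.0

    @given(st.lists(st.tuples(st.integers(0, 500), st.integers(1, 50)), min_size=1, max_size=8))
    @settings(max_examples=100, deadline=None)
    def test_duty_cycle_bounded(self, raw):
        # build non-overlapping steps from (gap, duration) pairs
        t, steps = 0, []
        for gap, dur in raw:
            t += gap + 1
            steps.append(step(PawLabel.LEFT_FRONT, t, t + dur))
            t += dur
        ss = swing_and_stance(steps, 60)
        assert 0.0 <= ss.duty_cycle <= 1.0
        # identity: DC equals the stance fraction of the same step set
        total = sum(ss.stances_s) + sum(ss.swings_s)
        if total > 0:
            assert ss.duty_cycle == pytest.approx(sum(ss.stances_s) / total)


class TestPawSupport:
    def test_all_four_down(self):
        steps = {lab: [step(lab, 0, 29)] for lab in (
            PawLabel.LEFT_FRONT, PawLabel.RIGHT_FRONT, PawLabel.LEFT_REAR, PawLabel.RIGHT_REAR
        )}
        sup = paw_support(steps, run_duration_s=0.5, fps=60)
        assert sup.four_point_s == pytest.approx(0.5)
        assert sup.three_point_s == pytest.approx(0.5)

    def test_disjoint_contacts(self):
        steps = {
            PawLabel.LEFT_FRONT: [step(PawLabel.LEFT_FRONT, 0, 10)],
            PawLabel.RIGHT_REAR: [step(PawLabel.RIGHT_REAR, 20, 30)],
        }
        sup = paw_support(steps, run_duration_s=0.5, fps=60)
        assert sup.diagonal_dual_s == sup.three_point_s == sup.four_point_s == 0.0

    def test_diagonal_overlap_window(self):
        steps = {
            PawLabel.LEFT_FRONT: [step(PawLabel.LEFT_FRONT, 0, 10)],
            PawLabel.RIGHT_REAR: [step(PawLabel.RIGHT_REAR, 5, 15)],
        }
        sup = paw_support(steps, run_duration_s=0.25, fps=60)
        assert sup.diagonal_dual_s == pytest.approx(6 / 60)  # shared frames 5..10
        assert sup.three_point_s == 0.0 and sup.four_point_s == 0.0

    def test_four_point_never_exceeds_three_point(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            steps = {}
            for lab in (PawLabel.LEFT_FRONT, PawLabel.RIGHT_FRONT,
                        PawLabel.LEFT_REAR, PawLabel.RIGHT_REAR):
                t0 = int(rng.integers(0, 40))
                steps[lab] = [step(lab, t0, t0 + int(rng.integers(1, 30)))]
            sup = paw_support(steps, run_duration_s=1.0, fps=60)
            assert sup.four_point_s <= sup.three_point_s


class TestAreaIntensity:
    def test_average_area(self):
        c1 = PawCluster(0, np.column_stack([np.arange(80), np.zeros(80, int)]), np.full(80, 200))
        c2 = PawCluster(1, np.column_stack([np.arange(120), np.zeros(120, int)]), np.full(120, 220))
        area, _ = paw_area_intensity([c1, c2])
        assert area == 100.0

    def test_uniform_intensity(self):
        c = PawCluster(0, np.array([[0, 0], [1, 0]]), np.array([255, 255]))
        assert paw_area_intensity([c])[1] == 255.0

    def test_two_level_mean(self):
        c1 = PawCluster(0, np.array([[0, 0], [1, 0], [2, 0]]), np.array([200, 220, 240]))
        c2 = PawCluster(1, np.array([[0, 0]]), np.array([255]))
        _, intensity = paw_area_intensity([c1, c2])
        assert intensity == 237.5  # mean of per-cluster means 220 and 255


class TestSummarize:
    def test_recovers_generator_parameters(self, clean_run, clean_run_config):
        from mousegait.pipeline import run_pipeline

        result = run_pipeline(clean_run.frames, clean_run_config)
        got, want = result.summary, clean_run.expected
        cfg = clean_run.config
        assert got.run_duration_s == pytest.approx(want.run_duration_s)
        for lab, w in want.per_paw.items():
            g = got.per_paw[lab]
            assert g.step_count == w.step_count
            assert g.avg_stride_length_px == pytest.approx(w.avg_stride_length_px, abs=1.0)
            assert g.avg_stance_s == pytest.approx(w.avg_stance_s, abs=1 / cfg.fps + 1e-9)
            assert g.avg_swing_duration_s == pytest.approx(w.avg_swing_duration_s, abs=1 / cfg.fps + 1e-9)
            # one-frame quantisation per contact phase bounds the DC error
            active = w.step_count * cfg.stance_frames + (w.step_count - 1) * cfg.swing_frames
            assert abs(g.duty_cycle - w.duty_cycle) <= w.step_count / active + 1e-9

    def test_empty_run_rejected(self):
        with pytest.raises(ValueError):
            summarize_gait([], GaitConfig())

    def test_front_only_run_keeps_partial_summary(self):
        ff = [footfall(t, x=t, label=PawLabel.LEFT_FRONT) for t in range(0, 20)]
        ff += [footfall(t, x=t, y=30, label=PawLabel.RIGHT_FRONT) for t in range(5, 25)]
        summary = summarize_gait(ff, GaitConfig())
        assert set(summary.per_paw) == {"Left-Front", "Right-Front"}
        assert summary.run_duration_s == pytest.approx(24 / 60)

    def test_position_table_covers_labelled_frames(self, clean_run, clean_run_config):
        from mousegait.pipeline import run_pipeline

        result = run_pipeline(clean_run.frames, clean_run_config)
        table = paw_position_table(result.footfalls)
        assert set(table.columns) == {"frame_index", "paw", "x", "y"}
        assert len(table) == sum(not f.excluded for f in result.footfalls)
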