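"""Phase detection, support classification, TUG sub-phases and stride length."""

import numpy as np
import pytest

from gaitsole import (
    GaitConfig,
    InsoleRecording,
    SegmentationConfig,
    SegmentationError,
    TrialMeta,
    TrialRecording,
    classify_support,
    detect_phases,
    estimate_stride_lengths,
    extract_cycles,
    preprocess_and_count,
    segment_tug,
    simulate_tug_trial,
)
from gaitsole.segmentation import GaitCycle, PhaseInterval

from conftest import noise_free
from helpers import (
    brute_force_counts,
    brute_force_debounce,
    brute_force_support,
    random_phase_tiling,
    transition_hit_fraction,
)


def rec_from_pressure(pressure, fs=100.0, side="left"):
    n = len(pressure)
    return InsoleRecording(side=side, fs=fs, pressure=np.asarray(pressure, float),
                           accel=np.zeros((n, 3)), gyro=np.zeros((n, 3)))


def phases_of(counts, fs=100.0, min_phase=0.0, side="left"):
    cfg = SegmentationConfig(min_phase_duration_s=min_phase)
    return detect_phases(np.asarray(counts), fs, cfg, side=side)


class TestActivationCounting:
    def test_threshold_is_inclusive(self):
        pressure = np.zeros((1, 8))
        pressure[0, 0] = 4.3
        rec = rec_from_pressure(pressure)
        cfg = SegmentationConfig(median_filter_width_samples=1)
        assert preprocess_and_count(rec, cfg).tolist() == [1]

    def test_all_zero_recording_counts_zero(self):
        rec = rec_from_pressure(np.zeros((50, 8)))
        assert np.all(preprocess_and_count(rec) == 0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_counts_match_brute_force_median_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pressure = rng.uniform(0, 10, size=(60, 8))
        rec = rec_from_pressure(pressure)
        cfg = SegmentationConfig(median_filter_width_samples=5)
        np.testing.assert_array_equal(
            preprocess_and_count(rec, cfg),
            brute_force_counts(pressure, 5, 4.3))

    def test_too_short_series_rejected(self):
        rec = rec_from_pressure(np.zeros((3, 8)))
        with pytest.raises(Exception):
            preprocess_and_count(rec, SegmentationConfig(median_filter_width_samples=5))


class TestPhaseDetection:
    def test_literal_partition_of_count_runs(self):
        phases = phases_of([0, 0, 2, 3, 3, 0, 0, 1, 1, 0])
        got = [(p.phase, p.start_idx, p.end_idx) for p in phases]
        assert got == [("swing", 0, 2), ("stance", 2, 5), ("swing", 5, 7),
                       ("stance", 7, 9), ("swing", 9, 10)]

    def test_all_zero_counts_single_swing(self):
        phases = phases_of([0] * 30)
        assert [(p.phase, p.start_idx, p.end_idx) for p in phases] == [("swing", 0, 30)]

    def test_single_sample_dropout_absorbed(self):
        phases = phases_of([3, 3, 0, 3, 3], min_phase=0.02)
        assert [(p.phase, p.start_idx, p.end_idx) for p in phases] == [("stance", 0, 5)]

    @pytest.mark.parametrize("seed", range(6))
    def test_debounce_matches_brute_force_merge(self, seed):
        rng = np.random.default_rng(seed)
        counts = (rng.random(200) < 0.5).astype(int) * rng.integers(1, 5, 200)
        phases = phases_of(counts, min_phase=0.05)
        oracle = brute_force_debounce(counts, 100.0, 0.05)
        got = [(p.start_idx, p.end_idx, p.phase == "stance") for p in phases]
        assert got == oracle

    def test_phases_alternate_and_tile(self):
        rng = np.random.default_rng(7)
        counts = (rng.random(500) < 0.6).astype(int)
        phases = phases_of(counts, min_phase=0.06)
        assert phases[0].start_idx == 0 and phases[-1].end_idx == 500
        for a, b in zip(phases[:-1], phases[1:]):
            assert a.end_idx == b.start_idx
            assert a.phase != b.phase


class TestSupportClassification:
    def tiling(self, spec, side, fs=100.0):
        return [PhaseInterval(side, ph, a, b, fs) for ph, a, b in spec]

    def test_overlapping_stances_give_double_support(self):
        left = self.tiling([("stance", 0, 10), ("swing", 10, 18)], "left")
        right = self.tiling([("swing", 0, 8), ("stance", 8, 18)], "right")
        got = [(s.kind, s.start_idx, s.end_idx) for s in classify_support(left, right)]
        assert got == [("single_left", 0, 8), ("double", 8, 10), ("single_right", 10, 18)]

    def test_identical_feet_give_double_and_none_only(self):
        spec = [("stance", 0, 10), ("swing", 10, 15), ("stance", 15, 25)]
        left = self.tiling(spec, "left")
        right = self.tiling(spec, "right")
        kinds = {s.kind for s in classify_support(left, right)}
        assert kinds == {"double", "none"}

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_per_frame_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(20, 120))
        left = random_phase_tiling(rng, "left", n)
        right = random_phase_tiling(rng, "right", n)
        got = [(s.kind, s.start_idx, s.end_idx) for s in classify_support(left, right)]
        assert got == brute_force_support(left, right)


class TestCycles:
    def test_cycle_from_definition(self):
        phases = [PhaseInterval("left", "stance", 0, 60, 100.0),
                  PhaseInterval("left", "swing", 60, 100, 100.0),
                  PhaseInterval("left", "stance", 100, 160, 100.0)]
        (c,) = extract_cycles(phases)
        assert (c.cycle_s, c.stance_s, c.swing_s) == (1.0, 0.6, 0.4)
        assert c.stance_s + c.swing_s == pytest.approx(c.cycle_s)

    def test_single_stance_yields_no_cycles(self):
        phases = [PhaseInterval("left", "stance", 0, 60, 100.0)]
        assert extract_cycles(phases) == []

    def test_noise_free_cycles_match_ground_truth(self, control_trial_noise_free, seg_cfg):
        trial, truth = control_trial_noise_free
        for side in ("left", "right"):
            counts = preprocess_and_count(getattr(trial, side), seg_cfg)
            phases = detect_phases(counts, trial.fs, seg_cfg, side=side)
            cycles = extract_cycles(phases)
            walk = [c for c in cycles
                    if c.start_idx >= truth.walking[0] * trial.fs - 1
                    and c.end_idx <= truth.walking[1] * trial.fs + 1]
            assert len(walk) == len(truth.cycles[side])
            for meas, true in zip(walk, truth.cycles[side]):
                assert meas.cycle_s == pytest.approx(true.cycle_s, abs=1.5 / trial.fs)
                assert meas.stance_s == pytest.approx(true.stance_s, abs=1.5 / trial.fs)
                assert meas.swing_s == pytest.approx(true.swing_s, abs=1.5 / trial.fs)


class TestTUGSegmentation:
    def test_all_sitting_trial_fails_segmentation(self, seg_cfg):
        rng = np.random.default_rng(0)
        n = 2000
        mk = lambda side: InsoleRecording(
            side=side, fs=100.0, pressure=np.abs(rng.normal(0, 0.5, (n, 8))),
            accel=rng.normal(0, 0.05, (n, 3)), gyro=rng.normal(0, 1, (n, 3)))
        trial = TrialRecording(mk("left"), mk("right"),
                               TrialMeta("S1", "control", "none"))
        counts_l = preprocess_and_count(trial.left, seg_cfg)
        counts_r = preprocess_and_count(trial.right, seg_cfg)
        pl = detect_phases(counts_l, 100.0, seg_cfg, side="left")
        pr = detect_phases(counts_r, 100.0, seg_cfg, side="right")
        with pytest.raises(SegmentationError):
            segment_tug(trial, pl, pr, seg_cfg)

    def test_noise_free_windows_match_truth(self, control_trial_noise_free, seg_cfg):
        trial, truth = control_trial_noise_free
        counts_l = preprocess_and_count(trial.left, seg_cfg)
        counts_r = preprocess_and_count(trial.right, seg_cfg)
        pl = detect_phases(counts_l, trial.fs, seg_cfg, side="left")
        pr = detect_phases(counts_r, trial.fs, seg_cfg, side="right")
        tug = segment_tug(trial, pl, pr, seg_cfg)
        assert tug.sit_to_stand[0] == pytest.approx(truth.sit_to_stand[0], abs=0.05)
        assert tug.sit_to_stand[1] == pytest.approx(truth.sit_to_stand[1], abs=0.05)
        assert tug.walking[0] == pytest.approx(truth.walking[0], abs=0.05)
        assert tug.walking[1] == pytest.approx(truth.walking[1], abs=0.05)
        assert tug.tug[0] == pytest.approx(truth.tug[0], abs=0.05)
        assert tug.tug[1] == pytest.approx(truth.tug[1], abs=0.05)

    def test_step_count_is_two_per_stride_pair(self, seg_cfg):
        cfg = noise_free(GaitConfig.symmetric, swing_mean_s=0.4,
                         double_support_s=0.1, n_strides_per_leg=6, turn_s=0.0)
        trial, truth = simulate_tug_trial(cfg, seed=5)
        counts_l = preprocess_and_count(trial.left, seg_cfg)
        counts_r = preprocess_and_count(trial.right, seg_cfg)
        pl = detect_phases(counts_l, trial.fs, seg_cfg, side="left")
        pr = detect_phases(counts_r, trial.fs, seg_cfg, side="right")
        tug = segment_tug(trial, pl, pr, seg_cfg)
        assert tug.step_count == 12 == truth.step_count

    def test_boundaries_within_filter_halfwidth_noise_free(
            self, control_trial_noise_free, seg_cfg):
        trial, truth = control_trial_noise_free
        phases = {}
        for side in ("left", "right"):
            counts = preprocess_and_count(getattr(trial, side), seg_cfg)
            phases[side] = detect_phases(counts, trial.fs, seg_cfg, side=side)
        tol = (seg_cfg.median_filter_width_samples // 2 + 1) / trial.fs
        hits, total = transition_hit_fraction(truth, phases, tol_s=tol)
        assert hits == total


class TestStrideLength:
    def cycle(self, start, end, stance_s, fs=100.0):
        swing = (end - start) / fs - stance_s
        return GaitCycle("left", start, end, stance_s, swing, (end - start) / fs)

    def test_zero_acceleration_gives_zero_strides(self):
        cycles = [self.cycle(0, 100, 0.6), self.cycle(100, 200, 0.6)]
        out = estimate_stride_lengths(np.zeros(250), cycles, 100.0)
        assert all(c.stride_length_m == pytest.approx(0.0, abs=1e-12) for c in out)

    def test_rectangular_pulse_closed_form(self):
        # +4 m/s^2 for 0.2 s then -4 for 0.2 s inside the swing: a*(T/2)^2 = 0.16 m
        fs = 100.0
        accel = np.zeros(300)
        accel[120:140] = 4.0
        accel[140:160] = -4.0
        cycles = [self.cycle(0, 200, 1.0)]  # stance [0,100), swing [100,200)
        (c,) = estimate_stride_lengths(accel, cycles, fs)
        assert c.stride_length_m == pytest.approx(0.16, abs=1e-3)

    def test_noise_free_simulated_stride_within_one_percent(self, seg_cfg):
        cfg = noise_free(GaitConfig.symmetric, swing_mean_s=0.4,
                         double_support_s=0.1, stride_length_mean_m=0.6,
                         stride_length_sd_m=0.0, n_strides_per_leg=8, turn_s=0.0)
        trial, truth = simulate_tug_trial(cfg, seed=6)
        counts = preprocess_and_count(trial.left, seg_cfg)
        phases = detect_phases(counts, trial.fs, seg_cfg, side="left")
        cycles = [c for c in extract_cycles(phases)
                  if c.start_idx >= truth.walking[0] * trial.fs - 1
                  and c.end_idx <= truth.walking[1] * trial.fs + 1]
        out = estimate_stride_lengths(trial.left.accel[:, 0], cycles, trial.fs)
        for c in out:
            assert c.stride_length_m == pytest.approx(0.6, rel=0.01)

    def test_cycle_beyond_series_is_bounds_error(self):
        with pytest.raises(Exception):
            estimate_stride_lengths(np.zeros(50), [self.cycle(0, 100, 0.6)], 100.0)


class TestMonotonicity:
    def test_longer_hemi_swing_increases_measured_swing(self, seg_cfg):
        measured = []
        for hemi_swing in (0.45, 0.55, 0.65):
            cfg = noise_free(GaitConfig.asymmetric, swing_sound_s=0.35,
                             swing_hemi_s=hemi_swing, affected_side="left",
                             double_support_s=0.15, n_strides_per_leg=8)
            meta = TrialMeta("P", "patient", "left")
            trial, _ = simulate_tug_trial(cfg, seed=8, meta=meta)
            counts = preprocess_and_count(trial.left, seg_cfg)
            phases = detect_phases(counts, trial.fs, seg_cfg, side="left")
            cycles = extract_cycles(phases)
            walk = [c for c in cycles if 0.2 < c.swing_s < 1.5]
            measured.append(np.mean([c.swing_s for c in walk]))
        assert measured[0] < measured[1] < measured[2]
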