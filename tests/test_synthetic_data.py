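"""Timeline construction, signal synthesis and cohort generation contracts."""

import numpy as np
import pytest

from gaitsole import (
    CohortConfig,
    ConfigError,
    GaitConfig,
    ScoreModel,
    build_gait_timeline,
    default_control_config,
    simulate_cohort,
    simulate_tug_trial,
    truth_parameter_set,
)
from gaitsole.cohort_stats import correlate
from gaitsole.synthetic_data import sigma_for_target_r2

from conftest import noise_free


def rigid_config(**kw):
    """Deterministic symmetric gait: stance 0.6, swing 0.4, overlap 0.1."""
    kw.setdefault("n_strides_per_leg", 6)
    kw.setdefault("turn_s", 0.0)
    return GaitConfig.symmetric(swing_mean_s=0.4, swing_sd_s=0.0,
                                double_support_s=0.1, **kw)


class TestTimeline:
    def test_deterministic_symmetric_cycles_are_exact(self):
        _, _, truth = build_gait_timeline(rigid_config(), np.random.default_rng(0))
        for side in ("left", "right"):
            for c in truth.cycles[side]:
                assert c.cycle_s == pytest.approx(1.0, abs=1e-12)
                assert c.stance_s == pytest.approx(0.6, abs=1e-12)
                assert c.swing_s == pytest.approx(0.4, abs=1e-12)

    def test_double_support_fraction_matches_construction(self):
        # two 0.1 s overlaps per 1.0 s cycle -> double support is 0.2 of the cycle
        _, _, truth = build_gait_timeline(rigid_config(), np.random.default_rng(0))
        p = truth_parameter_set(truth)
        assert p.double_support_mean_s == pytest.approx(0.1, abs=1e-9)
        assert p.double_support_mean_pct == pytest.approx(0.1, abs=1e-9)
        assert p.single_support_mean_s == pytest.approx(0.4, abs=1e-9)

    @pytest.mark.parametrize("seed", range(8))
    def test_truth_intervals_disjoint_and_alternating(self, seed):
        rng = np.random.default_rng(seed)
        cfg = GaitConfig.symmetric(
            swing_mean_s=float(rng.uniform(0.25, 0.6)),
            swing_sd_s=float(rng.uniform(0, 0.05)),
            double_support_s=float(rng.uniform(0.05, 0.1)),
            n_strides_per_leg=int(rng.integers(3, 10)))
        left, right, truth = build_gait_timeline(cfg, rng)
        for ivals in (left, right):
            # brute-force scan over all interval pairs
            for i in range(len(ivals)):
                for j in range(i + 1, len(ivals)):
                    a, b = sorted([ivals[i], ivals[j]])
                    assert a[1] <= b[0], "stance intervals overlap"
        # walking window never has both feet airborne
        w0, w1 = truth.walking
        grid = np.arange(w0, w1, 0.005)
        in_stance = lambda ivals, t: any(a <= t < b for a, b in ivals)
        for t in grid:
            assert in_stance(left, t) or in_stance(right, t)

    def test_negative_single_support_is_config_error(self):
        with pytest.raises(ConfigError, match="stance"):
            GaitConfig(stance_mean_left_s=0.2, stance_mean_right_s=0.2,
                       double_support_target_s=0.25)

    def test_inconsistent_stance_swing_pair_rejected(self):
        with pytest.raises(ConfigError, match="inconsistent"):
            GaitConfig(swing_mean_left_s=0.4, swing_mean_right_s=0.4,
                       stance_mean_right_s=0.55, double_support_target_s=0.1)

    def test_stance_spec_derives_swing(self):
        cfg = GaitConfig(stance_mean_left_s=0.6, stance_mean_right_s=0.6,
                         double_support_target_s=0.1)
        assert cfg.swing_mean_left_s == pytest.approx(0.4)
        assert cfg.cycle_mean_s == pytest.approx(1.0)


class TestSignals:
    def test_noise_free_activation_is_frame_perfect(self, control_trial_noise_free):
        trial, truth = control_trial_noise_free
        fs = trial.fs
        for side in ("left", "right"):
            rec = getattr(trial, side)
            active = (rec.pressure >= 4.3).any(axis=1)
            expected = np.zeros(rec.n_samples, dtype=bool)
            for a, b in truth.stance_intervals[side]:
                ia = int(np.ceil(a * fs - 1e-9))
                ib = int(np.ceil(b * fs - 1e-9))
                expected[ia:ib] = True
            assert np.array_equal(active, expected)

    def test_swing_velocity_integrates_to_stride_length(self):
        cfg = noise_free(GaitConfig.symmetric, swing_mean_s=0.4,
                         double_support_s=0.1, stride_length_mean_m=0.6,
                         stride_length_sd_m=0.0, n_strides_per_leg=6, turn_s=0.0)
        trial, truth = simulate_tug_trial(cfg, seed=3)
        fs = trial.fs
        for side in ("left", "right"):
            accel = getattr(trial, side).accel[:, 0]
            vel = np.concatenate(([0.0], np.cumsum((accel[1:] + accel[:-1]) / 2 / fs)))
            for t_off, land in zip(truth.toeoffs[side], truth.onsets[side]):
                ia, ib = int(np.ceil(t_off * fs)), int(np.ceil(land * fs))
                disp = np.trapezoid(vel[ia:ib], dx=1 / fs)
                assert disp == pytest.approx(0.600, abs=1e-3)

    def test_swing_noise_rarely_activates(self):
        # Monte-Carlo of the folded-normal tail at the default noise SD
        rng = np.random.default_rng(99)
        frames = np.abs(rng.normal(0, 0.5, size=(10**5, 8)))
        frac = np.mean((frames >= 4.3).any(axis=1))
        assert frac < 1e-4

    def test_trial_duration_matches_segment_budget(self):
        cfg = rigid_config(sit_s=2.0, sit_to_stand_s=3.0, turn_s=2.0,
                           stand_to_sit_s=2.0)
        trial, truth = simulate_tug_trial(cfg, seed=0)
        assert 14.0 <= truth.duration_s <= 16.0
        assert truth.sit_to_stand == (2.0, 5.0)
        assert truth.tug[0] == 2.0

    def test_seed_determinism(self):
        cfg = default_control_config()
        t1, _ = simulate_tug_trial(cfg, seed=42)
        t2, _ = simulate_tug_trial(cfg, seed=42)
        t3, _ = simulate_tug_trial(cfg, seed=43)
        assert np.array_equal(t1.left.pressure, t2.left.pressure)
        assert np.array_equal(t1.right.accel, t2.right.accel)
        assert not np.array_equal(t1.left.pressure, t3.left.pressure)


class TestCohort:
    def test_degenerate_score_model_is_constant(self):
        cc = CohortConfig(n_patients=4, n_controls=2,
                          score_models={"fma_lex": ScoreModel(a=20.0, b=0.0, sigma=0.0)})
        _, records, _ = simulate_cohort(cc, seed=1)
        for r in records:
            if r.group == "patient":
                assert r.scores.fma_lex == pytest.approx(20.0, abs=1e-12)

    def test_noise_free_scores_lie_on_the_line(self):
        cc = CohortConfig(n_patients=8, n_controls=2,
                          score_models={"fma_lex": ScoreModel(a=26.39, b=-38.64, sigma=0.0)})
        _, records, _ = simulate_cohort(cc, seed=2)
        patients = [r for r in records if r.group == "patient"]
        x = [r.params.diff_stance_pct for r in patients]
        y = [r.scores.fma_lex for r in patients]
        res = correlate(x, y)
        assert res.r_squared == pytest.approx(1.0, abs=1e-12)
        assert res.slope == pytest.approx(-38.64, abs=1e-9)
        assert res.intercept == pytest.approx(26.39, abs=1e-9)

    def test_patient_asymmetry_structure(self):
        _, records, _ = simulate_cohort(CohortConfig(n_patients=8, n_controls=2), seed=3)
        for r in records:
            if r.group == "patient":
                assert r.params.stance_sound_mean_s > r.params.stance_hemi_mean_s
                assert r.params.swing_hemi_mean_s > r.params.swing_sound_mean_s

    def test_control_true_asymmetry_within_sampling_bound(self):
        # per-subject true diff ~ |N(0, sd*sqrt(2/n))|; check a generous 5-sigma cap
        cc = CohortConfig(n_patients=2, n_controls=20)
        _, records, _ = simulate_cohort(cc, seed=4)
        controls = [r for r in records if r.group == "control"]
        sd = cc.control_base.swing_sd_left_s
        diffs, bounds = [], []
        for r in controls:
            n_cycles = 2 * 3.0 / r.params.stride_length_m  # ~strides per leg
            bound = sd * np.sqrt(2.0 / max(n_cycles, 1))
            diffs.append(r.params.diff_swing_s)
            bounds.append(bound)
        within3 = np.mean([d <= 3 * b for d, b in zip(diffs, bounds)])
        assert within3 >= 0.85
        assert all(d <= 5 * b for d, b in zip(diffs, bounds))

    def test_small_groups_rejected(self):
        with pytest.raises(ConfigError):
            CohortConfig(n_patients=1, n_controls=10)

    def test_sigma_for_target_r2_hits_target_on_average(self):
        cc = CohortConfig(n_patients=10, n_controls=2)
        sigma = sigma_for_target_r2(cc, b=-38.64, target_r2=0.6)
        r2s = []
        for seed in range(40):
            cc_i = CohortConfig(
                n_patients=10, n_controls=2,
                score_models={"fma_lex": ScoreModel(a=26.39, b=-38.64, sigma=sigma)})
            _, records, _ = simulate_cohort(cc_i, seed=seed)
            pats = [r for r in records if r.group == "patient"]
            res = correlate([r.params.diff_stance_pct for r in pats],
                            [r.scores.fma_lex for r in pats])
            r2s.append(res.r_squared)
        assert abs(np.mean(r2s) - 0.6) < 0.12
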