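import numpy as np
import pytest
from scipy.stats import binomtest

from connmanifold.behavior import (
    FLAG_CURSOR_JUMP,
    FLAG_KEPT,
    FLAG_SLOW,
    FLAG_TIMEOUT,
    LearningCurve,
    TaskGeometry,
    Trajectory,
    TrialSet,
    TrialTimeoutError,
    bin_scores,
    compute_scores,
    filter_trials,
    learning_scores,
    path_variability,
    score_trajectory,
    simulate_learner,
    trial_kinematics,
)
from connmanifold.io import ValidationError
from connmanifold.synth import SyntheticStudyConfig, make_learning_curves

GEOM = TaskGeometry()


def sine_trajectory(amplitude, geom=GEOM, n=631, duration=1.0, t0=0.0):
    """Constant-velocity trace x = a sin(pi y / D), passing exactly through
    the scoring offsets (n chosen so the grid contains multiples of D/6)."""
    y = np.linspace(0.0, 1.05 * geom.target_distance, n)
    t = t0 + np.linspace(0.0, duration, n)
    x = amplitude * np.sin(np.pi * np.clip(y, 0, geom.target_distance) / geom.target_distance)
    return Trajectory(t=t, x=x, y=y, trial=0)


class TestScoreTrajectory:
    def test_visible_path_scores_forty(self):
        traj = sine_trajectory(GEOM.visible_amplitude)
        assert score_trajectory(traj) == pytest.approx(40.0, abs=1e-6)

    def test_reward_path_scores_hundred(self):
        traj = sine_trajectory(-GEOM.visible_amplitude)
        assert score_trajectory(traj) == pytest.approx(100.0, abs=1e-6)

    def test_straight_line_scores_seventy(self):
        # closed form: E/N = 0.15/0.5, score = 100 * (1 - 0.3)
        traj = sine_trajectory(0.0)
        assert score_trajectory(traj) == pytest.approx(70.0, abs=1e-6)

    def test_scores_clipped_to_range(self):
        far = sine_trajectory(5 * GEOM.target_distance)
        assert score_trajectory(far) == 0.0
        assert 0.0 <= score_trajectory(sine_trajectory(-10.0)) <= 100.0

    def test_mirror_symmetry(self, rng):
        for a in rng.uniform(-30, 30, 5):
            traj = sine_trajectory(a)
            mirrored = Trajectory(t=traj.t, x=-traj.x, y=traj.y)
            assert score_trajectory(mirrored, GEOM.mirrored()) == pytest.approx(
                score_trajectory(traj, GEOM), abs=1e-9
            )

    def test_monotone_in_distance_from_reward_amplitude(self):
        """For pure sine traces, the score strictly decreases as the amplitude
        moves away from the rewarded one, until clipping at 0."""
        reward_a = -GEOM.visible_amplitude
        offsets = np.array([0.0, 2.0, 5.0, 9.0, 18.0, 25.0])
        scores = [score_trajectory(sine_trajectory(reward_a + o)) for o in offsets]
        assert all(s1 > s2 for s1, s2 in zip(scores, scores[1:]) if s1 > 0)
        down = [score_trajectory(sine_trajectory(reward_a - o)) for o in offsets]
        assert all(s1 > s2 for s1, s2 in zip(down, down[1:]) if s1 > 0)

    def test_incomplete_trajectory_is_timeout(self):
        y = np.linspace(0, 30, 50)
        traj = Trajectory(t=np.linspace(0, 1, 50), x=np.zeros(50), y=y)
        with pytest.raises(TrialTimeoutError):
            score_trajectory(traj)


class TestKinematics:
    def test_constant_velocity_split(self):
        # cover D in exactly 1 s: RT = 0.1 s (10% of distance), MT = 0.9 s
        y = np.linspace(0, GEOM.target_distance, 1001)
        traj = Trajectory(t=np.linspace(0, 1, 1001), x=np.zeros(1001), y=y)
        rt, mt = trial_kinematics(traj)
        assert rt == pytest.approx(0.1, abs=1e-9)
        assert mt == pytest.approx(0.9, abs=1e-9)

    def test_rt_plus_mt_is_time_to_target(self, rng):
        for seed in range(5):
            r = np.random.default_rng(seed)
            y = np.cumsum(r.uniform(0.0, 1.0, 400))
            y = y / y[-1] * 70.0
            y += np.arange(400) * 1e-9  # strictly increasing
            t = np.linspace(0, 2, 400)
            traj = Trajectory(t=t, x=r.standard_normal(400), y=y)
            rt, mt = trial_kinematics(traj)
            # brute-force first-crossing scan
            def cross(level):
                for i in range(1, 400):
                    if y[i] >= level and y[i - 1] < level:
                        f = (level - y[i - 1]) / (y[i] - y[i - 1])
                        return t[i - 1] + f * (t[i] - t[i - 1])
                raise AssertionError
            assert rt == pytest.approx(cross(6.0), abs=1e-12)
            assert rt + mt == pytest.approx(cross(60.0), abs=1e-12)


class TestFilterTrials:
    def _valid_set(self, n):
        return TrialSet(trajectories=[
            sine_trajectory(0.0, duration=1.0 + 0.001 * i) for i in range(n)
        ])

    def test_all_valid_set_keeps_everything_except_slow_trim(self):
        out = filter_trials(self._valid_set(100))
        # ceil(0.0005 * 100) = 1 slowest by MT and by RT (may coincide)
        assert out.flags.count(FLAG_SLOW) in (1, 2)
        assert out.flags.count(FLAG_TIMEOUT) == 0

    def test_sentinel_sample_flags_cursor_jump(self):
        traj = sine_trajectory(0.0)
        x, y = traj.x.copy(), traj.y.copy()
        x[10], y[10] = GEOM.sentinel  # mid-flight device dropout; path resumes after
        jumped = Trajectory(t=traj.t, x=x, y=y)
        ts = TrialSet(trajectories=[jumped, sine_trajectory(0.0)])
        out = filter_trials(ts)
        assert out.flags[0] == FLAG_CURSOR_JUMP

    def test_slow_trim_count_is_ceil_of_fraction(self):
        n = 2000
        ts = self._valid_set(n)
        out = filter_trials(ts)
        # exactly ceil(0.0005*2000) = 1 slowest-MT trial; RT identical for all
        slow = [i for i, f in enumerate(out.flags) if f == FLAG_SLOW]
        assert len(slow) <= 2 and out.flags[n - 1] == FLAG_SLOW

    def test_late_arrival_flagged_timeout(self):
        slow = sine_trajectory(0.0, duration=5.0)  # crosses D after 4.5 s
        out = filter_trials(TrialSet(trajectories=[slow, sine_trajectory(0.0)]))
        assert out.flags[0] == FLAG_TIMEOUT


class TestPathVariability:
    def test_identical_trajectories_give_zero(self):
        ts = TrialSet(trajectories=[sine_trajectory(5.0) for _ in range(10)])
        assert np.allclose(path_variability(ts), 0.0)

    def test_single_trial_is_zero(self):
        ts = TrialSet(trajectories=[sine_trajectory(5.0)])
        assert path_variability(ts).tolist() == [0.0]

    def test_matches_brute_force_double_loop(self, rng):
        trajs = [sine_trajectory(a) for a in rng.uniform(-10, 10, 20)]
        ts = TrialSet(trajectories=trajs)
        got = path_variability(ts)
        from connmanifold.behavior import resample_paths

        X = resample_paths(ts)
        expected = np.empty(20)
        for t in range(20):
            window = [i for i in range(max(0, t - 3), min(20, t + 4))]
            xbar = sum(X[i] for i in window) / len(window)
            expected[t] = sum(abs(X[t, k] - xbar[k]) for k in range(10)) / 10
        assert np.allclose(got, expected)


class TestLearningScores:
    def test_noiseless_single_mode_recovery(self, rng):
        t = np.arange(25.0)
        mode = 1 - np.exp(-t / 6.0)
        a = rng.normal(0, 5, 12)
        curves = [
            LearningCurve(np.clip(40 + 20 * mode + ai * mode, 0, 100), f"s{i}")
            for i, ai in enumerate(a)
        ]
        scores, _ = learning_scores(curves)
        s = np.array([x.score for x in scores])
        assert scores[0].variance_explained > 0.99
        assert abs(np.corrcoef(s, a)[0, 1]) > 0.999

    def test_fast_learner_has_positive_score(self):
        t = np.arange(25.0)
        mode = 1 - np.exp(-t / 6.0)
        curves = [
            LearningCurve(np.clip(40 + (15 if i < 4 else -5) * mode, 0, 100), f"s{i}")
            for i in range(8)
        ]
        # add a distinguishable fast learner and tiny jitter to avoid degeneracy
        scores, _ = learning_scores(curves)
        by_subject = {s.subject: s.score for s in scores}
        assert by_subject["s0"] > 0
        assert by_subject["s7"] < 0

    def test_identical_curves_rejected(self):
        curves = [LearningCurve(np.full(25, 50.0), f"s{i}") for i in range(5)]
        with pytest.raises(ValidationError, match="identical"):
            learning_scores(curves)

    def test_generator_aptitude_recovery(self):
        """fPCA scores recover the generator's ground-truth aptitude on a
        default-size draw (36 subjects, 200 trials, default noise)."""
        cfg = SyntheticStudyConfig(seed=11)
        raw, aptitude = make_learning_curves(cfg)
        curves = [LearningCurve(bin_scores(raw[i]), f"s{i}") for i in range(cfg.n_subjects)]
        scores, _ = learning_scores(curves)
        s = np.array([x.score for x in scores])
        assert np.corrcoef(s, aptitude)[0, 1] > 0.9


class TestBinScores:
    def test_bins_average_eight_trials(self):
        scores = np.arange(16.0)
        assert bin_scores(scores).tolist() == [3.5, 11.5]

    def test_excluded_trials_skipped(self):
        scores = np.arange(16.0)
        kept = np.ones(16, bool)
        kept[0] = False
        assert bin_scores(scores, kept)[0] == pytest.approx(np.arange(1.0, 8.0).mean())


class TestSimulateLearner:
    def test_zero_aptitude_stays_near_visible_path(self):
        ts = simulate_learner(aptitude=0.0, exploration_sd=1.0, n_trials=60, seed=3)
        kept = np.isfinite(ts.scores)
        assert abs(np.nanmean(ts.scores) - 40.0) < 8.0

    def test_same_seed_reproduces_trialset(self):
        a = simulate_learner(aptitude=0.6, n_trials=30, seed=9)
        b = simulate_learner(aptitude=0.6, n_trials=30, seed=9)
        assert np.array_equal(a.scores, b.scores)
        assert np.array_equal(a.trajectories[-1].x, b.trajectories[-1].x)

    def test_high_aptitude_learns_across_seeds(self):
        wins = 0
        for seed in range(10):
            ts = simulate_learner(aptitude=0.9, exploration_sd=2.0, n_trials=200, seed=seed)
            wins += np.nanmean(ts.scores[-20:]) > np.nanmean(ts.scores[:20])
        assert binomtest(wins, 10, alternative="greater").pvalue < 0.05
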