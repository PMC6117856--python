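import numpy as np
import pytest

from conftest import build_record
from ticlab.analytics import (
    MIN_FANO_EVENTS,
    benjamini_hochberg,
    compute_metrics,
    fano_curve,
    reward_timing_test,
    reward_timing_test_arrays,
)
from ticlab.simulator import TicProcessParams, simulate_tic_stream


# ---------------------------------------------------------------------------
# independent oracle: greedy per-window scan over tic-free segments


def oracle_metrics(tic_times, duration, window):
    bounds = [0.0] + sorted(tic_times) + [duration]
    segments = [b - a for a, b in zip(bounds, bounds[1:])]
    longest = max(segments)
    n_windows = 0
    for seg in segments:
        t = 0.0
        while t + window <= seg + 1e-9:
            n_windows += 1
            t += window
    return longest, n_windows


class TestComputeMetrics:
    def test_sixty_second_session_two_tics(self):
        # oracle: segments 20/20/20 -> longest 20, two disjoint 10-s windows
        # per segment, six in total
        rec = build_record(tic_times_s=[20, 40], duration_s=60)
        m = compute_metrics(rec)
        longest, n_windows = oracle_metrics([20, 40], 60, 10)
        assert m.longest_tic_free_s == longest == 20
        assert m.n_tic_free_windows == n_windows == 6
        assert m.mean_tic_frequency == pytest.approx(2.0)
        assert m.iti_list == (20.0,)

    def test_no_tics(self):
        rec = build_record(duration_s=60)
        m = compute_metrics(rec)
        assert m.longest_tic_free_s == 60
        assert m.n_tic_free_windows == 6
        assert m.mean_tic_frequency == 0
        assert m.personal_record_s == 60

    def test_tic_every_second(self):
        rec = build_record(tic_times_s=list(range(1, 60)), duration_s=60)
        m = compute_metrics(rec)
        assert m.n_tic_free_windows == 0
        assert m.longest_tic_free_s == pytest.approx(1.0)

    def test_reward_count(self):
        rec = build_record(reward_times_s=[1, 2, 3], duration_s=30)
        assert compute_metrics(rec).reward_count == 3

    def test_zero_duration_rejected(self):
        rec = build_record(duration_s=10)
        rec.end_ms = rec.start_ms
        with pytest.raises(ValueError):
            compute_metrics(rec)

    def test_open_record_rejected(self):
        rec = build_record(duration_s=10)
        rec.end_ms = None
        with pytest.raises(ValueError):
            compute_metrics(rec)

    def test_agrees_with_oracle_on_random_logs(self, rng):
        for _ in range(300):
            duration = float(rng.uniform(20, 200))
            tics = np.sort(rng.uniform(0.001, duration - 0.001, int(rng.integers(0, 30))))
            window = float(rng.choice([5.0, 10.0, 15.0]))
            rec = build_record(tic_times_s=tics, duration_s=duration)
            m = compute_metrics(rec, window_s=window)
            # re-read quantized times from the record so oracle and
            # implementation see the identical stream
            quantized = [(ev.timestamp_ms - rec.start_ms) / 1000.0
                         for ev in rec.events if ev.kind == "tic"]
            longest, n_windows = oracle_metrics(quantized, (rec.end_ms - rec.start_ms) / 1000.0, window)
            assert m.longest_tic_free_s == pytest.approx(longest)
            assert m.n_tic_free_windows == n_windows
            assert m.mean_tic_frequency == pytest.approx(60 * len(quantized) / m.duration_s)

    def test_invariants_hold(self, rng):
        for _ in range(50):
            duration = float(rng.uniform(20, 120))
            tics = np.sort(rng.uniform(0, duration, int(rng.integers(0, 15))))
            m = compute_metrics(build_record(tic_times_s=tics, duration_s=duration))
            assert m.longest_tic_free_s <= m.duration_s + 1e-9
            assert m.n_tic_free_windows <= int(m.duration_s / m.window_s) + 1


class TestFanoCurve:
    WINDOWS = (2.0, 5.0, 10.0, 20.0, 40.0)

    def test_poisson_fano_near_one_and_ci_covers_zero(self):
        # homogeneous Poisson: Fano ~ 1 at every scale, slope ~ 0
        covered = 0
        in_band = 0
        runs = 60
        for seed in range(runs):
            times = simulate_tic_stream(
                TicProcessParams(baseline_rate=12.0, duration_s=3600, seed=seed)
            )
            res = fano_curve(times, 3600, self.WINDOWS, n_surrogates=0, n_bootstrap=100,
                            rng=np.random.default_rng(seed))
            assert res.ok
            if all(0.7 <= f <= 1.3 for f in res.fano_factors):
                in_band += 1
            if res.slope_ci[0] <= 0 <= res.slope_ci[1]:
                covered += 1
        assert in_band >= 0.9 * runs
        assert covered >= 0.9 * runs

    def test_pareto_positive_control_slope_positive(self):
        # heavy-tailed renewal ITIs: Fano grows with window size, so the
        # slope CI should sit above zero in most runs
        positive = 0
        runs = 50
        for seed in range(runs):
            times = simulate_tic_stream(
                TicProcessParams(baseline_rate=12.0, duration_s=3600, seed=seed,
                                 process_kind="pareto_renewal", pareto_alpha=1.5)
            )
            res = fano_curve(times, 3600, self.WINDOWS, n_surrogates=0, n_bootstrap=100,
                            rng=np.random.default_rng(seed))
            if res.ok and res.slope_ci[0] > 0:
                positive += 1
        assert positive >= 0.8 * runs

    def test_insufficient_events(self, rng):
        res = fano_curve([1, 2, 3, 4, 5], 100, self.WINDOWS, rng=rng)
        assert not res.ok
        assert "insufficient events" in res.reason
        assert np.isnan(res.loglog_slope)

    def test_window_too_large(self, rng):
        times = np.linspace(1, 99, MIN_FANO_EVENTS)
        res = fano_curve(times, 100, (5, 10, 20, 80), rng=rng)
        assert not res.ok

    def test_surrogate_p_defined(self, rng):
        times = simulate_tic_stream(TicProcessParams(baseline_rate=12, duration_s=1200, seed=1))
        res = fano_curve(times, 1200, self.WINDOWS, n_surrogates=99, n_bootstrap=50, rng=rng)
        assert res.ok
        assert 0 < res.surrogate_p <= 1


class TestRewardTiming:
    def test_constructed_dependence_detected(self, rng):
        # every tic lands exactly 2 s after a reward: the [0,5) bin rate must
        # dwarf the session mean with p <= 0.01
        rewards = np.arange(10, 590, 20.0)
        tics = rewards + 2.0
        res = reward_timing_test_arrays(tics, rewards, 600.0,
                                        lag_bins=(0, 5, 10, 20),
                                        n_permutations=999, rng=rng)
        assert res.conditional_tic_rate[0] > 3 * res.session_mean_rate
        assert res.permutation_p[0] <= 0.01
        assert res.bh_reject[0]

    def test_zero_rewards_error(self, rng):
        with pytest.raises(ValueError, match="no reward"):
            reward_timing_test_arrays([1.0, 2.0], [], 60.0, rng=rng)

    def test_zero_tics_error(self, rng):
        with pytest.raises(ValueError, match="no tic"):
            reward_timing_test_arrays([], [1.0], 60.0, rng=rng)

    def test_record_wrapper(self, rng):
        rec = build_record(tic_times_s=[12, 30, 44], reward_times_s=[10, 28, 42],
                           duration_s=60)
        res = reward_timing_test(rec, lag_bins=(0, 5, 10), n_permutations=99, rng=rng)
        assert sum(res.tic_counts) == 3

    def test_null_rejection_rate_near_alpha(self):
        # scaled-down calibration; the full 1000-simulation check lives in
        # the acceptance suite
        rejections = 0
        sims = 200
        for seed in range(sims):
            g = np.random.default_rng(seed)
            tics = np.sort(g.uniform(0, 600, 60))
            rewards = np.arange(5, 600, 10.0)
            res = reward_timing_test_arrays(tics, rewards, 600.0, lag_bins=(0, 5),
                                            n_permutations=199, rng=g)
            if res.permutation_p[0] <= 0.05:
                rejections += 1
        assert 0.015 <= rejections / sims <= 0.095

    def test_occupancy_sums_to_duration(self, rng):
        rewards = np.sort(rng.uniform(0, 600, 30))
        res = reward_timing_test_arrays(rng.uniform(0, 600, 50), rewards, 600.0,
                                        lag_bins=(0, 5, 10, 1000), n_permutations=9, rng=rng)
        # lag bins spanning [0, >max gap) capture all post-first-reward time
        assert sum(res.occupancy_s) == pytest.approx(600.0 - rewards[0])


class TestBenjaminiHochberg:
    def test_all_large_p_none_rejected(self):
        assert not benjamini_hochberg([0.5, 0.9, 0.7]).any()

    def test_small_p_rejected(self):
        reject = benjamini_hochberg([0.001, 0.9, 0.002, 0.8])
        assert list(reject) == [True, False, True, False]

    def test_step_up_property(self):
        # classic BH example: with m=4 and alpha=.05, p=(.01,.02,.03,.04)
        # all pass because p_(4)=.04 <= .05
        assert benjamini_hochberg([0.01, 0.02, 0.03, 0.04]).all()
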