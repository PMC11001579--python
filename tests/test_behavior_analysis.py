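"""Press-table construction, filtered reward ratio, and conditional outcome analyses."""

import numpy as np
import pandas as pd
import pytest

from neuroforage.behavior_analysis import (
    WAIT_CATEGORY_PRESET,
    HalfGaussianFilter,
    _filtered_reward_ratio,
    bin_and_correlate,
    build_press_table,
    conditional_wait_analysis,
    switch_probability,
    tune_filter_width,
)
from neuroforage.foraging_agents import ThresholdAgentParams, run_threshold_agent
from neuroforage.task_model import BehavioralSession, VISchedule, prob_reward_available


def _session(times, boxes, rewarded, pairs=((20, 20),), blocks=None):
    times = np.asarray(times, float)
    n = len(times)
    return BehavioralSession(
        times=times, boxes=np.asarray(boxes, int),
        rewarded=np.asarray(rewarded, bool),
        block_index=np.zeros(n, int) if blocks is None else np.asarray(blocks),
        schedule=VISchedule.from_pairs(pairs))


class TestHalfGaussianFilter:
    def test_weights_causal_normalized(self):
        w = HalfGaussianFilter(2.0).weights(6)
        assert np.all(w >= 0)
        assert w.sum() == pytest.approx(1.0)
        assert np.all(np.diff(w) <= 0)  # most recent press weighted most

    def test_positive_width_required(self):
        with pytest.raises(ValueError):
            HalfGaussianFilter(0.0)

    def test_worked_example_matches_direct_weighted_sum(self):
        """5-press example, width=2 presses, computed by an explicit oracle."""
        boxes = np.array([1, 2, 1, 1, 2])
        rew = np.array([1, 1, 0, 1, 0], bool)
        got = _filtered_reward_ratio(boxes, rew, HalfGaussianFilter(2.0))
        w = lambda lag: np.exp(-((lag - 1) ** 2) / (2 * 2.0**2))
        # press 3 (box 1): history presses 0..2 at lags 3,2,1
        den = w(3) * 1 + w(2) * 1 + w(1) * 0
        num = w(3) * 1 + w(1) * 0  # rewards on box 1
        assert got[3] == pytest.approx(num / den)
        # press 4 (box 2): lags 4..1 over presses 0..3
        den4 = w(4) * 1 + w(3) * 1 + w(2) * 0 + w(1) * 1
        num4 = w(3) * 1  # box-2 rewards in history
        assert got[4] == pytest.approx(num4 / den4)

    def test_all_rewards_on_own_box_gives_one(self):
        boxes = np.ones(6, int)
        rew = np.ones(6, bool)
        got = _filtered_reward_ratio(boxes, rew, HalfGaussianFilter(3.0))
        assert np.allclose(got[1:], 1.0)

    def test_no_history_defaults_to_half(self):
        got = _filtered_reward_ratio(np.array([1, 2]), np.array([False, False]),
                                     HalfGaussianFilter(2.0))
        assert np.allclose(got, 0.5)

    def test_alternating_rewards_wide_filter_near_half(self):
        boxes = np.tile([1, 2], 40)
        rew = np.ones(80, bool)
        got = _filtered_reward_ratio(boxes, rew, HalfGaussianFilter(25.0))
        assert np.all(np.abs(got[40:] - 0.5) < 0.05)


class TestPressTable:
    def test_columns_and_exclusions(self):
        sess = _session([5, 10, 80, 85, 90], [1, 1, 2, 2, 1],
                        [1, 0, 1, 0, 1])
        tab = build_press_table(sess, 2.0)
        # first press (undefined wait) and the 70 s wait are excluded
        assert list(tab["time_s"]) == [10.0, 85.0, 90.0]
        assert list(tab["waiting_time"]) == [5.0, 5.0, 5.0]
        assert tab.iloc[0]["choice"] == "switch"  # next press is box 2
        assert tab.iloc[1]["choice"] == "switch"  # box 2 -> box 1

    def test_prob_avail_uses_same_box_gap(self):
        sess = _session([5, 10, 18], [1, 2, 1], [0, 0, 0])
        tab = build_press_table(sess, 2.0, drop_excluded=False)
        # third press: box 1 last pressed at t=5 -> gap 13 s
        assert tab.iloc[2]["prob_avail"] == pytest.approx(
            prob_reward_available(13.0, 20.0, 0.01))

    def test_requires_two_presses(self):
        with pytest.raises(ValueError):
            build_press_table(_session([1.0], [1], [True]), 2.0)


class TestTuneFilterWidth:
    def test_single_candidate_returned(self, mvt_session):
        assert tune_filter_width(mvt_session, [4]) == 4.0

    def test_constant_scheduled_ratio_errors(self):
        sess = _session(np.arange(1, 240, 2.0), [1, 2] * 60, [1, 0] * 60)
        with pytest.raises(ValueError):
            tune_filter_width(sess, [2, 5])

    def test_returns_a_candidate(self, mvt_session):
        got = tune_filter_width(mvt_session, [2, 8, 30])
        assert got in (2.0, 8.0, 30.0)


class TestBinAndCorrelate:
    def test_perfect_predictor(self, mvt_session):
        tab = build_press_table(mvt_session, 5.0)
        tab = tab.assign(oracle=tab["rewarded"].astype(float))
        stat = bin_and_correlate(tab, "oracle")
        assert stat.pearson_r == pytest.approx(1.0)
        assert np.all(stat.bin_sizes[:-1] == 50)

    def test_permuted_predictor_near_zero(self, mvt_session):
        tab = build_press_table(mvt_session, 5.0)
        rng = np.random.default_rng(0)
        tab = tab.assign(noise=rng.permutation(tab["waiting_time"].to_numpy()))
        stat = bin_and_correlate(tab, "noise")
        assert abs(stat.pearson_r) < 0.6  # ~10 bins; null sd is large

    def test_sort_invariance(self, mvt_session):
        tab = build_press_table(mvt_session, 5.0)
        shuffled = tab.sample(frac=1.0, random_state=1).reset_index(drop=True)
        a = bin_and_correlate(tab, "waiting_time").pearson_r
        b = bin_and_correlate(shuffled, "waiting_time").pearson_r
        assert a == pytest.approx(b)

    def test_too_few_presses(self):
        sess = _session(np.arange(1, 60, 2.0), [1, 2] * 15, [1, 0] * 15)
        with pytest.raises(ValueError):
            bin_and_correlate(build_press_table(sess, 2.0), "waiting_time")


class TestConditionalAnalyses:
    def test_identical_distributions_give_chance_auc(self):
        n = 240
        rng = np.random.default_rng(1)
        waits = np.tile([4.0, 6.0, 10.0], n // 3)
        times = np.cumsum(waits)
        rew = rng.random(n) < 0.5
        sess = _session(times, np.ones(n, int), rew)
        tab = build_press_table(sess, 3.0)
        # next wait is independent of the outcome by construction
        out = conditional_wait_analysis(tab, bounds=WAIT_CATEGORY_PRESET)
        valid = out[out["valid"]]
        assert np.all(np.abs(valid["auc"] - 0.5) < 0.12)
        assert np.all(np.abs(valid["percent_change"]) < 15)

    def test_preset_bounds_categorize_four_seconds_as_short(self):
        lo, hi = WAIT_CATEGORY_PRESET[0]
        assert lo <= 4.0 <= hi

    def test_auc_matches_exhaustive_pair_counting(self):
        nw = np.array([2.0, 9.0, 3.0, 7.0, 7.0, 1.0])
        rew = np.array([True, False, True, False, True, True])
        times = np.cumsum(np.full(7, 5.0))
        sess = _session(times, np.ones(7, int),
                        np.append(rew, False))
        # attach next waits by hand
        tab = pd.DataFrame({
            "waiting_time": np.full(6, 5.0), "rewarded": rew,
            "next_waiting_time": nw, "choice": ["stay"] * 6})
        out = conditional_wait_analysis(tab, bounds=[(0.0, 60.0)])
        pos = nw[~rew]
        neg = nw[rew]
        wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        assert out.iloc[0]["auc"] == pytest.approx(wins / (len(pos) * len(neg)))

    def test_switch_probability_of_degenerate_agent(self, rng):
        sched = VISchedule.from_pairs([(15, 15)] * 2, n_rewards=40)
        sess = run_threshold_agent(
            ThresholdAgentParams(loss_mean=1.0, loss_sd=0.0), sched, rng)
        tab = build_press_table(sess, 5.0)
        out = switch_probability(tab, bounds=[(0.0, 60.0)])
        assert out.iloc[0]["p_switch_unrewarded"] == pytest.approx(1.0)
        assert out.iloc[0]["p_switch_rewarded"] == pytest.approx(0.0)
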