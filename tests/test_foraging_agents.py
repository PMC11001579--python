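"""Strategy agents and the generalized matching-law diagnostics."""

import numpy as np
import pandas as pd
import pytest

from neuroforage.foraging_agents import (
    MatchingFit,
    MVTAgentParams,
    ThresholdAgentParams,
    matching_law_fit,
    run_mvt_agent,
    run_threshold_agent,
)
from neuroforage.task_model import BehavioralSession, ForagingEnvironment, VISchedule


@pytest.fixture
def balanced_schedule():
    return VISchedule.from_pairs([(20, 20), (20, 20)], n_rewards=40)


class TestThresholdAgent:
    def test_degenerate_threshold_switches_after_every_loss(self, rng):
        """loss_mean=1, loss_sd=0: a single unrewarded press always triggers a
        switch and a rewarded press never does."""
        sched = VISchedule.from_pairs([(15, 15)] * 2, n_rewards=50)
        params = ThresholdAgentParams(loss_mean=1.0, loss_sd=0.0)
        sess = run_threshold_agent(params, sched, rng)
        switches = sess.boxes[1:] != sess.boxes[:-1]
        unrewarded = ~sess.rewarded[:-1]
        assert np.all(switches[unrewarded])
        assert not np.any(switches[~unrewarded])

    def test_equal_schedules_are_symmetric(self, balanced_schedule):
        ratios = []
        for seed in range(6):
            s = run_threshold_agent(ThresholdAgentParams(), balanced_schedule,
                                    np.random.default_rng(seed))
            p1, p2 = np.sum(s.boxes == 1), np.sum(s.boxes == 2)
            ratios.append(np.log(p1 / p2))
        assert abs(np.mean(ratios)) < 0.4

    def test_blind_to_schedule_given_reward_sequence(self, monkeypatch):
        """Permuting the VI labels while replaying identical reward outcomes
        leaves the threshold agent's choice sequence unchanged."""
        outcomes = np.random.default_rng(0).random(500) < 0.4
        choices = []
        for pairs in ([(10, 40)], [(40, 10)]):
            counter = {"i": 0}

            def scripted_press(self, box, time):
                i = counter["i"]
                counter["i"] += 1
                return bool(outcomes[i]), 0

            monkeypatch.setattr(ForagingEnvironment, "press", scripted_press)
            sched = VISchedule.from_pairs(pairs, n_rewards=1000)
            sess = run_threshold_agent(ThresholdAgentParams(), sched,
                                       np.random.default_rng(99),
                                       n_rewards_total=120)
            choices.append(list(sess.boxes))
        assert choices[0] == choices[1]

    def test_rejects_nonpositive_total(self, rng, balanced_schedule):
        with pytest.raises(ValueError):
            run_threshold_agent(ThresholdAgentParams(), balanced_schedule, rng,
                                n_rewards_total=0)


class TestMVTAgent:
    def test_huge_cost_never_switches(self, rng):
        sched = VISchedule.from_pairs([(15, 30)], n_rewards=60)
        params = MVTAgentParams(switching_cost=50.0, switch_noise_sd=0.0)
        sess = run_mvt_agent(params, sched, rng)
        assert np.all(sess.boxes == sess.boxes[0])

    def test_equal_schedules_are_symmetric(self, balanced_schedule):
        ratios = []
        for seed in range(6):
            s = run_mvt_agent(MVTAgentParams(), balanced_schedule,
                              np.random.default_rng(seed))
            p1, p2 = np.sum(s.boxes == 1), np.sum(s.boxes == 2)
            ratios.append(np.log(max(p1, 1) / max(p2, 1)))
        assert abs(np.mean(ratios)) < 0.6

    def test_switch_frequency_nonincreasing_in_cost(self):
        sched = VISchedule.from_pairs([(20, 30), (30, 20)], n_rewards=50)
        freqs = []
        for cost in (0.2, 0.5, 0.9):
            f = []
            for seed in range(4):
                s = run_mvt_agent(MVTAgentParams(switching_cost=cost),
                                  sched, np.random.default_rng(seed))
                f.append(np.mean(s.boxes[1:] != s.boxes[:-1]))
            freqs.append(np.mean(f))
        assert freqs[0] >= freqs[1] >= freqs[2]

    def test_session_satisfies_press_invariants(self, mvt_session):
        assert np.all(np.diff(mvt_session.times) > 0)
        assert set(np.unique(mvt_session.boxes)) <= {1, 2}
        assert len(mvt_session) > 50


class TestMatchingLaw:
    def _session_from_counts(self, counts):
        """Build a minimal session with given per-block (p1, r1, p2, r2)."""
        times, boxes, rewarded, blocks = [], [], [], []
        t = 0.0
        for blk, (p1, r1, p2, r2) in enumerate(counts):
            for i in range(p1):
                t += 5.0
                times.append(t); boxes.append(1); rewarded.append(i < r1)
                blocks.append(blk)
            for i in range(p2):
                t += 5.0
                times.append(t); boxes.append(2); rewarded.append(i < r2)
                blocks.append(blk)
        sched = VISchedule.from_pairs([(20, 20)] * len(counts))
        return BehavioralSession(
            times=np.array(times), boxes=np.array(boxes),
            rewarded=np.array(rewarded), block_index=np.array(blocks),
            schedule=sched)

    def test_identity_points_give_unit_slope(self):
        # press ratios equal to reward ratios in every block
        sess = self._session_from_counts(
            [(40, 20, 10, 5), (10, 5, 40, 20), (30, 9, 10, 3)])
        fit = matching_law_fit(sess)
        assert fit.slope == pytest.approx(1.0, abs=1e-9)
        assert fit.intercept == pytest.approx(0.0, abs=1e-9)

    def test_two_point_slope(self):
        # log ratios (0, 0) and (1, 0.8) -> slope 0.8
        e = np.e
        sess = self._session_from_counts(
            [(10, 5, 10, 5),
             (int(round(10 * e**0.8)) * 5, int(round(5 * e)) * 2,
              5 * 5, 5 * 2)])
        fit = matching_law_fit(sess)
        x = fit.points["log_reward_ratio"].to_numpy()
        y = fit.points["log_press_ratio"].to_numpy()
        expected = (y[1] - y[0]) / (x[1] - x[0])
        assert fit.slope == pytest.approx(expected, rel=1e-9)

    def test_zero_count_block_excluded_with_warning(self):
        sess = self._session_from_counts(
            [(10, 5, 10, 5), (20, 10, 5, 2), (10, 4, 0, 0)])
        with pytest.warns(UserWarning):
            fit = matching_law_fit(sess)
        assert fit.n_points == 2

    def test_agent_slope_ordering(self):
        """Threshold agent undermatches relative to the MVT agent on the
        same unbalanced schedule set (fixed seeds)."""
        sched = VISchedule.from_pairs(
            [(15, 25), (25, 15), (15, 25), (25, 15)], n_rewards=34)
        thr = [run_threshold_agent(ThresholdAgentParams(), sched,
                                   np.random.default_rng(s)) for s in range(4)]
        mvt = [run_mvt_agent(MVTAgentParams(), sched,
                             np.random.default_rng(s)) for s in range(4)]
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert matching_law_fit(thr).slope < matching_law_fit(mvt).slope

    def test_requires_two_blocks(self):
        sess = self._session_from_counts([(10, 5, 10, 5)])
        with pytest.raises(ValueError):
            matching_law_fit(sess)
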