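"""Rate matrices, press-locked tensors, engagement mask, confound removal."""

import numpy as np
import pytest

from neuroforage.neural_preprocess import (
    LocomotionProjector,
    RateGrid,
    RateMatrix,
    bin_and_smooth,
    engagement_mask,
    press_locked,
    remove_locomotion,
)
from neuroforage.synthetic_data import LocomotionTrace, SpikeTrainSet


def _spikes(trains, t_stop):
    return SpikeTrainSet(spike_times=[np.asarray(t, float) for t in trains],
                         t_stop=t_stop)


class TestBinAndSmooth:
    def test_single_spike_unsmoothed(self):
        grid = RateGrid(start=0.0, step=1.0, n_bins=10)
        rm = bin_and_smooth(_spikes([[5.2]], 10.0), grid, smooth_window=0.0)
        assert rm.rates[0, 5] == pytest.approx(1.0)
        assert rm.rates[0].sum() == pytest.approx(1.0)

    def test_empty_unit_is_zero_row(self):
        grid = RateGrid(start=0.0, step=0.5, n_bins=8)
        rm = bin_and_smooth(_spikes([[], [1.2]], 4.0), grid)
        assert np.all(rm.rates[0] == 0)

    def test_smoothing_preserves_interior_mass(self, rng):
        spikes = np.sort(rng.uniform(10, 40, 200))
        grid = RateGrid(start=0.0, step=0.2, n_bins=250)
        raw = bin_and_smooth(_spikes([spikes], 50.0), grid, smooth_window=0.0)
        sm = bin_and_smooth(_spikes([spikes], 50.0), grid, smooth_window=1.0)
        assert sm.rates.sum() * 0.2 == pytest.approx(raw.rates.sum() * 0.2,
                                                     rel=1e-9)

    def test_constant_rate_recovered(self, rng):
        rate = 8.0
        t_stop = 200.0
        n = rng.poisson(rate * t_stop)
        spikes = np.sort(rng.uniform(0, t_stop, n))
        grid = RateGrid(start=0.0, step=0.2, n_bins=1000)
        rm = bin_and_smooth(_spikes([spikes], t_stop), grid, smooth_window=1.0)
        assert abs(rm.rates.mean() - rate) < 4 * np.sqrt(rate / t_stop)


class TestPressLocked:
    def test_shifted_copies_give_identical_slices(self):
        pattern = np.array([-1.87, -1.43, -0.31, 0.45])
        presses = np.array([10.0, 30.0, 55.0])
        st = np.sort(np.concatenate([p + pattern for p in presses]))
        out = press_locked(_spikes([st], 60.0), presses, window=(-2, 1), step=0.2)
        assert out.rates.shape[0] == 3
        assert np.allclose(out.rates[0], out.rates[1])
        assert np.allclose(out.rates[0], out.rates[2])

    def test_silent_unit_zero(self):
        out = press_locked(_spikes([[]], 40.0), np.array([10.0, 30.0]))
        assert np.all(out.rates == 0)

    def test_manual_three_press_oracle(self):
        presses = np.array([10.0, 12.5, 30.0])
        st = np.array([8.3, 9.95, 29.1, 30.5])
        out = press_locked(_spikes([st], 40.0), presses, window=(-2, 1),
                          step=0.5, min_gap=2.0)
        # press at 12.5 is 2.5 s after 10.0 -> kept; all three survive
        assert list(out.press_index) == [0, 1, 2]
        # manual binning for press 0: bins [-2,-1.5).. : 8.3 -> [-2,-1.5), 9.95 -> [-0.5, 0)
        row = out.rates[0, :, 0]
        assert row[0] == pytest.approx(1 / 0.5)
        assert row[3] == pytest.approx(1 / 0.5)
        # press 2: 29.1 -> offset -0.9 -> bin [-1,-0.5); 30.5 -> [0.5, 1)
        row2 = out.rates[2, :, 0]
        assert row2[2] == pytest.approx(1 / 0.5)
        assert row2[5] == pytest.approx(1 / 0.5)

    def test_close_press_excluded(self):
        presses = np.array([10.0, 11.0, 30.0])
        out = press_locked(_spikes([[5.0]], 40.0), presses, min_gap=2.0)
        assert 1 not in out.press_index


class TestEngagementMask:
    def test_dense_presses_all_included(self):
        grid = RateGrid(start=0.0, step=0.5, n_bins=80)
        mask = engagement_mask(np.arange(0, 41, 4.0), grid, max_gap=5.0)
        assert mask.all()

    def test_long_gap_excluded(self):
        grid = RateGrid(start=0.0, step=1.0, n_bins=100)
        mask = engagement_mask(np.array([10.0, 70.0]), grid, max_gap=5.0)
        centers = grid.centers
        inside = (np.abs(centers - 10.0) <= 5) | (np.abs(centers - 70.0) <= 5)
        assert np.array_equal(mask, inside)

    def test_matches_brute_force(self, rng):
        presses = np.sort(rng.uniform(0, 100, 12))
        grid = RateGrid(start=0.0, step=0.37, n_bins=270)
        mask = engagement_mask(presses, grid, max_gap=5.0)
        brute = np.array([np.min(np.abs(presses - c)) <= 5.0
                          for c in grid.centers])
        assert np.array_equal(mask, brute)


class TestLocomotionProjection:
    def _loco(self, speed, step=0.2):
        times = np.arange(len(speed)) * step
        pos = np.column_stack([np.cumsum(speed) * step, np.zeros(len(speed))])
        return LocomotionTrace(times=times, position=pos,
                               speed=np.asarray(speed, float))

    def test_rate_proportional_to_speed_removed(self, rng):
        speed = rng.random(200) * 10
        proj = LocomotionProjector().fit(speed)
        res = proj.transform(3.0 * speed)
        assert np.allclose(res, 0.0, atol=1e-9)

    def test_orthogonal_component_unchanged(self, rng):
        speed = rng.random(300)
        proj = LocomotionProjector().fit(speed)
        r = rng.random(300)
        basis = proj.basis_
        r_orth = r - basis @ (basis.T @ r)
        assert np.allclose(proj.transform(r_orth), r_orth, atol=1e-10)

    def test_residual_correlation_is_zero(self, rng):
        speed = rng.random(500) * 20
        rates = rng.random((15, 500)) * 10
        res = LocomotionProjector().fit(speed).transform(rates)
        for row in res:
            if row.std() > 0:
                assert abs(np.corrcoef(row, speed)[0, 1]) < 1e-10

    def test_idempotent_and_contractive(self, rng):
        speed = rng.random(400)
        rates = rng.random((5, 400))
        proj = LocomotionProjector().fit(speed)
        once = proj.transform(rates)
        twice = proj.transform(once)
        assert np.allclose(once, twice, atol=1e-12)
        assert np.all((once**2).sum(1) <= (rates**2).sum(1) + 1e-12)

    def test_zero_trace_warns_identity(self, rng):
        with pytest.warns(UserWarning):
            proj = LocomotionProjector().fit(np.zeros(50))
        r = rng.random(50)
        assert np.allclose(proj.transform(r), r)

    def test_literal_rank_one_formula(self, rng):
        """with_intercept=False reproduces r - L (L^T L)^{-1} L^T r."""
        L = rng.random(100)
        r = rng.random(100)
        proj = LocomotionProjector(with_intercept=False).fit(L)
        expected = r - L * (L @ r) / (L @ L)
        assert np.allclose(proj.transform(r), expected, atol=1e-10)

    def test_planted_locomotion_unit_cleaned(self, tiny_bundle):
        """Units with planted locomotion weight lose their speed correlation
        after projection; the wait-ramp correlation survives."""
        from neuroforage.neural_preprocess import bin_and_smooth

        b = tiny_bundle
        grid = RateGrid.covering(b.spikes.t_stop, step=0.2)
        rm = bin_and_smooth(b.spikes, grid)
        rm.mask = engagement_mask(b.session.times, grid)
        cleaned = remove_locomotion(rm, b.locomotion)
        L = b.locomotion.speed_at(grid.centers)[rm.mask]
        for row in cleaned.masked():
            if row.std() > 0:
                assert abs(np.corrcoef(row, L)[0, 1]) < 1e-10
        wait = np.interp(grid.centers[rm.mask], b.ground_truth.grid,
                         b.ground_truth.channels["wait_ramp"])
        names = list(b.ground_truth.channel_names)
        w = b.ground_truth.weights
        k = int(np.argmax(np.abs(w[:, names.index("wait_ramp")])))
        r_before = np.corrcoef(rm.masked()[k], wait)[0, 1]
        r_after = np.corrcoef(cleaned.masked()[k], wait)[0, 1]
        assert np.sign(r_after) == np.sign(r_before)
        assert abs(r_after) > 0.5 * abs(r_before)
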