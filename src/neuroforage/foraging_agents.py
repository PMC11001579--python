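"""Strategy agents for the concurrent-VI task and matching-law diagnostics.

Two agents bracket the space of strategies that both produce matching behavior:

* a win-stay/lose-switch **threshold agent** that leaves a box once its run of
  consecutive unrewarded presses exceeds a Gaussian-sampled threshold — blind
  to the schedules and to reward-availability dynamics (undermatching);
* a **marginal-value-theorem (MVT) agent** with complete task knowledge that
  tracks the true probability of reward availability on both boxes and
  switches when the other box's probability exceeds the current one by a fixed
  switching cost (overmatching).

The generalized matching law is diagnosed by regressing the log press ratio on
the log obtained-reward ratio across schedule blocks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .task_model import BehavioralSession, ForagingEnvironment, VISchedule

__all__ = [
    "ThresholdAgentParams",
    "MVTAgentParams",
    "MatchingFit",
    "AR1BeliefNoise",
    "run_threshold_agent",
    "run_mvt_agent",
    "matching_law_fit",
]


@dataclass(frozen=True)
class ThresholdAgentParams:
    """Win-stay/lose-switch agent: switch when consecutive losses exceed a
    per-visit threshold drawn from N(loss_mean, loss_sd**2)."""

    loss_mean: float = 2.5
    loss_sd: float = 1.5
    wait_log_mean: float = np.log(6.0)  # median wait 6 s
    wait_log_sd: float = 0.55
    travel_time: float = 3.0  # s, walking the 120 cm between boxes

    def __post_init__(self) -> None:
        if self.loss_sd < 0:
            raise ValueError("loss_sd must be nonnegative")
        if self.travel_time < 0:
            raise ValueError("travel_time must be nonnegative")


@dataclass(frozen=True)
class MVTAgentParams:
    """Fully informed agent pressing when P_rew crosses a threshold and
    switching when the other box exceeds the current by a switching cost.

    "When": the agent waits until the true current-box P_rew reaches a press
    threshold drawn per press as theta_press + patience_gain*(reward_ratio -
    1/2) + Gaussian jitter — patient on a box with a good recent record,
    quicker on a poor one.  "Where": at that decision time it switches iff
    P_rew(other) - theta_press exceeds the cost; the cost is scaled by
    (VI_other / VI_current)**cost_vi_exponent (leaving toward a slower box
    demands a larger margin — the rate-sensitive reading of a fixed travel
    cost) and carries a private log-normal decision noise.
    """

    switching_cost: float = 0.5  # probability units, at equal schedules
    theta_press: float = 0.5  # press when current-box P_rew reaches this
    theta_jitter_sd: float = 0.22  # per-press Gaussian jitter on theta
    patience_gain: float = 0.18  # coupling of theta to the local reward ratio
    patience_filter_width: float = 10.0  # presses, half-Gaussian for that ratio
    switch_noise_sd: float = 0.1  # private log-noise on the switching cost
    cost_vi_exponent: float = 0.5  # cost scaling with the VI ratio
    belief_timing_gain: float = 0.4  # how strongly belief noise shifts press timing
    travel_time: float = 3.0
    decision_step: float = 0.2  # s, granularity of decision times
    max_wait: float = 90.0  # s, safety cap on a single wait

    def __post_init__(self) -> None:
        if self.switching_cost < 0:
            raise ValueError("switching_cost must be nonnegative")
        if not 0 < self.theta_press < 1:
            raise ValueError("theta_press must be in (0, 1)")


class AR1BeliefNoise:
    """Slowly drifting perturbation of the agent's subjective log-P_rew.

    An AR(1) process on a fixed grid (time constant ``tau``, stationary s.d.
    ``sd``), extended lazily and interpolated at query times.  The same series
    is injected into synthetic spike rates, making it a latent shared between
    behavior and neural activity.
    """

    def __init__(self, rng: np.random.Generator, tau: float = 10.0,
                 sd: float = 0.35, grid_dt: float = 0.1):
        if tau <= 0 or sd < 0 or grid_dt <= 0:
            raise ValueError("tau and grid_dt must be positive, sd nonnegative")
        self.tau = tau
        self.sd = sd
        self.grid_dt = grid_dt
        self._rho = float(np.exp(-grid_dt / tau))
        self._innov_sd = sd * float(np.sqrt(1 - self._rho**2))
        self._rng = rng
        self._values = [rng.normal(0.0, sd) if sd > 0 else 0.0]

    def _extend(self, n: int) -> None:
        while len(self._values) < n:
            prev = self._values[-1]
            self._values.append(
                self._rho * prev + self._rng.normal(0.0, self._innov_sd)
                if self.sd > 0 else 0.0
            )

    def value(self, t: float) -> float:
        i = int(np.floor(t / self.grid_dt))
        self._extend(i + 2)
        frac = t / self.grid_dt - i
        return (1 - frac) * self._values[i] + frac * self._values[i + 1]

    def series(self, times: np.ndarray) -> np.ndarray:
        times = np.asarray(times, dtype=float)
        self._extend(int(np.floor(times.max() / self.grid_dt)) + 2)
        grid = np.arange(len(self._values)) * self.grid_dt
        return np.interp(times, grid, np.asarray(self._values))


def _finalize_session(times, boxes, rewarded, blocks, schedule, meta) -> BehavioralSession:
    return BehavioralSession(
        times=np.asarray(times), boxes=np.asarray(boxes),
        rewarded=np.asarray(rewarded, dtype=bool),
        block_index=np.asarray(blocks), schedule=schedule, meta=meta,
    )


def run_threshold_agent(
    params: ThresholdAgentParams,
    schedule: VISchedule,
    rng: np.random.Generator,
    n_rewards_total: int | None = None,
    max_presses: int = 200_000,
) -> BehavioralSession:
    """Simulate the noisy-threshold win-stay/lose-switch agent.

    The choice rule uses only the count of consecutive unrewarded presses at
    the current box versus a per-visit Gaussian threshold; it never consults
    the schedule or elapsed time, so it is blind to reward-rate structure.
    """
    total = schedule.total_rewards if n_rewards_total is None else int(n_rewards_total)
    if total <= 0:
        raise ValueError("n_rewards_total must be positive")
    env = ForagingEnvironment(schedule, rng)
    box = int(rng.integers(1, 3))
    threshold = rng.normal(params.loss_mean, params.loss_sd)
    losses = 0
    t = 0.0
    times, boxes, rewarded, blocks = [], [], [], []
    n_rew = 0
    while n_rew < total and not env.done and len(times) < max_presses:
        wait = rng.lognormal(params.wait_log_mean, params.wait_log_sd)
        t += wait
        rew, blk = env.press(box, t)
        times.append(t); boxes.append(box); rewarded.append(rew); blocks.append(blk)
        n_rew += int(rew)
        if rew:
            losses = 0  # win-stay
        else:
            losses += 1
            if losses >= threshold:  # lose-switch once the noisy threshold is reached
                box = 3 - box
                losses = 0
                threshold = rng.normal(params.loss_mean, params.loss_sd)
                t += params.travel_time
    return _finalize_session(times, boxes, rewarded, blocks, schedule,
                             {"agent": "threshold"})


def run_mvt_agent(
    params: MVTAgentParams,
    schedule: VISchedule,
    rng: np.random.Generator,
    n_rewards_total: int | None = None,
    belief_noise: AR1BeliefNoise | None = None,
    max_presses: int = 200_000,
) -> BehavioralSession:
    """Simulate the fully informed marginal-value-theorem agent.

    The agent knows the current VI pair and its own press history, hence the
    exact P_rew of both boxes.  It presses the current box when its true
    P_rew reaches the (reward-ratio-modulated, jittered) press threshold; at
    that decision time it switches iff the subjective margin
    exp(eps_t) * (P_rew(other) - theta_press) exceeds the VI-scaled, noised
    switching cost.  ``belief_noise`` supplies eps_t — the latent shared with
    the synthetic neural population, so choice deviations are visible in
    spikes but not in the true task variables (high eps -> early switches).
    """
    total = schedule.total_rewards if n_rewards_total is None else int(n_rewards_total)
    if total <= 0:
        raise ValueError("n_rewards_total must be positive")
    env = ForagingEnvironment(schedule, rng)
    box = int(rng.integers(1, 3))
    t = 0.0
    times, boxes, rewarded, blocks = [], [], [], []
    n_rew = 0
    dt = schedule.dt
    # online causal half-Gaussian reward ratio for the patience modulation
    kernel = np.exp(-(np.arange(8192) ** 2)
                    / (2.0 * params.patience_filter_width**2))
    hist_rew: list[float] = []
    hist_box: list[int] = []

    def local_reward_ratio(b: int) -> float:
        if not hist_rew:
            return 0.5
        r = np.asarray(hist_rew[::-1], dtype=float)
        bx = np.asarray(hist_box[::-1])
        w = kernel[: len(r)]
        den = float(np.dot(w, r))
        return float(np.dot(w, r * (bx == b)) / den) if den > 0 else 0.5

    while n_rew < total and not env.done and len(times) < max_presses:
        theta = (params.theta_press
                 + params.patience_gain * (local_reward_ratio(box) - 0.5)
                 + rng.normal(0.0, params.theta_jitter_sd))
        # belief noise shifts the subjective availability estimate, so an
        # optimistic agent presses at a lower true P_rew (eps varies slowly;
        # evaluate it at the previous press)
        if belief_noise is not None and params.belief_timing_gain > 0:
            theta *= float(np.exp(-params.belief_timing_gain
                                  * belief_noise.value(t)))
        theta = float(np.clip(theta, 0.05, 0.95))
        # closed-form crossing time of the true current-box P_rew
        vi = env.vi(box)
        t_star = dt * np.log1p(-theta) / np.log1p(-dt / vi)  # wait for P=theta
        t_cross = env.state.last_press_time[box - 1] + t_star
        decision_t = min(max(t + params.decision_step, t_cross), t + params.max_wait)
        # round up to the decision grid
        decision_t = t + params.decision_step * np.ceil(
            (decision_t - t) / params.decision_step - 1e-9)
        p_oth = env.prob_available(3 - box, decision_t)
        gain = 1.0
        if belief_noise is not None:
            gain = float(np.exp(belief_noise.value(decision_t)))
        cost = params.switching_cost * (
            env.vi(3 - box) / vi) ** params.cost_vi_exponent
        if params.switch_noise_sd > 0:
            cost *= float(np.exp(rng.normal(0.0, params.switch_noise_sd)))
        if gain * (min(1.0, p_oth) - params.theta_press) > cost:
            box = 3 - box
            decision_t += params.travel_time
        t = decision_t
        rew, blk = env.press(box, t)
        times.append(t); boxes.append(box); rewarded.append(rew); blocks.append(blk)
        hist_rew.append(float(rew)); hist_box.append(box)
        n_rew += int(rew)
    return _finalize_session(times, boxes, rewarded, blocks, schedule,
                             {"agent": "mvt"})


@dataclass
class MatchingFit:
    """Generalized matching-law fit: log press ratio vs log obtained-reward ratio."""

    slope: float
    intercept: float
    points: pd.DataFrame = field(repr=False)  # columns: log_reward_ratio, log_press_ratio

    @property
    def n_points(self) -> int:
        return len(self.points)


def matching_law_fit(sessions: list[BehavioralSession] | BehavioralSession) -> MatchingFit:
    """Least-squares generalized matching-law fit, one point per schedule block.

    Blocks where either box has zero presses or zero obtained rewards are
    excluded with a warning (the log ratio is undefined).  Requires at least
    two usable blocks.
    """
    if isinstance(sessions, BehavioralSession):
        sessions = [sessions]
    rows = []
    for s_i, sess in enumerate(sessions):
        for blk in np.unique(sess.block_index):
            m = sess.block_index == blk
            p1 = int(np.sum(m & (sess.boxes == 1)))
            p2 = int(np.sum(m & (sess.boxes == 2)))
            r1 = int(np.sum(m & (sess.boxes == 1) & sess.rewarded))
            r2 = int(np.sum(m & (sess.boxes == 2) & sess.rewarded))
            if min(p1, p2, r1, r2) == 0:
                warnings.warn(
                    f"session {s_i} block {blk}: zero press or reward count on one box;"
                    " excluded from matching fit", stacklevel=2)
                continue
            rows.append({
                "session": s_i, "block": int(blk),
                "log_reward_ratio": np.log(r1 / r2),
                "log_press_ratio": np.log(p1 / p2),
            })
    pts = pd.DataFrame(rows)
    if len(pts) < 2:
        raise ValueError("matching fit needs at least two usable blocks")
    slope, intercept = np.polyfit(pts["log_reward_ratio"], pts["log_press_ratio"], 1)
    return MatchingFit(slope=float(slope), intercept=float(intercept), points=pts)
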