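"""Concurrent variable-interval (VI) reward process.

Two reward boxes independently arm according to latching Bernoulli ("telegraph")
processes: in every bin of width ``dt`` an unarmed box becomes armed with
probability ``dt/VI``, and an armed box stays armed until the next press on it.
The probability that a reward is waiting therefore grows with the time ``t``
elapsed since the preceding press on that box:

    P_rew(t) = 1 - (1 - dt/VI)**(t/dt)

which converges to the constant-hazard form ``1 - exp(-t/VI)`` as ``dt -> 0``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ScheduleBlock",
    "VISchedule",
    "BoxState",
    "BehavioralSession",
    "prob_reward_available",
    "step_availability",
    "press",
    "ForagingEnvironment",
]


@dataclass(frozen=True)
class ScheduleBlock:
    """One block of the session: a (VI box1, VI box2) pair and its reward budget."""

    box1_vi: float
    box2_vi: float
    n_rewards: int = 34

    def __post_init__(self) -> None:
        if self.box1_vi <= 0 or self.box2_vi <= 0:
            raise ValueError("VI means must be positive")
        if self.n_rewards <= 0:
            raise ValueError("n_rewards must be a positive count")

    def vi(self, box: int) -> float:
        if box == 1:
            return self.box1_vi
        if box == 2:
            return self.box2_vi
        raise ValueError(f"box must be 1 or 2, got {box}")


@dataclass(frozen=True)
class VISchedule:
    """Sequence of schedule blocks plus the availability-simulation bin width."""

    blocks: tuple[ScheduleBlock, ...]
    dt: float = 0.01  # 10 ms availability bins

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError("schedule needs at least one block")
        object.__setattr__(self, "blocks", tuple(self.blocks))
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        min_vi = min(min(b.box1_vi, b.box2_vi) for b in self.blocks)
        if self.dt >= min_vi:
            raise ValueError("dt must be smaller than every VI mean")

    @classmethod
    def from_pairs(
        cls,
        pairs: Iterable[tuple[float, float]],
        n_rewards: int | Sequence[int] = 34,
        dt: float = 0.01,
    ) -> "VISchedule":
        pairs = list(pairs)
        if np.isscalar(n_rewards):
            counts = [int(n_rewards)] * len(pairs)
        else:
            counts = [int(n) for n in n_rewards]
        blocks = tuple(
            ScheduleBlock(v1, v2, n) for (v1, v2), n in zip(pairs, counts, strict=True)
        )
        return cls(blocks=blocks, dt=dt)

    @property
    def total_rewards(self) -> int:
        return sum(b.n_rewards for b in self.blocks)


def prob_reward_available(t, vi, dt: float = 0.01):
    """Closed-form probability that a latched reward is waiting after ``t`` seconds.

    Parameters
    ----------
    t : float or array-like
        Time since the preceding press on the box, in seconds.
    vi : float or array-like
        Mean of the variable-interval schedule, in seconds.
    dt : float
        Width of the Bernoulli availability bin (default 10 ms).

    Returns
    -------
    float or ndarray in [0, 1], nondecreasing in ``t`` and nonincreasing in ``vi``.
    """
    t = np.asarray(t, dtype=float)
    vi = np.asarray(vi, dtype=float)
    if np.any(vi <= 0):
        raise ValueError("vi must be positive")
    if dt <= 0 or np.any(dt > vi):
        raise ValueError("dt must satisfy 0 < dt <= vi")
    if np.any(t < 0):
        raise ValueError("t must be nonnegative")
    # exp(log1p(-dt/vi) * t/dt) is stable for small dt/vi and large t/dt
    p = -np.expm1(np.log1p(-dt / vi) * (t / dt))
    out = np.clip(p, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


@dataclass
class BoxState:
    """Mutable availability state of the two boxes.

    ``avail_time`` holds, per box, the absolute time at which the pending reward
    becomes (or became) available; availability latches until a press.  Sampling
    the geometric first-arming bin lazily is distributionally identical to
    stepping every ``dt`` bin, by memorylessness of the Bernoulli process.
    """

    avail_time: np.ndarray  # shape (2,), absolute seconds
    last_press_time: np.ndarray  # shape (2,), absolute seconds

    @classmethod
    def initial(cls, vis: Sequence[float], dt: float, rng: np.random.Generator,
                t0: float = 0.0) -> "BoxState":
        avail = np.array(
            [t0 + rng.geometric(dt / vi) * dt for vi in vis], dtype=float
        )
        return cls(avail_time=avail, last_press_time=np.full(2, t0))

    def available(self, box: int, time: float) -> bool:
        return time >= self.avail_time[box - 1]

    def time_since_press(self, box: int, time: float) -> float:
        return time - self.last_press_time[box - 1]

    def rearm(self, box: int, time: float, vi: float, dt: float,
              rng: np.random.Generator) -> None:
        self.avail_time[box - 1] = time + rng.geometric(dt / vi) * dt

    def reschedule_pending(self, time: float, vis: Sequence[float], dt: float,
                           rng: np.random.Generator) -> None:
        """On a block change, resample arming times of not-yet-armed boxes."""
        for b in (1, 2):
            if self.avail_time[b - 1] > time:
                self.avail_time[b - 1] = time + rng.geometric(dt / vis[b - 1]) * dt


def step_availability(available: np.ndarray, p: np.ndarray,
                      rng: np.random.Generator) -> np.ndarray:
    """Advance the latching availability flags by one ``dt`` bin.

    An unavailable box becomes available with probability ``p = dt/vi``; an
    available box stays available.  Used as the per-bin oracle that the lazy
    geometric sampler in :class:`BoxState` is tested against.
    """
    available = np.asarray(available, dtype=bool)
    p = np.broadcast_to(np.asarray(p, dtype=float), available.shape)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("per-bin probability must lie in [0, 1]")
    arm = rng.random(available.shape) < p
    return available | arm


def press(state: BoxState, box: int, time: float, vi: float, dt: float,
          rng: np.random.Generator) -> bool:
    """Press ``box`` at ``time``: collect the reward if armed, then reset.

    The other box's state is untouched.  Raises on out-of-order times.
    """
    if box not in (1, 2):
        raise ValueError("box must be 1 or 2")
    if time < state.last_press_time.max():
        raise ValueError("press times must be nondecreasing within a session")
    rewarded = state.available(box, time)
    state.last_press_time[box - 1] = time
    state.rearm(box, time, vi, dt, rng)
    return rewarded


@dataclass
class BehavioralSession:
    """Ordered press events plus the schedule that generated them."""

    times: np.ndarray  # seconds, strictly increasing
    boxes: np.ndarray  # in {1, 2}
    rewarded: np.ndarray  # bool
    block_index: np.ndarray  # 0-based block of each press
    schedule: VISchedule
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.boxes = np.asarray(self.boxes, dtype=int)
        self.rewarded = np.asarray(self.rewarded, dtype=bool)
        self.block_index = np.asarray(self.block_index, dtype=int)
        n = len(self.times)
        if not (len(self.boxes) == len(self.rewarded) == len(self.block_index) == n):
            raise ValueError("press-event arrays must share one length")
        if n and np.any(np.diff(self.times) <= 0):
            raise ValueError("press times must be strictly increasing")
        if n and not np.isin(self.boxes, (1, 2)).all():
            raise ValueError("box labels must be 1 or 2")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def n_rewards(self) -> int:
        return int(self.rewarded.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.times,
                "box": self.boxes,
                "rewarded": self.rewarded.astype(int),
                "block_index": self.block_index,
            }
        )

    def vi_of_press(self, i: int) -> float:
        """Scheduled VI (s) of the box pressed at event ``i``."""
        return self.schedule.blocks[self.block_index[i]].vi(int(self.boxes[i]))

    def scheduled_rate_of_press(self, i: int) -> float:
        return 1.0 / self.vi_of_press(i)


class ForagingEnvironment:
    """Stateful two-box VI environment driven by an agent's presses.

    Handles reward arming, latching, collection, and the silent block
    transition immediately after the block's reward budget is exhausted.
    """

    def __init__(self, schedule: VISchedule, rng: np.random.Generator,
                 t0: float = 0.0):
        self.schedule = schedule
        self.rng = rng
        self.block = 0
        self.rewards_in_block = 0
        self.state = BoxState.initial(
            (schedule.blocks[0].box1_vi, schedule.blocks[0].box2_vi),
            schedule.dt, rng, t0=t0,
        )
        self._last_time = t0

    @property
    def done(self) -> bool:
        return self.block >= len(self.schedule.blocks)

    def vi(self, box: int) -> float:
        b = min(self.block, len(self.schedule.blocks) - 1)
        return self.schedule.blocks[b].vi(box)

    def time_since_press(self, box: int, time: float) -> float:
        return self.state.time_since_press(box, time)

    def prob_available(self, box: int, time: float) -> float:
        return prob_reward_available(
            self.state.time_since_press(box, time), self.vi(box), self.schedule.dt
        )

    def press(self, box: int, time: float) -> tuple[bool, int]:
        """Returns (rewarded, block index of this press)."""
        if time < self._last_time:
            raise ValueError("press times must be nondecreasing")
        if self.done:
            raise RuntimeError("schedule exhausted")
        self._last_time = time
        block_of_press = self.block
        rewarded = press(self.state, box, time, self.vi(box),
                         self.schedule.dt, self.rng)
        if rewarded:
            self.rewards_in_block += 1
            if self.rewards_in_block >= self.schedule.blocks[self.block].n_rewards:
                self.block += 1
                self.rewards_in_block = 0
                if not self.done:
                    blk = self.schedule.blocks[self.block]
                    self.state.reschedule_pending(
                        time, (blk.box1_vi, blk.box2_vi), self.schedule.dt, self.rng
                    )
        return rewarded, block_of_press
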