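"""Synthetic sessions: behavior, locomotion, and spiking populations.

Generates complete datasets with known ground truth so that every analysis
stage (confound removal, basis features, sparse CCA, decoding) can be
validated by parameter recovery.  The generator emulates the structure of a
freely moving two-box foraging session:

* behavior from one of the strategy agents (MVT by default), optionally with
  an AR(1) *belief noise* perturbing the agent's subjective reward estimate;
* an overhead-camera locomotion trace (6 Hz) dwelling at the pressed box and
  transiting the 120 cm between boxes on switches;
* 40-100 units with mixed selectivity: inhomogeneous Poisson spiking with
  softplus rates driven by a waiting-time ramp, the reward ratio, short
  post-press/reward/choice kernels, locomotion speed, and the belief-noise
  latent shared with the agent's choices.

The belief coupling plants the study's headline effect: units encode the
*subjective* (noisy) waiting-time estimate, so neural readouts of the wait
carry choice-relevant variability that the true task variables lack.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import lfilter

from .behavior_analysis import HalfGaussianFilter, _filtered_reward_ratio
from .foraging_agents import (
    AR1BeliefNoise,
    MVTAgentParams,
    ThresholdAgentParams,
    run_mvt_agent,
    run_threshold_agent,
)
from .task_model import BehavioralSession, VISchedule

__all__ = [
    "LocomotionTrace",
    "SpikeTrainSet",
    "EncodingSpec",
    "GroundTruth",
    "DatasetConfig",
    "SessionBundle",
    "generate_locomotion",
    "generate_population",
    "generate_dataset",
]

BOX_POSITIONS = {1: np.array([0.0, 30.0]), 2: np.array([120.0, 30.0])}  # cm

CHANNELS = ("wait_ramp", "reward_ratio", "press", "reward", "choice",
            "locomotion", "belief")


@dataclass
class LocomotionTrace:
    """Timestamped 2-D position (cm) and derived speed (cm/s)."""

    times: np.ndarray
    position: np.ndarray  # (n, 2)
    speed: np.ndarray  # (n,), speed[0] = 0

    def __post_init__(self) -> None:
        if self.position.shape != (len(self.times), 2):
            raise ValueError("position must be (n, 2)")
        if np.any(self.speed < 0):
            raise ValueError("speed must be nonnegative")

    def speed_at(self, t: np.ndarray) -> np.ndarray:
        return np.interp(t, self.times, self.speed)

    def position_at(self, t: np.ndarray) -> np.ndarray:
        return np.column_stack([
            np.interp(t, self.times, self.position[:, 0]),
            np.interp(t, self.times, self.position[:, 1]),
        ])


@dataclass
class SpikeTrainSet:
    """Sorted spike times (s) per unit."""

    spike_times: list  # of 1-D float arrays
    t_stop: float

    def __post_init__(self) -> None:
        for i, st in enumerate(self.spike_times):
            st = np.asarray(st, dtype=float)
            if np.any(np.diff(st) < 0):
                raise ValueError(f"unit {i}: spike times must be nondecreasing")
            if len(st) and (st[0] < 0 or st[-1] > self.t_stop):
                raise ValueError(f"unit {i}: spikes outside session span")
            self.spike_times[i] = st

    @property
    def n_units(self) -> int:
        return len(self.spike_times)


@dataclass(frozen=True)
class EncodingSpec:
    """Population-level encoding parameters.

    ``weight_scales`` are the s.d. of each unit's Gaussian weight on the
    corresponding z-scored latent channel; ``belief_coupling`` is the fixed
    gain with which the belief-noise latent rides on each unit's waiting-time
    weight (units encode the subjective, not the objective, wait).
    """

    n_units: int = 60
    baseline_range: tuple[float, float] = (2.0, 8.0)  # spikes/s
    weight_scales: dict = field(default_factory=lambda: {
        "wait_ramp": 0.9, "reward_ratio": 0.7, "press": 1.0, "reward": 1.0,
        "choice": 0.6, "locomotion": 0.8, "belief": 0.15,
    })
    belief_coupling: float = 0.6
    private_noise_sd: float = 0.3  # AR(1) drive noise per unit
    private_noise_tau: float = 5.0  # s
    sim_dt: float = 0.01  # 10 ms rate grid

    def __post_init__(self) -> None:
        if self.baseline_range[0] <= 0:
            raise ValueError("baseline rates must be positive")
        if self.n_units < 0:
            raise ValueError("n_units must be nonnegative")


@dataclass
class GroundTruth:
    """Planted latent channels (z-scored, on the simulation grid) and weights."""

    grid: np.ndarray
    channels: dict  # name -> (T,) array
    weights: np.ndarray  # (n_units, n_channels), order = CHANNELS
    baselines: np.ndarray
    channel_names: tuple = CHANNELS


def generate_locomotion(
    session: BehavioralSession,
    rng: np.random.Generator,
    fps: float = 6.0,
    jitter_sd: float = 2.0,
    travel_time: float = 3.0,
    pad: float = 2.0,
) -> LocomotionTrace:
    """Overhead-camera-like position trace for a session.

    The animal dwells near the pressed box (smooth Gaussian jitter) and
    transits the 120 cm between boxes with a smoothstep profile ending at the
    next press on the other box.
    """
    t_end = session.times[-1] + pad if len(session) else pad
    times = np.arange(0.0, t_end, 1.0 / fps)
    pos = np.empty((len(times), 2))

    press_t = session.times
    press_box = session.boxes
    # box occupied at each camera frame: box of the previous press, with a
    # smooth transit inserted just before each switch press
    if len(session) == 0:
        pos[:] = BOX_POSITIONS[1]
    else:
        idx = np.searchsorted(press_t, times, side="right") - 1
        current = press_box[np.maximum(idx, 0)].astype(float)
        base = np.array([BOX_POSITIONS[int(b)] for b in current])
        # smooth transitions over the travel window before each switch press
        x = base[:, 0].copy()
        for i in range(1, len(press_t)):
            if press_box[i] != press_box[i - 1]:
                t1 = press_t[i]
                t0 = max(press_t[i - 1], t1 - travel_time)
                m = (times >= t0) & (times <= t1)
                if m.any():
                    s = (times[m] - t0) / max(t1 - t0, 1e-9)
                    s = s * s * (3 - 2 * s)  # smoothstep
                    x0 = BOX_POSITIONS[int(press_box[i - 1])][0]
                    x1 = BOX_POSITIONS[int(press_box[i])][0]
                    x[m] = x0 + (x1 - x0) * s
        pos[:, 0] = x
        pos[:, 1] = base[:, 1]
    # smooth positional jitter (correlated over ~0.5 s)
    jit = rng.normal(0.0, jitter_sd, size=pos.shape)
    jit = gaussian_filter1d(jit, sigma=3.0, axis=0)
    pos += jit
    d = np.linalg.norm(np.diff(pos, axis=0), axis=1)
    speed = np.concatenate([[0.0], d * fps])
    return LocomotionTrace(times=times, position=pos, speed=speed)


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def _softplus_inv(y: np.ndarray) -> np.ndarray:
    return np.log(np.expm1(y))


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else x - x.mean()


def _event_kernel(grid: np.ndarray, events: np.ndarray, tau: float) -> np.ndarray:
    """Sum of causal exponential bumps (decay ``tau`` s) after each event."""
    dt = grid[1] - grid[0] if len(grid) > 1 else 1.0
    decay = np.exp(-dt / tau)
    idx = np.searchsorted(grid, events)
    impulse = np.zeros_like(grid)
    np.add.at(impulse, idx[idx < len(grid)], 1.0)
    return lfilter([1.0], [1.0, -decay], impulse)


def latent_channels(
    session: BehavioralSession,
    locomotion: LocomotionTrace,
    grid: np.ndarray,
    belief_noise: AR1BeliefNoise | None = None,
    reward_filter_width: float = 5.0,
) -> dict:
    """Z-scored latent channel time series on ``grid``.

    wait_ramp: seconds since the last press (any box), the within-interval ramp;
    reward_ratio: box-1 filtered reward ratio, piecewise constant between presses;
    press/reward/choice: 200-300 ms causal kernels after the matching events;
    locomotion: interpolated speed; belief: the AR(1) subjective-belief latent.
    """
    t = session.times
    last_press = np.full(len(grid), 0.0)
    idx = np.searchsorted(t, grid, side="right") - 1
    has_prev = idx >= 0
    last_press[has_prev] = t[idx[has_prev]]
    wait = grid - last_press

    # current option's share of recently delivered rewards, carried forward
    # from the most recent press (jumps at presses, constant between them)
    rr = _filtered_reward_ratio(session.boxes, session.rewarded,
                                HalfGaussianFilter(reward_filter_width))
    rr_trace = np.full(len(grid), 0.5)
    rr_trace[has_prev] = rr[idx[has_prev]]

    switch_presses = t[1:][session.boxes[1:] != session.boxes[:-1]]
    ch = {
        "wait_ramp": wait,
        "reward_ratio": rr_trace,
        "press": _event_kernel(grid, t, tau=0.2),
        "reward": _event_kernel(grid, t[session.rewarded], tau=0.3),
        "choice": _event_kernel(grid, switch_presses, tau=0.2),
        "locomotion": locomotion.speed_at(grid),
        "belief": belief_noise.series(grid) if belief_noise is not None
                  else np.zeros(len(grid)),
    }
    return {k: _zscore(v) for k, v in ch.items()}


def generate_population(
    session: BehavioralSession,
    locomotion: LocomotionTrace,
    spec: EncodingSpec,
    rng: np.random.Generator,
    belief_noise: AR1BeliefNoise | None = None,
) -> tuple[SpikeTrainSet, GroundTruth]:
    """Inhomogeneous-Poisson population with mixed selectivity.

    Unit k's rate is ``softplus(b_k + sum_c w_kc z_c(t) + eta_k(t))`` on a
    10 ms grid, where the waiting-time channel is encoded *subjectively*:
    the belief latent rides on the wait weight with gain ``belief_coupling``.
    Spikes are Poisson counts per bin, uniformly jittered within the bin.
    """
    t_stop = float(session.times[-1] + 2.0) if len(session) else 2.0
    grid = np.arange(0.0, t_stop, spec.sim_dt)
    ch = latent_channels(session, locomotion, grid, belief_noise)
    names = list(CHANNELS)
    Z = np.stack([ch[c] for c in names], axis=0)  # (C, T)

    n = spec.n_units
    baselines = rng.uniform(*spec.baseline_range, size=n)
    W = np.stack([
        rng.normal(0.0, spec.weight_scales.get(c, 0.0), size=n) for c in names
    ], axis=1)  # (n, C)
    # subjective waiting time: belief noise rides on the wait weight
    i_wait, i_belief = names.index("wait_ramp"), names.index("belief")
    W[:, i_belief] += spec.belief_coupling * W[:, i_wait]

    drive = W @ Z  # (n, T)
    if spec.private_noise_sd > 0:
        rho = np.exp(-spec.sim_dt / spec.private_noise_tau)
        innov = rng.normal(0.0, np.sqrt(1 - rho**2), size=drive.shape)
        innov[:, 0] = rng.normal(0.0, 1.0, size=drive.shape[0])
        eta = lfilter([1.0], [1.0, -rho], innov, axis=1)
        drive += spec.private_noise_sd * eta
    rates = _softplus(_softplus_inv(baselines)[:, None] + drive)

    spikes = []
    for k in range(n):
        counts = rng.poisson(rates[k] * spec.sim_dt)
        reps = np.repeat(grid, counts)
        st = reps + rng.uniform(0.0, spec.sim_dt, size=len(reps))
        spikes.append(np.sort(np.minimum(st, t_stop)))
    gt = GroundTruth(grid=grid, channels=ch, weights=W,
                     baselines=baselines, channel_names=tuple(names))
    return SpikeTrainSet(spike_times=spikes, t_stop=t_stop), gt


@dataclass(frozen=True)
class DatasetConfig:
    """Everything needed to regenerate a session bundle (with a seed)."""

    agent: str = "mvt"  # or "threshold"
    schedule_pairs: tuple = ((20.0, 40.0), (40.0, 20.0), (15.0, 25.0), (25.0, 15.0))
    n_rewards_per_block: int = 34
    dt: float = 0.01
    encoding: EncodingSpec = field(default_factory=EncodingSpec)
    belief_noise_sd: float = 0.35
    belief_noise_tau: float = 10.0
    # recording-session default: a cheaper switch so sessions contain enough
    # stay/switch events for choice analyses
    agent_params: MVTAgentParams | ThresholdAgentParams | None = field(
        default_factory=lambda: MVTAgentParams(switching_cost=0.3,
                                               switch_noise_sd=0.15))

    def schedule(self) -> VISchedule:
        return VISchedule.from_pairs(self.schedule_pairs,
                                     n_rewards=self.n_rewards_per_block, dt=self.dt)


def belief_noise_bundle_config(n_units: int = 60) -> DatasetConfig:
    """The belief-noise study condition for choice/reward prediction analyses.

    Long balanced sessions (VI 20/20 and 30/30 blocks, 200 rewards) with a
    strong subjective-belief latent: the wait-ramp encoding is weakened and
    the belief coupling raised so that the agent's subjective (noisy) waiting
    estimate — not the objective wait — dominates the population's
    choice-relevant variability, and a high switching cost keeps arrival
    presses rare.  Under these conditions the true task variables predict the
    reward best while neural components carry the extra choice information.
    """
    scales = {"wait_ramp": 0.45, "reward_ratio": 0.7, "press": 1.0,
              "reward": 1.0, "choice": 0.6, "locomotion": 0.8, "belief": 0.15}
    return DatasetConfig(
        schedule_pairs=((20.0, 20.0), (30.0, 30.0), (20.0, 20.0), (30.0, 30.0)),
        n_rewards_per_block=50,
        belief_noise_sd=0.4,
        encoding=EncodingSpec(n_units=n_units, belief_coupling=1.8,
                              weight_scales=scales),
        agent_params=MVTAgentParams(switching_cost=0.75, switch_noise_sd=0.15,
                                    belief_timing_gain=0.8, patience_gain=0.0),
    )


@dataclass
class SessionBundle:
    """One full synthetic dataset."""

    config: DatasetConfig
    seed: int
    session: BehavioralSession
    locomotion: LocomotionTrace
    spikes: SpikeTrainSet
    ground_truth: GroundTruth
    belief_noise: AR1BeliefNoise | None


def generate_dataset(config: DatasetConfig, seed: int) -> SessionBundle:
    """Generate behavior + locomotion + population from (config, seed).

    Fully reproducible: all randomness flows from named child streams of the
    root seed.  A missing seed is refused (reproducibility contract).
    """
    if seed is None:
        raise ValueError("a seed is required for reproducible generation")
    ss = np.random.SeedSequence(int(seed))
    r_agent, r_belief, r_loco, r_pop = [np.random.default_rng(s)
                                        for s in ss.spawn(4)]
    schedule = config.schedule()
    belief = None
    if config.agent == "mvt":
        if config.belief_noise_sd > 0:
            belief = AR1BeliefNoise(r_belief, tau=config.belief_noise_tau,
                                    sd=config.belief_noise_sd)
        params = config.agent_params or MVTAgentParams()
        session = run_mvt_agent(params, schedule, r_agent, belief_noise=belief)
    elif config.agent == "threshold":
        params = config.agent_params or ThresholdAgentParams()
        session = run_threshold_agent(params, schedule, r_agent)
    else:
        raise ValueError(f"unknown agent {config.agent!r}")
    locomotion = generate_locomotion(session, r_loco)
    if config.encoding.n_units > 0:
        spikes, gt = generate_population(session, locomotion, config.encoding,
                                         r_pop, belief_noise=belief)
    else:
        grid = np.arange(0.0, session.times[-1] + 2.0, config.encoding.sim_dt)
        spikes = SpikeTrainSet(spike_times=[], t_stop=float(grid[-1]))
        gt = GroundTruth(grid=grid,
                         channels=latent_channels(session, locomotion, grid, belief),
                         weights=np.empty((0, len(CHANNELS))),
                         baselines=np.empty(0))
    return SessionBundle(config=config, seed=int(seed), session=session,
                         locomotion=locomotion, spikes=spikes,
                         ground_truth=gt, belief_noise=belief)
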