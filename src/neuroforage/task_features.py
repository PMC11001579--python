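"""Basis-expanded task design matrix on the continuous time grid.

Six task variables become 51 predictor columns:

* press events:   7 pre-press tiles on [-1.4, 0) + 7 post-press on [0, 1.4)
* choice events:  7 post-choice tiles on [0, 1.4)   (switch presses)
* reward events: 10 post-reward tiles on [0, 2.0)
* waiting time:   5 monomials, powers {0.5, 1, 2, 3, 5}
* reward ratio:   5 monomials
* 2-D location:   5 monomials per coordinate (10 columns)

Event tiles are 200 ms boxcars at fixed offsets: column j is the indicator
that the nearest relevant event sits in offset tile j.  Continuous traces are
rescaled to [0, 1] per session before the powers are applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .behavior_analysis import HalfGaussianFilter, _filtered_reward_ratio
from .neural_preprocess import RateGrid
from .synthetic_data import LocomotionTrace
from .task_model import BehavioralSession

__all__ = [
    "POWERS",
    "FeatureMatrix",
    "event_basis",
    "power_basis",
    "build_feature_matrix",
    "reward_predictor_features",
]

POWERS = (0.5, 1.0, 2.0, 3.0, 5.0)
TILE = 0.2  # s, boxcar width of the event delay tiles


@dataclass
class FeatureMatrix:
    """time-bin x column design matrix with per-column metadata."""

    X: np.ndarray  # (n_bins, n_columns), unstandardized
    grid: RateGrid
    mask: np.ndarray  # engagement mask per bin
    columns: pd.DataFrame  # variable, kind, index, detail

    def __post_init__(self) -> None:
        if self.X.shape != (self.grid.n_bins, len(self.columns)):
            raise ValueError("X shape must be (n_bins, n_columns)")

    @property
    def n_columns(self) -> int:
        return self.X.shape[1]

    def standardized(self) -> np.ndarray:
        """Columns z-scored over masked-in bins (constant columns -> zero)."""
        Xm = self.X[self.mask]
        mu = Xm.mean(axis=0)
        sd = Xm.std(axis=0)
        sd[sd == 0] = 1.0
        return (Xm - mu) / sd

    def column_groups(self) -> dict:
        return {v: np.flatnonzero((self.columns["variable"] == v).to_numpy())
                for v in self.columns["variable"].unique()}


def event_basis(event_times: np.ndarray, n_basis: int, window: tuple,
                grid: RateGrid) -> np.ndarray:
    """Offset-tile indicator columns for one event stream.

    ``window = (lo, hi)`` must span ``n_basis`` contiguous 200 ms tiles and
    lie entirely before (hi <= 0) or after (lo >= 0) the event.  Column j is
    1 at bins whose offset from the nearest relevant event — the next event
    for pre-event windows, the most recent for post-event windows — falls in
    tile j; tiles therefore partition the window and at most one column is
    active per bin.
    """
    lo, hi = window
    if n_basis < 1:
        raise ValueError("n_basis must be >= 1")
    if not np.isclose(hi - lo, n_basis * TILE):
        raise ValueError("window must span n_basis contiguous 200 ms tiles")
    if not (hi <= 1e-9 or lo >= -1e-9):
        raise ValueError("window must be entirely pre- or post-event")
    event_times = np.sort(np.asarray(event_times, dtype=float))
    out = np.zeros((grid.n_bins, n_basis))
    if len(event_times) == 0:
        return out
    centers = grid.centers
    if hi <= 1e-9:  # pre-event: offset to the next event
        i = np.searchsorted(event_times, centers, side="left")
        valid = i < len(event_times)
        offset = np.full(len(centers), np.nan)
        offset[valid] = centers[valid] - event_times[np.minimum(i, len(event_times) - 1)][valid]
    else:  # post-event: offset to the most recent event
        i = np.searchsorted(event_times, centers, side="right") - 1
        valid = i >= 0
        offset = np.full(len(centers), np.nan)
        offset[valid] = centers[valid] - event_times[np.maximum(i, 0)][valid]
    tile = np.floor((offset - lo) / TILE)
    inside = valid & (offset >= lo) & (offset < hi)
    j = tile[inside].astype(int)
    out[np.flatnonzero(inside), j] = 1.0
    return out


def power_basis(trace: np.ndarray, powers=POWERS) -> np.ndarray:
    """Instantaneous monomials ``trace**a`` for each power.

    The trace must be nonnegative (fractional powers); rescaling to [0, 1] is
    the caller's responsibility.
    """
    trace = np.asarray(trace, dtype=float)
    if np.any(trace < 0):
        raise ValueError("power basis input must be nonnegative; "
                         "rescale the trace to [0, 1] first")
    return np.column_stack([trace**a for a in powers])


def _rescale01(x: np.ndarray) -> np.ndarray:
    rng_ = np.ptp(x)
    return (x - x.min()) / rng_ if rng_ > 0 else np.zeros_like(x)


def build_feature_matrix(
    session: BehavioralSession,
    locomotion: LocomotionTrace | None,
    grid: RateGrid,
    mask: np.ndarray,
    reward_filter_width: float = 5.0,
) -> FeatureMatrix:
    """Assemble the 51-column design matrix on ``grid``.

    The waiting-time channel resets to 0 at each press and ramps linearly;
    the reward-ratio channel (box-1 share of causally filtered rewards) is
    piecewise constant, jumping at presses.  A missing locomotion trace fills
    the location columns with the session-mean position (flagged in the
    column metadata).
    """
    t = session.times
    centers = grid.centers
    blocks: list[np.ndarray] = []
    meta: list[dict] = []

    def add(cols: np.ndarray, variable: str, kind: str, details) -> None:
        for j in range(cols.shape[1]):
            meta.append({"variable": variable, "kind": kind, "index": j,
                         "detail": details[j]})
        blocks.append(cols)

    switch_times = t[1:][session.boxes[1:] != session.boxes[:-1]]
    reward_times = t[session.rewarded]

    pre = event_basis(t, 7, (-1.4, 0.0), grid)
    add(pre, "press", "pre_tile", [f"[{-1.4 + TILE * j:.1f},{-1.4 + TILE * (j + 1):.1f})" for j in range(7)])
    post = event_basis(t, 7, (0.0, 1.4), grid)
    add(post, "press", "post_tile", [f"[{TILE * j:.1f},{TILE * (j + 1):.1f})" for j in range(7)])
    cho = event_basis(switch_times, 7, (0.0, 1.4), grid)
    add(cho, "choice", "post_tile", [f"[{TILE * j:.1f},{TILE * (j + 1):.1f})" for j in range(7)])
    rew = event_basis(reward_times, 10, (0.0, 2.0), grid)
    add(rew, "reward", "post_tile", [f"[{TILE * j:.1f},{TILE * (j + 1):.1f})" for j in range(10)])

    # waiting time: linear ramp since the last press (session start before it)
    idx = np.searchsorted(t, centers, side="right") - 1
    last = np.where(idx >= 0, t[np.maximum(idx, 0)], 0.0)
    wait = centers - last
    add(power_basis(_rescale01(wait)), "waiting_time", "power",
        [str(a) for a in POWERS])

    # current option's share of recent rewards, carried forward from the
    # most recent press (piecewise constant, jumping at presses)
    rr = _filtered_reward_ratio(session.boxes, session.rewarded,
                                HalfGaussianFilter(reward_filter_width))
    rr_trace = np.full(len(centers), 0.5)
    has_prev = idx >= 0
    rr_trace[has_prev] = rr[np.maximum(idx, 0)][has_prev]
    add(power_basis(_rescale01(rr_trace)), "reward_ratio", "power",
        [str(a) for a in POWERS])

    if locomotion is not None:
        pos = locomotion.position_at(centers)
    else:
        import warnings

        warnings.warn("no locomotion trace: location columns filled with the "
                      "session-mean position", stacklevel=2)
        pos = np.zeros((len(centers), 2))
    add(power_basis(_rescale01(pos[:, 0])), "location_x", "power",
        [str(a) for a in POWERS])
    add(power_basis(_rescale01(pos[:, 1])), "location_y", "power",
        [str(a) for a in POWERS])

    X = np.column_stack(blocks)
    return FeatureMatrix(X=X, grid=grid, mask=np.asarray(mask, bool),
                         columns=pd.DataFrame(meta))


def reward_predictor_features(session: BehavioralSession,
                              grid: RateGrid) -> np.ndarray:
    """10-D reward-predictor design: waiting time and the scheduled reward
    rate of the current box, each through the five power bases.

    The waiting-time channel ramps since the last press; the rate channel is
    1/VI of the most recently pressed box, piecewise constant within blocks.
    This is the task-side space used for the time-resolved reward/choice/wait
    predictions.
    """
    t = session.times
    centers = grid.centers
    idx = np.searchsorted(t, centers, side="right") - 1
    last = np.where(idx >= 0, t[np.maximum(idx, 0)], 0.0)
    wait = centers - last
    rate = np.full(len(centers), np.nan)
    rates_per_press = np.array([session.scheduled_rate_of_press(i)
                                for i in range(len(session))])
    has_prev = idx >= 0
    rate[has_prev] = rates_per_press[np.maximum(idx, 0)][has_prev]
    rate[~has_prev] = rates_per_press[0] if len(rates_per_press) else 0.0
    return np.column_stack([
        power_basis(_rescale01(wait)),
        power_basis(_rescale01(rate)),
    ])
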