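"""Reward predictors and press-level behavioral analyses.

Builds a per-press table of reward predictors — waiting time, causally
filtered reward ratio, the (hidden) probability of reward availability and the
scheduled reward rate — then quantifies how well each predicts the next reward
(equal-occupancy binning + Pearson correlation) and how reward outcomes
reshape the next waiting time and the probability of switching boxes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .metrics import auc
from .task_model import BehavioralSession, prob_reward_available

__all__ = [
    "HalfGaussianFilter",
    "BinnedStat",
    "build_press_table",
    "tune_filter_width",
    "bin_and_correlate",
    "conditional_wait_analysis",
    "switch_probability",
    "WAIT_CATEGORY_PRESET",
]

#: Explicit short/medium/long wait bounds (s) usable instead of terciles.
WAIT_CATEGORY_PRESET = ((3.0, 5.0), (5.0, 8.0), (8.0, 60.0))


@dataclass(frozen=True)
class HalfGaussianFilter:
    """Causal half-Gaussian over the press-indexed reward sequence.

    ``width`` is the standard deviation in units of presses.  Weight on the
    press ``lag`` steps back (lag >= 1, the press immediately preceding the
    current one has lag 1) is ``exp(-(lag-1)^2 / (2 width^2))``; future
    presses and the current press get zero weight.  Weights are normalized to
    sum to 1 over the available history.
    """

    width: float = 5.0

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("filter width must be positive")

    def weights(self, n_history: int) -> np.ndarray:
        """Normalized weights for lags 1..n_history (most recent first)."""
        if n_history <= 0:
            return np.empty(0)
        lags = np.arange(n_history)
        w = np.exp(-(lags**2) / (2.0 * self.width**2))
        return w / w.sum()


def _filtered_reward_ratio(boxes: np.ndarray, rewarded: np.ndarray,
                           filt: HalfGaussianFilter) -> np.ndarray:
    """Per press: filtered rewards of the pressed box / filtered rewards of both.

    History strictly precedes the current press; an empty filtered denominator
    (no rewards delivered yet) maps to the uninformative value 0.5.
    """
    n = len(boxes)
    out = np.full(n, 0.5)
    kernel = np.exp(-(np.arange(n) ** 2) / (2.0 * filt.width**2))
    rew = rewarded.astype(float)
    for i in range(n):
        if i == 0:
            continue
        w = kernel[:i]  # lag 1..i, most recent first
        r_hist = rew[i - 1 :: -1][:i]
        b_hist = boxes[i - 1 :: -1][:i]
        denom = float(np.dot(w, r_hist))
        if denom > 0:
            numer = float(np.dot(w, r_hist * (b_hist == boxes[i])))
            out[i] = numer / denom
    return out


def build_press_table(
    session: BehavioralSession,
    filt: HalfGaussianFilter | float = 5.0,
    max_wait: float = 60.0,
    drop_excluded: bool = True,
) -> pd.DataFrame:
    """Per-press reward predictors and next-choice bookkeeping.

    Columns: time_s, box, rewarded, block_index, waiting_time (s since the
    preceding press on either box), log_waiting_time (natural log),
    reward_ratio, prob_avail (oracle, from the schedule and the time since the
    preceding same-box press), scheduled_rate (rewards/s of the pressed box),
    scheduled_ratio, choice ('stay'/'switch', location of the next press) and
    next_waiting_time.  Presses with waiting_time > ``max_wait`` (and the
    first press, whose wait is undefined) are dropped when ``drop_excluded``.
    """
    if isinstance(filt, (int, float)):
        filt = HalfGaussianFilter(float(filt))
    n = len(session)
    if n < 2:
        raise ValueError("press table needs at least two presses")
    t, boxes, rew = session.times, session.boxes, session.rewarded

    waiting = np.full(n, np.nan)
    waiting[1:] = np.diff(t)

    # time since the preceding press on the same box (session start for first)
    t_same = np.full(n, np.nan)
    last = {1: 0.0, 2: 0.0}
    for i in range(n):
        b = int(boxes[i])
        t_same[i] = t[i] - last[b]
        last[b] = t[i]

    vi = np.array([session.vi_of_press(i) for i in range(n)])
    prob_avail = prob_reward_available(t_same, vi, session.schedule.dt)
    sched_rate = 1.0 / vi
    vi_other = np.array(
        [session.schedule.blocks[session.block_index[i]].vi(3 - int(boxes[i]))
         for i in range(n)]
    )
    sched_ratio = sched_rate / (sched_rate + 1.0 / vi_other)

    choice = np.where(boxes[1:] != boxes[:-1], "switch", "stay")
    table = pd.DataFrame(
        {
            "time_s": t,
            "box": boxes,
            "rewarded": rew,
            "block_index": session.block_index,
            "waiting_time": waiting,
            "log_waiting_time": np.log(waiting, where=waiting > 0,
                                       out=np.full(n, np.nan)),
            "reward_ratio": _filtered_reward_ratio(boxes, rew, filt),
            "prob_avail": prob_avail,
            "scheduled_rate": sched_rate,
            "scheduled_ratio": sched_ratio,
            "choice": np.append(choice, [None]),
            "next_waiting_time": np.append(waiting[1:], np.nan),
        }
    )
    if drop_excluded:
        table = table[(table["waiting_time"] > 0) & (table["waiting_time"] <= max_wait)]
        table = table.reset_index(drop=True)
    return table


def tune_filter_width(
    sessions: list[BehavioralSession] | BehavioralSession,
    candidate_widths=(1, 2, 3, 5, 8, 12, 20),
) -> float:
    """Width (presses) maximizing pooled r(observed reward ratio, scheduled ratio).

    Ties go to the smallest width.  Raises if the scheduled ratio is constant
    across the pooled presses (the correlation is then undefined).
    """
    if isinstance(sessions, BehavioralSession):
        sessions = [sessions]
    widths = sorted(float(w) for w in candidate_widths)
    best_w, best_r = None, -np.inf
    for w in widths:
        obs, sched = [], []
        for sess in sessions:
            tab = build_press_table(sess, HalfGaussianFilter(w))
            obs.append(tab["reward_ratio"].to_numpy())
            sched.append(tab["scheduled_ratio"].to_numpy())
        obs = np.concatenate(obs)
        sched = np.concatenate(sched)
        if np.ptp(sched) == 0:
            raise ValueError("scheduled reward ratio is constant; "
                             "correlation undefined — use >=2 schedule conditions")
        r = float(np.corrcoef(obs, sched)[0, 1])
        if r > best_r:  # strict: ties keep the earlier (smaller) width
            best_w, best_r = w, r
    return best_w


@dataclass
class BinnedStat:
    """Equal-occupancy binning of presses along one predictor."""

    predictor: str
    bin_means: np.ndarray
    rewarded_fraction: np.ndarray
    bin_sizes: np.ndarray
    pearson_r: float


def bin_and_correlate(table: pd.DataFrame, predictor: str,
                      bin_size: int = 50) -> BinnedStat:
    """Sort presses by ``predictor``, chunk into ``bin_size``-press bins, and
    correlate the per-bin mean predictor with the per-bin rewarded fraction."""
    sub = table.dropna(subset=[predictor])
    if len(sub) < 2 * bin_size:
        raise ValueError(f"need at least {2 * bin_size} presses for >=2 bins")
    order = np.argsort(sub[predictor].to_numpy(), kind="stable")
    x = sub[predictor].to_numpy()[order]
    y = sub["rewarded"].to_numpy()[order].astype(float)
    edges = np.arange(0, len(x) + bin_size, bin_size)
    edges[-1] = len(x)
    if edges[-1] - edges[-2] == 0:
        edges = edges[:-1]
    means = np.array([x[a:b].mean() for a, b in zip(edges[:-1], edges[1:])])
    frac = np.array([y[a:b].mean() for a, b in zip(edges[:-1], edges[1:])])
    sizes = np.diff(edges)
    r = float(np.corrcoef(means, frac)[0, 1])
    return BinnedStat(predictor=predictor, bin_means=means,
                      rewarded_fraction=frac, bin_sizes=sizes, pearson_r=r)


def _categorize(values: np.ndarray, bounds) -> np.ndarray:
    """Category index per value, or -1 outside all bounds."""
    cat = np.full(len(values), -1)
    for j, (lo, hi) in enumerate(bounds):
        cat[(values >= lo) & (values <= hi) & (cat == -1)] = j
    return cat


def _tercile_bounds(values: np.ndarray) -> tuple[tuple[float, float], ...]:
    qs = np.quantile(values, [0, 1 / 3, 2 / 3, 1])
    return tuple((float(qs[i]), float(qs[i + 1])) for i in range(3))


def conditional_wait_analysis(
    table: pd.DataFrame,
    variable: str = "waiting_time",
    bounds=None,
    max_next_wait: float = 60.0,
) -> pd.DataFrame:
    """Effect of the reward outcome on the next waiting time, per category.

    Categories of ``variable`` (waiting_time or reward_ratio) come from
    terciles of the valid presses unless explicit ``bounds`` are given.  Per
    category the output row holds the rewarded/unrewarded next-wait means, the
    percent increase of the unrewarded mean over the rewarded one, and the AUC
    discriminating unrewarded from rewarded presses by their next wait.
    Categories missing either outcome are flagged (``valid = False``).
    """
    sub = table.dropna(subset=[variable, "next_waiting_time"])
    sub = sub[sub["next_waiting_time"] <= max_next_wait]
    vals = sub[variable].to_numpy()
    if bounds is None:
        bounds = _tercile_bounds(vals)
    cat = _categorize(vals, bounds)
    rows = []
    for j, (lo, hi) in enumerate(bounds):
        m = cat == j
        nw = sub["next_waiting_time"].to_numpy()[m]
        rw = sub["rewarded"].to_numpy()[m].astype(bool)
        row = {"category": j, "lo": lo, "hi": hi,
               "n_rewarded": int(rw.sum()), "n_unrewarded": int((~rw).sum())}
        if rw.sum() and (~rw).sum():
            mean_r, mean_u = float(nw[rw].mean()), float(nw[~rw].mean())
            row.update(
                mean_next_wait_rewarded=mean_r,
                mean_next_wait_unrewarded=mean_u,
                percent_change=100.0 * (mean_u - mean_r) / mean_r,
                auc=auc(nw, ~rw),
                valid=True,
            )
        else:
            row.update(mean_next_wait_rewarded=np.nan,
                       mean_next_wait_unrewarded=np.nan,
                       percent_change=np.nan, auc=np.nan, valid=False)
        rows.append(row)
    return pd.DataFrame(rows)


def switch_probability(
    table: pd.DataFrame,
    variable: str = "waiting_time",
    bounds=None,
) -> pd.DataFrame:
    """Per category: P(switch | unrewarded), P(switch | rewarded), and their
    difference (the extra switching induced by a denied reward)."""
    sub = table.dropna(subset=[variable, "choice"])
    vals = sub[variable].to_numpy()
    if bounds is None:
        bounds = _tercile_bounds(vals)
    cat = _categorize(vals, bounds)
    sw = (sub["choice"] == "switch").to_numpy()
    rw = sub["rewarded"].to_numpy().astype(bool)
    rows = []
    for j, (lo, hi) in enumerate(bounds):
        m = cat == j
        n_u, n_r = int((m & ~rw).sum()), int((m & rw).sum())
        p_u = float(sw[m & ~rw].mean()) if n_u else np.nan
        p_r = float(sw[m & rw].mean()) if n_r else np.nan
        rows.append({
            "category": j, "lo": lo, "hi": hi,
            "n_unrewarded": n_u, "n_rewarded": n_r,
            "p_switch_unrewarded": p_u, "p_switch_rewarded": p_r,
            "switch_increase": p_u - p_r if n_u and n_r else np.nan,
            "valid": bool(n_u and n_r),
        })
    return pd.DataFrame(rows)
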