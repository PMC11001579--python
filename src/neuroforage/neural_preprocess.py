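"""Spike trains -> analysis-ready rate matrices; locomotion confound removal.

Continuous rates are spike counts on a uniform grid divided by the bin width
and boxcar-smoothed with a 1 s sliding window.  Analysis is restricted to
engaged time (bins within 5 s of a press).  The locomotion confound is
removed per unit by subtracting the orthogonal projection of the rate onto
the locomotion-speed time series L:  r_perp = r - Pi r with
Pi = L (L^T L)^{-1} L^T.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d
from sklearn.base import BaseEstimator, TransformerMixin

from .synthetic_data import LocomotionTrace, SpikeTrainSet

__all__ = [
    "RateGrid",
    "RateMatrix",
    "PressLockedTensor",
    "bin_and_smooth",
    "press_locked",
    "engagement_mask",
    "LocomotionProjector",
    "remove_locomotion",
]

PRE_PRESS_WINDOW = (-1.1, -0.1)  # s, spike-count window for press decoding


@dataclass(frozen=True)
class RateGrid:
    """Uniform half-open time bins [start + i*step, start + i*step + width)."""

    start: float
    step: float
    n_bins: int
    width: float | None = None  # defaults to step (contiguous bins)

    def __post_init__(self) -> None:
        if self.step <= 0 or self.n_bins <= 0:
            raise ValueError("step and n_bins must be positive")
        if self.width is None:
            object.__setattr__(self, "width", self.step)

    @property
    def starts(self) -> np.ndarray:
        return self.start + self.step * np.arange(self.n_bins)

    @property
    def centers(self) -> np.ndarray:
        return self.starts + self.width / 2

    @classmethod
    def covering(cls, t_stop: float, step: float = 0.2,
                 start: float = 0.0) -> "RateGrid":
        n = int(np.ceil((t_stop - start) / step))
        return cls(start=start, step=step, n_bins=max(n, 1))


@dataclass
class RateMatrix:
    """units x time-bins rate matrix with its grid and engagement mask."""

    rates: np.ndarray  # (n_units, n_bins), spikes/s
    grid: RateGrid
    mask: np.ndarray | None = None  # bool per bin; None = all engaged

    def __post_init__(self) -> None:
        if self.rates.ndim != 2 or self.rates.shape[1] != self.grid.n_bins:
            raise ValueError("rates must be (n_units, grid.n_bins)")
        if self.mask is not None and len(self.mask) != self.grid.n_bins:
            raise ValueError("mask length must equal the number of bins")

    @property
    def n_units(self) -> int:
        return self.rates.shape[0]

    def masked(self) -> np.ndarray:
        """Rates restricted to engaged bins, (n_units, n_engaged)."""
        if self.mask is None:
            return self.rates
        return self.rates[:, self.mask]


@dataclass
class PressLockedTensor:
    """press x offset-bin x unit rates aligned to press times."""

    rates: np.ndarray  # (n_presses, n_offsets, n_units)
    offsets: np.ndarray  # bin start offsets relative to press time (s)
    press_index: np.ndarray  # indices into the session's press list
    window: tuple
    bin_width: float


def bin_and_smooth(spikes: SpikeTrainSet, grid: RateGrid,
                   smooth_window: float = 1.0) -> RateMatrix:
    """Counts per bin / width, boxcar-smoothed over ``smooth_window`` seconds.

    An empty unit yields an all-zero row.  Smoothing preserves the mean rate
    in the interior (boxcar weights sum to one).
    """
    edges = np.append(grid.starts, grid.starts[-1] + grid.step)
    rates = np.empty((spikes.n_units, grid.n_bins))
    for k, st in enumerate(spikes.spike_times):
        counts, _ = np.histogram(st, bins=edges)
        rates[k] = counts / grid.step
    if smooth_window and smooth_window > grid.step:
        size = max(int(round(smooth_window / grid.step)), 1)
        rates = uniform_filter1d(rates, size=size, axis=1, mode="nearest")
    return RateMatrix(rates=rates, grid=grid)


def press_locked(
    spikes: SpikeTrainSet,
    press_times: np.ndarray,
    window: tuple = (-2.0, 1.0),
    step: float = 0.2,
    min_gap: float = 2.0,
) -> PressLockedTensor:
    """Rates in ``step``-wide bins at fixed offsets around each press.

    Presses made less than ``min_gap`` s after the previous press are
    excluded, as are presses whose window leaves the session span.
    """
    press_times = np.asarray(press_times, dtype=float)
    gaps = np.diff(press_times, prepend=-np.inf)
    keep = gaps >= min_gap
    lo, hi = window
    edge_ok = (press_times + lo >= 0) & (press_times + hi <= spikes.t_stop)
    dropped_edge = keep & ~edge_ok
    if dropped_edge.any():
        import warnings

        warnings.warn(f"{int(dropped_edge.sum())} presses too close to the "
                      "session edge were dropped", stacklevel=2)
    keep &= edge_ok
    idx = np.flatnonzero(keep)
    offsets = lo + step * np.arange(int(round((hi - lo) / step)))
    tensor = np.empty((len(idx), len(offsets), spikes.n_units))
    for k, st in enumerate(spikes.spike_times):
        for i, pi in enumerate(idx):
            t0 = press_times[pi] + offsets
            counts = np.searchsorted(st, t0 + step) - np.searchsorted(st, t0)
            tensor[i, :, k] = counts / step
    return PressLockedTensor(rates=tensor, offsets=offsets, press_index=idx,
                             window=tuple(window), bin_width=step)


def engagement_mask(press_times: np.ndarray, grid: RateGrid,
                    max_gap: float = 5.0) -> np.ndarray:
    """Bin included iff its center is within ``max_gap`` s of some press."""
    press_times = np.sort(np.asarray(press_times, dtype=float))
    if len(press_times) == 0:
        raise ValueError("engagement mask needs at least one press")
    centers = grid.centers
    i = np.searchsorted(press_times, centers)
    d_next = np.where(i < len(press_times), press_times[np.minimum(i, len(press_times) - 1)] - centers, np.inf)
    d_prev = np.where(i > 0, centers - press_times[np.maximum(i - 1, 0)], np.inf)
    return np.minimum(np.abs(d_next), np.abs(d_prev)) <= max_gap


class LocomotionProjector(BaseEstimator, TransformerMixin):
    """Remove the locomotion-speed component from each unit's rate row.

    Builds the projector Pi = D (D^T D)^{-1} D^T from the locomotion speed
    and transforms rates to r - Pi r.  With ``with_intercept=True`` (default)
    the removed subspace is span{1, L}, which makes the residuals' *Pearson
    correlation* with L exactly zero (projecting off the raw speed vector
    alone only zeroes the inner product, not the mean-removed correlation);
    ``with_intercept=False`` applies the literal rank-1 formula on L.
    """

    def __init__(self, with_intercept: bool = True):
        self.with_intercept = with_intercept

    def fit(self, L: np.ndarray, y=None) -> "LocomotionProjector":
        L = np.asarray(L, dtype=float).ravel()
        if np.all(L == 0):
            import warnings

            warnings.warn("locomotion trace is identically zero; projection "
                          "is the identity", stacklevel=2)
            self.basis_ = np.zeros((len(L), 0))
            return self
        D = np.column_stack([np.ones_like(L), L]) if self.with_intercept \
            else L[:, None]
        # orthonormal basis of the removed subspace
        q, r = np.linalg.qr(D)
        keep = np.abs(np.diag(r)) > 1e-12 * max(np.abs(np.diag(r)).max(), 1.0)
        self.basis_ = q[:, keep]
        return self

    def transform(self, rates: np.ndarray) -> np.ndarray:
        if not hasattr(self, "basis_"):
            raise RuntimeError("projector must be fitted first")
        rates = np.asarray(rates, dtype=float)
        one_d = rates.ndim == 1
        rates = np.atleast_2d(rates)
        out = rates - (rates @ self.basis_) @ self.basis_.T
        return out[0] if one_d else out


def remove_locomotion(rates: RateMatrix, loco: LocomotionTrace,
                      with_intercept: bool = True) -> RateMatrix:
    """Project each unit's engaged-bin rates off the locomotion speed.

    The projector is fitted and applied on engaged bins only; masked-out bins
    are left untouched (they are excluded from all downstream analyses).
    Residual rows are exactly uncorrelated with the (optionally centered)
    speed and the operation is idempotent.
    """
    L = loco.speed_at(rates.grid.centers)
    m = rates.mask if rates.mask is not None else np.ones(rates.grid.n_bins, bool)
    proj = LocomotionProjector(with_intercept=with_intercept).fit(L[m])
    out = rates.rates.copy()
    out[:, m] = proj.transform(rates.rates[:, m])
    return RateMatrix(rates=out, grid=rates.grid, mask=rates.mask)
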