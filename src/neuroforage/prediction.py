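"""Time-resolved, cross-validated prediction of reward, choice and next wait.

Presses are grouped into contiguous CV blocks delimited by >30 s gaps in
press times; decoders are trained leave-one-block-out, separately for every
200 ms time bin from 3 s before to 1 s after the press.  Binary targets
(reward, stay/switch) use logistic regression scored by held-out AUC;
the next waiting time uses a log-link Gamma GLM scored by held-out Pearson r.
Three predictor families are compared on identical folds and time grids:
task canonical components, their neural counterparts, and the full
(locomotion-decorrelated) population.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.linear_model import LogisticRegression, Ridge

from .latent_cca import SparseCCA, _safe_corr
from .metrics import auc
from .neural_preprocess import RateMatrix

__all__ = [
    "PredictionResult",
    "make_blocks",
    "auc",
    "predict_binary",
    "predict_continuous",
    "compare_predictor_families",
    "neuron_dropping_curve",
]

DEFAULT_WINDOW = (-3.0, 1.0)
BIN_STEP = 0.2
PEAK_WINDOW = (-2.0, 0.0)  # peak = mean of the 5 best bins in the 2 s pre-press
N_PEAK_BINS = 5


def make_blocks(press_times: np.ndarray, gap: float = 30.0) -> np.ndarray:
    """CV block id per press: blocks are delimited by press gaps > ``gap`` s."""
    press_times = np.asarray(press_times, dtype=float)
    if len(press_times) == 0:
        raise ValueError("no presses")
    ids = np.concatenate([[0], np.cumsum(np.diff(press_times) > gap)])
    if ids[-1] == 0:
        raise ValueError("only one CV block; session too short or gaps too "
                         "small — need at least two >30 s gaps-delimited blocks")
    return ids


@dataclass
class PredictionResult:
    """Per-time-bin held-out decoding performance for one family and target."""

    family: str
    target: str
    metric: str  # 'auc' or 'pearson_r'
    offsets: np.ndarray  # bin start offsets relative to press (s)
    values: np.ndarray  # held-out metric per bin (NaN where undefined)

    @property
    def peak(self) -> float:
        """Mean of the ``N_PEAK_BINS`` best bins within the pre-press window."""
        m = (self.offsets >= PEAK_WINDOW[0]) & (self.offsets < PEAK_WINDOW[1])
        vals = np.sort(self.values[m & ~np.isnan(self.values)])[::-1]
        if len(vals) == 0:
            return np.nan
        return float(vals[:N_PEAK_BINS].mean())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"offset_s": self.offsets, "family": self.family,
                             "target": self.target, "metric": self.metric,
                             "value": self.values})


def _fit_logistic(Xtr, ytr):
    # ridge-stabilized: C = 1/(2*1e-6) ~ weak penalty for degenerate folds
    clf = LogisticRegression(C=1e4, max_iter=2000)
    clf.fit(Xtr, ytr)
    return clf


def predict_binary(
    features: np.ndarray,
    labels: np.ndarray,
    block_ids: np.ndarray,
    offsets: np.ndarray,
    family: str = "features",
    target: str = "binary",
) -> PredictionResult:
    """Held-out AUC per time bin, leave-one-block-out.

    ``features`` is (n_presses, n_offsets, n_feat); held-out scores are
    pooled across folds before a single AUC per bin.  Folds with a single
    class in training are skipped for that bin.
    """
    features = np.asarray(features, float)
    labels = np.asarray(labels).astype(bool)
    n, n_off, _ = features.shape
    values = np.full(n_off, np.nan)
    for j in range(n_off):
        scores, obs = [], []
        for f in np.unique(block_ids):
            tr = block_ids != f
            te = ~tr
            ytr = labels[tr]
            if ytr.all() or (~ytr).all() or te.sum() == 0:
                continue
            Xtr, Xte = features[tr, j, :], features[te, j, :]
            mu, sd = Xtr.mean(0), Xtr.std(0)
            sd[sd == 0] = 1.0
            clf = _fit_logistic((Xtr - mu) / sd, ytr)
            scores.append(clf.decision_function((Xte - mu) / sd))
            obs.append(labels[te])
        if scores:
            s = np.concatenate(scores)
            o = np.concatenate(obs)
            if o.any() and not o.all():
                values[j] = auc(s, o)
    return PredictionResult(family=family, target=target, metric="auc",
                            offsets=np.asarray(offsets), values=values)


def _fit_gamma_glm(Xtr, ytr, Xte):
    """Log-link Gamma GLM on a strictly positive target; ridge fallback."""
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.GLM(ytr, sm.add_constant(Xtr, has_constant="add"),
                           family=sm.families.Gamma(sm.families.links.Log()))
            res = model.fit(maxiter=100)
        if not np.all(np.isfinite(res.params)):
            raise ValueError("non-finite GLM fit")
        return res.predict(sm.add_constant(Xte, has_constant="add"))
    except Exception:
        r = Ridge(alpha=1e-6).fit(Xtr, np.log(ytr))
        return np.exp(r.predict(Xte))


def predict_continuous(
    features: np.ndarray,
    target_values: np.ndarray,
    block_ids: np.ndarray,
    offsets: np.ndarray,
    family: str = "features",
    target: str = "continuous",
    glm: bool = True,
) -> PredictionResult:
    """Held-out Pearson r per time bin for a positive continuous target.

    Uses a log-link Gamma GLM (``glm=True``) or ridge regression on the raw
    target.  Folds with a constant training target are skipped.
    """
    features = np.asarray(features, float)
    y = np.asarray(target_values, float)
    n, n_off, _ = features.shape
    values = np.full(n_off, np.nan)
    for j in range(n_off):
        preds, obs = [], []
        for f in np.unique(block_ids):
            tr = block_ids != f
            te = ~tr
            if np.ptp(y[tr]) == 0 or te.sum() == 0:
                continue
            Xtr, Xte = features[tr, j, :], features[te, j, :]
            mu, sd = Xtr.mean(0), Xtr.std(0)
            sd[sd == 0] = 1.0
            Xtr = (Xtr - mu) / sd
            Xte = (Xte - mu) / sd
            if glm and np.all(y[tr] > 0):
                yhat = _fit_gamma_glm(Xtr, y[tr], Xte)
            else:
                yhat = Ridge(alpha=1e-6).fit(Xtr, y[tr]).predict(Xte)
            preds.append(yhat)
            obs.append(y[te])
        if preds:
            values[j] = _safe_corr(np.concatenate(preds), np.concatenate(obs))
    return PredictionResult(family=family, target=target, metric="pearson_r",
                            offsets=np.asarray(offsets), values=values)


def _press_bin_features(M: np.ndarray, grid, press_times: np.ndarray,
                        offsets: np.ndarray) -> np.ndarray:
    """(n_presses, n_offsets, n_cols) rows of ``M`` at press-relative bins."""
    idx = np.floor(
        (press_times[:, None] + offsets[None, :] - grid.start) / grid.step
    ).astype(int)
    idx = np.clip(idx, 0, M.shape[0] - 1)
    return M[idx]


def compare_predictor_families(
    X_task: np.ndarray,
    rates: RateMatrix,
    press_times: np.ndarray,
    targets: dict,
    window: tuple = DEFAULT_WINDOW,
    step: float = BIN_STEP,
    n_components: int = 10,
    gap: float = 30.0,
    min_gap: float = 2.0,
) -> dict:
    """Paired comparison of the three predictor families.

    ``X_task`` is the (n_bins, p) reward-predictor design on ``rates.grid``
    (waiting-time + reward-ratio power columns); ``targets`` maps target
    names to per-press label arrays: 'reward'/'choice' boolean, 'next_wait'
    positive float (NaN to drop a press).  Canonical components are refit on
    the training blocks of every fold *without* sparsification, so the
    held-out block never touches the CCA; the same folds, presses and time
    bins are used for all three families.

    Returns {target: {family: PredictionResult}}.
    """
    press_times = np.asarray(press_times, float)
    grid = rates.grid
    mask = rates.mask if rates.mask is not None else np.ones(grid.n_bins, bool)
    keep = np.diff(press_times, prepend=-np.inf) >= min_gap
    lo, hi = window
    keep &= (press_times + lo >= grid.start)
    keep &= (press_times + hi <= grid.start + grid.step * grid.n_bins)
    p_idx = np.flatnonzero(keep)
    pt = press_times[p_idx]
    block_of_press = make_blocks(press_times, gap=gap)[p_idx]
    offsets = lo + step * np.arange(int(round((hi - lo) / step)))

    # assign every engaged bin to the block of its nearest press
    centers = grid.centers
    i_near = np.clip(np.searchsorted(press_times, centers), 1, len(press_times) - 1)
    d_next = np.abs(press_times[i_near] - centers)
    d_prev = np.abs(centers - press_times[i_near - 1])
    nearest = np.where(d_next < d_prev, i_near, i_near - 1)
    bin_block = make_blocks(press_times, gap=gap)[nearest]

    Y = rates.rates.T  # (n_bins, n_units)
    n_units = Y.shape[1]
    k_eff = min(n_components, X_task.shape[1], n_units)
    feats_full = _press_bin_features(Y, grid, pt, offsets)

    # Per-fold CCA projections for *all* presses: the model of fold f is
    # fitted on bins outside block f and supplies both the training and the
    # test features of fold f, so the held-out block never touches any fit.
    families = ("task_components", "neural_components", "full_population")
    fold_list = list(np.unique(block_of_press))
    proj = {}  # fold -> (feats_task, feats_neur)
    for f in fold_list:
        tr_bins = mask & (bin_block != f)
        model = SparseCCA(n_components=k_eff, fullness=1.0).fit(
            X_task[tr_bins], Y[tr_bins])
        tx, ty = model.transform(X_task, Y)
        proj[f] = (_press_bin_features(tx, grid, pt, offsets),
                   _press_bin_features(ty, grid, pt, offsets))

    results: dict = {t: {} for t in targets}
    for name, labels in targets.items():
        lab = np.asarray(labels, float)[p_idx]
        valid = np.isfinite(lab)
        binary = name in ("reward", "choice")
        for fam in families:
            n_off = len(offsets)
            values = np.full(n_off, np.nan)
            for j in range(n_off):
                out_scores, out_obs = [], []
                for f in fold_list:
                    tr = valid & (block_of_press != f)
                    te = valid & (block_of_press == f)
                    if te.sum() == 0:
                        continue
                    if fam == "full_population":
                        F = feats_full
                    else:
                        F = proj[f][0] if fam == "task_components" else proj[f][1]
                    Xtr, Xte = F[tr, j, :], F[te, j, :]
                    mu, sd = Xtr.mean(0), Xtr.std(0)
                    sd[sd == 0] = 1.0
                    Xtr = (Xtr - mu) / sd
                    Xte = (Xte - mu) / sd
                    if binary:
                        ytr = lab[tr].astype(bool)
                        if ytr.all() or (~ytr).all():
                            continue
                        clf = _fit_logistic(Xtr, ytr)
                        out_scores.append(clf.decision_function(Xte))
                    else:
                        ytr = lab[tr]
                        if np.ptp(ytr) == 0:
                            continue
                        if np.all(ytr > 0):
                            out_scores.append(_fit_gamma_glm(Xtr, ytr, Xte))
                        else:
                            out_scores.append(
                                Ridge(alpha=1e-6).fit(Xtr, ytr).predict(Xte))
                    out_obs.append(lab[te])
                if out_scores:
                    s = np.concatenate(out_scores)
                    o = np.concatenate(out_obs)
                    if binary:
                        ob = o.astype(bool)
                        if ob.any() and not ob.all():
                            values[j] = auc(s, ob)
                    else:
                        values[j] = _safe_corr(s, o)
            results[name][fam] = PredictionResult(
                family=fam, target=name,
                metric="auc" if binary else "pearson_r",
                offsets=np.asarray(offsets), values=values)
    return results


def neuron_dropping_curve(
    features: np.ndarray,
    target_values: np.ndarray,
    block_ids: np.ndarray,
    subset_sizes,
    rng: np.random.Generator,
    n_draws: int = 20,
) -> pd.DataFrame:
    """Decoding performance vs population size.

    ``features`` is (n_presses, n_units) — e.g. pre-press spike counts; for
    each subset size, ``n_draws`` random unit subsets are decoded with ridge
    regression (leave-one-block-out) and the held-out Pearson r summarized
    as mean +/- s.e.m.  Sizes above the population are truncated with a
    warning.
    """
    features = np.asarray(features, float)
    y = np.asarray(target_values, float)
    n_units = features.shape[1]
    rows = []
    for size in subset_sizes:
        if size > n_units:
            warnings.warn(f"subset size {size} > {n_units} units; truncated",
                          stacklevel=2)
            size = n_units
        draws = []
        n_d = 1 if size == n_units else n_draws
        for _ in range(n_d):
            cols = (np.arange(n_units) if size == n_units
                    else rng.choice(n_units, size=size, replace=False))
            preds, obs = [], []
            for f in np.unique(block_ids):
                tr = block_ids != f
                te = ~tr
                if np.ptp(y[tr]) == 0:
                    continue
                model = Ridge(alpha=1e-6).fit(features[tr][:, cols], y[tr])
                preds.append(model.predict(features[te][:, cols]))
                obs.append(y[te])
            draws.append(_safe_corr(np.concatenate(preds), np.concatenate(obs)))
        draws = np.asarray(draws)
        rows.append({"size": int(size), "mean_r": float(draws.mean()),
                     "sem_r": float(draws.std(ddof=1) / np.sqrt(len(draws)))
                     if len(draws) > 1 else 0.0,
                     "n_draws": len(draws)})
    return pd.DataFrame(rows)
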