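"""Sparse canonical correlation analysis between task and neural spaces.

The model finds paired directions (a_k, b_k) maximizing the correlation
between the projected task features X a_k and neural activity Y b_k.  After
whitening both spaces, components are extracted as a penalized rank-1 SVD of
the whitened cross-covariance with an l1 budget on the task-side weights
(penalized-matrix-decomposition style soft-thresholding), deflating the
cross-covariance after each component.  With the penalty released the
procedure reduces to classical CCA.

The "fullness" parameter f in [0, 1] maps to the l1 budget
c = 1 + f (sqrt(p) - 1), the natural range for a unit-l2 vector in R^p:
f = 1 leaves the weights unconstrained, small f forces few active columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.base import BaseEstimator

__all__ = [
    "SparseCCA",
    "fit_scca",
    "assign_components",
    "component_vs_single_unit",
    "cluster_neurons_by_reconstruction",
]


def _inv_sqrt(S: np.ndarray, rel_eps: float = 1e-12) -> np.ndarray:
    w, V = np.linalg.eigh(S)
    thr = rel_eps * w.max()
    w_inv = np.where(w > thr, 1.0 / np.sqrt(np.maximum(w, thr)), 0.0)
    return (V * w_inv) @ V.T


def _soft(x: np.ndarray, delta: float) -> np.ndarray:
    return np.sign(x) * np.maximum(np.abs(x) - delta, 0.0)


def _l1_project(x: np.ndarray, c: float) -> np.ndarray:
    """Unit-l2 vector proportional to soft(x, delta) with l1 norm <= c."""
    norm = np.linalg.norm(x)
    if norm == 0:
        return x
    u = x / norm
    if np.abs(u).sum() <= c:
        return u
    lo, hi = 0.0, np.abs(x).max()
    for _ in range(80):  # bisection on the threshold
        delta = (lo + hi) / 2
        s = _soft(x, delta)
        ns = np.linalg.norm(s)
        if ns == 0:
            hi = delta
            continue
        if np.abs(s).sum() / ns > c:
            lo = delta
        else:
            hi = delta
    s = _soft(x, hi)
    return s / np.linalg.norm(s)


class SparseCCA(BaseEstimator):
    """CCA with an l1 budget on the task-side weights.

    Parameters
    ----------
    n_components : number of canonical pairs (K).
    fullness : f in (0, 1]; task-side l1 budget c = 1 + f (sqrt(p) - 1).
        f = 1 disables the penalty (classical CCA).
    reg : relative ridge added to both within-covariances before whitening.
    max_iter, tol : alternating-update control per component.

    Attributes (after fit)
    ----------------------
    x_weights_, y_weights_ : (p, K), (q, K) weights in the original
        (standardized) coordinates; components ordered by descending
        training canonical correlation.
    correlations_ : (K,) training canonical correlations.
    x_mean_, x_std_, y_mean_, y_std_ : standardization parameters.
    """

    def __init__(self, n_components: int = 10, fullness: float = 0.3,
                 reg: float = 1e-9, max_iter: int = 200, tol: float = 1e-10):
        self.n_components = n_components
        self.fullness = fullness
        self.reg = reg
        self.max_iter = max_iter
        self.tol = tol

    def _standardize(self, Z, mean, std):
        return (Z - mean) / std

    def fit(self, X: np.ndarray, Y: np.ndarray) -> "SparseCCA":
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        if X.shape[0] != Y.shape[0]:
            raise ValueError("X and Y must share the sample axis")
        n, p = X.shape
        q = Y.shape[1]
        if not 0 < self.fullness <= 1:
            raise ValueError("fullness must be in (0, 1]")
        self.x_mean_, self.x_std_ = X.mean(0), X.std(0)
        self.y_mean_, self.y_std_ = Y.mean(0), Y.std(0)
        self.x_std_[self.x_std_ == 0] = 1.0
        self.y_std_[self.y_std_ == 0] = 1.0
        Xs = self._standardize(X, self.x_mean_, self.x_std_)
        Ys = self._standardize(Y, self.y_mean_, self.y_std_)

        Sx = Xs.T @ Xs / (n - 1) + self.reg * np.eye(p)
        Sy = Ys.T @ Ys / (n - 1) + self.reg * np.eye(q)
        Sxy = Xs.T @ Ys / (n - 1)
        Wx = _inv_sqrt(Sx)
        Wy = _inv_sqrt(Sy)
        K = Wx @ Sxy @ Wy

        k_max = min(self.n_components, p, q)
        if k_max < self.n_components:
            import warnings

            warnings.warn(f"rank limits components to {k_max}", stacklevel=2)
        c = 1.0 + self.fullness * (np.sqrt(p) - 1.0)
        us, vs, ds = [], [], []
        Kd = K.copy()
        for _ in range(k_max):
            # initialize from the leading singular pair
            U0, s0, V0t = np.linalg.svd(Kd, full_matrices=False)
            u, v = U0[:, 0], V0t[0]
            if self.fullness < 1:
                for _ in range(self.max_iter):
                    u_new = _l1_project(Kd @ v, c)
                    v_new = Kd.T @ u_new
                    nv = np.linalg.norm(v_new)
                    if nv == 0:
                        u, v = u_new, v_new
                        break
                    v_new /= nv
                    if (np.linalg.norm(u_new - u) < self.tol
                            and np.linalg.norm(v_new - v) < self.tol):
                        u, v = u_new, v_new
                        break
                    u, v = u_new, v_new
            d = float(u @ Kd @ v)
            us.append(u); vs.append(v); ds.append(d)
            Kd = Kd - d * np.outer(u, v)
        U = np.stack(us, axis=1)
        V = np.stack(vs, axis=1)
        A = Wx @ U  # task weights in standardized coordinates
        B = Wy @ V
        # order by training canonical correlation, descending
        tx, ty = Xs @ A, Ys @ B
        corrs = np.array([
            _safe_corr(tx[:, k], ty[:, k]) for k in range(k_max)
        ])
        order = np.argsort(-corrs)
        self.x_weights_ = A[:, order]
        self.y_weights_ = B[:, order]
        self.x_weights_whitened_ = U[:, order]
        self.correlations_ = corrs[order]
        self.singular_values_ = np.asarray(ds)[order]
        self.n_components_ = k_max
        return self

    def transform(self, X: np.ndarray | None = None,
                  Y: np.ndarray | None = None):
        """Project X and/or Y onto the fitted canonical directions."""
        out = []
        if X is not None:
            Xs = self._standardize(np.asarray(X, float), self.x_mean_, self.x_std_)
            out.append(Xs @ self.x_weights_)
        if Y is not None:
            Ys = self._standardize(np.asarray(Y, float), self.y_mean_, self.y_std_)
            out.append(Ys @ self.y_weights_)
        return out[0] if len(out) == 1 else tuple(out)

    def n_active_task_columns(self) -> np.ndarray:
        """Nonzero task-side (whitened) weights per component."""
        return (np.abs(self.x_weights_whitened_) > 1e-10).sum(axis=0)


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    if a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


@dataclass
class CCAResult:
    """Cross-validated sparse-CCA fit."""

    model: SparseCCA
    heldout_correlations: np.ndarray  # (n_folds, K)
    fold_ids: np.ndarray
    assignment: dict = field(default_factory=dict)


def fit_scca(
    X: np.ndarray,
    Y: np.ndarray,
    n_components: int = 10,
    fullness: float = 0.3,
    fold_ids: np.ndarray | None = None,
    **kwargs,
) -> CCAResult:
    """Fit sparse CCA with leave-one-fold-out held-out correlations.

    ``fold_ids`` labels each sample (masked time bin) with its CV block; the
    final model is refitted on all samples.
    """
    folds = np.unique(fold_ids) if fold_ids is not None else []
    held = []
    for f in folds:
        tr = fold_ids != f
        te = ~tr
        if tr.sum() < 10 or te.sum() < 10:
            continue
        m = SparseCCA(n_components=n_components, fullness=fullness, **kwargs).fit(
            X[tr], Y[tr])
        tx, ty = m.transform(X[te], Y[te])
        held.append([_safe_corr(tx[:, k], ty[:, k])
                     for k in range(m.n_components_)])
    model = SparseCCA(n_components=n_components, fullness=fullness, **kwargs).fit(X, Y)
    held = np.array(held) if held else np.empty((0, model.n_components_))
    return CCAResult(model=model, heldout_correlations=held,
                     fold_ids=fold_ids if fold_ids is not None else np.array([]))


def assign_components(model: SparseCCA, column_groups: dict,
                      variables=("reward", "choice", "waiting_time", "reward_ratio")) -> dict:
    """Map each task variable to the component where its columns' summed
    absolute weight dominates the other variables' (relative share).

    The relative share is weighted by the component's training canonical
    correlation: several components can be dominated by the same variable
    (sparse solutions often produce weak duplicate directions), and the
    variable's representative should be the one that actually co-varies
    across the two spaces.  Ties break toward the lower component index; a
    variable whose weights are zero everywhere is left unassigned (None).
    """
    # the l1-budgeted (whitened) task weights are the interpretable ones:
    # original-coordinate weights amplify near-collinear column groups
    W = (model.x_weights_whitened_ if hasattr(model, "x_weights_whitened_")
         else model.x_weights_)
    A = np.abs(W)
    # relative share is taken against ALL task variables' weights, so a
    # component dominated by, e.g., location cannot be claimed by another
    # variable that merely rides along
    all_scores = {v: A[cols].sum(axis=0) for v, cols in column_groups.items()}
    total = np.sum(list(all_scores.values()), axis=0)
    total[total == 0] = 1.0
    corrs = np.abs(getattr(model, "correlations_", np.ones(A.shape[1])))
    out = {}
    for v in variables:
        if v not in all_scores:
            continue
        s = all_scores[v]
        if np.all(s == 0):
            out[v] = None
            continue
        rel = s / total * corrs
        out[v] = int(np.argmax(rel))  # argmax takes the first (lowest) index on ties
    return out


def cluster_neurons_by_reconstruction(
    Y: np.ndarray,
    X: np.ndarray,
    min_size: int = 5,
    distance_threshold: float = 0.5,
    ridge: float = 1e-6,
) -> list:
    """Cluster units by the similarity of their task-reconstructed activity.

    Each unit's trace is ridge-reconstructed from the task design X, units are
    linked by average-linkage hierarchical clustering on correlation distance
    between reconstructions, the tree is cut at ``distance_threshold``, and
    clusters smaller than ``min_size`` are discarded.  Returns a list of unit
    index arrays.
    """
    Y = np.asarray(Y, float)
    X = np.asarray(X, float)
    n, q = Y.shape
    if q < min_size:
        return []
    Xc = X - X.mean(0)
    G = Xc.T @ Xc + ridge * np.eye(X.shape[1])
    beta = np.linalg.solve(G, Xc.T @ (Y - Y.mean(0)))
    recon = Xc @ beta  # (n, q)
    sd = recon.std(0)
    sd[sd == 0] = 1.0
    R = np.corrcoef((recon / sd).T)
    R = np.nan_to_num(R, nan=0.0)
    dist = 1.0 - R
    iu = np.triu_indices(q, k=1)
    Z = linkage(dist[iu], method="average")
    labels = fcluster(Z, t=distance_threshold, criterion="distance")
    clusters = [np.flatnonzero(labels == lab) for lab in np.unique(labels)]
    return [c for c in clusters if len(c) >= min_size]


def component_vs_single_unit(
    X: np.ndarray,
    Y: np.ndarray,
    column_groups: dict,
    targets: dict,
    fold_ids: np.ndarray,
    n_components: int = 10,
    fullness: float = 0.3,
    min_cluster_size: int = 5,
) -> pd.DataFrame:
    """Held-out correlation of a reward predictor with (a) the best single
    unit, (b) the best cluster mean, (c) its assigned canonical component.

    Best unit/cluster are chosen on the training folds; all three readouts
    are evaluated on pooled held-out samples of the same leave-one-block-out
    folds used for the CCA.
    """
    folds = np.unique(fold_ids)
    rows = []
    for name, target in targets.items():
        target = np.asarray(target, float)
        pooled = {"single_unit": ([], []), "cluster": ([], []), "component": ([], [])}
        for f in folds:
            tr = fold_ids != f
            te = ~tr
            if te.sum() < 10 or tr.sum() < 20:
                continue
            # (c) canonical component assigned to this variable
            model = SparseCCA(n_components=n_components, fullness=fullness).fit(
                X[tr], Y[tr])
            assign = assign_components(model, column_groups,
                                       variables=tuple(column_groups))
            k = assign.get(name)
            if k is None:
                continue
            comp_tr = model.transform(Y=Y[tr])[:, k]
            sign = np.sign(_safe_corr(comp_tr, target[tr])) or 1.0
            pooled["component"][0].append(sign * model.transform(Y=Y[te])[:, k])
            pooled["component"][1].append(target[te])
            # (a) best single unit on training data
            tr_corrs = [abs(_safe_corr(Y[tr, j], target[tr])) for j in range(Y.shape[1])]
            j_best = int(np.argmax(tr_corrs))
            sign = np.sign(_safe_corr(Y[tr, j_best], target[tr])) or 1.0
            pooled["single_unit"][0].append(sign * Y[te, j_best])
            pooled["single_unit"][1].append(target[te])
            # (b) best cluster mean on training data
            clusters = cluster_neurons_by_reconstruction(
                Y[tr], X[tr], min_size=min_cluster_size)
            if clusters:
                means_tr = [Y[tr][:, c].mean(1) for c in clusters]
                cc = [abs(_safe_corr(m, target[tr])) for m in means_tr]
                c_best = clusters[int(np.argmax(cc))]
                sign = np.sign(_safe_corr(Y[tr][:, c_best].mean(1), target[tr])) or 1.0
                pooled["cluster"][0].append(sign * Y[te][:, c_best].mean(1))
                pooled["cluster"][1].append(target[te])
        row = {"target": name}
        for key, (preds, obs) in pooled.items():
            row[f"r_{key}"] = (_safe_corr(np.concatenate(preds), np.concatenate(obs))
                               if preds else np.nan)
        rows.append(row)
    return pd.DataFrame(rows)
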