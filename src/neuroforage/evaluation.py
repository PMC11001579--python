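"""End-to-end validation analyses on synthetic data.

Each function regenerates its inputs from a seed, runs the relevant part of
the pipeline, and returns the summary quantities: the availability-law fit,
matching-law slopes of the two agents, locomotion-projection exactness,
the design-matrix contract, solver-vs-oracle gaps, latent parameter
recovery, the predictor-family ordering, and the pooled reward-predictor
correlations.  Both the test suite and ``scripts/acceptance.py`` are thin
wrappers over these functions.
"""

from __future__ import annotations


import warnings

import numpy as np
import pandas as pd

from . import behavior_analysis as ba
from .foraging_agents import (
    MVTAgentParams,
    ThresholdAgentParams,
    matching_law_fit,
    run_mvt_agent,
    run_threshold_agent,
)
from .latent_cca import (
    SparseCCA,
    assign_components,
    cluster_neurons_by_reconstruction,
    _safe_corr,
)
from .metrics import auc
from .neural_preprocess import LocomotionProjector, RateGrid, engagement_mask
from .pipeline_io import RunConfig, _bin_blocks, _prepare
from .prediction import compare_predictor_families, make_blocks
from .synthetic_data import belief_noise_bundle_config, generate_dataset
from .task_features import build_feature_matrix, reward_predictor_features
from .task_model import VISchedule, prob_reward_available

__all__ = [
    "availability_law",
    "matching_slopes",
    "projection_exactness",
    "feature_contract",
    "cca_oracle_gap",
    "parameter_recovery",
    "prediction_ordering",
    "auc_and_blocks_oracle",
    "reward_predictor_correlations",
]


def availability_law(seed: int, n_sim: int = 20_000,
                     vi: float = 20.0, dt: float = 0.01,
                     checkpoints=(5.0, 10.0, 20.0, 40.0)) -> dict:
    """Empirical availability from per-bin telegraph simulations vs the
    closed form, plus the dt-refinement gap to the continuous-hazard limit."""
    rng = np.random.default_rng(seed)
    armed = np.zeros(n_sim, dtype=bool)
    t = 0.0
    out = {}
    max_dev_se = 0.0
    for cp in sorted(checkpoints):
        n_steps = int(round((cp - t) / dt))
        p = dt / vi
        for _ in range(n_steps):
            armed = armed | (rng.random(n_sim) < p)
        t = cp
        emp = armed.mean()
        theo = prob_reward_available(cp, vi, dt)
        se = np.sqrt(theo * (1 - theo) / n_sim)
        out[f"t{int(cp)}"] = {"empirical": float(emp), "closed_form": float(theo),
                              "deviation_se": float(abs(emp - theo) / se)}
        max_dev_se = max(max_dev_se, abs(emp - theo) / se)
    limit = 1.0 - np.exp(-10.0 / vi)
    gaps = [abs(prob_reward_available(10.0, vi, d) - limit)
            for d in (dt, dt / 2, dt / 4)]
    out["max_deviation_se"] = float(max_dev_se)
    out["dt_gap_monotone"] = bool(gaps[0] > gaps[1] > gaps[2])
    return out


CRIT_PAIRS = ((15.0, 25.0), (10.0, 30.0), (20.0, 40.0))


def _sessions_for_pair(agent: str, pair, seed0: int, min_presses: int = 3000):
    pairs = [pair, (pair[1], pair[0])] * 6
    sched = VISchedule.from_pairs(pairs, n_rewards=34)
    sessions, n, seed = [], 0, seed0
    while n < min_presses:
        seed += 1
        rng = np.random.default_rng(seed)
        if agent == "mvt":
            s = run_mvt_agent(MVTAgentParams(), sched, rng)
        else:
            s = run_threshold_agent(ThresholdAgentParams(), sched, rng)
        sessions.append(s)
        n += len(s)
    return sessions, n


def matching_slopes(seed: int) -> dict:
    """Generalized matching-law slopes of both agents over the unbalanced
    schedule pairs, >=3000 presses per pair."""
    out = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for agent in ("threshold", "mvt"):
            allsess, total = [], 0
            for i, pair in enumerate(CRIT_PAIRS):
                sess, n = _sessions_for_pair(agent, pair, seed + 1000 * i)
                allsess.extend(sess)
                total += n
            fit = matching_law_fit(allsess)
            out[agent] = {"slope": float(fit.slope),
                          "intercept": float(fit.intercept),
                          "n_presses": int(total),
                          "n_blocks": int(fit.n_points)}
    return out


def projection_exactness(seed: int, n_units: int = 40,
                         n_bins: int = 2000) -> dict:
    """Max |corr(residual, L)| over units and the idempotence error of Pi."""
    rng = np.random.default_rng(seed)
    L = np.abs(rng.normal(10, 5, n_bins)) + rng.random(n_bins)
    rates = rng.random((n_units, n_bins)) * 10 + np.outer(
        rng.normal(0, 1, n_units), L)
    proj = LocomotionProjector().fit(L)
    res = proj.transform(rates)
    max_corr = max(abs(np.corrcoef(r, L)[0, 1]) for r in res if r.std() > 0)
    idem = float(np.max(np.abs(proj.transform(res) - res)))
    return {"max_abs_corr": float(max_corr), "idempotence_error": idem}


def feature_contract(seed: int = 0) -> dict:
    """Column count, per-variable layout, tile-partition property, and the
    2 s reward-window span of the design matrix on a synthetic session."""
    from .synthetic_data import DatasetConfig, EncodingSpec

    cfg = DatasetConfig(schedule_pairs=((20.0, 40.0), (40.0, 20.0)),
                        n_rewards_per_block=15,
                        encoding=EncodingSpec(n_units=0))
    b = generate_dataset(cfg, seed)
    grid = RateGrid.covering(b.session.times[-1] + 2.0, step=0.2)
    mask = engagement_mask(b.session.times, grid)
    fm = build_feature_matrix(b.session, b.locomotion, grid, mask)
    counts = fm.columns["variable"].value_counts().to_dict()
    tiles = fm.columns["kind"].str.contains("tile").to_numpy()
    groups = fm.column_groups()
    partition_ok = True
    for var in ("press", "choice", "reward"):
        for kind in ("pre_tile", "post_tile"):
            cols = np.flatnonzero((fm.columns["variable"] == var).to_numpy()
                                  & (fm.columns["kind"] == kind).to_numpy())
            if len(cols):
                partition_ok &= bool((fm.X[:, cols].sum(1) <= 1).all())
    rew_cols = groups["reward"]
    t_rew = b.session.times[b.session.rewarded]
    active = fm.X[:, rew_cols].sum(1) > 0
    span_ok = True
    for c, a in zip(grid.centers, active):
        d = c - t_rew[t_rew <= c][-1] if np.any(t_rew <= c) else np.inf
        span_ok &= a == (d < 2.0)
    return {"n_columns": int(fm.n_columns), "layout": counts,
            "tiles_partition": bool(partition_ok),
            "reward_span_2s": bool(span_ok),
            "binary_tiles": bool(set(np.unique(fm.X[:, tiles])) <= {0.0, 1.0})}


def _classical_cca(X, Y, k):
    X = X - X.mean(0)
    Y = Y - Y.mean(0)
    n = X.shape[0]
    Sxx = X.T @ X / (n - 1)
    Syy = Y.T @ Y / (n - 1)
    Sxy = X.T @ Y / (n - 1)
    M = np.linalg.solve(Sxx, Sxy) @ np.linalg.solve(Syy, Sxy.T)
    w = np.sort(np.real(np.linalg.eigvals(M)))[::-1]
    return np.sqrt(np.clip(w[:k], 0, 1))


def cca_oracle_gap(seed: int, n_instances: int = 50) -> dict:
    """Worst-case |solver - generalized-eigenproblem| gap in canonical
    correlations over random instances, plus the sparsity-monotonicity flag."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_instances):
        n = int(rng.integers(100, 300))
        p = int(rng.integers(3, 8))
        q = int(rng.integers(3, 10))
        X = rng.normal(size=(n, p))
        Y = rng.normal(size=(n, q)) + 0.5 * X @ rng.normal(size=(p, q))
        k = min(p, q)
        m = SparseCCA(n_components=k, fullness=1.0, reg=0.0).fit(X, Y)
        worst = max(worst, float(np.max(np.abs(
            m.correlations_ - _classical_cca(X, Y, k)))))
    X = rng.normal(size=(300, 20))
    Y = 0.7 * X @ rng.normal(size=(20, 10)) + rng.normal(size=(300, 10))
    nnz = [int(SparseCCA(n_components=3, fullness=f).fit(X, Y)
               .n_active_task_columns().sum()) for f in (1.0, 0.5, 0.3, 0.15)]
    return {"max_abs_gap": worst,
            "sparsity_monotone": bool(all(a >= b for a, b in zip(nnz, nnz[1:]))),
            "nonzeros_by_fullness": nnz}


def parameter_recovery(seed: int) -> dict:
    """Held-out correlation of the assigned waiting-time / reward-ratio
    components with the planted latents on the default 60-unit bundle, and
    the comparison against the best single unit and cluster mean."""
    cfg = RunConfig(seed=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        b = generate_dataset(cfg.dataset, seed)
        rates, feats = _prepare(cfg, b)
        Xs = feats.standardized()
        Ys = rates.masked().T
        bb = _bin_blocks(b.session.times, rates.grid, cfg.cv_gap)[feats.mask]
        centers = rates.grid.centers[feats.mask]
        gt = b.ground_truth
        truth = {
            "waiting_time": np.interp(centers, gt.grid, gt.channels["wait_ramp"]),
            "reward_ratio": np.interp(centers, gt.grid, gt.channels["reward_ratio"]),
        }
        groups = feats.column_groups()
        out = {}
        for name, target in truth.items():
            preds, obs = [], []
            best_unit_preds, best_unit_obs = [], []
            cluster_preds = []
            for f in np.unique(bb):
                tr = bb != f
                m = SparseCCA(n_components=cfg.n_components,
                              fullness=cfg.fullness).fit(Xs[tr], Ys[tr])
                k = assign_components(m, groups).get(name)
                if k is None:
                    continue
                sign = np.sign(_safe_corr(m.transform(Y=Ys[tr])[:, k],
                                          target[tr])) or 1.0
                preds.append(sign * m.transform(Y=Ys[~tr])[:, k])
                obs.append(target[~tr])
                tr_corrs = [abs(_safe_corr(Ys[tr, j], target[tr]))
                            for j in range(Ys.shape[1])]
                j = int(np.argmax(tr_corrs))
                s_u = np.sign(_safe_corr(Ys[tr, j], target[tr])) or 1.0
                best_unit_preds.append(s_u * Ys[~tr, j])
                best_unit_obs.append(target[~tr])
                clusters = cluster_neurons_by_reconstruction(Ys[tr], Xs[tr])
                if clusters:
                    cm = [Ys[tr][:, c].mean(1) for c in clusters]
                    cc = [abs(_safe_corr(x, target[tr])) for x in cm]
                    cb = clusters[int(np.argmax(cc))]
                    s_c = np.sign(_safe_corr(Ys[tr][:, cb].mean(1),
                                             target[tr])) or 1.0
                    cluster_preds.append((s_c * Ys[~tr][:, cb].mean(1),
                                          target[~tr]))
            out[name] = {
                "r_component": float(_safe_corr(np.concatenate(preds),
                                                np.concatenate(obs))),
                "r_single_unit": float(_safe_corr(
                    np.concatenate(best_unit_preds),
                    np.concatenate(best_unit_obs))),
                "r_cluster": float(_safe_corr(
                    np.concatenate([p for p, _ in cluster_preds]),
                    np.concatenate([o for _, o in cluster_preds])))
                if cluster_preds else float("nan"),
            }
    return out


def prediction_ordering(session_seeds=(5, 11, 7, 3)) -> dict:
    """Session-averaged peak pre-press decoding of reward and choice for the
    three predictor families on the belief-noise bundle."""
    peaks = {t: {f: [] for f in ("task_components", "neural_components",
                                 "full_population")}
             for t in ("reward", "choice")}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for seed in session_seeds:
            cfg = RunConfig(seed=int(seed), dataset=belief_noise_bundle_config())
            b = generate_dataset(cfg.dataset, int(seed))
            rates, feats = _prepare(cfg, b)
            X10 = reward_predictor_features(b.session, rates.grid)
            t = b.session.times
            targets = {
                "reward": b.session.rewarded.astype(float),
                "choice": np.append(
                    (b.session.boxes[1:] != b.session.boxes[:-1]).astype(float),
                    np.nan),
            }
            res = compare_predictor_families(X10, rates, t, targets,
                                             n_components=cfg.n_components)
            for tgt, d in res.items():
                for fam, r in d.items():
                    peaks[tgt][fam].append(r.peak)
    out = {t: {f: float(np.mean(v)) for f, v in d.items()}
           for t, d in peaks.items()}
    out["n_sessions"] = len(session_seeds)
    return out


def auc_and_blocks_oracle(seed: int, n_instances: int = 60) -> dict:
    """Rank-AUC vs exhaustive pair counting; gap blocks vs brute-force scan."""
    rng = np.random.default_rng(seed)
    worst_auc = 0.0
    for _ in range(n_instances):
        n = int(rng.integers(5, 201))
        scores = rng.integers(0, 10, n).astype(float)
        labels = rng.random(n) < 0.4
        if labels.all() or not labels.any():
            continue
        pos, neg = scores[labels], scores[~labels]
        brute = sum((p > x) + 0.5 * (p == x) for p in pos for x in neg) / (
            len(pos) * len(neg))
        worst_auc = max(worst_auc, abs(auc(scores, labels) - brute))
    worst_blocks = 0
    for _ in range(n_instances):
        times = np.sort(rng.uniform(0, 600, int(rng.integers(5, 40))))
        expected = [0]
        for a, b2 in zip(times[:-1], times[1:]):
            expected.append(expected[-1] + (b2 - a > 30.0))
        if expected[-1] == 0:
            continue
        got = make_blocks(times, gap=30.0)
        worst_blocks = max(worst_blocks, int(np.max(np.abs(got - expected))))
    return {"max_auc_gap": float(worst_auc),
            "max_block_id_gap": int(worst_blocks)}


ANALOG_PAIRS = ((20.0, 20.0), (30.0, 30.0), (20.0, 40.0), (40.0, 20.0),
                (15.0, 25.0), (25.0, 15.0))


def reward_predictor_correlations(seed: int, n_sessions: int = 16,
                                  filter_width: float = 60.0) -> dict:
    """Pooled 50-press-binned correlations of each reward predictor with the
    rewarded fraction on MVT-agent sessions (mixed balanced/unbalanced
    schedules) — the behavioral analog of the reward-predictability ranking."""
    sched = VISchedule.from_pairs(ANALOG_PAIRS, n_rewards=66)
    tabs = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(n_sessions):
            rng = np.random.default_rng(seed + i)
            s = run_mvt_agent(MVTAgentParams(), sched, rng)
            tabs.append(ba.build_press_table(s, filter_width))
        pooled = pd.concat(tabs, ignore_index=True)
        out = {"n_presses": int(len(pooled))}
        for p in ("prob_avail", "waiting_time", "scheduled_rate",
                  "reward_ratio"):
            out[f"r_{p}"] = float(ba.bin_and_correlate(pooled, p).pearson_r)
    return out
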