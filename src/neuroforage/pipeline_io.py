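"""Formats, run configuration, and the end-to-end pipeline.

Press-level data travel as delimited text (one row per press) with a YAML
sidecar holding the schedule blocks and the availability bin width; spikes
and rate matrices as compressed columnar containers; configs and manifests
as YAML.  A run is fully determined by (config, seed): all randomness flows
from a single root seed through named child streams, and every artifact
carries the config hash.
"""

from __future__ import annotations


import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior_analysis as ba
from . import prediction as pred
from .latent_cca import assign_components, fit_scca
from .neural_preprocess import (
    RateGrid,
    bin_and_smooth,
    engagement_mask,
    remove_locomotion,
)
from .synthetic_data import (
    DatasetConfig,
    SessionBundle,
    SpikeTrainSet,
    generate_dataset,
)
from .task_features import build_feature_matrix, reward_predictor_features
from .task_model import BehavioralSession, ScheduleBlock, VISchedule

__all__ = [
    "RunConfig",
    "read_session",
    "write_session",
    "write_spikes",
    "read_spikes",
    "run_pipeline",
]


def write_session(session: BehavioralSession, path: str | Path) -> None:
    """Delimited press table + YAML sidecar with the schedule and dt."""
    path = Path(path)
    # %.17g guarantees float round-trip through text
    session.to_frame().to_csv(path, sep="\t", index=False, float_format="%.17g")
    sidecar = {
        "dt": session.schedule.dt,
        "blocks": [
            {"box1_vi": b.box1_vi, "box2_vi": b.box2_vi, "n_rewards": b.n_rewards}
            for b in session.schedule.blocks
        ],
        "meta": {k: str(v) for k, v in session.meta.items()},
    }
    path.with_suffix(path.suffix + ".yaml").write_text(yaml.safe_dump(sidecar))


def read_session(path: str | Path) -> BehavioralSession:
    """Read a press table + sidecar; schema violations raise with the row."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    required = {"time_s", "box", "rewarded", "block_index"}
    if not required.issubset(df.columns):
        raise ValueError(f"missing columns: {sorted(required - set(df.columns))}")
    t = df["time_s"].to_numpy(float)
    bad = np.flatnonzero(np.diff(t) <= 0)
    if len(bad):
        raise ValueError(f"non-increasing press time at row {bad[0] + 1}")
    bad = np.flatnonzero(~df["box"].isin([1, 2]))
    if len(bad):
        raise ValueError(f"invalid box label at row {bad[0]}")
    side = yaml.safe_load(path.with_suffix(path.suffix + ".yaml").read_text())
    schedule = VISchedule(
        blocks=tuple(ScheduleBlock(b["box1_vi"], b["box2_vi"], b["n_rewards"])
                     for b in side["blocks"]),
        dt=side["dt"],
    )
    return BehavioralSession(
        times=t, boxes=df["box"].to_numpy(int),
        rewarded=df["rewarded"].to_numpy().astype(bool),
        block_index=df["block_index"].to_numpy(int),
        schedule=schedule, meta=side.get("meta", {}),
    )


def write_spikes(spikes: SpikeTrainSet, path: str | Path) -> None:
    np.savez_compressed(
        path, t_stop=spikes.t_stop,
        **{f"unit_{k}": st for k, st in enumerate(spikes.spike_times)},
    )


def read_spikes(path: str | Path) -> SpikeTrainSet:
    with np.load(path) as z:
        n = len([k for k in z.files if k.startswith("unit_")])
        return SpikeTrainSet(
            spike_times=[z[f"unit_{k}"] for k in range(n)],
            t_stop=float(z["t_stop"]),
        )


@dataclass(frozen=True)
class RunConfig:
    """Everything that determines a pipeline run, minus the code version."""

    seed: int
    dataset: DatasetConfig = field(default_factory=DatasetConfig)
    grid_step: float = 0.2  # s
    smooth_window: float = 1.0  # s
    engagement_gap: float = 5.0  # s
    reward_filter_width: float = 5.0  # presses
    n_components: int = 10
    fullness: float = 0.3
    cv_gap: float = 30.0  # s

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _prepare(config: RunConfig, bundle: SessionBundle):
    """Shared preprocessing: rates, mask, projection, features, CV folds."""
    grid = RateGrid.covering(bundle.spikes.t_stop, step=config.grid_step)
    rates = bin_and_smooth(bundle.spikes, grid, smooth_window=config.smooth_window)
    mask = engagement_mask(bundle.session.times, grid, max_gap=config.engagement_gap)
    rates.mask = mask
    rates = remove_locomotion(rates, bundle.locomotion)
    feats = build_feature_matrix(bundle.session, bundle.locomotion, grid, mask,
                                 reward_filter_width=config.reward_filter_width)
    return rates, feats


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """simulate -> analyze-behavior -> preprocess -> features -> CCA -> predict.

    Writes all intermediates plus a manifest carrying the config hash and
    returns a summary dictionary.  Deterministic given (config, seed).
    """
    if config.seed is None:
        raise ValueError("config.seed is required")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = generate_dataset(config.dataset, config.seed)
    write_session(bundle.session, out / "session.tsv")
    write_spikes(bundle.spikes, out / "spikes.npz")

    table = ba.build_press_table(bundle.session, config.reward_filter_width)
    table.to_csv(out / "press_table.tsv", sep="\t", index=False)
    behavior = {}
    for p in ("prob_avail", "waiting_time", "scheduled_rate", "reward_ratio"):
        try:
            behavior[f"r_{p}"] = float(ba.bin_and_correlate(table, p).pearson_r)
        except ValueError:
            behavior[f"r_{p}"] = None

    summary = {"config_hash": config.hash(), "seed": config.seed,
               "n_presses": len(bundle.session),
               "n_units": bundle.spikes.n_units,
               "behavior": behavior}

    if bundle.spikes.n_units:
        rates, feats = _prepare(config, bundle)
        Xs = feats.standardized()
        Ys = rates.masked().T
        bin_block = _bin_blocks(bundle.session.times, rates.grid, config.cv_gap)
        res = fit_scca(Xs, Ys, n_components=config.n_components,
                       fullness=config.fullness, fold_ids=bin_block[feats.mask])
        groups_masked = feats.column_groups()
        assignment = assign_components(res.model, groups_masked)
        summary["cca"] = {
            "train_correlations": res.model.correlations_.tolist(),
            "heldout_correlations": res.heldout_correlations.mean(0).tolist()
            if len(res.heldout_correlations) else [],
            "assignment": {k: (int(v) if v is not None else None)
                           for k, v in assignment.items()},
        }
        # predictor-family comparison on the reward-predictor subspace
        X10 = reward_predictor_features(bundle.session, rates.grid)
        t = bundle.session.times
        targets = {
            "reward": bundle.session.rewarded.astype(float),
            "choice": np.append(
                (bundle.session.boxes[1:] != bundle.session.boxes[:-1]).astype(float),
                np.nan),
            "next_wait": np.append(np.diff(t), np.nan),
        }
        fam = pred.compare_predictor_families(
            X10, rates, t, targets, n_components=config.n_components,
            gap=config.cv_gap)
        rows = []
        for tgt, d in fam.items():
            for f, r in d.items():
                rows.append({"target": tgt, "family": f, "metric": r.metric,
                             "peak": r.peak})
        pd.DataFrame(rows).to_csv(out / "prediction_peaks.tsv", sep="\t",
                                  index=False)
        summary["prediction_peaks"] = rows

    (out / "manifest.yaml").write_text(yaml.safe_dump(
        {"config": config.to_dict(), "config_hash": config.hash(),
         "summary_keys": sorted(summary)}, default_flow_style=False))
    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=str))
    return summary


def _bin_blocks(press_times: np.ndarray, grid: RateGrid, gap: float) -> np.ndarray:
    """CV block id of every grid bin = block of the nearest press."""
    blocks = pred.make_blocks(press_times, gap=gap)
    centers = grid.centers
    i = np.clip(np.searchsorted(press_times, centers), 1, len(press_times) - 1)
    nearer_next = np.abs(press_times[i] - centers) < np.abs(centers - press_times[i - 1])
    return blocks[np.where(nearer_next, i, i - 1)]
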