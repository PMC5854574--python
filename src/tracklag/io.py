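"""Plain-text on-disk formats for sessions and analysis products.

A session directory holds ``trials.csv`` (long-format behavior),
``spikes.csv``, ``truth.json`` (per-cell ground truth) and
``session.json`` (task configuration, condition, seeds).  Analysis
products are ``preprocessed.csv``, ``profiles.csv``, ``peaks.csv`` and
plain-CSV firing-map grids.  All coordinates are cm, screen-centered,
+x right, +y up.
"""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .encoding import FiringMap
from .simulate import (
    BehaviorTrial,
    CellGroundTruth,
    CellRecording,
    NoiseParams,
    Session,
    SpikeTrain,
)
from .task import Condition, TaskConfig

__all__ = [
    "write_session",
    "read_session",
    "write_preprocessed",
    "write_profiles",
    "write_peaks",
    "write_firing_map",
]


def _trial_frame(cell_id: int, block: str, trial: BehaviorTrial) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cell_id": cell_id,
            "block": block,
            "trial_id": trial.trial_index,
            "t_ms": trial.t_ms,
            "target_x": trial.target_xy[:, 0],
            "target_y": trial.target_xy[:, 1],
            "hand_x": trial.hand_xy[:, 0],
            "hand_y": trial.hand_xy[:, 1],
            "cursor_x": trial.cursor_xy[:, 0],
            "cursor_y": trial.cursor_xy[:, 1],
            "visible": trial.visible.astype(int),
        }
    )


def write_session(session: Session, outdir: str | Path) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    trial_frames, spike_rows, truths = [], [], []
    for c, cell in enumerate(session.cells):
        truths.append(dataclasses.asdict(cell.truth))
        for block in ("baseline", "manipulation"):
            for trial, spikes in getattr(cell, block):
                trial_frames.append(_trial_frame(c, block, trial))
                spike_rows.append(
                    pd.DataFrame(
                        {
                            "cell_id": c,
                            "block": block,
                            "trial_id": trial.trial_index,
                            "spike_time_ms": spikes.spike_times_ms,
                        }
                    )
                )
    pd.concat(trial_frames, ignore_index=True).to_csv(outdir / "trials.csv", index=False)
    pd.concat(spike_rows, ignore_index=True).to_csv(outdir / "spikes.csv", index=False)
    (outdir / "truth.json").write_text(json.dumps(truths, indent=1, sort_keys=True))
    meta = {
        "config": dataclasses.asdict(session.config),
        "condition": dataclasses.asdict(session.condition),
        "noise": dataclasses.asdict(session.noise),
        "seed": session.seed,
    }
    (outdir / "session.json").write_text(json.dumps(meta, indent=1, sort_keys=True))
    return outdir


def read_session(indir: str | Path) -> Session:
    indir = Path(indir)
    meta = json.loads((indir / "session.json").read_text())
    cfg = meta["config"]
    cfg["hold_range_ms"] = tuple(cfg["hold_range_ms"])
    config = TaskConfig(**cfg)
    condition = Condition(**meta["condition"])
    noise = NoiseParams(**meta["noise"])
    truths = json.loads((indir / "truth.json").read_text())
    trials = pd.read_csv(indir / "trials.csv")
    spikes = pd.read_csv(indir / "spikes.csv")

    cells = []
    for c, tdict in enumerate(truths):
        for key in ("lead_gain_xy", "lag_gain_xy", "pos_gain_xy", "vel_gain_xy"):
            tdict[key] = tuple(tdict[key])
        truth = CellGroundTruth(**tdict)
        blocks = {}
        for block in ("baseline", "manipulation"):
            cond = condition if block == "manipulation" else Condition("baseline")
            tsel = trials[(trials.cell_id == c) & (trials.block == block)]
            ssel = spikes[(spikes.cell_id == c) & (spikes.block == block)]
            block_trials = []
            for tid, g in tsel.groupby("trial_id", sort=True):
                trial = BehaviorTrial(
                    t_ms=g.t_ms.to_numpy(),
                    target_xy=g[["target_x", "target_y"]].to_numpy(),
                    hand_xy=g[["hand_x", "hand_y"]].to_numpy(),
                    cursor_xy=g[["cursor_x", "cursor_y"]].to_numpy(),
                    visible=g.visible.to_numpy().astype(bool),
                    condition=cond,
                    trial_index=int(tid),
                    session_index=c,
                )
                st = ssel[ssel.trial_id == tid].spike_time_ms.to_numpy()
                block_trials.append((trial, SpikeTrain(st, trial_ref=int(tid))))
            blocks[block] = block_trials
        cells.append(
            CellRecording(
                truth=truth,
                baseline=blocks["baseline"],
                manipulation=blocks["manipulation"],
            )
        )
    return Session(
        config=config,
        condition=condition,
        noise=noise,
        seed=meta["seed"],
        cells=cells,
    )


def write_preprocessed(preprocessed, outpath: str | Path) -> Path:
    """``preprocessed.csv``: one row per cell, block, trial and 50-Hz bin."""
    frames = []
    for cell_id, blocks in enumerate(preprocessed):
        for block, (rates, kins) in blocks.items():
            for rate, kin in zip(rates, kins):
                frames.append(
                    pd.DataFrame(
                        {
                            "cell_id": cell_id,
                            "block": block,
                            "trial_id": rate.trial_ref,
                            "t_ms": rate.t_ms,
                            "rate": rate.rate,
                            "X": kin.X,
                            "Y": kin.Y,
                            "VX": kin.VX,
                            "VY": kin.VY,
                            "XE": kin.XE,
                            "YE": kin.YE,
                            "inside_target": kin.inside_target.astype(int),
                        }
                    )
                )
    outpath = Path(outpath)
    pd.concat(frames, ignore_index=True).to_csv(outpath, index=False)
    return outpath


def write_profiles(analyses, outpath: str | Path) -> Path:
    rows = []
    for ana in analyses:
        for (pair, block), p in ana.profiles.items():
            for i in range(len(p.tau_ms)):
                rows.append(
                    {
                        "cell_id": ana.cell_id,
                        "parameter_pair": pair,
                        "condition": block,
                        "tau_ms": int(p.tau_ms[i]),
                        "r2": p.r2[i],
                        "beta1": p.beta1[i],
                        "beta2": p.beta2[i],
                        "sensitivity": p.sensitivity[i],
                        "null_mean": p.null_mean[i] if p.has_null else np.nan,
                        "null_sd": p.null_sd[i] if p.has_null else np.nan,
                    }
                )
    outpath = Path(outpath)
    pd.DataFrame(rows).to_csv(outpath, index=False)
    return outpath


def write_peaks(analyses, outpath: str | Path) -> Path:
    rows = []
    for ana in analyses:
        for (pair, block), ps in ana.peaks.items():
            for side in ("lead", "lag"):
                peak = getattr(ps, side)
                if peak is None:
                    continue
                rows.append(
                    {
                        "cell_id": ana.cell_id,
                        "parameter_pair": pair,
                        "condition": block,
                        "side": side,
                        "tau_ms": peak.tau_ms,
                        "r2": peak.r2,
                        "beta1": peak.beta_pair[0],
                        "beta2": peak.beta_pair[1],
                        "significant": peak.significant,
                    }
                )
    outpath = Path(outpath)
    pd.DataFrame(
        rows,
        columns=[
            "cell_id",
            "parameter_pair",
            "condition",
            "side",
            "tau_ms",
            "r2",
            "beta1",
            "beta2",
            "significant",
        ],
    ).to_csv(outpath, index=False)
    return outpath


def write_firing_map(fmap: FiringMap, outpath: str | Path) -> Path:
    """A firing map as a plain CSV grid (rows: first pair member bins)."""
    outpath = Path(outpath)
    header = (
        f"# firing map pair={fmap.parameter_pair} tau_ms={fmap.tau_ms} "
        f"edges={fmap.edges.tolist()}\n"
    )
    with open(outpath, "w") as fh:
        fh.write(header)
        pd.DataFrame(fmap.grid).to_csv(fh, index=False, header=False)
    return outpath
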