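"""Delimited-text I/O for sessions, ground truth and results.

All files are plain tab-separated text so that fixtures stay diffable and a
synthetic session is indistinguishable from a real one. Floats are written
with 17 significant digits, which round-trips IEEE doubles exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import EmgRecording, ForceTrace, GaitTimeline
from .synthetic import GroundTruth, SyntheticSession

_FLOAT = "%.17g"


# --- session files ---------------------------------------------------------

def write_emg(path: Path, rec: EmgRecording) -> None:
    df = pd.DataFrame(rec.data, columns=rec.channels)
    df.insert(0, "time_s", rec.times)
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT)

def read_emg(path: Path) -> EmgRecording:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    t = df["time_s"].to_numpy()
    if t.size < 2:
        raise ValueError(f"{path}: need at least two samples")
    rate = 1.0 / np.median(np.diff(t))
    return EmgRecording(channels=[c for c in df.columns if c != "time_s"],
                        rate=round(rate, 6),
                        data=df.drop(columns="time_s").to_numpy(),
                        t0=float(t[0]))

def write_events(path: Path, timeline: GaitTimeline) -> None:
    pd.DataFrame(timeline.events, columns=["time_s", "side", "type"]).to_csv(
        path, sep="\t", index=False, float_format=_FLOAT)

def read_events(path: Path) -> GaitTimeline:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    events = [(float(r.time_s), str(r.side), str(r.type)) for r in df.itertuples()]
    return GaitTimeline(events=events)

def write_force(path: Path, force: ForceTrace) -> None:
    pd.DataFrame({"time_s": force.times, "force_N": force.values}).to_csv(
        path, sep="\t", index=False, float_format=_FLOAT)

def read_force(path: Path) -> ForceTrace:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    t = df["time_s"].to_numpy()
    if t.size < 2:
        raise ValueError(f"{path}: need at least two samples")
    rate = 1.0 / np.median(np.diff(t))
    return ForceTrace(rate=round(rate, 6), values=df["force_N"].to_numpy(), t0=float(t[0]))

def write_interruptions(path: Path, intervals: list[tuple[float, float]]) -> None:
    pd.DataFrame(intervals, columns=["start_s", "end_s"]).to_csv(
        path, sep="\t", index=False, float_format=_FLOAT)

def read_interruptions(path: Path) -> list[tuple[float, float]]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return [(float(r.start_s), float(r.end_s)) for r in df.itertuples()]


def write_session(directory: Path, session: SyntheticSession) -> dict[str, str]:
    """Write a complete session; returns the file map for a study config."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_emg(directory / "emg.tsv", session.emg)
    write_events(directory / "events.tsv", session.timeline)
    write_force(directory / "force.tsv", session.force)
    write_force(directory / "weighing.tsv", session.weighing)
    write_interruptions(directory / "interruptions.tsv", session.interruptions)
    return {key: str(directory / f"{name}.tsv")
            for key, name in [("emg", "emg"), ("events", "events"), ("force", "force"),
                              ("weighing", "weighing"), ("interruptions", "interruptions")]}


# --- ground truth ----------------------------------------------------------

def write_ground_truth(directory: Path, gt: GroundTruth) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    cols = [f"S{i + 1}" for i in range(gt.n_synergies)]
    pd.DataFrame(gt.weights, index=gt.channels, columns=cols).to_csv(
        directory / "weights.tsv", sep="\t", float_format=_FLOAT)
    pd.DataFrame(gt.templates.T, columns=cols).to_csv(
        directory / "templates.tsv", sep="\t", index=False, float_format=_FLOAT)
    pd.DataFrame(gt.stride_plan, columns=["duration_s", "bws_percent", "level"]).to_csv(
        directory / "stride_plan.tsv", sep="\t", index=False, float_format=_FLOAT)
    meta = {"seed": gt.seed,
            "level_gains": {lv: list(map(float, g)) for lv, g in gt.level_gains.items()}}
    (directory / "meta.json").write_text(json.dumps(meta, indent=2))

def read_ground_truth(directory: Path) -> GroundTruth:
    directory = Path(directory)
    w = pd.read_csv(directory / "weights.tsv", sep="\t", index_col=0,
                    float_precision="round_trip")
    templates = pd.read_csv(directory / "templates.tsv", sep="\t", float_precision="round_trip").to_numpy().T
    plan_df = pd.read_csv(directory / "stride_plan.tsv", sep="\t", float_precision="round_trip")
    plan = [(float(r.duration_s), float(r.bws_percent), str(r.level))
            for r in plan_df.itertuples()]
    meta = json.loads((directory / "meta.json").read_text())
    return GroundTruth(weights=w.to_numpy(), templates=templates,
                       level_gains={lv: np.array(g) for lv, g in meta["level_gains"].items()},
                       stride_plan=plan, seed=int(meta["seed"]),
                       channels=list(w.index))
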