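"""End-to-end study pipeline: sessions in, synergies and networks out.

``run_pipeline`` sequences the full analysis — artifact interpolation,
filtering, envelope extraction, stride selection, support stratification,
low-support amplitude scaling, grand averaging, level concatenation, model
order selection, synergy ordering, amplitude/shape metrics, and muscle
networks — and writes every result as delimited text together with a
machine-readable run manifest. Given fixed seeds the whole run is
bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import gait, io, network, preprocess, synergy
from .datatypes import LEVELS

logger = logging.getLogger(__name__)

_FLOAT = "%.17g"


@dataclass
class SessionPaths:
    """File locations for one recording session (one subject visit)."""

    emg: str
    events: str
    force: str
    weighing: str
    interruptions: str | None = None
    subject: str = "s1"


@dataclass
class StudyConfig:
    """All settings of a study run; defaults follow the study protocol."""

    sessions: list[SessionPaths] = field(default_factory=list)
    group_label: str = "FS"
    averaging: str = "pooled"            # pooled | per_subject
    # preprocessing
    artifact_sd_multiple: float = 10.0
    artifact_half_window_s: float = 0.150
    highpass_hz: float = 30.0
    notch_hz: float = 50.0
    envelope_lowpass_hz: float = 5.0
    cycle_samples: int = 200
    # body-weight support
    force_lowpass_hz: float = 20.0
    # synergy extraction
    n_range: tuple[int, int] = (1, 7)
    criterion_percent: float = 88.0
    nnmf_seed: int = 0
    nnmf_restarts: int = 20
    nnmf_max_iter: int = 2000
    nnmf_tol: float = 1e-8
    # networks
    network_threshold: float = 5e-5

    @classmethod
    def from_yaml(cls, path: Path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text())
        sessions = [SessionPaths(**s) for s in raw.pop("sessions", [])]
        if "n_range" in raw:
            raw["n_range"] = tuple(raw["n_range"])
        return cls(sessions=sessions, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["n_range"] = list(self.n_range)
        return d

    def to_yaml(self, path: Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class StudyResult:
    """In-memory bundle of everything the pipeline computed."""

    config: StudyConfig
    model: synergy.SynergyModel
    metrics: synergy.SynergyMetrics
    networks: list[network.SynergyNetwork]
    averages: dict
    cycles_per_level: dict[str, int]
    strides_per_session: dict[str, dict[str, int]]


def process_session(paths: SessionPaths, config: StudyConfig):
    """One session: raw files -> labelled, scaled 200-sample cycles."""
    rec = io.read_emg(Path(paths.emg))
    timeline = io.read_events(Path(paths.events))
    force = io.read_force(Path(paths.force))
    weighing = io.read_force(Path(paths.weighing))
    interruptions = (io.read_interruptions(Path(paths.interruptions))
                     if paths.interruptions else [])

    rec = preprocess.interpolate_artifacts(rec, config.artifact_sd_multiple,
                                           config.artifact_half_window_s)
    rec = preprocess.filter_emg(rec, config.highpass_hz, config.notch_hz)
    env = preprocess.envelope(rec, config.envelope_lowpass_hz)

    timeline = gait.select_valid_strides(timeline, interruptions)
    body_weight = gait.estimate_body_weight(weighing)
    support = gait.bws_per_stride(force, timeline, body_weight)

    cycles = preprocess.time_normalize(env, timeline, config.cycle_samples,
                                       subject=paths.subject)
    cycles = preprocess.attach_levels(cycles, support.level)
    # per-subject amplitude scaling makes sessions comparable before pooling
    cycles = preprocess.scale_to_low_support(cycles)

    counts = {lv: len(cycles.by_level(lv)) for lv in LEVELS}
    logger.info("session %s: strides per level %s", paths.subject, counts)
    return cycles, counts


def run_pipeline(config: StudyConfig, out_dir: Path | None = None) -> StudyResult:
    """Run the complete analysis for a study and optionally write results."""
    if not config.sessions:
        raise ValueError("config lists no sessions")

    all_cycles = None
    per_session: dict[str, dict[str, int]] = {}
    for paths in config.sessions:
        try:
            cycles, counts = process_session(paths, config)
        except Exception as exc:
            raise RuntimeError(f"session {paths.subject!r}: {exc}") from exc
        per_session[paths.subject] = counts
        if all_cycles is None:
            all_cycles = cycles
        else:
            if cycles.channels != all_cycles.channels:
                raise RuntimeError(f"session {paths.subject!r}: channel set differs")
            all_cycles.cycles.extend(cycles.cycles)

    averages = preprocess.grand_average(all_cycles,
                                        per_subject=(config.averaging == "per_subject"))
    X, level_index = synergy.concatenate_levels(averages)
    lo, hi = config.n_range
    model = synergy.select_n(X, level_index, n_range=range(lo, hi + 1),
                             criterion=config.criterion_percent,
                             seed=config.nnmf_seed, restarts=config.nnmf_restarts,
                             max_iter=config.nnmf_max_iter, tol=config.nnmf_tol,
                             channels=all_cycles.channels)
    model = synergy.order_synergies(model)
    metrics = synergy.amplitude_metrics(model)
    nets = network.networks_from_model(model, threshold=config.network_threshold)

    result = StudyResult(
        config=config, model=model, metrics=metrics, networks=nets,
        averages=averages,
        cycles_per_level={lv: len(all_cycles.by_level(lv)) for lv in LEVELS},
        strides_per_session=per_session,
    )
    if out_dir is not None:
        write_results(Path(out_dir), result)
    return result


def write_results(out_dir: Path, result: StudyResult) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    model, metrics = result.model, result.metrics
    cols = [f"S{i + 1}" for i in range(model.n)]
    chash = result.config.config_hash()

    def save(df: pd.DataFrame, name: str, index: bool = False) -> None:
        path = out_dir / name
        with open(path, "w") as fh:
            fh.write(f"# config_hash: {chash}\n")
            df.to_csv(fh, sep="\t", index=index, float_format=_FLOAT)

    save(pd.DataFrame(model.W, index=model.channels or None, columns=cols),
         "weights.tsv", index=True)
    for lv in LEVELS:
        if lv in model.P:
            save(pd.DataFrame(model.P[lv], columns=cols), f"patterns_{lv}.tsv")

    lam_rows = [{"selection": lv, "lambda_percent": model.lambda_by_level[lv]}
                for lv in LEVELS if lv in model.lambda_by_level]
    lam_rows.append({"selection": "overall", "lambda_percent": model.lambda_overall})
    save(pd.DataFrame(lam_rows), "lambda.tsv")

    amp_rows = [{"level": lv, "synergy": c, "mean_amplitude_change_percent": v}
                for lv, vec in metrics.mean_amplitude_change.items()
                for c, v in zip(cols, vec)]
    save(pd.DataFrame(amp_rows), "amplitude_metrics.tsv")

    xc_rows = [{"level_a": a, "level_b": b, "synergy": c,
                "circ_xcorr": r, "lag_samples": int(g)}
               for (a, b), rv in metrics.circ_xcorr.items()
               for c, r, g in zip(cols, rv, metrics.circ_lag[(a, b)])]
    save(pd.DataFrame(xc_rows), "circular_xcorr.tsv")

    edge_rows = [{"synergy": f"S{net.synergy}", "muscle_a": a, "muscle_b": b, "weight": w}
                 for net in result.networks for a, b, w in net.edges()]
    save(pd.DataFrame(edge_rows, columns=["synergy", "muscle_a", "muscle_b", "weight"]),
         "network_edges.tsv")
    net_rows = [{"synergy": f"S{net.synergy}", "density": net.density,
                 "transitivity": net.transitivity} for net in result.networks]
    save(pd.DataFrame(net_rows), "network_metrics.tsv")

    manifest = {
        "config_hash": chash,
        "config": result.config.to_dict(),
        "n_synergies": model.n,
        "criterion_met": model.criterion_met,
        "fit_meta": {k: (v if isinstance(v, (int, float, bool, str, type(None))) else str(v))
                     for k, v in model.fit_meta.items()},
        "cycles_per_level": result.cycles_per_level,
        "strides_per_session": result.strides_per_session,
        "versions": _versions(),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def _versions() -> dict[str, str]:
    import scipy
    import sklearn

    from . import __version__

    return {"synergait": __version__, "numpy": np.__version__,
            "scipy": scipy.__version__, "pandas": pd.__version__,
            "scikit-learn": sklearn.__version__}
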