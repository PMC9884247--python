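"""Serialization of every pipeline artifact.

Eye traces and 1-D results travel as tidy CSV, epochs as HDF5 with a JSON
trial-metadata sidecar, model fits and cluster results as JSON, configs as
YAML. All writers are deterministic (HDF5 object timestamps disabled) so a
re-run with identical inputs reproduces identical bytes.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd
import yaml

from .behavior import ScreeningReport, TraceDistanceResult
from .containers import DissimilarityTrace, EpochSet, EyeTrace, traces_meta
from .linmodel import LinearModelFit
from .mvpa import PreprocessSpec
from .stats import Cluster, ClusterResult
from .synth import SimulationConfig

# --------------------------------------------------------------------------
# eye traces


def save_eye_traces(traces: Sequence[EyeTrace], out_dir: str | Path) -> tuple[Path, Path]:
    """Write samples.csv (trial x ms rows) and trials.csv (metadata)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    frames = []
    for tr in traces:
        frames.append(pd.DataFrame({
            "trial_id": tr.trial_id,
            "time": tr.time,
            "pos_h": tr.pos_h, "pos_v": tr.pos_v,
            "vel_h": tr.vel_h, "vel_v": tr.vel_v,
        }))
    samples_path = out_dir / "samples.csv"
    trials_path = out_dir / "trials.csv"
    pd.concat(frames, ignore_index=True).to_csv(samples_path, index=False)
    traces_meta(traces).to_csv(trials_path, index=False)
    return samples_path, trials_path


def load_eye_traces(in_dir: str | Path) -> list[EyeTrace]:
    in_dir = Path(in_dir)
    samples_path = in_dir / "samples.csv"
    trials_path = in_dir / "trials.csv"
    for p in (samples_path, trials_path):
        if not p.exists():
            raise FileNotFoundError(f"eye-trace input missing: {p}")
    samples = pd.read_csv(samples_path)
    meta = pd.read_csv(trials_path)
    traces = []
    grouped = dict(tuple(samples.groupby("trial_id", sort=False)))
    for _, row in meta.iterrows():
        g = grouped[row["trial_id"]]
        lat = row.get("latency_true", np.nan)
        traces.append(EyeTrace(
            time=g["time"].to_numpy(),
            pos_h=g["pos_h"].to_numpy(), pos_v=g["pos_v"].to_numpy(),
            vel_h=g["vel_h"].to_numpy(), vel_v=g["vel_v"].to_numpy(),
            target_direction=float(row["target_direction"]),
            cue_direction=float(row["cue_direction"]),
            contrast=float(row["contrast"]),
            block=str(row["block"]),
            day=str(row["day"]),
            trial_id=str(row["trial_id"]),
            latency_true=None if pd.isna(lat) else float(lat),
        ))
    return traces


# --------------------------------------------------------------------------
# epochs


def save_epochs(epochs: EpochSet, path: str | Path) -> Path:
    """HDF5 container (data/time datasets, channel names attribute) + JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data, track_times=False)
        f.create_dataset("time", data=epochs.time, track_times=False)
        f.attrs["channel_names"] = [np.bytes_(c) for c in epochs.channel_names]
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    sidecar.write_text(epochs.trial_meta.to_json(orient="table", index=False))
    return path


def load_epochs(path: str | Path) -> EpochSet:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"epochs input missing: {path}")
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    if not sidecar.exists():
        raise FileNotFoundError(f"epochs metadata sidecar missing: {sidecar}")
    with h5py.File(path, "r") as f:
        data = f["data"][()]
        time = f["time"][()]
        channel_names = [c.decode() if isinstance(c, bytes) else str(c)
                         for c in f.attrs["channel_names"]]
    meta = pd.read_json(sidecar, orient="table")
    return EpochSet(data=data, channel_names=channel_names, time=time, trial_meta=meta)


# --------------------------------------------------------------------------
# dissimilarity traces


def save_dissimilarity(trace: DissimilarityTrace, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame({"time": trace.time, "value": trace.value})
    header = {
        "condition_pair": list(trace.condition_pair),
        "slice_label": trace.slice_label,
        "n_trials_used": list(trace.n_trials_used),
        "subsample_iterations": trace.subsample_iterations,
        "seed": trace.seed,
    }
    with open(path, "w") as fh:
        fh.write("# " + json.dumps(header) + "\n")
        df.to_csv(fh, index=False)
    return path


def load_dissimilarity(path: str | Path) -> DissimilarityTrace:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"dissimilarity input missing: {path}")
    with open(path) as fh:
        first = fh.readline()
        header = json.loads(first.lstrip("# ").strip()) if first.startswith("#") else {}
        df = pd.read_csv(fh)
    return DissimilarityTrace(
        time=df["time"].to_numpy(), value=df["value"].to_numpy(),
        condition_pair=tuple(header.get("condition_pair", ("cond1", "cond2"))),
        slice_label=header.get("slice_label", ""),
        n_trials_used=tuple(header.get("n_trials_used", (0, 0))),
        subsample_iterations=int(header.get("subsample_iterations", 1)),
        seed=header.get("seed"),
    )


# --------------------------------------------------------------------------
# fits, cluster results, reports


def _cond_key(cond) -> str:
    if isinstance(cond, tuple):
        return "@".join(str(c) for c in cond)
    return str(cond)


def save_fit(fit: LinearModelFit, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "weights": fit.weights,
        "t_s": fit.t_s, "t_m": fit.t_m,
        "r_squared": fit.r_squared, "rss": fit.rss,
        "window": list(fit.window), "variant": fit.variant,
        "intercept": fit.intercept,
        "search": fit.search,
        "conditions": [_cond_key(c) for c in fit.conditions],
        "predictions": {_cond_key(c): v.tolist() for c, v in fit.predictions.items()},
        "residuals": {_cond_key(c): v.tolist() for c, v in fit.residuals.items()},
        "observed": {_cond_key(c): v.tolist() for c, v in fit.observed.items()},
    }
    path.write_text(json.dumps(payload, indent=1, sort_keys=True))
    return path


def save_cluster_result(result: ClusterResult, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "threshold_p": result.threshold_p,
        "n_permutations": result.n_permutations,
        "seed": result.seed,
        "clusters": [dataclasses.asdict(c) for c in result.clusters],
    }
    path.write_text(json.dumps(payload, indent=1, sort_keys=True))
    return path


def load_cluster_result(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def save_screening_report(report: ScreeningReport, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps({
        "kept_trial_ids": report.kept_trial_ids,
        "rejected": report.rejected,
        "thresholds": {k: list(v) if isinstance(v, tuple) else v
                       for k, v in report.thresholds.items()},
    }, indent=1, sort_keys=True))
    return path


def save_distance_result(result: TraceDistanceResult, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cols = {"time": result.time}
    for block, arr in result.delta_y.items():
        cols[f"delta_y_{block}"] = arr
    if result.delta_delta_y is not None:
        cols["delta_delta_y"] = result.delta_delta_y
    pd.DataFrame(cols).to_csv(path, index=False)
    summary = path.with_suffix(".summary.json")
    summary.write_text(json.dumps({
        "value_at_100ms": result.value_at_100ms,
        "align": result.align,
        "mean_latency": result.mean_latency,
    }, indent=1, sort_keys=True))
    return path


# --------------------------------------------------------------------------
# configs


def _dataclass_to_dict(obj) -> dict:
    out = {}
    for f in dataclasses.fields(obj):
        v = getattr(obj, f.name)
        if isinstance(v, tuple):
            v = list(v)
        out[f.name] = v
    return out


def save_simulation_config(config: SimulationConfig, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump(_dataclass_to_dict(config), sort_keys=True))
    return path


def load_simulation_config(path: str | Path) -> SimulationConfig:
    raw = yaml.safe_load(Path(path).read_text())
    raw["target_reliability_by_contrast"] = {
        float(k): float(v) for k, v in raw["target_reliability_by_contrast"].items()}
    raw["latency_mean_by_contrast"] = {
        float(k): float(v) for k, v in raw["latency_mean_by_contrast"].items()}
    return SimulationConfig(**raw)


def save_preprocess_spec(spec: PreprocessSpec, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(_dataclass_to_dict(spec), sort_keys=True))
    return path


def load_preprocess_spec(path: str | Path) -> PreprocessSpec:
    raw = yaml.safe_load(Path(path).read_text())
    raw["analysis_window"] = tuple(raw["analysis_window"])
    return PreprocessSpec(**raw)
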