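"""End-to-end pipeline: simulate -> screen -> features -> dissimilarity ->
linear model -> residuals -> cluster test.

Runs the whole analysis over a small cohort of simulated participants (each
participant is one generator seed) and writes every intermediate artifact
plus a manifest with seeds and SHA-256 hashes, so identical configurations
reproduce identical outputs byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from . import behavior, features, io, linmodel, mvpa, stats
from .containers import INVALID, VALID, EpochSet
from .mvpa import PreprocessSpec
from .synth import SimulationConfig, generate_epochs, generate_eye_traces


@dataclass
class PipelineConfig:
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    pre: PreprocessSpec = field(default_factory=PreprocessSpec)
    n_participants: int = 4
    upper_dir: float = 0.0
    lower_dir: float = -60.0
    fit_window: tuple = (30.0, 330.0)
    shift_bounds: tuple = (-60, 60)
    variant: str = "reduced"
    cluster_threshold_p: float = 0.05
    n_permutations: int = 1000
    dissim_seed: int = 11
    cluster_seed: int = 12

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        payload = dataclasses.asdict(self)
        path.write_text(yaml.safe_dump(_tuples_to_lists(payload), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        sim = raw.pop("sim")
        sim["target_reliability_by_contrast"] = {
            float(k): float(v) for k, v in sim["target_reliability_by_contrast"].items()}
        sim["latency_mean_by_contrast"] = {
            float(k): float(v) for k, v in sim["latency_mean_by_contrast"].items()}
        pre = raw.pop("pre")
        pre["analysis_window"] = tuple(pre["analysis_window"])
        raw["fit_window"] = tuple(raw["fit_window"])
        raw["shift_bounds"] = tuple(raw["shift_bounds"])
        return cls(sim=SimulationConfig(**sim), pre=PreprocessSpec(**pre), **raw)


def _tuples_to_lists(obj):
    if isinstance(obj, dict):
        return {k: _tuples_to_lists(v) for k, v in obj.items()}
    if isinstance(obj, tuple):
        return [_tuples_to_lists(v) for v in obj]
    if isinstance(obj, list):
        return [_tuples_to_lists(v) for v in obj]
    return obj


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def condition_cells(config: PipelineConfig) -> list[tuple]:
    return [(block, contrast)
            for block in (VALID, INVALID)
            for contrast in config.sim.contrasts]


def analyze_participant(config: PipelineConfig, participant_seed: int,
                        out_dir: Path | None = None) -> dict:
    """Full single-participant analysis; returns traces, fits and residuals."""
    sim = replace(config.sim, seed=participant_seed)
    traces = generate_eye_traces(sim)
    report = behavior.screen_saccades(traces)
    kept = report.kept_traces(traces)

    dist = {c: behavior.rotate_and_distance(
        [tr for tr in kept if np.isclose(tr.contrast, c)],
        upper_dir=config.upper_dir, lower_dir=config.lower_dir)
        for c in sim.contrasts}

    epochs = generate_epochs(kept, sim)
    epochs = mvpa.preprocess_epochs(epochs, config.pre)

    neural, sens, motor = {}, {"irve": {}}, {"eye_velocity": {}}
    if config.variant == "full":
        sens["retinal_velocity_error"] = {}
        motor["eye_position"] = {}
    for cond in condition_cells(config):
        block, contrast = cond
        ep_cell = epochs.select_trials(block=block, contrast=contrast)
        ep_u = ep_cell.select_trials(target_direction=config.upper_dir)
        ep_l = ep_cell.select_trials(target_direction=config.lower_dir)
        neural[cond] = mvpa.crossval_dissimilarity(
            ep_u, ep_l, seed=config.dissim_seed,
            condition_pair=(config.upper_dir, config.lower_dir),
            slice_label=f"{block}@{contrast}")
        tr_cell = [tr for tr in kept
                   if tr.block == block and np.isclose(tr.contrast, contrast)]
        tr_u = [t for t in tr_cell if np.isclose(t.target_direction, config.upper_dir)]
        tr_l = [t for t in tr_cell if np.isclose(t.target_direction, config.lower_dir)]
        for kind, store in [*[(k, sens[k]) for k in sens], *[(k, motor[k]) for k in motor]]:
            fa = [features.feature_for_trial(t, kind, sim.target_speed) for t in tr_u]
            fb = [features.feature_for_trial(t, kind, sim.target_speed) for t in tr_l]
            store[cond] = mvpa.feature_dissimilarity(fa, fb, seed=config.dissim_seed)

    design = linmodel.build_design(neural, {**sens, **motor}, window=config.fit_window)
    fit = linmodel.fit(design, variant=config.variant, shift_bounds=config.shift_bounds)
    residuals, diffs = linmodel.residual_analysis(fit)

    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        io.save_eye_traces(kept, out_dir / "traces")
        io.save_screening_report(report, out_dir / "screening.json")
        for contrast, d in dist.items():
            io.save_distance_result(d, out_dir / f"distance_contrast{contrast}.csv")
        io.save_epochs(epochs, out_dir / "epochs.h5")
        for cond, tr in neural.items():
            io.save_dissimilarity(tr, out_dir / f"dissim_{cond[0]}_{cond[1]}.csv")
        io.save_fit(fit, out_dir / "fit.json")
    return {"screening": report, "distance": dist, "neural": neural,
            "fit": fit, "residuals": residuals, "residual_diffs": diffs}


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Run every stage for all participants and write a hashed manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": _tuples_to_lists(dataclasses.asdict(config)),
        "stages": [],
        "files": {},
        "status": "running",
    }
    manifest_path = out_dir / "manifest.json"
    try:
        per_part = []
        for p in range(config.n_participants):
            seed = config.sim.seed + 1000 * p
            res = analyze_participant(config, seed, out_dir / f"participant{p:02d}")
            per_part.append(res)
            manifest["stages"].append({"stage": f"participant{p:02d}", "seed": seed,
                                       "status": "ok"})

        # group-level: cluster test of valid-minus-invalid residuals per contrast
        window = per_part[0]["fit"].window
        fit_time = np.arange(window[0], window[1] + 1.0)
        for contrast in config.sim.contrasts:
            mat = np.stack([res["residual_diffs"][contrast] for res in per_part])
            cres = stats.cluster_test(mat, time=fit_time,
                                      threshold_p=config.cluster_threshold_p,
                                      n_perm=config.n_permutations,
                                      seed=config.cluster_seed)
            io.save_cluster_result(cres, out_dir / f"cluster_contrast{contrast}.json")
        manifest["stages"].append({"stage": "cluster_test", "status": "ok"})
        manifest["status"] = "complete"
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["stages"].append({"stage": "failed", "error": f"{type(exc).__name__}: {exc}"})
        manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
        raise
    for path in sorted(out_dir.rglob("*")):
        if path.is_file() and path != manifest_path:
            manifest["files"][str(path.relative_to(out_dir))] = _sha256(path)
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
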