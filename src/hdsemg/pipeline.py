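"""End-to-end orchestration: simulate -> qc -> maps -> features -> classify.

One RunConfig drives every stage; a single global seed fans out to per-stage
seeds through a named SeedSequence derivation so stages are individually
reproducible. The run manifest records the verbatim stage parameters, the
derived seeds, and SHA-256 hashes of every written output.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import classify_task_effort, classify_tasks
from .features import FEATURE_KINDS, build_feature_set
from .grids import channels_to_grid
from .maps import average_maps, compute_am, segment_for_muscles
from .preprocessing import EpochSpec, bandpass_zero_phase, epoch_signal, \
    select_stability_window
from .quality import compute_channel_features, detect_outliers_ldof, \
    detect_outliers_rules
from .simulate import SimulationConfig, make_dataset

__all__ = ["RunConfig", "run_pipeline", "stage_seed"]

STAGES = ("simulate", "qc", "maps", "features", "classify")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed by name."""
    h = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


@dataclass
class RunConfig:
    """Pipeline configuration; round-trips losslessly through YAML."""
    stages: tuple = STAGES
    source: str = "synthetic"  # or a dataset path
    seed: int = 0
    out_dir: str = "hdsemg_run"
    n_reps: int = 1
    duration: float = 10.0
    qc_method: str = "rules"
    feature_kinds: tuple = FEATURE_KINDS
    n_repeats: int = 20
    epoch_s: float = 0.15

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        d["stages"] = tuple(d.get("stages", STAGES))
        d["feature_kinds"] = tuple(d.get("feature_kinds", FEATURE_KINDS))
        return cls(**d)


def _hash_array(a: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(a).tobytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the selected stages in dependency order and return the manifest.

    Later stages recompute their inputs from the simulate stage held in
    memory; requesting a downstream stage without ``simulate`` (on synthetic
    input) is a dependency error.
    """
    stages = list(config.stages)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stage(s) {sorted(unknown)}")
    if config.source == "synthetic" and stages and "simulate" not in stages:
        raise ValueError("stage 'simulate' is required for synthetic input "
                         f"before {stages[0]!r}")
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {"version": __version__, "seed": config.seed,
                "stage_seeds": {s: stage_seed(config.seed, s) for s in stages},
                "config": asdict(config), "outputs": {}}

    base = SimulationConfig(duration=config.duration)
    dataset = make_dataset(stage_seed(config.seed, "simulate"),
                           n_reps=config.n_reps, base_config=base)
    manifest["outputs"]["simulate"] = {
        "n_recordings": len(dataset),
        "hash": _hash_array(np.concatenate(
            [r.recordings[0].signals[:1] for r in dataset], axis=None)),
    }

    if "qc" in stages:
        rows = []
        for i, rec in enumerate(dataset):
            for g, r in enumerate(rec.recordings):
                feats = compute_channel_features(r.signals, r.grid, r.fs)
                rep = (detect_outliers_rules(feats, r.grid)
                       if config.qc_method == "rules"
                       else detect_outliers_ldof(feats))
                for ch in range(r.n_channels):
                    rows.append({"recording": i, "grid": g, "channel": ch,
                                 "flagged": bool(rep.flags[ch]),
                                 "rules": "+".join(rep.rules[ch])})
        qc_table = pd.DataFrame(rows)
        path = out_dir / "qc_report.tsv"
        qc_table.to_csv(path, sep="\t", index=False)
        manifest["outputs"]["qc"] = {
            "path": str(path),
            "fraction_flagged": float(qc_table["flagged"].mean()),
            "hash": hashlib.sha256(path.read_bytes()).hexdigest()}

    if "maps" in stages:
        spec = None
        map_rows = []
        for i, rec in enumerate(dataset):
            fs = rec.recordings[0].fs
            start, end = select_stability_window(rec.torque, fs)
            spec = EpochSpec(length_s=0.5, fs=fs)
            for g, r in enumerate(rec.recordings):
                sig = bandpass_zero_phase(r.signals, fs)[:, start:end]
                ams = [compute_am(channels_to_grid(ep, r.grid), grid=r.grid)
                       for ep in epoch_signal(sig, spec)]
                avg = average_maps(ams)
                np.savetxt(out_dir / f"map_rec{i}_grid{g}.tsv",
                           avg.values, delimiter="\t")
                map_rows.append({"recording": i, "grid": g,
                                 "task": rec.truth["task"],
                                 "effort": rec.truth["effort"],
                                 "max_rms": float(avg.values.max())})
        table = pd.DataFrame(map_rows)
        path = out_dir / "maps_summary.tsv"
        table.to_csv(path, sep="\t", index=False)
        manifest["outputs"]["maps"] = {
            "path": str(path), "n_maps": len(map_rows),
            "hash": hashlib.sha256(path.read_bytes()).hexdigest()}

    feature_sets = {}
    if "features" in stages or "classify" in stages:
        for kind in config.feature_kinds:
            feature_sets[kind] = build_feature_set(
                kind, dataset, epoch_s=config.epoch_s,
                seed=stage_seed(config.seed, "features"))
        if "features" in stages:
            info = {}
            for kind, fsset in feature_sets.items():
                path = out_dir / f"features_{kind}.tsv"
                df = pd.DataFrame(fsset.X)
                df.insert(0, "task", fsset.tasks)
                df.insert(1, "effort", fsset.efforts)
                df.to_csv(path, sep="\t", index=False)
                info[kind] = {"path": str(path), "shape": list(fsset.X.shape),
                              "hash": hashlib.sha256(
                                  path.read_bytes()).hexdigest()}
            manifest["outputs"]["features"] = info

    if "classify" in stages:
        seed = stage_seed(config.seed, "classify")
        results = {}
        for kind, fsset in feature_sets.items():
            task_res = classify_tasks(fsset, n_repeats=config.n_repeats,
                                      seed=seed)
            both_res = classify_task_effort(fsset, n_repeats=config.n_repeats,
                                            seed=seed)
            results[kind] = {
                "task": {"acc": task_res.acc_mean, "acc_sd": task_res.acc_sd,
                         "f1": task_res.f1_mean, "auc": task_res.auc_mean,
                         "auc_sd": task_res.auc_sd},
                "task_effort": {"acc": both_res.acc_mean,
                                "f1": both_res.f1_mean,
                                "auc": both_res.auc_mean,
                                "auc_sd": both_res.auc_sd},
            }
        path = out_dir / "classification_summary.json"
        path.write_text(json.dumps(results, indent=2))
        manifest["outputs"]["classify"] = {
            "path": str(path),
            "hash": hashlib.sha256(path.read_bytes()).hexdigest()}

    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
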