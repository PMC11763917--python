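"""End-to-end experiment orchestration on synthetic cohorts.

``run_pipeline`` chains the workflow stages — simulate, pretrain, finetune,
explain, report — writing every artifact with a provenance record (stage,
seed, config hash) so that a rerun under the same configuration and seeds
reproduces the metric files exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .core_data import Cohort, read_cohort, write_cohort, split_subjects
from .model import ModelConfig, SequenceClassifier
from .synthetic import ChirpParams, EpisodicCohortParams, generate_chirp_cohort, generate_episodic_cohort
from .training import TrainConfig, cross_validate, pretrain, reverse_time
from .interpretability import (
    SaliencyMap,
    alignment_correlation,
    emd_spikiness,
    flip_time_saliency,
    integrated_gradients,
    submodular_pick,
)

__all__ = ["ExperimentConfig", "PipelineError", "run_pipeline", "STAGES"]

log = logging.getLogger("arrowtime")

STAGES = ("simulate", "pretrain", "finetune", "explain", "report")


class PipelineError(RuntimeError):
    """A stage cannot run, typically because an upstream artifact is missing."""


@dataclass
class ExperimentConfig:
    """Everything one experiment needs: paths, model, training, analysis knobs."""

    data_dir: str = "data"
    output_dir: str = "output"
    # simulation
    n_pretrain_subjects: int = 60
    chirp: ChirpParams = field(default_factory=lambda: ChirpParams(n_components=8, n_timepoints=160))
    episodic: EpisodicCohortParams = field(default_factory=EpisodicCohortParams)
    # model / training
    model: ModelConfig = field(default_factory=lambda: ModelConfig(input_size=8))
    train: TrainConfig = field(default_factory=TrainConfig)
    pretrain_method: str = "tr"
    from_scratch: bool = False
    # attribution / analysis
    ig_steps: int = 64
    top_fraction: float = 0.05
    emd_normalize: bool = False
    n_explain_subjects: int = 8
    pick_budget: int = 5
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "ExperimentConfig":
        kwargs = dict(raw)
        for key, sub in (("chirp", ChirpParams), ("episodic", EpisodicCohortParams),
                         ("model", ModelConfig), ("train", TrainConfig)):
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = sub(**kwargs[key])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _record_provenance(out_dir: Path, stage: str, config: ExperimentConfig, artifacts: list[str]) -> None:
    path = out_dir / "provenance.json"
    records = []
    if path.exists():
        records = json.loads(path.read_text())
    records.append(
        {
            "stage": stage,
            "seed": config.seed,
            "config_hash": config.config_hash(),
            "artifacts": artifacts,
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        }
    )
    path.write_text(json.dumps(records, indent=1))


def _require(path: Path, stage: str, needed_by: str) -> Path:
    if not path.exists():
        raise PipelineError(
            f"stage '{needed_by}' needs {path}, which is produced by stage '{stage}'; "
            f"run '{stage}' first"
        )
    return path


def _stage_simulate(config: ExperimentConfig) -> list[str]:
    data_dir = Path(config.data_dir)
    chirp_cohort = generate_chirp_cohort(config.n_pretrain_subjects, config.chirp)
    m1 = write_cohort(chirp_cohort, data_dir / "pretrain")
    episodic = generate_episodic_cohort(config.episodic)
    m2 = write_cohort(episodic, data_dir / "downstream")
    log.info("simulate: wrote %d pretraining and %d downstream subjects",
             len(chirp_cohort), len(episodic))
    return [str(m1), str(m2)]


def _stage_pretrain(config: ExperimentConfig) -> list[str]:
    data_dir, out_dir = Path(config.data_dir), Path(config.output_dir)
    manifest = _require(data_dir / "pretrain" / "manifest.json", "simulate", "pretrain")
    cohort = read_cohort(manifest)
    train_subjects, test_subjects = split_subjects(cohort, 0.2, config.seed, stratify=False)
    train_cohort = Cohort(cohort.name + "-train", train_subjects)
    model, test_acc = pretrain(config.pretrain_method, train_cohort, config.model, config.train)
    out_dir.mkdir(parents=True, exist_ok=True)
    ckpt = out_dir / "pretrained"
    model.provenance = f"pretrained:{config.pretrain_method}"
    model.save(ckpt)
    holdout_ids = [s.subject_id for s in test_subjects]
    summary = {"method": config.pretrain_method, "example_holdout_accuracy": test_acc,
               "holdout_subjects": holdout_ids}
    (out_dir / "pretrain_summary.json").write_text(json.dumps(summary, indent=1))
    log.info("pretrain[%s]: held-out example accuracy %.3f", config.pretrain_method, test_acc)
    return [str(ckpt) + ".npz", str(out_dir / "pretrain_summary.json")]


def _load_pretrained(config: ExperimentConfig) -> SequenceClassifier:
    out_dir = Path(config.output_dir)
    _require(out_dir / "pretrained.npz", "pretrain", "finetune/explain")
    return SequenceClassifier.load(out_dir / "pretrained")


def _stage_finetune(config: ExperimentConfig) -> list[str]:
    data_dir, out_dir = Path(config.data_dir), Path(config.output_dir)
    manifest = _require(data_dir / "downstream" / "manifest.json", "simulate", "finetune")
    cohort = read_cohort(manifest)
    init_from = None if config.from_scratch else _load_pretrained(config)
    folds = cross_validate(cohort, config.model, config.train, init_from=init_from)
    out_dir.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(
        [
            {"fold": f.fold_index, "auc": f.auc, "accuracy": f.accuracy,
             "balanced_accuracy": f.balanced_accuracy}
            for f in folds
        ]
    )
    csv_path = out_dir / ("folds_scratch.csv" if config.from_scratch else "folds_pretrained.csv")
    df.to_csv(csv_path, index=False)
    summary = {
        "init": "scratch" if config.from_scratch else "pretrained",
        "median_auc": float(df["auc"].median()),
        "iqr_auc": float(df["auc"].quantile(0.75) - df["auc"].quantile(0.25)),
        "median_balanced_accuracy": float(df["balanced_accuracy"].median()),
    }
    summary_path = csv_path.with_suffix(".summary.json")
    summary_path.write_text(json.dumps(summary, indent=1))
    log.info("finetune[%s]: median AUC %.3f", summary["init"], summary["median_auc"])
    return [str(csv_path), str(summary_path)]


def _stage_explain(config: ExperimentConfig) -> list[str]:
    data_dir, out_dir = Path(config.data_dir), Path(config.output_dir)
    manifest = _require(data_dir / "pretrain" / "manifest.json", "simulate", "explain")
    model = _load_pretrained(config)
    cohort = read_cohort(manifest)
    summary_path = _require(out_dir / "pretrain_summary.json", "pretrain", "explain")
    holdout_ids = set(json.loads(summary_path.read_text())["holdout_subjects"])
    subjects = [s for s in cohort if s.subject_id in holdout_ids][: config.n_explain_subjects]
    maps_dir = out_dir / "saliency"
    maps_dir.mkdir(parents=True, exist_ok=True)
    index = []
    for s in subjects:
        fwd = integrated_gradients(model, s.values, steps=config.ig_steps,
                                   subject_id=s.subject_id, direction="forward")
        rev = integrated_gradients(model, reverse_time(s.values), steps=config.ig_steps,
                                   subject_id=s.subject_id, direction="reverse")
        for tag, smap in (("forward", fwd), ("reverse", rev)):
            fname = f"{s.subject_id}_{tag}.csv"
            np.savetxt(maps_dir / fname, smap.attributions, delimiter=",", fmt="%.17g")
            index.append({"subject": s.subject_id, "direction": tag, "aligned": False,
                          "file": fname, "steps": config.ig_steps, "baseline": "zeros"})
    (maps_dir / "index.json").write_text(json.dumps(index, indent=1))
    log.info("explain: wrote %d saliency maps", len(index))
    return [str(maps_dir / "index.json")]


def _load_maps(maps_dir: Path) -> dict[str, dict[str, SaliencyMap]]:
    index = json.loads(_require(maps_dir / "index.json", "explain", "report").read_text())
    by_subject: dict[str, dict[str, SaliencyMap]] = {}
    for rec in index:
        attr = np.loadtxt(maps_dir / rec["file"], delimiter=",", ndmin=2)
        by_subject.setdefault(rec["subject"], {})[rec["direction"]] = SaliencyMap(
            rec["subject"], attr, direction=rec["direction"], aligned=rec["aligned"]
        )
    return by_subject


def _stage_report(config: ExperimentConfig) -> list[str]:
    out_dir = Path(config.output_dir)
    by_subject = _load_maps(out_dir / "saliency")
    rows, emd_rows, fwd_maps = [], [], []
    for sid, directions in sorted(by_subject.items()):
        fwd, rev = directions.get("forward"), directions.get("reverse")
        if fwd is None or rev is None:
            continue
        r = alignment_correlation(fwd, flip_time_saliency(rev))
        rows.append({"subject": sid, "pearson_r": r})
        emd_rows.append({"subject": sid,
                         "emd_spikiness": emd_spikiness(fwd, config.top_fraction,
                                                        normalize=config.emd_normalize)})
        fwd_maps.append(fwd)
    align_csv = out_dir / "alignment_correlation.csv"
    pd.DataFrame(rows).to_csv(align_csv, index=False)
    emd_csv = out_dir / "emd_report.csv"
    pd.DataFrame(emd_rows).to_csv(emd_csv, index=False)
    picks = submodular_pick(fwd_maps, config.pick_budget)
    pick_path = out_dir / "submodular_pick.json"
    pick_path.write_text(json.dumps(
        {"picked_subjects": [fwd_maps[i].subject_id for i in picks]}, indent=1))
    log.info("report: %d subjects, median alignment r=%.3f", len(rows),
             float(np.median([r["pearson_r"] for r in rows])) if rows else float("nan"))
    return [str(align_csv), str(emd_csv), str(pick_path)]


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "pretrain": _stage_pretrain,
    "finetune": _stage_finetune,
    "explain": _stage_explain,
    "report": _stage_report,
}


def run_pipeline(config: ExperimentConfig, stages: Sequence[str]) -> dict[str, list[str]]:
    """Execute the requested stages in canonical order; returns artifacts per stage."""
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, list[str]] = {}
    for stage in STAGES:
        if stage not in stages:
            continue
        log.info("=== stage %s (seed %d) ===", stage, config.seed)
        produced = _STAGE_FUNCS[stage](config)
        _record_provenance(out_dir, stage, config, produced)
        artifacts[stage] = produced
    return artifacts
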