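"""Declarative pipeline wiring the stages: curate → train → score → report →
geometry filter.

A single config (YAML mapping or dict) drives the run; every stage writes
its artifacts under ``outdir`` and records a content stamp (SHA-256 of its
inputs and of its section of the config), so unchanged stages are skipped
on re-runs and two runs with the same config and seed produce identical
artifacts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

import yaml

from . import datamodel_io, geometry, ise_core, screening, synthetic
from .datamodel_io import DescriptorTable, ISEConfig

logger = logging.getLogger(__name__)

DEFAULT_BORDERS = (-3.0, 3.0, 6.0, 9.0, 10.0, 13.0)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Validated pipeline configuration."""

    raw: dict
    outdir: Path
    seed: int

    @classmethod
    def load(cls, source: str | Path | Mapping) -> "PipelineConfig":
        if isinstance(source, (str, Path)):
            raw = yaml.safe_load(Path(source).read_text())
        else:
            raw = dict(source)
        if not isinstance(raw, dict):
            raise ValueError("pipeline config must be a mapping")
        outdir = Path(raw.get("outdir", "ise_out"))
        seed = int(raw.get("seed", 0))
        known = {"outdir", "seed", "simulate", "prune", "pick_inactives",
                 "train", "score", "report", "geometry"}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown pipeline config sections: {sorted(unknown)}")
        for section in ("simulate", "train", "score", "report", "geometry",
                        "prune", "pick_inactives"):
            value = raw.get(section)
            if value is not None and not isinstance(value, dict):
                raise ValueError(f"config section {section!r} must be a mapping")
        return cls(raw, outdir, seed)


def _sha256_of(paths: list[Path], extra: Any) -> str:
    h = hashlib.sha256(json.dumps(extra, sort_keys=True, default=str).encode())
    for p in paths:
        h.update(p.read_bytes())
    return h.hexdigest()


class _Stages:
    def __init__(self, cfg: PipelineConfig):
        self.cfg = cfg
        self.outdir = cfg.outdir
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.artifacts: dict[str, Path] = {}

    def _stamp_path(self, stage: str) -> Path:
        return self.outdir / f".{stage}.stamp"

    def skip_or_run(self, stage: str, inputs: list[Path], section: Any,
                    outputs: list[Path], fn) -> None:
        for p in inputs:
            if not p.exists():
                raise StageError(stage, FileNotFoundError(p))
        digest = _sha256_of(inputs, section)
        stamp = self._stamp_path(stage)
        if stamp.exists() and all(o.exists() for o in outputs):
            if json.loads(stamp.read_text()).get("digest") == digest:
                logger.info("stage %s: unchanged, skipped", stage)
                return
        if stamp.exists():
            stamp.unlink()  # mark partial outputs invalid while running
        try:
            fn()
        except Exception as exc:
            for o in outputs:
                if o.exists():
                    o.rename(o.with_suffix(o.suffix + ".invalid"))
            raise StageError(stage, exc) from exc
        stamp.write_text(json.dumps({"digest": digest}))

    # -- stages ------------------------------------------------------------
    def simulate(self, section: dict) -> None:
        spec = synthetic.SyntheticSpec(
            seed=int(section.get("seed", self.cfg.seed)),
            **{k: section[k] for k in ("n_actives", "n_inactives", "n_informative",
                                       "n_noise", "shift") if k in section})
        train_csv = self.outdir / "train.csv"
        test_csv = self.outdir / "test.csv"
        self.artifacts["train_table"] = train_csv
        self.artifacts["test_table"] = test_csv

        def run() -> None:
            synthetic.gen_descriptor_dataset(spec).table.to_csv(train_csv)
            test_spec = synthetic.SyntheticSpec(**{**spec.__dict__,
                                                   "seed": spec.seed + 1})
            synthetic.gen_descriptor_dataset(test_spec).table.to_csv(test_csv)

        self.skip_or_run("simulate", [], spec.__dict__, [train_csv, test_csv], run)

    def train(self, section: dict) -> None:
        table_path = Path(section.get("table", self.artifacts.get("train_table", "")))
        model_path = self.outdir / "model.json"
        self.artifacts["model"] = model_path
        ise_cfg = ISEConfig.from_dict({"seed": self.cfg.seed,
                                       **section.get("ise", {})})

        def run() -> None:
            table = DescriptorTable.from_csv(table_path).drop_incomplete()
            model = ise_core.build_model(table, ise_cfg)
            datamodel_io.save_model(model, model_path)

        self.skip_or_run("train", [table_path], ise_cfg.to_dict(), [model_path], run)

    def score(self, section: dict) -> None:
        model_path = Path(section.get("model", self.artifacts.get("model", "")))
        table_path = Path(section.get("table", self.artifacts.get("test_table", "")))
        scores_path = self.outdir / "scores.csv"
        self.artifacts["scores"] = scores_path

        def run() -> None:
            model = datamodel_io.load_model(model_path)
            table = DescriptorTable.from_csv(table_path).drop_incomplete()
            screening.score_table(model, table,
                                  normalize=bool(section.get("normalize", False))
                                  ).to_csv(scores_path, index_label="id")

        self.skip_or_run("score", [model_path, table_path], section,
                         [scores_path], run)

    def report(self, section: dict) -> None:
        import pandas as pd

        scores_path = Path(section.get("scores", self.artifacts.get("scores", "")))
        borders = [float(b) for b in section.get("borders", DEFAULT_BORDERS)]
        report_path = self.outdir / "report.csv"
        self.artifacts["report"] = report_path

        def run() -> None:
            df = pd.read_csv(scores_path, index_col=0)
            rep = screening.threshold_report(df["mbi"], df["label"], borders)
            rep.to_csv(report_path)
            logger.info("threshold report:\n%s", screening.format_threshold_report(rep))

        self.skip_or_run("report", [scores_path], {"borders": borders},
                         [report_path], run)

    def geometry(self, section: dict) -> None:
        receptor = Path(section["receptor"])
        pose_files = [Path(p) for p in section["poses"]]
        criteria_path = Path(section["criteria"])
        verdicts_path = self.outdir / "verdicts.json"
        self.artifacts["verdicts"] = verdicts_path

        def run() -> None:
            residues, _ = geometry.read_receptor(receptor)
            crit = geometry.read_criteria(criteria_path)
            out = {}
            for pf in pose_files:
                poses = geometry.read_poses_sdf(pf, section.get("energy_tag", "energy"))
                verdict = geometry.molecule_dock_verdict(poses, residues, crit)
                out[pf.stem] = {
                    "accepted": verdict.accepted,
                    "n_passing": verdict.n_passing,
                    "selected_pose": (verdict.selected_pose.index
                                      if verdict.selected_pose else None),
                }
            verdicts_path.write_text(json.dumps(out, indent=1))

        self.skip_or_run("geometry", [receptor, criteria_path, *pose_files],
                         {k: str(v) for k, v in section.items()},
                         [verdicts_path], run)


def run_pipeline(config: str | Path | Mapping) -> dict[str, Path]:
    """Execute the configured stages in order; returns artifact paths.

    A resolved copy of the configuration is written next to the outputs.
    """
    cfg = PipelineConfig.load(config)
    stages = _Stages(cfg)
    (cfg.outdir / "resolved_config.yaml").parent.mkdir(parents=True, exist_ok=True)
    (cfg.outdir / "resolved_config.yaml").write_text(yaml.safe_dump(cfg.raw))
    for name in ("simulate", "train", "score", "report", "geometry"):
        section = cfg.raw.get(name)
        if section is None:
            continue
        getattr(stages, name)(section)
    (cfg.outdir / "run_summary.json").write_text(json.dumps(
        {k: str(v) for k, v in stages.artifacts.items()}, indent=1))
    return stages.artifacts
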