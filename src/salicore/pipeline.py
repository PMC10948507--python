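"""End-to-end orchestration: traits -> scoring -> model -> core -> validation.

A :class:`PipelineConfig` fully determines a run; given the same inputs and
seed the artifacts are bit-identical. Each stage writes a CSV/YAML/JSON
artifact with a provenance comment, and a manifest records input checksums,
the seed, package versions, and aggregated warnings.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .core import core_objectives, gower_matrix, select_core
from .exceptions import PipelineConfigError
from .scoring import classify_tolerance, comprehensive_d, fit_tolerance_model, membership_matrix
from .traits import (
    DEFAULT_DIRECTIONS,
    assemble_trait_table,
    load_directions_yaml,
    load_raw_phenotypes,
    load_trait_table,
    write_trait_table,
)
from .validation import representativeness_metrics

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths and stage parameters for a full run."""

    output_dir: str = "salicore_run"
    trait_table: str | None = None
    raw_phenotypes: str | None = None
    directions: str | None = None
    cut_height: float = 0.12
    linkage: str = "complete"
    model_mode: str = "fixed_predictors"
    core_fraction: float = 0.20
    core_weights: tuple[float, float] = (0.5, 0.5)
    seed: int = 0
    patience: int = 5000
    replicas: int = 4
    log_level: str = "INFO"

    def validate(self) -> None:
        if not (0 < self.core_fraction <= 1):
            raise PipelineConfigError(f"core fraction {self.core_fraction} outside (0, 1]")
        if self.trait_table is None and self.raw_phenotypes is None:
            raise PipelineConfigError("either trait_table or raw_phenotypes must be given")
        for path in (self.trait_table, self.raw_phenotypes, self.directions):
            if path is not None and not Path(path).exists():
                raise PipelineConfigError(f"input path does not exist: {path}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if "core_weights" in raw:
            raw["core_weights"] = tuple(raw["core_weights"])
        return cls(**raw)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and return the run manifest (also written to disk)."""
    config.validate()
    logging.basicConfig(level=config.log_level)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    prov = f"salicore {__version__} seed={config.seed}"
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "inputs": {},
        "artifacts": {},
        "warnings": [],
        "stages": [],
    }

    def _stage(name: str):
        t0 = time.perf_counter()
        manifest["stages"].append({"stage": name})
        logger.info("stage %s started", name)
        return t0

    def _done(name: str, t0: float, rows: int | None = None) -> None:
        # wall time goes to the log only, keeping the manifest bit-reproducible
        manifest["stages"][-1].update(rows=rows)
        logger.info("stage %s done in %.3fs", name, time.perf_counter() - t0)

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")

        directions = (load_directions_yaml(config.directions)
                      if config.directions else dict(DEFAULT_DIRECTIONS))

        t0 = _stage("traits")
        if config.trait_table is not None:
            manifest["inputs"]["trait_table"] = _checksum(Path(config.trait_table))
            table = load_trait_table(config.trait_table, directions)
        else:
            manifest["inputs"]["raw_phenotypes"] = _checksum(Path(config.raw_phenotypes))
            records = load_raw_phenotypes(config.raw_phenotypes)
            result = assemble_trait_table(records, directions)
            table = result.table
            manifest["exclusions"] = [
                {"genotype_id": e.genotype_id, "reason": e.reason, "trait": e.trait}
                for e in result.exclusions]
        table_path = out / "trait_table.csv"
        write_trait_table(table, table_path, provenance=prov)
        manifest["artifacts"]["trait_table"] = str(table_path)
        _done("traits", t0, len(table.data))

        t0 = _stage("scoring")
        mfv = membership_matrix(table)
        d = comprehensive_d(mfv)
        _write_csv(mfv.values, out / "mfv.csv", prov)
        _write_csv(d.to_frame(), out / "d_values.csv", prov)
        manifest["artifacts"]["mfv"] = str(out / "mfv.csv")
        manifest["artifacts"]["d_values"] = str(out / "d_values.csv")
        _done("scoring", t0, len(d))

        t0 = _stage("classification")
        classes = classify_tolerance(d, cut_height=config.cut_height,
                                     linkage=config.linkage)
        _write_csv(classes.labels.to_frame(), out / "classes.csv", prov)
        manifest["artifacts"]["classes"] = str(out / "classes.csv")
        _done("classification", t0, len(classes.labels))

        t0 = _stage("model")
        model = fit_tolerance_model(table, d, mode=config.model_mode)
        model.to_yaml(out / "model.yaml")
        manifest["artifacts"]["model"] = str(out / "model.yaml")
        _done("model", t0)

        t0 = _stage("core")
        dist = gower_matrix(table)
        selection = select_core(dist, fraction=config.core_fraction,
                                weights=config.core_weights, seed=config.seed,
                                replicas=config.replicas, patience=config.patience)
        (out / "core_ids.txt").write_text("\n".join(selection.genotype_ids) + "\n")
        objectives = core_objectives(dist, selection.selected, config.core_weights)
        (out / "objectives.json").write_text(json.dumps(objectives, indent=2) + "\n")
        manifest["artifacts"]["core_ids"] = str(out / "core_ids.txt")
        manifest["artifacts"]["objectives"] = str(out / "objectives.json")
        _done("core", t0, len(selection.selected))

        t0 = _stage("validation")
        core_table = table.subset(selection.genotype_ids)
        report = representativeness_metrics(table, core_table)
        _write_csv(report.per_trait, out / "validation.csv", prov)
        payload = {"summary": report.summary, "verdicts": report.verdicts}
        (out / "validation.json").write_text(json.dumps(payload, indent=2) + "\n")
        manifest["artifacts"]["validation"] = str(out / "validation.csv")
        _done("validation", t0, len(report.per_trait))

        manifest["warnings"] = sorted({str(w.message) for w in caught})

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def _write_csv(df: pd.DataFrame, path: Path, provenance: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# {provenance}\n")
        df.to_csv(fh, float_format="%.17g")
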