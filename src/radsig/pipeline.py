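"""Configuration-driven orchestration of discovery and validation runs.

A YAML run configuration names the datasets (with roles ``derive`` or
``validate``), the gene panel, the feature-selection algorithms, the
optimized criterion, the (C, sigma) cells to sweep, and the seeds.  A
discovery run executes preprocessing -> mRMR ranking -> feature selection
for every configured cell, applies the post-selection grid search to each
selected signature, and writes signature files, trajectories and a
manifest.  A validation run k-fold-validates (and, where a paired training
dataset is given, traditionally validates) each signature against each
validation dataset, skipping signatures that are not fully contained in a
dataset.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .containers import DoseLabels, ExpressionMatrix, GenePanel, ProbeAnnotation
from .feature_selection import Signature, bsfs, csfs, fsfs
from .mrmr import discretize_expression, mid_rank
from .preprocess import preprocess_pipeline
from .svm import HyperParams, grid_search
from .validation import (
    check_signature_eligibility,
    kfold_validate_signature,
    traditional_validate,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_discovery", "run_validate"]

_FS_FUNCS = {"CSFS": csfs, "FSFS": fsfs, "BSFS": bsfs}


@dataclass
class DatasetSpec:
    id: str
    expression: str
    labels: str
    role: str = "derive"  # derive | validate
    annotation: str | None = None


@dataclass
class RunConfig:
    datasets: list[DatasetSpec]
    panel: str
    algorithms: list[str] = field(default_factory=lambda: ["FSFS"])
    criterion: str = "log_loss"
    cells: list[tuple[float, float]] = field(default_factory=lambda: [(10.0, 1.0)])
    n_rank: int = 50
    k: int = 5
    repeats: int = 20
    seed: int = 0
    alpha: float = 0.5
    out_dir: str = "radsig_run"

    def __post_init__(self) -> None:
        if self.criterion not in {"misclassification", "log_loss"}:
            raise ValueError(f"unknown criterion {self.criterion!r}")
        for algo in self.algorithms:
            if algo not in _FS_FUNCS:
                raise ValueError(f"unknown FS algorithm {algo!r}")
        if not any(d.role == "derive" for d in self.datasets):
            raise ValueError("config needs at least one derivation dataset")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        datasets = [DatasetSpec(**d) for d in raw.pop("datasets")]
        cells = [tuple(map(float, c)) for c in raw.pop("cells", [[10.0, 1.0]])]
        return cls(datasets=datasets, cells=cells, **raw)


def _load_datasets(config: RunConfig, role: str):
    out = []
    for spec in config.datasets:
        if spec.role != role:
            continue
        matrix = ExpressionMatrix.from_tsv(spec.expression)
        labels = DoseLabels.from_tsv(spec.labels)
        annot = ProbeAnnotation.from_tsv(spec.annotation) if spec.annotation else None
        out.append((spec.id, matrix, labels, annot))
    return out


def run_discovery(config: RunConfig) -> list[Signature]:
    """Preprocess every derivation dataset, rank, select and grid-search a
    signature per (dataset, algorithm, C, sigma) cell; write files plus a
    manifest under ``config.out_dir``."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    panel = GenePanel.from_file(config.panel)
    derive = _load_datasets(config, "derive")
    if not derive:
        raise ValueError("no derivation datasets configured")
    signatures: list[Signature] = []
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "criterion": config.criterion,
        "cells": [],
    }
    for dataset_id, matrix, labels, annot in derive:
        (processed,) = preprocess_pipeline(
            [matrix], panel, [annot] if annot else None
        )
        disc = discretize_expression(processed, config.alpha)
        n_rank = min(config.n_rank, len(processed.row_ids))
        ranking = mid_rank(disc, labels, n_rank)
        ranking.to_tsv(out_dir / f"{dataset_id}.ranking.tsv")
        for algo in config.algorithms:
            for C, sigma in config.cells:
                cell_name = f"{dataset_id}.{algo}.C{C:g}.s{sigma:g}"
                try:
                    params = HyperParams(C=C, sigma=sigma)
                    sig, traj = _FS_FUNCS[algo](
                        ranking, processed, labels, params,
                        criterion=config.criterion, k=config.k,
                        seed=config.seed, dataset_id=dataset_id,
                    )
                    tuned = grid_search(
                        processed.restrict_rows(sig.genes), labels,
                        criterion=config.criterion, folds=config.k,
                        seed=config.seed,
                    )
                    sig.params = tuned
                    sig.to_file(out_dir / f"{cell_name}.signature.tsv")
                    traj.to_tsv(out_dir / f"{cell_name}.trajectory.tsv")
                    signatures.append(sig)
                    manifest["cells"].append(
                        {"cell": cell_name, "status": "ok",
                         "n_genes": len(sig.genes),
                         "tuned": {"C": tuned.C, "sigma": tuned.sigma}}
                    )
                    logger.info("cell %s: %d genes, score %.4f",
                                cell_name, len(sig.genes), sig.internal_score)
                except Exception as exc:  # isolate per-cell failures
                    logger.error("cell %s failed: %s", cell_name, exc)
                    manifest["cells"].append(
                        {"cell": cell_name, "status": "failed", "error": str(exc)}
                    )
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return signatures


def run_validate(config: RunConfig, signature_paths: list[str | Path]) -> pd.DataFrame:
    """Validate each signature file against each validation dataset;
    ineligible signatures are skipped with a logged reason.  Writes one
    JSON report per (signature, dataset) pair and a combined TSV."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    panel = GenePanel.from_file(config.panel)
    validate = _load_datasets(config, "validate")
    if not validate:
        raise ValueError("no validation datasets configured")
    rows = []
    for sig_path in signature_paths:
        sig = Signature.from_file(sig_path)
        sig_name = Path(sig_path).stem
        for dataset_id, matrix, labels, annot in validate:
            (processed,) = preprocess_pipeline(
                [matrix], panel, [annot] if annot else None
            )
            absent = check_signature_eligibility(processed, sig)
            if absent:
                logger.warning(
                    "signature %s skipped on %s: genes absent: %s",
                    sig_name, dataset_id, absent,
                )
                continue
            report = kfold_validate_signature(
                processed, labels, sig, k=config.k, params=sig.params,
                repeats=config.repeats, seed=config.seed, dataset_id=dataset_id,
            )
            report.to_json(out_dir / f"{sig_name}.{dataset_id}.kfold.json")
            row = {"signature": sig_name, "algorithm": sig.fs_algorithm,
                   "C": sig.params.C, "sigma": sig.params.sigma,
                   "criterion": sig.criterion,
                   "fs_score": sig.internal_score, **report.tsv_row()}
            rows.append(row)
    combined = pd.DataFrame(rows)
    combined.to_csv(out_dir / "validation_summary.tsv", sep="\t", index=False)
    return combined


def traditional_validate_pair(
    config: RunConfig,
    signature_path: str | Path,
    train_id: str,
    test_id: str,
):
    """Traditional (model-centric) validation of one signature: fit on the
    ``train_id`` dataset, predict ``test_id``, after signature-restricted
    quantile normalization."""
    panel = GenePanel.from_file(config.panel)
    by_id = {}
    for spec in config.datasets:
        matrix = ExpressionMatrix.from_tsv(spec.expression)
        labels = DoseLabels.from_tsv(spec.labels)
        annot = ProbeAnnotation.from_tsv(spec.annotation) if spec.annotation else None
        (processed,) = preprocess_pipeline([matrix], panel, [annot] if annot else None)
        by_id[spec.id] = (processed, labels)
    sig = Signature.from_file(signature_path)
    train, train_labels = by_id[train_id]
    test, test_labels = by_id[test_id]
    return traditional_validate(
        train, train_labels, test, test_labels, sig, params=sig.params,
        repeats=config.repeats, seed=config.seed, dataset_id=test_id,
    )
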