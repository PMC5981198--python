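"""Greedy wrapper feature selection over the mRMR ranking.

Three algorithms derive a signature from a ranked gene list, scoring
candidate gene sets by stratified k-fold cross-validation of the RBF-SVM
under a single run-level criterion (misclassification or log loss — never
both):

* CSFS (complete sequential FS) evaluates every prefix of the ranking and
  keeps the best-scoring one (ties go to the shorter prefix).
* FSFS (forward sequential FS) greedily adds, from the top-``pool`` ranked
  genes (default 50), the gene whose addition improves the score by the
  greatest margin, until no addition strictly improves.
* BSFS (backward sequential FS) starts from the full top-``pool`` ranked
  genes (default 30) and greedily removes the gene whose removal improves
  the score most, until no removal strictly improves; it never empties the
  signature.

"Plateaus" means no candidate step strictly improves the criterion
(tolerance 0).  Feature selection runs at a fixed (C, sigma); the grid
search is applied afterwards to the selected signature.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import DoseLabels, ExpressionMatrix
from .mrmr import MrmrRanking
from .svm import HyperParams
from .validation import internal_cv_score

__all__ = ["Signature", "FsTrajectory", "internal_score", "csfs", "fsfs", "bsfs"]


@dataclass
class Signature:
    """An ordered gene list plus its derivation provenance."""

    genes: list[str]
    fs_algorithm: str  # CSFS | FSFS | BSFS
    dataset_id: str
    params: HyperParams
    criterion: str  # misclassification | log_loss
    internal_score: float

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("a signature must contain at least one gene")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("signature genes must be unique")

    def __len__(self) -> int:
        return len(self.genes)

    def without(self, gene: str) -> list[str]:
        if gene not in self.genes:
            raise ValueError(f"{gene} is not in the signature")
        return [g for g in self.genes if g != gene]

    def to_file(self, path: str | Path) -> None:
        lines = [
            f"# algorithm\t{self.fs_algorithm}",
            f"# dataset\t{self.dataset_id}",
            f"# C\t{self.params.C:g}",
            f"# sigma\t{self.params.sigma:g}",
            f"# criterion\t{self.criterion}",
            f"# internal_score\t{self.internal_score!r}",
        ]
        lines += self.genes
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "Signature":
        meta: dict[str, str] = {}
        genes: list[str] = []
        for line in Path(path).read_text().splitlines():
            if line.startswith("#"):
                key, _, val = line[1:].strip().partition("\t")
                meta[key.strip()] = val.strip()
            elif line.strip():
                genes.append(line.strip())
        return cls(
            genes=genes,
            fs_algorithm=meta.get("algorithm", "?"),
            dataset_id=meta.get("dataset", ""),
            params=HyperParams(C=float(meta["C"]), sigma=float(meta["sigma"])),
            criterion=meta.get("criterion", "log_loss"),
            internal_score=float(meta.get("internal_score", "nan")),
        )


@dataclass
class FsTrajectory:
    """Audit trail of the selection run: one record per evaluated prefix
    (CSFS) or per accepted step (FSFS/BSFS)."""

    records: list[dict] = field(default_factory=list)

    def add(self, action: str, gene: str, score: float, size: int) -> None:
        if not np.isfinite(score):
            raise ValueError("trajectory scores must be finite")
        self.records.append(
            {"step": len(self.records) + 1, "action": action, "gene": gene,
             "score": score, "size": size}
        )

    @property
    def accepted_scores(self) -> list[float]:
        return [r["score"] for r in self.records]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def internal_score(
    data: ExpressionMatrix,
    labels: DoseLabels,
    genes: Sequence[str],
    params: HyperParams,
    criterion: str = "log_loss",
    k: int = 5,
    seed: int = 0,
) -> float:
    """Cross-validated criterion for a candidate gene set (lower is
    better); see :func:`radsig.validation.internal_cv_score`."""
    return internal_cv_score(data, labels, genes, params, criterion, k, seed)


def _ranked_genes(ranking: MrmrRanking | Sequence[str]) -> list[str]:
    return list(getattr(ranking, "genes", ranking))


def csfs(
    ranking: MrmrRanking | Sequence[str],
    data: ExpressionMatrix,
    labels: DoseLabels,
    params: HyperParams,
    criterion: str = "log_loss",
    k: int = 5,
    seed: int = 0,
    dataset_id: str = "",
) -> tuple[Signature, FsTrajectory]:
    """Complete sequential FS: score every prefix of the ranking and return
    the best one (ties to the shorter prefix)."""
    ranked = _ranked_genes(ranking)
    if not ranked:
        raise ValueError("ranking is empty")
    traj = FsTrajectory()
    best_score, best_len = np.inf, 0
    for size in range(1, len(ranked) + 1):
        prefix = ranked[:size]
        score = internal_score(data, labels, prefix, params, criterion, k, seed)
        traj.add("prefix", prefix[-1], score, size)
        if score < best_score:
            best_score, best_len = score, size
    sig = Signature(ranked[:best_len], "CSFS", dataset_id, params, criterion,
                    best_score)
    return sig, traj


def fsfs(
    ranking: MrmrRanking | Sequence[str],
    data: ExpressionMatrix,
    labels: DoseLabels,
    params: HyperParams,
    criterion: str = "log_loss",
    k: int = 5,
    seed: int = 0,
    pool: int = 50,
    dataset_id: str = "",
) -> tuple[Signature, FsTrajectory]:
    """Forward sequential FS from the top-``pool`` ranked genes.

    Each step adds the candidate with the best resulting score; candidates
    tied on score resolve to the better mRMR rank.  The first gene is
    always accepted (a signature is non-empty by contract); later additions
    must strictly improve the score.
    """
    candidates = _ranked_genes(ranking)[:pool]
    if not candidates:
        raise ValueError("ranking is empty")
    selected: list[str] = []
    traj = FsTrajectory()
    current = np.inf
    while True:
        best: tuple[float, int] | None = None  # (score, rank position)
        for pos, gene in enumerate(candidates):
            if gene in selected:
                continue
            score = internal_score(data, labels, selected + [gene], params,
                                   criterion, k, seed)
            if best is None or score < best[0]:
                best = (score, pos)
        if best is None:  # pool exhausted
            break
        score, pos = best
        if score < current:
            selected.append(candidates[pos])
            traj.add("add", candidates[pos], score, len(selected))
            current = score
        else:
            break
    sig = Signature(selected, "FSFS", dataset_id, params, criterion, current)
    return sig, traj


def bsfs(
    ranking: MrmrRanking | Sequence[str],
    data: ExpressionMatrix,
    labels: DoseLabels,
    params: HyperParams,
    criterion: str = "log_loss",
    k: int = 5,
    seed: int = 0,
    pool: int = 30,
    dataset_id: str = "",
) -> tuple[Signature, FsTrajectory]:
    """Backward sequential FS from the top-``pool`` ranked genes.

    Each step removes the gene whose removal improves the score most;
    removals tied on score resolve to dropping the worse-mRMR-ranked gene.
    Stops at the first non-improving removal and never empties the
    signature.
    """
    selected = _ranked_genes(ranking)[:pool]
    if not selected:
        raise ValueError("ranking is empty")
    traj = FsTrajectory()
    current = internal_score(data, labels, selected, params, criterion, k, seed)
    traj.add("start", "", current, len(selected))
    while len(selected) > 1:
        best: tuple[float, int] | None = None  # (score, -position): prefer
        for pos, gene in enumerate(selected):  # removing later-ranked genes
            reduced = selected[:pos] + selected[pos + 1 :]
            score = internal_score(data, labels, reduced, params, criterion,
                                   k, seed)
            if best is None or score < best[0] or (score == best[0] and pos > best[1]):
                best = (score, pos)
        assert best is not None
        score, pos = best
        if score < current:
            gene = selected.pop(pos)
            traj.add("remove", gene, score, len(selected))
            current = score
        else:
            break
    sig = Signature(selected, "BSFS", dataset_id, params, criterion, current)
    return sig, traj
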