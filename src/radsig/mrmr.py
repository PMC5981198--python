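"""Minimum-redundancy-maximum-relevance (mRMR) gene ranking.

Genes are ranked by incremental selection under the mutual-information
difference (MID) criterion: at each step the gene i maximizing

    I(i, h) - (1/|S|) * sum_{j in S} I(i, j)

is appended, where h is the radiation dose class, S the already-selected
set, and I(.,.) the plug-in mutual information (natural log, nats) between
discretized expression states.  When S is empty the redundancy term is
defined as 0.  Continuous expression is made discrete with the three-level
scheme conventional in the mRMR literature: per gene, values beyond
mean +/- alpha*sd map to +1/-1 and the rest to 0 (alpha = 0.5 by default).

Pairwise MI values are computed once per (candidate, selected) pair and
accumulated incrementally, so ranking n genes to depth d costs O(n*d) MI
evaluations.  Tie-breaking is deterministic: higher relevance first, then
lexicographic gene symbol.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import mutual_info_score

from .containers import DoseLabels, ExpressionMatrix

__all__ = [
    "DiscretizedMatrix",
    "MrmrRanking",
    "discretize_expression",
    "mutual_information",
    "mid_rank",
]


@dataclass
class DiscretizedMatrix:
    """Gene-by-sample integer matrix with levels {-1, 0, +1} and the
    binning parameter ``alpha`` (in per-gene sd multiples)."""

    data: pd.DataFrame
    alpha: float

    def __post_init__(self) -> None:
        vals = self.data.to_numpy()
        if not np.isin(vals, (-1, 0, 1)).all():
            raise ValueError("discretized entries must lie in {-1, 0, +1}")
        self.data = self.data.astype(np.int8)

    @property
    def row_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def col_ids(self) -> list[str]:
        return list(self.data.columns)


def discretize_expression(
    matrix: ExpressionMatrix, alpha: float = 0.5
) -> DiscretizedMatrix:
    """Three-level discretization at mean +/- alpha*sd, computed per gene
    over samples.  Expects gene-level (typically z-scored) expression with
    no missing values."""
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    vals = matrix.values
    if np.isnan(vals).any():
        raise ValueError("discretization requires a complete matrix")
    mean = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=1, keepdims=True)
    out = np.zeros_like(vals, dtype=np.int8)
    out[vals > mean + alpha * sd] = 1
    out[vals < mean - alpha * sd] = -1
    return DiscretizedMatrix(
        pd.DataFrame(out, index=matrix.data.index, columns=matrix.data.columns),
        alpha=alpha,
    )


def mutual_information(x, y) -> float:
    """Plug-in mutual information between two equal-length discrete vectors,
    in nats: sum over the joint empirical frequencies of
    p(x,y) * ln[p(x,y) / (p(x) p(y))]."""
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if len(x) < 2:
        raise ValueError("need at least 2 observations")
    return float(mutual_info_score(x, y))


def _mi_one_vs_many(rows: np.ndarray, vec: np.ndarray) -> np.ndarray:
    """MI of each row of a {-1,0,1} matrix against one discrete vector.

    Vectorized over rows via per-row contingency counts; matches
    mutual_information() to floating-point precision.
    """
    n = rows.shape[1]
    codes, n_states = np.unique(vec, return_inverse=True)[1], len(np.unique(vec))
    joint = (rows + 1) * n_states + codes[None, :]  # states 0..3*n_states-1
    mis = np.empty(rows.shape[0])
    for r in range(rows.shape[0]):
        counts = np.bincount(joint[r], minlength=3 * n_states).reshape(3, n_states)
        pxy = counts / n
        px = pxy.sum(axis=1, keepdims=True)
        py = pxy.sum(axis=0, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            term = pxy * np.log(pxy / (px * py))
        mis[r] = np.nansum(term)
    return np.maximum(mis, 0.0)


@dataclass
class MrmrRanking:
    """Ordered ranking with, per selected gene, the relevance I(i,h), the
    redundancy penalty (mean MI with previously selected genes) and the MID
    score at the moment of selection, all in nats."""

    table: pd.DataFrame  # columns: rank, gene, relevance_nats, redundancy_nats, mid_score

    @property
    def genes(self) -> list[str]:
        return list(self.table["gene"])

    def top(self, n: int) -> list[str]:
        return self.genes[:n]

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "MrmrRanking":
        return cls(pd.read_csv(path, sep="\t"))


def mid_rank(
    matrix: DiscretizedMatrix, labels: DoseLabels, n_select: int
) -> MrmrRanking:
    """Greedy incremental gene selection under the MID criterion.

    Step 1 picks the argmax of relevance I(i,h) (empty-set convention:
    redundancy 0); later steps maximize relevance minus the mean MI with the
    already-selected genes.  Ties break toward higher relevance, then the
    lexicographically smaller symbol.
    """
    genes = matrix.row_ids
    if not 1 <= n_select <= len(genes):
        raise ValueError("n_select must be in [1, number of genes]")
    y = labels.for_samples(matrix.col_ids)
    rows = matrix.data.to_numpy()
    _, y_codes = np.unique(y, return_inverse=True)

    relevance = _mi_one_vs_many(rows, y_codes)
    redundancy_sum = np.zeros(len(genes))
    remaining = list(range(len(genes)))
    records = []
    for step in range(1, n_select + 1):
        n_sel = step - 1
        best = None
        for idx in remaining:
            red = redundancy_sum[idx] / n_sel if n_sel else 0.0
            score = relevance[idx] - red
            # scores are compared at 1e-12 resolution so that exact
            # mathematical ties are not broken by summation order
            key = (round(score, 12), round(relevance[idx], 12), _NegStr(genes[idx]))
            if best is None or key > best[0]:
                best = (key, idx, red)
        assert best is not None
        _, pick, red = best
        records.append(
            {
                "rank": step,
                "gene": genes[pick],
                "relevance_nats": relevance[pick],
                "redundancy_nats": red,
                "mid_score": relevance[pick] - red,
            }
        )
        remaining.remove(pick)
        if remaining and step < n_select:
            mis = _mi_one_vs_many(rows[remaining], rows[pick] + 1)
            redundancy_sum[remaining] += mis
    return MrmrRanking(pd.DataFrame(records))


class _NegStr(str):
    """String whose ordering is reversed, so that max() prefers the
    lexicographically smaller symbol."""

    def __lt__(self, other) -> bool:  # type: ignore[override]
        return str.__gt__(self, other)

    def __gt__(self, other) -> bool:  # type: ignore[override]
        return str.__lt__(self, other)
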