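"""Expression preprocessing: completeness filtering, nearest-neighbor
imputation, per-row z-scoring, probe-to-gene collapsing and cross-dataset
harmonization against a curated panel.

The pipeline order is fixed: filter -> impute -> z-score -> collapse ->
harmonize.  Re-running the full pipeline on its own output is a no-op to
numerical precision, because z-scoring is idempotent on standardized rows
and collapsing is idempotent once rows are genes.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.impute import KNNImputer

from .containers import ExpressionMatrix, GenePanel, ProbeAnnotation, canonical_symbol

logger = logging.getLogger(__name__)

__all__ = [
    "filter_incomplete",
    "impute_knn",
    "zscore_rows",
    "collapse_probes",
    "harmonize_datasets",
    "preprocess_pipeline",
]


def filter_incomplete(
    matrix: ExpressionMatrix,
    completeness: float = 0.95,
    order: str = "rows_first",
) -> ExpressionMatrix:
    """Drop rows, then columns, whose observed fraction is below
    ``completeness`` (strictly; a row exactly at the threshold is kept).

    ``order`` may be ``"rows_first"`` (default) or ``"columns_first"``.
    Raises ``ValueError`` if nothing survives.
    """
    if not 0 < completeness <= 1:
        raise ValueError("completeness must be in (0, 1]")
    if order not in {"rows_first", "columns_first"}:
        raise ValueError(f"unknown filtering order {order!r}")
    df = matrix.data

    def keep_rows(d: pd.DataFrame) -> pd.DataFrame:
        frac = d.notna().mean(axis=1)
        return d.loc[frac >= completeness]

    def keep_cols(d: pd.DataFrame) -> pd.DataFrame:
        frac = d.notna().mean(axis=0)
        return d.loc[:, frac >= completeness]

    if order == "rows_first":
        out = keep_cols(keep_rows(df))
    else:
        out = keep_rows(keep_cols(df))
    logger.info(
        "completeness filter (%s, >=%g): %d/%d rows, %d/%d columns kept",
        order, completeness, out.shape[0], df.shape[0], out.shape[1], df.shape[1],
    )
    if out.empty:
        raise ValueError(
            "no rows/columns survive the completeness filter; dataset unusable"
        )
    return ExpressionMatrix(out.copy())


def impute_knn(matrix: ExpressionMatrix, k: int = 10) -> ExpressionMatrix:
    """Fill missing entries from the k nearest rows.

    Neighbors live in row space: distance is Euclidean over mutually
    observed columns (nan-aware), and each missing cell becomes the
    unweighted mean of the k nearest rows observed at that column.
    Observed entries are returned bit-identical.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    df = matrix.data
    if not df.isna().to_numpy().any():
        return matrix.copy()
    if (df.isna().all(axis=1)).any():
        bad = df.index[df.isna().all(axis=1)].tolist()
        raise ValueError(f"rows with no observed values cannot be imputed: {bad}")
    if (df.isna().all(axis=0)).any():
        bad = df.columns[df.isna().all(axis=0)].tolist()
        raise ValueError(f"columns with no observed values cannot be imputed: {bad}")
    imputer = KNNImputer(n_neighbors=min(k, df.shape[0] - 1), weights="uniform")
    filled = imputer.fit_transform(df.to_numpy())
    out = pd.DataFrame(filled, index=df.index, columns=df.columns)
    observed = df.notna()
    out = out.where(~observed, df)  # exact equality on observed entries
    return ExpressionMatrix(out)


def zscore_rows(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Standardize each row to mean 0 and unit sample (n-1) standard
    deviation.  Constant rows cannot be standardized and are dropped with a
    warning."""
    df = matrix.data
    if df.isna().to_numpy().any():
        raise ValueError("z-scoring requires a complete matrix; impute first")
    vals = df.to_numpy()
    sd = vals.std(axis=1, ddof=1)
    constant = sd == 0
    if constant.any():
        dropped = df.index[constant].tolist()
        logger.warning("dropping %d constant rows before z-scoring: %s",
                       len(dropped), dropped[:10])
        df = df.loc[~constant]
        vals = vals[~constant]
        sd = sd[~constant]
    z = (vals - vals.mean(axis=1, keepdims=True)) / sd[:, None]
    return ExpressionMatrix(pd.DataFrame(z, index=df.index, columns=df.columns))


def collapse_probes(
    matrix: ExpressionMatrix, annot: ProbeAnnotation
) -> ExpressionMatrix:
    """Average probes mapping to the same gene; drop unmapped probes.

    Output rows are gene symbols (the first-seen spelling per canonical
    symbol).  Raises if no probe maps to any gene.
    """
    groups: dict[str, list[str]] = {}
    display: dict[str, str] = {}
    for probe in matrix.row_ids:
        gene = annot.gene_for(probe)
        if gene is None:
            continue
        key = canonical_symbol(gene)
        groups.setdefault(key, []).append(probe)
        display.setdefault(key, gene)
    if not groups:
        raise ValueError("no probe maps to a gene symbol; cannot collapse")
    rows = {}
    for key, probes in groups.items():
        rows[display[key]] = matrix.data.loc[probes].mean(axis=0)
    out = pd.DataFrame(rows).T
    out.columns = matrix.data.columns
    return ExpressionMatrix(out)


def harmonize_datasets(
    matrices: Sequence[ExpressionMatrix], panel: GenePanel
) -> list[ExpressionMatrix]:
    """Restrict every gene-level matrix to the genes common to all of them
    and to the panel, in a shared sorted row order."""
    if not matrices:
        raise ValueError("need at least one matrix")
    common: set[str] | None = None
    canon_to_display: dict[str, str] = {}
    for m in matrices:
        canon = {canonical_symbol(g) for g in m.row_ids}
        for g in m.row_ids:
            canon_to_display.setdefault(canonical_symbol(g), g)
        common = canon if common is None else common & canon
    assert common is not None
    common &= {canonical_symbol(g) for g in panel.genes}
    if not common:
        raise ValueError("gene intersection with the panel is empty")
    order = sorted(common)
    outs = []
    for m in matrices:
        lookup = {canonical_symbol(g): g for g in m.row_ids}
        rows = [lookup[c] for c in order]
        sub = m.data.loc[rows].copy()
        sub.index = [canon_to_display[c] for c in order]
        outs.append(ExpressionMatrix(sub))
    return outs


def preprocess_pipeline(
    matrices: Sequence[ExpressionMatrix],
    panel: GenePanel,
    annotations: Sequence[ProbeAnnotation | None] | None = None,
    completeness: float = 0.95,
    k: int = 10,
) -> list[ExpressionMatrix]:
    """Full preprocessing for one or more datasets: per-dataset completeness
    filtering, KNN imputation and z-scoring, optional probe collapsing, then
    cross-dataset harmonization against the panel."""
    if annotations is None:
        annotations = [None] * len(matrices)
    staged = []
    for m, annot in zip(matrices, annotations):
        m = filter_incomplete(m, completeness)
        m = impute_knn(m, k)
        m = zscore_rows(m)
        if annot is not None:
            m = collapse_probes(m, annot)
        staged.append(m)
    return harmonize_datasets(staged, panel)
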