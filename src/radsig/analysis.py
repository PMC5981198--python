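"""Cross-signature analyses.

Given an ensemble of signatures, each validated on one or more external
datasets, these routines reproduce the downstream summaries used to
interpret a signature ensemble: the top-n signatures per source dataset by
average validation log loss, a gene-by-dataset table of scaled appearance
frequencies (heat-map values), the correlation between a gene's appearance
frequency and its mutual information with dose, and per-gene removal
weights (the change in validation metrics when a gene is deleted from its
signature).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .containers import DoseLabels, ExpressionMatrix
from .feature_selection import Signature
from .svm import HyperParams
from .validation import (
    ValidationReport,
    confusion_matrix,
    goodness_of_fit,
    kfold_validate_signature,
    misclassification,
    multiclass_log_loss,
    null_predict,
    uniform_proba,
)

__all__ = [
    "SignatureCollection",
    "top_signatures",
    "gene_frequency",
    "frequency_mi_correlation",
    "gene_removal_weight",
]


@dataclass
class SignatureCollection:
    """Signatures with their per-dataset validation reports, grouped by the
    dataset each signature was derived from."""

    entries: list[tuple[Signature, dict[str, ValidationReport]]] = field(
        default_factory=list
    )

    def __post_init__(self) -> None:
        for sig, reports in self.entries:
            if not reports:
                raise ValueError(
                    f"signature {sig.genes} has no validation report"
                )

    def __len__(self) -> int:
        return len(self.entries)

    def groups(self) -> dict[str, list[tuple[Signature, dict[str, ValidationReport]]]]:
        out: dict[str, list] = {}
        for entry in self.entries:
            out.setdefault(entry[0].dataset_id, []).append(entry)
        return out


def _mean_metric(reports: Mapping[str, ValidationReport], metric: str) -> float:
    return float(np.mean([getattr(r, metric) for r in reports.values()]))


def top_signatures(collection: SignatureCollection, n: int = 20) -> SignatureCollection:
    """Per source dataset, the n signatures with the lowest mean validation
    log loss (ties: lower mean misclassification, then fewer genes)."""
    if not collection.entries:
        raise ValueError("empty signature collection")
    kept = []
    for _, entries in collection.groups().items():
        ranked = sorted(
            entries,
            key=lambda e: (
                _mean_metric(e[1], "log_loss"),
                _mean_metric(e[1], "misclassification"),
                len(e[0].genes),
            ),
        )
        kept.extend(ranked[:n])
    return SignatureCollection(kept)


def gene_frequency(collection: SignatureCollection) -> pd.DataFrame:
    """Gene-by-source-dataset table of scaled appearance frequencies.

    Raw frequency is the number of signatures in a group containing the
    gene; frequencies are scaled within each group by the group maximum,
    then across groups by the global maximum of the scaled values, so all
    entries lie in [0, 1] and at least one entry equals 1.  Genes appearing
    nowhere are excluded.
    """
    groups = collection.groups()
    raw: dict[str, dict[str, int]] = {}
    for dataset, entries in groups.items():
        counts: dict[str, int] = {}
        for sig, _ in entries:
            for gene in sig.genes:
                counts[gene] = counts.get(gene, 0) + 1
        raw[dataset] = counts
    table = pd.DataFrame(raw).fillna(0.0)
    within = table / table.max(axis=0).replace(0, 1)
    global_max = within.to_numpy().max()
    scaled = within / (global_max if global_max > 0 else 1)
    scaled = scaled.loc[scaled.sum(axis=1) > 0]
    return scaled.sort_index()


def frequency_mi_correlation(
    freqs: pd.DataFrame,
    mi: Mapping[str, float] | pd.Series,
    method: str = "pearson",
) -> float:
    """Correlation between per-gene signature-appearance frequency (mean of
    the scaled frequencies across dataset columns) and per-gene mutual
    information with dose (nats)."""
    mi = pd.Series(mi, dtype=float)
    common = sorted(set(freqs.index) & set(mi.index))
    if len(common) < 3:
        raise ValueError("need at least 3 genes common to both inputs")
    f = freqs.loc[common].mean(axis=1).to_numpy()
    m = mi.loc[common].to_numpy()
    if method == "pearson":
        return float(stats.pearsonr(f, m).statistic)
    if method == "spearman":
        return float(stats.spearmanr(f, m).statistic)
    raise ValueError("method must be 'pearson' or 'spearman'")


def _null_report_metrics(
    labels: DoseLabels, classes: np.ndarray
) -> tuple[float, float, float, pd.DataFrame]:
    samples = labels.sample_ids
    pred = null_predict(samples, classes)
    proba = uniform_proba(samples, classes)
    return (
        misclassification(labels, pred),
        multiclass_log_loss(labels, proba),
        goodness_of_fit(labels, pred),
        confusion_matrix(labels, pred, classes),
    )


def gene_removal_weight(
    signature: Signature,
    gene: str,
    evaluation: Sequence[tuple[str, ExpressionMatrix, DoseLabels]],
    k: int = 5,
    params: HyperParams | None = None,
    repeats: int = 20,
    seed: int = 0,
    suppress_gof_for: str | None = None,
) -> pd.DataFrame:
    """Weight of a gene within a signature: the change in each validation
    metric when the gene is removed.

    The full signature and the signature minus ``gene`` are k-fold
    validated on each evaluation dataset with identical seeds; the deltas
    are (metric without gene) - (metric with gene), so a positive delta
    means the gene was helping.  Removing the only gene of a single-gene
    signature leaves the null predictor (uniform class probabilities,
    lowest-dose class call).  The ``suppress_gof_for`` dataset (typically
    the signature's own derivation dataset, where dose distance is never
    the optimized quantity) gets an NaN GoF delta.  Returns per-dataset
    rows plus an ``Average`` row of arithmetic means.
    """
    if gene not in signature.genes:
        raise ValueError(f"{gene} is not in the signature")
    if params is None:
        params = signature.params
    if suppress_gof_for is None:
        suppress_gof_for = signature.dataset_id
    reduced = signature.without(gene)
    rows = {}
    for dataset_id, matrix, labels in evaluation:
        full = kfold_validate_signature(
            matrix, labels, signature.genes, k=k, params=params,
            repeats=repeats, seed=seed, dataset_id=dataset_id,
        )
        if reduced:
            part = kfold_validate_signature(
                matrix, labels, reduced, k=k, params=params,
                repeats=repeats, seed=seed, dataset_id=dataset_id,
            )
            mc, ll, gof = part.misclassification, part.log_loss, part.goodness_of_fit
        else:
            lab = labels.subset(matrix.col_ids)
            mc, ll, gof, _ = _null_report_metrics(lab, lab.classes)
        d_gof = gof - full.goodness_of_fit
        if dataset_id == suppress_gof_for:
            d_gof = float("nan")
        rows[dataset_id] = {
            "delta_misclassification": mc - full.misclassification,
            "delta_log_loss": ll - full.log_loss,
            "delta_gof_cGy": d_gof,
        }
    out = pd.DataFrame(rows).T
    out.loc["Average"] = out.mean(axis=0, skipna=True)
    return out
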