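"""Validation protocols and performance metrics.

Two external-validation protocols are provided.  Signature-centric k-fold
validation repartitions an independent dataset itself (stratified by dose
class), so no cross-dataset normalization is needed; every sample is
predicted by a model that never saw it.  "Traditional" model-centric
validation fits on one dataset and predicts another after quantile
normalization restricted to the signature genes, which forces the two
datasets' per-sample expression distributions onto a common reference.

Three metrics summarize performance: misclassification (fraction of
wrongly-classified samples), multi-class log loss

    -(1/N) * sum_i sum_j y_ij * ln(p_ij)

with y_ij the true-class indicator and p_ij the predicted probability, and
goodness-of-fit (GoF), the mean absolute difference between predicted and
true dose in cGy.  Reports carry mean +/- standard error over repeated
partitions, plus a pooled confusion matrix.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import DoseLabels, ExpressionMatrix
from .svm import HyperParams, PROBA_EPS, fit, predict, predict_proba

__all__ = [
    "misclassification",
    "multiclass_log_loss",
    "goodness_of_fit",
    "confusion_matrix",
    "adjacent_error_fraction",
    "FoldAssignment",
    "stratified_kfold",
    "internal_cv_score",
    "kfold_validate_signature",
    "quantile_normalize",
    "traditional_validate",
    "ValidationReport",
    "uniform_proba",
    "null_predict",
]


# ---------------------------------------------------------------- metrics

def _aligned(true: DoseLabels, pred: DoseLabels) -> tuple[np.ndarray, np.ndarray]:
    if set(true.sample_ids) != set(pred.sample_ids):
        raise ValueError("true and predicted labels cover different samples")
    samples = true.sample_ids
    return true.for_samples(samples), pred.for_samples(samples)


def misclassification(true: DoseLabels, pred: DoseLabels) -> float:
    """Fraction of samples whose predicted dose class differs from the
    true class."""
    t, p = _aligned(true, pred)
    return float(np.mean(t != p))


def goodness_of_fit(true: DoseLabels, pred: DoseLabels) -> float:
    """Mean absolute difference between predicted and true dose (cGy)."""
    t, p = _aligned(true, pred)
    return float(np.mean(np.abs(t - p)))


def multiclass_log_loss(true: DoseLabels, proba: pd.DataFrame) -> float:
    """Multi-class log loss in nats.

    ``proba`` is sample-by-class with numeric class columns; rows must sum
    to 1 (tolerance 1e-6).  Probabilities are clipped at 1e-15 before
    taking logs, so the value is always finite.
    """
    rows = proba.to_numpy(dtype=float)
    if not np.allclose(rows.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("probability rows must sum to 1")
    samples = list(proba.index)
    t = true.for_samples(samples)
    classes = np.asarray(proba.columns, dtype=float)
    col = np.searchsorted(classes, t)
    if not np.array_equal(classes[col], t):
        raise ValueError("a true class is absent from the probability columns")
    p_true = np.clip(rows[np.arange(len(samples)), col], PROBA_EPS, None)
    return float(-np.mean(np.log(p_true)))


def confusion_matrix(
    true: DoseLabels, pred: DoseLabels, classes: Sequence[float] | None = None
) -> pd.DataFrame:
    """Class-by-class count matrix; rows are true classes, columns
    predicted, both in ascending cGy order.  Row sums equal the per-class
    sample counts."""
    t, p = _aligned(true, pred)
    if classes is None:
        classes = np.union1d(np.unique(t), np.unique(p))
    classes = np.sort(np.asarray(classes, dtype=float))
    idx = {c: i for i, c in enumerate(classes)}
    mat = np.zeros((len(classes), len(classes)), dtype=int)
    for ti, pi in zip(t, p):
        mat[idx[ti], idx[pi]] += 1
    return pd.DataFrame(mat, index=classes, columns=classes)


def adjacent_error_fraction(confusion: pd.DataFrame) -> float:
    """Of all misclassified samples, the fraction predicted into a class
    adjacent (one ordered step away) to the true class.  Returns NaN when
    there are no errors."""
    mat = confusion.to_numpy()
    off = mat.copy()
    np.fill_diagonal(off, 0)
    total_err = off.sum()
    if total_err == 0:
        return float("nan")
    adj = sum(
        off[i, j]
        for i in range(mat.shape[0])
        for j in range(mat.shape[1])
        if abs(i - j) == 1
    )
    return float(adj / total_err)


# ------------------------------------------------------- fold assignment

@dataclass
class FoldAssignment:
    """Per-sample fold index in 1..k from a stratified, seeded partition."""

    assignments: pd.Series  # sample_id -> fold (1..k)
    k: int
    seed: int

    def fold_samples(self, fold: int) -> list[str]:
        return list(self.assignments.index[self.assignments == fold])

    def train_samples(self, fold: int) -> list[str]:
        return list(self.assignments.index[self.assignments != fold])


def stratified_kfold(labels: DoseLabels, k: int, seed: int = 0) -> FoldAssignment:
    """Stratified partition: within each dose class, samples are shuffled
    by the seed and dealt round-robin into k folds, so per-class fold
    counts differ by at most one."""
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    assignment: dict[str, int] = {}
    for cls in labels.classes:
        members = sorted(labels.series.index[labels.series == cls])
        if len(members) < k:
            raise ValueError(
                f"class {cls:g} has {len(members)} samples < k={k}; use a smaller k"
            )
        order = rng.permutation(len(members))
        for pos, sample_idx in enumerate(order):
            assignment[members[sample_idx]] = pos % k + 1
    ser = pd.Series(assignment).loc[labels.sample_ids]
    return FoldAssignment(assignments=ser, k=k, seed=seed)


# ---------------------------------------------------- internal CV scoring

def _genes_of(signature) -> list[str]:
    return list(getattr(signature, "genes", signature))


def internal_cv_score(
    data: ExpressionMatrix,
    labels: DoseLabels,
    genes: Sequence[str],
    params: HyperParams,
    criterion: str = "log_loss",
    k: int = 5,
    seed: int = 0,
) -> float:
    """Mean criterion (misclassification or log loss; lower is better) over
    stratified k-fold cross-validation on ``data`` restricted to ``genes``."""
    if criterion not in {"misclassification", "log_loss"}:
        raise ValueError(f"unknown criterion {criterion!r}")
    sub = data.restrict_rows(_genes_of(genes))
    folds = stratified_kfold(labels.subset(sub.col_ids), k, seed)
    scores = []
    for fold in range(1, k + 1):
        tr = folds.train_samples(fold)
        te = folds.fold_samples(fold)
        model = fit(
            ExpressionMatrix(sub.data[tr]), labels.subset(tr), params, seed=seed
        )
        te_mat = ExpressionMatrix(sub.data[te])
        true = labels.subset(te)
        if criterion == "misclassification":
            scores.append(misclassification(true, predict(model, te_mat)))
        else:
            scores.append(multiclass_log_loss(true, predict_proba(model, te_mat)))
    return float(np.mean(scores))


# ------------------------------------------------------- null predictor

def uniform_proba(samples: Sequence[str], classes: Sequence[float]) -> pd.DataFrame:
    """The null (empty-signature) predictor's probabilities: uniform over
    the dose classes."""
    classes = np.sort(np.asarray(classes, dtype=float))
    return pd.DataFrame(
        np.full((len(samples), len(classes)), 1.0 / len(classes)),
        index=list(samples),
        columns=classes,
    )


def null_predict(samples: Sequence[str], classes: Sequence[float]) -> DoseLabels:
    """The null predictor's class call: the lowest dose class (the
    deterministic argmax-with-low-dose-ties of the uniform row)."""
    low = float(np.min(np.asarray(classes, dtype=float)))
    return DoseLabels(pd.Series(low, index=list(samples)))


# ------------------------------------------------------------- reports

@dataclass
class ValidationReport:
    """Validation metrics as mean +/- standard error over repeats, with a
    confusion matrix pooled over all repeats."""

    protocol: str  # "kfold" | "traditional"
    misclassification: float
    misclassification_se: float
    log_loss: float
    log_loss_se: float
    goodness_of_fit: float
    goodness_of_fit_se: float
    confusion: pd.DataFrame
    n_samples: int
    n_repeats: int
    k: int | None = None
    seed: int | None = None
    dataset_id: str = ""
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "protocol": self.protocol,
            "dataset_id": self.dataset_id,
            "misclassification": {"mean": self.misclassification, "se": self.misclassification_se},
            "log_loss": {"mean": self.log_loss, "se": self.log_loss_se},
            "goodness_of_fit": {"mean": self.goodness_of_fit, "se": self.goodness_of_fit_se},
            "confusion": {
                "classes": [float(c) for c in self.confusion.index],
                "counts": self.confusion.to_numpy().tolist(),
            },
            "n_samples": self.n_samples,
            "n_repeats": self.n_repeats,
            "k": self.k,
            "seed": self.seed,
            **({"extra": self.extra} if self.extra else {}),
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    def tsv_row(self) -> dict:
        """Flat row for cross-signature tabulation."""
        return {
            "protocol": self.protocol,
            "dataset": self.dataset_id,
            "misclassification": self.misclassification,
            "misclassification_se": self.misclassification_se,
            "log_loss": self.log_loss,
            "log_loss_se": self.log_loss_se,
            "goodness_of_fit_cGy": self.goodness_of_fit,
            "goodness_of_fit_se": self.goodness_of_fit_se,
            "n_samples": self.n_samples,
            "n_repeats": self.n_repeats,
        }


def _summarize(
    protocol: str,
    per_repeat: list[tuple[float, float, float]],
    confusion: pd.DataFrame,
    n_samples: int,
    k: int | None,
    seed: int | None,
    dataset_id: str,
) -> ValidationReport:
    arr = np.asarray(per_repeat)
    n = arr.shape[0]
    se = arr.std(axis=0, ddof=1) / np.sqrt(n)
    return ValidationReport(
        protocol=protocol,
        misclassification=float(arr[:, 0].mean()),
        misclassification_se=float(se[0]),
        log_loss=float(arr[:, 1].mean()),
        log_loss_se=float(se[1]),
        goodness_of_fit=float(arr[:, 2].mean()),
        goodness_of_fit_se=float(se[2]),
        confusion=confusion,
        n_samples=n_samples,
        n_repeats=n,
        k=k,
        seed=seed,
        dataset_id=dataset_id,
    )


def check_signature_eligibility(dataset: ExpressionMatrix, signature) -> list[str]:
    """Genes of the signature absent from the dataset (the eligibility
    gate: a signature is usable only if fully contained)."""
    rows = set(dataset.row_ids)
    return [g for g in _genes_of(signature) if g not in rows]


def kfold_validate_signature(
    dataset: ExpressionMatrix,
    labels: DoseLabels,
    signature,
    k: int = 5,
    params: HyperParams | None = None,
    repeats: int = 20,
    seed: int = 0,
    dataset_id: str = "",
) -> ValidationReport:
    """Signature-centric validation: repeated stratified k-fold on the
    dataset itself.  Per repeat, a fresh partition is drawn, each fold is
    predicted by a model trained on the remaining folds, and the metrics
    are computed on the pooled predictions."""
    if repeats < 2:
        raise ValueError("repeats must be >= 2 to estimate a standard error")
    genes = _genes_of(signature)
    absent = check_signature_eligibility(dataset, genes)
    if absent:
        raise KeyError(f"signature genes absent from dataset: {absent}")
    if params is None:
        params = getattr(signature, "params", None) or HyperParams(C=10.0, sigma=1.0)
    sub = dataset.restrict_rows(genes)
    labels = labels.subset(sub.col_ids)
    classes = labels.classes
    per_repeat = []
    confusion = None
    for r in range(repeats):
        rep_seed = (seed * 1_000_003 + r) % (2**31)
        folds = stratified_kfold(labels, k, rep_seed)
        pred_parts, proba_parts = [], []
        for fold in range(1, k + 1):
            tr = folds.train_samples(fold)
            te = folds.fold_samples(fold)
            model = fit(ExpressionMatrix(sub.data[tr]), labels.subset(tr),
                        params, seed=rep_seed)
            te_mat = ExpressionMatrix(sub.data[te])
            pred_parts.append(predict(model, te_mat).series)
            proba_parts.append(predict_proba(model, te_mat))
        pred = DoseLabels(pd.concat(pred_parts))
        proba = pd.concat(proba_parts)
        mc = misclassification(labels, pred)
        ll = multiclass_log_loss(labels, proba)
        gof = goodness_of_fit(labels, pred)
        per_repeat.append((mc, ll, gof))
        cm = confusion_matrix(labels, pred, classes)
        confusion = cm if confusion is None else confusion + cm
    return _summarize("kfold", per_repeat, confusion, len(labels.sample_ids),
                      k, seed, dataset_id)


# ------------------------------------------------ quantile normalization

def _apply_reference(values: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Replace a sample's values by the reference values at its
    within-sample ranks; tied values receive the mean of the reference over
    the tied span."""
    order = np.argsort(values, kind="mergesort")
    sv = values[order]
    out = np.empty_like(reference, dtype=float)
    i = 0
    n = len(values)
    while i < n:
        j = i
        while j + 1 < n and sv[j + 1] == sv[i]:
            j += 1
        out[order[i : j + 1]] = reference[i : j + 1].mean()
        i = j + 1
    return out


def quantile_normalize(
    train: ExpressionMatrix,
    test: ExpressionMatrix,
    signature,
    reference: str = "pooled",
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Signature-restricted quantile normalization of two datasets.

    Both matrices are restricted to the signature genes; the reference
    distribution is the per-rank mean of each sample's sorted expression
    vector over the pooled train+test samples (or train only when
    ``reference="train"``).  Every sample's values are then replaced by the
    reference values at its within-sample ranks, so afterwards every
    sample's sorted vector is identical across both datasets.
    """
    genes = _genes_of(signature)
    for name, mat in (("train", train), ("test", test)):
        absent = check_signature_eligibility(mat, genes)
        if absent:
            raise KeyError(f"signature genes absent from {name} matrix: {absent}")
    tr = train.restrict_rows(genes).data.to_numpy()
    te = test.restrict_rows(genes).data.to_numpy()
    if reference == "pooled":
        pool = np.concatenate([tr, te], axis=1)
    elif reference == "train":
        pool = tr
    else:
        raise ValueError("reference must be 'pooled' or 'train'")
    ref = np.sort(pool, axis=0).mean(axis=1)
    tr_out = np.column_stack([_apply_reference(tr[:, j], ref) for j in range(tr.shape[1])])
    te_out = np.column_stack([_apply_reference(te[:, j], ref) for j in range(te.shape[1])])
    return (
        ExpressionMatrix(pd.DataFrame(tr_out, index=genes, columns=train.col_ids)),
        ExpressionMatrix(pd.DataFrame(te_out, index=genes, columns=test.col_ids)),
    )


def traditional_validate(
    train: ExpressionMatrix,
    train_labels: DoseLabels,
    test: ExpressionMatrix,
    test_labels: DoseLabels,
    signature,
    params: HyperParams | None = None,
    repeats: int = 20,
    seed: int = 0,
    normalize: bool = True,
    reference: str = "pooled",
    dataset_id: str = "",
) -> ValidationReport:
    """Model-centric validation: quantile-normalize (signature-restricted),
    fit on the training dataset, predict the test dataset.

    Requires the two datasets to share the signature genes and the same
    dose class set.  ``repeats`` re-runs the stochastic internals (the
    probability-calibration folds) for the +/- SE.
    """
    if repeats < 2:
        raise ValueError("repeats must be >= 2 to estimate a standard error")
    genes = _genes_of(signature)
    tr_classes = set(train_labels.subset(train.col_ids).classes)
    te_classes = set(test_labels.subset(test.col_ids).classes)
    if tr_classes != te_classes:
        raise ValueError(
            f"train and test dose class sets differ: {sorted(tr_classes)} vs "
            f"{sorted(te_classes)}; traditional validation needs matching "
            "exposure levels"
        )
    if params is None:
        params = getattr(signature, "params", None) or HyperParams(C=10.0, sigma=1.0)
    if normalize:
        tr_mat, te_mat = quantile_normalize(train, test, genes, reference)
    else:
        tr_mat = train.restrict_rows(genes)
        te_mat = test.restrict_rows(genes)
    tr_lab = train_labels.subset(tr_mat.col_ids)
    te_lab = test_labels.subset(te_mat.col_ids)
    classes = np.union1d(tr_lab.classes, te_lab.classes)
    per_repeat = []
    confusion = None
    for r in range(repeats):
        rep_seed = (seed * 1_000_003 + r) % (2**31)
        model = fit(tr_mat, tr_lab, params, seed=rep_seed)
        pred = predict(model, te_mat)
        proba = predict_proba(model, te_mat)
        per_repeat.append(
            (
                misclassification(te_lab, pred),
                multiclass_log_loss(te_lab, proba),
                goodness_of_fit(te_lab, pred),
            )
        )
        cm = confusion_matrix(te_lab, pred, classes)
        confusion = cm if confusion is None else confusion + cm
    return _summarize("traditional", per_repeat, confusion,
                      len(te_lab.sample_ids), None, seed, dataset_id)
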