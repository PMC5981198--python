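"""Multi-class RBF-kernel SVM dose classifiers.

The kernel is k(u, v) = exp(-||u - v||^2 / (2 sigma^2)); the box constraint
C sets how severely training misclassifications are penalized and sigma is
the kernel width.  Multi-class problems are decomposed one-vs-one with
pairwise-coupled, sigmoid-calibrated probability estimates fitted on the
training data only.  Class predictions are the argmax of the probability
row, with exact ties broken toward the lower dose class.

Hyperparameters are searched over the lattice of powers of ten
{10^0 ... 10^5}^2 restricted to C >= sigma — 21 candidate pairs — scored by
stratified k-fold cross-validation on the training data.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .containers import DoseLabels, ExpressionMatrix

__all__ = [
    "HyperParams",
    "TrainedClassifier",
    "fit",
    "predict",
    "predict_proba",
    "grid_search",
    "grid_candidates",
    "PROBA_EPS",
]

PROBA_EPS = 1e-15


@dataclass(frozen=True)
class HyperParams:
    """SVM hyperparameters: box constraint C and RBF kernel scale sigma."""

    C: float
    sigma: float

    def __post_init__(self) -> None:
        if self.C <= 0 or self.sigma <= 0:
            raise ValueError("C and sigma must be positive")

    @property
    def gamma(self) -> float:
        return 1.0 / (2.0 * self.sigma**2)


def grid_candidates() -> list[HyperParams]:
    """The (C, sigma) lattice: powers of ten from 1 to 100000 inclusive,
    restricted to C >= sigma (21 pairs)."""
    powers = [10.0**p for p in range(6)]
    return [HyperParams(C=c, sigma=s) for c in powers for s in powers if c >= s]


@dataclass
class TrainedClassifier:
    """A fitted multi-class RBF-SVM bound to an ordered training gene list.

    Predicts only the dose classes seen in training; prediction requires
    exactly the training gene list, in order.
    """

    params: HyperParams
    genes: list[str]
    classes: np.ndarray  # ascending cGy
    _svc: SVC

    def _design(self, matrix: ExpressionMatrix) -> np.ndarray:
        missing = [g for g in self.genes if g not in matrix.data.index]
        if missing:
            raise KeyError(f"test matrix lacks signature genes: {missing}")
        return matrix.data.loc[self.genes].to_numpy().T

    def save(self, path: str | Path) -> None:
        import pickle

        payload = {
            "format": "radsig-svm-v1",
            "params": {"C": self.params.C, "sigma": self.params.sigma},
            "classes": self.classes.tolist(),
            "genes": self.genes,
        }
        with open(path, "wb") as fh:
            fh.write(json.dumps(payload).encode() + b"\n")
            pickle.dump(self._svc, fh)

    @classmethod
    def load(cls, path: str | Path) -> "TrainedClassifier":
        import pickle

        with open(path, "rb") as fh:
            header = json.loads(fh.readline().decode())
            if header.get("format") != "radsig-svm-v1":
                raise ValueError("unrecognized model archive")
            svc = pickle.load(fh)
        return cls(
            params=HyperParams(**header["params"]),
            genes=header["genes"],
            classes=np.asarray(header["classes"], dtype=float),
            _svc=svc,
        )


def fit(
    train: ExpressionMatrix,
    labels: DoseLabels,
    params: HyperParams,
    seed: int = 0,
) -> TrainedClassifier:
    """Fit the RBF-SVM on the given matrix (rows = signature genes) and
    dose labels.  Deterministic for fixed input, params and seed."""
    y = labels.for_samples(train.col_ids)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("training requires at least 2 dose classes")
    if (counts < 2).any():
        small = classes[counts < 2].tolist()
        raise ValueError(f"classes with fewer than 2 training samples: {small}")
    X = train.values.T
    svc = SVC(
        C=params.C,
        kernel="rbf",
        gamma=params.gamma,
        probability=True,
        random_state=seed % (2**31),
    )
    with warnings.catch_warnings():
        # sklearn >=1.9 deprecates probability=True; we rely on its
        # one-vs-one pairwise-coupled Platt probabilities deliberately.
        warnings.simplefilter("ignore", FutureWarning)
        svc.fit(X, y)
    return TrainedClassifier(
        params=params, genes=train.row_ids, classes=classes, _svc=svc
    )


def predict_proba(
    model: TrainedClassifier, test: ExpressionMatrix
) -> pd.DataFrame:
    """Sample-by-class predicted probabilities; columns are the training
    classes in ascending cGy order.  Entries are clipped away from 0/1 at
    1e-15 and rows renormalized to sum to 1."""
    X = model._design(test)
    raw = model._svc.predict_proba(X)
    # svc.classes_ is ascending, matching model.classes
    raw = np.clip(raw, PROBA_EPS, 1 - PROBA_EPS)
    raw /= raw.sum(axis=1, keepdims=True)
    return pd.DataFrame(raw, index=test.col_ids, columns=model.classes)


def predict(model: TrainedClassifier, test: ExpressionMatrix) -> DoseLabels:
    """Class predictions: per-sample argmax of the probability row, ties
    broken toward the lower dose class (columns are ascending, argmax picks
    the first maximum)."""
    proba = predict_proba(model, test)
    picks = model.classes[np.argmax(proba.to_numpy(), axis=1)]
    return DoseLabels(pd.Series(picks, index=proba.index))


def grid_search(
    train: ExpressionMatrix,
    labels: DoseLabels,
    criterion: str = "log_loss",
    folds: int = 5,
    seed: int = 0,
    candidates: Sequence[HyperParams] | None = None,
) -> HyperParams:
    """Pick the best (C, sigma) by stratified k-fold cross-validation on
    the training data under ``criterion`` (misclassification or log_loss;
    lower is better).  Ties break toward smaller C, then larger sigma."""
    from .validation import internal_cv_score  # local import: avoid cycle

    if candidates is None:
        candidates = grid_candidates()
    ordered = sorted(candidates, key=lambda p: (p.C, -p.sigma))
    best: tuple[float, HyperParams] | None = None
    for params in ordered:
        score = internal_cv_score(
            train, labels, train.row_ids, params, criterion, folds, seed
        )
        if best is None or score < best[0]:
            best = (score, params)
    assert best is not None
    return best[1]
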