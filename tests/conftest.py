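import numpy as np
import pandas as pd
import pytest

from radsig import DoseLabels, ExpressionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_matrix(values, rows=None, cols=None) -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    rows = rows or [f"g{i}" for i in range(values.shape[0])]
    cols = cols or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=rows, columns=cols))


def make_labels(doses, samples=None) -> DoseLabels:
    doses = np.asarray(doses, dtype=float)
    samples = samples or [f"s{j}" for j in range(len(doses))]
    return DoseLabels(pd.Series(doses, index=samples))


def separable_dataset(
    n_per_class=10, classes=(0.0, 200.0), n_genes=2, gap=6.0, seed=0
):
    """Well-separated Gaussian clusters: class c's genes are shifted by
    gap * class_index.  Trivially classifiable."""
    rng = np.random.default_rng(seed)
    cols, doses, blocks = [], [], []
    for ci, dose in enumerate(classes):
        blocks.append(rng.standard_normal((n_genes, n_per_class)) * 0.3 + gap * ci)
        doses += [dose] * n_per_class
        cols += [f"c{ci}_{j}" for j in range(n_per_class)]
    mat = make_matrix(np.hstack(blocks), cols=cols)
    return mat, make_labels(doses, samples=cols)


def mixed_direction_dataset(
    n_per_class=10, classes=(0.0, 200.0), gap=4.0, seed=0, prefix=""
):
    """Two up-regulated and two down-regulated genes plus stable noise
    genes; within-sample gene ranks carry the class signal, so per-sample
    quantile normalization preserves separability."""
    rng = np.random.default_rng(seed)
    cols, doses, blocks = [], [], []
    for ci, dose in enumerate(classes):
        up = rng.standard_normal((2, n_per_class)) * 0.3 + gap * ci
        down = rng.standard_normal((2, n_per_class)) * 0.3 - gap * ci
        stable = rng.standard_normal((2, n_per_class)) * 0.3
        blocks.append(np.vstack([up, down, stable]))
        doses += [dose] * n_per_class
        cols += [f"{prefix}m{ci}_{j}" for j in range(n_per_class)]
    mat = make_matrix(
        np.hstack(blocks),
        rows=["up1", "up2", "dn1", "dn2", "st1", "st2"],
        cols=cols,
    )
    return mat, make_labels(doses, samples=cols)


@pytest.fixture
def separable_2class():
    return separable_dataset()


@pytest.fixture
def separable_4class():
    return separable_dataset(n_per_class=8, classes=(0.0, 50.0, 200.0, 1000.0))
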