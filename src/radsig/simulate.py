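"""Synthetic expression data with the statistical structure the pipeline
assumes.

The generator emulates a radiation-exposure microarray study: a panel of
background genes with standard-normal (z-score-scale) expression, a small
set of planted dose-responsive genes — alternately induced and repressed,
their means shifting by +/-beta per unit log10(1 + dose_cGy) — blocks of
redundant genes correlated with a planted
driver through a shared latent factor, missing values placed completely at
random, and — for paired datasets — a monotone cubic batch distortion that
survives z-scoring (it is non-affine) but is rank-preserving, so quantile
normalization can in principle remove it.

Default study conditions: 500 panel genes, 5 planted responders with
beta = 1 (one z-score unit per log10 dose decade), four dose classes
{0, 50, 200, 1000} cGy with 30 samples each, three 5-gene redundant blocks
at within-block correlation 0.8, and 1% missingness.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import DoseLabels, ExpressionMatrix

__all__ = ["SimConfig", "GroundTruth", "generate_dataset", "generate_paired_datasets"]

# Synthetic stand-in for a curated radiation-response symbol list: a small
# set of gene symbols widely associated with DNA damage / radiation
# response, used only to give simulated panels realistic-looking names.
RADIATION_SYMBOLS = [
    "DDB2", "CDKN1A", "BAX", "GADD45A", "MDM2", "XPC", "PCNA", "TNFRSF10B",
    "AEN", "BBC3", "PHPT1", "ASTN2", "RPS27L", "SESN1", "SESN2", "TRIM22",
    "TP53I3", "POLH", "FDXR", "CCNG1", "PPM1D", "TNFSF8", "ATF3", "BTG2",
    "EI24", "TRIAP1", "ZMAT3", "ACTA2", "APOBEC3H", "TIGAR", "PLK3", "DDIT3",
    "GDF15", "IER5", "LIG1", "RRM2B", "TP53INP1", "CD70", "BLNK", "PRKDC",
    "ATM", "ATR", "CHEK1", "CHEK2", "TP53", "BRCA1", "BRCA2", "RAD51",
    "RAD17", "RAD9A", "HUS1", "RRM1", "XRCC1", "XRCC4", "XRCC5", "XRCC6",
    "ERCC1", "ERCC2", "ERCC4", "ERCC5", "MLH1", "MSH2", "MSH6", "PMS2",
    "OGG1", "APEX1", "PARP1", "PARP2", "LIG3", "LIG4", "NBN", "MRE11",
    "RAD50", "H2AX", "MDC1", "TP53BP1", "RNF8", "RNF168", "UBE2N", "UIMC1",
    "BARD1", "PALB2", "FANCA", "FANCC", "FANCD2", "FANCI", "TOPBP1", "CLSPN",
    "TIMELESS", "TIPIN", "WRN", "BLM", "RECQL4", "EXO1", "DCLRE1C", "NHEJ1",
    "PSMD9", "ITK", "FCER1G", "CYSLTR1",
]


@dataclass
class SimConfig:
    """Study-design parameters for the synthetic generator."""

    n_genes: int = 500
    n_planted: int = 5
    n_blocks: int = 3
    block_size: int = 5
    samples_per_class: int = 30
    dose_classes: tuple[float, ...] = (0.0, 50.0, 200.0, 1000.0)
    beta: float = 1.0            # z-score shift per unit log10(1+dose)
    rho_block: float = 0.8       # latent-factor correlation of block genes
    missing_fraction: float = 0.01
    distortion: tuple[float, float] = (1.0, 0.15)  # g(x) = a*x + b*x^3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_planted + self.n_blocks * self.block_size > self.n_genes:
            raise ValueError("planted + block genes exceed n_genes")
        if not 0 <= self.missing_fraction < 0.05:
            raise ValueError("missing_fraction must be in [0, 0.05)")
        if self.beta < 0:
            raise ValueError("effect size beta must be >= 0")
        if not 0 <= self.rho_block < 1:
            raise ValueError("rho_block must be in [0, 1)")
        if len(self.dose_classes) < 2:
            raise ValueError("need at least 2 dose classes")
        if self.n_blocks > self.n_planted and self.n_blocks > 0 and self.n_planted == 0:
            raise ValueError("blocks need planted drivers")


@dataclass
class GroundTruth:
    """What was planted: responsive gene ids, per-gene true effect sizes,
    and redundant-block memberships keyed by their planted driver."""

    planted: list[str]
    effects: dict[str, float]
    blocks: dict[str, list[str]] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {"planted": self.planted, "effects": self.effects,
                 "blocks": self.blocks},
                indent=2,
            )
            + "\n"
        )


def _gene_names(n: int, rng: np.random.Generator) -> list[str]:
    base = list(RADIATION_SYMBOLS[: min(n, len(RADIATION_SYMBOLS))])
    base += [f"G{i:04d}" for i in range(1, n - len(base) + 1)]
    perm = rng.permutation(n)
    return [base[i] for i in perm]


def _raw_dataset(
    config: SimConfig, rng: np.random.Generator, names: list[str],
    effects: dict[str, float], blocks: dict[str, list[str]], sample_prefix: str,
) -> tuple[pd.DataFrame, DoseLabels]:
    n_samples = config.samples_per_class * len(config.dose_classes)
    doses = np.repeat(np.asarray(config.dose_classes, dtype=float),
                      config.samples_per_class)
    samples = [f"{sample_prefix}S{i:04d}" for i in range(1, n_samples + 1)]
    values = rng.standard_normal((config.n_genes, n_samples))
    df = pd.DataFrame(values, index=names, columns=samples)
    log_dose = np.log10(1.0 + doses)
    for gene, beta_g in effects.items():
        df.loc[gene] = df.loc[gene].to_numpy() + beta_g * log_dose
    rho = config.rho_block
    for driver, members in blocks.items():
        latent = df.loc[driver].to_numpy()
        for member in members:
            noise = rng.standard_normal(n_samples)
            df.loc[member] = rho * latent + np.sqrt(1 - rho**2) * noise
    labels = DoseLabels(pd.Series(doses, index=samples))
    return df, labels


def _add_missing(df: pd.DataFrame, fraction: float,
                 rng: np.random.Generator) -> pd.DataFrame:
    if fraction <= 0:
        return df
    mask = rng.random(df.shape) < fraction
    arr = df.to_numpy().copy()
    arr[mask] = np.nan
    return pd.DataFrame(arr, index=df.index, columns=df.columns)


def _truth(config: SimConfig, rng: np.random.Generator):
    names = _gene_names(config.n_genes, rng)
    planted = names[: config.n_planted]
    cursor = config.n_planted
    blocks: dict[str, list[str]] = {}
    for b in range(config.n_blocks):
        driver = planted[b % max(config.n_planted, 1)] if config.n_planted else names[cursor]
        members = names[cursor : cursor + config.block_size]
        cursor += config.block_size
        blocks.setdefault(driver, []).extend(members)
    # radiation response includes both induced and repressed genes; planted
    # effects alternate sign so within-sample gene ranks carry dose
    # information (per-sample quantile normalization preserves only ranks)
    effects = {
        g: config.beta * (1 if i % 2 == 0 else -1) for i, g in enumerate(planted)
    }
    return names, GroundTruth(planted=planted, effects=effects, blocks=blocks)


def generate_dataset(
    config: SimConfig,
) -> tuple[ExpressionMatrix, DoseLabels, GroundTruth]:
    """One synthetic dataset, fully reproducible from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    names, truth = _truth(config, rng)
    df, labels = _raw_dataset(config, rng, names, truth.effects, truth.blocks, "")
    df = _add_missing(df, config.missing_fraction, rng)
    return ExpressionMatrix(df), labels, truth


def _distort(df: pd.DataFrame, coeffs: tuple[float, float]) -> pd.DataFrame:
    a, b = coeffs
    if b < 0 or a <= 0:
        raise ValueError("distortion must be monotone: a > 0, b >= 0")
    x = df.to_numpy()
    return pd.DataFrame(a * x + b * x**3, index=df.index, columns=df.columns)


def generate_paired_datasets(
    config: SimConfig,
) -> tuple[
    tuple[ExpressionMatrix, DoseLabels],
    tuple[ExpressionMatrix, DoseLabels],
    GroundTruth,
]:
    """Two datasets with identical generative truth (same planted genes and
    effects) but independent samples; the second dataset's raw values pass
    through the monotone cubic batch distortion before any preprocessing."""
    rng = np.random.default_rng(config.seed)
    names, truth = _truth(config, rng)
    df1, labels1 = _raw_dataset(config, rng, names, truth.effects, truth.blocks, "D1_")
    df2, labels2 = _raw_dataset(config, rng, names, truth.effects, truth.blocks, "D2_")
    df2 = _distort(df2, config.distortion)
    df1 = _add_missing(df1, config.missing_fraction, rng)
    df2 = _add_missing(df2, config.missing_fraction, rng)
    return (
        (ExpressionMatrix(df1), labels1),
        (ExpressionMatrix(df2), labels2),
        truth,
    )
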