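"""Core data containers for the radiation-signature pipeline.

The substrate of every stage is a gene-by-sample expression matrix with an
optional missing-value mask (represented as NaN), together with per-sample
radiation dose labels in centigray (cGy), a probe-to-gene annotation, and a
curated gene panel.  Gene symbols are matched case-insensitively after
canonicalization; the original spelling is preserved for display.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "DoseLabels",
    "ProbeAnnotation",
    "GenePanel",
    "canonical_symbol",
]


def canonical_symbol(symbol: str) -> str:
    """Canonical form of a gene symbol used for matching (uppercased,
    stripped).  Display code keeps the original spelling, so human DDB2 and
    murine Ddb2 panels each round-trip unchanged."""
    return symbol.strip().upper()


def _check_unique(ids: Iterable[str], what: str) -> None:
    ids = list(ids)
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if list(ids).count(i) > 1})[:5]
        raise ValueError(f"duplicate {what}: {dupes}")


@dataclass
class ExpressionMatrix:
    """Gene/probe-by-sample real-valued matrix.

    Missing values are encoded as NaN in ``data``; ``missing_mask`` exposes
    them as a boolean frame aligned to the values.  Row and column
    identifiers must be unique.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        self.data = self.data.astype(float)
        self.data.index = self.data.index.astype(str)
        self.data.columns = self.data.columns.astype(str)
        _check_unique(self.data.index, "row ids")
        _check_unique(self.data.columns, "sample ids")

    @property
    def row_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def col_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.data.isna()

    @property
    def n_missing(self) -> int:
        return int(self.data.isna().to_numpy().sum())

    def restrict_rows(self, rows: Sequence[str]) -> "ExpressionMatrix":
        missing = [r for r in rows if r not in self.data.index]
        if missing:
            raise KeyError(f"rows absent from matrix: {missing}")
        return ExpressionMatrix(self.data.loc[list(rows)].copy())

    def samples_x_genes(self, genes: Sequence[str]) -> np.ndarray:
        """Samples-by-genes array for the given ordered gene list (the
        orientation classifiers consume)."""
        return self.restrict_rows(genes).data.to_numpy().T

    # -- I/O: tab-delimited, first column id, header row of sample ids ----

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA", "NaN", ""])
        return cls(df)

    def to_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", na_rep="NA")

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.copy())


@dataclass
class DoseLabels:
    """Per-sample radiation dose class in cGy.

    Doses are treated as unordered classes for classification but carry
    their numeric cGy value for goodness-of-fit.
    """

    series: pd.Series

    def __post_init__(self) -> None:
        s = pd.Series(self.series)
        s.index = s.index.astype(str)
        _check_unique(s.index, "sample ids")
        self.series = s.astype(float)
        if (self.series < 0).any():
            raise ValueError("dose values must be non-negative cGy")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.series.index)

    @property
    def classes(self) -> np.ndarray:
        """Ordered (ascending cGy) class set."""
        return np.sort(self.series.unique())

    def for_samples(self, samples: Sequence[str]) -> np.ndarray:
        missing = [s for s in samples if s not in self.series.index]
        if missing:
            raise KeyError(f"samples without dose labels: {missing}")
        return self.series.loc[list(samples)].to_numpy()

    def subset(self, samples: Sequence[str]) -> "DoseLabels":
        return DoseLabels(self.series.loc[list(samples)].copy())

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DoseLabels":
        df = pd.read_csv(path, sep="\t", header=0)
        if df.shape[1] < 2:
            raise ValueError("label file needs two columns: sample_id, dose_cGy")
        return cls(pd.Series(df.iloc[:, 1].to_numpy(), index=df.iloc[:, 0].astype(str)))

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"sample_id": self.series.index, "dose_cGy": self.series.to_numpy()}
        ).to_csv(path, sep="\t", index=False)


@dataclass
class ProbeAnnotation:
    """Probe-to-gene mapping; probes with a blank symbol are unmapped."""

    mapping: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[str, str] = {}
        for probe, gene in dict(self.mapping).items():
            gene = "" if gene is None or (isinstance(gene, float) and np.isnan(gene)) else str(gene).strip()
            clean[str(probe)] = gene
        self.mapping = clean

    def gene_for(self, probe: str) -> str | None:
        gene = self.mapping.get(probe, "")
        return gene if gene else None

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ProbeAnnotation":
        df = pd.read_csv(path, sep="\t", header=0, dtype=str, keep_default_na=False)
        if df.shape[1] < 2:
            raise ValueError("annotation needs two columns: probe_id, gene_symbol")
        return cls(dict(zip(df.iloc[:, 0], df.iloc[:, 1])))


@dataclass
class GenePanel:
    """Curated gene panel (e.g. a literature-derived radiation-response
    list).  Canonicalized symbols must be unique and the panel non-empty."""

    genes: Sequence[str]

    def __post_init__(self) -> None:
        genes = [g.strip() for g in self.genes if g.strip()]
        if not genes:
            raise ValueError("gene panel is empty")
        canon = [canonical_symbol(g) for g in genes]
        _check_unique(canon, "panel gene symbols (canonicalized)")
        self.genes = genes
        self._canon = set(canon)

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, symbol: str) -> bool:
        return canonical_symbol(symbol) in self._canon

    @classmethod
    def from_file(cls, path: str | Path) -> "GenePanel":
        genes = []
        for line in Path(path).read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if line:
                genes.append(line)
        return cls(genes)

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text("\n".join(self.genes) + "\n")
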