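"""Core in-memory containers: expression and enrichment matrices.

Both wrap a :class:`pandas.DataFrame` (features in rows, samples in columns)
and add the validation and metadata the analysis relies on — the expression
scale (linear vs log2) and whether enrichment scores were range-normalized.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

PathLike = Union[str, Path]


def normalize_symbol(symbol: str) -> str:
    """Case/whitespace-normalize a gene symbol (mixed-source tables)."""
    return str(symbol).strip().upper()


@dataclass
class ExpressionMatrix:
    """Gene-by-sample expression values.

    Parameters
    ----------
    data
        DataFrame with unique gene symbols as the index and unique
        sample (or cell) identifiers as columns. Values must be finite,
        and non-negative when ``scale == "linear"``.
    scale
        ``"linear"`` (e.g. TPM) or ``"log2"`` (e.g. log2(x+1)).
        Rank-based scoring is scale-invariant but geometric-mean ratios
        are not, so the scale is carried explicitly.
    """

    data: pd.DataFrame
    scale: str = "linear"

    def __post_init__(self) -> None:
        if self.scale not in ("linear", "log2"):
            raise ValueError(f"unknown scale {self.scale!r}; use 'linear' or 'log2'")
        if self.data.shape[0] == 0 or self.data.shape[1] == 0:
            raise ValueError("expression matrix must have at least one gene and one sample")
        self.data = self.data.copy()
        self.data.index = [normalize_symbol(g) for g in self.data.index]
        self.data.columns = [str(c) for c in self.data.columns]
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene identifiers after normalization: {dups[:5]}")
        if self.data.columns.has_duplicates:
            raise ValueError("duplicate sample identifiers")
        values = self.data.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise ValueError("expression values must be finite")
        if self.scale == "linear" and (values < 0).any():
            raise ValueError("linear-scale expression must be non-negative")

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def to_linear(self) -> "ExpressionMatrix":
        """Return a linear-scale copy (2**x for log2 data)."""
        if self.scale == "linear":
            return self
        return ExpressionMatrix(np.exp2(self.data), scale="linear")

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[:, list(sample_ids)], scale=self.scale)


@dataclass
class EnrichmentMatrix:
    """Gene-set-by-sample enrichment scores (the clustering substrate)."""

    scores: pd.DataFrame
    normalized: bool = False
    # bookkeeping for reproducibility reports
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.scores.shape[0] == 0 or self.scores.shape[1] == 0:
            raise ValueError("enrichment matrix must be non-empty")
        values = self.scores.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise ValueError("enrichment scores must be finite")
        if self.normalized:
            rng = values.max() - values.min()
            if rng > 0 and not np.isclose(rng, 1.0):
                raise ValueError("normalized enrichment matrix must have global range 1")

    @property
    def set_ids(self) -> list[str]:
        return list(self.scores.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.scores.columns)

    def sample_means(self) -> pd.Series:
        """Per-sample mean enrichment over all gene sets."""
        return self.scores.mean(axis=0)


def read_expression(path: PathLike, scale: str = "linear", sep: str = "\t") -> ExpressionMatrix:
    """Read a gene-by-sample TSV/CSV (first column gene symbols, header of sample IDs).

    Lines starting with ``#`` are ignored; gzip input is accepted via pandas.
    """
    df = pd.read_csv(path, sep=sep, index_col=0, comment="#")
    return ExpressionMatrix(df, scale=scale)


def write_expression(matrix: ExpressionMatrix, path: PathLike, sep: str = "\t",
                     header_comment: str | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write(f"# scale={matrix.scale}\n")
        matrix.data.to_csv(fh, sep=sep)


def read_enrichment(path: PathLike, sep: str = "\t") -> EnrichmentMatrix:
    df = pd.read_csv(path, sep=sep, index_col=0, comment="#")
    return EnrichmentMatrix(df)


def write_enrichment(matrix: EnrichmentMatrix, path: PathLike, sep: str = "\t") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# normalized={matrix.normalized}\n")
        matrix.scores.to_csv(fh, sep=sep)
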