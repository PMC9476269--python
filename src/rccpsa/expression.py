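"""Expression-matrix container, I/O, scale conversion and signature alignment.

Expression data are handled as genes × samples tables with an explicit
scale declaration (``linear`` FPKM/TPM-like values, or ``log2`` microarray
intensities).  Deconvolution requires linear-scale values, so log2 matrices
must be exponentiated with :func:`to_linear` before use.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import TYPE_CHECKING, Sequence

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .signature import SignatureMatrix

log = logging.getLogger(__name__)

LINEAR = "linear"
LOG2 = "log2"
_SCALES = (LINEAR, LOG2)


class ExpressionError(ValueError):
    """Invalid expression matrix content or usage."""


class ZeroVarianceError(ExpressionError):
    """A vector with zero variance cannot be standardized."""


@dataclass
class ExpressionMatrix:
    """Genes × samples expression matrix with a declared scale.

    Parameters
    ----------
    data
        DataFrame with gene identifiers as index and sample identifiers as
        columns.  Gene ids are opaque strings; no identifier mapping is done.
    scale
        ``"linear"`` (values must be non-negative) or ``"log2"``.
    """

    data: pd.DataFrame
    scale: str = LINEAR

    def __post_init__(self) -> None:
        if self.scale not in _SCALES:
            raise ExpressionError(f"unknown scale {self.scale!r}; expected one of {_SCALES}")
        if not isinstance(self.data, pd.DataFrame):
            self.data = pd.DataFrame(self.data)
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ExpressionError(f"duplicate gene identifiers: {dups[:10]}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ExpressionError(f"duplicate sample identifiers: {dups[:10]}")
        values = self.data.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.number):
            raise ExpressionError("expression values must be numeric")
        if values.size and np.isnan(values.astype(float)).any():
            raise ExpressionError("expression matrix contains missing values")
        if self.scale == LINEAR and values.size and float(values.min()) < 0:
            raise ExpressionError("linear-scale expression values must be non-negative")

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def sample_vector(self, sample: str) -> np.ndarray:
        return self.data[sample].to_numpy(dtype=float)


def read_expression_matrix(
    path, scale: str = LINEAR, delimiter: str = "\t"
) -> ExpressionMatrix:
    """Read a delimited expression matrix (gene ids in the first column).

    Duplicated gene rows are collapsed by keeping the row with the maximum
    mean expression (a common microarray convention); the collapse is logged.
    A non-numeric cell raises an error naming the offending gene and sample.
    """
    with open(path) as fh:  # pandas mangles duplicate header names, check raw
        header = ""
        for line in fh:
            if not line.startswith("#"):
                header = line.rstrip("\n")
                break
    sample_ids = header.split(delimiter)[1:]
    if len(set(sample_ids)) != len(sample_ids):
        dups = sorted({s for s in sample_ids if sample_ids.count(s) > 1})
        raise ExpressionError(f"duplicate sample identifiers in {path}: {dups[:10]}")
    raw = pd.read_csv(
        path, sep=delimiter, index_col=0, comment="#",
        dtype=str, keep_default_na=False,
    )
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().to_numpy()
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ExpressionError(
            f"non-numeric value {raw.iat[i, j]!r} at gene {raw.index[i]!r}, "
            f"sample {raw.columns[j]!r} in {path}"
        )
    if numeric.index.has_duplicates:
        n_before = len(numeric)
        means = numeric.mean(axis=1).to_numpy()
        keep = (
            pd.Series(means)
            .groupby(numeric.index.to_numpy(), sort=False)
            .idxmax()
            .to_numpy()
        )
        numeric = numeric.iloc[np.sort(keep)]
        log.info(
            "collapsed %d duplicated gene rows by maximum mean expression",
            n_before - len(numeric),
        )
    return ExpressionMatrix(numeric, scale=scale)


def write_expression_matrix(m: ExpressionMatrix, path, delimiter: str = "\t") -> None:
    m.data.to_csv(path, sep=delimiter, index_label="gene_id")


def to_linear(m: ExpressionMatrix) -> ExpressionMatrix:
    """Exponentiate a log2-scale matrix (values v → 2**v).

    Refuses a matrix already declared linear, so a matrix can never be
    silently double-exponentiated.
    """
    if m.scale != LOG2:
        raise ExpressionError("matrix is already on linear scale; refusing to exponentiate")
    return ExpressionMatrix(np.exp2(m.data), scale=LINEAR)


def standardize_vector(v: Sequence[float] | np.ndarray) -> np.ndarray:
    """Mean-center and scale to unit sample standard deviation (n−1 denominator).

    Raises :class:`ZeroVarianceError` for constant vectors — a sample that is
    flat over the signature genes carries no compositional information.
    """
    arr = np.asarray(v, dtype=float)
    if arr.ndim != 1:
        raise ExpressionError("standardize_vector expects a 1-D vector")
    if arr.size < 2:
        raise ExpressionError("standardize_vector needs at least 2 values")
    sd = arr.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ZeroVarianceError("zero variance: vector is constant over the gene set")
    return (arr - arr.mean()) / sd


def standardize_columns(values: np.ndarray) -> np.ndarray:
    """Column-wise version of :func:`standardize_vector` for a 2-D array."""
    arr = np.asarray(values, dtype=float)
    mean = arr.mean(axis=0)
    sd = arr.std(axis=0, ddof=1)
    if np.any(sd == 0) or not np.all(np.isfinite(sd)):
        bad = np.flatnonzero((sd == 0) | ~np.isfinite(sd))
        raise ZeroVarianceError(f"zero variance in column(s) {bad.tolist()[:10]}")
    return (arr - mean) / sd


def align_to_signature(
    m: ExpressionMatrix,
    sig: "SignatureMatrix",
    min_overlap_fraction: float = 0.8,
) -> tuple[ExpressionMatrix, "SignatureMatrix", list[str]]:
    """Subset/reorder a matrix to a signature's gene space.

    Signature genes absent from ``m`` are dropped from both the matrix and
    the signature for this run.  Returns the aligned matrix, the (possibly
    reduced) signature and the list of missing genes.  Fails if fewer than
    ``min_overlap_fraction`` of the signature genes are present.
    """
    if m.scale != LINEAR:
        raise ExpressionError("alignment requires a linear-scale matrix; call to_linear first")
    sig_genes = sig.genes
    have = set(m.genes)
    present = [g for g in sig_genes if g in have]
    missing = [g for g in sig_genes if g not in have]
    frac = len(present) / len(sig_genes)
    if frac < min_overlap_fraction:
        raise ExpressionError(
            f"only {len(present)}/{len(sig_genes)} signature genes present "
            f"({frac:.2f} < {min_overlap_fraction}); missing: {missing}"
        )
    if missing:
        log.info("dropping %d signature genes absent from matrix: %s", len(missing), missing)
        sig = sig.subset(present)
    aligned = ExpressionMatrix(m.data.loc[present], scale=LINEAR)
    return aligned, sig, missing
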