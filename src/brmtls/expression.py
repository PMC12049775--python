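"""Expression-matrix container, normalisations and delimited-text I/O.

The rest of the pipeline assumes a genes x samples matrix with a declared
unit. Counts are normalised to RPKM (reads per kilobase of merged exon model
per million mapped reads) or TPM, log2-transformed with a pseudocount for
marker scoring, and z-scored per gene for clustering heatmap inputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

UNITS = ("counts", "RPKM", "TPM", "log2")

PathLike = Union[str, Path]


@dataclass
class ExpressionMatrix:
    """Non-negative gene x sample expression values with a declared unit.

    Parameters
    ----------
    values
        DataFrame indexed by unique gene symbols, columns are unique
        sample identifiers.
    unit
        One of ``counts``, ``RPKM``, ``TPM`` or ``log2``. Negative values
        are rejected unless the unit is ``log2``.
    """

    values: pd.DataFrame
    unit: str = "counts"

    def __post_init__(self) -> None:
        if self.unit not in UNITS:
            raise ValueError(f"unknown unit {self.unit!r}; expected one of {UNITS}")
        if not self.values.index.is_unique:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene symbols: {dups}")
        if not self.values.columns.is_unique:
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample IDs: {dups}")
        arr = self.values.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise ValueError("expression values must be finite")
        if self.unit != "log2" and (arr < 0).any():
            raise ValueError(f"negative values not allowed for unit {self.unit!r}")

    @property
    def genes(self) -> list:
        return list(self.values.index)

    @property
    def samples(self) -> list:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple:
        return self.values.shape

    def subset_genes(self, genes) -> "ExpressionMatrix":
        present = [g for g in genes if g in self.values.index]
        return ExpressionMatrix(self.values.loc[present].copy(), self.unit)


def _check_lengths(m: ExpressionMatrix, lengths: pd.Series) -> pd.Series:
    missing = [g for g in m.genes if g not in lengths.index]
    if missing:
        raise KeyError(f"no exon-model length for gene(s): {missing[:10]}")
    lk = lengths.loc[m.genes].astype(float)
    if (lk <= 0).any():
        bad = lk.index[lk <= 0].tolist()
        raise ValueError(f"non-positive gene length for: {bad[:10]}")
    return lk


def compute_rpkm(counts: ExpressionMatrix, lengths: pd.Series) -> ExpressionMatrix:
    """Reads per kilobase of exon model per million mapped reads.

    For gene g and sample s: ``count(g,s) / (length_kb(g) * total_reads_millions(s))``
    where the per-sample total is the column sum of the count matrix.
    """
    if counts.unit != "counts":
        raise ValueError(f"compute_rpkm expects counts, got {counts.unit!r}")
    lk = _check_lengths(counts, lengths) / 1000.0  # bp -> kb
    totals = counts.values.sum(axis=0)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0].tolist()
        raise ValueError(f"zero total read count for sample(s): {bad}")
    rpkm = counts.values.div(lk, axis=0).div(totals / 1e6, axis=1)
    return ExpressionMatrix(rpkm, "RPKM")


def compute_tpm(counts: ExpressionMatrix, lengths: pd.Series) -> ExpressionMatrix:
    """Transcripts per million: length-normalised rates rescaled so each
    sample column sums to 1e6."""
    if counts.unit != "counts":
        raise ValueError(f"compute_tpm expects counts, got {counts.unit!r}")
    lk = _check_lengths(counts, lengths) / 1000.0
    rate = counts.values.div(lk, axis=0)
    denom = rate.sum(axis=0)
    if (denom <= 0).any():
        bad = denom.index[denom <= 0].tolist()
        raise ValueError(f"zero total read count for sample(s): {bad}")
    tpm = rate.div(denom, axis=1) * 1e6
    return ExpressionMatrix(tpm, "TPM")


def log_transform(m: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """log2(x + pseudocount); monotone in x."""
    if m.unit == "log2":
        raise ValueError("matrix is already log2-transformed")
    if pseudocount <= 0:
        raise ValueError(f"pseudocount must be positive, got {pseudocount}")
    return ExpressionMatrix(np.log2(m.values + pseudocount), "log2")


def zscore_genes(m: ExpressionMatrix, ddof: int = 0) -> pd.DataFrame:
    """Center and scale each gene row to mean 0 and SD 1.

    Population SD (``ddof=0``) by default. Constant rows are returned as
    all-zero with a logged warning rather than NaN.
    """
    if m.shape[1] < 2:
        raise ValueError("z-scoring requires at least 2 samples")
    arr = m.values.to_numpy(dtype=float)
    mean = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, ddof=ddof, keepdims=True)
    flat = (sd == 0).ravel()
    if flat.any():
        log.warning(
            "%d constant gene row(s) set to zero in z-score: %s",
            int(flat.sum()),
            list(m.values.index[flat][:10]),
        )
    sd[sd == 0] = 1.0
    z = (arr - mean) / sd
    z[np.asarray(flat), :] = 0.0
    return pd.DataFrame(z, index=m.values.index, columns=m.values.columns)


# ---------------------------------------------------------------------------
# I/O: tab-separated (default) or comma-separated by extension; genes in rows,
# first column the gene symbol, samples in columns.
# ---------------------------------------------------------------------------

def _sep_for(path: PathLike) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_expression(path: PathLike, unit: str = "counts") -> ExpressionMatrix:
    # round_trip parsing keeps the write -> read cycle bit-exact
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0, float_precision="round_trip")
    df.index = df.index.astype(str)
    if not df.index.is_unique:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene symbols in {path}: {dups}")
    return ExpressionMatrix(df.astype(float), unit)


def write_expression(m: ExpressionMatrix, path: PathLike) -> None:
    # %.17g round-trips IEEE doubles exactly
    m.values.to_csv(path, sep=_sep_for(path), index_label="gene", float_format="%.17g")


def read_gene_lengths(path: PathLike) -> pd.Series:
    """Two-column table: gene symbol, merged exon-unit length in bp."""
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    s = df.iloc[:, 0].astype(float)
    s.index = s.index.astype(str)
    if (s <= 0).any():
        raise ValueError("gene lengths must be positive")
    return s


def write_gene_lengths(lengths: pd.Series, path: PathLike) -> None:
    lengths.rename("length_bp").to_csv(path, sep=_sep_for(path), index_label="gene")
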