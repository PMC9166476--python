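"""Gene expression matrix (GEM) I/O and preprocessing.

A GEM is a genes × samples table of non-negative expression values
(FPKM-like before the log step).  This module reads and writes the
tab-delimited interchange format, merges matrices from multiple sources,
and implements the standard preprocessing chain applied before model
training: log2 transform, quantile normalization, and minimum-value
imputation of missing entries.

Missing values are represented as NaN throughout; they are never silently
coerced to zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "ExpressionMatrix",
    "read_gem",
    "write_gem",
    "read_labels",
    "write_labels",
    "align_labels",
    "merge_gems",
    "log2_transform",
    "quantile_normalize",
    "impute_missing",
]


@dataclass(frozen=True)
class ExpressionMatrix:
    """Genes × samples expression table with unique row/column identifiers.

    Parameters
    ----------
    data
        DataFrame indexed by gene ID with one column per sample ID.
        NaN marks a missing measurement.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        idx = self.data.index
        cols = self.data.columns
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise ValueError(f"duplicate gene ID: {dup!r}")
        if cols.has_duplicates:
            dup = cols[cols.duplicated()][0]
            raise ValueError(f"duplicate sample ID: {dup!r}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def select_samples(self, sample_ids: list[str]) -> "ExpressionMatrix":
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise KeyError(f"unknown sample ID(s): {missing}")
        return ExpressionMatrix(self.data[sample_ids])


def read_gem(path) -> ExpressionMatrix:
    """Read a tab-delimited GEM: first column gene IDs, header sample IDs.

    Empty cells and ``NA`` denote missing values.  Gzip-compressed files
    are handled transparently by extension.  Duplicated identifiers or a
    non-numeric cell raise ``ValueError`` naming the offender.
    """
    header = pd.read_csv(path, sep="\t", dtype=str, header=None, nrows=1)
    sample_ids = header.iloc[0, 1:].tolist()
    dup = pd.Index(sample_ids)
    if dup.has_duplicates:  # pandas would silently rename these
        raise ValueError(
            f"duplicate sample ID: {dup[dup.duplicated()][0]!r}")
    raw = pd.read_csv(path, sep="\t", dtype=str, index_col=0,
                      keep_default_na=False, na_values=["", "NA"])
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & raw.notna()
    if bad.to_numpy().any():
        rows, cols = np.nonzero(bad.to_numpy())
        g, s = raw.index[rows[0]], raw.columns[cols[0]]
        raise ValueError(
            f"non-numeric value {raw.iat[rows[0], cols[0]]!r} "
            f"at gene {g!r}, sample {s!r}"
        )
    return ExpressionMatrix(numeric.astype(float))


def write_gem(gem: ExpressionMatrix, path) -> None:
    """Write a GEM as TSV with a ``GENE`` corner label; NaN written as NA."""
    out = gem.data.copy()
    out.index.name = "GENE"
    out.to_csv(path, sep="\t", float_format="%.6g", na_rep="NA")


def read_labels(path) -> pd.Series:
    """Read a two-column headerless sample→class TSV into a Series."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str,
                     names=["sample_id", "label"])
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"duplicate sample ID in labels: {dup!r}")
    return pd.Series(df["label"].to_numpy(), index=df["sample_id"], name="label")


def write_labels(labels: pd.Series, path) -> None:
    labels.to_csv(path, sep="\t", header=False)


def align_labels(labels: pd.Series, gem: ExpressionMatrix) -> pd.Series:
    """Return labels reindexed to the GEM's sample order.

    Raises ``KeyError`` if the labels reference a sample absent from the
    GEM or if a GEM sample has no label.
    """
    extra = [s for s in labels.index if s not in gem.data.columns]
    if extra:
        raise KeyError(f"labels reference sample(s) not in GEM: {extra}")
    unlabeled = [s for s in gem.sample_ids if s not in labels.index]
    if unlabeled:
        raise KeyError(f"GEM sample(s) without label: {unlabeled}")
    return labels.reindex(gem.sample_ids)


def merge_gems(gems: list[ExpressionMatrix]) -> ExpressionMatrix:
    """Concatenate sample columns across matrices from different sources.

    Gene rows are restricted to the intersection of the inputs' gene sets,
    kept in the first input's order.  Sample IDs must be pairwise disjoint.
    """
    if len(gems) < 2:
        raise ValueError("merge_gems requires at least two matrices")
    seen: set[str] = set()
    for g in gems:
        overlap = seen.intersection(g.sample_ids)
        if overlap:
            raise ValueError(f"sample ID(s) shared across inputs: {sorted(overlap)}")
        seen.update(g.sample_ids)
    common = set(gems[0].gene_ids)
    for g in gems[1:]:
        common &= set(g.gene_ids)
    if not common:
        raise ValueError("gene intersection across inputs is empty")
    order = [g for g in gems[0].gene_ids if g in common]
    parts = [g.data.loc[order] for g in gems]
    return ExpressionMatrix(pd.concat(parts, axis=1))


def log2_transform(gem: ExpressionMatrix) -> ExpressionMatrix:
    """log2 each positive entry; zeros become missing; negatives are an error.

    Zeros carry no information after the log step, so they join the missing
    pool and are later filled by minimum-value imputation.
    """
    vals = gem.values
    finite = np.isfinite(vals)
    if (vals[finite] < 0).any():
        r, c = next(zip(*np.nonzero(finite & (vals < 0))))
        raise ValueError(
            f"negative expression value at gene {gem.gene_ids[r]!r}, "
            f"sample {gem.sample_ids[c]!r}"
        )
    out = np.where(finite & (vals > 0), np.log2(np.where(vals > 0, vals, 1.0)), np.nan)
    return ExpressionMatrix(pd.DataFrame(out, index=gem.data.index,
                                         columns=gem.data.columns))


def _column_reference(vals: np.ndarray) -> np.ndarray:
    """Per-rank means of the columns' sorted values, interpolated to a
    common grid so columns with unequal missing counts contribute equally."""
    n_cols = vals.shape[1]
    counts = [int(np.isfinite(vals[:, j]).sum()) for j in range(n_cols)]
    m = max(counts)
    grid = np.linspace(0.0, 1.0, m)
    ref = np.zeros(m)
    for j in range(n_cols):
        col = np.sort(vals[np.isfinite(vals[:, j]), j])
        if len(col) == 1:
            ref += col[0]
        else:
            ref += np.interp(grid, np.linspace(0.0, 1.0, len(col)), col)
    return ref / n_cols


def quantile_normalize(gem: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample column onto one shared empirical distribution.

    The reference distribution is the per-rank mean of all columns; each
    column's values are replaced by the reference value at their rank.
    Tied values receive the mean of the reference values their ranks span.
    Missing entries are excluded from ranking and preserved.
    """
    if gem.n_samples < 2:
        raise ValueError("quantile normalization requires at least two samples")
    vals = gem.values
    for j in range(gem.n_samples):
        if not np.isfinite(vals[:, j]).any():
            raise ValueError(f"sample {gem.sample_ids[j]!r} is entirely missing")
    ref = _column_reference(vals)
    m = len(ref)
    out = np.full_like(vals, np.nan)
    for j in range(vals.shape[1]):
        mask = np.isfinite(vals[:, j])
        col = vals[mask, j]
        k = len(col)
        if k == 1:
            out[mask, j] = ref[0]
            continue
        targets = np.interp(np.linspace(0.0, 1.0, k),
                            np.linspace(0.0, 1.0, m), ref)
        order = np.argsort(col, kind="mergesort")
        assigned = np.empty(k)
        assigned[order] = targets
        # average the targets within each group of tied input values
        ranks = rankdata(col, method="dense")
        sums = np.bincount(ranks, weights=assigned)
        cnts = np.bincount(ranks)
        out[mask, j] = sums[ranks] / cnts[ranks]
    return ExpressionMatrix(pd.DataFrame(out, index=gem.data.index,
                                         columns=gem.data.columns))


def impute_missing(gem: ExpressionMatrix,
                   reference: ExpressionMatrix) -> ExpressionMatrix:
    """Fill missing entries with the global minimum of the reference matrix.

    The reference is the training GEM; held-out and perturbed matrices are
    imputed with the training minimum so no held-out information leaks into
    the fill value.
    """
    ref_vals = reference.values
    finite = ref_vals[np.isfinite(ref_vals)]
    if finite.size == 0:
        raise ValueError("reference matrix is entirely missing")
    fill = float(finite.min())
    return ExpressionMatrix(gem.data.fillna(fill))
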