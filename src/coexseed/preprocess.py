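"""Within- and cross-platform normalization, probe collapsing, DEG selection.

The preprocessing chain mirrors standard multi-platform microarray
practice: quantile normalization within a platform, exclusion of probes
lacking both a gene symbol and an entrez id, averaging of duplicate
probes per gene, median-rank-scores (MRS) normalization onto a reference
platform when merging platforms, and fold-change DEG selection.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .datatypes import Contrast, DegList, ExpressionDataset

__all__ = [
    "quantile_normalize",
    "median_rank_transform",
    "collapse_probes",
    "filter_unannotated",
    "fold_change_filter",
]


def quantile_normalize(values: pd.DataFrame) -> pd.DataFrame:
    """Classic quantile normalization of a probe-by-sample matrix.

    Every column is mapped onto the reference distribution formed by the
    row-wise mean of the column-sorted input, so all columns share
    identical sorted values afterwards. Tied values within a column
    receive the mean of the reference values at their occupied positions.
    A single-column matrix is returned unchanged with a warning.
    """
    X = values.to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("matrix contains non-finite values")
    n, s = X.shape
    if s < 2:
        warnings.warn("quantile_normalize: single sample, returning input unchanged")
        return values.copy()
    reference = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for j in range(s):
        col = X[:, j]
        order = np.argsort(col, kind="stable")
        mapped = np.empty(n)
        mapped[order] = reference
        # Average the reference values across tied positions.
        ser = pd.Series(mapped)
        out[:, j] = ser.groupby(pd.Series(col)).transform("mean").to_numpy()
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def median_rank_transform(
    datasets: list[ExpressionDataset], reference_id: str | None = None
) -> ExpressionDataset:
    """Median-rank-scores cross-platform normalization and merge.

    The datasets are restricted to their shared genes; the reference
    vector is the per-rank median of the reference dataset's
    column-sorted values, and every sample's value at rank r is replaced
    by the r-th entry of that vector. All samples therefore share
    identical sorted values on output, which undoes any strictly monotone
    per-platform intensity distortion. Rank ties are broken by the stable
    order of row ids.

    The reference defaults to the dataset with the most samples (the
    larger merged platform).
    """
    if len(datasets) < 2:
        raise ValueError("median_rank_transform needs >= 2 datasets")
    ids = [d.dataset_id for d in datasets]
    if reference_id is None:
        reference_id = max(datasets, key=lambda d: d.n_samples).dataset_id
    if reference_id not in ids:
        raise ValueError(f"reference dataset {reference_id!r} not among {ids}")

    shared = datasets[0].values.index
    for d in datasets[1:]:
        shared = shared.intersection(d.values.index)
    shared = shared.sort_values()
    if len(shared) < 2:
        raise ValueError("datasets share fewer than 2 genes")

    all_samples = pd.concat([d.samples for d in datasets], axis=0)
    if all_samples.index.duplicated().any():
        raise ValueError("duplicate sample ids across datasets")

    ref = next(d for d in datasets if d.dataset_id == reference_id)
    ref_sorted = np.sort(ref.values.loc[shared].to_numpy(dtype=float), axis=0)
    ref_vector = np.median(ref_sorted, axis=1)

    blocks = []
    for d in datasets:
        X = d.values.loc[shared].to_numpy(dtype=float)
        out = np.empty_like(X)
        for j in range(X.shape[1]):
            order = np.argsort(X[:, j], kind="stable")
            out[order, j] = ref_vector
        blocks.append(pd.DataFrame(out, index=shared, columns=d.values.columns))
    values = pd.concat(blocks, axis=1)
    merged_id = "+".join(ids)
    return ExpressionDataset(merged_id, values, all_samples, annotation=None)


def filter_unannotated(dataset: ExpressionDataset) -> ExpressionDataset:
    """Drop probes lacking a gene symbol or an entrez id."""
    if dataset.annotation is None:
        raise ValueError("dataset has no probe annotation")
    ann = dataset.annotation
    keep = ann.index[ann["symbol"].notna() & ann["entrez"].notna()]
    keep = dataset.values.index.intersection(keep)
    if len(keep) == 0:
        raise ValueError("all probes removed: no probe has both symbol and entrez id")
    return dataset.subset_rows(keep)


def collapse_probes(dataset: ExpressionDataset) -> ExpressionDataset:
    """Average duplicate probes of each gene into a single row.

    Rows become gene symbols; probes without a symbol are dropped. The
    per-gene value is the arithmetic mean of that gene's probe rows.
    """
    if dataset.annotation is None:
        raise ValueError("dataset has no probe annotation")
    ann = dataset.annotation.reindex(dataset.values.index)
    symbols = ann["symbol"]
    keep = symbols.notna()
    values = dataset.values.loc[keep].groupby(symbols[keep]).mean()
    values = values.sort_index()
    values.index.name = "gene"
    return ExpressionDataset(dataset.dataset_id, values, dataset.samples.copy(), None)


def fold_change_filter(
    dataset: ExpressionDataset,
    contrast: Contrast,
    threshold: float | None = 1.2,
    retain_all: bool = False,
) -> DegList:
    """Select genes by linear fold change between the contrast groups.

    FC = 2^(mean_case - mean_baseline) on log2 data; a gene is retained
    iff FC >= threshold or FC <= 1/threshold. ``retain_all`` (or
    ``threshold=None``) bypasses the filter, the convention for small
    targeted arrays where every gene is carried forward.
    """
    groups = dataset.groups
    case_cols = dataset.values.columns[groups == contrast.case]
    base_cols = dataset.values.columns[groups == contrast.baseline]
    if len(case_cols) == 0 or len(base_cols) == 0:
        raise ValueError(
            f"contrast {contrast.name}: empty group "
            f"(case n={len(case_cols)}, baseline n={len(base_cols)})"
        )
    log_fc = dataset.values[case_cols].mean(axis=1) - dataset.values[base_cols].mean(
        axis=1
    )
    fc = np.power(2.0, log_fc)
    if retain_all or threshold is None:
        mask = pd.Series(True, index=fc.index)
        used = None
    else:
        mask = (fc >= threshold) | (fc <= 1.0 / threshold)
        used = float(threshold)
    return DegList(genes=list(fc.index[mask]), fold_changes=fc[mask], threshold=used)
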