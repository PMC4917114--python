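"""Module membership, cross-dataset meta statistics, final assignment.

A gene's module membership (MM) for a module is its average Pearson
correlation with the module's five genes of highest within-module
connectivity (kin), the scored gene itself excluded — a cheap proxy for
the gene-eigengene correlation (an exact eigengene mode is available).
Per-dataset MM correlations are combined by t-transforming each
(t = r sqrt(n-2) / sqrt(1-r^2)), averaging the t-scores, scaling by
sqrt(D) where D is the number of datasets covering the gene, and
converting to a two-sided P on Student's t with the pooled
df = sum_d (n_d - 2). Genes with mean R > 0.2 and P < 1e-13 receive a
final module label.
"""
from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ModuleAssignment

__all__ = [
    "within_module_connectivity",
    "module_membership",
    "meta_membership",
    "assign_final_modules",
    "module_eigengene",
    "module_trait_correlation",
    "null_membership_pvalues",
]

_R_CLAMP = 1.0 - 1e-12


def within_module_connectivity(
    adjacency: pd.DataFrame, assignment: ModuleAssignment
) -> pd.Series:
    """kin_i = sum of adjacency from gene i to the other genes of its module.

    Unassigned genes (label 0) and singleton-module genes get kin = 0.
    """
    kin = pd.Series(0.0, index=adjacency.index)
    for m in assignment.modules:
        members = [g for g in assignment.module_genes(m) if g in adjacency.index]
        if len(members) < 2:
            continue
        sub = adjacency.loc[members, members].to_numpy(dtype=float)
        kin.loc[members] = sub.sum(axis=1) - np.diag(sub)
    return kin


def _standardize(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    sd[sd == 0] = np.nan
    return (X - mu) / sd


def module_membership(
    values: pd.DataFrame,
    assignment: ModuleAssignment,
    adjacency: pd.DataFrame,
    top_n: int = 5,
    mode: str = "top_kin",
) -> pd.DataFrame:
    """MM correlation of every gene with every module.

    ``values`` is genes x samples for one dataset; ``adjacency`` (used
    only for the kin ranking of reference genes) may come from the merged
    matrix so that all datasets share reference genes. Returns a
    genes x modules frame of correlations. Modules of size < 2 yield NaN.

    ``mode='eigengene'`` correlates each gene with the module eigengene
    instead of the top-kin reference genes.
    """
    if mode not in ("top_kin", "eigengene"):
        raise ValueError("mode must be 'top_kin' or 'eigengene'")
    modules = assignment.modules
    out = pd.DataFrame(np.nan, index=values.index, columns=pd.Index(modules, name="module"))
    if not modules:
        return out
    Z = _standardize(values.to_numpy(dtype=float))
    n = Z.shape[1]
    gene_pos = {g: i for i, g in enumerate(values.index)}

    if mode == "eigengene":
        mes = module_eigengene(values, assignment)
        zg = np.nan_to_num(Z)
        for m in mes.columns:
            me = mes[m].to_numpy()
            me = (me - me.mean()) / me.std()
            out[m] = zg @ me / n
        return out

    kin = within_module_connectivity(adjacency, assignment)
    for m in modules:
        members = [g for g in assignment.module_genes(m) if g in values.index]
        if len(members) < 2:
            continue
        ranked = sorted(members, key=lambda g: (-kin.get(g, 0.0), g))
        top = ranked[: top_n + 1]
        top_pos = [gene_pos[g] for g in top]
        C = np.nan_to_num(Z) @ Z[top_pos].T / n  # all genes vs reference pool

        default_refs = top[:top_n]
        col = C[:, : len(default_refs)].mean(axis=1)
        # Genes appearing in their own reference set use the next-ranked gene.
        for g in top:
            refs = [h for h in top if h != g][:top_n]
            ref_idx = [top.index(h) for h in refs]
            col[gene_pos[g]] = C[gene_pos[g], ref_idx].mean() if refs else np.nan
        out[m] = col
    return out


def meta_membership(
    tables: Sequence[tuple[pd.DataFrame, int]],
) -> pd.DataFrame:
    """Combine per-dataset MM correlations into meta statistics.

    ``tables`` is a sequence of (genes x modules MM frame, n_samples)
    pairs, one per dataset; genes absent from a dataset are NaN there and
    simply do not contribute. Returns a tidy frame indexed by
    (gene, module) with columns R (mean r), t_bar, T_scaled, D, df and P.
    Invariant to the order of datasets.
    """
    if not tables:
        raise ValueError("no MM tables given")
    for _, n in tables:
        if n < 4:
            raise ValueError("each dataset needs n >= 4 samples")
    genes = tables[0][0].index
    modules = tables[0][0].columns
    for t, _ in tables[1:]:
        genes = genes.union(t.index)
        modules = modules.union(t.columns)
    genes = genes.sort_values()
    modules = modules.sort_values()

    R = np.stack(
        [t.reindex(index=genes, columns=modules).to_numpy(dtype=float) for t, _ in tables]
    )  # (D, G, M)
    ns = np.array([n for _, n in tables], dtype=float)

    if np.nanmax(np.abs(R), initial=0.0) >= 1.0:
        warnings.warn("|r| = 1 encountered; clamping before the t transform")
    Rc = np.clip(R, -_R_CLAMP, _R_CLAMP)
    with np.errstate(invalid="ignore"):
        T = Rc * np.sqrt(ns[:, None, None] - 2.0) / np.sqrt(1.0 - Rc**2)

    covered = ~np.isnan(R)
    D = covered.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore"):
        t_bar = np.nansum(np.where(covered, T, 0.0), axis=0) / D
        r_mean = np.nansum(np.where(covered, R, 0.0), axis=0) / D
    t_scaled = t_bar * np.sqrt(D)
    df = np.einsum("dgm,d->gm", covered.astype(float), ns - 2.0)
    with np.errstate(invalid="ignore"):
        P = 2.0 * stats.t.sf(np.abs(t_scaled), df=np.where(df > 0, df, 1.0))
    P = np.where(D > 0, np.minimum(P, 1.0), np.nan)

    idx = pd.MultiIndex.from_product([genes, modules], names=["gene", "module"])
    out = pd.DataFrame(
        {
            "R": r_mean.ravel(),
            "t_bar": t_bar.ravel(),
            "T_scaled": t_scaled.ravel(),
            "D": D.ravel(),
            "df": df.ravel(),
            "P": P.ravel(),
        },
        index=idx,
    )
    return out.dropna(subset=["R"])


def assign_final_modules(
    meta: pd.DataFrame, r_min: float = 0.2, p_max: float = 1e-13
) -> ModuleAssignment:
    """Final module labels from the meta MM table.

    A gene is assigned to the module maximizing R among the (gene,
    module) pairs with R > r_min and P < p_max; genes passing for no
    module are unassigned (0).
    """
    genes = meta.index.get_level_values("gene").unique().sort_values()
    labels = pd.Series(0, index=pd.Index(genes, name="gene"), dtype=int)
    passing = meta[(meta["R"] > r_min) & (meta["P"] < p_max)]
    if len(passing):
        best = passing["R"].groupby(level="gene").idxmax()
        for gene, (g, module) in best.items():
            labels.loc[gene] = int(module)
    return ModuleAssignment(labels, method="meta")


def module_eigengene(
    values: pd.DataFrame, assignment: ModuleAssignment
) -> pd.DataFrame:
    """First principal component of each module's standardized submatrix.

    Returns a samples x modules frame; each eigengene is sign-oriented so
    that its mean correlation with the module's genes is non-negative and
    scaled to unit standard deviation. Modules of size < 2 are skipped;
    a zero-variance gene inside a module raises.
    """
    out = {}
    for m in assignment.modules:
        members = [g for g in assignment.module_genes(m) if g in values.index]
        if len(members) < 2:
            continue
        X = values.loc[members].to_numpy(dtype=float)
        if np.any(X.std(axis=1) == 0):
            bad = [g for g in members if values.loc[g].std() == 0]
            raise ValueError(f"zero-variance gene(s) in module {m}: {bad[:5]}")
        Z = _standardize(X)
        _, _, vt = np.linalg.svd(Z, full_matrices=False)
        me = vt[0]
        if (Z @ me).mean() < 0:
            me = -me
        out[m] = me / me.std()
    return pd.DataFrame(out, index=values.columns).rename_axis(columns="module")


def module_trait_correlation(
    eigengenes: pd.DataFrame,
    trait: pd.Series,
    r_min: float = 0.2,
    top_m: int | None = None,
) -> pd.DataFrame:
    """Pearson correlation of each module eigengene with a 0/1 trait.

    Returns a frame (module, r, abs_r, selected) ranked by |r|;
    ``selected`` marks |r| >= r_min, or the top_m modules when ``top_m``
    is given.
    """
    t = trait.reindex(eigengenes.index).to_numpy(dtype=float)
    if np.isnan(t).any():
        raise ValueError("trait is missing for some samples")
    if t.std() == 0:
        raise ValueError("trait is constant across samples")
    rows = []
    for m in eigengenes.columns:
        r = float(np.corrcoef(eigengenes[m].to_numpy(), t)[0, 1])
        rows.append({"module": m, "r": r, "abs_r": abs(r)})
    out = pd.DataFrame(rows).sort_values("abs_r", ascending=False, ignore_index=True)
    if top_m is not None:
        out["selected"] = out.index < top_m
    else:
        out["selected"] = out["abs_r"] >= r_min
    return out


def null_membership_pvalues(
    n_genes: int = 2100,
    n_datasets: int = 3,
    n_samples: int = 40,
    n_modules: int = 21,
    seed: int = 0,
) -> np.ndarray:
    """Meta P values under the global null, for calibration checks.

    Genes are independent Gaussians and module labels are arbitrary; each
    gene is scored (exact eigengene mode) against a module it does not
    belong to, so its MM correlation is a genuine null correlation and
    the meta P should be approximately Uniform(0, 1).
    """
    rng = np.random.default_rng(seed)
    genes = [f"N{i:05d}" for i in range(n_genes)]
    labels = pd.Series(np.arange(n_genes) % n_modules + 1, index=genes)
    assignment = ModuleAssignment(labels, method="tree_cut")
    target = (labels % n_modules) + 1  # the "next" module: never the gene's own

    tables = []
    for d in range(n_datasets):
        X = rng.normal(size=(n_genes, n_samples))
        values = pd.DataFrame(X, index=genes, columns=[f"d{d}s{j}" for j in range(n_samples)])
        mes = module_eigengene(values, assignment)
        Z = _standardize(X)
        r = np.empty(n_genes)
        for m in mes.columns:
            me = mes[m].to_numpy()
            me = (me - me.mean()) / me.std()
            rows = np.flatnonzero(target.to_numpy() == m)
            r[rows] = Z[rows] @ me / n_samples
        tables.append((pd.DataFrame({"null": r}, index=genes), n_samples))
    meta = meta_membership(tables)
    return meta["P"].to_numpy()
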