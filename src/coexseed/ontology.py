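"""Ontology-based gene filtering, over-representation tests, kappa network.

Genes with no known ontology term are dropped; enrichment of the
remaining gene list against a gene-set collection is tested with the
hypergeometric over-representation test and Benjamini-Hochberg FDR
control; enriched terms are linked into a network weighted by Cohen's
kappa between their gene-membership vectors (edges kept at kappa >= 0.4,
terms kept when they hold >= 4% of their genes in the query with
p < 0.05, the ClueGO-style conventions).
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .datatypes import GeneSetCollection

__all__ = [
    "annotation_filter",
    "ora_test",
    "bh_adjust",
    "enrich_collection",
    "term_kappa",
    "build_term_network",
    "EnrichmentResult",
]


def annotation_filter(
    genes: Sequence[str], collection: GeneSetCollection
) -> list[str]:
    """Retain the genes belonging to at least one term, preserving order."""
    if not collection.terms:
        raise ValueError("gene-set collection is empty")
    covered = collection.covered_genes()
    return [g for g in genes if g in covered]


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    k: int  # overlap
    n: int  # query size
    K: int  # term size within universe
    N: int  # universe size
    p: float
    q: float | None = None


def ora_test(
    query: Iterable[str],
    term_genes: Iterable[str],
    universe: Iterable[str],
    term_id: str = "",
) -> EnrichmentResult:
    """Hypergeometric over-representation p value, P(X >= k).

    X ~ Hypergeometric(N, K, n) with N the universe size, K the term size
    within the universe and n the query size.
    """
    universe = set(universe)
    query = set(query)
    if not query:
        raise ValueError("query gene list is empty")
    if not query <= universe:
        raise ValueError(f"query genes outside universe: {sorted(query - universe)[:5]}")
    term = set(term_genes) & universe
    if not term:
        raise ValueError(f"term {term_id!r} does not intersect the universe")
    N, K, n = len(universe), len(term), len(query)
    k = len(query & term)
    p = float(hypergeom.sf(k - 1, N, K, n))
    return EnrichmentResult(term_id, k, n, K, N, min(p, 1.0))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich_collection(
    query: Sequence[str],
    collection: GeneSetCollection,
    universe: Sequence[str],
) -> pd.DataFrame:
    """ORA of the query against every term; pooled BH across the collection.

    Terms with no gene in the universe are skipped.
    """
    rows = []
    for tid, members in collection.terms.items():
        if not set(members) & set(universe):
            continue
        r = ora_test(query, members, universe, term_id=tid)
        rows.append({"term": tid, "k": r.k, "n": r.n, "K": r.K, "N": r.N, "p": r.p})
    out = pd.DataFrame(rows, columns=["term", "k", "n", "K", "N", "p"])
    out["q"] = bh_adjust(out["p"].to_numpy()) if len(out) else []
    return out


def term_kappa(
    term_a: Iterable[str], term_b: Iterable[str], universe: Iterable[str]
) -> float:
    """Cohen's kappa between two terms' membership vectors over the universe."""
    universe = set(universe)
    A = set(term_a) & universe
    B = set(term_b) & universe
    if not A or not B:
        raise ValueError("both terms must intersect the universe")
    N = len(universe)
    a = len(A & B)
    b = len(A - B)
    c = len(B - A)
    d = N - a - b - c
    p_o = (a + d) / N
    pa, pb = len(A) / N, len(B) / N
    p_e = pa * pb + (1 - pa) * (1 - pb)
    if p_e >= 1.0:
        if A == B:
            return 1.0
        raise ValueError("kappa undefined: both terms cover the whole universe")
    return (p_o - p_e) / (1.0 - p_e)


def build_term_network(
    enrichment: pd.DataFrame,
    collection: GeneSetCollection,
    query: Sequence[str],
    universe: Sequence[str],
    kappa_min: float = 0.4,
    gene_fraction_min: float = 0.04,
    p_max: float = 0.05,
) -> nx.Graph:
    """Kappa-weighted network over the retained enriched terms.

    A term is retained iff p < p_max and its query overlap holds at least
    ``gene_fraction_min`` of the term's genes (k / K); retained terms are
    linked when their membership kappa reaches ``kappa_min``. Output is
    invariant to term input order (nodes and edge scans are sorted).
    """
    keep = enrichment[
        (enrichment["p"] < p_max)
        & (enrichment["k"] / enrichment["K"] >= gene_fraction_min)
    ]["term"].tolist()
    G = nx.Graph()
    G.add_nodes_from(sorted(keep))
    for ta, tb in combinations(sorted(keep), 2):
        kappa = term_kappa(collection.terms[ta], collection.terms[tb], universe)
        if kappa >= kappa_min:
            G.add_edge(ta, tb, kappa=float(kappa))
    return G
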