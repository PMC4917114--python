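"""Seed-gene network expansion, hub ranking and candidate classification.

Filtered module genes act as seeds on a reference interaction network
(directed, signed edges: activation / inhibition / co-expression). The
induced subgraph within a given undirected radius of the seeds is
extracted, its highest-degree nodes are the hubs, and candidate targets
are the hubs holding a network role: initiation (pure source on the
directed edges), termination (pure sink), or critical connection (high
betweenness or articulation point of the undirected skeleton).
Candidates from the two severity contrasts are merged (union by
default) into the final target list.
"""
from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .datatypes import CandidateSet

__all__ = [
    "expand_from_seeds",
    "rank_hubs",
    "classify_candidates",
    "merge_candidates",
    "EDGE_SIGNS",
]

EDGE_SIGNS = ("activation", "inhibition", "co-expression")


def expand_from_seeds(
    network: nx.DiGraph, seeds: Sequence[str], radius: int = 1
) -> nx.DiGraph:
    """Induced subgraph on nodes within undirected distance <= radius of a seed."""
    if not len(seeds):
        raise ValueError("no seed genes given")
    if radius < 0:
        raise ValueError("radius must be >= 0")
    present = [s for s in seeds if s in network]
    missing = [s for s in seeds if s not in network]
    if not present:
        raise ValueError(f"no seed present in the network; missing: {sorted(missing)}")
    if missing:
        warnings.warn(f"{len(missing)} seed(s) not in the network: {sorted(missing)[:5]}")
    UG = network.to_undirected(as_view=True)
    nodes: set[str] = set()
    for s in present:
        nodes |= set(nx.single_source_shortest_path_length(UG, s, cutoff=radius))
    return network.subgraph(nodes).copy()


def rank_hubs(network: nx.DiGraph, k: int) -> list[tuple[str, int]]:
    """Top-k nodes by total degree (each stored edge counted once per endpoint).

    Ties are broken lexicographically by gene id. If k exceeds the node
    count, all nodes are returned with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    n = network.number_of_nodes()
    if k > n:
        warnings.warn(f"k={k} exceeds node count {n}; returning all nodes")
        k = n
    ranked = sorted(network.degree(), key=lambda item: (-item[1], item[0]))
    return [(node, int(deg)) for node, deg in ranked[:k]]


def _directed_degrees(network: nx.DiGraph, node: str) -> tuple[int, int]:
    """(in, out) degree over activation/inhibition edges only."""
    in_d = sum(
        1 for _, _, s in network.in_edges(node, data="sign") if s != "co-expression"
    )
    out_d = sum(
        1 for _, _, s in network.out_edges(node, data="sign") if s != "co-expression"
    )
    return in_d, out_d


def classify_candidates(
    network: nx.DiGraph,
    hubs: Sequence[str],
    betweenness_quantile: float = 0.9,
    contrast: str = "",
) -> CandidateSet:
    """Tag hubs with network roles and keep those holding at least one.

    initiation: no incoming directed edge but at least one outgoing;
    termination: the reverse; critical: positive betweenness centrality
    at or above the given quantile among the hubs, or an articulation
    point of the undirected skeleton. Co-expression edges are ignored for
    the source/sink roles but participate in the skeleton.
    """
    if not (0.0 <= betweenness_quantile <= 1.0):
        raise ValueError("betweenness_quantile must lie in [0, 1]")
    missing = [h for h in hubs if h not in network]
    if missing:
        raise ValueError(f"hubs not in network: {sorted(missing)[:5]}")
    UG = network.to_undirected(as_view=True)
    btw = nx.betweenness_centrality(UG)
    cut_points = set(nx.articulation_points(nx.Graph(UG)))
    hub_btw = np.array([btw[h] for h in hubs], dtype=float)
    thr = float(np.quantile(hub_btw, betweenness_quantile)) if len(hubs) else np.inf

    roles: dict[str, set[str]] = {}
    degrees: dict[str, int] = {}
    for h in hubs:
        degrees[h] = int(network.degree(h))
        tags: set[str] = set()
        in_d, out_d = _directed_degrees(network, h)
        if in_d == 0 and out_d > 0:
            tags.add("initiation")
        if out_d == 0 and in_d > 0:
            tags.add("termination")
        if (btw[h] > 0 and btw[h] >= thr) or h in cut_points:
            tags.add("critical")
        roles[h] = tags
    candidates = [h for h in hubs if roles[h]]
    return CandidateSet(contrast, degrees, roles, candidates)


def merge_candidates(
    set_a: CandidateSet | Iterable[str],
    set_b: CandidateSet | Iterable[str],
    mode: str = "union",
) -> list[str]:
    """Merge two contrasts' candidate gene lists.

    ``union`` deduplicates while preserving first-seen order (the
    convention that removes duplicates across the two severity groups);
    ``intersection`` keeps the common genes in the first list's order.
    """
    a = list(set_a.candidates) if isinstance(set_a, CandidateSet) else list(set_a)
    b = list(set_b.candidates) if isinstance(set_b, CandidateSet) else list(set_b)
    if mode == "union":
        return list(dict.fromkeys(a + b))
    if mode == "intersection":
        b_set = set(b)
        return [g for g in a if g in b_set]
    raise ValueError("mode must be 'union' or 'intersection'")
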