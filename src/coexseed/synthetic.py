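"""Synthetic multi-platform expression studies with planted structure.

The generator emulates the shape of a small multi-platform SMA
transcriptomics compendium: two or three "platforms" measuring the same
genes under monotone intensity distortions, two severity contrasts
(type I SMA vs control, and type I vs type III SMA), planted
co-expression modules whose shared latent factor shifts with disease
severity, duplicated probes and a fraction of unannotated probes.

Module model
------------
Each module m has a latent factor f_m ~ N(severity * effect_m, 1) drawn
per sample; a member gene is

    x = baseline + lambda_m * f_m + eps,   eps ~ N(0, noise_sd^2)

with the loading chosen as ``lambda = noise_sd * sqrt(rho / (1 - rho))``
so that the pairwise within-module correlation equals ``rho =
within_module_cor`` when the factor variance is 1. Severity is coded
1 for type I SMA samples and 0 for control / type III samples, which
fixes the sign convention of module-trait correlations.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import (
    GROUP_CONTROL,
    GROUP_SMA_I,
    GROUP_SMA_III,
    SEVERITY,
    CtTable,
    ExpressionDataset,
    GeneSetCollection,
)

__all__ = [
    "StudyConfig",
    "GroundTruth",
    "StudyBundle",
    "generate_multi_platform_study",
    "generate_gene_sets",
    "generate_interaction_network",
    "generate_qpcr_table",
    "generate_study_bundle",
]

# Strictly monotone per-platform intensity maps (no-ties preserving).
DISTORTIONS = {
    "identity": lambda x: x,
    "affine": lambda x: 0.8 * x + 2.0,
    "cubic": lambda x: 8.0 + 0.9 * (x - 8.0) + 0.02 * (x - 8.0) ** 3,
}

# Measurement noise added to an individual probe on top of its gene's
# profile; keeps duplicate probes distinct without masking the signal.
PROBE_NOISE_SD = 0.05


class ConfigurationError(ValueError):
    """Invalid synthetic-study configuration."""


@dataclass
class StudyConfig:
    """Parameters of a synthetic multi-platform study.

    ``samples_per_group`` is the number of samples for each group on each
    platform. Platforms ``0 .. n-2`` carry the SI/C contrast (type I SMA
    vs control); the last platform carries SI/SIII (type I vs type III),
    mirroring a compendium in which the severity contrast comes from a
    separate experiment. Override with ``platform_groups``.
    """

    n_platforms: int = 3
    samples_per_group: int = 10
    n_genes: int = 300
    module_sizes: Sequence[int] = (50, 40, 30)
    module_trait_effect: float | Sequence[float] = 1.0
    n_trait_modules: int = 2
    within_module_cor: float = 0.7
    noise_sd: float = 0.5
    platform_distortion: Sequence[str] = ("identity", "affine", "cubic")
    duplicate_probe_fraction: float = 0.1
    unannotated_fraction: float = 0.05
    platform_groups: Sequence[tuple[str, str]] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_platforms < 1:
            raise ConfigurationError("need at least one platform")
        if self.samples_per_group < 2:
            raise ConfigurationError("need >= 2 samples per group")
        if sum(self.module_sizes) > self.n_genes:
            raise ConfigurationError("sum(module_sizes) exceeds n_genes")
        if any(s < 1 for s in self.module_sizes):
            raise ConfigurationError("module sizes must be positive")
        if not (0.0 <= self.within_module_cor < 1.0):
            raise ConfigurationError("within_module_cor must be in [0, 1)")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be positive")
        for frac in (self.duplicate_probe_fraction, self.unannotated_fraction):
            if not (0.0 <= frac < 1.0):
                raise ConfigurationError("fractions must be in [0, 1)")
        unknown = set(self.platform_distortion) - set(DISTORTIONS)
        if unknown:
            raise ConfigurationError(f"unknown distortion ids: {sorted(unknown)}")

    @property
    def n_modules(self) -> int:
        return len(self.module_sizes)

    def effects(self) -> np.ndarray:
        """Per-module standardized trait shift."""
        if isinstance(self.module_trait_effect, (int, float)):
            eff = np.zeros(self.n_modules)
            eff[: self.n_trait_modules] = float(self.module_trait_effect)
            return eff
        eff = np.asarray(self.module_trait_effect, dtype=float)
        if eff.shape != (self.n_modules,):
            raise ConfigurationError("per-module effects must match n_modules")
        return eff

    def loading(self) -> float:
        rho = self.within_module_cor
        return self.noise_sd * math.sqrt(rho / (1.0 - rho)) if rho > 0 else 0.0

    def groups_for_platform(self, p: int) -> tuple[str, str]:
        if self.platform_groups is not None:
            return tuple(self.platform_groups[p])
        if self.n_platforms >= 2 and p == self.n_platforms - 1:
            return (GROUP_SMA_I, GROUP_SMA_III)
        return (GROUP_SMA_I, GROUP_CONTROL)


@dataclass
class GroundTruth:
    """What was planted: used as the oracle for recovery benchmarks."""

    module_of: pd.Series  # gene -> module (0 = background)
    trait_modules: list[int]
    annotated_genes: list[str]
    duplicated_genes: list[str]
    true_fold_changes: dict[str, float]  # linear FC per unit severity
    hubs: list[str] = field(default_factory=list)
    hub_roles: dict[str, str] = field(default_factory=dict)
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "module_of": {g: int(m) for g, m in self.module_of.items()},
            "trait_modules": [int(m) for m in self.trait_modules],
            "annotated_genes": list(self.annotated_genes),
            "duplicated_genes": list(self.duplicated_genes),
            "true_fold_changes": {g: float(v) for g, v in self.true_fold_changes.items()},
            "hubs": list(self.hubs),
            "hub_roles": dict(self.hub_roles),
            "seed": int(self.seed),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            module_of=pd.Series(d["module_of"], dtype=int),
            trait_modules=[int(m) for m in d["trait_modules"]],
            annotated_genes=list(d["annotated_genes"]),
            duplicated_genes=list(d["duplicated_genes"]),
            true_fold_changes={g: float(v) for g, v in d["true_fold_changes"].items()},
            hubs=list(d.get("hubs", [])),
            hub_roles=dict(d.get("hub_roles", {})),
            seed=int(d.get("seed", 0)),
        )


def _gene_ids(n: int) -> list[str]:
    return [f"G{i:04d}" for i in range(n)]


def generate_multi_platform_study(
    config: StudyConfig,
) -> tuple[list[ExpressionDataset], GroundTruth]:
    """Generate one expression dataset per platform plus the ground truth.

    Deterministic for a fixed config (including its seed).
    """
    rng = np.random.default_rng(config.seed)
    genes = _gene_ids(config.n_genes)

    module_labels = np.zeros(config.n_genes, dtype=int)
    start = 0
    for m, size in enumerate(config.module_sizes, start=1):
        module_labels[start : start + size] = m
        start += size

    baselines = rng.normal(8.0, 1.0, size=config.n_genes)
    lam = config.loading()
    effects = config.effects()

    n_dup = int(round(config.duplicate_probe_fraction * config.n_genes))
    dup_idx = np.sort(rng.choice(config.n_genes, size=n_dup, replace=False))
    n_unann = int(round(config.unannotated_fraction * config.n_genes))
    unann_idx = np.sort(rng.choice(config.n_genes, size=n_unann, replace=False))
    unann_set = set(unann_idx.tolist())

    # Probe layout shared across platforms: one primary probe per gene plus
    # a "_b" duplicate for the selected genes.
    probe_gene: list[int] = list(range(config.n_genes)) + dup_idx.tolist()
    probe_ids = [f"P{i:05d}" for i in range(config.n_genes)] + [
        f"P{i:05d}_b" for i in dup_idx
    ]

    annotation = pd.DataFrame(
        {
            "symbol": [genes[g] for g in probe_gene],
            "entrez": [
                (np.nan if g in unann_set else 10000 + g) for g in probe_gene
            ],
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )

    datasets: list[ExpressionDataset] = []
    for p in range(config.n_platforms):
        case, base = config.groups_for_platform(p)
        group_of_sample = [case] * config.samples_per_group + [
            base
        ] * config.samples_per_group
        n_samples = len(group_of_sample)
        dataset_id = f"SYN{p}"
        sample_ids = [f"{dataset_id}_s{i:02d}" for i in range(n_samples)]
        severity = np.array([SEVERITY[g] for g in group_of_sample], dtype=float)

        factors = rng.normal(size=(config.n_modules, n_samples))
        factors += effects[:, None] * severity[None, :]

        expr = baselines[:, None] + rng.normal(
            0.0, config.noise_sd, size=(config.n_genes, n_samples)
        )
        for m in range(1, config.n_modules + 1):
            member = module_labels == m
            expr[member, :] += lam * factors[m - 1][None, :]

        probe_values = expr[probe_gene, :] + rng.normal(
            0.0, PROBE_NOISE_SD, size=(len(probe_gene), n_samples)
        )
        distortion = DISTORTIONS[
            config.platform_distortion[p % len(config.platform_distortion)]
        ]
        probe_values = distortion(probe_values)

        values = pd.DataFrame(
            probe_values, index=pd.Index(probe_ids, name="probe_id"), columns=sample_ids
        )
        samples = pd.DataFrame(
            {"dataset_id": dataset_id, "group": group_of_sample},
            index=pd.Index(sample_ids, name="sample_id"),
        )
        datasets.append(
            ExpressionDataset(dataset_id, values, samples, annotation.copy())
        )

    true_fc = {}
    for i, g in enumerate(genes):
        m = module_labels[i]
        log2fc = lam * effects[m - 1] if m > 0 else 0.0
        true_fc[g] = float(2.0**log2fc)

    truth = GroundTruth(
        module_of=pd.Series(module_labels, index=genes),
        trait_modules=[m + 1 for m in range(config.n_modules) if effects[m] != 0],
        annotated_genes=[genes[i] for i in range(config.n_genes) if i not in unann_set],
        duplicated_genes=[genes[i] for i in dup_idx],
        true_fold_changes=true_fc,
        seed=config.seed,
    )
    return datasets, truth


def generate_gene_sets(
    n_terms: int,
    term_size_range: tuple[int, int],
    universe: Sequence[str],
    overlap_level: float = 0.0,
    seed: int = 0,
    coverage: float = 1.0,
    must_cover: Sequence[str] = (),
) -> GeneSetCollection:
    """Random ontology-like gene sets over ``universe``.

    ``coverage`` is the fraction of the universe that belongs to at least
    one term; ``overlap_level`` is the fraction of each term (after the
    first) drawn from genes already covered, so 0 yields pairwise-disjoint
    terms. Genes in ``must_cover`` are guaranteed to be annotated.
    """
    if not len(universe):
        raise ConfigurationError("universe is empty")
    lo, hi = term_size_range
    if hi > len(universe):
        raise ConfigurationError("term size exceeds universe size")
    if not (0.0 < coverage <= 1.0):
        raise ConfigurationError("coverage must be in (0, 1]")
    if not (0.0 <= overlap_level < 1.0):
        raise ConfigurationError("overlap_level must be in [0, 1)")
    rng = np.random.default_rng(seed)
    universe = list(universe)
    missing = set(must_cover) - set(universe)
    if missing:
        raise ConfigurationError(f"must_cover genes outside universe: {sorted(missing)}")

    pool_n = max(1, int(round(coverage * len(universe))))
    perm = [universe[i] for i in rng.permutation(len(universe))]
    pool = list(dict.fromkeys(list(must_cover) + perm))[:pool_n]

    uncovered = [pool[i] for i in rng.permutation(len(pool))]
    covered: list[str] = []
    terms: dict[str, frozenset[str]] = {}
    names: dict[str, str] = {}
    members_by_term: list[set[str]] = []
    for t in range(n_terms):
        size = int(rng.integers(lo, hi + 1))
        n_old = int(round(overlap_level * size)) if covered else 0
        n_old = min(n_old, len(covered))
        members: set[str] = set()
        if n_old:
            members |= {covered[i] for i in rng.choice(len(covered), n_old, replace=False)}
        take = min(size - len(members), len(uncovered))
        fresh = uncovered[:take]
        uncovered = uncovered[take:]
        members |= set(fresh)
        if len(members) < size and covered:
            # Pool exhausted: top up from already-covered genes.
            extra = [g for g in covered if g not in members]
            k = min(size - len(members), len(extra))
            if k:
                members |= {extra[i] for i in rng.choice(len(extra), k, replace=False)}
        if not members:
            raise ConfigurationError("cannot build a non-empty term; enlarge the pool")
        covered.extend(g for g in members if g not in covered)
        members_by_term.append(set(members))
    # Every pool gene must end up annotated: park leftovers in random terms.
    for g in uncovered:
        members_by_term[int(rng.integers(0, n_terms))].add(g)
    for t, members in enumerate(members_by_term):
        tid = f"T{t:03d}"
        terms[tid] = frozenset(members)
        names[tid] = f"synthetic process {t}"
    return GeneSetCollection(terms, names, source="synthetic")


def generate_interaction_network(
    n_nodes: int,
    planted_hub_degrees: Sequence[int],
    signed: bool = True,
    seed: int = 0,
    node_ids: Sequence[str] | None = None,
    hub_ids: Sequence[str] | None = None,
    hub_roles: Sequence[str] | None = None,
    background_out_degree: tuple[int, int] = (1, 2),
    leaves_per_hub: int = 2,
) -> tuple[nx.DiGraph, dict]:
    """Directed signed interaction network with planted high-degree hubs.

    Background nodes receive 1-2 random out-edges among themselves, so
    their total degree stays low; each planted hub receives exactly its
    stated degree. Every hub keeps ``leaves_per_hub`` degree-1 neighbours,
    making it an articulation point of the undirected skeleton (a
    "critical connection" by construction). ``hub_roles`` entries in
    {"initiation", "termination", "any"} constrain edge directions at the
    hub (a pure source / pure sink / mixed).
    """
    nodes = list(node_ids) if node_ids is not None else _gene_ids(n_nodes)
    if len(nodes) != n_nodes:
        raise ConfigurationError("node_ids length must equal n_nodes")
    if any(d >= n_nodes for d in planted_hub_degrees):
        raise ConfigurationError("hub degree must be below n_nodes")
    rng = np.random.default_rng(seed)
    n_hubs = len(planted_hub_degrees)
    if hub_ids is None:
        hubs = [nodes[i] for i in rng.choice(n_nodes, n_hubs, replace=False)]
    else:
        hubs = list(hub_ids)
        if len(hubs) != n_hubs:
            raise ConfigurationError("hub_ids length must match planted_hub_degrees")
    roles = list(hub_roles) if hub_roles is not None else ["any"] * n_hubs

    hub_set = set(hubs)
    non_hub = [v for v in nodes if v not in hub_set]
    n_leaves = min(leaves_per_hub * n_hubs, max(0, len(non_hub) - n_hubs))
    leaf_pool = [non_hub[i] for i in rng.choice(len(non_hub), n_leaves, replace=False)]
    leaf_set = set(leaf_pool)
    background = [v for v in non_hub if v not in leaf_set]

    def _sign() -> str:
        if not signed:
            return "activation"
        return "activation" if rng.random() < 0.7 else "inhibition"

    G = nx.DiGraph()
    G.add_nodes_from(nodes)
    lo, hi = background_out_degree
    for v in background:
        k_out = int(rng.integers(lo, hi + 1))
        for _ in range(k_out):
            w = background[int(rng.integers(0, len(background)))]
            if w == v or G.has_edge(v, w) or G.has_edge(w, v):
                continue
            G.add_edge(v, w, sign=_sign())

    leaf_iter = iter(leaf_pool)
    for hub, degree, role in zip(hubs, planted_hub_degrees, roles):
        for _ in range(leaves_per_hub):
            leaf = next(leaf_iter, None)
            if leaf is None:
                break
            if role == "termination":
                G.add_edge(leaf, hub, sign=_sign())
            else:
                G.add_edge(hub, leaf, sign=_sign())
        attempts = 0
        while G.degree(hub) < degree and attempts < 50 * degree:
            attempts += 1
            w = background[int(rng.integers(0, len(background)))]
            if w == hub or G.has_edge(hub, w) or G.has_edge(w, hub):
                continue
            if role == "initiation":
                G.add_edge(hub, w, sign=_sign())
            elif role == "termination":
                G.add_edge(w, hub, sign=_sign())
            elif rng.random() < 0.5:
                G.add_edge(hub, w, sign=_sign())
            else:
                G.add_edge(w, hub, sign=_sign())
        if G.degree(hub) != degree:
            raise ConfigurationError(
                f"could not realize degree {degree} for hub {hub}"
            )

    truth = {"hubs": hubs, "roles": dict(zip(hubs, roles)), "seed": int(seed)}
    return G, truth


def generate_qpcr_table(
    genes: Sequence[str],
    true_fold_changes: dict[str, float],
    n_replicates: int = 4,
    ct_noise_sd: float = 0.15,
    seed: int = 0,
    reference_gene: str = "Gapdh",
) -> CtTable:
    """Ct table whose noise-free comparative-Ct fold change equals the truth.

    One SMA and one control cohort of ``n_replicates`` animals each. The
    per-gene baseline dCt (target minus reference) is drawn once; SMA
    animals' target Ct is lowered by log2(FC). Gaussian noise with sd
    ``ct_noise_sd`` is added to each individual Ct measurement.
    """
    if n_replicates < 2:
        raise ConfigurationError("need >= 2 replicates per group (SD undefined)")
    for g in genes:
        if true_fold_changes.get(g, 1.0) <= 0:
            raise ConfigurationError(f"fold change for {g} must be positive")
    rng = np.random.default_rng(seed)
    base_dct = {g: float(rng.uniform(3.0, 8.0)) for g in genes}
    rows = []
    for group, prefix, is_sma in (("control", "C", 0), ("SMA", "S", 1)):
        for i in range(n_replicates):
            animal = f"{prefix}{i + 1}"
            ref_ct = 18.0 + rng.normal(0.0, ct_noise_sd)
            rows.append((animal, group, reference_gene, ref_ct))
            for g in genes:
                fc = true_fold_changes.get(g, 1.0)
                ct = (
                    ref_ct
                    + base_dct[g]
                    - is_sma * math.log2(fc)
                    + rng.normal(0.0, ct_noise_sd)
                )
                rows.append((animal, group, g, ct))
    data = pd.DataFrame(rows, columns=["animal_id", "group", "gene", "ct"])
    return CtTable(data, reference_gene)


@dataclass
class StudyBundle:
    """Everything the pipeline consumes, plus the planted truth."""

    datasets: list[ExpressionDataset]
    gene_sets: GeneSetCollection
    network: nx.DiGraph
    ct_table: CtTable
    truth: GroundTruth


def generate_study_bundle(
    config: StudyConfig | None = None,
    n_hubs: int = 6,
    hub_degree: int = 30,
    n_terms: int = 25,
    term_size_range: tuple[int, int] = (10, 30),
    coverage: float = 0.85,
    ct_noise_sd: float = 0.12,
    seed: int | None = None,
) -> StudyBundle:
    """Full synthetic study: expression, gene sets, interactome, Ct table.

    Planted target genes (the benchmark's "candidate SMA targets") are
    drawn from the trait-associated modules and wired as high-degree hubs
    of the interaction network, with roles cycling through initiation /
    termination / mixed; all trait-module genes are guaranteed ontology
    annotations so the annotation filter exercises counting rather than
    deleting the planted signal.
    """
    if config is None:
        config = StudyConfig(
            samples_per_group=25,
            n_genes=400,
            module_sizes=(40, 40, 40),
            module_trait_effect=(2.0, -2.0, 0.0),
            within_module_cor=0.8,
            noise_sd=0.5,
            seed=0 if seed is None else seed,
        )
    if seed is not None and seed != config.seed:
        from dataclasses import replace

        config = replace(config, seed=seed)
    datasets, truth = generate_multi_platform_study(config)

    trait_genes = [
        g
        for g in truth.module_of.index
        if truth.module_of[g] in truth.trait_modules and g in truth.annotated_genes
    ]
    rng = np.random.default_rng(config.seed + 1)
    per_module: dict[int, list[str]] = {}
    for g in trait_genes:
        per_module.setdefault(int(truth.module_of[g]), []).append(g)
    hubs: list[str] = []
    mods = sorted(per_module)
    i = 0
    while len(hubs) < n_hubs and mods:
        m = mods[i % len(mods)]
        pool = [g for g in per_module[m] if g not in hubs]
        if pool:
            hubs.append(pool[int(rng.integers(0, len(pool)))])
        i += 1
    roles = [("initiation", "termination", "any")[k % 3] for k in range(len(hubs))]

    genes = list(truth.module_of.index)
    network, net_truth = generate_interaction_network(
        n_nodes=len(genes),
        planted_hub_degrees=[hub_degree] * len(hubs),
        signed=True,
        seed=config.seed + 2,
        node_ids=genes,
        hub_ids=hubs,
        hub_roles=roles,
    )
    truth.hubs = hubs
    truth.hub_roles = net_truth["roles"]

    gene_sets = generate_gene_sets(
        n_terms=n_terms,
        term_size_range=term_size_range,
        universe=truth.annotated_genes,
        overlap_level=0.2,
        seed=config.seed + 3,
        coverage=coverage,
        must_cover=trait_genes,
    )

    ct_table = generate_qpcr_table(
        genes=hubs,
        true_fold_changes=truth.true_fold_changes,
        n_replicates=4,
        ct_noise_sd=ct_noise_sd,
        seed=config.seed + 4,
    )
    return StudyBundle(datasets, gene_sets, network, ct_table, truth)
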