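"""End-to-end orchestration: preprocess -> network -> modules ->
meta-membership -> ontology filter -> seed network -> candidates ->
merge -> (optional) qPCR classification.

The two severity contrasts (type I SMA vs control, and type I vs
type III SMA) are analyzed independently and merged only at the
candidate level. Every numeric default matches the printed analysis
parameters: soft-threshold power 6, +/-1.2 fold change, MM thresholds
R > 0.2 and P < 1e-13, ClueGO-style kappa 0.4 and 4% term restriction,
ORA q < 0.05.
"""
from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

from . import io as cio
from .datatypes import (
    SEVERITY,
    SI_C,
    SI_SIII,
    CandidateSet,
    Contrast,
    CtTable,
    ExpressionDataset,
    GeneSetCollection,
)
from .membership import (
    assign_final_modules,
    meta_membership,
    module_eigengene,
    module_membership,
    module_trait_correlation,
)
from .network import cluster_genes, dynamic_tree_cut, soft_adjacency, topological_overlap
from .ontology import annotation_filter, build_term_network, enrich_collection
from .preprocess import (
    collapse_probes,
    filter_unannotated,
    fold_change_filter,
    median_rank_transform,
    quantile_normalize,
)
from .qpcr import classify_regulation, ddct_fold_change, regulation_table
from .seednet import classify_candidates, expand_from_seeds, merge_candidates, rank_hubs

logger = logging.getLogger("coexseed")

__all__ = ["PipelineConfig", "PipelineError", "PipelineResult", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name for context."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """All tunable parameters of a run, with the published defaults."""

    beta: float = 6.0
    fc_threshold: float | None = 1.2
    retain_all_contrasts: tuple[str, ...] = ("SI/SIII",)
    mrs_reference: str | None = None
    min_module_size: int = 20
    cut_height: float | None = None  # None -> adaptive largest-gap cut
    mm_top_n: int = 5
    mm_mode: str = "top_kin"
    r_min: float = 0.2
    p_max: float = 1e-13
    trait_r_min: float = 0.2
    kappa_min: float = 0.4
    gene_fraction_min: float = 0.04
    ora_p_max: float = 0.05
    ora_q_max: float = 0.05
    hub_k: int = 10
    radius: int = 1
    betweenness_quantile: float = 0.9
    merge_mode: str = "union"
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["retain_all_contrasts"] = list(d["retain_all_contrasts"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "retain_all_contrasts" in d:
            d["retain_all_contrasts"] = tuple(d["retain_all_contrasts"])
        return cls(**d)


@dataclass
class ContrastResult:
    contrast: str
    deg_genes: list[str]
    initial_assignment: object | None = None
    meta: pd.DataFrame | None = None
    final_assignment: object | None = None
    trait_stats: pd.DataFrame | None = None
    module_genes: list[str] = field(default_factory=list)
    filtered_genes: list[str] = field(default_factory=list)
    enrichment: pd.DataFrame | None = None
    term_network: nx.Graph | None = None
    expanded: nx.DiGraph | None = None
    hubs: list[tuple[str, int]] = field(default_factory=list)
    candidates: CandidateSet | None = None
    counts: dict = field(default_factory=dict)


@dataclass
class PipelineResult:
    manifest: dict
    contrasts: dict[str, ContrastResult]
    merged_candidates: list[str]
    regulation: pd.DataFrame | None = None
    fold_changes: pd.DataFrame | None = None


def _contrast_of(dataset: ExpressionDataset) -> Contrast | None:
    groups = set(dataset.groups.unique())
    for contrast in (SI_C, SI_SIII):
        if groups == {contrast.case, contrast.baseline}:
            return contrast
    return None


def _run_contrast(
    contrast: Contrast,
    datasets: list[ExpressionDataset],
    gene_sets: GeneSetCollection,
    interaction: nx.DiGraph,
    config: PipelineConfig,
) -> ContrastResult:
    res = ContrastResult(contrast=contrast.name, deg_genes=[])
    counts = res.counts

    try:
        collapsed = [
            collapse_probes(
                filter_unannotated(
                    ExpressionDataset(
                        d.dataset_id, quantile_normalize(d.values), d.samples, d.annotation
                    )
                )
            )
            for d in datasets
        ]
    except ValueError as e:
        raise PipelineError("preprocess", str(e)) from e

    if len(collapsed) > 1:
        merged = median_rank_transform(collapsed, reference_id=config.mrs_reference)
    else:
        merged = collapsed[0]
    counts["samples"] = merged.n_samples
    counts["genes"] = merged.values.shape[0]

    retain_all = contrast.name in config.retain_all_contrasts
    try:
        deg = fold_change_filter(
            merged, contrast, threshold=config.fc_threshold, retain_all=retain_all
        )
    except ValueError as e:
        raise PipelineError("deg", str(e)) from e
    res.deg_genes = deg.genes
    counts["degs"] = len(deg)
    if len(deg) < 3:
        logger.warning("%s: %d DEGs; stopping at the DEG stage", contrast.name, len(deg))
        return res

    expr = merged.values.loc[deg.genes]
    try:
        adjacency = soft_adjacency(expr, beta=config.beta)
    except ValueError as e:
        raise PipelineError("network", str(e)) from e
    tom = topological_overlap(adjacency)
    dendro = cluster_genes(tom)
    initial = dynamic_tree_cut(
        dendro, min_module_size=config.min_module_size, cut_height=config.cut_height
    )
    res.initial_assignment = initial
    counts["initial_modules"] = len(initial.modules)
    if not initial.modules:
        logger.warning("%s: no module survived the tree cut", contrast.name)
        return res

    tables = []
    for d in collapsed:
        sub = d.values.loc[d.values.index.intersection(deg.genes)]
        mm = module_membership(
            sub, initial, adjacency, top_n=config.mm_top_n, mode=config.mm_mode
        )
        tables.append((mm, d.n_samples))
    meta = meta_membership(tables)
    res.meta = meta
    final = assign_final_modules(meta, r_min=config.r_min, p_max=config.p_max)
    res.final_assignment = final
    counts["assigned_genes"] = int((final.labels > 0).sum())

    try:
        eigengenes = module_eigengene(expr, final)
    except ValueError as e:
        raise PipelineError("eigengene", str(e)) from e
    if eigengenes.shape[1] == 0:
        logger.warning("%s: no module passed the meta thresholds", contrast.name)
        return res
    trait = merged.groups.map(SEVERITY).astype(float)
    trait_stats = module_trait_correlation(eigengenes, trait, r_min=config.trait_r_min)
    res.trait_stats = trait_stats
    selected = set(trait_stats.loc[trait_stats["selected"], "module"])
    counts["selected_modules"] = len(selected)

    module_genes = [
        g for g in final.labels.index if final.labels[g] in selected and final.labels[g] > 0
    ]
    res.module_genes = module_genes
    counts["module_genes"] = len(module_genes)
    if not module_genes:
        return res

    filtered = annotation_filter(module_genes, gene_sets)
    res.filtered_genes = filtered
    counts["ontology_filtered_genes"] = len(filtered)
    universe = list(merged.values.index)
    if filtered:
        res.enrichment = enrich_collection(filtered, gene_sets, universe)
        res.term_network = build_term_network(
            res.enrichment,
            gene_sets,
            filtered,
            universe,
            kappa_min=config.kappa_min,
            gene_fraction_min=config.gene_fraction_min,
            p_max=config.ora_p_max,
        )
        counts["enriched_terms"] = int(res.term_network.number_of_nodes())
    else:
        return res

    try:
        expanded = expand_from_seeds(interaction, filtered, radius=config.radius)
    except ValueError as e:
        raise PipelineError("seed_network", str(e)) from e
    res.expanded = expanded
    counts["expanded_network_genes"] = expanded.number_of_nodes()
    hubs = rank_hubs(expanded, config.hub_k)
    res.hubs = hubs
    counts["hubs"] = len(hubs)
    res.candidates = classify_candidates(
        expanded,
        [h for h, _ in hubs],
        betweenness_quantile=config.betweenness_quantile,
        contrast=contrast.name,
    )
    counts["candidates"] = len(res.candidates.candidates)
    return res


def run_pipeline(
    datasets: list[ExpressionDataset],
    gene_sets: GeneSetCollection,
    interaction: nx.DiGraph,
    config: PipelineConfig | None = None,
    ct_table: CtTable | None = None,
    out_dir: Path | None = None,
) -> PipelineResult:
    """Run the full target-discovery flow and return results + manifest.

    Datasets are routed to the contrast their sample groups define; each
    contrast with at least one dataset is analyzed independently, and the
    candidate lists are merged at the end. When a Ct table is supplied,
    the merged candidates are classified by the comparative-Ct method.
    Identical inputs, config and seed give an identical manifest (up to
    the timestamp).
    """
    config = config or PipelineConfig()
    by_contrast: dict[str, list[ExpressionDataset]] = {}
    for d in datasets:
        c = _contrast_of(d)
        if c is None:
            logger.warning("dataset %s matches no contrast; skipped", d.dataset_id)
            continue
        by_contrast.setdefault(c.name, []).append(d)
    if not by_contrast:
        raise PipelineError("input", "no dataset matches a known contrast")

    results: dict[str, ContrastResult] = {}
    for contrast in (SI_C, SI_SIII):
        if contrast.name in by_contrast:
            logger.info("running contrast %s", contrast.name)
            results[contrast.name] = _run_contrast(
                contrast, by_contrast[contrast.name], gene_sets, interaction, config
            )

    candidate_sets = [
        r.candidates for r in results.values() if r.candidates is not None
    ]
    if len(candidate_sets) >= 2:
        merged = merge_candidates(candidate_sets[0], candidate_sets[1], config.merge_mode)
    elif len(candidate_sets) == 1:
        merged = list(candidate_sets[0].candidates)
    else:
        merged = []

    regulation = None
    fold_changes = None
    if ct_table is not None and merged:
        calls = {}
        rows = []
        for g in merged:
            if g not in ct_table.genes():
                continue
            fc = ddct_fold_change(ct_table, g)
            calls[g] = classify_regulation(fc.mean_fc, fc.p_value, gene=g)
            rows.append(
                {"gene": g, "mean_fc": fc.mean_fc, "sd_fc": fc.sd_fc, "p": fc.p_value}
            )
        if rows:
            fold_changes = pd.DataFrame(rows).set_index("gene")
            regulation = regulation_table({"validation": calls})

    manifest = {
        "seed": config.seed,
        "parameters": config.to_dict(),
        "contrasts": {name: dict(r.counts) for name, r in results.items()},
        "merged_targets": merged,
        "n_merged_targets": len(merged),
        "created": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    result = PipelineResult(manifest, results, merged, regulation, fold_changes)
    if out_dir is not None:
        _write_artifacts(result, Path(out_dir))
    return result


def _write_artifacts(result: PipelineResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=1, sort_keys=True)
    for name, r in result.contrasts.items():
        tag = name.replace("/", "_")
        if r.final_assignment is not None:
            cio.write_module_assignment(
                r.final_assignment, out_dir / f"modules_{tag}.tsv"
            )
        if r.meta is not None:
            r.meta.to_csv(out_dir / f"meta_membership_{tag}.tsv", sep="\t")
        if r.enrichment is not None:
            r.enrichment.to_csv(out_dir / f"enrichment_{tag}.tsv", sep="\t", index=False)
        if r.candidates is not None:
            with open(out_dir / f"candidates_{tag}.json", "w") as fh:
                json.dump(
                    {
                        "contrast": r.candidates.contrast,
                        "hubs": r.candidates.hub_degrees,
                        "roles": {k: sorted(v) for k, v in r.candidates.roles.items()},
                        "candidates": r.candidates.candidates,
                    },
                    fh,
                    indent=1,
                )
    if result.regulation is not None:
        result.regulation.to_csv(out_dir / "regulation.tsv", sep="\t")
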