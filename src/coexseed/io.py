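"""Plain-text readers and writers for the pipeline's file dialects.

Expression matrices and sample metadata are tab-separated; gene sets use
GMT; interaction networks use a SIF-like three-column TSV (source,
interaction, target) with interactions ``activates`` / ``inhibits`` /
``co-expressed``; Ct tables are CSV. The ground-truth sidecar of a
synthetic study is JSON.
"""
from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import pandas as pd

from .datatypes import CtTable, DegList, ExpressionDataset, ModuleAssignment
from .synthetic import GroundTruth

SIF_TO_SIGN = {
    "activates": "activation",
    "inhibits": "inhibition",
    "co-expressed": "co-expression",
}
SIGN_TO_SIF = {v: k for k, v in SIF_TO_SIGN.items()}


def write_expression(dataset: ExpressionDataset, directory: Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    dataset.values.to_csv(directory / f"expr_{dataset.dataset_id}.tsv", sep="\t")
    if dataset.annotation is not None:
        dataset.annotation.to_csv(directory / f"annotation_{dataset.dataset_id}.tsv", sep="\t")


def save_study(
    datasets: list[ExpressionDataset], truth: GroundTruth | None, directory: Path
) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for d in datasets:
        write_expression(d, directory)
    samples = pd.concat([d.samples for d in datasets], axis=0)
    samples.to_csv(directory / "samples.tsv", sep="\t")
    if truth is not None:
        with open(directory / "truth.json", "w") as fh:
            json.dump(truth.to_dict(), fh, indent=1, sort_keys=True)


def load_study(directory: Path) -> tuple[list[ExpressionDataset], GroundTruth | None]:
    directory = Path(directory)
    samples = pd.read_csv(directory / "samples.tsv", sep="\t", index_col=0)
    datasets = []
    for path in sorted(directory.glob("expr_*.tsv")):
        dataset_id = path.stem[len("expr_") :]
        values = pd.read_csv(path, sep="\t", index_col=0)
        ann_path = directory / f"annotation_{dataset_id}.tsv"
        annotation = (
            pd.read_csv(ann_path, sep="\t", index_col=0) if ann_path.exists() else None
        )
        meta = samples[samples["dataset_id"] == dataset_id].loc[values.columns]
        datasets.append(ExpressionDataset(dataset_id, values, meta, annotation))
    truth = None
    truth_path = directory / "truth.json"
    if truth_path.exists():
        with open(truth_path) as fh:
            truth = GroundTruth.from_dict(json.load(fh))
    return datasets, truth


def write_deg_list(deg: DegList, path: Path) -> None:
    pd.DataFrame(
        {"gene": deg.genes, "fold_change": deg.fold_changes.loc[deg.genes].to_numpy()}
    ).to_csv(path, sep="\t", index=False)


def read_deg_list(path: Path) -> DegList:
    df = pd.read_csv(path, sep="\t")
    fc = pd.Series(df["fold_change"].to_numpy(), index=df["gene"])
    return DegList(genes=list(df["gene"]), fold_changes=fc, threshold=None)


def write_module_assignment(assignment: ModuleAssignment, path: Path) -> None:
    out = assignment.labels.rename("module").rename_axis("gene").reset_index()
    out.to_csv(path, sep="\t", index=False)


def read_module_assignment(path: Path, method: str = "tree_cut") -> ModuleAssignment:
    df = pd.read_csv(path, sep="\t")
    labels = pd.Series(df["module"].to_numpy(dtype=int), index=df["gene"])
    return ModuleAssignment(labels, method=method)


def write_sif(network: nx.DiGraph, path: Path) -> None:
    rows = [
        (u, SIGN_TO_SIF.get(data.get("sign", "activation"), "activates"), v)
        for u, v, data in network.edges(data=True)
    ]
    pd.DataFrame(rows, columns=["source", "interaction", "target"]).to_csv(
        path, sep="\t", index=False
    )


def read_sif(path: Path) -> nx.DiGraph:
    df = pd.read_csv(path, sep="\t")
    G = nx.DiGraph()
    for source, interaction, target in df.itertuples(index=False):
        sign = SIF_TO_SIGN.get(interaction)
        if sign is None:
            raise ValueError(f"unknown interaction type {interaction!r}")
        if source == target:
            continue
        G.add_edge(source, target, sign=sign)
    return G


def write_ct_table(ct: CtTable, path: Path) -> None:
    ct.data.to_csv(path, index=False)


def read_ct_table(path: Path, reference_gene: str = "Gapdh") -> CtTable:
    return CtTable(pd.read_csv(path), reference_gene)
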