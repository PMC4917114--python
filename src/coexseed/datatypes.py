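"""Core containers shared across the pipeline.

All expression values are assumed to be on the log2 scale (the standard
post-summarization convention for microarray intensities). Fold changes
are reported on the linear scale.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

# Group labels used throughout. Severity coding for trait correlations:
# type I SMA (most severe) = 1, type III SMA and control = 0.
GROUP_SMA_I = "SMA_I"
GROUP_SMA_III = "SMA_III"
GROUP_CONTROL = "control"

SEVERITY = {GROUP_SMA_I: 1, GROUP_SMA_III: 0, GROUP_CONTROL: 0}


@dataclass(frozen=True)
class Contrast:
    """A two-group comparison (case vs baseline)."""

    name: str
    case: str
    baseline: str

    def __post_init__(self) -> None:
        if self.case == self.baseline:
            raise ValueError("contrast case and baseline must differ")


#: Type I SMA vs control.
SI_C = Contrast("SI/C", GROUP_SMA_I, GROUP_CONTROL)
#: Type I SMA vs type III SMA (severity contrast).
SI_SIII = Contrast("SI/SIII", GROUP_SMA_I, GROUP_SMA_III)


@dataclass
class ExpressionDataset:
    """One platform's probe-by-sample (or gene-by-sample) expression matrix.

    Parameters
    ----------
    dataset_id : str
        Platform / accession identifier.
    values : DataFrame
        Rows are probes (or genes after collapsing), columns are samples,
        log2 scale.
    samples : DataFrame
        Indexed by sample id, with at least ``dataset_id`` and ``group``
        columns; ``group`` is one of ``SMA_I``, ``SMA_III``, ``control``.
    annotation : DataFrame or None
        Indexed by probe id, columns ``symbol`` and ``entrez`` (either may
        be missing for a probe). ``None`` after probes have been collapsed
        to gene symbols.
    """

    dataset_id: str
    values: pd.DataFrame
    samples: pd.DataFrame
    annotation: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.values.columns.duplicated().any():
            raise ValueError(f"{self.dataset_id}: duplicate sample ids")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError(f"{self.dataset_id}: non-finite expression values")
        if list(self.values.columns) != list(self.samples.index):
            missing = set(self.values.columns) ^ set(self.samples.index)
            raise ValueError(
                f"{self.dataset_id}: sample metadata does not match matrix "
                f"columns (mismatch: {sorted(missing)[:5]})"
            )
        if self.annotation is not None:
            extra = self.annotation.index.difference(self.values.index)
            if len(extra):
                raise ValueError(
                    f"{self.dataset_id}: annotation refers to unknown probes "
                    f"{list(extra[:5])}"
                )

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def groups(self) -> pd.Series:
        return self.samples["group"]

    def subset_rows(self, ids: Iterable[str]) -> "ExpressionDataset":
        ids = list(ids)
        ann = None
        if self.annotation is not None:
            ann = self.annotation.loc[self.annotation.index.intersection(ids)]
        return ExpressionDataset(
            self.dataset_id, self.values.loc[ids], self.samples.copy(), ann
        )


@dataclass
class DegList:
    """Differentially expressed genes selected by linear fold change."""

    genes: list[str]
    fold_changes: pd.Series  # linear scale, indexed by gene
    threshold: float | None  # None when all genes were retained

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class ModuleAssignment:
    """gene -> module label; 0 means unassigned."""

    labels: pd.Series  # int labels indexed by gene
    method: str = "tree_cut"  # "tree_cut" or "meta"

    def __post_init__(self) -> None:
        self.labels = self.labels.astype(int)

    def module_genes(self, module: int) -> list[str]:
        return list(self.labels.index[self.labels == module])

    @property
    def modules(self) -> list[int]:
        return sorted(int(m) for m in self.labels.unique() if m > 0)

    def sizes(self) -> dict[int, int]:
        return {m: int((self.labels == m).sum()) for m in self.modules}


@dataclass
class GeneSetCollection:
    """Named gene sets (ontology terms), GMT-serializable."""

    terms: dict[str, frozenset[str]]
    names: dict[str, str] = field(default_factory=dict)
    source: str = "synthetic"

    def __post_init__(self) -> None:
        for tid, members in self.terms.items():
            if not members:
                raise ValueError(f"term {tid!r} has no members")

    def covered_genes(self) -> set[str]:
        out: set[str] = set()
        for members in self.terms.values():
            out |= members
        return out

    def to_gmt(self, path) -> None:
        with open(path, "w") as fh:
            for tid, members in self.terms.items():
                desc = self.names.get(tid, self.source)
                fh.write("\t".join([tid, desc, *sorted(members)]) + "\n")

    @classmethod
    def from_gmt(cls, path, source: str = "gmt") -> "GeneSetCollection":
        terms: dict[str, frozenset[str]] = {}
        names: dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                fields = line.split("\t")
                if len(fields) < 3:
                    raise ValueError(f"malformed GMT line: {line[:60]!r}")
                tid, desc, *members = fields
                terms[tid] = frozenset(m for m in members if m)
                names[tid] = desc
        return cls(terms, names, source)


@dataclass
class CandidateSet:
    """Hub genes of one contrast's expanded network, with role tags."""

    contrast: str
    hub_degrees: dict[str, int]  # insertion order = rank order
    roles: dict[str, set[str]]  # hub -> subset of {initiation, critical, termination}
    candidates: list[str]  # hubs holding >= 1 role, in rank order

    def __post_init__(self) -> None:
        unknown = [g for g in self.candidates if g not in self.hub_degrees]
        if unknown:
            raise ValueError(f"candidates not among hubs: {unknown}")


@dataclass
class CtTable:
    """qPCR threshold-cycle table.

    ``data`` has columns ``animal_id``, ``group`` (``SMA`` / ``control``),
    ``gene`` and ``ct``; every animal must have a Ct for the reference
    (housekeeping) gene.
    """

    data: pd.DataFrame
    reference_gene: str = "Gapdh"

    def __post_init__(self) -> None:
        required = {"animal_id", "group", "gene", "ct"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"Ct table missing columns: {sorted(missing)}")
        if not np.isfinite(self.data["ct"].to_numpy(dtype=float)).all():
            raise ValueError("non-finite Ct values")
        has_ref = set(self.data.loc[self.data["gene"] == self.reference_gene, "animal_id"])
        without = sorted(set(self.data["animal_id"]) - has_ref)
        if without:
            raise ValueError(
                f"animals lack a {self.reference_gene} reference Ct: {without}"
            )

    def genes(self) -> list[str]:
        out = [g for g in self.data["gene"].unique() if g != self.reference_gene]
        return list(out)


@dataclass
class FoldChangeResult:
    """Comparative-Ct relative expression of one gene (case vs control)."""

    gene: str
    per_animal_fc: np.ndarray  # per case animal
    mean_fc: float
    sd_fc: float
    p_value: float
    n_case: int
    n_control: int


REGULATION_CODES = ("up_sig", "up_trend", "down_sig", "down_trend", "unchanged")

SYMBOLS = {
    "up_sig": "↑*",
    "up_trend": "↑",
    "down_sig": "↓*",
    "down_trend": "↓",
    "unchanged": "Ο",
}
ASCII_SYMBOLS = {
    "up_sig": "+*",
    "up_trend": "+",
    "down_sig": "-*",
    "down_trend": "-",
    "unchanged": "O",
}


@dataclass(frozen=True)
class RegulationCall:
    """Direction/significance call for one gene in one condition."""

    gene: str
    code: str

    def __post_init__(self) -> None:
        if self.code not in REGULATION_CODES:
            raise ValueError(f"unknown regulation code {self.code!r}")

    @property
    def symbol(self) -> str:
        return SYMBOLS[self.code]

    @property
    def ascii_symbol(self) -> str:
        return ASCII_SYMBOLS[self.code]
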