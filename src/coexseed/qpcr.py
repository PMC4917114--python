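"""Comparative-Ct (ddCt) relative quantification and regulation calls.

Relative expression of a target gene against a housekeeping reference
(GAPDH role) is computed by the comparative Ct method: per animal
dCt = Ct(target) - Ct(reference); per case animal
FC = 2^-(dCt - mean control dCt); group difference tested with Welch's
two-sided t-test on the dCt values. Calls follow the usual convention:
p < 0.05 significant arrow, 0.05 <= p < 0.1 trend arrow, p >= 0.1
unchanged; at the boundaries, p = 0.05 counts as a trend and p = 0.1 as
unchanged.
"""
from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ASCII_SYMBOLS, SYMBOLS, CtTable, FoldChangeResult, RegulationCall

__all__ = ["ddct_fold_change", "classify_regulation", "regulation_table"]


def _delta_ct(ct: CtTable, gene: str) -> pd.DataFrame:
    data = ct.data
    ref = data[data["gene"] == ct.reference_gene].set_index("animal_id")["ct"]
    tgt = data[data["gene"] == gene]
    if tgt.empty:
        raise ValueError(f"gene {gene!r} absent from the Ct table")
    tgt = tgt.set_index("animal_id")
    missing = tgt.index.difference(ref.index)
    if len(missing):
        raise ValueError(
            f"animal(s) lack a {ct.reference_gene} Ct: {sorted(missing)}"
        )
    out = pd.DataFrame(
        {"group": tgt["group"], "dct": tgt["ct"] - ref.loc[tgt.index]}
    )
    return out


def ddct_fold_change(
    ct: CtTable, gene: str, case_group: str = "SMA", control_group: str = "control"
) -> FoldChangeResult:
    """Fold change of ``gene`` in the case group relative to controls."""
    d = _delta_ct(ct, gene)
    case = d.loc[d["group"] == case_group, "dct"].to_numpy(dtype=float)
    ctrl = d.loc[d["group"] == control_group, "dct"].to_numpy(dtype=float)
    if len(case) < 2 or len(ctrl) < 2:
        raise ValueError(
            f"{gene}: need >= 2 animals per group (case {len(case)}, control {len(ctrl)})"
        )
    fc = np.power(2.0, -(case - ctrl.mean()))
    if case.std() == 0 and ctrl.std() == 0:
        # Degenerate noise-free data: the t statistic is undefined, so fall
        # back to exact equality of the group means.
        p = 1.0 if np.isclose(case.mean(), ctrl.mean()) else 0.0
    else:
        p = float(stats.ttest_ind(case, ctrl, equal_var=False).pvalue)
    return FoldChangeResult(
        gene=gene,
        per_animal_fc=fc,
        mean_fc=float(fc.mean()),
        sd_fc=float(fc.std(ddof=1)),
        p_value=p,
        n_case=len(case),
        n_control=len(ctrl),
    )


def classify_regulation(fc_mean: float, p: float, gene: str = "") -> RegulationCall:
    """Map a (fold change, p) pair to a regulation call.

    Total over its domain: exactly one call per input. A fold change of
    exactly 1 is reported unchanged regardless of p.
    """
    if fc_mean <= 0:
        raise ValueError("fold change must be positive")
    if not (0.0 <= p <= 1.0):
        raise ValueError("p must lie in [0, 1]")
    if p >= 0.1 or fc_mean == 1.0:
        return RegulationCall(gene, "unchanged")
    up = fc_mean > 1.0
    if p < 0.05:
        return RegulationCall(gene, "up_sig" if up else "down_sig")
    return RegulationCall(gene, "up_trend" if up else "down_trend")


def regulation_table(
    calls: Mapping[str, Mapping[str, RegulationCall]], ascii_symbols: bool = False
) -> pd.DataFrame:
    """Genes x conditions grid of regulation symbols.

    ``calls`` maps condition name -> gene -> call. Row order follows the
    first appearance of each gene across conditions.
    """
    genes: list[str] = []
    for per_gene in calls.values():
        for g in per_gene:
            if g not in genes:
                genes.append(g)
    table = SYMBOLS if not ascii_symbols else ASCII_SYMBOLS
    out = pd.DataFrame(index=pd.Index(genes, name="gene"), columns=list(calls.keys()), dtype=object)
    for cond, per_gene in calls.items():
        for g, call in per_gene.items():
            out.loc[g, cond] = table[call.code]
    return out
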