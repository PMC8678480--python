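"""Biomarker evaluation: ROC/AUC, gene-set enrichment, pair correlation.

AUC uses the Mann-Whitney rank identity with half-credit for ties; by
default the orientation is chosen automatically (reporting
max(AUC, 1 - AUC) with a flag), so down-regulated markers still score
above 0.5, as ROC packages conventionally do. Enrichment is the
one-sided hypergeometric upper tail (equivalent to a one-sided Fisher
exact test on the 2x2 table) with Benjamini-Hochberg adjustment across
sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_adjust, spearman
from .data_model import ExpressionMatrix, GeneSetCollection, GroupDesign

__all__ = ["RocSummary", "auc", "auc_table", "enrich", "pair_correlation"]


@dataclass(frozen=True)
class RocSummary:
    feature_id: str
    auc: float
    flipped: bool
    n_case: int
    n_control: int


def _auc_case_over_control(case: np.ndarray, control: np.ndarray) -> float:
    """P(case > control) + 0.5 P(case == control) via ranks."""
    n1, n2 = case.size, control.size
    ranks = stats.rankdata(np.concatenate([case, control]))
    rank_sum_case = float(ranks[:n1].sum())
    u = rank_sum_case - n1 * (n1 + 1) / 2.0
    return u / (n1 * n2)


def auc(
    values,
    design: GroupDesign,
    feature_id: str = "",
    auto_orient: bool = True,
) -> RocSummary:
    """AUC of one feature's per-sample values for case vs control.

    `values` is a mapping/Series sample -> value covering both groups.
    """
    values = pd.Series(values)
    case = values[[s for s in values.index if design.groups.get(s) == "case"]].to_numpy(float)
    ctrl = values[[s for s in values.index if design.groups.get(s) == "control"]].to_numpy(float)
    if case.size < 2 or ctrl.size < 2:
        raise ValueError("need >= 2 samples per group for ROC")
    a = _auc_case_over_control(case, ctrl)
    flipped = False
    if auto_orient and a < 0.5:
        a, flipped = 1.0 - a, True
    return RocSummary(feature_id, a, flipped, case.size, ctrl.size)


def auc_table(
    m: ExpressionMatrix, design: GroupDesign, features=None, auto_orient: bool = True
) -> pd.DataFrame:
    """RocSummary per feature (defaults to every feature in the matrix)."""
    features = m.feature_ids if features is None else list(features)
    rows = []
    for f in features:
        r = auc(m.values.loc[f], design, f, auto_orient)
        rows.append((r.feature_id, r.auc, r.flipped, r.n_case, r.n_control))
    return pd.DataFrame(
        rows, columns=["feature_id", "auc", "flipped", "n_case", "n_control"]
    ).set_index("feature_id")


def enrich(query, sets: GeneSetCollection, background) -> pd.DataFrame:
    """Hypergeometric over-representation of `query` in each gene set.

    p = P(overlap >= k) for a draw of n = |query| from the background of
    size N containing K set members; q is the BH adjustment across sets.
    Query ids outside the background are dropped with a warning.
    """
    background = set(background)
    query = set(query)
    stray = query - background
    if stray:
        warnings.warn(
            f"{len(stray)} query id(s) not in background, e.g. "
            f"{sorted(stray)[:5]}; intersecting"
        )
        query &= background
    n = len(query)
    big_n = len(background)
    rows = []
    for name in sets.names():
        members = set(sets[name]) & background
        big_k = len(members)
        k = len(query & members)
        p = float(stats.hypergeom.sf(k - 1, big_n, big_k, n)) if big_k else 1.0
        rows.append((name, k, big_k, n, big_n, min(p, 1.0)))
    out = pd.DataFrame(
        rows, columns=["set_name", "k", "K", "n", "N", "p_value"]
    ).set_index("set_name")
    out["q_value"] = bh_adjust(out["p_value"].to_numpy())
    return out.sort_values(["p_value", "set_name"])


def pair_correlation(m: ExpressionMatrix, a: str, b: str) -> tuple[float, float]:
    """Spearman rho and p of two features' expression (shared engine)."""
    return spearman(m.row(a), m.row(b))
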