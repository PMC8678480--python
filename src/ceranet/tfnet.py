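"""TF-target transcriptional regulatory network and driver ranking.

Starting from database TF->target records, an edge is retained when
(a) at least one endpoint is a differentially expressed member of the
supplied gene list (e.g. immunosuppressive-related genes), (b) both
endpoints are measured in the expression matrix, and (c) the Spearman
correlation of the two expression rows passes |rho| >= 0.5 with
p < 0.05 (published cutoffs; absolute rho admits repressive TFs).
Driver TFs are ranked by degree in the retained network, ties broken by
higher mean |rho| then lexicographically; the top 3 are the default
drivers.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from sklearn.base import BaseEstimator

from ._stats import spearman
from .data_model import ExpressionMatrix, InteractionTable

__all__ = ["TfEdge", "TFNetworkBuilder", "build_tf_network", "rank_drivers"]


@dataclass(frozen=True)
class TfEdge:
    tf: str
    target: str
    rho: float
    p_value: float
    tf_direction: str
    target_direction: str
    source: str


class TFNetworkBuilder(BaseEstimator):
    """Correlation-filtered TF network with degree-ranked drivers.

    Attributes
    ----------
    edges_ : list of retained TfEdge.
    drivers_ : top_n TF ids by degree.
    degrees_ : Series TF -> retained-target count.
    n_skipped_ : edges dropped because an endpoint was unmeasured.
    """

    def __init__(self, rho_min: float = 0.5, p_max: float = 0.05, top_n: int = 3):
        self.rho_min = rho_min
        self.p_max = p_max
        self.top_n = top_n

    def fit(
        self,
        de: pd.DataFrame,
        m: ExpressionMatrix,
        tf_edges: InteractionTable,
        restrict_to,
    ) -> "TFNetworkBuilder":
        restrict = set(restrict_to)
        direction = de["direction"]
        measured = set(m.feature_ids)
        edges: list[TfEdge] = []
        skipped = 0
        for r in tf_edges.of_regulator_class("TF").itertuples(index=False):
            tf, tgt = r.regulator, r.target
            tf_dir = direction.get(tf, "ns")
            tgt_dir = direction.get(tgt, "ns")
            in_scope = (tgt in restrict and tgt_dir != "ns") or (
                tf in restrict and tf_dir != "ns"
            )
            if not in_scope:
                continue
            if tf not in measured or tgt not in measured:
                skipped += 1
                continue
            rho, p = spearman(m.row(tf), m.row(tgt))
            if rho != rho:  # constant row
                skipped += 1
                continue
            if abs(rho) >= self.rho_min and p < self.p_max:
                edges.append(TfEdge(tf, tgt, rho, p, tf_dir, tgt_dir, r.source))
        self.n_skipped_ = skipped
        self.edges_ = edges
        self.degrees_, self.drivers_ = _rank(edges, self.top_n)
        return self


def _rank(edges: list[TfEdge], top_n: int) -> tuple[pd.Series, list[str]]:
    if not edges:
        return pd.Series(dtype=int), []
    df = pd.DataFrame(
        [(e.tf, e.target, abs(e.rho)) for e in edges],
        columns=["tf", "target", "abs_rho"],
    )
    stats = df.groupby("tf").agg(degree=("target", "nunique"), mean_abs_rho=("abs_rho", "mean"))
    order = sorted(
        stats.index, key=lambda t: (-stats.at[t, "degree"], -stats.at[t, "mean_abs_rho"], t)
    )
    return stats["degree"].loc[order], order[:top_n]


def build_tf_network(
    de: pd.DataFrame,
    m: ExpressionMatrix,
    tf_edges: InteractionTable,
    restrict_to,
    rho_min: float = 0.5,
    p_max: float = 0.05,
) -> list[TfEdge]:
    return TFNetworkBuilder(rho_min, p_max).fit(de, m, tf_edges, restrict_to).edges_


def rank_drivers(edges: list[TfEdge], top_n: int = 3) -> list[str]:
    """Top-n TFs by retained degree (ties: higher mean |rho|, then id)."""
    return _rank(edges, top_n)[1]


def edges_to_frame(edges: list[TfEdge]) -> pd.DataFrame:
    cols = ["tf", "target", "rho", "p_value", "tf_direction", "target_direction", "source"]
    return pd.DataFrame([[getattr(e, c) for c in cols] for e in edges], columns=cols)
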