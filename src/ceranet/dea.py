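"""Two-group differential expression on log2-scale intensity matrices.

The default test is a moderated t: per-feature pooled variances are shrunk
toward an empirical-Bayes prior fitted across all features (scaled
inverse chi-square, method of moments on the log variances), and the t
statistic uses the posterior variance with d0 + d_g degrees of freedom.
With ``moderation=False`` a plain Welch t is used instead. Features are
called ``up`` when log2FC > lfc_threshold and p < p_threshold, ``down``
on the mirrored condition, ``ns`` otherwise (defaults 1.5 and 0.01; raw,
unadjusted p-values).

log2FC is the difference of group means of the log2 values
(case minus control), not the log of a ratio of linear means.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from ._stats import squeeze_variances
from .data_model import ExpressionMatrix, GroupDesign

__all__ = [
    "DifferentialExpression",
    "differential_expression",
    "call_directions",
    "write_de_table",
    "read_de_table",
]

DIRECTIONS = ("up", "down", "ns")


def call_directions(
    table: pd.DataFrame, lfc_threshold: float = 1.5, p_threshold: float = 0.01
) -> pd.Series:
    """Direction call per feature: up / down / ns under strict thresholds."""
    lfc = table["log2fc"]
    p = table["p_value"]
    direction = pd.Series("ns", index=table.index, dtype=object)
    direction[(lfc > lfc_threshold) & (p < p_threshold)] = "up"
    direction[(lfc < -lfc_threshold) & (p < p_threshold)] = "down"
    return direction


class DifferentialExpression(BaseEstimator):
    """Moderated (or Welch) two-sample t-test over all features of a matrix.

    Parameters
    ----------
    moderation : bool, default True
        Shrink per-feature variances toward the empirical-Bayes prior.
    lfc_threshold, p_threshold : float
        Direction-call gates: |log2FC| must exceed lfc_threshold AND
        p must fall below p_threshold (both strict).

    Attributes
    ----------
    table_ : DataFrame with columns log2fc, stat, p_value, direction.
    prior_df_, prior_var_ : fitted prior (moderation mode only).
    n_zero_variance_ : features with zero variance in both groups
        (reported with stat 0, p 1).
    """

    def __init__(
        self,
        moderation: bool = True,
        lfc_threshold: float = 1.5,
        p_threshold: float = 0.01,
    ):
        self.moderation = moderation
        self.lfc_threshold = lfc_threshold
        self.p_threshold = p_threshold

    def fit(self, m: ExpressionMatrix, design: GroupDesign) -> "DifferentialExpression":
        design.check_covers(m)
        case = [s for s in m.sample_ids if design.groups[s] == "case"]
        ctrl = [s for s in m.sample_ids if design.groups[s] == "control"]
        if len(case) < 2 or len(ctrl) < 2:
            raise ValueError("need >= 2 samples per group in the matrix")
        x = m.values[case].to_numpy()
        y = m.values[ctrl].to_numpy()
        n1, n2 = x.shape[1], y.shape[1]
        lfc = x.mean(axis=1) - y.mean(axis=1)
        v1 = x.var(axis=1, ddof=1)
        v2 = y.var(axis=1, ddof=1)
        zero = (v1 == 0) & (v2 == 0)
        self.n_zero_variance_ = int(zero.sum())
        if self.n_zero_variance_:
            warnings.warn(
                f"{self.n_zero_variance_} feature(s) have zero variance in both "
                "groups; reported with statistic 0 and p 1"
            )

        if self.moderation:
            df_resid = n1 + n2 - 2
            s2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df_resid
            if (s2 > 0).sum() >= 2:
                post, d0, s0_2 = squeeze_variances(s2, df_resid)
            else:  # too few informative features to fit a prior
                post, d0, s0_2 = s2, 0.0, math.nan
            self.prior_df_ = d0
            self.prior_var_ = s0_2
            se = np.sqrt(post * (1.0 / n1 + 1.0 / n2))
            with np.errstate(divide="ignore", invalid="ignore"):
                t = lfc / se
            if math.isinf(d0):
                p = 2.0 * stats.norm.sf(np.abs(t))
            else:
                p = 2.0 * stats.t.sf(np.abs(t), df=d0 + df_resid)
        else:
            # Welch t with Satterthwaite df
            se2 = v1 / n1 + v2 / n2
            with np.errstate(divide="ignore", invalid="ignore"):
                t = lfc / np.sqrt(se2)
                df_w = se2**2 / (
                    (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
                )
            p = 2.0 * stats.t.sf(np.abs(t), df=df_w)

        t = np.where(zero, 0.0, t)
        p = np.where(zero, 1.0, p)
        p = np.minimum(np.nan_to_num(p, nan=1.0), 1.0)
        table = pd.DataFrame(
            {"log2fc": lfc, "stat": t, "p_value": p},
            index=m.values.index,
        )
        table["direction"] = call_directions(
            table, self.lfc_threshold, self.p_threshold
        )
        self.table_ = table
        return self


def differential_expression(
    m: ExpressionMatrix,
    design: GroupDesign,
    moderation: bool = True,
    lfc_threshold: float = 1.5,
    p_threshold: float = 0.01,
) -> pd.DataFrame:
    """Functional wrapper; returns the DE table."""
    est = DifferentialExpression(moderation, lfc_threshold, p_threshold)
    return est.fit(m, design).table_


def write_de_table(table: pd.DataFrame, path) -> None:
    out = table.copy()
    out.index.name = "feature_id"
    out.to_csv(path, sep="\t", float_format="%.12g")


def read_de_table(path) -> pd.DataFrame:
    t = pd.read_csv(path, sep="\t", index_col=0)
    needed = {"log2fc", "stat", "p_value", "direction"}
    if not needed.issubset(t.columns):
        raise ValueError(f"DE table must have columns {sorted(needed)}")
    return t
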