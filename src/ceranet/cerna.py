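"""ceRNA (lncRNA-miRNA-mRNA) triplet assembly.

A triplet requires three pieces of evidence:

1. database edges: the miRNA has recorded interactions with both the
   lncRNA and the mRNA;
2. direction opposition: the miRNA and both targets are differentially
   expressed, with the miRNA's direction opposite to both targets';
3. co-expression of the lncRNA-mRNA pair: Spearman rho > 0.6 with an
   empirical permutation p-value Pe < 0.01.

The empirical p-value calibrates the raw Spearman p (Pr) against a null
built from random lncRNAs: the mRNA's expression is held fixed, n_perm
random other lncRNAs are tested the same way, giving permutation
p-values Pp, and

    Pe = (#{Pp <= Pr} + 1) / (n_perm + 1)

with a pseudo-count of 1 (denominator 1001 at the default n_perm=1000).
Pe lives on the grid {k/(n_perm+1)} and is uniform on it under an
exchangeable null. All threshold inequalities are strict, as stated;
rho is signed (ceRNA theory predicts positive co-expression).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from ._stats import spearman, spearman_many_vs_one
from .data_model import ExpressionMatrix, InteractionTable

__all__ = [
    "CoexpressionPair",
    "CeRNATriplet",
    "CeRNATripletAssembler",
    "opposite_direction_pairs",
    "empirical_p",
    "empirical_coexpression",
    "assemble_triplets",
    "triplets_to_frame",
]


def empirical_p(pp, pr: float) -> float:
    """Pe = (#{Pp <= Pr} + 1) / (n_perm + 1), pseudo-count included.

    Lies on the grid {k/(n_perm+1), k = 1..n_perm+1}: 1/(n_perm+1) when no
    permutation p-value reaches Pr, 1 when all do.
    """
    pp = np.asarray(pp, dtype=float)
    if pp.size < 1:
        raise ValueError("need at least one permutation p-value")
    return (int(np.sum(pp <= pr)) + 1) / (pp.size + 1)


@dataclass(frozen=True)
class CoexpressionPair:
    lncrna: str
    mrna: str
    rho: float
    pr: float       # raw Spearman p
    pe: float       # empirical permutation p
    n_perm: int


@dataclass(frozen=True)
class CeRNATriplet:
    lncrna: str
    mirna: str
    mrna: str
    lnc_source: str
    mrna_source: str
    mir_direction: str
    lnc_direction: str
    mrna_direction: str
    rho: float
    pe: float


def opposite_direction_pairs(
    de_rna: pd.DataFrame, de_mir: pd.DataFrame, interactions: InteractionTable
) -> pd.DataFrame:
    """miRNA-target candidates: DB edge present, both DE, opposite directions.

    Returns a frame with columns (mirna, target, target_class, source,
    mir_direction, target_direction).
    """
    rec = interactions.of_regulator_class("miRNA")
    if rec.empty:
        warnings.warn("interaction table has no miRNA-regulator edges")
    mir_dir = de_mir["direction"]
    rna_dir = de_rna["direction"]
    rows = []
    for r in rec.itertuples(index=False):
        md = mir_dir.get(r.regulator, "ns")
        td = rna_dir.get(r.target, "ns")
        if md == "ns" or td == "ns" or md == td:
            continue
        rows.append((r.regulator, r.target, r.target_class, r.source, md, td))
    return pd.DataFrame(
        rows,
        columns=[
            "mirna",
            "target",
            "target_class",
            "source",
            "mir_direction",
            "target_direction",
        ],
    )


def empirical_coexpression(
    m: ExpressionMatrix,
    lnc: str,
    mrna: str,
    n_perm: int = 1000,
    rng: np.random.Generator | int | None = None,
) -> CoexpressionPair | None:
    """Spearman test of one lncRNA-mRNA pair with a permutation-null Pe.

    The permutation pool is every other measured lncRNA in the matrix
    (constant rows excluded); pool members are drawn without replacement
    when the pool is large enough, with replacement otherwise, and each
    is tested against the *same* mRNA row. Returns None (with a warning)
    when either tested row is constant.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    x = m.row(lnc)
    y = m.row(mrna)
    if x.size < 4:
        raise ValueError("need >= 4 shared samples")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn(f"constant expression for pair ({lnc}, {mrna}); excluded")
        return None
    rho, pr = spearman(x, y)

    pool_ids = [f for f in m.features_of_class("lncRNA") if f != lnc]
    pool = m.values.loc[pool_ids].to_numpy()
    keep = np.ptp(pool, axis=1) > 0
    pool = pool[keep]
    if pool.shape[0] == 0:
        raise ValueError("no non-constant lncRNAs available for the permutation pool")
    replace = pool.shape[0] < n_perm
    idx = rng.choice(pool.shape[0], size=n_perm, replace=replace)
    _, pp = spearman_many_vs_one(pool[idx], y)
    return CoexpressionPair(lnc, mrna, rho, pr, empirical_p(pp, pr), n_perm)


def assemble_triplets(
    candidates: pd.DataFrame,
    pairs: dict[tuple[str, str], CoexpressionPair],
    rho_min: float = 0.6,
    pe_max: float = 0.01,
) -> list[CeRNATriplet]:
    """Join miRNA-target candidates with gated co-expression pairs.

    A triplet (L, M, R) is emitted iff (M, L) and (M, R) both survived the
    direction filter and the (L, R) pair has rho > rho_min and Pe < pe_max
    (strict). Output is de-duplicated and sorted by (miRNA, lncRNA, mRNA).
    """
    out: dict[tuple[str, str, str], CeRNATriplet] = {}
    if candidates.empty:
        return []
    by_mir = dict(tuple(candidates.groupby("mirna", sort=True)))
    for mirna, grp in by_mir.items():
        lncs = grp[grp["target_class"] == "lncRNA"]
        mrnas = grp[grp["target_class"] == "mRNA"]
        for lrow in lncs.itertuples(index=False):
            for rrow in mrnas.itertuples(index=False):
                cp = pairs.get((lrow.target, rrow.target))
                if cp is None or not (cp.rho > rho_min and cp.pe < pe_max):
                    continue
                key = (mirna, lrow.target, rrow.target)
                out.setdefault(
                    key,
                    CeRNATriplet(
                        lncrna=lrow.target,
                        mirna=mirna,
                        mrna=rrow.target,
                        lnc_source=lrow.source,
                        mrna_source=rrow.source,
                        mir_direction=lrow.mir_direction,
                        lnc_direction=lrow.target_direction,
                        mrna_direction=rrow.target_direction,
                        rho=cp.rho,
                        pe=cp.pe,
                    ),
                )
    return [out[k] for k in sorted(out)]


class CeRNATripletAssembler(BaseEstimator):
    """End-to-end triplet assembly from DE tables and an interaction table.

    Parameters mirror the published gates: n_perm permutation lncRNAs
    (default 1000), co-expression thresholds rho_min=0.6 / pe_max=0.01.

    Attributes
    ----------
    candidates_ : miRNA-target pairs surviving the direction filter.
    pairs_ : dict (lncRNA, mRNA) -> CoexpressionPair for every tested pair.
    triplets_ : list of CeRNATriplet.
    """

    def __init__(
        self,
        n_perm: int = 1000,
        rho_min: float = 0.6,
        pe_max: float = 0.01,
        random_state: int | None = None,
    ):
        self.n_perm = n_perm
        self.rho_min = rho_min
        self.pe_max = pe_max
        self.random_state = random_state

    def fit(
        self,
        expr_rna: ExpressionMatrix,
        de_rna: pd.DataFrame,
        de_mir: pd.DataFrame,
        interactions: InteractionTable,
    ) -> "CeRNATripletAssembler":
        rng = np.random.default_rng(self.random_state)
        cand = opposite_direction_pairs(de_rna, de_mir, interactions)
        self.candidates_ = cand
        pair_keys: set[tuple[str, str]] = set()
        if not cand.empty:
            for _, grp in cand.groupby("mirna", sort=True):
                ls = grp.loc[grp["target_class"] == "lncRNA", "target"]
                rs = grp.loc[grp["target_class"] == "mRNA", "target"]
                for L in ls:
                    for R in rs:
                        pair_keys.add((L, R))
        measured = set(expr_rna.feature_ids)
        pairs: dict[tuple[str, str], CoexpressionPair] = {}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for L, R in sorted(pair_keys):
                if L not in measured or R not in measured:
                    continue
                cp = empirical_coexpression(expr_rna, L, R, self.n_perm, rng)
                if cp is not None:
                    pairs[(L, R)] = cp
        self.pairs_ = pairs
        self.triplets_ = assemble_triplets(cand, pairs, self.rho_min, self.pe_max)
        return self


def triplets_to_frame(triplets: list[CeRNATriplet]) -> pd.DataFrame:
    cols = [
        "lncrna",
        "mirna",
        "mrna",
        "lnc_source",
        "mrna_source",
        "mir_direction",
        "lnc_direction",
        "mrna_direction",
        "rho",
        "pe",
    ]
    return pd.DataFrame([[getattr(t, c) for c in cols] for t in triplets], columns=cols)
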