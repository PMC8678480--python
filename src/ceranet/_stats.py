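"""Shared statistical primitives.

Spearman correlation (scalar and vectorized many-vs-one), the
empirical-Bayes variance shrinkage used by the moderated t-test, and the
Benjamini-Hochberg helper. The Spearman p-value uses the classical
t-approximation on the rank correlation for n > 7 and an exact
rank-permutation null for n <= 7 (the approximation is poor there).
"""

from __future__ import annotations

import itertools
import math
from functools import lru_cache

import numpy as np
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "spearman",
    "spearman_many_vs_one",
    "squeeze_variances",
    "bh_adjust",
]


def _rank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, axis=-1)


def _pearson_of_ranks(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt(float(rx @ rx) * float(ry @ ry))
    if denom == 0.0:
        return math.nan
    return float(rx @ ry) / denom


@lru_cache(maxsize=8)
def _exact_null(ranks_key: tuple, n: int) -> np.ndarray:
    """All |rho| values of one rank vector against every permutation of 0..n-1."""
    rx = np.asarray(ranks_key, dtype=float)
    rhos = np.empty(math.factorial(n))
    base = np.arange(1.0, n + 1.0)
    for i, perm in enumerate(itertools.permutations(range(n))):
        rhos[i] = _pearson_of_ranks(rx, base[list(perm)])
    return np.abs(rhos)


def spearman(x, y) -> tuple[float, float]:
    """Spearman rho and two-sided p-value.

    Exact permutation p for n <= 7 (conditional on the tie pattern of x),
    t-approximation otherwise. Returns (nan, nan) when either vector is
    constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return math.nan, math.nan
    rx, ry = _rank(x), _rank(y)
    rho = _pearson_of_ranks(rx, ry)
    if n <= 7:
        null = _exact_null(tuple(rx), n)
        p = float(np.mean(null >= abs(rho) - 1e-12))
        return rho, p
    return rho, _t_approx_p(np.asarray(rho), n).item()


def _t_approx_p(rho: np.ndarray, n: int) -> np.ndarray:
    r = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    return np.minimum(p, 1.0)


def spearman_many_vs_one(rows: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Spearman rho and two-sided p of each row of `rows` against `y`.

    Vectorized t-approximation; rows or y that are constant yield nan.
    Intended for permutation pools where n > 7.
    """
    rows = np.asarray(rows, dtype=float)
    y = np.asarray(y, dtype=float)
    n = y.size
    rr = _rank(rows)
    ry = _rank(y)
    rr = rr - rr.mean(axis=1, keepdims=True)
    ryc = ry - ry.mean()
    num = rr @ ryc
    denom = np.sqrt((rr * rr).sum(axis=1) * float(ryc @ ryc))
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = num / denom
    p = _t_approx_p(rho, n)
    p = np.where(np.isfinite(rho), p, np.nan)
    return rho, p


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton on the monotone trigamma)."""
    if y <= 0:
        return math.inf
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(75):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return x


def squeeze_variances(s2: np.ndarray, df: float) -> tuple[np.ndarray, float, float]:
    """Empirical-Bayes shrinkage of per-feature sample variances.

    Fits a scaled inverse chi-square prior (s0^2, d0) to the observed
    variances by method of moments on log s2 and returns the posterior
    variances (d0*s0^2 + df*s2) / (d0 + df) together with (d0, s0^2).
    Features with zero variance are excluded from prior estimation and
    shrink fully toward s0^2. d0 may be inf when the observed spread of
    log-variances is no larger than chi-square sampling noise alone.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        raise ValueError("need at least two positive variances to fit the prior")
    z = np.log(s2[ok])
    e = z - float(special.digamma(df / 2.0)) + math.log(df / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1))
    evar_excess = evar - float(special.polygamma(1, df / 2.0))
    if evar_excess > 0:
        d0 = 2.0 * _trigamma_inverse(evar_excess)
        s0_2 = math.exp(
            emean + float(special.digamma(d0 / 2.0)) - math.log(d0 / 2.0)
        )
    else:
        d0 = math.inf
        s0_2 = math.exp(emean)
    if math.isinf(d0):
        post = np.full_like(s2, s0_2)
    else:
        post = (d0 * s0_2 + df * s2) / (d0 + df)
    return post, d0, s0_2


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (q-values)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]
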