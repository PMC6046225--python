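"""Shared statistical primitives: p-value combination, FDR, exact tests.

Fisher's method combines k independent p-values as X = -2 * sum(ln p_i),
which is chi-square with 2k degrees of freedom under the global null.
The inverse-normal (Stouffer) method combines probit-transformed
p-values, Z = sum(w_i * z_i) / sqrt(sum(w_i^2)); with equal weights it
reduces to the classic mean-z statistic.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

log = logging.getLogger("senesplice")

_TINY = np.finfo(float).tiny  # clamp for log(0)
_EPS = 1e-15


def combine_fisher(pvals: Sequence[float]) -> float:
    """Fisher's combined probability over independent p-values in (0, 1]."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("combine_fisher needs at least one p-value")
    if np.any(p <= 0):
        log.warning("[W-CLAMP] combine_fisher: p=0 clamped to %g", _TINY)
        p = np.maximum(p, _TINY)
    if np.any(p > 1):
        raise ValueError("p-values must be <= 1")
    x = -2.0 * np.sum(np.log(p))
    return float(sps.chi2.sf(x, 2 * p.size))


def combine_stouffer(pvals: Sequence[float], weights: Sequence[float] | None = None) -> float:
    """Weighted inverse-normal combination; returns the upper-tail p."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("combine_stouffer needs at least one p-value")
    if np.any((p <= 0) | (p >= 1)):
        log.warning("[W-CLAMP] combine_stouffer: p clamped into (%g, 1-%g)", _EPS, _EPS)
        p = np.clip(p, _EPS, 1 - _EPS)
    if weights is None:
        w = np.ones_like(p)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != p.shape:
            raise ValueError("weights must match p-values in length")
        if np.any(w <= 0):
            raise ValueError("weights must be positive")
    z = sps.norm.isf(p)  # z_i = Phi^-1(1 - p_i)
    big_z = float(np.sum(w * z) / np.sqrt(np.sum(w * w)))
    return float(sps.norm.sf(big_z))


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (q-values)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.array([])
    return multipletests(p, method="fdr_bh")[1]


def bonferroni_adjust(pvals: Sequence[float], m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment; ``m`` defaults to the vector length."""
    p = np.asarray(pvals, dtype=float)
    if m is None:
        m = p.size
    return np.minimum(p * m, 1.0)


def fisher_exact_enrichment(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """One-sided (enrichment) Fisher exact test on the table [[a, b], [c, d]].

    Returns (odds_ratio, p) where the alternative is "the a-cell is larger
    than expected" (hypergeometric upper tail) and the odds ratio is the
    sample estimate a*d / (b*c); inf when b*c = 0 and a*d > 0, nan for a
    fully degenerate table.
    """
    table = np.array([[a, b], [c, d]])
    if np.any(table < 0):
        raise ValueError("2x2 cells must be nonnegative")
    p = float(sps.fisher_exact(table, alternative="greater")[1])
    if b * c > 0:
        oratio = (a * d) / (b * c)
    elif a * d > 0:
        oratio = float("inf")
    else:
        oratio = float("nan")
    return oratio, p


def hypergeom_sf(overlap: int, universe: int, set1: int, set2: int) -> float:
    """P(X >= overlap) for X ~ Hypergeom(universe, set1, draws=set2)."""
    return float(sps.hypergeom.sf(overlap - 1, universe, set1, set2))


def welch_t(
    x: np.ndarray, mask1: np.ndarray, alternative: str = "two-sided"
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised Welch t-test on the rows of ``x`` between two sample groups.

    ``mask1`` marks group-1 columns (senescent); the statistic is
    mean(group1) - mean(group2).  Rows with zero variance in both groups
    and equal means get t = 0 and a two-sided p of 1 (one-sided 0.5).
    ``alternative``: "two-sided", "less" (group1 < group2, i.e. down in
    senescent) or "greater".
    """
    x = np.asarray(x, dtype=float)
    g1 = x[:, mask1]
    g2 = x[:, ~mask1]
    n1, n2 = g1.shape[1], g2.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs >= 2 samples")
    m1, m2 = g1.mean(axis=1), g2.mean(axis=1)
    v1, v2 = g1.var(axis=1, ddof=1), g2.var(axis=1, ddof=1)
    se2 = v1 / n1 + v2 / n2
    zero = se2 <= 0
    t = np.zeros(x.shape[0])
    df = np.ones(x.shape[0])
    nz = ~zero
    t[nz] = (m1[nz] - m2[nz]) / np.sqrt(se2[nz])
    with np.errstate(divide="ignore", invalid="ignore"):
        df[nz] = se2[nz] ** 2 / (
            (v1[nz] / n1) ** 2 / (n1 - 1) + (v2[nz] / n2) ** 2 / (n2 - 1)
        )
    # degenerate but unequal means: treat as infinitely significant
    inf_sig = zero & (m1 != m2)
    t[inf_sig] = np.sign(m1[inf_sig] - m2[inf_sig]) * np.inf
    if alternative == "two-sided":
        p = 2.0 * sps.t.sf(np.abs(t), df)
    elif alternative == "less":
        p = sps.t.cdf(t, df)
    elif alternative == "greater":
        p = sps.t.sf(t, df)
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    p = np.where(zero & (m1 == m2), 1.0 if alternative == "two-sided" else 0.5, p)
    p = np.clip(p, _TINY, 1.0)
    return t, p


def two_proportion_z(
    inc1: float, tot1: float, inc2: float, tot2: float
) -> float:
    """Two-sided continuity-corrected two-proportion z-test p-value.

    Used by the synthetic-data generator as its documented internal
    differential-splicing test on pooled inclusion fractions.
    """
    if tot1 <= 0 or tot2 <= 0:
        return 1.0
    p1, p2 = inc1 / tot1, inc2 / tot2
    pool = (inc1 + inc2) / (tot1 + tot2)
    var = pool * (1 - pool) * (1 / tot1 + 1 / tot2)
    if var <= 0:
        return 1.0
    cc = 0.5 * (1 / tot1 + 1 / tot2)
    num = max(abs(p1 - p2) - cc, 0.0)
    z = num / np.sqrt(var)
    return float(max(2.0 * sps.norm.sf(z), _TINY))
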