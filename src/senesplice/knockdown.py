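"""Knockdown-based validation of candidate splicing regulators.

For each RBP knockdown experiment the differential events (fdr < 0.05,
|dPSI| >= 0.1) are intersected with the consensus senescence event set;
a one-sided Fisher test measures the overlap enrichment; RBPs are
ranked by ascending enrichment p; and a weighted pre-ranked GSEA
enrichment score tests whether the candidate regulators sit at the top
of that ranking.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import AnalysisConfig, EventStatRecord
from .splice_meta import filter_event_coverage
from .stats import fisher_exact_enrichment

log = logging.getLogger("senesplice")


@dataclass
class KnockdownResult:
    rbp: str
    kd_events: set[str]
    overlap_table: tuple[int, int, int, int]
    odds_ratio: float
    p_overlap: float
    rank: int = 0


@dataclass
class GseaResult:
    es: float
    hit_positions: list[int]  # 1-based ranks of the candidate RBPs
    p_perm: float
    n_perm: int
    running: np.ndarray | None = None


def kd_differential_events(
    records: list[EventStatRecord],
    fdr_thresh: float = 0.05,
    dpsi_thresh: float = 0.1,
    min_mean: float = 5.0,
) -> set[str]:
    """Differential events of one knockdown table, after coverage filtering."""
    return {
        rec.event_id
        for rec in records
        if filter_event_coverage(rec, min_mean)
        and rec.fdr < fdr_thresh
        and abs(rec.delta_psi) >= dpsi_thresh
    }


def knockdown_overlap(
    kd_events: set[str], consensus: set[str], universe: set[str]
) -> tuple[tuple[int, int, int, int], float, float]:
    """2x2 overlap table and one-sided Fisher p over the testable universe.

    Cells: (in both, knockdown only, consensus only, neither).
    """
    if not kd_events <= universe or not consensus <= universe:
        raise ValueError("kd_events and consensus must be subsets of the universe")
    a = len(kd_events & consensus)
    b = len(kd_events - consensus)
    c = len(consensus - kd_events)
    d = len(universe) - a - b - c
    oratio, p = fisher_exact_enrichment(a, b, c, d)
    return (a, b, c, d), oratio, p


def rank_rbps(results: list[KnockdownResult]) -> list[KnockdownResult]:
    """Rank ascending by p; ties by descending odds ratio, then RBP id."""

    def sort_key(r: KnockdownResult):
        oratio = r.odds_ratio if np.isfinite(r.odds_ratio) else np.inf
        return (r.p_overlap, -oratio if np.isfinite(oratio) else -np.inf, r.rbp)

    ordered = sorted(results, key=sort_key)
    for i, r in enumerate(ordered, start=1):
        r.rank = i
    return ordered


def gsea_preranked(
    ranked_rbps: list[str],
    metrics: list[float],
    candidate_set: set[str],
    weight_exponent: float = 1.0,
) -> tuple[float, np.ndarray, list[int]]:
    """Weighted pre-ranked GSEA enrichment score.

    ``ranked_rbps`` is the list sorted by decreasing metric (the metric is
    -log10 of the overlap p in the pipeline).  Hits add
    |metric|^w / sum_hits |metric|^w, misses subtract 1 / (N - n_hits);
    the ES is the signed maximum deviation of the running sum from zero.
    When every hit metric is zero the hit increments are uniform.
    """
    n = len(ranked_rbps)
    if n == 0:
        raise ValueError("empty ranked list")
    hits = np.array([r in candidate_set for r in ranked_rbps])
    n_hits = int(hits.sum())
    if n_hits == 0:
        raise ValueError("no candidate appears in the ranked list")
    w = np.abs(np.asarray(metrics, dtype=float)) ** weight_exponent
    hit_mass = w * hits
    total = hit_mass.sum()
    if total <= 0:
        hit_mass = hits.astype(float)
        total = hit_mass.sum()
    steps = np.where(
        hits,
        hit_mass / total,
        -1.0 / (n - n_hits) if n > n_hits else 0.0,
    )
    running = np.cumsum(steps)
    imax = int(np.argmax(np.abs(running)))
    es = float(running[imax])
    positions = [i + 1 for i, h in enumerate(hits) if h]
    return es, running, positions


def gsea_permutation_p(
    ranked_rbps: list[str],
    metrics: list[float],
    candidate_set: set[str],
    n_perm: int = 1000,
    seed: int = 0,
    weight_exponent: float = 1.0,
) -> GseaResult:
    """Gene-set permutation p for a positive enrichment score.

    Random same-size sets are drawn from the ranked list;
    p = (1 + #{permutation ES >= observed}) / (1 + n_perm).
    """
    es, running, positions = gsea_preranked(
        ranked_rbps, metrics, candidate_set, weight_exponent
    )
    rng = np.random.default_rng(seed)
    size = len([r for r in ranked_rbps if r in candidate_set])
    count = 0
    for _ in range(n_perm):
        perm = set(rng.choice(ranked_rbps, size=size, replace=False))
        es_p, _, _ = gsea_preranked(ranked_rbps, metrics, perm, weight_exponent)
        if es_p >= es:
            count += 1
    return GseaResult(
        es=es,
        hit_positions=positions,
        p_perm=(1 + count) / (1 + n_perm),
        n_perm=n_perm,
        running=running,
    )


def validate_knockdowns(
    kd_tables: dict[str, list[EventStatRecord]],
    consensus: set[str],
    tested_universe: set[str],
    candidates: set[str],
    config: AnalysisConfig | None = None,
) -> tuple[list[KnockdownResult], GseaResult | None]:
    """Full validation stage: overlap tests, ranking and pre-ranked GSEA.

    The testable universe for each knockdown is the intersection of its
    coverage-passing events with the consensus-testable event universe.
    """
    config = config or AnalysisConfig()
    results = []
    for rbp in sorted(kd_tables):
        records = kd_tables[rbp]
        covered = {
            rec.event_id
            for rec in records
            if filter_event_coverage(rec, config.event_min_mean_coverage)
        }
        universe = covered & tested_universe
        kd = kd_differential_events(
            records, config.kd_fdr, config.kd_dpsi, config.event_min_mean_coverage
        ) & universe
        table, oratio, p = knockdown_overlap(kd, consensus & universe, universe)
        results.append(
            KnockdownResult(
                rbp=rbp, kd_events=kd, overlap_table=table, odds_ratio=oratio, p_overlap=p
            )
        )
    ranked = rank_rbps(results)
    present = {r.rbp for r in ranked} & candidates
    gsea = None
    if present:
        names = [r.rbp for r in ranked]
        metrics = [-np.log10(max(r.p_overlap, 1e-300)) for r in ranked]
        gsea = gsea_permutation_p(
            names,
            metrics,
            present,
            n_perm=config.gsea_permutations,
            seed=config.seed,
            weight_exponent=config.gsea_weight,
        )
    else:
        log.warning("[W-NOCAND] no candidate RBP among the knocked-down RBPs")
    return ranked, gsea


def knockdown_frame(results: list[KnockdownResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "rbp": r.rbp,
                "rank": r.rank,
                "n_kd_events": len(r.kd_events),
                "overlap": r.overlap_table[0],
                "kd_only": r.overlap_table[1],
                "consensus_only": r.overlap_table[2],
                "neither": r.overlap_table[3],
                "odds_ratio": r.odds_ratio,
                "p_overlap": r.p_overlap,
            }
            for r in results
        ]
    )
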