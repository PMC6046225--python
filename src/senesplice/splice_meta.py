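"""Consensus differential-splicing-event calling across experiments.

Each experiment contributes an rMATS-like event table.  Events with mean
combined (inclusion + skipping) read support below 5 in either group are
dropped per experiment; an event is differential within an experiment at
fdr < 0.1 and |dPSI| >= 0.05; a consensus event must be differential in
more than three experiments (strictly: at least four) AND have a
Fisher-combined, BH-adjusted p below 0.05 across the experiments in
which it was testable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import EVENT_TYPES, AnalysisConfig, EventStatRecord, SplicingEvent
from .stats import bh_adjust, combine_fisher

log = logging.getLogger("senesplice")

EventTable = list[tuple[SplicingEvent, EventStatRecord]]


@dataclass
class ConsensusEventResult:
    event_id: str
    n_tested: int
    n_significant: int
    p_combined: float
    fdr_combined: float
    is_consensus: bool
    delta_psi: dict[str, float] = field(default_factory=dict)  # per experiment


def filter_event_coverage(record: EventStatRecord, min_mean: float = 5.0) -> bool:
    """Keep an event when mean(inc+skip) >= min_mean in BOTH groups.

    (The published filter removes events with average combined reads
    below five "in either" group, i.e. failing either side drops it.)
    """
    sen = record.inc_counts_sen + record.skip_counts_sen
    gro = record.inc_counts_gro + record.skip_counts_gro
    if sen.size == 0 or gro.size == 0:
        return False
    return bool(sen.mean() >= min_mean and gro.mean() >= min_mean)


def call_per_experiment(
    records: list[EventStatRecord],
    fdr_thresh: float = 0.1,
    dpsi_thresh: float = 0.05,
    min_mean: float = 5.0,
) -> set[str]:
    """Event ids differential in one experiment, after the coverage filter.

    Thresholds follow the published inequalities exactly: fdr strictly
    below, |dPSI| inclusive.
    """
    out = set()
    for rec in records:
        if not filter_event_coverage(rec, min_mean):
            continue
        if rec.fdr < fdr_thresh and abs(rec.delta_psi) >= dpsi_thresh:
            out.add(rec.event_id)
    return out


def consensus_events(
    tables: dict[str, EventTable],
    config: AnalysisConfig | None = None,
) -> list[ConsensusEventResult]:
    """Combine per-experiment event tables into consensus calls.

    ``tables`` maps experiment id -> list of (event, record).  P-values
    are Fisher-combined over the experiments where the event passed the
    coverage filter; BH adjustment is applied across events.
    """
    config = config or AnalysisConfig()
    if len(tables) < config.vote_min:
        log.warning(
            "[W-VOTE] only %d experiments supplied; the vote rule needs "
            "significance in >= %d and can never be met",
            len(tables), config.vote_min,
        )
    sig_sets = {
        expt: call_per_experiment(
            [rec for _, rec in table],
            config.event_fdr,
            config.event_dpsi,
            config.event_min_mean_coverage,
        )
        for expt, table in tables.items()
    }
    tested_p: dict[str, dict[str, float]] = {}
    dpsi: dict[str, dict[str, float]] = {}
    for expt, table in tables.items():
        for _, rec in table:
            if filter_event_coverage(rec, config.event_min_mean_coverage):
                tested_p.setdefault(rec.event_id, {})[expt] = rec.p
                dpsi.setdefault(rec.event_id, {})[expt] = rec.delta_psi
    all_ids = sorted({rec.event_id for table in tables.values() for _, rec in table})
    skipped = [eid for eid in all_ids if eid not in tested_p]
    if skipped:
        log.info("[I-UNTESTED] %d events passed coverage in no experiment", len(skipped))
    event_ids = [eid for eid in all_ids if eid in tested_p]
    p_comb = np.array(
        [combine_fisher(list(tested_p[eid].values())) for eid in event_ids]
    )
    fdr_comb = bh_adjust(p_comb) if event_ids else np.array([])
    results = []
    for i, eid in enumerate(event_ids):
        n_tested = len(tested_p[eid])
        n_sig = sum(eid in sig_sets[expt] for expt in tested_p[eid])
        is_consensus = n_sig >= config.vote_min and fdr_comb[i] < config.consensus_fdr
        results.append(
            ConsensusEventResult(
                event_id=eid,
                n_tested=n_tested,
                n_significant=n_sig,
                p_combined=float(p_comb[i]),
                fdr_combined=float(fdr_comb[i]),
                is_consensus=bool(is_consensus),
                delta_psi=dpsi[eid],
            )
        )
    return results


def consensus_ids(results: list[ConsensusEventResult]) -> set[str]:
    return {r.event_id for r in results if r.is_consensus}


def event_type_breakdown(
    consensus: list[ConsensusEventResult], events_by_id: dict[str, SplicingEvent]
) -> dict[str, int]:
    """Count consensus events per splicing class (SE, A5SS, A3SS, MXE, RI)."""
    counts = {t: 0 for t in EVENT_TYPES}
    for r in consensus:
        if r.is_consensus:
            counts[events_by_id[r.event_id].event_type] += 1
    return counts


def results_frame(results: list[ConsensusEventResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "event_id": r.event_id,
                "n_tested": r.n_tested,
                "n_significant": r.n_significant,
                "p_combined": r.p_combined,
                "fdr_combined": r.fdr_combined,
                "is_consensus": r.is_consensus,
                "mean_delta_psi": float(np.mean(list(r.delta_psi.values()))) if r.delta_psi else np.nan,
            }
            for r in results
        ]
    )
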