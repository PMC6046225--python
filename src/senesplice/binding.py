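"""Dual-evidence RBP enrichment in consensus-event regions.

Event regions are the alternatively spliced exon body plus up to 250 bp
of flanking intron on each side, minus the splice-site consensus zones
(6 intronic bp next to the donor / 5' splice site, 20 intronic bp next
to the acceptor / 3' splice site).  For each RBP the frequency of motif
hits and of high-confidence eCLIP peaks in consensus-event regions is
compared against type-matched control events by one-sided Fisher tests;
the two evidence channels are combined by Fisher's and the
inverse-normal method, BH-adjusted across RBPs, and an RBP is enriched
only when significant under both combinations.  Enriched RBPs that are
consistently down-regulated are the candidate splicing regulators.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import Genome
from .model import AnalysisConfig, GenomicInterval, Peak, PwmMotif, SplicingEvent
from .pwm import MotifScanner
from .stats import bh_adjust, combine_fisher, combine_stouffer, fisher_exact_enrichment

log = logging.getLogger("senesplice")


@dataclass
class EventRegionSet:
    """Scannable intervals of one splicing event (sorted, non-overlapping)."""

    event_id: str
    intervals: tuple[GenomicInterval, ...]


@dataclass
class RbpEvidence:
    """Per-RBP 2x2 evidence tables and their one-sided Fisher p-values."""

    rbp: str
    has_motif: bool
    has_peaks: bool
    motif_table: tuple[int, int, int, int] | None = None
    peak_table: tuple[int, int, int, int] | None = None
    p_motif: float | None = None
    p_peak: float | None = None
    best_motif_id: str | None = None
    ase_with_motif: set[str] = field(default_factory=set)
    ase_with_peak: set[str] = field(default_factory=set)


@dataclass
class EnrichmentRecord:
    rbp: str
    p_combined_fisher: float
    p_combined_stouffer: float
    q_fisher: float
    q_stouffer: float
    enriched: bool
    is_de_down: bool
    is_candidate_regulator: bool


def _merge_sorted(intervals: list[GenomicInterval], event_id: str) -> tuple[GenomicInterval, ...]:
    intervals = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    out: list[GenomicInterval] = []
    for iv in intervals:
        if out and out[-1].chrom == iv.chrom and iv.start < out[-1].end:
            log.warning("[W-MERGE] %s: overlapping region intervals merged", event_id)
            prev = out.pop()
            iv = GenomicInterval(iv.chrom, prev.start, max(prev.end, iv.end), iv.strand)
        out.append(iv)
    return tuple(out)


def build_event_regions(
    event: SplicingEvent,
    flank: int = 250,
    donor_excl: int = 6,
    acceptor_excl: int = 20,
    chrom_lengths: dict[str, int] | None = None,
) -> EventRegionSet:
    """Exon body plus trimmed intron flanks, in genomic coordinates.

    Upstream/downstream are transcript-oriented: on the plus strand the
    acceptor (3' splice site) is the exon's genomic start and the donor
    (5' splice site) its genomic end; on the minus strand they swap.  The
    upstream intron flank extends ``flank`` bp from the exon boundary and
    loses the ``acceptor_excl`` bp adjacent to the exon; the downstream
    flank loses the ``donor_excl`` bp adjacent to the exon.  MXE events
    contribute both alternative exons.  Flanks are clipped at chromosome
    bounds.
    """
    intervals: list[GenomicInterval] = []
    for seg in event.alt_segments:
        limit = None if chrom_lengths is None else chrom_lengths.get(seg.chrom)
        intervals.append(seg)
        if seg.strand == "+":
            up = (seg.start - flank, seg.start - acceptor_excl)
            down = (seg.end + donor_excl, seg.end + flank)
        else:
            up = (seg.end + acceptor_excl, seg.end + flank)
            down = (seg.start - flank, seg.start - donor_excl)
        for lo, hi in (up, down):
            lo = max(lo, 0)
            if limit is not None:
                hi = min(hi, limit)
            if hi > lo:
                intervals.append(GenomicInterval(seg.chrom, lo, hi, seg.strand))
    return EventRegionSet(event.event_id, _merge_sorted(intervals, event.event_id))


def sample_control_events(
    events_by_id: dict[str, SplicingEvent],
    consensus: set[str],
    seed: int = 0,
) -> list[str]:
    """Type-matched control (non-consensus) events, sampled uniformly.

    For each splicing class the control set has exactly as many events as
    the consensus set, drawn without replacement from the non-consensus
    background of that class.
    """
    rng = np.random.default_rng(seed)
    by_type_consensus: dict[str, int] = {}
    by_type_background: dict[str, list[str]] = {}
    for eid in sorted(events_by_id):
        etype = events_by_id[eid].event_type
        if eid in consensus:
            by_type_consensus[etype] = by_type_consensus.get(etype, 0) + 1
        else:
            by_type_background.setdefault(etype, []).append(eid)
    controls: list[str] = []
    for etype in sorted(by_type_consensus):
        want = by_type_consensus[etype]
        pool = by_type_background.get(etype, [])
        if len(pool) < want:
            log.warning(
                "[W-BG] only %d background %s events for %d consensus ones; "
                "using all of them", len(pool), etype, want,
            )
            controls.extend(pool)
        else:
            controls.extend(rng.choice(pool, size=want, replace=False))
    return sorted(controls)


def filter_peaks(peaks: list[Peak], min_fold: float = 3.0, max_p: float = 1e-5) -> list[Peak]:
    """High-confidence peaks: fold >= 3 and p <= 1e-5, both inclusive."""
    min_nlp = -math.log10(max_p)
    return [
        pk
        for pk in peaks
        if pk.fold_enrichment >= min_fold and pk.neg_log10_p >= min_nlp - 1e-12
    ]


def region_sequences(region_set: EventRegionSet, genome: Genome) -> list[str]:
    return [genome.extract(iv) for iv in region_set.intervals]


def region_has_motif(
    region_set: EventRegionSet,
    motif: PwmMotif,
    genome: Genome,
    scanner: MotifScanner | None = None,
    p_thresh: float = 0.05,
) -> bool:
    """True when any interval's transcript-oriented sequence has >= 1 hit."""
    scanner = scanner or MotifScanner(p_thresh)
    return any(
        scanner.has_hit(seq, motif) for seq in region_sequences(region_set, genome)
    )


def region_has_peak(
    region_set: EventRegionSet,
    peaks: list[Peak],
    strand_aware: bool = False,
) -> bool:
    """True when any interval overlaps any retained peak by >= 1 bp.

    Peak matching is strand-blind by default; ``strand_aware`` restricts
    to peaks annotated on the region's strand.
    """
    for iv in region_set.intervals:
        for pk in peaks:
            if strand_aware and pk.interval.strand != iv.strand:
                continue
            if iv.overlaps(pk.interval):
                return True
    return False


def evidence_tables(
    ase_regions: list[EventRegionSet],
    control_regions: list[EventRegionSet],
    motifs_by_rbp: dict[str, list[PwmMotif]],
    peaks_by_rbp: dict[str, list[Peak]],
    genome: Genome,
    config: AnalysisConfig | None = None,
) -> list[RbpEvidence]:
    """Per-RBP motif and peak 2x2 tables with one-sided Fisher p-values.

    For an RBP with several motifs the smallest motif p-value (and its
    presence pattern) is kept.  RBPs with neither motifs nor peaks are
    excluded.  Peaks are pre-filtered to the high-confidence set.
    """
    config = config or AnalysisConfig()
    scanner = MotifScanner(config.motif_scan_p)
    rbps = sorted(set(motifs_by_rbp) | set(peaks_by_rbp))
    out: list[RbpEvidence] = []
    for rbp in rbps:
        motifs = motifs_by_rbp.get(rbp, [])
        peaks = filter_peaks(
            peaks_by_rbp.get(rbp, []), config.peak_min_fold, config.peak_max_p
        )
        if not motifs and not peaks_by_rbp.get(rbp):
            log.info("[I-NOEVIDENCE] %s has neither motifs nor peaks; skipped", rbp)
            continue
        ev = RbpEvidence(rbp=rbp, has_motif=bool(motifs), has_peaks=bool(peaks_by_rbp.get(rbp)))
        if motifs:
            best_p, best = None, None
            for motif in sorted(motifs, key=lambda m: m.motif_id):
                ase_hit = {
                    rs.event_id
                    for rs in ase_regions
                    if region_has_motif(rs, motif, genome, scanner)
                }
                ctl_hit = {
                    rs.event_id
                    for rs in control_regions
                    if region_has_motif(rs, motif, genome, scanner)
                }
                a = len(ase_hit)
                b = len(ase_regions) - a
                c = len(ctl_hit)
                d = len(control_regions) - c
                _, p = fisher_exact_enrichment(a, b, c, d)
                if best_p is None or p < best_p:
                    best_p, best = p, (motif.motif_id, (a, b, c, d), ase_hit)
            ev.p_motif = best_p
            ev.best_motif_id, ev.motif_table, ev.ase_with_motif = best
        if peaks_by_rbp.get(rbp):
            ase_hit = {
                rs.event_id
                for rs in ase_regions
                if region_has_peak(rs, peaks, config.peak_strand_aware)
            }
            ctl_hit = {
                rs.event_id
                for rs in control_regions
                if region_has_peak(rs, peaks, config.peak_strand_aware)
            }
            a = len(ase_hit)
            b = len(ase_regions) - a
            c = len(ctl_hit)
            d = len(control_regions) - c
            _, p = fisher_exact_enrichment(a, b, c, d)
            ev.p_peak = p
            ev.peak_table = (a, b, c, d)
            ev.ase_with_peak = ase_hit
        out.append(ev)
    return out


def call_enriched_rbps(
    evidence: list[RbpEvidence],
    de_results: pd.DataFrame | None,
    config: AnalysisConfig | None = None,
) -> list[EnrichmentRecord]:
    """Combine motif and peak evidence and nominate candidate regulators.

    Default rule ("combined"): the two channel p-values are combined by
    Fisher's method and by the inverse-normal method, each BH-adjusted
    across RBPs, and an RBP is enriched only when both q-values pass.
    With a single evidence channel the lone p-value passes through both
    combinations.  Alternative rule ("each"): both channels must be
    individually significant after BH adjustment within channel.
    A candidate regulator is an enriched RBP that the DE meta-analysis
    calls consistently down-regulated.
    """
    config = config or AnalysisConfig()
    if not evidence:
        raise ValueError("evidence list is empty")
    down = set()
    if de_results is not None:
        down = set(de_results.loc[de_results["direction"] == "down", "gene"])
    rbps = [ev.rbp for ev in evidence]
    if config.evidence_rule == "combined":
        p1, p2 = [], []
        for ev in evidence:
            ps = [p for p in (ev.p_motif, ev.p_peak) if p is not None]
            p1.append(combine_fisher(ps))
            p2.append(combine_stouffer(ps))
        q1, q2 = bh_adjust(p1), bh_adjust(p2)
    else:  # "each": both channels individually significant
        pm = [ev.p_motif if ev.p_motif is not None else 1.0 for ev in evidence]
        pp = [ev.p_peak if ev.p_peak is not None else 1.0 for ev in evidence]
        p1, p2 = pm, pp
        q1, q2 = bh_adjust(pm), bh_adjust(pp)
    records = []
    for i, ev in enumerate(evidence):
        enriched = bool(q1[i] < config.enrichment_q and q2[i] < config.enrichment_q)
        is_down = ev.rbp in down
        records.append(
            EnrichmentRecord(
                rbp=rbps[i],
                p_combined_fisher=float(p1[i]),
                p_combined_stouffer=float(p2[i]),
                q_fisher=float(q1[i]),
                q_stouffer=float(q2[i]),
                enriched=enriched,
                is_de_down=is_down,
                is_candidate_regulator=bool(enriched and is_down),
            )
        )
    return records


def enrichment_frame(records: list[EnrichmentRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])
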