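"""Event regions, control sampling and dual-evidence RBP enrichment."""

import math

import numpy as np
import pandas as pd
import pytest

from senesplice.binding import (
    build_event_regions,
    call_enriched_rbps,
    evidence_tables,
    filter_peaks,
    region_has_peak,
    sample_control_events,
    RbpEvidence,
)
from senesplice.io import Genome
from senesplice.model import (
    AnalysisConfig,
    GenomicInterval,
    Peak,
    PwmMotif,
    SplicingEvent,
)


def se_event(start, end, strand="+", event_id="EV1", chrom="chr1"):
    return SplicingEvent(event_id, "g1", "SE", (GenomicInterval(chrom, start, end, strand),))


class TestRegionConstruction:
    def test_plus_strand_exon(self):
        regions = build_event_regions(se_event(10000, 10200, "+"))
        got = [(iv.start, iv.end) for iv in regions.intervals]
        assert got == [(9750, 9980), (10000, 10200), (10206, 10450)]

    def test_minus_strand_mirror(self):
        regions = build_event_regions(se_event(10000, 10200, "-"))
        got = [(iv.start, iv.end) for iv in regions.intervals]
        assert got == [(9750, 9994), (10000, 10200), (10220, 10450)]

    def test_total_length_invariant(self):
        for strand in "+-":
            regions = build_event_regions(se_event(5000, 5137, strand))
            total = sum(len(iv) for iv in regions.intervals)
            assert total == 137 + 2 * 250 - 26

    def test_clipped_at_chromosome_start(self):
        regions = build_event_regions(se_event(100, 300, "+"))
        assert regions.intervals[0].start == 0

    def test_clipped_at_chromosome_end(self):
        regions = build_event_regions(
            se_event(700, 900, "+"), chrom_lengths={"chr1": 1000}
        )
        assert regions.intervals[-1].end == 1000

    def test_mxe_contributes_both_segments(self):
        ev = SplicingEvent(
            "M1", "g", "MXE",
            (GenomicInterval("chr1", 10000, 10100, "+"),
             GenomicInterval("chr1", 20000, 20100, "+")),
        )
        regions = build_event_regions(ev)
        assert len(regions.intervals) == 6

    def test_intervals_sorted_non_overlapping(self):
        regions = build_event_regions(se_event(10000, 10200, "+"))
        for a, b in zip(regions.intervals, regions.intervals[1:]):
            assert a.end <= b.start


class TestControlSampling:
    def _events(self):
        events = {}
        for i in range(30):
            events[f"SE{i}"] = se_event(1000 * i + 500, 1000 * i + 600, event_id=f"SE{i}")
        for i in range(5):
            ev = SplicingEvent(
                f"RI{i}", "g", "RI",
                (GenomicInterval("chr2", 1000 * i + 500, 1000 * i + 700, "+"),),
            )
            events[f"RI{i}"] = ev
        return events

    def test_type_matched_counts(self):
        events = self._events()
        consensus = {"SE0", "SE1", "SE2", "RI0"}
        control = sample_control_events(events, consensus, seed=3)
        types = [events[e].event_type for e in control]
        assert types.count("SE") == 3 and types.count("RI") == 1
        assert not set(control) & consensus

    def test_empty_consensus_empty_control(self):
        assert sample_control_events(self._events(), set(), seed=0) == []

    def test_same_seed_identical(self):
        events = self._events()
        consensus = {"SE0", "SE5", "RI1"}
        a = sample_control_events(events, consensus, seed=7)
        b = sample_control_events(events, consensus, seed=7)
        assert a == b

    def test_insufficient_background_takes_all(self):
        events = self._events()
        consensus = {f"RI{i}" for i in range(4)}  # only 1 RI left as background
        control = sample_control_events(events, consensus, seed=1)
        assert control == ["RI4"]


class TestPeakOverlap:
    def test_filter_boundaries_inclusive(self):
        peaks = [
            Peak(GenomicInterval("chr1", 0, 50, "+"), "R", 3.0, 5.0),
            Peak(GenomicInterval("chr1", 0, 50, "+"), "R", 2.99, 9.0),
            Peak(GenomicInterval("chr1", 0, 50, "+"), "R", 9.0, 4.99),
        ]
        kept = filter_peaks(peaks)
        assert len(kept) == 1 and kept[0].fold_enrichment == 3.0

    def test_one_bp_overlap_counts(self):
        from senesplice.binding import EventRegionSet

        region = EventRegionSet("e", (GenomicInterval("chr1", 149, 300, "+"),))
        hit = [Peak(GenomicInterval("chr1", 100, 150, "+"), "R", 5, 9)]
        miss = [Peak(GenomicInterval("chr1", 100, 149, "+"), "R", 5, 9)]
        assert region_has_peak(region, hit)
        assert not region_has_peak(region, miss)

    def test_strand_blind_by_default(self):
        from senesplice.binding import EventRegionSet

        region = EventRegionSet("e", (GenomicInterval("chr1", 100, 200, "+"),))
        peaks = [Peak(GenomicInterval("chr1", 150, 180, "-"), "R", 5, 9)]
        assert region_has_peak(region, peaks)
        assert not region_has_peak(region, peaks, strand_aware=True)


class TestEvidenceTables:
    def _setup(self):
        genome = {"chr1": "A" * 40000}
        motif = PwmMotif(
            "R1", "M1",
            np.array([[0, 1, 0, 0]] * 6, dtype=float),
            np.array([0.25, 0.25, 0.25, 0.25]),
        )
        events = {}
        for i in range(20):
            events[f"E{i}"] = se_event(2000 * i + 600, 2000 * i + 700, event_id=f"E{i}")
        return genome, motif, events

    def test_perfect_motif_separation(self):
        genome, motif, events = self._setup()
        seq = list(genome["chr1"])
        ase_ids = [f"E{i}" for i in range(10)]
        for i in range(10):  # plant CCCCCC inside ASE exons only
            start = 2000 * i + 620
            seq[start : start + 6] = "CCCCCC"
        genome = Genome({"chr1": "".join(seq)})
        ase = [build_event_regions(events[e]) for e in ase_ids]
        ctl = [build_event_regions(events[f"E{i}"]) for i in range(10, 20)]
        ev = evidence_tables(ase, ctl, {"R1": [motif]}, {}, genome)
        assert ev[0].motif_table == (10, 0, 0, 10)
        assert ev[0].p_motif == pytest.approx(1 / 184756, rel=1e-9)
        assert ev[0].ase_with_motif == set(ase_ids)

    def test_motif_everywhere_gives_p_one(self):
        genome, motif, events = self._setup()
        seq = list(genome["chr1"])
        for i in range(20):
            start = 2000 * i + 620
            seq[start : start + 6] = "CCCCCC"
        genome = Genome({"chr1": "".join(seq)})
        ase = [build_event_regions(events[f"E{i}"]) for i in range(10)]
        ctl = [build_event_regions(events[f"E{i}"]) for i in range(10, 20)]
        ev = evidence_tables(ase, ctl, {"R1": [motif]}, {}, genome)
        assert ev[0].p_motif == pytest.approx(1.0)

    def test_smallest_motif_p_kept(self):
        genome, motif, events = self._setup()
        seq = list(genome["chr1"])
        for i in range(10):
            start = 2000 * i + 620
            seq[start : start + 6] = "CCCCCC"
        genome = Genome({"chr1": "".join(seq)})
        weak = PwmMotif(
            "R1", "M_weak",
            np.array([[0, 0, 0, 1]] * 6, dtype=float),
        )
        ase = [build_event_regions(events[f"E{i}"]) for i in range(10)]
        ctl = [build_event_regions(events[f"E{i}"]) for i in range(10, 20)]
        ev = evidence_tables(ase, ctl, {"R1": [weak, motif]}, {}, genome)
        assert ev[0].best_motif_id == "M1"
        assert ev[0].p_motif == pytest.approx(1 / 184756, rel=1e-9)


class TestCallEnriched:
    def _de(self, down=()):
        genes = [f"R{i}" for i in range(1, 4)]
        return pd.DataFrame(
            {"gene": genes, "direction": ["down" if g in down else "none" for g in genes]}
        )

    def test_single_rbp_closed_forms(self):
        ev = [RbpEvidence("R1", True, True, p_motif=0.05, p_peak=0.05)]
        recs = call_enriched_rbps(ev, self._de(down=("R1",)))
        r = recs[0]
        assert r.p_combined_fisher == pytest.approx(0.01748, abs=5e-6)
        assert r.p_combined_stouffer == pytest.approx(0.010005, abs=1e-5)
        assert r.q_fisher == pytest.approx(r.p_combined_fisher)
        assert r.enriched and r.is_candidate_regulator

    def test_enriched_but_not_down_is_no_candidate(self):
        ev = [RbpEvidence("R1", True, True, p_motif=1e-6, p_peak=1e-6)]
        recs = call_enriched_rbps(ev, self._de(down=()))
        assert recs[0].enriched and not recs[0].is_candidate_regulator

    def test_single_evidence_passes_through(self):
        ev = [RbpEvidence("R1", True, False, p_motif=0.004)]
        recs = call_enriched_rbps(ev, self._de())
        assert recs[0].p_combined_fisher == pytest.approx(0.004)
        assert recs[0].p_combined_stouffer == pytest.approx(0.004)

    def test_each_rule_requires_both_channels(self):
        cfg = AnalysisConfig(evidence_rule="each")
        ev = [RbpEvidence("R1", True, True, p_motif=1e-6, p_peak=0.9)]
        recs = call_enriched_rbps(ev, self._de(), cfg)
        assert not recs[0].enriched

    def test_empty_evidence_rejected(self):
        with pytest.raises(ValueError):
            call_enriched_rbps([], self._de())
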