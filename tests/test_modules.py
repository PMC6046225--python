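"""Regulatory modules: target assignment, GO enrichment, kappa classes."""

import numpy as np
import pandas as pd
import pytest

from senesplice.binding import RbpEvidence
from senesplice.model import GeneSet, GenomicInterval, SplicingEvent
from senesplice.modules import assign_targets, cluster_terms, go_enrichment, kappa


def event(eid, gene):
    return SplicingEvent(eid, gene, "SE", (GenomicInterval("chr1", 100, 200, "+"),))


class TestAssignTargets:
    def test_peak_only_evidence_assigns(self):
        ev = RbpEvidence("R1", False, True, ase_with_peak={"e1"})
        mods = assign_targets(["R1"], {"e1", "e2"}, {"e1": event("e1", "gA"), "e2": event("e2", "gB")}, [ev])
        assert mods["R1"].target_events == {"e1"}
        assert mods["R1"].target_genes == {"gA"}

    def test_no_evidence_empty_module(self):
        mods = assign_targets(["R1"], {"e1"}, {"e1": event("e1", "gA")}, [])
        assert mods["R1"].target_events == set()

    def test_union_of_motif_and_peak(self):
        ev = RbpEvidence("R1", True, True, ase_with_motif={"e1"}, ase_with_peak={"e2"})
        mods = assign_targets(
            ["R1"], {"e1", "e2"},
            {"e1": event("e1", "gA"), "e2": event("e2", "gB")}, [ev],
        )
        assert mods["R1"].target_events == {"e1", "e2"}


class TestGoEnrichment:
    def test_hand_example(self):
        universe = {f"g{i}" for i in range(100)}
        term = GeneSet("GO:1", "t", frozenset(f"g{i}" for i in range(10)))
        gene_list = {f"g{i}" for i in range(5)} | {f"g{i}" for i in range(50, 55)}
        res = go_enrichment(gene_list, [term], universe)
        assert res["overlap"].iloc[0] == 5
        assert res["p"].iloc[0] == pytest.approx(6.716e-4, rel=1e-3)

    def test_list_equals_universe_term_p_one(self):
        universe = {f"g{i}" for i in range(20)}
        term = GeneSet("GO:1", "t", frozenset(universe))
        res = go_enrichment(universe, [term], universe)
        assert res["p"].iloc[0] == pytest.approx(1.0)

    def test_zero_overlap_p_one(self):
        universe = {f"g{i}" for i in range(20)}
        term = GeneSet("GO:1", "t", frozenset({"g0", "g1"}))
        res = go_enrichment({"g10", "g11"}, [term], universe)
        assert res["p"].iloc[0] == pytest.approx(1.0)

    def test_matches_enumeration_oracle(self):
        import math

        rng = np.random.default_rng(8)
        universe = [f"g{i}" for i in range(60)]
        for _ in range(20):
            term = set(rng.choice(universe, size=12, replace=False))
            lst = set(rng.choice(universe, size=15, replace=False))
            res = go_enrichment(lst, [GeneSet("GO:x", "t", frozenset(term))], set(universe))
            k = len(term & lst)
            oracle = sum(
                math.comb(12, x) * math.comb(48, 15 - x) / math.comb(60, 15)
                for x in range(k, 13)
                if 15 - x <= 48
            )
            assert res["p"].iloc[0] == pytest.approx(oracle, abs=1e-10)


class TestKappa:
    def test_identical_sets(self):
        universe = {f"g{i}" for i in range(50)}
        a = frozenset(f"g{i}" for i in range(10))
        assert kappa(a, a, universe) == pytest.approx(1.0)

    def test_hand_example(self):
        universe = {f"g{i}" for i in range(100)}
        a = frozenset(f"g{i}" for i in range(20))
        b = frozenset(f"g{i}" for i in range(10, 30))
        # Po = 0.8, Pe = 0.68, kappa = 0.375
        assert kappa(a, b, universe) == pytest.approx(0.375, abs=1e-12)

    def test_complement_is_negative(self):
        universe = {f"g{i}" for i in range(40)}
        a = frozenset(f"g{i}" for i in range(15))
        b = frozenset(universe - a)
        assert kappa(a, b, universe) < 0

    def test_symmetric_and_bounded(self):
        rng = np.random.default_rng(2)
        universe = {f"g{i}" for i in range(30)}
        names = sorted(universe)
        for _ in range(20):
            a = frozenset(rng.choice(names, size=rng.integers(1, 25), replace=False))
            b = frozenset(rng.choice(names, size=rng.integers(1, 25), replace=False))
            kab = kappa(a, b, universe)
            assert kab == pytest.approx(kappa(b, a, universe), abs=1e-12)
            assert -1 - 1e-9 <= kab <= 1 + 1e-9

    def test_degenerate_universe_terms(self):
        universe = {f"g{i}" for i in range(10)}
        full = frozenset(universe)
        assert kappa(full, full, universe) == 1.0


class TestClusterTerms:
    def _frame(self, ids, ps):
        return pd.DataFrame({"set_id": ids, "name": ids, "overlap": 1,
                             "term_size": 5, "p": ps, "q": ps})

    def test_all_dissimilar_terms_singletons(self):
        universe = {f"g{i}" for i in range(60)}
        sets = [
            GeneSet(f"T{i}", f"T{i}", frozenset(f"g{j}" for j in range(10 * i, 10 * i + 10)))
            for i in range(4)
        ]
        out = cluster_terms(self._frame([s.set_id for s in sets], [0.01] * 4), sets, universe)
        assert out["class_id"].nunique() == 4
        assert out["is_representative"].all()

    def test_transitive_closure_chain(self):
        universe = {f"g{i}" for i in range(30)}
        a = GeneSet("A", "A", frozenset(f"g{i}" for i in range(0, 10)))
        b = GeneSet("B", "B", frozenset(f"g{i}" for i in range(5, 15)))
        c = GeneSet("C", "C", frozenset(f"g{i}" for i in range(10, 20)))
        assert kappa(a, c, universe) <= 0.05 < min(kappa(a, b, universe), kappa(b, c, universe))
        out = cluster_terms(self._frame(["A", "B", "C"], [0.01, 0.02, 0.03]), [a, b, c], universe)
        assert out["class_id"].nunique() == 1

    def test_top_k_representatives_by_p(self):
        universe = {f"g{i}" for i in range(20)}
        base = [f"g{i}" for i in range(10)]
        sets = [GeneSet(f"T{i}", f"T{i}", frozenset(base)) for i in range(5)]
        out = cluster_terms(
            self._frame([s.set_id for s in sets], [0.05, 0.01, 0.04, 0.02, 0.03]),
            sets, universe, top_k=3,
        )
        reps = set(out.loc[out["is_representative"], "set_id"])
        assert reps == {"T1", "T3", "T4"}

    def test_order_invariance(self):
        universe = {f"g{i}" for i in range(30)}
        sets = [
            GeneSet("A", "A", frozenset(f"g{i}" for i in range(0, 10))),
            GeneSet("B", "B", frozenset(f"g{i}" for i in range(5, 15))),
            GeneSet("C", "C", frozenset(f"g{i}" for i in range(20, 30))),
        ]
        f1 = self._frame(["A", "B", "C"], [0.01, 0.02, 0.03])
        f2 = self._frame(["C", "B", "A"], [0.03, 0.02, 0.01])
        o1 = cluster_terms(f1, sets, universe).set_index("set_id")
        o2 = cluster_terms(f2, sets, universe).set_index("set_id")
        for sid_a in "ABC":
            for sid_b in "ABC":
                assert (o1.loc[sid_a, "class_id"] == o1.loc[sid_b, "class_id"]) == (
                    o2.loc[sid_a, "class_id"] == o2.loc[sid_b, "class_id"]
                )
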