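"""Regulatory-module construction: target assignment, GO enrichment and
kappa-based collapsing of redundant terms.

An event is a target of a candidate RBP when its region set carries that
RBP's motif hit or overlaps its retained peaks.  Term enrichment is a
one-sided hypergeometric test with BH adjustment; redundant terms are
grouped by Cohen's kappa on their membership vectors (pairs with kappa
above the threshold share a class, classes are connected components) and
only the top terms per class are reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .binding import RbpEvidence
from .model import GeneSet, SplicingEvent
from .stats import bh_adjust, hypergeom_sf

log = logging.getLogger("senesplice")


@dataclass
class RegulatoryModule:
    rbp: str
    target_events: set[str]
    target_genes: set[str]
    enriched_terms: list[tuple[str, float, float, int, bool]] = field(
        default_factory=list
    )  # (set_id, p, q, class id, is representative)


def assign_targets(
    candidate_rbps: list[str],
    consensus_events: set[str],
    events_by_id: dict[str, SplicingEvent],
    evidence: list[RbpEvidence],
) -> dict[str, RegulatoryModule]:
    """Assign consensus events to candidate RBPs by binding evidence.

    Motif OR peak presence in the event's regions suffices.
    """
    by_rbp = {ev.rbp: ev for ev in evidence}
    modules: dict[str, RegulatoryModule] = {}
    for rbp in sorted(candidate_rbps):
        ev = by_rbp.get(rbp)
        targets = set()
        if ev is not None:
            targets = (ev.ase_with_motif | ev.ase_with_peak) & consensus_events
        if not targets:
            log.warning("[W-EMPTYMODULE] candidate %s has no target events", rbp)
        genes = {events_by_id[eid].gene for eid in targets}
        modules[rbp] = RegulatoryModule(rbp=rbp, target_events=targets, target_genes=genes)
    return modules


def go_enrichment(
    gene_list: set[str],
    gene_sets: list[GeneSet],
    universe: set[str],
) -> pd.DataFrame:
    """One-sided hypergeometric enrichment of each term in ``gene_list``.

    Terms are intersected with the universe first; BH adjustment is
    applied across terms.
    """
    gene_list = set(gene_list) & universe
    rows = []
    for gs in sorted(gene_sets, key=lambda s: s.set_id):
        term = gs.genes & universe
        if not term:
            continue
        overlap = len(gene_list & term)
        p = hypergeom_sf(overlap, len(universe), len(term), len(gene_list))
        rows.append({"set_id": gs.set_id, "name": gs.name, "overlap": overlap,
                     "term_size": len(term), "p": p})
    df = pd.DataFrame(rows, columns=["set_id", "name", "overlap", "term_size", "p"])
    df["q"] = bh_adjust(df["p"]) if len(df) else []
    return df


def kappa(term_a: GeneSet | frozenset, term_b: GeneSet | frozenset, universe: set[str]) -> float:
    """Cohen's kappa between two term memberships over the gene universe.

    kappa = (Po - Pe) / (1 - Pe) on the 2x2 agreement table of the two
    indicator vectors; defined as 1 when Pe = 1 (both terms equal the
    whole universe).
    """
    a = (term_a.genes if isinstance(term_a, GeneSet) else set(term_a)) & universe
    b = (term_b.genes if isinstance(term_b, GeneSet) else set(term_b)) & universe
    n = len(universe)
    if n == 0:
        raise ValueError("empty universe")
    both = len(a & b)
    only_a = len(a - b)
    only_b = len(b - a)
    neither = n - both - only_a - only_b
    po = (both + neither) / n
    pa, pb = len(a) / n, len(b) / n
    pe = pa * pb + (1 - pa) * (1 - pb)
    if pe >= 1.0:
        return 1.0
    return (po - pe) / (1 - pe)


def cluster_terms(
    enriched: pd.DataFrame,
    gene_sets: list[GeneSet],
    universe: set[str],
    kappa_thresh: float = 0.05,
    top_k: int = 3,
) -> pd.DataFrame:
    """Group enriched terms into kappa classes and mark representatives.

    Pairs with kappa strictly above ``kappa_thresh`` share a class;
    classes are the connected components of that graph (single-linkage
    transitive closure).  Within a class the ``top_k`` terms by ascending
    p (ties by term id) are flagged as representatives.
    """
    sets_by_id = {gs.set_id: gs for gs in gene_sets}
    ids = list(enriched["set_id"])
    graph = nx.Graph()
    graph.add_nodes_from(ids)
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            if kappa(sets_by_id[a], sets_by_id[b], universe) > kappa_thresh:
                graph.add_edge(a, b)
    class_of: dict[str, int] = {}
    components = sorted(nx.connected_components(graph), key=lambda c: min(c))
    for ci, comp in enumerate(components, start=1):
        for sid in comp:
            class_of[sid] = ci
    df = enriched.copy()
    df["class_id"] = [class_of[s] for s in df["set_id"]]
    df["is_representative"] = False
    for ci in sorted(set(class_of.values())):
        members = df[df["class_id"] == ci].sort_values(["p", "set_id"], kind="stable")
        keep = members.head(top_k).index
        df.loc[keep, "is_representative"] = True
    return df
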