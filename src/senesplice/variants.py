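"""Map phenotype-annotated variants onto consensus-event regions.

A variant (1-based position) maps to an event when its 0-based position
falls inside any interval of that event's region set; one variant may
hit several events.  The per-gene summary counts each distinct variant
once per gene.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .binding import EventRegionSet
from .model import SplicingEvent, VariantRecord


@dataclass(frozen=True)
class VariantHit:
    variant: VariantRecord
    event_id: str


def map_variants(
    variants: list[VariantRecord], region_sets: list[EventRegionSet]
) -> list[VariantHit]:
    hits = []
    for v in variants:
        for rs in region_sets:
            if any(
                iv.chrom == v.chrom and iv.contains_point(v.pos0)
                for iv in rs.intervals
            ):
                hits.append(VariantHit(v, rs.event_id))
    return hits


def summarize_variants(
    hits: list[VariantHit], events_by_id: dict[str, SplicingEvent]
) -> tuple[pd.DataFrame, int, int]:
    """Per-gene distinct-variant counts plus (n_variants_total, n_genes).

    A variant hitting two events of the same gene counts once for that
    gene; ``n_variants_total`` is the number of distinct mapped variants.
    """
    per_gene: dict[str, set] = {}
    all_variants = set()
    for h in hits:
        gene = events_by_id[h.event_id].gene
        key = (h.variant.chrom, h.variant.pos, h.variant.ref, h.variant.alt)
        per_gene.setdefault(gene, set()).add(key)
        all_variants.add(key)
    df = pd.DataFrame(
        [{"gene": g, "n_variants": len(v)} for g, v in sorted(per_gene.items())],
        columns=["gene", "n_variants"],
    )
    return df, len(all_variants), len(per_gene)


def hits_frame(
    hits: list[VariantHit], events_by_id: dict[str, SplicingEvent]
) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": h.variant.chrom,
                "pos": h.variant.pos,
                "ref": h.variant.ref,
                "alt": h.variant.alt,
                "event_id": h.event_id,
                "gene": events_by_id[h.event_id].gene,
                "phenotype": h.variant.phenotype,
            }
            for h in hits
        ],
        columns=["chrom", "pos", "ref", "alt", "event_id", "gene", "phenotype"],
    )
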