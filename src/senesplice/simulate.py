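"""Synthetic study generator with planted ground truth.

Emulates the structure of a multi-experiment senescence study: ~14
two-group RNA-seq experiments with shared differentially expressed
genes (including a down-regulated RBP subset), rMATS-like splicing
event tables with a planted consensus-differential subset, an AT-rich
genome carrying RBP motifs planted preferentially in true event
regions, eCLIP-style peaks over a fraction of the planted sites, and
per-RBP knockdown event tables whose differential events overlap the
consensus set preferentially for the true regulators.

Counts are negative binomial with experiment size factors and
per-experiment batch effects; inclusion counts are beta-binomial so the
per-sample PSI carries biological overdispersion.  The p-values written
into event tables come from a documented internal test (two-sided
continuity-corrected two-proportion z on pooled inclusion fractions) —
the pipeline's contract is "consumes rMATS-like tables", not the rMATS
likelihood model.

Every generator is deterministic under a fixed seed; independent
substreams are derived from the master seed via ``SeedSequence`` spawn
keys (one fixed integer key per generator).
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np

from . import io as sio
from .binding import build_event_regions
from .model import (
    AnalysisConfig,
    EventStatRecord,
    ExperimentTable,
    GeneSet,
    GenomicInterval,
    Peak,
    PwmMotif,
    SplicingEvent,
    VariantRecord,
)
from .stats import bh_adjust, two_proportion_z

# spawn keys for independent substreams
_K_EXPERIMENTS = 1
_K_EVENTS = 2
_K_BINDING = 3
_K_KNOCKDOWN = 4
_K_VARIANTS = 5
_K_GENESETS = 6


@dataclass
class StudyTruth:
    """Planted ground truth; consumed only by tests and benchmarks."""

    de_up: set[str] = field(default_factory=set)
    de_down: set[str] = field(default_factory=set)
    true_events: set[str] = field(default_factory=set)
    true_regulators: set[str] = field(default_factory=set)
    rbp_is_down: dict[str, bool] = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "de_up": sorted(self.de_up),
                    "de_down": sorted(self.de_down),
                    "true_events": sorted(self.true_events),
                    "true_regulators": sorted(self.true_regulators),
                    "rbp_is_down": dict(sorted(self.rbp_is_down.items())),
                },
                fh,
                indent=1,
            )

    @classmethod
    def from_json(cls, path) -> "StudyTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            de_up=set(d["de_up"]),
            de_down=set(d["de_down"]),
            true_events=set(d["true_events"]),
            true_regulators=set(d["true_regulators"]),
            rbp_is_down={k: bool(v) for k, v in d["rbp_is_down"].items()},
        )


@dataclass
class SimulationParams:
    """Study conditions for the synthetic cohort.

    ``n_genes`` counts the whole gene universe; the last ``n_rbps`` genes
    are the RBPs (named RBP01..).  All probabilities are in [0, 1].
    """

    n_experiments: int = 14
    group_size_choices: tuple[int, ...] = (2, 3, 4)
    # draw weights over the choices; the published cohort averages ~3.4
    # replicates per group (51 + 44 samples over 14 comparisons)
    group_size_probs: tuple[float, ...] = (0.05, 0.25, 0.7)
    n_genes: int = 2000
    n_rbps: int = 20
    fraction_de: float = 0.1
    log2_effect: float = 1.0  # 2-fold
    nb_dispersion: float = 0.03
    base_mean_log_mean: float = 5.0  # ln scale, ~150 reads
    base_mean_log_sd: float = 1.0
    # splicing RBPs are abundant transcripts; their baseline expression
    # is drawn higher and tighter than the bulk of the transcriptome
    rbp_base_mean_log_mean: float = 6.5
    rbp_base_mean_log_sd: float = 0.5
    size_factor_log_sd: float = 0.3
    batch_log_sd: float = 0.2
    rbp_down_fraction: float = 0.25
    n_true_regulators: int = 3
    # splicing events
    n_events: int = 400
    event_type_props: tuple[float, ...] = (0.6, 0.1, 0.1, 0.1, 0.1)  # SE A5SS A3SS MXE RI
    consensus_fraction: float = 0.15
    n_affected_experiments: int = 6
    dpsi_effect: float = 0.2
    bb_concentration: float = 75.0
    coverage_mean: float = 50.0
    event_spacing: int = 2000
    # binding landscape
    genome_base_probs: tuple[float, ...] = (0.375, 0.125, 0.125, 0.375)  # A C G T
    motif_k: int = 14
    motif_sharpness: float = 0.985
    motif_background: tuple[float, ...] = (0.08, 0.42, 0.42, 0.08)  # A C G T
    motif_min_distance: int = 5  # pairwise Hamming distance of consensi
    motif_plant_rate_true: float = 0.6
    motif_plant_rate_bg: float = 0.05
    peak_rate: float = 0.5  # fraction of planted sites covered by a peak
    peak_width: int = 50
    n_decoy_peaks_per_rbp: int = 20
    # knockdown screens
    kd_p_hit: float = 0.5
    kd_p_bg: float = 0.05
    kd_dpsi_effect: float = 0.3
    kd_group_size: int = 3
    # variants / gene sets
    n_variants: int = 60
    n_gene_sets: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "fraction_de",
            "rbp_down_fraction",
            "consensus_fraction",
            "motif_plant_rate_true",
            "motif_plant_rate_bg",
            "peak_rate",
            "kd_p_hit",
            "kd_p_bg",
        ):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("nb_dispersion", "bb_concentration", "coverage_mean"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if abs(sum(self.event_type_props) - 1) > 1e-9:
            raise ValueError("event_type_props must sum to 1")
        if abs(sum(self.genome_base_probs) - 1) > 1e-9:
            raise ValueError("genome_base_probs must sum to 1")
        if self.n_rbps > self.n_genes:
            raise ValueError("n_rbps cannot exceed n_genes")

    def rng(self, key: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=(key,)))


def gene_names(params: SimulationParams) -> tuple[list[str], list[str]]:
    """(all genes, rbp genes); RBPs are the tail of the universe."""
    n_plain = params.n_genes - params.n_rbps
    plain = [f"G{i + 1:05d}" for i in range(n_plain)]
    rbps = [f"RBP{i + 1:02d}" for i in range(params.n_rbps)]
    return plain + rbps, rbps


# ------------------------------------------------------------ experiments


def simulate_experiments(
    params: SimulationParams,
) -> tuple[list[ExperimentTable], StudyTruth]:
    """Negative-binomial count matrices with consistent planted DE genes."""
    rng = params.rng(_K_EXPERIMENTS)
    genes, rbps = gene_names(params)
    n = params.n_genes
    truth = StudyTruth()
    n_down_rbp = int(round(params.rbp_down_fraction * params.n_rbps))
    down_rbps = sorted(map(str, rng.choice(rbps, size=n_down_rbp, replace=False))) if n_down_rbp else []
    truth.rbp_is_down = {r: (r in set(down_rbps)) for r in rbps}
    n_reg = min(params.n_true_regulators, len(down_rbps))
    truth.true_regulators = set(
        map(str, rng.choice(down_rbps, size=n_reg, replace=False))
    ) if n_reg else set()
    n_de = int(round(params.fraction_de * n))
    n_de_plain = max(n_de - len(down_rbps), 0)
    plain = [g for g in genes if g not in set(rbps)]
    chosen = [str(g) for g in rng.choice(plain, size=min(n_de_plain, len(plain)), replace=False)]
    half = len(chosen) // 2
    truth.de_up = set(chosen[:half])
    truth.de_down = set(chosen[half:]) | set(down_rbps)
    if params.log2_effect == 0 or params.fraction_de == 0:
        # global null: nothing is planted even if sets were drawn
        truth.de_up, truth.de_down = set(), set()
        truth.rbp_is_down = {r: False for r in rbps}
        truth.true_regulators = set()
    base_mean = rng.lognormal(params.base_mean_log_mean, params.base_mean_log_sd, size=n)
    rbp_mask = np.array([g in set(rbps) for g in genes])
    base_mean[rbp_mask] = rng.lognormal(
        params.rbp_base_mean_log_mean, params.rbp_base_mean_log_sd, size=int(rbp_mask.sum())
    )
    base_mean = np.maximum(base_mean, 5.0)
    effect = np.zeros(n)
    for i, g in enumerate(genes):
        if g in truth.de_up:
            effect[i] = params.log2_effect
        elif g in truth.de_down:
            effect[i] = -params.log2_effect
    tables = []
    for e in range(params.n_experiments):
        n_sen = int(rng.choice(params.group_size_choices, p=params.group_size_probs))
        n_gro = int(rng.choice(params.group_size_choices, p=params.group_size_probs))
        group = ["senescent"] * n_sen + ["growing"] * n_gro
        samples = [f"S{j + 1}" for j in range(n_sen)] + [f"C{j + 1}" for j in range(n_gro)]
        batch = rng.lognormal(0.0, params.batch_log_sd, size=n)
        sf = rng.lognormal(0.0, params.size_factor_log_sd, size=n_sen + n_gro)
        mean = base_mean[:, None] * batch[:, None] * sf[None, :]
        sen_cols = np.array([g == "senescent" for g in group])
        mean[:, sen_cols] *= 2.0 ** effect[:, None]
        if params.nb_dispersion > 0:
            shape = 1.0 / params.nb_dispersion
            lam = rng.gamma(shape, mean / shape)
            counts = rng.poisson(lam)
        else:
            counts = rng.poisson(mean)
        tables.append(
            ExperimentTable(
                experiment_id=f"EXP{e + 1:02d}",
                genes=list(genes),
                samples=samples,
                counts=counts.astype(np.int64),
                group=group,
                cell_type=f"cell{e % 5}",
                induction=("replicative", "oncogene", "drug")[e % 3],
            )
        )
    return tables, truth


# ----------------------------------------------------------------- events


@dataclass
class EventLayout:
    """Events plus their baseline inclusion levels (internal bookkeeping)."""

    events: list[SplicingEvent]
    base_psi: dict[str, float]
    chrom_length: int


def layout_events(params: SimulationParams, rng: np.random.Generator) -> EventLayout:
    """Place non-overlapping events along one synthetic chromosome.

    Spacing guarantees that flanked event regions (250 bp each side)
    never collide between neighbouring events.
    """
    genes, rbps = gene_names(params)
    plain = [g for g in genes if not g.startswith("RBP")]
    types = np.array(["SE", "A5SS", "A3SS", "MXE", "RI"])
    props = np.asarray(params.event_type_props)
    events = []
    base_psi = {}
    pos = 1000
    for i in range(params.n_events):
        etype = str(rng.choice(types, p=props))
        strand = "+" if rng.random() < 0.5 else "-"
        gene = str(rng.choice(plain))
        length = int(rng.integers(100, 301))
        segs = [GenomicInterval("chr1", pos, pos + length, strand)]
        if etype == "MXE":
            length2 = int(rng.integers(100, 301))
            segs.append(GenomicInterval("chr1", pos + length + 600, pos + length + 600 + length2, strand))
        eid = f"EV{i + 1:04d}"
        events.append(SplicingEvent(eid, gene, etype, tuple(segs)))
        base_psi[eid] = float(rng.uniform(0.25, 0.75))
        pos += params.event_spacing + (600 + 300 if etype == "MXE" else 0)
    return EventLayout(events, base_psi, chrom_length=pos + 1000)


def _event_record(
    rng: np.random.Generator,
    event_id: str,
    experiment_id: str,
    mu_sen: float,
    mu_gro: float,
    n_sen: int,
    n_gro: int,
    params: SimulationParams,
) -> tuple[EventStatRecord, float]:
    """One beta-binomial event record; returns (record, raw p)."""
    c = params.bb_concentration
    def draw(mu, m):
        if c > 0:
            psi = rng.beta(mu * c, (1 - mu) * c, size=m)
        else:
            psi = np.full(m, mu)
        tot = rng.poisson(params.coverage_mean, size=m)
        inc = rng.binomial(tot, psi)
        return inc, tot - inc
    inc_s, skip_s = draw(mu_sen, n_sen)
    inc_g, skip_g = draw(mu_gro, n_gro)
    def mean_psi(inc, skip):
        tot = inc + skip
        ok = tot > 0
        if not np.any(ok):
            return np.nan
        return float(np.mean(inc[ok] / tot[ok]))
    ms, mg = mean_psi(inc_s, skip_s), mean_psi(inc_g, skip_g)
    dpsi = 0.0 if (np.isnan(ms) or np.isnan(mg)) else ms - mg
    p = two_proportion_z(
        inc_s.sum(), (inc_s + skip_s).sum(), inc_g.sum(), (inc_g + skip_g).sum()
    )
    rec = EventStatRecord(
        event_id=event_id,
        experiment_id=experiment_id,
        inc_counts_sen=inc_s,
        skip_counts_sen=skip_s,
        inc_counts_gro=inc_g,
        skip_counts_gro=skip_g,
        delta_psi=dpsi,
        p=p,
        fdr=p,  # replaced by BH below
    )
    return rec, p


def simulate_event_tables(
    params: SimulationParams,
    truth: StudyTruth,
    experiments: list[ExperimentTable],
) -> tuple[dict[str, list[tuple[SplicingEvent, EventStatRecord]]], EventLayout]:
    """Per-experiment rMATS-like tables with a planted consensus subset.

    Fills ``truth.true_events``.  True events get a PSI shift of
    ``dpsi_effect`` (consistent sign) in ``n_affected_experiments``
    randomly chosen experiments; all other event/experiment combinations
    are exchangeable between the groups.
    """
    rng = params.rng(_K_EVENTS)
    layout = layout_events(params, rng)
    n_true = int(round(params.consensus_fraction * params.n_events))
    ids = [ev.event_id for ev in layout.events]
    true_ids = sorted(map(str, rng.choice(ids, size=n_true, replace=False))) if n_true else []
    if params.dpsi_effect == 0:
        true_ids = []
    truth.true_events = set(true_ids)
    signs = {eid: (1 if rng.random() < 0.5 else -1) for eid in true_ids}
    affected: dict[str, set[str]] = {}
    expt_ids = [t.experiment_id for t in experiments]
    for eid in true_ids:
        k = min(params.n_affected_experiments, len(expt_ids))
        affected[eid] = set(rng.choice(expt_ids, size=k, replace=False))
    tables: dict[str, list[tuple[SplicingEvent, EventStatRecord]]] = {}
    for table in experiments:
        n_sen, n_gro = table.n_sen, table.n_gro
        pairs = []
        raw_p = []
        for ev in layout.events:
            mu = layout.base_psi[ev.event_id]
            mu_sen = mu
            if ev.event_id in truth.true_events and table.experiment_id in affected[ev.event_id]:
                mu_sen = float(np.clip(mu + signs[ev.event_id] * params.dpsi_effect, 0.02, 0.98))
            rec, p = _event_record(
                rng, ev.event_id, table.experiment_id, mu_sen, mu, n_sen, n_gro, params
            )
            pairs.append((ev, rec))
            raw_p.append(p)
        fdr = bh_adjust(raw_p)
        for (ev, rec), q in zip(pairs, fdr):
            rec.fdr = float(q)
        tables[table.experiment_id] = pairs
    return tables, layout


# ---------------------------------------------------------------- binding


def _consensus_code(
    rng: np.random.Generator, n_words: int, k: int, min_distance: int
) -> list[str]:
    """Greedy random GC-alphabet code with pairwise Hamming distance
    >= ``min_distance``, so no RBP's planted site can score as a hit for
    another RBP's motif.
    """
    # deterministic binary lexicode base; Hamming distance is invariant
    # under XOR with a random mask and a random permutation of positions,
    # which gives seed-dependent variety
    base: list[np.ndarray] = []
    for value in range(2**k):
        cand = np.array([(value >> j) & 1 for j in range(k)], dtype=np.int8)
        if all(int(np.sum(cand != w)) >= min_distance for w in base):
            base.append(cand)
        if len(base) >= n_words:
            break
    if len(base) < n_words:
        raise RuntimeError(
            f"cannot build {n_words} motif consensi of length {k} at "
            f"distance {min_distance}"
        )
    mask = rng.integers(0, 2, size=k)
    perm = rng.permutation(k)
    order = rng.permutation(n_words)
    words = [(base[i] ^ mask)[perm] for i in order]
    return ["".join("CG"[int(b)] for b in w) for w in words]


def _motif_from_consensus(consensus: str, rbp: str, params: SimulationParams) -> PwmMotif:
    """A sharp PWM around the consensus, with a GC-rich stated background.

    The scan's score p-value is computed under the motif's own background
    model, which keeps nominal p <= 0.05 hits close to exact consensus
    matches in the AT-rich genome.
    """
    bases = "ACGT"
    mat = np.full((len(consensus), 4), (1 - params.motif_sharpness) / 3)
    for j, ch in enumerate(consensus):
        mat[j, bases.index(ch)] = params.motif_sharpness
    return PwmMotif(
        rbp=rbp,
        motif_id=f"M_{rbp}",
        matrix=mat,
        background=np.array(params.motif_background),
    )


_RC = str.maketrans("ACGT", "TGCA")


def simulate_binding_landscape(
    params: SimulationParams,
    layout: EventLayout,
    truth: StudyTruth,
    config: AnalysisConfig | None = None,
) -> tuple[sio.Genome, list[PwmMotif], list[Peak]]:
    """AT-rich i.i.d. genome with motifs planted into event regions.

    True regulators' consensus sequences are planted in a fraction
    ``motif_plant_rate_true`` of true-event region sets and
    ``motif_plant_rate_bg`` of the others; every other RBP is planted at
    the background rate everywhere.  A fraction ``peak_rate`` of planted
    sites is covered by a high-confidence peak (fold >= 3, p <= 1e-5);
    decoy peaks below those thresholds are scattered per RBP.
    """
    rng = params.rng(_K_BINDING)
    config = config or AnalysisConfig()
    _, rbps = gene_names(params)
    seq = rng.choice(list("ACGT"), size=layout.chrom_length, p=params.genome_base_probs)
    codes = _consensus_code(rng, len(rbps), params.motif_k, params.motif_min_distance)
    motifs, consensus_of = [], {}
    for rbp, cons in zip(rbps, codes):
        motifs.append(_motif_from_consensus(cons, rbp, params))
        consensus_of[rbp] = cons
    chrom_lengths = {"chr1": layout.chrom_length}
    regions = {
        ev.event_id: build_event_regions(
            ev, config.flank, config.donor_exclusion, config.acceptor_exclusion, chrom_lengths
        )
        for ev in layout.events
    }
    peaks: list[Peak] = []
    for rbp in rbps:
        cons = consensus_of[rbp]
        for ev in layout.events:
            is_true_target = rbp in truth.true_regulators and ev.event_id in truth.true_events
            rate = params.motif_plant_rate_true if is_true_target else params.motif_plant_rate_bg
            if rng.random() >= rate:
                continue
            region = regions[ev.event_id]
            iv = region.intervals[int(rng.integers(len(region.intervals)))]
            if len(iv) <= params.motif_k + 2:
                continue
            off = int(rng.integers(1, len(iv) - params.motif_k - 1))
            start = iv.start + off
            planted = cons if iv.strand == "+" else cons.translate(_RC)[::-1]
            # masked (N) guard bases delimit each planted site, so a scan
            # window can only cover the site in exact register; together
            # with the distance-5 consensus code this makes every planted
            # site attributable to exactly one RBP
            seq[start - 1] = "N"
            seq[start : start + params.motif_k] = list(planted)
            seq[start + params.motif_k] = "N"
            if rng.random() < params.peak_rate:
                half = params.peak_width // 2
                lo = max(start + params.motif_k // 2 - half, 0)
                hi = min(lo + params.peak_width, layout.chrom_length)
                peaks.append(
                    Peak(
                        interval=GenomicInterval("chr1", lo, hi, iv.strand),
                        rbp=rbp,
                        fold_enrichment=float(rng.uniform(3.0, 8.0)),
                        neg_log10_p=float(rng.uniform(5.0, 10.0)),
                    )
                )
        for _ in range(params.n_decoy_peaks_per_rbp):
            lo = int(rng.integers(0, layout.chrom_length - params.peak_width))
            peaks.append(
                Peak(
                    interval=GenomicInterval("chr1", lo, lo + params.peak_width, "+"),
                    rbp=rbp,
                    fold_enrichment=float(rng.uniform(0.5, 2.9)),
                    neg_log10_p=float(rng.uniform(0.5, 4.9)),
                )
            )
    genome = sio.Genome({"chr1": "".join(seq)})
    peaks.sort(key=lambda pk: (pk.interval.chrom, pk.interval.start, pk.rbp))
    return genome, motifs, peaks


# -------------------------------------------------------------- knockdown


def simulate_knockdown_tables(
    params: SimulationParams,
    layout: EventLayout,
    truth: StudyTruth,
) -> dict[str, list[tuple[SplicingEvent, EventStatRecord]]]:
    """Per-RBP knockdown event tables.

    For a true regulator each true consensus event is differential with
    probability ``kd_p_hit``; every other event/RBP combination with
    probability ``kd_p_bg``.
    """
    rng = params.rng(_K_KNOCKDOWN)
    _, rbps = gene_names(params)
    out = {}
    m = params.kd_group_size
    for rbp in rbps:
        pairs, raw_p = [], []
        for ev in layout.events:
            is_hit_slot = rbp in truth.true_regulators and ev.event_id in truth.true_events
            p_diff = params.kd_p_hit if is_hit_slot else params.kd_p_bg
            mu = layout.base_psi[ev.event_id]
            mu_kd = mu
            if rng.random() < p_diff:
                sign = 1 if rng.random() < 0.5 else -1
                mu_kd = float(np.clip(mu + sign * params.kd_dpsi_effect, 0.02, 0.98))
            rec, p = _event_record(
                rng, ev.event_id, f"KD_{rbp}", mu_kd, mu, m, m, params
            )
            pairs.append((ev, rec))
            raw_p.append(p)
        fdr = bh_adjust(raw_p)
        for (ev, rec), q in zip(pairs, fdr):
            rec.fdr = float(q)
        out[rbp] = pairs
    return out


# ----------------------------------------------------- variants, gene sets


def simulate_variants(
    params: SimulationParams, layout: EventLayout, truth: StudyTruth
) -> list[VariantRecord]:
    """Phenotype-annotated SNVs, half inside true-event regions."""
    rng = params.rng(_K_VARIANTS)
    config = AnalysisConfig()
    chrom_lengths = {"chr1": layout.chrom_length}
    events_by_id = {ev.event_id: ev for ev in layout.events}
    inside_pool = sorted(truth.true_events) or [ev.event_id for ev in layout.events]
    variants = []
    bases = "ACGT"
    phenotypes = ["degenerative disorder", "progeria-like syndrome", "myopathy", "benign"]
    n_inside = params.n_variants // 2
    for i in range(params.n_variants):
        if i < n_inside:
            eid = str(rng.choice(inside_pool))
            ev = events_by_id[eid]
            region = build_event_regions(
                ev, config.flank, config.donor_exclusion, config.acceptor_exclusion, chrom_lengths
            )
            iv = region.intervals[int(rng.integers(len(region.intervals)))]
            pos0 = int(rng.integers(iv.start, iv.end))
            gene = ev.gene
        else:
            pos0 = int(rng.integers(0, layout.chrom_length))
            gene = f"G{int(rng.integers(1, params.n_genes - params.n_rbps + 1)):05d}"
        ref = str(rng.choice(list(bases)))
        alt = str(rng.choice([b for b in bases if b != ref]))
        variants.append(
            VariantRecord(
                chrom="chr1",
                pos=pos0 + 1,
                ref=ref,
                alt=alt,
                gene=gene,
                phenotype=str(rng.choice(phenotypes)),
            )
        )
    variants.sort(key=lambda v: (v.chrom, v.pos))
    return variants


def simulate_gene_sets(
    params: SimulationParams, layout: EventLayout, truth: StudyTruth
) -> list[GeneSet]:
    """GO-like gene sets; a few are biased toward spliced-event genes."""
    rng = params.rng(_K_GENESETS)
    genes, _ = gene_names(params)
    true_genes = sorted(
        {ev.gene for ev in layout.events if ev.event_id in truth.true_events}
    ) or sorted({ev.gene for ev in layout.events})
    sets = []
    for i in range(params.n_gene_sets):
        size = int(rng.integers(10, 51))
        n_biased = min(size // 2, len(true_genes))
        if i < max(params.n_gene_sets // 5, 1) and n_biased:
            members = set(rng.choice(true_genes, size=n_biased, replace=False))
            members |= set(rng.choice(genes, size=size - len(members), replace=False))
        else:
            members = set(rng.choice(genes, size=size, replace=False))
        sets.append(GeneSet(f"GO:{i + 1:07d}", f"process_{i + 1}", frozenset(members)))
    return sets


# ------------------------------------------------------------ full study


@dataclass
class SyntheticStudy:
    params: SimulationParams
    truth: StudyTruth
    experiments: list[ExperimentTable]
    event_tables: dict[str, list[tuple[SplicingEvent, EventStatRecord]]]
    layout: EventLayout
    genome: sio.Genome
    motifs: list[PwmMotif]
    peaks: list[Peak]
    knockdown_tables: dict[str, list[tuple[SplicingEvent, EventStatRecord]]]
    variants: list[VariantRecord]
    gene_sets: list[GeneSet]

    @property
    def events_by_id(self) -> dict[str, SplicingEvent]:
        return {ev.event_id: ev for ev in self.layout.events}

    @property
    def rbps(self) -> list[str]:
        return gene_names(self.params)[1]


def simulate_study(params: SimulationParams | None = None) -> SyntheticStudy:
    """Generate the complete synthetic study with planted ground truth."""
    params = params or SimulationParams()
    experiments, truth = simulate_experiments(params)
    event_tables, layout = simulate_event_tables(params, truth, experiments)
    genome, motifs, peaks = simulate_binding_landscape(params, layout, truth)
    kd_tables = simulate_knockdown_tables(params, layout, truth)
    variants = simulate_variants(params, layout, truth)
    gene_sets = simulate_gene_sets(params, layout, truth)
    return SyntheticStudy(
        params=params,
        truth=truth,
        experiments=experiments,
        event_tables=event_tables,
        layout=layout,
        genome=genome,
        motifs=motifs,
        peaks=peaks,
        knockdown_tables=kd_tables,
        variants=variants,
        gene_sets=gene_sets,
    )


def write_fixture_dir(study: SyntheticStudy, outdir, config: AnalysisConfig | None = None) -> None:
    """Write the full fixture tree consumed by the pipeline CLI."""
    config = config or AnalysisConfig(seed=study.params.seed)
    os.makedirs(outdir, exist_ok=True)
    for sub in ("counts", "groups", "events", "knockdown"):
        os.makedirs(os.path.join(outdir, sub), exist_ok=True)
    for t in study.experiments:
        sio.write_count_matrix(os.path.join(outdir, "counts", f"{t.experiment_id}.tsv"), t)
        sio.write_group_map(
            os.path.join(outdir, "groups", f"{t.experiment_id}.tsv"),
            dict(zip(t.samples, t.group)),
        )
    for expt_id, pairs in study.event_tables.items():
        sio.write_event_table(os.path.join(outdir, "events", f"{expt_id}.tsv"), pairs)
    sio.write_fasta(os.path.join(outdir, "genome.fa"), study.genome.sequences)
    sio.write_pwm(os.path.join(outdir, "motifs.meme"), study.motifs)
    sio.write_narrowpeak(os.path.join(outdir, "peaks.bed"), study.peaks)
    for rbp, pairs in study.knockdown_tables.items():
        sio.write_event_table(os.path.join(outdir, "knockdown", f"{rbp}.tsv"), pairs)
    sio.write_variants(os.path.join(outdir, "variants.tsv"), study.variants)
    sio.write_gmt(os.path.join(outdir, "go_sets.gmt"), study.gene_sets)
    with open(os.path.join(outdir, "rbp_list.txt"), "w") as fh:
        fh.write("\n".join(study.rbps) + "\n")
    study.truth.to_json(os.path.join(outdir, "truth.json"))
    config.to_yaml(os.path.join(outdir, "config.yaml"))
    with open(os.path.join(outdir, "sim_params.json"), "w") as fh:
        json.dump(dataclasses.asdict(study.params), fh, indent=1)
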