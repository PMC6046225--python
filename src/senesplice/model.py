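"""Domain types shared by every pipeline stage.

Coordinates are 0-based half-open throughout the package; 1-based inputs
(variant tables, printed genomic positions) are converted at the I/O
boundary.  Strand is ``+`` or ``-``; upstream/downstream always refer to
transcript orientation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import yaml

EVENT_TYPES = ("SE", "A5SS", "A3SS", "MXE", "RI")

SENESCENT = "senescent"
GROWING = "growing"


class ValidationError(ValueError):
    """Raised when an input violates a domain invariant."""


class FormatError(ValueError):
    """Raised when an input file cannot be parsed."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A strand-aware 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValidationError(f"interval start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValidationError(
                f"interval end must exceed start, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """1-bp overlap on the same chromosome; strand is ignored here."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains_point(self, pos0: int) -> bool:
        return self.start <= pos0 < self.end


def from_one_based(chrom: str, pos: int, strand: str = "+") -> GenomicInterval:
    """Convert a 1-based inclusive position to a 1-bp half-open interval."""
    return GenomicInterval(chrom, pos - 1, pos, strand)


@dataclass
class ExperimentTable:
    """One two-group RNA-seq experiment: a raw count matrix plus labels."""

    experiment_id: str
    genes: list[str]
    samples: list[str]
    counts: np.ndarray  # genes x samples, nonnegative integers
    group: list[str]  # per-sample, 'senescent' or 'growing'
    cell_type: str = ""
    induction: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.genes), len(self.samples)):
            raise ValidationError(
                f"{self.experiment_id}: counts shape {self.counts.shape} does not "
                f"match {len(self.genes)} genes x {len(self.samples)} samples"
            )
        if len(self.group) != len(self.samples):
            raise ValidationError(f"{self.experiment_id}: group labels != samples")
        bad = set(self.group) - {SENESCENT, GROWING}
        if bad:
            raise ValidationError(f"{self.experiment_id}: unknown group labels {bad}")
        if np.any(self.counts < 0):
            raise ValidationError(f"{self.experiment_id}: negative counts")
        if len(set(self.genes)) != len(self.genes):
            dupes = [g for g in set(self.genes) if self.genes.count(g) > 1]
            raise ValidationError(
                f"{self.experiment_id}: duplicate gene ids {sorted(dupes)[:5]}"
            )
        if self.n_sen < 2 or self.n_gro < 2:
            raise ValidationError(
                f"{self.experiment_id}: each group needs >= 2 replicates "
                f"(senescent={self.n_sen}, growing={self.n_gro})"
            )

    @property
    def n_sen(self) -> int:
        return sum(g == SENESCENT for g in self.group)

    @property
    def n_gro(self) -> int:
        return sum(g == GROWING for g in self.group)

    @property
    def sen_mask(self) -> np.ndarray:
        return np.array([g == SENESCENT for g in self.group])


@dataclass(frozen=True)
class SplicingEvent:
    """A candidate alternative-splicing event.

    ``alt_segments`` holds the alternatively spliced exon(s): one segment
    for SE/A5SS/A3SS/RI, two for MXE.  For RI the segment is the retained
    intron.
    """

    event_id: str
    gene: str
    event_type: str
    alt_segments: tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise ValidationError(
                f"{self.event_id}: unknown event type {self.event_type!r}; "
                f"legal codes are {', '.join(EVENT_TYPES)}"
            )
        want = 2 if self.event_type == "MXE" else 1
        if len(self.alt_segments) != want:
            raise ValidationError(
                f"{self.event_id}: {self.event_type} needs {want} alt segment(s), "
                f"got {len(self.alt_segments)}"
            )
        chroms = {s.chrom for s in self.alt_segments}
        strands = {s.strand for s in self.alt_segments}
        if len(chroms) > 1 or len(strands) > 1:
            raise ValidationError(f"{self.event_id}: segments on mixed chrom/strand")

    @property
    def chrom(self) -> str:
        return self.alt_segments[0].chrom

    @property
    def strand(self) -> str:
        return self.alt_segments[0].strand


@dataclass
class EventStatRecord:
    """Per-experiment differential statistics for one splicing event."""

    event_id: str
    experiment_id: str
    inc_counts_sen: np.ndarray
    skip_counts_sen: np.ndarray
    inc_counts_gro: np.ndarray
    skip_counts_gro: np.ndarray
    delta_psi: float  # mean PSI(senescent) - mean PSI(growing)
    p: float
    fdr: float

    def __post_init__(self) -> None:
        for name in ("inc_counts_sen", "skip_counts_sen", "inc_counts_gro", "skip_counts_gro"):
            arr = np.asarray(getattr(self, name), dtype=np.int64)
            if np.any(arr < 0):
                raise ValidationError(f"{self.event_id}: negative {name}")
            setattr(self, name, arr)
        if len(self.inc_counts_sen) != len(self.skip_counts_sen) or len(
            self.inc_counts_gro
        ) != len(self.skip_counts_gro):
            raise ValidationError(f"{self.event_id}: inc/skip vector length mismatch")
        if abs(self.delta_psi) > 1 + 1e-9:
            raise ValidationError(f"{self.event_id}: |delta_psi| > 1")
        if not (0 < self.p <= 1) or not (0 < self.fdr <= 1):
            raise ValidationError(f"{self.event_id}: p/fdr outside (0, 1]")

    @staticmethod
    def _psi(inc: np.ndarray, skip: np.ndarray) -> np.ndarray:
        tot = inc + skip
        with np.errstate(invalid="ignore"):
            psi = np.where(tot > 0, inc / np.maximum(tot, 1), np.nan)
        return psi

    @property
    def psi_sen(self) -> np.ndarray:
        return self._psi(self.inc_counts_sen, self.skip_counts_sen)

    @property
    def psi_gro(self) -> np.ndarray:
        return self._psi(self.inc_counts_gro, self.skip_counts_gro)


@dataclass
class PwmMotif:
    """Position probability matrix over A, C, G, T (U mapped to T on read)."""

    rbp: str
    motif_id: str
    matrix: np.ndarray  # k x 4 probabilities
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValidationError(f"{self.motif_id}: matrix must be k x 4")
        if np.any(self.matrix < 0) or np.any(self.background < 0):
            raise ValidationError(f"{self.motif_id}: negative probabilities")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-6):
            raise ValidationError(f"{self.motif_id}: PWM columns must sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-6):
            raise ValidationError(f"{self.motif_id}: background must sum to 1")

    @property
    def k(self) -> int:
        return self.matrix.shape[0]


@dataclass(frozen=True)
class Peak:
    """One eCLIP binding peak (narrowPeak record)."""

    interval: GenomicInterval
    rbp: str
    fold_enrichment: float
    neg_log10_p: float

    def __post_init__(self) -> None:
        if self.fold_enrichment < 0:
            raise ValidationError(f"peak for {self.rbp}: negative fold enrichment")


@dataclass(frozen=True)
class GeneSet:
    set_id: str
    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValidationError(f"gene set {self.set_id} is empty")


@dataclass(frozen=True)
class VariantRecord:
    """A phenotype-annotated single-nucleotide variant; ``pos`` is 1-based."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    phenotype: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"variant position must be >= 1, got {self.pos}")

    @property
    def pos0(self) -> int:
        return self.pos - 1


@dataclass
class AnalysisConfig:
    """All pipeline thresholds; defaults follow the published analysis."""

    # splicing consensus
    event_min_mean_coverage: float = 5.0  # mean inc+skip per group
    event_fdr: float = 0.1
    event_dpsi: float = 0.05
    vote_min: int = 4  # "more than three" experiments, read strictly
    consensus_fdr: float = 0.05
    # event regions
    flank: int = 250
    donor_exclusion: int = 6  # intronic bp next to the 5' splice site
    acceptor_exclusion: int = 20  # intronic bp next to the 3' splice site
    # binding evidence
    motif_scan_p: float = 0.05
    peak_min_fold: float = 3.0
    peak_max_p: float = 1e-5  # as a p-value; neg_log10_p >= 5
    enrichment_q: float = 0.05
    evidence_rule: str = "combined"  # or "each": both evidence types separately
    peak_strand_aware: bool = False
    # differential expression
    de_bonferroni_alpha: float = 0.01
    n_permutations: int = 1000
    fwer_rank: int = 50  # the 50th smallest min-p of the permutations
    fwer_alpha: float = 0.05
    stouffer_weighting: str = "sqrt_n"  # or "n"
    stratified_shuffle: bool = False
    # knockdown validation
    kd_fdr: float = 0.05
    kd_dpsi: float = 0.1
    gsea_weight: float = 1.0
    gsea_permutations: int = 1000
    # GO modules
    kappa_threshold: float = 0.05
    top_k_go: int = 3
    go_q: float = 0.05
    # randomness
    seed: int = 0

    def __post_init__(self) -> None:
        if self.vote_min < 1:
            raise ValidationError("vote_min must be >= 1")
        for name in (
            "event_fdr",
            "event_dpsi",
            "consensus_fdr",
            "motif_scan_p",
            "enrichment_q",
            "de_bonferroni_alpha",
            "fwer_alpha",
            "kd_fdr",
            "kd_dpsi",
            "go_q",
        ):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValidationError(f"{name} must be in (0, 1], got {v}")
        if self.evidence_rule not in ("combined", "each"):
            raise ValidationError("evidence_rule must be 'combined' or 'each'")
        if self.stouffer_weighting not in ("sqrt_n", "n"):
            raise ValidationError("stouffer_weighting must be 'sqrt_n' or 'n'")
        if self.fwer_rank > self.n_permutations:
            raise ValidationError("fwer_rank cannot exceed n_permutations")
        if min(self.flank, self.donor_exclusion, self.acceptor_exclusion) < 0:
            raise ValidationError("region widths must be nonnegative")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def psi_from_counts(inc: Sequence[float], skip: Sequence[float]) -> np.ndarray:
    """Per-sample percent-spliced-in, inc / (inc + skip); NaN where no reads."""
    inc = np.asarray(inc, dtype=float)
    skip = np.asarray(skip, dtype=float)
    tot = inc + skip
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(tot > 0, inc / np.where(tot > 0, tot, 1), np.nan)
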