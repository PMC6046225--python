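"""Readers and writers for every external format the pipeline touches.

Formats
-------
* count matrix: TSV, header row = sample ids, first column = gene id
* group map: 2-column TSV ``sample<TAB>{senescent,growing}``
* event table: TSV dialect mirroring rMATS output (0-based half-open
  coordinates, comma-separated per-sample inclusion/skipping counts)
* genome: FASTA (via pyfaidx when read from disk)
* peaks: 10-column BED narrowPeak
* motifs: MEME minimal motif format, ``MOTIF <motif_id> <rbp>`` headers
* gene sets: GMT
* variants: TSV ``chrom pos(1-based) ref alt gene phenotype``
"""

from __future__ import annotations

import logging
import os
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .model import (
    EVENT_TYPES,
    AnalysisConfig,
    EventStatRecord,
    ExperimentTable,
    FormatError,
    GeneSet,
    GenomicInterval,
    Peak,
    PwmMotif,
    SplicingEvent,
    ValidationError,
    VariantRecord,
)

log = logging.getLogger("senesplice")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

EVENT_COLUMNS = [
    "event_id",
    "gene",
    "type",
    "chrom",
    "strand",
    "seg1_start",
    "seg1_end",
    "seg2_start",
    "seg2_end",
    "inc_counts_sen",
    "skip_counts_sen",
    "inc_counts_gro",
    "skip_counts_gro",
    "delta_psi",
    "p",
    "fdr",
]


# ---------------------------------------------------------------- counts


def read_group_map(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "group"], dtype=str)
    return dict(zip(df["sample"], df["group"]))


def write_group_map(path, group_map: Mapping[str, str]) -> None:
    with open(path, "w") as fh:
        for sample, grp in group_map.items():
            fh.write(f"{sample}\t{grp}\n")


def read_count_matrix(path, group_map: Mapping[str, str], experiment_id: str | None = None) -> ExperimentTable:
    """Parse a gene x sample TSV count matrix into an ExperimentTable."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    samples = [str(s) for s in df.columns]
    genes = [str(g) for g in df.index]
    counts = df.to_numpy()
    if not np.issubdtype(counts.dtype, np.number):
        for j, col in enumerate(df.columns):
            bad = pd.to_numeric(df[col], errors="coerce").isna()
            if bad.any():
                row = df.index[np.argmax(bad.to_numpy())]
                raise FormatError(
                    f"{path}: non-numeric count at gene {row!r}, sample {col!r}"
                )
    if np.any(counts != np.floor(counts)):
        i, j = np.argwhere(counts != np.floor(counts))[0]
        raise FormatError(
            f"{path}: non-integer count at gene {genes[i]!r}, sample {samples[j]!r}"
        )
    if np.any(counts < 0):
        i, j = np.argwhere(counts < 0)[0]
        raise FormatError(
            f"{path}: negative count at gene {genes[i]!r}, sample {samples[j]!r}"
        )
    missing = [s for s in samples if s not in group_map]
    if missing:
        raise ValidationError(f"{path}: samples without group label: {missing}")
    group = [group_map[s] for s in samples]
    if experiment_id is None:
        experiment_id = os.path.splitext(os.path.basename(str(path)))[0]
    return ExperimentTable(
        experiment_id=experiment_id,
        genes=genes,
        samples=samples,
        counts=counts.astype(np.int64),
        group=group,
    )


def write_count_matrix(path, table: ExperimentTable) -> None:
    df = pd.DataFrame(table.counts, index=table.genes, columns=table.samples)
    df.index.name = "gene"
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------- events


def _fmt_counts(arr: np.ndarray) -> str:
    return ",".join(str(int(v)) for v in arr)


def _parse_counts(cell: str, where: str) -> np.ndarray:
    try:
        return np.array([int(v) for v in str(cell).split(",")], dtype=np.int64)
    except ValueError as exc:
        raise FormatError(f"{where}: bad count vector {cell!r}") from exc


def read_event_table(path) -> list[tuple[SplicingEvent, EventStatRecord]]:
    """Read an rMATS-like event TSV; returns (event, per-experiment stats)."""
    df = pd.read_csv(path, sep="\t", dtype={"seg2_start": "Int64", "seg2_end": "Int64"})
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    experiment_id = os.path.splitext(os.path.basename(str(path)))[0]
    out: list[tuple[SplicingEvent, EventStatRecord]] = []
    for ln, row in enumerate(df.itertuples(index=False), start=2):
        where = f"{path}:{ln}"
        etype = str(row.type)
        if etype not in EVENT_TYPES:
            raise FormatError(
                f"{where}: unknown event type {etype!r}; legal codes are "
                f"{', '.join(EVENT_TYPES)}"
            )
        segs = [GenomicInterval(str(row.chrom), int(row.seg1_start), int(row.seg1_end), str(row.strand))]
        has_seg2 = not (pd.isna(row.seg2_start) or pd.isna(row.seg2_end))
        if etype == "MXE":
            if not has_seg2:
                raise ValidationError(f"{where}: MXE requires two alt segments")
            segs.append(
                GenomicInterval(str(row.chrom), int(row.seg2_start), int(row.seg2_end), str(row.strand))
            )
        elif has_seg2:
            raise ValidationError(f"{where}: seg2 only legal for MXE events")
        event = SplicingEvent(str(row.event_id), str(row.gene), etype, tuple(segs))
        rec = EventStatRecord(
            event_id=str(row.event_id),
            experiment_id=experiment_id,
            inc_counts_sen=_parse_counts(row.inc_counts_sen, where),
            skip_counts_sen=_parse_counts(row.skip_counts_sen, where),
            inc_counts_gro=_parse_counts(row.inc_counts_gro, where),
            skip_counts_gro=_parse_counts(row.skip_counts_gro, where),
            delta_psi=float(row.delta_psi),
            p=float(row.p),
            fdr=float(row.fdr),
        )
        out.append((event, rec))
    return out


def write_event_table(path, pairs: Sequence[tuple[SplicingEvent, EventStatRecord]]) -> None:
    rows = []
    for event, rec in pairs:
        seg1 = event.alt_segments[0]
        seg2 = event.alt_segments[1] if len(event.alt_segments) > 1 else None
        rows.append(
            {
                "event_id": event.event_id,
                "gene": event.gene,
                "type": event.event_type,
                "chrom": event.chrom,
                "strand": event.strand,
                "seg1_start": seg1.start,
                "seg1_end": seg1.end,
                "seg2_start": "" if seg2 is None else seg2.start,
                "seg2_end": "" if seg2 is None else seg2.end,
                "inc_counts_sen": _fmt_counts(rec.inc_counts_sen),
                "skip_counts_sen": _fmt_counts(rec.skip_counts_sen),
                "inc_counts_gro": _fmt_counts(rec.inc_counts_gro),
                "skip_counts_gro": _fmt_counts(rec.skip_counts_gro),
                "delta_psi": f"{rec.delta_psi:.6g}",
                "p": f"{rec.p:.6g}",
                "fdr": f"{rec.fdr:.6g}",
            }
        )
    pd.DataFrame(rows, columns=EVENT_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------- genome


class Genome:
    """Uppercase in-memory genome with strand-aware, clipping extraction.

    Construct from a dict of chromosome sequences or load from FASTA with
    :meth:`from_fasta` (pyfaidx-backed).
    """

    def __init__(self, sequences: Mapping[str, str]):
        self.sequences = {c: str(s).upper() for c, s in sequences.items()}

    @classmethod
    def from_fasta(cls, path) -> "Genome":
        from pyfaidx import Fasta

        with Fasta(str(path)) as fa:
            return cls({name: str(fa[name][:]) for name in fa.keys()})

    def lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}

    def extract(self, iv: GenomicInterval) -> str:
        """Sequence of ``iv``, reverse-complemented on the minus strand.

        Intervals running past chromosome ends are clipped with a warning.
        """
        if iv.chrom not in self.sequences:
            raise KeyError(f"unknown chromosome {iv.chrom!r}")
        seq = self.sequences[iv.chrom]
        start, end = iv.start, min(iv.end, len(seq))
        if end != iv.end or start > len(seq):
            log.warning(
                "[W-CLIP] interval %s:[%d,%d) clipped to chromosome length %d",
                iv.chrom, iv.start, iv.end, len(seq),
            )
            start = min(start, len(seq))
        sub = seq[start:end]
        if iv.strand == "-":
            sub = sub.translate(_COMPLEMENT)[::-1]
        return sub


def extract_sequence(genome: Genome, iv: GenomicInterval) -> str:
    return genome.extract(iv)


def write_fasta(path, sequences: Mapping[str, str], width: int = 80) -> None:
    with open(path, "w") as fh:
        for name in sequences:
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ----------------------------------------------------------------- peaks


def read_narrowpeak(path) -> list[Peak]:
    """Parse a 10-column BED narrowPeak file.

    Column 4 (name) carries the RBP identifier, column 7 signalValue is
    the fold enrichment and column 8 is -log10(p).
    """
    peaks: list[Peak] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 10:
                raise FormatError(f"{path}:{ln}: narrowPeak needs 10 columns")
            try:
                iv = GenomicInterval(parts[0], int(parts[1]), int(parts[2]), parts[5])
                peaks.append(
                    Peak(
                        interval=iv,
                        rbp=parts[3],
                        fold_enrichment=float(parts[6]),
                        neg_log10_p=float(parts[7]),
                    )
                )
            except (ValueError, ValidationError) as exc:
                raise FormatError(f"{path}:{ln}: {exc}") from exc
    return peaks


def write_narrowpeak(path, peaks: Iterable[Peak]) -> None:
    with open(path, "w") as fh:
        for pk in peaks:
            iv = pk.interval
            fh.write(
                "\t".join(
                    [
                        iv.chrom,
                        str(iv.start),
                        str(iv.end),
                        pk.rbp,
                        "0",
                        iv.strand,
                        f"{pk.fold_enrichment:.6g}",
                        f"{pk.neg_log10_p:.6g}",
                        "-1",
                        "-1",
                    ]
                )
                + "\n"
            )


# ------------------------------------------------------------- gene sets


def read_gmt(path) -> list[GeneSet]:
    sets: list[GeneSet] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{ln}: GMT needs id, name, >=1 gene")
            sets.append(GeneSet(parts[0], parts[1], frozenset(parts[2:])))
    return sets


def write_gmt(path, sets: Iterable[GeneSet]) -> None:
    with open(path, "w") as fh:
        for gs in sets:
            fh.write("\t".join([gs.set_id, gs.name, *sorted(gs.genes)]) + "\n")


# ---------------------------------------------------------------- motifs


def read_pwm(path) -> list[PwmMotif]:
    """Parse a MEME minimal motif file.

    The second word of each MOTIF line (the MEME "alternate name") is the
    RBP the motif belongs to.  A ``U`` column header in the alphabet is
    treated as ``T``.
    """
    motifs: list[PwmMotif] = []
    background = np.full(4, 0.25)
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("Background letter frequencies"):
            i += 1
            parts = lines[i].split()
            freq = {parts[j].upper().replace("U", "T"): float(parts[j + 1]) for j in range(0, len(parts), 2)}
            background = np.array([freq.get(b, 0.25) for b in "ACGT"])
        elif line.startswith("MOTIF"):
            parts = line.split()
            if len(parts) < 3:
                raise FormatError(f"{path}:{i + 1}: MOTIF line needs '<id> <rbp>'")
            motif_id, rbp = parts[1], parts[2]
            while i < len(lines) and not lines[i].strip().startswith("letter-probability matrix"):
                i += 1
            if i >= len(lines):
                raise FormatError(f"{path}: motif {motif_id} has no matrix")
            header = lines[i]
            width = None
            toks = header.replace("=", " = ").split()
            for j, tok in enumerate(toks):
                if tok == "w" and j + 2 < len(toks):
                    width = int(toks[j + 2])
            if width is None:
                raise FormatError(f"{path}:{i + 1}: matrix header lacks 'w='")
            rows = []
            for j in range(width):
                i += 1
                vals = [float(v) for v in lines[i].split()]
                if len(vals) != 4:
                    raise FormatError(f"{path}:{i + 1}: matrix row needs 4 entries")
                rows.append(vals)
            try:
                motifs.append(PwmMotif(rbp=rbp, motif_id=motif_id, matrix=np.array(rows), background=background))
            except ValidationError as exc:
                raise ValidationError(f"{path}: motif {motif_id}: {exc}") from exc
        i += 1
    return motifs


def write_pwm(path, motifs: Sequence[PwmMotif]) -> None:
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: +\n\n")
        if motifs:
            bg = motifs[0].background
            fh.write("Background letter frequencies\n")
            fh.write(f"A {bg[0]:.6f} C {bg[1]:.6f} G {bg[2]:.6f} T {bg[3]:.6f}\n\n")
        for m in motifs:
            fh.write(f"MOTIF {m.motif_id} {m.rbp}\n")
            fh.write(f"letter-probability matrix: alength= 4 w= {m.k} nsites= 20 E= 0\n")
            for row in m.matrix:
                fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")
            fh.write("\n")


# -------------------------------------------------------------- variants

_VARIANT_COLUMNS = ["chrom", "pos", "ref", "alt", "gene", "phenotype"]


def read_variants(path) -> list[VariantRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _VARIANT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    out = []
    for ln, row in enumerate(df.itertuples(index=False), start=2):
        try:
            out.append(
                VariantRecord(
                    chrom=str(row.chrom),
                    pos=int(row.pos),
                    ref=str(row.ref),
                    alt=str(row.alt),
                    gene=str(row.gene),
                    phenotype=str(row.phenotype),
                )
            )
        except (ValueError, ValidationError) as exc:
            raise FormatError(f"{path}:{ln}: {exc}") from exc
    return out


def write_variants(path, variants: Iterable[VariantRecord]) -> None:
    rows = [
        {
            "chrom": v.chrom,
            "pos": v.pos,
            "ref": v.ref,
            "alt": v.alt,
            "gene": v.gene,
            "phenotype": v.phenotype,
        }
        for v in variants
    ]
    pd.DataFrame(rows, columns=_VARIANT_COLUMNS).to_csv(path, sep="\t", index=False)
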