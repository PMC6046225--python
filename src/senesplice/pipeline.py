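"""End-to-end orchestration of the six analysis stages.

Reads a fixture directory (the layout written by ``senesplice simulate``
or assembled from real exports), runs

    de -> splice -> enrich -> modules -> validate -> variants

and writes one TSV/JSON per output plus a manifest recording the config
hash, seed, package version and row counts.  Stages whose inputs are
missing are skipped with a manifest note.  All randomness is derived
from the config seed through fixed per-stage spawn keys, so a rerun
with the same inputs and config is byte-identical.
"""

from __future__ import annotations

import glob
import hashlib
import json
import logging
import os
from dataclasses import asdict

import numpy as np
import pandas as pd

from . import __version__
from . import io as sio
from .binding import (
    build_event_regions,
    call_enriched_rbps,
    enrichment_frame,
    evidence_tables,
    sample_control_events,
)
from .de_meta import (
    call_consensus_de,
    cluster_rank_matrix,
    normalize_counts,
    per_experiment_test,
    rank_transform,
    rbp_down_enrichment,
)
from .knockdown import knockdown_frame, validate_knockdowns
from .model import AnalysisConfig
from .modules import assign_targets, cluster_terms, go_enrichment
from .splice_meta import (
    consensus_events,
    consensus_ids,
    event_type_breakdown,
    results_frame,
)
from .variants import hits_frame, map_variants, summarize_variants

log = logging.getLogger("senesplice")

STAGES = ("de", "splice", "enrich", "modules", "validate", "variants")

# stage seeds: SeedSequence(config.seed, spawn_key=(offset,))
_STAGE_KEY = {name: 100 + i for i, name in enumerate(STAGES)}


def stage_seed(config: AnalysisConfig, stage: str) -> int:
    ss = np.random.SeedSequence(config.seed, spawn_key=(_STAGE_KEY[stage],))
    return int(ss.generate_state(1)[0] % (2**31))


def _write_tsv(df: pd.DataFrame, path: str, manifest: dict, stage: str) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    manifest["stages"][stage]["outputs"][os.path.basename(path)] = int(len(df))


class PipelineRun:
    """Holds intermediate state while executing the requested stages."""

    def __init__(self, config: AnalysisConfig, indir: str, outdir: str):
        self.config = config
        self.indir = indir
        self.outdir = outdir
        os.makedirs(outdir, exist_ok=True)
        self.manifest: dict = {
            "seed": config.seed,
            "package_version": __version__,
            "config_sha256": hashlib.sha256(
                json.dumps(asdict(config), sort_keys=True).encode()
            ).hexdigest(),
            "stages": {},
        }
        self._experiments = None
        self._de = None
        self._event_tables = None
        self._consensus = None
        self._evidence = None
        self._enrichment = None
        self._regions = None
        self._control_ids = None

    # ---------------------------------------------------------- loading

    def _in(self, *parts) -> str:
        return os.path.join(self.indir, *parts)

    def experiments(self):
        if self._experiments is None:
            paths = sorted(glob.glob(self._in("counts", "*.tsv")))
            if not paths:
                raise FileNotFoundError(f"no count matrices under {self._in('counts')}")
            tables = []
            for path in paths:
                expt = os.path.splitext(os.path.basename(path))[0]
                gmap = sio.read_group_map(self._in("groups", f"{expt}.tsv"))
                tables.append(sio.read_count_matrix(path, gmap, expt))
            self._experiments = tables
        return self._experiments

    def event_tables(self):
        if self._event_tables is None:
            paths = sorted(glob.glob(self._in("events", "*.tsv")))
            self._event_tables = {
                os.path.splitext(os.path.basename(p))[0]: sio.read_event_table(p)
                for p in paths
            }
        return self._event_tables

    def events_by_id(self):
        out = {}
        for pairs in self.event_tables().values():
            for ev, _ in pairs:
                out.setdefault(ev.event_id, ev)
        return out

    def rbp_list(self) -> list[str]:
        path = self._in("rbp_list.txt")
        if os.path.exists(path):
            with open(path) as fh:
                return [line.strip() for line in fh if line.strip()]
        return []

    # ----------------------------------------------------------- stages

    def run_de(self) -> None:
        entry = self.manifest["stages"]["de"] = {"status": "run", "outputs": {}}
        tables = self.experiments()
        cfg = self.config
        norm = normalize_counts(tables)
        de = call_consensus_de(tables, cfg, norm=norm)
        self._de = de
        _write_tsv(de, os.path.join(self.outdir, "de_results.tsv"), self.manifest, "de")
        entry["fwer_threshold"] = de.attrs["fwer_threshold"]
        down_p = {
            t.experiment_id: per_experiment_test(t, "down") for t in tables
        }
        rank = rank_transform(down_p)
        rank_out = rank.reset_index().rename(columns={"index": "gene"})
        _write_tsv(rank_out, os.path.join(self.outdir, "rank_matrix.tsv"), self.manifest, "de")
        k_rows = min(4, len(rank))
        k_cols = min(3, rank.shape[1])
        row_lab, col_lab, _, _ = cluster_rank_matrix(rank, k_rows, k_cols)
        labels = pd.DataFrame(
            {"item": list(rank.index) + list(rank.columns),
             "axis": ["gene"] * len(rank.index) + ["experiment"] * rank.shape[1],
             "cluster": list(row_lab) + list(col_lab)}
        )
        _write_tsv(labels, os.path.join(self.outdir, "cluster_labels.tsv"), self.manifest, "de")
        rbps = [r for r in self.rbp_list() if r in set(de["gene"])]
        if rbps:
            oratio, p, table = rbp_down_enrichment(de, rbps)
            entry["rbp_down_enrichment"] = {
                "odds_ratio": oratio if np.isfinite(oratio) else None,
                "p": p,
                "table": list(table),
            }

    def run_splice(self) -> None:
        self.manifest["stages"]["splice"] = {"status": "run", "outputs": {}}
        tables = self.event_tables()
        if not tables:
            self.manifest["stages"]["splice"] = {
                "status": "skipped", "reason": "no event tables", "outputs": {}
            }
            return
        results = consensus_events(tables, self.config)
        self._consensus = results
        df = results_frame(results)
        _write_tsv(df, os.path.join(self.outdir, "consensus_events.tsv"), self.manifest, "splice")
        breakdown = event_type_breakdown(results, self.events_by_id())
        self.manifest["stages"]["splice"]["event_type_breakdown"] = breakdown

    def _ensure_consensus(self):
        if self._consensus is None:
            self.run_splice()
        return self._consensus

    def run_enrich(self) -> None:
        needed = [self._in("genome.fa"), self._in("motifs.meme"), self._in("peaks.bed")]
        missing = [p for p in needed if not os.path.exists(p)]
        if missing:
            self.manifest["stages"]["enrich"] = {
                "status": "skipped",
                "reason": f"missing inputs: {[os.path.basename(p) for p in missing]}",
                "outputs": {},
            }
            return
        entry = self.manifest["stages"]["enrich"] = {"status": "run", "outputs": {}}
        cfg = self.config
        consensus = self._ensure_consensus()
        if consensus is None:
            entry.update(status="skipped", reason="no splice results")
            return
        events_by_id = self.events_by_id()
        cons_ids = consensus_ids(consensus)
        genome = sio.Genome.from_fasta(self._in("genome.fa"))
        motifs = sio.read_pwm(self._in("motifs.meme"))
        peaks = sio.read_narrowpeak(self._in("peaks.bed"))
        chrom_lengths = genome.lengths()
        control = sample_control_events(events_by_id, cons_ids, seed=stage_seed(cfg, "enrich"))
        def regions_for(ids):
            return [
                build_event_regions(
                    events_by_id[eid], cfg.flank, cfg.donor_exclusion,
                    cfg.acceptor_exclusion, chrom_lengths,
                )
                for eid in sorted(ids)
            ]
        ase_regions = regions_for(cons_ids)
        control_regions = regions_for(control)
        self._regions = {rs.event_id: rs for rs in ase_regions + control_regions}
        self._control_ids = control
        motifs_by_rbp: dict = {}
        for m in motifs:
            motifs_by_rbp.setdefault(m.rbp, []).append(m)
        peaks_by_rbp: dict = {}
        for pk in peaks:
            peaks_by_rbp.setdefault(pk.rbp, []).append(pk)
        if self._de is None and os.path.exists(os.path.join(self.outdir, "de_results.tsv")):
            self._de = pd.read_csv(os.path.join(self.outdir, "de_results.tsv"), sep="\t")
        if self._de is None:
            self.run_de()
        evidence = evidence_tables(
            ase_regions, control_regions, motifs_by_rbp, peaks_by_rbp, genome, cfg
        )
        self._evidence = evidence
        records = call_enriched_rbps(evidence, self._de, cfg) if evidence else []
        self._enrichment = records
        _write_tsv(
            enrichment_frame(records) if records else pd.DataFrame(
                columns=["rbp", "p_combined_fisher", "p_combined_stouffer",
                         "q_fisher", "q_stouffer", "enriched", "is_de_down",
                         "is_candidate_regulator"]
            ),
            os.path.join(self.outdir, "rbp_enrichment.tsv"), self.manifest, "enrich",
        )
        ev_rows = []
        for ev in evidence:
            ev_rows.append({
                "rbp": ev.rbp,
                "best_motif": ev.best_motif_id or "",
                "motif_table": ",".join(map(str, ev.motif_table)) if ev.motif_table else "",
                "p_motif": ev.p_motif if ev.p_motif is not None else "",
                "peak_table": ",".join(map(str, ev.peak_table)) if ev.peak_table else "",
                "p_peak": ev.p_peak if ev.p_peak is not None else "",
            })
        _write_tsv(
            pd.DataFrame(ev_rows, columns=["rbp", "best_motif", "motif_table",
                                           "p_motif", "peak_table", "p_peak"]),
            os.path.join(self.outdir, "evidence_tables.tsv"), self.manifest, "enrich",
        )
        bed_rows = []
        for rs in ase_regions + control_regions:
            kind = "ASE" if rs.event_id in cons_ids else "control"
            for iv in rs.intervals:
                bed_rows.append(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{rs.event_id}|{kind}\t0\t{iv.strand}"
                )
        with open(os.path.join(self.outdir, "regions.bed"), "w") as fh:
            fh.write("\n".join(bed_rows) + ("\n" if bed_rows else ""))
        entry["outputs"]["regions.bed"] = len(bed_rows)

    def run_modules(self) -> None:
        if self._enrichment is None:
            self.run_enrich()
        if self._enrichment is None:
            self.manifest["stages"]["modules"] = {
                "status": "skipped", "reason": "no enrichment results", "outputs": {}
            }
            return
        entry = self.manifest["stages"]["modules"] = {"status": "run", "outputs": {}}
        cfg = self.config
        events_by_id = self.events_by_id()
        cons_ids = consensus_ids(self._consensus)
        candidates = [r.rbp for r in self._enrichment if r.is_candidate_regulator]
        mods = assign_targets(candidates, cons_ids, events_by_id, self._evidence or [])
        rows = []
        for rbp in sorted(mods):
            for eid in sorted(mods[rbp].target_events):
                rows.append({"rbp": rbp, "event_id": eid, "gene": events_by_id[eid].gene})
        _write_tsv(
            pd.DataFrame(rows, columns=["rbp", "event_id", "gene"]),
            os.path.join(self.outdir, "modules.tsv"), self.manifest, "modules",
        )
        gmt_path = self._in("go_sets.gmt")
        if not os.path.exists(gmt_path):
            entry["go"] = "skipped: no go_sets.gmt"
            return
        gene_sets = sio.read_gmt(gmt_path)
        # universe: genes with >= 1 consensus-testable event
        universe = {ev.gene for ev in events_by_id.values()}
        go_rows, class_rows = [], []
        for rbp in sorted(mods):
            genes = mods[rbp].target_genes
            if not genes:
                continue
            enr = go_enrichment(genes, gene_sets, universe)
            enr = enr[enr["q"] < cfg.go_q]
            if len(enr) == 0:
                continue
            clustered = cluster_terms(
                enr, gene_sets, universe, cfg.kappa_threshold, cfg.top_k_go
            )
            for _, row in clustered.iterrows():
                rec = dict(row)
                rec["rbp"] = rbp
                go_rows.append(rec)
                if row["is_representative"]:
                    class_rows.append(
                        {"rbp": rbp, "class_id": row["class_id"], "set_id": row["set_id"],
                         "name": row["name"], "p": row["p"], "q": row["q"]}
                    )
        _write_tsv(
            pd.DataFrame(go_rows, columns=["rbp", "set_id", "name", "overlap",
                                           "term_size", "p", "q", "class_id",
                                           "is_representative"]),
            os.path.join(self.outdir, "go_enrichment.tsv"), self.manifest, "modules",
        )
        _write_tsv(
            pd.DataFrame(class_rows, columns=["rbp", "class_id", "set_id", "name", "p", "q"]),
            os.path.join(self.outdir, "go_classes.tsv"), self.manifest, "modules",
        )

    def run_validate(self) -> None:
        kd_paths = sorted(glob.glob(self._in("knockdown", "*.tsv")))
        if not kd_paths:
            self.manifest["stages"]["validate"] = {
                "status": "skipped", "reason": "no knockdown tables", "outputs": {}
            }
            return
        entry = self.manifest["stages"]["validate"] = {"status": "run", "outputs": {}}
        consensus = self._ensure_consensus()
        cons_ids = consensus_ids(consensus)
        tested = {r.event_id for r in consensus}
        if self._enrichment is None:
            self.run_enrich()
        candidates = {
            r.rbp for r in (self._enrichment or []) if r.is_candidate_regulator
        }
        kd_tables = {
            os.path.splitext(os.path.basename(p))[0]: [
                rec for _, rec in sio.read_event_table(p)
            ]
            for p in kd_paths
        }
        cfg = AnalysisConfig(**{**asdict(self.config), "seed": stage_seed(self.config, "validate")})
        ranked, gsea = validate_knockdowns(kd_tables, cons_ids, tested, candidates, cfg)
        _write_tsv(
            knockdown_frame(ranked),
            os.path.join(self.outdir, "knockdown_validation.tsv"), self.manifest, "validate",
        )
        gsea_payload = None
        if gsea is not None:
            gsea_payload = {
                "es": gsea.es,
                "p_perm": gsea.p_perm,
                "n_perm": gsea.n_perm,
                "hit_positions": gsea.hit_positions,
                "candidates": sorted(candidates),
            }
        with open(os.path.join(self.outdir, "gsea_result.json"), "w") as fh:
            json.dump(gsea_payload, fh, indent=1, sort_keys=True)
        entry["outputs"]["gsea_result.json"] = 1

    def run_variants(self) -> None:
        path = self._in("variants.tsv")
        if not os.path.exists(path):
            self.manifest["stages"]["variants"] = {
                "status": "skipped", "reason": "no variants.tsv", "outputs": {}
            }
            return
        entry = self.manifest["stages"]["variants"] = {"status": "run", "outputs": {}}
        consensus = self._ensure_consensus()
        cons_ids = consensus_ids(consensus)
        events_by_id = self.events_by_id()
        cfg = self.config
        chrom_lengths = None
        if os.path.exists(self._in("genome.fa")):
            chrom_lengths = sio.Genome.from_fasta(self._in("genome.fa")).lengths()
        region_sets = [
            build_event_regions(
                events_by_id[eid], cfg.flank, cfg.donor_exclusion,
                cfg.acceptor_exclusion, chrom_lengths,
            )
            for eid in sorted(cons_ids)
        ]
        variants = sio.read_variants(path)
        hits = map_variants(variants, region_sets)
        _write_tsv(
            hits_frame(hits, events_by_id),
            os.path.join(self.outdir, "variant_hits.tsv"), self.manifest, "variants",
        )
        summary, n_var, n_gene = summarize_variants(hits, events_by_id)
        _write_tsv(
            summary, os.path.join(self.outdir, "variant_summary.tsv"), self.manifest, "variants",
        )
        entry["n_variants_mapped"] = n_var
        entry["n_genes_with_variants"] = n_gene


def run_pipeline(
    config: AnalysisConfig,
    indir: str,
    outdir: str,
    stages: tuple[str, ...] = STAGES,
) -> dict:
    """Execute the requested stages and return the manifest dict."""
    bad = set(stages) - set(STAGES)
    if bad:
        raise ValueError(f"unknown stages {sorted(bad)}; legal: {STAGES}")
    run = PipelineRun(config, indir, outdir)
    runners = {
        "de": run.run_de,
        "splice": run.run_splice,
        "enrich": run.run_enrich,
        "modules": run.run_modules,
        "validate": run.run_validate,
        "variants": run.run_variants,
    }
    for stage in STAGES:
        if stage in stages:
            log.info("[I-STAGE] running %s", stage)
            runners[stage]()
    for stage in STAGES:
        self_entry = run.manifest["stages"].setdefault(
            stage, {"status": "not requested", "outputs": {}}
        )
        del self_entry
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(run.manifest, fh, indent=1, sort_keys=True)
    return run.manifest
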