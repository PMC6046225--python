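# Methods

## The analysis model

The pipeline treats a senescence study as a collection of independent
two-group RNA-seq experiments (senescent vs growing), each with at
least two biological replicates per group, plus external binding
resources (a PWM motif library, eCLIP peak files), knockdown screens
and a variant table. Nothing is assumed about how the per-experiment
splicing statistics were produced beyond "an rMATS-like event table":
per-sample inclusion/skipping read counts, a ΔPSI estimate, a p-value
and a within-experiment fdr. All genomic coordinates are 0-based
half-open internally; 1-based inputs are converted at the I/O boundary.

### Differential expression

Counts are normalised per experiment by median-of-ratios size factors,
log2(x+1)-transformed, then quantile-normalised jointly across all
samples. Three meta-analytic routes are run:

* **Pooled t** — Welch's t on the joint normalised matrix. Its
  significance threshold is the 50th smallest of 1000 min-p statistics
  obtained by shuffling all sample labels, which controls the FWER at
  50/1000 = 0.05. The shuffle is pooled across experiments (a
  stratified option exists). With per-experiment batch effects in the
  data this threshold is conservative, because label shuffles that mix
  experiments pick up batch differences; the FWER calibration study
  therefore simulates a fully exchangeable null (no batch term). That is
  a property of the published procedure, not of this implementation.
* **Fisher combination** — per-experiment two-sided p-values (default
  engine: Welch t on that experiment's normalised log counts; any
  externally computed p-table can be injected) combined as
  X = −2 Σ ln pᵢ ~ χ²₂ₖ, Bonferroni < 0.01.
* **Inverse-normal (Stouffer)** — the same p-values combined as
  Z = Σ wᵢ zᵢ / √(Σ wᵢ²). "Weighting by sample size" is implemented as
  wᵢ = √nᵢ (variance-optimal under equal per-sample information;
  configurable to wᵢ = nᵢ).

A gene is differentially expressed only when all three routes pass and
the pooled direction agrees with at least half of the per-experiment
mean differences. One-sided p-values at t = 0 are 0.5 by convention;
degenerate zero-variance genes get p = 1 (two-sided).

### Consensus splicing events

Within each experiment an event is testable when its mean combined
(inclusion + skipping) read count is at least 5 in both groups, and
differential at fdr < 0.1 and |ΔPSI| ≥ 0.05 (fdr strict, ΔPSI
inclusive). A consensus call requires (a) differentiality in at least
four experiments ("more than three", read strictly) and (b) a
Fisher-combined p over the experiments in which the event was testable,
BH-adjusted across events, below 0.05. Events are matched across
experiments by exact coordinate identity.

### Event regions and binding evidence

For each alternative segment the scanned region is the exon body plus up
to 250 bp of flanking intron on each side, in transcript orientation,
minus the splice-site consensus zones: the 6 intronic bp adjacent to the
donor (5' splice site) and the 20 intronic bp adjacent to the acceptor
(3' splice site). (The source protocol's wording places the exclusions
ambiguously; the implementation excludes the canonical intronic
consensus zones, with both widths configurable.) Without clipping, the
scanned length per segment is exon + 2·250 − 26 bp. MXE events
contribute both exons; RI events use the retained segment the same way.

PWM scanning computes each window's log-odds score against the motif's
stated background (pseudocount 1e−3 on matrix and background), with
scores discretised on a 1e−3 grid. The null score distribution is
computed exactly by dynamic programming (position-wise convolution), and
a window is a hit when its upper-tail probability is ≤ 0.05. Windows
containing N never match; regions are extracted reverse-complemented on
the minus strand so only the given strand is scanned.

Evidence is region-level presence/absence (not hit counts): for each RBP
a 2×2 table of consensus vs type-matched control events with/without a
motif hit, and an analogous table for overlap (≥ 1 bp, strand-blind by
default) with high-confidence peaks (fold ≥ 3 and p ≤ 1e−5, both
inclusive). Control events are sampled uniformly without replacement per
splicing class from the non-consensus background. One-sided Fisher
tests give p_motif (minimum over the RBP's motifs) and p_peak; the two
are combined by Fisher's and by the inverse-normal method, BH-adjusted
across RBPs per method, and an RBP is *enriched* only when both
q-values pass 0.05 (an alternative "each channel individually
significant" rule is available behind `evidence_rule="each"`).
Candidate regulators are enriched RBPs that the DE meta-analysis calls
consistently down-regulated.

### Modules, knockdown validation, variants

Targets of a candidate RBP are the consensus events whose regions carry
its motif hit or peak overlap. GO-style enrichment is a one-sided
hypergeometric test against the universe of genes with at least one
testable event, BH-adjusted. Redundant terms are grouped by Cohen's
kappa on membership vectors; pairs with κ > 0.05 share a class (the
published threshold, reproduced verbatim despite being unusually low),
classes are connected components, and the top 3 terms per class by p
(ties by term id) are representatives.

Knockdown validation intersects each RBP's knockdown-differential
events (fdr < 0.05, |ΔPSI| ≥ 0.1, after the same coverage filter) with
the consensus set over the universe of events testable in both the
knockdown and the cohort, ranks RBPs by the one-sided Fisher p
(ties by descending odds ratio, then id), and computes a weighted
pre-ranked GSEA enrichment score for the candidate set with metric
−log10(p), weight exponent 1 (0 gives the classic ES). The ES is the
signed maximum deviation of the running sum; significance is by
gene-set permutation, p = (1 + #{ES_perm ≥ ES}) / (1 + n_perm).

Variants are mapped by position only (SNV assumption) into
consensus-event regions; a variant hitting several events of one gene
counts once for that gene.

## The synthetic study

The generator's defaults are the study conditions every calibration and
recovery figure refers to:

* **Cohort** — 14 experiments, group sizes drawn from {2, 3, 4} with
  weights (0.05, 0.25, 0.7) (mean ≈ 3.65 replicates per group, close to
  the emulated cohort's 95 samples over 14 comparisons); 2000 genes of
  which 20 are RBPs; negative-binomial counts (dispersion 0.03,
  cell-line-like) with lognormal size factors (σ = 0.3) and
  per-experiment, per-gene batch effects (σ = 0.2); 10% of genes DE at
  a consistent 2-fold effect, half up, half down; 25% of RBPs planted
  as down-regulated, 3 of them the true regulators. RBP baseline
  expression is drawn higher and tighter (lognormal meanlog 6.5,
  sdlog 0.5) than the transcriptome bulk — splicing RBPs are abundant
  transcripts.
* **Events** — 400 events (60% SE, 10% each A5SS/A3SS/MXE/RI) laid out
  non-overlapping with 2 kb spacing on one synthetic chromosome; 15%
  planted as consensus-differential with |ΔPSI| = 0.2 (consistent sign)
  in 6 randomly chosen experiments; per-sample PSI ~ Beta with
  concentration 75 (per-sample PSI sd ≈ 0.06), coverage ~ Poisson(50),
  inclusion counts binomial given PSI. The p-values written to the
  tables come from a two-sided continuity-corrected two-proportion
  z-test on pooled inclusion fractions, BH-adjusted within experiment —
  a deliberately simple, documented stand-in for an event-level test;
  the pipeline only contracts on rMATS-like tables. At concentration 75
  this test is approximately calibrated; at much stronger
  overdispersion it becomes anti-conservative and no test at this
  replication level carries enough information for reliable consensus
  recovery, which is why 75 is the default.
* **Binding landscape** — an i.i.d. AT-rich genome (A = T = 0.375,
  C = G = 0.125). Motifs are sharp 14-mers over {C, G} whose stated
  background is GC-rich (A = T = 0.08, C = G = 0.42); because the scan
  p-value is computed under the motif's own background model, nominal
  p ≤ 0.05 hits in the AT-rich genome are sparse (~3% of regions by
  chance), as for real motifs on real genomes. The 20 consensus words
  form a binary lexicode with pairwise Hamming distance ≥ 5, so a
  planted site can never be a hit for another RBP's motif in exact
  register, and every planted site is delimited by single masked (N)
  bases — as in repeat-masked genome assemblies — so off-register
  windows never score. Without these two properties, cross-motif
  matches concentrate in true-event regions and every RBP appears
  enriched. True regulators are planted in 60% of true-event region
  sets and 5% of the rest; all other RBPs at 5% everywhere. Half of
  the planted sites get a 50 bp peak with fold ∈ [3, 8] and
  −log10 p ∈ [5, 10]; 20 decoy peaks per RBP fall below the
  high-confidence thresholds.
* **Knockdowns** — each RBP knocked down at 3 vs 3 replicates; a true
  regulator perturbs each true consensus event with probability 0.5
  (|ΔPSI| = 0.3), all other combinations at 0.05.
* **Variants / gene sets** — 60 SNVs, half placed inside true-event
  regions; 30 GO-like sets, a fifth biased toward true-event genes.

Every generator draws from a substream of the master seed via fixed
`SeedSequence` spawn keys, so a study is bit-reproducible; the pipeline
derives per-stage seeds from the config seed the same way.

### What the generator does not emulate

Read-level artefacts (mapping bias, junction ambiguity), realistic
splicing grammar or isoform structure, correlated gene-gene expression,
motif families with shared specificity, and peak calling noise. Tests
passing on this generator demonstrate that the pipeline's statistics are
calibrated and that it recovers signal of the designed kind and size;
they do not certify performance on real cohorts, where per-experiment
test quality and motif-database redundancy dominate.

## Numerical choices and edge cases

* p = 0 inputs to Fisher combination are clamped to the smallest
  positive double (with a warning); Stouffer inputs are clamped into
  (1e−15, 1 − 1e−15).
* Odds ratios are the sample ad/bc with ∞ for a zero denominator and
  NaN for fully degenerate tables.
* Intervals running past chromosome ends are clipped with a warning,
  never rejected; overlapping region intervals are merged.
* Quantile normalisation assigns tied input values their tied-group
  mean so equal inputs map to equal outputs.
* Events testable in no experiment are excluded from consensus calling
  with a log entry; an experiment count below the vote minimum logs a
  warning (the rule is then unsatisfiable).
* Duplicate gene ids in a count matrix are an error, not aggregated.
* U in motif alphabets is mapped to T at read time.
* Ties are always broken by identifier (genes, terms, RBPs) so all
  outputs are order-deterministic; a rerun with the same seed and
  config is byte-identical.

## Scale of the shipped validation studies

The shipped tests run the calibration and recovery studies at the sizes
stated above (200 exchangeable-null datasets for FWER calibration at
500 genes; 20 global-null studies; 10-seed splicing recovery; 20-seed
regulator recovery), which completes in a few minutes on a single CPU.
Measured under these conditions: FWER discovery fraction 0.055 (nominal
0.05); empty consensus and candidate sets in 20/20 null studies;
splicing sensitivity ≈ 0.96 at a false-positive rate < 0.1%; exact
recovery of the three planted regulators, top-5 knockdown ranks and
GSEA ES ≥ 0.6 in 20/20 seeds.

## Known limitations

The per-experiment DE engine is a Welch t on normalised log counts, not
a count-model fit; it is pluggable precisely so that users can supply
negative-binomial p-values. The DAVID-style kappa clustering uses plain
connected components where DAVID's heuristic is more elaborate. The
min-over-motifs rule for an RBP's p_motif is multiplicity-liberal but
reproduces the published procedure. Consensus matching requires exact
coordinate identity; fuzzy event matching across annotation versions is
out of scope, as are alignment, read counting and peak calling.
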