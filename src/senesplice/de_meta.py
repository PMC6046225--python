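"""Three-method differential-expression meta-analysis across experiments.

The three routes, each multiplicity-controlled in its own way:

1. pooled Welch t-test over all samples of all experiments, thresholded
   at a permutation min-p FWER cutoff;
2. per-experiment tests combined by Fisher's method, Bonferroni < 0.01;
3. the same per-experiment p-values combined by the weighted
   inverse-normal (Stouffer) method, Bonferroni < 0.01.

A gene is differentially expressed only when all three agree and the
pooled direction matches the majority of per-experiment directions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.special import comb

from .model import SENESCENT, AnalysisConfig, ExperimentTable
from .stats import (
    bonferroni_adjust,
    combine_fisher,
    combine_stouffer,
    fisher_exact_enrichment,
    welch_t,
)

log = logging.getLogger("senesplice")


@dataclass
class GeneMetaResult:
    gene: str
    p_pooled: float
    sign_pooled: int
    p_fisher: float
    p_stouffer: float
    adj_fisher: float
    adj_stouffer: float
    pass_pooled: bool
    pass_fisher: bool
    pass_stouffer: bool
    is_de: bool
    direction: str  # up / down / none


@dataclass
class NormalizedExpression:
    """Jointly quantile-normalised log2 expression across all experiments."""

    genes: list[str]
    samples: list[str]  # "<experiment>:<sample>"
    matrix: np.ndarray  # genes x samples
    group: list[str]
    experiment_of: list[str]

    @property
    def sen_mask(self) -> np.ndarray:
        return np.array([g == SENESCENT for g in self.group])


def size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors (the DESeq convention).

    The reference is the per-gene geometric mean over samples, computed on
    genes expressed in every sample of the experiment.
    """
    counts = np.asarray(counts, dtype=float)
    pos = np.all(counts > 0, axis=1)
    if not np.any(pos):
        log.warning("[W-SF] no gene positive in all samples; size factors = 1")
        return np.ones(counts.shape[1])
    logs = np.log(counts[pos])
    ref = logs.mean(axis=1, keepdims=True)
    return np.exp(np.median(logs - ref, axis=0))


def quantile_normalize(matrix: np.ndarray) -> np.ndarray:
    """Classic quantile normalisation: each column gets the mean sorted
    profile, assigned by within-column rank (ties share their mean value).
    """
    x = np.asarray(matrix, dtype=float)
    order = np.argsort(x, axis=0, kind="stable")
    means = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    ranks = np.empty_like(order)
    ar = np.arange(x.shape[0])
    for j in range(x.shape[1]):
        ranks[order[:, j], j] = ar
        out[:, j] = means[ranks[:, j]]
        # average ranks over ties so equal inputs map to equal outputs
        col = x[:, j]
        uniq, inv = np.unique(col, return_inverse=True)
        if uniq.size < col.size:
            sums = np.bincount(inv, weights=out[:, j])
            cnts = np.bincount(inv)
            out[:, j] = (sums / cnts)[inv]
    return out


def normalize_counts(tables: list[ExperimentTable]) -> NormalizedExpression:
    """Per-experiment size-factor normalisation, log2(x+1), then joint
    quantile normalisation over the union of samples.

    The gene universe is the intersection of the experiments' gene lists;
    genes with positive counts in at least one sample are retained.
    """
    if not tables:
        raise ValueError("need at least one experiment")
    universe = set(tables[0].genes)
    for t in tables[1:]:
        universe &= set(t.genes)
    if not universe:
        raise ValueError("empty gene intersection across experiments")
    genes = sorted(universe)
    cols, samples, group, expt = [], [], [], []
    for t in tables:
        idx = {g: i for i, g in enumerate(t.genes)}
        sub = t.counts[[idx[g] for g in genes], :].astype(float)
        sf = size_factors(sub)
        norm = sub / sf[None, :]
        cols.append(np.log2(norm + 1.0))
        samples.extend(f"{t.experiment_id}:{s}" for s in t.samples)
        group.extend(t.group)
        expt.extend([t.experiment_id] * len(t.samples))
    mat = np.hstack(cols)
    keep = np.any(mat > 0, axis=1)
    genes = [g for g, k in zip(genes, keep) if k]
    mat = quantile_normalize(mat[keep])
    return NormalizedExpression(genes, samples, mat, group, expt)


def pooled_t_test(norm: NormalizedExpression) -> pd.DataFrame:
    """Welch t on the pooled normalised matrix; sign = sen minus gro."""
    t, p = welch_t(norm.matrix, norm.sen_mask, "two-sided")
    return pd.DataFrame(
        {"gene": norm.genes, "t": t, "p": p, "sign": np.sign(t).astype(int)}
    )


def permutation_fwer_threshold(
    norm: NormalizedExpression,
    n_perm: int = 1000,
    rank_index: int = 50,
    seed: int = 0,
    stratified: bool = False,
) -> float:
    """Min-p permutation threshold controlling the FWER of the pooled test.

    All sample labels are shuffled ``n_perm`` times; the smallest pooled-t
    p-value over genes is kept each time; the ``rank_index``-th smallest of
    those minima is the significance threshold (FWER rank_index / n_perm).
    """
    if n_perm < rank_index:
        raise ValueError("n_perm must be >= rank_index")
    x = norm.matrix
    n = x.shape[1]
    n_sen = int(norm.sen_mask.sum())
    total_perms = comb(n, n_sen, exact=True)
    if total_perms < n_perm:
        log.warning(
            "[W-PERM] only %d distinct label assignments < %d requested; "
            "sampling with replacement", total_perms, n_perm,
        )
    rng = np.random.default_rng(seed)
    expt_codes = np.array(norm.experiment_of)
    masks = np.zeros((n, n_perm), dtype=bool)
    for i in range(n_perm):
        if stratified:
            for e in np.unique(expt_codes):
                idx = np.nonzero(expt_codes == e)[0]
                k = int(norm.sen_mask[idx].sum())
                masks[rng.choice(idx, size=k, replace=False), i] = True
        else:
            masks[rng.choice(n, size=n_sen, replace=False), i] = True
    min_ps = _batched_min_welch_p(x, masks, n_sen if not stratified else None)
    min_ps.sort()
    return float(min_ps[rank_index - 1])


def _batched_min_welch_p(x: np.ndarray, masks: np.ndarray, n1_fixed: int | None) -> np.ndarray:
    """Min over genes of the two-sided Welch p, for many label permutations.

    ``masks`` is samples x permutations (True = senescent).  Group sizes
    are constant across permutations (label shuffles), so the group sums
    reduce to matrix products.
    """
    from scipy import stats as sps

    g, n = x.shape
    n_perm = masks.shape[1]
    x2 = x * x
    tot_s = x.sum(axis=1, keepdims=True)
    tot_q = x2.sum(axis=1, keepdims=True)
    out = np.empty(n_perm)
    block = max(1, int(2e7 // max(g, 1)))
    for lo in range(0, n_perm, block):
        m = masks[:, lo : lo + block].astype(float)
        n1 = m.sum(axis=0)
        n2 = n - n1
        s1 = x @ m
        q1 = x2 @ m
        s2 = tot_s - s1
        q2 = tot_q - q1
        m1, m2 = s1 / n1, s2 / n2
        v1 = np.maximum(q1 - s1 * s1 / n1, 0.0) / (n1 - 1)
        v2 = np.maximum(q2 - s2 * s2 / n2, 0.0) / (n2 - 1)
        se2 = v1 / n1 + v2 / n2
        zero = se2 <= 0
        se2 = np.where(zero, 1.0, se2)
        t = (m1 - m2) / np.sqrt(se2)
        with np.errstate(divide="ignore", invalid="ignore"):
            df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
        df = np.where(np.isfinite(df) & (df > 0), df, 1.0)
        p = 2.0 * sps.t.sf(np.abs(t), df)
        p = np.where(zero & (m1 == m2), 1.0, p)
        out[lo : lo + m.shape[1]] = p.min(axis=0)
    return out


def per_experiment_test(
    table: ExperimentTable, alternative: str = "two-sided"
) -> pd.DataFrame:
    """Default per-experiment engine: Welch t on size-factor-normalised
    log2 counts of that experiment alone.

    This is a pluggable contract — any per-gene p-value table (e.g. from a
    negative-binomial fit) may be substituted downstream.  ``alternative``
    is "two-sided", "down" (lower in senescent) or "up".
    """
    alt = {"two-sided": "two-sided", "down": "less", "up": "greater"}[alternative]
    sf = size_factors(table.counts.astype(float))
    mat = np.log2(table.counts / sf[None, :] + 1.0)
    t, p = welch_t(mat, table.sen_mask, alt)
    return pd.DataFrame({"gene": table.genes, "t": t, "p": p})


def call_consensus_de(
    tables: list[ExperimentTable],
    config: AnalysisConfig | None = None,
    norm: NormalizedExpression | None = None,
    per_experiment: dict[str, pd.DataFrame] | None = None,
    fwer_threshold: float | None = None,
) -> pd.DataFrame:
    """Run all three meta-analytic routes and call consensus DE genes.

    Returns one row per gene of the shared universe with the fields of
    GeneMetaResult.  ``per_experiment`` may inject externally computed
    two-sided p-value tables keyed by experiment id.
    """
    config = config or AnalysisConfig()
    if norm is None:
        norm = normalize_counts(tables)
    pooled = pooled_t_test(norm).set_index("gene")
    if fwer_threshold is None:
        fwer_threshold = permutation_fwer_threshold(
            norm,
            n_perm=config.n_permutations,
            rank_index=config.fwer_rank,
            seed=config.seed,
            stratified=config.stratified_shuffle,
        )
    genes = norm.genes
    gene_ix = {g: i for i, g in enumerate(genes)}
    k = len(tables)
    pmat = np.ones((len(genes), k))
    signs = np.zeros((len(genes), k))
    weights = np.empty(k)
    for j, t in enumerate(tables):
        if per_experiment is not None and t.experiment_id in per_experiment:
            df = per_experiment[t.experiment_id]
            p_by_gene = dict(zip(df["gene"], df["p"]))
            sgn_by_gene = dict(zip(df["gene"], np.sign(df.get("t", pd.Series(np.zeros(len(df)))))))
        else:
            df = per_experiment_test(t, "two-sided")
            p_by_gene = dict(zip(df["gene"], df["p"]))
            sgn_by_gene = dict(zip(df["gene"], np.sign(df["t"])))
        for g, p in p_by_gene.items():
            if g in gene_ix:
                pmat[gene_ix[g], j] = p
                signs[gene_ix[g], j] = sgn_by_gene.get(g, 0)
        n_j = len(t.samples)
        weights[j] = math.sqrt(n_j) if config.stouffer_weighting == "sqrt_n" else n_j
    p_fisher = np.array([combine_fisher(pmat[i]) for i in range(len(genes))])
    p_stouffer = np.array(
        [combine_stouffer(pmat[i], weights) for i in range(len(genes))]
    )
    # Stouffer on two-sided p-values is direction-blind; combined on the
    # two-sided scale, direction is enforced separately below.
    m = len(genes)
    adj_fisher = bonferroni_adjust(p_fisher, m)
    adj_stouffer = bonferroni_adjust(p_stouffer, m)
    rows = []
    for i, g in enumerate(genes):
        pp = float(pooled.loc[g, "p"])
        sign_pooled = int(pooled.loc[g, "sign"])
        pass_pooled = pp < fwer_threshold
        pass_fisher = adj_fisher[i] < config.de_bonferroni_alpha
        pass_stouffer = adj_stouffer[i] < config.de_bonferroni_alpha
        maj = np.sum(signs[i] == sign_pooled) >= k / 2.0
        is_de = bool(pass_pooled and pass_fisher and pass_stouffer and sign_pooled != 0 and maj)
        direction = "none"
        if is_de:
            direction = "up" if sign_pooled > 0 else "down"
        rows.append(
            GeneMetaResult(
                gene=g,
                p_pooled=pp,
                sign_pooled=sign_pooled,
                p_fisher=float(p_fisher[i]),
                p_stouffer=float(p_stouffer[i]),
                adj_fisher=float(adj_fisher[i]),
                adj_stouffer=float(adj_stouffer[i]),
                pass_pooled=bool(pass_pooled),
                pass_fisher=bool(pass_fisher),
                pass_stouffer=bool(pass_stouffer),
                is_de=is_de,
                direction=direction,
            )
        )
    df = pd.DataFrame([r.__dict__ for r in rows])
    df.attrs["fwer_threshold"] = fwer_threshold
    return df


def rank_transform(per_experiment_down_p: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Order-statistic normalisation of one-sided (down) p-values.

    Within each experiment the genes are sorted by increasing p; the gene
    at rank i of m receives (i - 0.5) / m, so 0 is the most down-regulated
    and 1 the most up-regulated.  Ties are broken by gene id.
    """
    cols = {}
    for expt_id in sorted(per_experiment_down_p):
        df = per_experiment_down_p[expt_id]
        sub = df[["gene", "p"]].sort_values(["p", "gene"], kind="stable")
        m = len(sub)
        ranks = (np.arange(1, m + 1) - 0.5) / m
        cols[expt_id] = pd.Series(ranks, index=sub["gene"].to_numpy())
    return pd.DataFrame(cols).sort_index()


def rbp_down_enrichment(
    de_results: pd.DataFrame, rbp_list: list[str]
) -> tuple[float, float, tuple[int, int, int, int]]:
    """Fisher enrichment of RBPs among consistently down-regulated genes.

    Returns (odds_ratio, one-sided p, (a, b, c, d)) for the 2x2 table
    {RBP, non-RBP} x {down-DE, not}.
    """
    if not rbp_list:
        raise ValueError("rbp_list must be nonempty")
    universe = set(de_results["gene"])
    rbps = set(rbp_list) & universe
    if not rbps:
        raise ValueError("no RBP from the list is in the tested gene universe")
    down = set(de_results.loc[de_results["direction"] == "down", "gene"])
    a = len(rbps & down)
    b = len(rbps - down)
    c = len(down - rbps)
    d = len(universe - rbps - down)
    oratio, p = fisher_exact_enrichment(a, b, c, d)
    return oratio, p, (a, b, c, d)


def cluster_rank_matrix(
    rank_matrix: pd.DataFrame, k_rows: int, k_cols: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Agglomerative clustering (Euclidean, average linkage) of the rank
    matrix on both the gene and the experiment dimension.

    Returns (row_labels, col_labels, row_linkage, col_linkage).
    """
    x = rank_matrix.to_numpy()
    row_link = linkage(x, method="average", metric="euclidean")
    col_link = linkage(x.T, method="average", metric="euclidean")
    row_labels = fcluster(row_link, t=k_rows, criterion="maxclust")
    col_labels = fcluster(col_link, t=k_cols, criterion="maxclust")
    return row_labels, col_labels, row_link, col_link
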