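"""Differential-expression meta-analysis: normalisation, tests, consensus."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from senesplice import de_meta
from senesplice.model import AnalysisConfig, ExperimentTable
from senesplice.simulate import simulate_experiments

from conftest import small_params


def make_table(counts, n_sen, experiment_id="E1"):
    counts = np.asarray(counts)
    n = counts.shape[1]
    return ExperimentTable(
        experiment_id=experiment_id,
        genes=[f"g{i}" for i in range(counts.shape[0])],
        samples=[f"s{j}" for j in range(n)],
        counts=counts,
        group=["senescent"] * n_sen + ["growing"] * (n - n_sen),
    )


class TestNormalization:
    def test_identical_samples_unit_size_factors(self):
        counts = np.tile([[10], [20], [30]], (1, 4))
        sf = de_meta.size_factors(counts)
        np.testing.assert_allclose(sf, np.ones(4))

    def test_doubled_sample_gets_size_factor_two(self):
        a = np.array([[10], [20], [30]])
        counts = np.hstack([a, 2 * a])
        sf = de_meta.size_factors(counts)
        np.testing.assert_allclose(sf[1] / sf[0], 2.0)
        norm = counts / sf
        np.testing.assert_allclose(norm[:, 0], norm[:, 1])

    def test_quantile_normalization_hand_example(self):
        # columns (1,5,9) and (3,7,11): both become the row-wise sorted means
        x = np.array([[1.0, 3], [5, 7], [9, 11]])
        out = de_meta.quantile_normalize(x)
        np.testing.assert_allclose(out[:, 0], [2, 6, 10])
        np.testing.assert_allclose(out[:, 1], [2, 6, 10])

    def test_quantile_normalization_respects_ranks(self):
        x = np.array([[5.0, 1], [1, 5], [3, 3]])
        out = de_meta.quantile_normalize(x)
        assert out[0, 0] == out[1, 1] and out[1, 0] == out[0, 1]

    def test_gene_universe_is_intersection(self):
        t1 = make_table(np.ones((3, 4), dtype=int), 2, "E1")
        t2 = make_table(np.ones((3, 4), dtype=int), 2, "E2")
        t2.genes = ["g1", "g2", "gX"]
        norm = de_meta.normalize_counts([t1, t2])
        assert norm.genes == ["g1", "g2"]


class TestPooledAndPermutation:
    def test_pooled_t_identical_groups(self):
        counts = np.tile([[10, 10, 10, 10]], (3, 1))
        norm = de_meta.normalize_counts([make_table(counts, 2)])
        res = de_meta.pooled_t_test(norm)
        assert (res["p"] == 1.0).all()

    def test_threshold_is_rank_order_statistic(self, monkeypatch):
        minps = (np.arange(1, 1001)) / 1000.0
        rng = np.random.default_rng(0)
        shuffled = rng.permutation(minps)
        monkeypatch.setattr(
            de_meta, "_batched_min_welch_p", lambda x, masks, n1: shuffled.copy()
        )
        counts = rng.integers(1, 100, size=(20, 8))
        norm = de_meta.normalize_counts([make_table(counts, 4)])
        thr = de_meta.permutation_fwer_threshold(norm, n_perm=1000, rank_index=50)
        assert thr == pytest.approx(0.05)
        thr1 = de_meta.permutation_fwer_threshold(norm, n_perm=1000, rank_index=1)
        assert thr1 == pytest.approx(0.001)

    def test_rank_exceeding_perms_rejected(self):
        counts = np.random.default_rng(0).integers(1, 100, size=(5, 8))
        norm = de_meta.normalize_counts([make_table(counts, 4)])
        with pytest.raises(ValueError):
            de_meta.permutation_fwer_threshold(norm, n_perm=10, rank_index=50)


class TestPerExperiment:
    def test_symmetric_data_one_sided_half(self):
        counts = np.array([[10, 10, 10, 10, 10, 10]])
        t = make_table(counts, 3)
        down = de_meta.per_experiment_test(t, "down")
        up = de_meta.per_experiment_test(t, "up")
        assert down["p"].iloc[0] == pytest.approx(0.5)
        assert up["p"].iloc[0] == pytest.approx(0.5)

    def test_constant_gene_two_sided_p_one(self):
        counts = np.array([[7, 7, 7, 7, 7, 7], [3, 3, 3, 3, 3, 3]])
        t = make_table(counts, 3)
        res = de_meta.per_experiment_test(t)
        assert (res["p"] == 1.0).all()

    def test_null_p_near_uniform(self):
        """Calibration: Welch p on null count data is close to uniform.

        The t approximation on log counts is not exact at n = 4 + 4, so
        the check bounds the deviation (KS statistic and lower-tail mass)
        rather than demanding exact uniformity.
        """
        rng = np.random.default_rng(12)
        counts = rng.poisson(200, size=(5000, 8))
        t = make_table(counts, 4)
        res = de_meta.per_experiment_test(t)
        stat, _ = sps.kstest(res["p"], "uniform")
        assert stat < 0.03
        assert abs((res["p"] < 0.05).mean() - 0.05) < 0.02
        assert abs((res["p"] < 0.5).mean() - 0.5) < 0.03


class TestConsensusCalling:
    def _study(self, seed=21):
        params = small_params(seed=seed)
        return simulate_experiments(params)

    def test_gene_passing_two_of_three_not_de(self):
        tables, _ = self._study()
        cfg = AnalysisConfig(seed=1, n_permutations=50, fwer_rank=5)
        de = de_meta.call_consensus_de(tables, cfg, fwer_threshold=0.0)
        # threshold 0 means nothing passes the pooled route
        assert not de["pass_pooled"].any()
        assert not de["is_de"].any()

    def test_recovery_on_planted_study(self):
        """Planted 2-fold DE recovered with high sensitivity, no false calls
        in the wrong direction."""
        sens_all, fdp_all = [], []
        for seed in (31, 32, 33):
            params = small_params(seed=seed, n_genes=800)
            tables, truth = simulate_experiments(params)
            de = de_meta.call_consensus_de(tables, AnalysisConfig(seed=seed))
            up = set(de[de["direction"] == "up"]["gene"])
            down = set(de[de["direction"] == "down"]["gene"])
            truth_all = truth.de_up | truth.de_down
            correct = (up & truth.de_up) | (down & truth.de_down)
            sens_all.append(len(correct) / len(truth_all))
            called = up | down
            fdp_all.append(len(called - truth_all) / max(len(called), 1))
        assert np.mean(sens_all) >= 0.7
        assert np.mean(fdp_all) <= 0.05

    def test_direction_labels_match_pooled_sign(self):
        tables, _ = self._study()
        de = de_meta.call_consensus_de(tables, AnalysisConfig(seed=2))
        called = de[de["is_de"]]
        assert ((called["direction"] == "up") == (called["sign_pooled"] > 0)).all()
        assert (de.loc[~de["is_de"], "direction"] == "none").all()


class TestRankTransform:
    def test_hand_example(self):
        df = pd.DataFrame({"gene": ["a", "b", "c"], "p": [0.01, 0.5, 0.99]})
        rank = de_meta.rank_transform({"E1": df})
        np.testing.assert_allclose(
            rank.loc[["a", "b", "c"], "E1"], [1 / 6, 3 / 6, 5 / 6]
        )

    def test_ties_broken_by_gene_id(self):
        df = pd.DataFrame({"gene": ["b", "a", "c"], "p": [0.5, 0.5, 0.5]})
        rank = de_meta.rank_transform({"E1": df})
        np.testing.assert_allclose(
            rank.loc[["a", "b", "c"], "E1"], [1 / 6, 3 / 6, 5 / 6]
        )

    def test_each_column_is_exact_permutation(self):
        rng = np.random.default_rng(5)
        dfs = {
            f"E{j}": pd.DataFrame(
                {"gene": [f"g{i}" for i in range(9)], "p": rng.uniform(size=9)}
            )
            for j in range(3)
        }
        rank = de_meta.rank_transform(dfs)
        for col in rank.columns:
            np.testing.assert_allclose(
                np.sort(rank[col]), (np.arange(1, 10) - 0.5) / 9
            )


class TestRbpEnrichment:
    def _de_frame(self, down_genes, universe):
        return pd.DataFrame(
            {
                "gene": sorted(universe),
                "direction": ["down" if g in down_genes else "none" for g in sorted(universe)],
            }
        )

    def test_perfect_enrichment(self):
        universe = {f"r{i}" for i in range(10)} | {f"g{i}" for i in range(10)}
        de = self._de_frame({f"r{i}" for i in range(10)}, universe)
        oratio, p, table = de_meta.rbp_down_enrichment(de, [f"r{i}" for i in range(10)])
        assert p == pytest.approx(1 / 184756, rel=1e-9)
        assert table == (10, 0, 0, 10)

    def test_no_down_rbps_gives_p_one(self):
        universe = {f"r{i}" for i in range(5)} | {f"g{i}" for i in range(10)}
        de = self._de_frame({"g1", "g2"}, universe)
        _, p, _ = de_meta.rbp_down_enrichment(de, [f"r{i}" for i in range(5)])
        assert p == pytest.approx(1.0)

    def test_empty_rbp_list_rejected(self):
        de = self._de_frame(set(), {"g1"})
        with pytest.raises(ValueError):
            de_meta.rbp_down_enrichment(de, [])


class TestClustering:
    def test_block_matrix_recovered(self):
        x = np.zeros((8, 6))
        x[:4, :3] = 1.0
        rank = pd.DataFrame(x)
        rows, cols, _, _ = de_meta.cluster_rank_matrix(rank, 2, 2)
        assert len(set(rows[:4])) == 1 and len(set(rows[4:])) == 1
        assert rows[0] != rows[4]
        assert cols[0] != cols[3]

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=(10, 5))
        rank = pd.DataFrame(x)
        rows, _, _, _ = de_meta.cluster_rank_matrix(rank, 3, 2)
        perm = rng.permutation(10)
        rows_p, _, _, _ = de_meta.cluster_rank_matrix(pd.DataFrame(x[perm]), 3, 2)
        # same partition up to relabeling
        for i in range(10):
            for j in range(10):
                same = rows[perm[i]] == rows[perm[j]]
                same_p = rows_p[i] == rows_p[j]
                assert same == same_p
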