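import itertools
import math

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from plexscreen.dge import (DgeThresholds, OraConfig, PseudobulkMatrix,
                            SubsampleConfig, aggregate_pseudobulk,
                            average_log2_cpm, count_degs,
                            filter_low_expression, moa_union_genes, nbql_test,
                            ora, partition_group, tmm_factors)
from plexscreen.io import (CountMatrixHandle, GeneAnnotation,
                           GeneSetCollection, ValidationError)


class TestPartition:
    @pytest.mark.parametrize("n,expected_sizes", [
        (29, [10, 10, 9]),
        (15, [10, 5]),
        (20, [10, 10]),
        (25, [10, 10, 5]),
    ])
    def test_chunking_rules(self, n, expected_sizes):
        subsets = partition_group([f"c{i}" for i in range(n)])
        assert sorted((len(s) for s in subsets), reverse=True) == expected_sizes

    @pytest.mark.parametrize("n", [1, 5, 10, 14])
    def test_small_groups_excluded(self, n):
        assert partition_group([f"c{i}" for i in range(n)]) is None

    def test_fourteen_cells_keep_single_subset_then_excluded(self):
        # 14 -> [10, 4]; the 4-cell remainder is dropped, one subset remains
        assert partition_group(list(range(14))) is None
        assert partition_group(list(range(15))) is not None

    def test_exclusion_boundary_by_enumeration(self):
        excluded = [n for n in range(1, 1001)
                    if partition_group(list(range(n))) is None]
        assert max(excluded) == 14
        assert excluded == list(range(1, 15))

    def test_subsets_partition_the_group(self):
        ids = [f"c{i}" for i in range(57)]
        subsets = partition_group(ids, SubsampleConfig(seed=3),
                                  group_key=("JHOS2", "drug01"))
        # 57 -> [10]*5 + [7]; the 7-cell remainder is kept, nothing dropped
        assert sorted(len(s) for s in subsets) == [7, 10, 10, 10, 10, 10]
        flat = [c for s in subsets for c in s]
        assert sorted(flat) == sorted(ids)

    def test_group_key_gives_independent_shuffles(self):
        ids = list(range(40))
        a = partition_group(ids, group_key=("m", "drug01"))
        b = partition_group(ids, group_key=("m", "drug02"))
        assert a != b
        a2 = partition_group(ids, group_key=("m", "drug01"))
        assert a == a2


def pb_from(counts, labels=None):
    counts = np.asarray(counts)
    n = counts.shape[1]
    return PseudobulkMatrix(counts, [f"G{i}" for i in range(counts.shape[0])],
                            [f"s{i}" for i in range(n)],
                            labels or [f"s{i}" for i in range(n)])


class TestAggregate:
    def handle(self, dense):
        dense = np.asarray(dense)
        return CountMatrixHandle(sp.csr_matrix(dense),
                                 [f"G{i}" for i in range(dense.shape[0])],
                                 [f"c{i}" for i in range(dense.shape[1])])

    def test_two_cell_sum(self):
        h = self.handle([[1, 3], [2, 4]])
        pb = aggregate_pseudobulk(h, {"s0": ["c0", "c1"]})
        np.testing.assert_array_equal(pb.counts[:, 0], [4, 6])

    def test_singleton_subset_equals_cell(self):
        h = self.handle([[5], [0]])
        pb = aggregate_pseudobulk(h, {"s0": ["c0"]})
        np.testing.assert_array_equal(pb.counts[:, 0], [5, 0])

    def test_total_count_conservation(self):
        rng = np.random.default_rng(0)
        dense = rng.integers(0, 20, size=(30, 25))
        h = self.handle(dense)
        cells = [f"c{i}" for i in range(25)]
        subsets = {f"s{j}": cells[j * 5:(j + 1) * 5] for j in range(5)}
        pb = aggregate_pseudobulk(h, subsets)
        assert pb.counts.sum() == dense.sum()

    def test_unknown_cell_rejected(self):
        h = self.handle([[1]])
        with pytest.raises(ValidationError, match="unknown cell"):
            aggregate_pseudobulk(h, {"s0": ["nope"]})


class TestLowExpressionFilter:
    def test_all_zero_gene_removed(self):
        # realistic library sizes (~1e6) so the prior count stays sub-CPM
        counts = np.array([[0, 0], [100, 100], [999900, 999900]])
        pb = pb_from(counts)
        filtered, _ = filter_low_expression(pb)
        assert "G0" not in filtered.gene_ids
        assert "G2" in filtered.gene_ids

    def test_boundary_follows_direct_formula_oracle(self):
        # independent oracle: avg log2 cpm with prior 2 computed by hand
        lib_target = 1.0e6
        counts = np.zeros((2, 2))
        counts[1] = lib_target - 1.0
        counts[0] = 1.0
        pb = pb_from(counts)
        lib = counts.sum(axis=0)
        prior = 2.0 * lib / lib.mean()
        oracle = np.log2((counts + prior) / (lib + 2 * prior) * 1e6).mean(axis=1)
        np.testing.assert_allclose(average_log2_cpm(pb), oracle, rtol=1e-12)
        filtered, _ = filter_low_expression(pb)
        expected = [g for g, v in zip(pb.gene_ids, oracle) if v >= 1.0]
        assert filtered.gene_ids == expected

    def test_gene_at_exact_cutoff_kept(self):
        pb = pb_from(np.array([[10, 10], [1000, 1000]]))
        avg = average_log2_cpm(pb)
        thr = DgeThresholds(low_expr_avg_log2cpm=float(avg[0]))
        filtered, _ = filter_low_expression(pb, thr)
        assert "G0" in filtered.gene_ids  # strict '<' removes, '==' keeps


class TestTmm:
    def test_identical_columns_give_unit_factors(self):
        rng = np.random.default_rng(1)
        col = rng.integers(0, 500, size=200)
        pb = pb_from(np.column_stack([col, col, col]))
        np.testing.assert_allclose(tmm_factors(pb), 1.0, atol=1e-12)

    def test_pure_depth_scaling_gives_unit_factors(self):
        rng = np.random.default_rng(2)
        col = rng.integers(1, 500, size=300)
        pb = pb_from(np.column_stack([col, 2 * col]))
        np.testing.assert_allclose(tmm_factors(pb), 1.0, atol=1e-9)

    def test_geometric_mean_is_one(self):
        rng = np.random.default_rng(3)
        counts = rng.negative_binomial(5, 0.01, size=(400, 6))
        pb = pb_from(counts)
        f = tmm_factors(pb)
        assert abs(np.log(f).mean()) < 1e-12
        assert np.all(f > 0)

    def test_all_zero_column_rejected(self):
        pb = pb_from(np.array([[1, 0], [2, 0]]))
        with pytest.raises(ValidationError):
            tmm_factors(pb)


def simulate_pseudobulk(rng, G=2000, n_per_arm=4, phi=0.05, lfc=None,
                        depth=10.0):
    base = rng.lognormal(3.0, 1.5, G)
    lfc = np.zeros(G) if lfc is None else lfc
    size = 1.0 / phi
    libf = rng.lognormal(0.0, 0.1, 2 * n_per_arm)
    mu_t = np.outer(base * np.exp2(lfc), libf[:n_per_arm]) * depth
    mu_c = np.outer(base, libf[n_per_arm:]) * depth
    mu = np.hstack([mu_t, mu_c])
    y = rng.negative_binomial(size, size / (size + mu))
    labels = ["treatment"] * n_per_arm + ["control"] * n_per_arm
    return pb_from(y, labels)


class TestNbqlTest:
    def test_null_type_one_error_is_calibrated(self):
        """Same-mean arms over 2,000 null genes: fraction of p < 0.05 in
        [0.03, 0.07]."""
        rng = np.random.default_rng(42)
        pb = simulate_pseudobulk(rng)
        pb, avg = filter_low_expression(pb)
        res = nbql_test(pb, factors=tmm_factors(pb), avg_log2cpm=avg)
        frac = float((res["pvalue"] < 0.05).mean())
        assert 0.03 <= frac <= 0.07

    def test_planted_log2fc_recovered(self):
        """Planted 4-fold genes recovered within +/-0.3 of log2FC=2 (median),
        4 subsets per arm."""
        rng = np.random.default_rng(7)
        G = 2000
        lfc = np.zeros(G)
        nonnull = rng.choice(G, size=200, replace=False)
        lfc[nonnull] = 2.0
        pb = simulate_pseudobulk(rng, G=G, lfc=lfc)
        pb, avg = filter_low_expression(pb)
        res = nbql_test(pb, factors=tmm_factors(pb), avg_log2cpm=avg)
        truth = dict(zip([f"G{i}" for i in range(G)], lfc))
        planted = res[res["gene"].map(truth) == 2.0]
        assert 1.7 <= planted["log2fc"].median() <= 2.3

    def test_empirical_fdr_controlled(self):
        """10% non-null at |log2FC|=2: empirical FDR among discoveries at
        FDR<0.01 stays below 0.05."""
        rng = np.random.default_rng(11)
        G = 2000
        lfc = np.zeros(G)
        nonnull = rng.choice(G, size=G // 10, replace=False)
        lfc[nonnull] = rng.choice([2.0, -2.0], size=nonnull.size)
        pb = simulate_pseudobulk(rng, G=G, lfc=lfc)
        pb, avg = filter_low_expression(pb)
        res = nbql_test(pb, factors=tmm_factors(pb), avg_log2cpm=avg)
        truth = dict(zip([f"G{i}" for i in range(G)], lfc))
        hits = res[res["fdr"] < 0.01]
        assert len(hits) > 0
        emp_fdr = float((hits["gene"].map(truth) == 0.0).mean())
        assert emp_fdr <= 0.05

    def test_fdr_dominates_pvalue(self):
        rng = np.random.default_rng(5)
        pb = simulate_pseudobulk(rng, G=300)
        pb, avg = filter_low_expression(pb)
        res = nbql_test(pb, factors=tmm_factors(pb), avg_log2cpm=avg)
        assert np.all(res["fdr"] >= res["pvalue"] - 1e-15)

    def test_undersized_group_rejected(self):
        pb = pb_from(np.ones((5, 3), dtype=int),
                     ["treatment", "control", "control"])
        with pytest.raises(ValidationError, match="fewer than 2"):
            nbql_test(pb, factors=np.ones(3))


class TestBenjaminiHochberg:
    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(st.lists(st.floats(1e-8, 1.0), min_size=1, max_size=10))
    def test_matches_step_up_definition(self, pvals):
        # brute-force step-up oracle
        p = np.asarray(pvals)
        n = p.size
        order = np.argsort(p, kind="stable")
        ranked = p[order]
        adj = ranked * n / np.arange(1, n + 1)
        adj = np.minimum.accumulate(adj[::-1])[::-1]
        oracle = np.empty(n)
        oracle[order] = np.minimum(adj, 1.0)
        np.testing.assert_allclose(
            multipletests(p, method="fdr_bh")[1], oracle, rtol=1e-12)


ANNOTATION = GeneAnnotation(pd.DataFrame({
    "symbol": ["A", "B", "C", "D", "LNC1"],
    "biotype": ["protein_coding"] * 4 + ["lncRNA"],
}))


class TestDegCounting:
    def dge_frame(self, rows):
        return pd.DataFrame(rows, columns=["gene", "log2fc", "fdr"])

    def test_thresholds_are_strict_and_biotype_aware(self):
        dge = self.dge_frame([
            ("A", 0.5, 0.005),    # log2FC exactly at cutoff: not counted
            ("B", 1.2, 0.005),    # counted up
            ("C", -0.8, 0.0099),  # counted down
            ("D", 0.9, 0.01),     # FDR exactly at cutoff: not counted
            ("LNC1", 2.0, 1e-5),  # non-coding: not counted
        ])
        assert count_degs(dge, ANNOTATION) == (1, 1)

    def test_moa_union(self):
        d1 = self.dge_frame([("A", 0.3, 0.005), ("B", 0.9, 0.001)])
        d2 = self.dge_frame([("B", 0.4, 0.002), ("C", 0.26, 0.003),
                             ("LNC1", 3.0, 1e-6)])
        union = moa_union_genes([d1, d2], "up", ANNOTATION)
        assert union == {"A", "B", "C"}  # 0.3 and 0.26 pass the 0.25 cutoff
        assert moa_union_genes([self.dge_frame([])], "down", ANNOTATION) == set()


class TestOra:
    def test_exact_hypergeometric_value(self):
        background = [f"g{i}" for i in range(20)]
        coll = GeneSetCollection({"S": background[:5]})
        table = ora(background[:5], coll, background,
                    OraConfig(fdr_cutoff=0.999999))
        expected = 1.0 / math.comb(20, 5)
        np.testing.assert_allclose(table["pvalue"].iloc[0], expected,
                                   rtol=1e-12)

    def test_matches_enumeration_oracle_on_small_universes(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            M = int(rng.integers(5, 31))
            background = [f"g{i}" for i in range(M)]
            n_set = int(rng.integers(1, M + 1))
            n_query = int(rng.integers(1, M + 1))
            gene_set = list(rng.choice(background, n_set, replace=False))
            query = list(rng.choice(background, n_query, replace=False))
            k = len(set(gene_set) & set(query))
            # oracle: enumerate P(overlap >= k) by summation of the
            # hypergeometric pmf written out with binomial coefficients
            p_oracle = sum(
                math.comb(n_set, j) * math.comb(M - n_set, n_query - j)
                for j in range(k, min(n_set, n_query) + 1)
            ) / math.comb(M, n_query)
            coll = GeneSetCollection({"S": gene_set})
            table = ora(query, coll, background, OraConfig(fdr_cutoff=0.999999))
            if len(table) == 0:
                # only p = 1 rows (zero enrichment) are ever suppressed
                assert p_oracle > 0.999999
            else:
                np.testing.assert_allclose(table["pvalue"].iloc[0], p_oracle,
                                           rtol=1e-10)

    def test_zero_overlap_never_reported(self):
        background = [f"g{i}" for i in range(30)]
        coll = GeneSetCollection({"S": background[10:20]})
        table = ora(background[:5], coll, background)
        assert len(table) == 0  # p = 1 region

    def test_cap_at_twenty_most_significant(self):
        rng = np.random.default_rng(1)
        background = [f"g{i}" for i in range(200)]
        query = background[:30]
        sets = {f"S{i}": background[:25 + i] for i in range(30)}
        table = ora(query, GeneSetCollection(sets), background,
                    OraConfig(fdr_cutoff=0.9999))
        assert len(table) <= 20

    def test_empty_query_gives_empty_table(self):
        coll = GeneSetCollection({"S": ["a", "b", "c"]})
        assert len(ora([], coll, ["A", "B", "C"])) == 0

    def test_query_outside_background_rejected(self):
        coll = GeneSetCollection({"S": ["a"]})
        with pytest.raises(ValidationError):
            ora(["z"], coll, ["a", "b"])

    def test_allowlist_filters_names(self):
        background = [f"g{i}" for i in range(20)]
        coll = GeneSetCollection({"KEEP": background[:5],
                                  "DROP": background[:5]})
        table = ora(background[:5], coll, background,
                    OraConfig(fdr_cutoff=0.999999, allowlist=["keep"]))
        assert list(table["name"]) == ["KEEP"]
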