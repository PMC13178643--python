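"""QC, normalization, classification and bootstrap-DEG tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import sparse

from stimpd import synthetic
from stimpd.transcriptomics import (
    BootstrapConfig,
    CountMatrix,
    DEGCountDistribution,
    EmptyFilterError,
    NormalizedMatrix,
    bootstrap_deg_counts,
    classify_projection,
    compare_regions,
    gene_sex_comparison,
    normalize_log1p,
    qc_filter,
    rank_genes_wilcoxon,
)


def matrix_from_dense(dense, gene_ids=None, sexes=None, samples=None):
    dense = np.asarray(dense)
    n_genes, n_cells = dense.shape
    gene_ids = gene_ids or [f"g{i}" for i in range(n_genes)]
    meta = pd.DataFrame(
        {
            "nucleus_id": [f"c{i}" for i in range(n_cells)],
            "sex": sexes if sexes is not None else ["F"] * n_cells,
            "sample": samples if samples is not None else ["s1"] * n_cells,
        }
    )
    return CountMatrix(sparse.csr_matrix(dense), gene_ids, meta)


class TestQcFilter:
    def test_min_genes_boundary(self):
        # 300 genes; cell 0 expresses 199, cell 1 expresses 200, rest 250
        dense = np.zeros((300, 5), dtype=int)
        dense[:199, 0] = 1
        dense[:200, 1] = 1
        dense[:250, 2:] = 1
        cm = matrix_from_dense(dense)
        filtered, report = qc_filter(cm, min_cells=1, max_genes_percentile=100.0)
        assert report["min_genes"] == 1
        kept = set(filtered.nucleus_meta["nucleus_id"])
        assert "c0" not in kept and "c1" in kept

    def test_min_cells_boundary(self):
        dense = np.ones((5, 10), dtype=int)
        dense[0, :] = 0
        dense[0, :2] = 1  # gene 0 in 2 cells -> removed
        dense[1, :] = 0
        dense[1, :3] = 1  # gene 1 in 3 cells -> kept
        cm = matrix_from_dense(dense)
        filtered, report = qc_filter(cm, min_genes=1, max_genes_percentile=100.0)
        assert report["min_cells"] == 1
        assert "g0" not in filtered.gene_ids and "g1" in filtered.gene_ids

    def test_mito_rule_on_toy(self):
        # 10 cells; cell 0 has 10% mito counts, everyone else 0%
        dense = np.full((10, 10), 9, dtype=int)
        dense[0, :] = 0
        dense[0, 0] = 9  # gene 0 is mito: cell 0 total 90, mito 9 -> 10%
        cm = matrix_from_dense(dense, gene_ids=["mt-1"] + [f"g{i}" for i in range(1, 10)])
        filtered, report = qc_filter(
            cm, mito_gene_set=["mt-1"], min_genes=1, min_cells=1,
            max_genes_percentile=100.0,
        )
        assert report["max_mito_frac"] == 1
        assert "c0" not in set(filtered.nucleus_meta["nucleus_id"])

    def test_percentile_rule_removes_top_cell(self):
        rng = np.random.default_rng(0)
        dense = rng.poisson(1.0, size=(400, 50))
        dense[:, 0] = 1  # cell 0 expresses every gene
        cm = matrix_from_dense(dense)
        filtered, report = qc_filter(cm, min_genes=1, min_cells=1,
                                     max_genes_percentile=98.0)
        assert report["max_genes_percentile"] >= 1
        assert "c0" not in set(filtered.nucleus_meta["nucleus_id"])

    def test_all_cells_removed_names_rule(self):
        dense = np.ones((10, 3), dtype=int)
        with pytest.raises(EmptyFilterError, match="min_genes"):
            qc_filter(matrix_from_dense(dense), min_genes=200)


class TestNormalize:
    def test_worked_example(self):
        dense = np.zeros((2, 1), dtype=int)
        dense[0, 0] = 2
        dense[1, 0] = 1998
        norm = normalize_log1p(matrix_from_dense(dense), target_sum=1e6)
        assert norm.values[0, 0] == pytest.approx(np.log1p(1000.0))

    def test_zero_count_stays_zero(self):
        dense = np.array([[0, 1], [5, 5]])
        norm = normalize_log1p(matrix_from_dense(dense))
        assert norm.values[0, 0] == 0.0

    def test_total_equal_target_is_log1p(self):
        dense = np.array([[3], [7]])
        norm = normalize_log1p(matrix_from_dense(dense), target_sum=10)
        assert norm.values[0, 0] == pytest.approx(np.log1p(3))

    def test_back_transformed_sums_hit_target(self):
        rng = np.random.default_rng(1)
        dense = rng.poisson(2.0, size=(50, 20)) + 1
        norm = normalize_log1p(matrix_from_dense(dense), target_sum=1e6)
        sums = np.asarray(np.expm1(norm.values.todense())).sum(axis=0)
        assert np.allclose(sums, 1e6, rtol=1e-6)

    def test_zero_total_cell_rejected(self):
        dense = np.array([[0, 1], [0, 1]])
        with pytest.raises(ValueError):
            normalize_log1p(matrix_from_dense(dense))


class TestClassify:
    def _norm(self, calb1, sox6, aldh1a1):
        values = np.array([calb1, sox6, aldh1a1], dtype=float)
        meta = pd.DataFrame({"nucleus_id": [f"c{i}" for i in range(values.shape[1])]})
        return NormalizedMatrix(sparse.csr_matrix(values),
                                ["Calb1", "Sox6", "Aldh1a1"], meta)

    def test_rule_table(self):
        norm = self._norm([1, 1, 1, 0], [1, 0, 1, 0], [0, 1, 1, 0])
        labels = classify_projection(norm)
        assert list(labels) == ["core", "shell", "ambiguous", "unassigned"]

    def test_monotone_rescaling_invariance(self):
        rng = np.random.default_rng(2)
        values = rng.poisson(1.0, size=(3, 30)).astype(float)
        meta = pd.DataFrame({"nucleus_id": [f"c{i}" for i in range(30)]})
        norm = NormalizedMatrix(sparse.csr_matrix(values),
                                ["Calb1", "Sox6", "Aldh1a1"], meta)
        scaled = NormalizedMatrix(sparse.csr_matrix(values * 7.3),
                                  ["Calb1", "Sox6", "Aldh1a1"], meta)
        assert list(classify_projection(norm)) == list(classify_projection(scaled))

    def test_missing_marker_rejected(self):
        norm = self._norm([1], [1], [1])
        with pytest.raises(ValueError):
            classify_projection(norm, markers=("Calb1", "Sox6", "Nosuch"))


class TestRankGenes:
    def test_identical_groups_null(self):
        values = np.tile(np.array([[1.0, 2.0, 3.0, 1.0, 2.0, 3.0]]), (1, 1))
        table = rank_genes_wilcoxon(values, ["g0"], np.arange(3), np.arange(3, 6))
        assert table.loc[0, "p_value"] == 1.0
        assert table.loc[0, "log2fc"] == pytest.approx(0.0)
        assert not table.loc[0, "significant"]

    def test_extreme_separation_statistic_matches_enumeration(self, u_oracle):
        values = np.array([[1.0, 2.0, 3.0, 4.0, 5.0, 6.0]])
        table = rank_genes_wilcoxon(values, ["g0"], np.arange(3), np.arange(3, 6))
        u_exp, _ = u_oracle([1, 2, 3], [4, 5, 6])
        assert table.loc[0, "statistic"] == u_exp == 0.0

    def test_log2fc_of_ratio_two(self):
        g1 = np.log1p(np.full(5, 4.0))
        g2 = np.log1p(np.full(5, 2.0))
        values = np.concatenate([g1, g2])[None, :]
        table = rank_genes_wilcoxon(values, ["g0"], np.arange(5), np.arange(5, 10))
        assert table.loc[0, "log2fc"] == pytest.approx(1.0, abs=1e-6)

    def test_padj_never_below_p(self):
        rng = np.random.default_rng(3)
        values = rng.normal(size=(40, 20))
        table = rank_genes_wilcoxon(values, [f"g{i}" for i in range(40)],
                                    np.arange(10), np.arange(10, 20))
        assert (table["padj"] >= table["p_value"] - 1e-15).all()
        assert (table["padj"] <= 1.0).all()


@pytest.fixture(scope="module")
def null_norm():
    cm = synthetic.simulate_counts(
        synthetic.CountSimParams(n_nuclei=30, n_genes=200, seed=4)
    )
    return normalize_log1p(cm)


class TestBootstrap:
    def test_single_iteration_length(self, null_norm):
        cfg = BootstrapConfig(n_boot=1, n_per_sex=10, seed=0)
        dist = bootstrap_deg_counts(null_norm, config=cfg, region="core")
        assert len(dist.counts) == 1

    def test_null_counts_small(self, null_norm):
        cfg = BootstrapConfig(n_boot=10, n_per_sex=20, seed=1)
        dist = bootstrap_deg_counts(null_norm, config=cfg)
        assert np.mean(dist.counts) <= 5

    def test_deterministic_given_seed(self, null_norm):
        cfg = BootstrapConfig(n_boot=5, n_per_sex=10, seed=7)
        a = bootstrap_deg_counts(null_norm, config=cfg)
        b = bootstrap_deg_counts(null_norm, config=cfg)
        assert a.counts == b.counts

    def test_permuted_labels_not_systematically_significant(self, null_norm):
        # label-exchangeability: permuting sexes should not manufacture
        # region differences (discrete p-values rule out a KS-vs-uniform check)
        rng = np.random.default_rng(5)
        sex = null_norm.nucleus_meta["sex"].to_numpy()
        pvals = []
        for k in range(8):
            perm = rng.permutation(sex)
            cfg_a = BootstrapConfig(n_boot=8, n_per_sex=15, seed=100 + k)
            cfg_b = BootstrapConfig(n_boot=8, n_per_sex=15, seed=200 + k)
            a = bootstrap_deg_counts(null_norm, sex_labels=perm, config=cfg_a)
            b = bootstrap_deg_counts(null_norm, sex_labels=perm, config=cfg_b)
            pvals.append(compare_regions(a, b).p_value)
        assert np.median(pvals) > 0.1

    def test_missing_sex_rejected(self, null_norm):
        labels = np.full(null_norm.values.shape[1], "F")
        with pytest.raises(ValueError):
            bootstrap_deg_counts(null_norm, sex_labels=labels)


class TestCompareRegions:
    def test_identical_distributions(self):
        a = DEGCountDistribution((3,) * 20, "core")
        b = DEGCountDistribution((3,) * 20, "shell")
        assert compare_regions(a, b).p_value >= 0.9

    def test_complete_separation_u(self):
        core = DEGCountDistribution(tuple(range(100, 150)), "core")
        shell = DEGCountDistribution(tuple(range(50)), "shell")
        res = compare_regions(core, shell)
        assert res.statistic == 2500  # n1 * n2

    def test_tiny_case_matches_enumeration(self, u_oracle):
        res = compare_regions(
            DEGCountDistribution((1, 2), "core"), DEGCountDistribution((3, 4), "shell")
        )
        u_exp, p_exp = u_oracle([1, 2], [3, 4])
        assert res.statistic == u_exp
        assert res.p_value == pytest.approx(p_exp)


class TestGeneSexComparison:
    def test_normal_samples_take_t_branch(self):
        rng = np.random.default_rng(6)
        vals = np.concatenate([rng.normal(0, 1, 20), rng.normal(0.5, 1, 20)])
        labels = ["F"] * 20 + ["M"] * 20
        assert gene_sex_comparison(vals, labels).method == "t_test"

    def test_skewed_samples_take_rank_branch(self):
        rng = np.random.default_rng(7)
        vals = np.concatenate([rng.lognormal(0, 2, 30), rng.lognormal(0.5, 2, 30)])
        labels = ["F"] * 30 + ["M"] * 30
        assert gene_sex_comparison(vals, labels).method == "mann_whitney"

    def test_identical_samples_p_one(self):
        vals = np.ones(10)
        labels = ["F"] * 5 + ["M"] * 5
        res = gene_sex_comparison(vals, labels)
        assert res.p_value == 1.0
        assert res.flagged

    def test_requires_three_per_sex(self):
        with pytest.raises(ValueError):
            gene_sex_comparison([1, 2, 3, 4], ["F", "F", "M", "M"])
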