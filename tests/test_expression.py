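"""Normalization, DE testing, shared-DEG intersection and PCA contracts."""

import numpy as np
import pandas as pd
import pytest

from thermotol.expression import CountMatrix, intersect_shared, normalize, run_pca
from thermotol.expression import test_de as run_de


def _cm(counts: dict, lengths: list) -> CountMatrix:
    df = pd.DataFrame(counts)
    df.index = pd.Index([f"g{i}" for i in range(len(df))], name="gene")
    return CountMatrix(df, pd.Series(lengths, index=df.index, name="length"))


class TestNormalize:
    def test_single_gene_tpm_is_one_million(self):
        cm = _cm({"s1": [7], "s2": [123]}, [500])
        tpm = normalize(cm, "TPM")
        assert np.allclose(tpm.to_numpy(), 1e6)

    def test_hand_worked_tpm(self):
        # counts (10, 90), equal lengths -> TPM (1e5, 9e5)
        cm = _cm({"s1": [10, 90]}, [1000, 1000])
        tpm = normalize(cm, "TPM")
        np.testing.assert_allclose(tpm["s1"].to_numpy(), [1e5, 9e5])

    def test_hand_worked_rpkm(self):
        # RPKM = 1e9 * c / (L * N); N = 100
        cm = _cm({"s1": [10, 90]}, [1000, 2000])
        rpkm = normalize(cm, "RPKM")
        np.testing.assert_allclose(
            rpkm["s1"].to_numpy(), [1e9 * 10 / (1000 * 100), 1e9 * 90 / (2000 * 100)]
        )

    def test_tpm_columns_sum_to_one_million(self, default_dataset):
        _, cm, _, _ = default_dataset
        tpm = normalize(cm, "TPM")
        np.testing.assert_allclose(tpm.sum(axis=0).to_numpy(), 1e6, rtol=1e-9)

    def test_zero_library_errors_with_sample_name(self):
        cm = _cm({"good": [5, 5], "empty": [0, 0]}, [100, 100])
        with pytest.raises(ValueError, match="empty"):
            normalize(cm, "TPM")

    def test_missing_length_errors_with_gene_name(self):
        df = pd.DataFrame({"s1": [1, 2]}, index=pd.Index(["a", "b"], name="gene"))
        with pytest.raises(ValueError, match="b"):
            CountMatrix(df, pd.Series([100.0], index=["a"]))


def _two_group(counts_a, counts_b, lengths=None):
    na, nb = counts_a.shape[1], counts_b.shape[1]
    cols = [f"a{i}" for i in range(na)] + [f"b{i}" for i in range(nb)]
    df = pd.DataFrame(np.hstack([counts_a, counts_b]), columns=cols)
    df.index = pd.Index([f"g{i}" for i in range(len(df))], name="gene")
    lengths = lengths or [1000] * len(df)
    cm = CountMatrix(df, pd.Series(lengths, index=df.index))
    meta = pd.DataFrame({"sample": cols, "group": ["A"] * na + ["B"] * nb})
    return cm, meta


class TestDifferentialExpression:
    def test_identical_groups_give_zero_lfc_p_one(self):
        x = np.array([[100, 110, 95, 100, 110, 95]] * 3)
        cm, meta = _two_group(x[:, :3], x[:, 3:])
        deg = run_de(cm, meta, "A", "B")
        np.testing.assert_allclose(deg["log2fc"], 0.0)
        assert (deg["p"] > 0.99).all()

    def test_all_zero_gene_is_filtered_with_sentinel(self):
        rng = np.random.default_rng(0)
        a = rng.poisson(50, size=(10, 3))
        b = rng.poisson(50, size=(10, 3))
        a[0] = b[0] = 0
        cm, meta = _two_group(a, b)
        deg = run_de(cm, meta, "A", "B")
        assert not deg.loc["g0", "passed_filter"]
        assert np.isnan(deg.loc["g0", "q"])
        assert not deg.loc["g0", "significant"]

    def test_missing_group_errors(self):
        cm, meta = _two_group(np.ones((3, 3), int) * 10, np.ones((3, 3), int) * 10)
        with pytest.raises(ValueError, match="'C'"):
            run_de(cm, meta, "A", "C")

    def test_single_replicate_errors(self):
        cm, meta = _two_group(np.ones((3, 1), int) * 10, np.ones((3, 3), int) * 10)
        with pytest.raises(ValueError, match="replicates"):
            run_de(cm, meta, "A", "B")

    def test_bh_q_monotone_in_p(self):
        rng = np.random.default_rng(1)
        cm, meta = _two_group(rng.poisson(30, (200, 4)), rng.poisson(30, (200, 4)))
        deg = run_de(cm, meta, "A", "B")
        sub = deg[deg["passed_filter"]].sort_values("p")
        assert (np.diff(sub["q"].to_numpy()) >= -1e-12).all()

    def test_filter_never_changes_p_order_of_retained_genes(self):
        rng = np.random.default_rng(2)
        counts_a = rng.poisson(rng.uniform(0.2, 50, 300)[:, None], (300, 5))
        counts_b = rng.poisson(rng.uniform(0.2, 50, 300)[:, None], (300, 5))
        cm, meta = _two_group(counts_a, counts_b)
        unfiltered = run_de(cm, meta, "A", "B", filter_threshold=0.0)
        filtered = run_de(cm, meta, "A", "B", filter_threshold=1.0)
        retained = filtered.index[filtered["passed_filter"]]
        np.testing.assert_allclose(
            filtered.loc[retained, "p"], unfiltered.loc[retained, "p"]
        )

    def test_planted_fold_change_recovered(self):
        """A 4-fold planted change (phi = 0.1, 6 vs 6) is estimated near
        log2FC = 2 on average across genes."""
        rng = np.random.default_rng(3)
        n = 300
        base = rng.lognormal(4.5, 1.0, n)
        # balanced up/down so normalization is not confounded by composition
        mu_a = base.copy()
        mu_a[:25] *= 4.0
        mu_a[25:50] /= 4.0
        phi = 0.1
        size = 1 / phi
        a = rng.negative_binomial(size, size / (size + mu_a[:, None]), (n, 6))
        b = rng.negative_binomial(size, size / (size + base[:, None]), (n, 6))
        cm, meta = _two_group(a, b)
        deg = run_de(cm, meta, "A", "B")
        med = float(np.median(deg["log2fc"].to_numpy()[:25]))
        assert 1.7 < med < 2.3


class TestIntersectShared:
    def test_worked_example(self, deg_table_factory):
        d1 = deg_table_factory({"g1": 2.0, "g2": -1.0, "g3": 4.0}, strain="s1")
        d2 = deg_table_factory({"g2": -3.0, "g3": 2.0, "g4": 1.0}, strain="s2")
        s = intersect_shared(d1, d2)
        assert s.shared_genes == ["g3", "g2"]  # ranked by avg log2FC desc
        np.testing.assert_allclose(s.table["avg_log2fc"].to_numpy(), [3.0, -2.0])
        assert s.venn == {"unique_s1": 1, "unique_s2": 1, "shared": 2}

    def test_disjoint_sets_share_nothing(self, deg_table_factory):
        d1 = deg_table_factory({"g1": 2.0}, strain="s1")
        d2 = deg_table_factory({"g2": 2.0}, strain="s2")
        s = intersect_shared(d1, d2)
        assert s.shared_genes == []
        assert s.shared_proportion == {"s1": 0.0, "s2": 0.0}

    def test_identical_sets_share_fully(self, deg_table_factory):
        sig = {"g1": 1.0, "g2": -2.0}
        s = intersect_shared(
            deg_table_factory(sig, strain="s1"), deg_table_factory(sig, strain="s2")
        )
        assert s.shared_proportion == {"s1": 1.0, "s2": 1.0}
        assert s.table["concordant"].all()

    def test_discordant_shared_gene_flagged_not_dropped(self, deg_table_factory):
        d1 = deg_table_factory({"g1": 2.0}, strain="s1")
        d2 = deg_table_factory({"g1": -2.0}, strain="s2")
        s = intersect_shared(d1, d2)
        assert s.shared_genes == ["g1"]
        assert not s.table["concordant"].iloc[0]

    def test_mismatched_comparisons_error(self, deg_table_factory):
        d1 = deg_table_factory({"g1": 1.0}, comparison="HvC")
        d2 = deg_table_factory({"g1": 1.0}, comparison="HvL")
        with pytest.raises(ValueError, match="comparison"):
            intersect_shared(d1, d2)


class TestPCA:
    def test_percent_variance_sums_to_100(self, default_dataset):
        _, cm, _, _ = default_dataset
        expr = normalize(cm, "TPM").iloc[:200]
        res = run_pca(expr)
        assert abs(res.percent_variance.sum() - 100.0) < 1e-6

    def test_perfectly_correlated_genes_load_on_pc1(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        expr = pd.DataFrame(
            [x, 2 * x + 5], index=["g1", "g2"], columns=[f"s{i}" for i in range(4)]
        )
        res = run_pca(expr)
        assert abs(res.percent_variance[0] - 100.0) < 1e-9
        assert res.n_retained == 1

    def test_constant_genes_dropped_then_error_if_too_few(self):
        expr = pd.DataFrame(
            np.ones((3, 4)), index=["a", "b", "c"], columns=list("wxyz")
        )
        with pytest.raises(ValueError, match="non-constant"):
            run_pca(expr)

    def test_group_structure_separates_on_leading_pcs(self):
        """Planted group mean shifts yield positive silhouette on PC1-PC2."""
        from sklearn.metrics import silhouette_score

        from thermotol.simulate import SimulationParams, simulate_counts
        from thermotol.expression import normalize as norm

        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            params = SimulationParams(n_genes=400, frac_de=0.2, seed=1000 + seed)
            cm, meta, truth = simulate_counts(params)
            sub = meta[meta["strain"] == params.strains[0]]
            expr = norm(cm, "TPM")[list(sub["sample"])]
            de_genes = sorted(
                set(truth.de[f"{params.strains[0]}:HvC"])
                | set(truth.de[f"{params.strains[0]}:LvC"])
            )
            res = run_pca(expr.loc[de_genes])
            scores = res.scores.iloc[:, :2].to_numpy()
            if silhouette_score(scores, sub["group"].to_numpy()) > 0:
                hits += 1
        assert hits >= int(0.95 * n_seeds)
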