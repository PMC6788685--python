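"""Discovery models: OLS against closed forms and statsmodels, BH, clustering."""
import numpy as np
import pandas as pd
import pytest
from scipy.cluster import hierarchy

from proteodiscover.containers import ProteinMatrix
from proteodiscover.discovery import (
    bh_adjust,
    build_design,
    cluster_candidates,
    fit_protein_lm,
    linkage_to_newick,
    nominate_candidates,
    run_discovery,
)


def _design_from(group, **covs):
    X = pd.DataFrame({"const": 1.0, "group": np.asarray(group, dtype=float)})
    for k, v in covs.items():
        X[k] = np.asarray(v, dtype=float)
    return X


class TestFitProteinLm:
    def test_two_sample_t_closed_form(self):
        """group-only OLS equals the pooled two-sample t test:
        y=(1,2,3 | 3,4,5) -> beta=2, se=sqrt(2/3), t=2.449, p~=0.0705."""
        y = pd.Series([1.0, 2, 3, 3, 4, 5])
        X = _design_from([0, 0, 0, 1, 1, 1])
        X.index = y.index
        row = fit_protein_lm(y, X)
        assert row["beta"] == pytest.approx(2.0)
        assert row["se"] == pytest.approx(0.8165, abs=1e-4)
        assert row["t"] == pytest.approx(2.449, abs=1e-3)
        assert row["df"] == 4
        assert row["p"] == pytest.approx(0.0705, abs=1e-3)

    def test_matches_statsmodels_on_random_battery(self):
        """Exhaustive small-fixture battery: <=10 samples, <=3 covariates,
        compared against the independent statsmodels OLS implementation."""
        import statsmodels.api as sm

        rng = np.random.default_rng(0)
        for trial in range(30):
            n = int(rng.integers(5, 11))
            k = int(rng.integers(0, 3))
            group = rng.integers(0, 2, n)
            if group.sum() in (0, n):
                group[0] = 1 - group[0]
            covs = {f"c{j}": rng.standard_normal(n) for j in range(k)}
            X = _design_from(group, **covs)
            y = pd.Series(rng.standard_normal(n))
            X.index = y.index
            row = fit_protein_lm(y, X)
            ref = sm.OLS(y.to_numpy(), X.to_numpy()).fit()
            assert row["beta"] == pytest.approx(ref.params[1], rel=1e-9)
            assert row["se"] == pytest.approx(ref.bse[1], rel=1e-9)
            assert row["p"] == pytest.approx(ref.pvalues[1], rel=1e-9)

    def test_orthogonal_covariate_leaves_group_beta(self):
        rng = np.random.default_rng(1)
        group = np.array([0, 0, 0, 0, 0, 1, 1, 1, 1, 1], dtype=float)
        z = rng.standard_normal(10)
        z = z - z.mean()
        # orthogonalize against group and intercept
        z = z - (z @ (group - group.mean())) / ((group - group.mean()) ** 2).sum() * (
            group - group.mean()
        )
        y = pd.Series(rng.standard_normal(10))
        X0 = _design_from(group)
        X1 = _design_from(group, z=z)
        X0.index = X1.index = y.index
        b0 = fit_protein_lm(y, X0)["beta"]
        b1 = fit_protein_lm(y, X1)["beta"]
        assert b1 == pytest.approx(b0, rel=1e-9)

    def test_collinear_terms_named(self):
        y = pd.Series(np.arange(6, dtype=float))
        X = _design_from([0, 0, 0, 1, 1, 1], dup=[0, 0, 0, 1, 1, 1])
        X.index = y.index
        with pytest.raises(ValueError, match="dup|group"):
            fit_protein_lm(y, X)

    def test_zero_residual_variance_rejected(self):
        y = pd.Series([0.0, 0, 0, 1, 1, 1])
        X = _design_from([0, 0, 0, 1, 1, 1])
        X.index = y.index
        with pytest.raises(ValueError, match="residual variance"):
            fit_protein_lm(y, X)


class TestRunDiscovery:
    def test_null_pvalues_roughly_uniform(self):
        rng = np.random.default_rng(2)
        n, p = 120, 400
        data = pd.DataFrame(
            rng.standard_normal((n, p)) + 3.0,
            index=[f"s{i}" for i in range(n)],
            columns=[f"p{j}" for j in range(p)],
        )
        meta = pd.DataFrame(
            {
                "group": ["PD"] * 60 + ["NC"] * 60,
                "age": rng.normal(70, 8, n),
                "sex": rng.choice(["F", "M"], n),
                "ledd": rng.uniform(0, 900, n),
            },
            index=data.index,
        )
        table = run_discovery(ProteinMatrix(data, scale="log10"), meta)
        from scipy import stats

        assert stats.kstest(table["p"], "uniform").pvalue > 0.01
        assert table["q"].ge(table["p"]).all()

    def test_permuted_labels_destroy_planted_signal(self, small_log_matrix):
        matrix, meta, truth = small_log_matrix
        rng = np.random.default_rng(3)
        perm_meta = meta.copy()
        perm_meta["group"] = rng.permutation(meta["group"].to_numpy())
        keep = [p for p in truth.planted_protein_ids if p in matrix.protein_ids]
        table = run_discovery(matrix, perm_meta)
        assert (table.loc[keep, "q"] >= 0.05).mean() >= 0.8

    def test_missing_ledd_column_raises_named_error(self, small_log_matrix):
        matrix, meta, _ = small_log_matrix
        with pytest.raises(KeyError, match="ledd"):
            run_discovery(matrix, meta.drop(columns=["ledd"]))


class TestNominate:
    def test_strict_threshold(self):
        table = pd.DataFrame(
            {"p": [0.004, 0.005, 0.006]},
            index=pd.Index(["a", "b", "c"], name="protein_id"),
        )
        assert nominate_candidates(table) == ["a"]

    def test_empty_and_permissive(self):
        empty = pd.DataFrame({"p": []}, index=pd.Index([], name="protein_id"))
        assert nominate_candidates(empty) == []
        table = pd.DataFrame(
            {"p": [0.9, 0.5]}, index=pd.Index(["a", "b"], name="protein_id")
        )
        assert nominate_candidates(table, p_threshold=1.0) == ["b", "a"]


class TestBH:
    @pytest.mark.parametrize(
        "pvals,expected",
        [
            ([0.03], [0.03]),
            ([0.01, 0.02, 0.03], [0.03, 0.03, 0.03]),
            ([0.005, 0.5], [0.01, 0.5]),
        ],
    )
    def test_hand_step_up(self, pvals, expected):
        assert np.allclose(bh_adjust(pvals), expected)

    def test_matches_hand_step_up_on_random_vectors(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            p = rng.uniform(size=int(rng.integers(1, 40)))
            # independent hand implementation of the step-up
            m = len(p)
            order = np.argsort(p)
            adj = p[order] * m / np.arange(1, m + 1)
            adj = np.minimum.accumulate(adj[::-1])[::-1]
            expected = np.empty(m)
            expected[order] = np.minimum(adj, 1.0)
            assert np.allclose(bh_adjust(p), expected)

    def test_monotone_and_bounded(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(size=50)
        q = bh_adjust(p)
        assert (q >= p).all() and (q <= 1).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()


class TestClustering:
    def test_identical_proteins_merge_at_zero(self):
        data = pd.DataFrame(
            {"a": [0.0, 1, 3], "b": [0.0, 1, 3], "c": [5.0, 1, 0]},
            index=["s1", "s2", "s3"],
        )
        res = cluster_candidates(ProteinMatrix(data, scale="log10"), ["a", "b", "c"])
        assert res.protein_linkage[0, 2] == pytest.approx(0.0)

    def test_average_linkage_hand_example(self):
        """Samples at 1-D positions {0,1,3} (duplicated over two identical
        proteins): merge {0,1} first, then join {3} at 2.5x that height --
        the average-linkage arithmetic, invariant to the affine z-scaling."""
        data = pd.DataFrame(
            {"a": [0.0, 1, 3], "b": [0.0, 1, 3]}, index=["s1", "s2", "s3"]
        )
        res = cluster_candidates(ProteinMatrix(data, scale="log10"), ["a", "b"])
        h = res.sample_linkage[:, 2]
        assert h[1] / h[0] == pytest.approx(2.5)
        assert res.sample_order.index("s3") in (0, 2)  # outlier is a terminal leaf

    def test_leaf_order_stable_under_column_shuffle(self, small_log_matrix):
        matrix, _, truth = small_log_matrix
        ids = [p for p in truth.planted_protein_ids if p in matrix.protein_ids][:6]
        r1 = cluster_candidates(matrix, ids)
        r2 = cluster_candidates(matrix, ids[::-1])
        # same partition structure: identical cophenetic heights
        assert np.allclose(
            np.sort(r1.protein_linkage[:, 2]), np.sort(r2.protein_linkage[:, 2])
        )

    def test_constant_protein_rejected(self):
        data = pd.DataFrame({"a": [1.0, 1, 1], "b": [0.0, 1, 2]}, index=list("xyz"))
        with pytest.raises(ValueError, match="constant"):
            cluster_candidates(ProteinMatrix(data, scale="log10"), ["a", "b"])

    def test_newick_export_parses(self):
        Z = hierarchy.linkage(np.array([[0.0], [1.0], [3.0]]), method="average")
        nwk = linkage_to_newick(Z, ["x", "y", "z"])
        assert nwk.endswith(";") and nwk.count("(") == 2
        for label in ("x", "y", "z"):
            assert label in nwk
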