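"""Replication design, direction concordance, specificity, rank-sum tests."""
import itertools

import numpy as np
import pandas as pd
import pytest

from proteodiscover.containers import ProteinMatrix
from proteodiscover.discovery import run_discovery
from proteodiscover.qc import log10_transform
from proteodiscover.replication import (
    check_replication,
    multigroup_specificity,
    never_treated_comparison,
    run_replication,
)
from proteodiscover.simulate import SimConfig, generate_cohort


@pytest.fixture(scope="module")
def replication_cohort():
    cfg = SimConfig(
        n_pd=215, n_nc=102, n_proteins=150, n_planted=8, delta=0.12,
        n_sites=2, n_batches=5, censor_frac_target=0.0, n_high_cv=0, seed=21,
    )
    matrix, meta, truth = generate_cohort(cfg)
    return log10_transform(matrix), meta, truth


class TestRunReplication:
    def test_planted_effects_replicate(self, replication_cohort):
        matrix, meta, truth = replication_cohort
        table = run_replication(matrix, meta, truth.planted_protein_ids)
        assert (table["q"] < 0.05).mean() >= 0.75
        signs = np.sign(truth.delta_per_protein[truth.planted_protein_ids])
        hits = table["q"] < 0.05
        assert (table.loc[hits, "direction"] == signs[hits]).all()

    def test_absent_protein_untestable_not_failed(self, replication_cohort):
        matrix, meta, truth = replication_cohort
        ids = truth.planted_protein_ids[:2] + ["prot_nonexistent"]
        table = run_replication(matrix, meta, ids)
        assert not table.loc["prot_nonexistent", "testable"]
        assert table.loc[ids[0], "testable"]

    def test_batch_shift_without_group_effect_absorbed(self):
        """Confound-only null: strong per-batch shifts but no group effect
        must not produce significant group coefficients."""
        cfg = SimConfig(n_pd=100, n_nc=100, n_proteins=120, n_planted=0,
                        n_sites=2, n_batches=5, batch_sd=0.4, site_sd=0.3,
                        censor_frac_target=0.0, n_high_cv=0, seed=22)
        matrix, meta, _ = generate_cohort(cfg)
        table = run_replication(log10_transform(matrix), meta,
                                list(matrix.protein_ids[:20]))
        assert (table["q"] >= 0.05).all()

    def test_design_nesting_matches_discovery(self):
        """Dropping site/batch from the replication design reproduces the
        discovery estimator on the same data."""
        cfg = SimConfig(n_pd=80, n_nc=60, n_proteins=40, n_planted=4,
                        censor_frac_target=0.0, n_high_cv=0, seed=23)
        matrix, meta, _ = generate_cohort(cfg)
        lg = log10_transform(matrix)
        ids = list(matrix.protein_ids[:10])
        rep = run_replication(lg, meta, ids, covariates=("age", "sex"))
        disc = run_discovery(lg, meta, covariates=("age", "sex")).loc[ids]
        assert np.allclose(rep["beta"], disc["beta"])
        assert np.allclose(rep["p"], disc["p"])


class TestCheckReplication:
    @staticmethod
    def _rows(q, beta):
        return pd.DataFrame({"q": q, "beta": beta},
                            index=pd.Index(["x"], name="protein_id"))

    @pytest.mark.parametrize(
        "q_d,q_r,b_d,b_r,expected",
        [
            (0.04, 0.04, 1.0, 1.0, ["x"]),
            (0.04, 0.04, 1.0, -1.0, []),   # direction mismatch
            (0.04, 0.06, 1.0, 1.0, []),    # threshold rule
        ],
    )
    def test_truth_table(self, q_d, q_r, b_d, b_r, expected):
        d = self._rows([q_d], [b_d])
        r = self._rows([q_r], [b_r])
        assert check_replication(d, r) == expected
        assert check_replication(r, d) == expected  # symmetry


class TestMultigroupSpecificity:
    @staticmethod
    def _three_group_cohort(pd_effect, als_effect, seed=0):
        rng = np.random.default_rng(seed)
        n_nc, n_pd, n_als = 80, 80, 60
        n = n_nc + n_pd + n_als
        groups = ["NC"] * n_nc + ["PD"] * n_pd + ["ALS"] * n_als
        ids = [f"s{i}" for i in range(n)]
        data = pd.DataFrame(
            rng.normal(3.0, 0.15, size=(n, 6)),
            index=ids, columns=[f"p{j}" for j in range(6)],
        )
        data.loc[np.array(groups) == "PD", "p0"] += pd_effect
        data.loc[np.array(groups) == "ALS", "p0"] += als_effect
        meta = pd.DataFrame(
            {
                "group": groups,
                "age": rng.normal(68, 9, n),
                "sex": rng.choice(["F", "M"], n),
                "site": rng.choice(["site1", "site2"], n),
            },
            index=ids,
        )
        return ProteinMatrix(data, scale="log10"), meta

    def test_pd_only_effect_pattern(self):
        matrix, meta = self._three_group_cohort(pd_effect=0.15, als_effect=0.0)
        out = multigroup_specificity(matrix, meta, ["p0", "p1", "p2"])
        assert out.loc["p0", "q_pd"] < 0.05
        assert out.loc["p0", "q_als"] >= 0.05

    def test_shared_effect_pattern(self):
        matrix, meta = self._three_group_cohort(pd_effect=0.15, als_effect=0.15)
        out = multigroup_specificity(matrix, meta, ["p0", "p1"])
        assert out.loc["p0", "q_pd"] < 0.05
        assert out.loc["p0", "q_als"] < 0.05

    def test_missing_group_level_named(self):
        matrix, meta = self._three_group_cohort(0.1, 0.0)
        meta2 = meta[meta["group"] != "ALS"]
        with pytest.raises(ValueError, match="ALS"):
            multigroup_specificity(matrix.subset(samples=meta2.index), meta2, ["p0"])


class TestNeverTreated:
    def test_exact_small_sample(self):
        vals = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        treated = pd.Series([True, True, False, False], index=list("abcd"))
        _, p = never_treated_comparison(vals, treated)
        assert p == pytest.approx(1 / 3)

    def test_identical_subgroups_p_one(self):
        vals = pd.Series([1.0, 2.0, 1.0, 2.0], index=list("abcd"))
        treated = pd.Series([True, True, False, False], index=list("abcd"))
        _, p = never_treated_comparison(vals, treated)
        assert p == pytest.approx(1.0)

    def test_empty_subgroup_rejected(self):
        vals = pd.Series([1.0, 2.0], index=list("ab"))
        treated = pd.Series([True, True], index=list("ab"))
        with pytest.raises(ValueError, match="nonempty"):
            never_treated_comparison(vals, treated)

    def test_exact_p_matches_enumeration(self):
        """All partitions with combined n <= 8: exact rank-sum p equals the
        full enumeration over group assignments."""
        rng = np.random.default_rng(7)
        for n1, n2 in [(2, 2), (2, 3), (3, 3), (3, 4), (4, 4)]:
            pool = rng.normal(size=n1 + n2)
            while len(np.unique(pool)) < len(pool):
                pool = rng.normal(size=n1 + n2)
            vals = pd.Series(pool, index=[f"i{k}" for k in range(n1 + n2)])
            treated = pd.Series([True] * n1 + [False] * n2, index=vals.index)
            u_obs, p = never_treated_comparison(vals, treated)

            # enumeration oracle over all choices of the treated subset
            ranks = pd.Series(pool).rank().to_numpy()
            obs_r = ranks[:n1].sum()
            mean_r = n1 * (n1 + n2 + 1) / 2
            count = total = 0
            for comb in itertools.combinations(range(n1 + n2), n1):
                r = ranks[list(comb)].sum()
                total += 1
                if abs(r - mean_r) >= abs(obs_r - mean_r) - 1e-12:
                    count += 1
            assert p == pytest.approx(count / total, abs=1e-12)
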