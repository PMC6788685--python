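"""Progression models: Spearman, mixed effects, events, tertiles, Cox."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from proteodiscover.progression import (
    assign_tertiles,
    classify_cognitive_state,
    compare_cox_education,
    derive_events,
    fit_cox,
    fit_lmm,
    spearman_baseline,
)


class TestSpearman:
    def test_monotone_extremes_and_hand_value(self):
        scores = pd.Series([10.0, 20.0, 30.0], index=list("abc"))
        bio = pd.DataFrame(
            {
                "up": [1.0, 2.0, 3.0],
                "down": [3.0, 2.0, 1.0],
                "mixed": [2.0, 1.0, 3.0],
            },
            index=list("abc"),
        )
        out = spearman_baseline(bio, scores)
        assert out.loc["up", "rho"] == pytest.approx(1.0)
        assert out.loc["down", "rho"] == pytest.approx(-1.0)
        # 1 - 6*sum(d^2)/(n(n^2-1)) with d = (1,-1,0)
        assert out.loc["mixed", "rho"] == pytest.approx(0.5)

    def test_too_few_pairs_rejected(self):
        scores = pd.Series([1.0, 2.0], index=list("ab"))
        bio = pd.DataFrame({"x": [1.0, 2.0]}, index=list("ab"))
        with pytest.raises(ValueError, match="3 complete pairs"):
            spearman_baseline(bio, scores)


def _longitudinal(n=40, n_visits=4, gamma=0.09, base_slope=-1.0,
                  intercept_sd=5.0, resid_sd=2.0, seed=0):
    rng = np.random.default_rng(seed)
    pids = [f"p{i}" for i in range(n)]
    x = pd.Series(rng.normal(3.5, 0.3, n), index=pids)
    cov = pd.DataFrame(
        {
            "age": rng.normal(68, 8, n),
            "sex": rng.choice(["F", "M"], n),
            "disease_duration": rng.gamma(2.5, 2.5, n),
            "education": rng.normal(15, 2.5, n),
        },
        index=pids,
    )
    t = np.arange(n_visits, dtype=float)
    b = rng.normal(0, intercept_sd, n)
    scores = (137.0 + b)[:, None] + (base_slope + gamma * x.to_numpy())[:, None] * t \
        + rng.normal(0, resid_sd, (n, n_visits))
    rec = pd.DataFrame(
        {
            "participant_id": np.repeat(pids, n_visits),
            "visit_time_yr": np.tile(t, n),
            "score": scores.ravel(),
        }
    )
    return rec, x, cov


class TestLmm:
    def test_noiseless_identification(self):
        rec, x, cov = _longitudinal(gamma=0.09, intercept_sd=0.0, resid_sd=0.0)
        res = fit_lmm(rec, x, cov)
        assert res.gamma == pytest.approx(0.09, abs=1e-5)

    def test_permuted_protein_destroys_interaction(self):
        rec, x, cov = _longitudinal(gamma=2.0, resid_sd=1.0, seed=1)
        rng = np.random.default_rng(2)
        x_perm = pd.Series(rng.permutation(x.to_numpy()), index=x.index)
        res_true = fit_lmm(rec, x, cov)
        res_perm = fit_lmm(rec, x_perm, cov)
        assert res_true.p < 0.01
        assert res_perm.p > 0.001
        assert abs(res_perm.gamma) < abs(res_true.gamma)

    def test_education_flag_adds_fixed_effect(self):
        rec, x, cov = _longitudinal(seed=3)
        res = fit_lmm(rec, x, cov, include_education=True)
        assert np.isfinite(res.gamma) and np.isfinite(res.p)


class TestCognitiveStates:
    @pytest.mark.parametrize(
        "score,state",
        [(30, "normal"), (26, "normal"), (25, "MCI"), (21, "MCI"),
         (20, "dementia"), (0, "dementia")],
    )
    def test_moca_norms(self, score, state):
        assert classify_cognitive_state(score, "MoCA") == state

    def test_drs_states_are_external(self):
        with pytest.raises(ValueError, match="externally"):
            classify_cognitive_state(130, "DRS")

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            classify_cognitive_state(31, "MoCA")


class TestDeriveEvents:
    @staticmethod
    def _states(seqs):
        rows = []
        for pid, seq in seqs.items():
            for t, s in enumerate(seq):
                rows.append((pid, float(t), s))
        return pd.DataFrame(rows, columns=["participant_id", "visit_time_yr", "state"])

    def test_conversion_and_exclusion_rules(self):
        states = self._states(
            {
                "conv": ["normal", "normal", "MCI"],
                "demconv": ["normal", "dementia"],
                "stable": ["normal", "normal", "normal"],
                "excl_dem": ["dementia", "dementia"],
                "excl_rev": ["MCI", "normal", "MCI"],
                "mci_conv": ["MCI", "MCI", "dementia"],
            }
        )
        rec, excl = derive_events(states)
        assert rec.loc["conv", "time"] == 2.0 and rec.loc["conv", "event"]
        assert rec.loc["demconv", "time"] == 1.0 and rec.loc["demconv", "event"]
        assert not rec.loc["stable", "event"] and rec.loc["stable", "time"] == 2.0
        assert rec.loc["mci_conv", "event"]
        assert set(excl["participant_id"]) == {"excl_dem", "excl_rev"}
        assert set(excl["reason"]) == {"dementia_at_baseline", "reversion_to_normal"}
        # excluded participants never appear in the records
        assert not set(excl["participant_id"]) & set(rec.index)

    def test_idempotent_and_order_stable(self):
        states = self._states({"a": ["normal", "MCI"], "b": ["normal", "normal"]})
        rec1, _ = derive_events(states)
        rec2, _ = derive_events(states.sample(frac=1.0, random_state=0))
        pd.testing.assert_frame_equal(rec1, rec2)


class TestTertiles:
    def test_one_to_nine(self):
        vals = pd.Series(np.arange(1.0, 10.0), index=[f"i{k}" for k in range(9)])
        t = assign_tertiles(vals)
        assert (t[vals <= 3] == "low").all()
        assert (t[(vals >= 4) & (vals <= 6)] == "medium").all()
        assert (t[vals >= 7] == "high").all()

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            assign_tertiles(pd.Series([2.0, 2.0, 2.0, 2.0]))

    @pytest.mark.parametrize("n", [7, 8, 9, 10, 11])
    def test_balanced_group_sizes(self, n):
        rng = np.random.default_rng(n)
        t = assign_tertiles(pd.Series(rng.normal(size=n)))
        sizes = t.value_counts()
        assert sizes.max() - sizes.min() <= 1


def _survival(n=600, loghr=np.log(2.0), seed=0, followup=50.0):
    rng = np.random.default_rng(seed)
    pids = [f"p{i}" for i in range(n)]
    x = pd.Series(rng.normal(3.5, 0.3, n), index=pids)
    tert = assign_tertiles(x)
    h = 0.2 * np.exp(loghr * (tert == "low").to_numpy())
    t_event = rng.exponential(1 / h)
    event = t_event <= followup
    return pd.DataFrame(
        {
            "time": np.minimum(t_event, followup),
            "event": event,
            "tertile": tert.to_numpy(),
            "age": rng.normal(68, 8, n),
            "sex": rng.choice(["F", "M"], n),
            "disease_duration": rng.gamma(2.5, 2.5, n),
            "education": rng.normal(15, 2.5, n),
        },
        index=pids,
    )


class TestCox:
    def test_recovers_true_hazard_ratio(self):
        df = _survival(n=600, loghr=np.log(2.0), seed=1)
        res = fit_cox(df)
        coef = res.table.loc["tertile_low", "coef"]
        se = res.table.loc["tertile_low", "se"]
        assert abs(coef - np.log(2.0)) < 3 * se

    def test_null_hazard_ratio_not_significant(self):
        df = _survival(n=400, loghr=0.0, seed=2)
        res = fit_cox(df)
        assert res.table.loc["tertile_low", "p"] > 0.001

    def test_matches_partial_likelihood_grid_search(self):
        """Tiny fixture, single binary covariate, no censoring: the Cox
        estimate matches a brute-force Efron partial-likelihood grid
        search to 1e-4."""
        rng = np.random.default_rng(3)
        n = 30
        low = rng.random(n) < 0.5
        t = rng.exponential(1 / (0.3 * np.exp(0.8 * low)))
        df = pd.DataFrame(
            {
                "time": t,
                "event": True,
                "tertile": pd.Categorical(
                    np.where(low, "low", "high"), categories=["low", "medium", "high"]
                ),
            },
            index=[f"p{i}" for i in range(n)],
        )
        res = fit_cox(df, contrast="low_vs_rest", covariates=())

        # vectorized partial-likelihood grid (no ties: Efron = Breslow)
        x = low.astype(float)
        order = np.argsort(t)
        xs = x[order]
        grid = np.linspace(-1.0, 2.5, 35001)
        eta = grid[:, None] * xs[None, :]
        risk = np.cumsum(np.exp(eta)[:, ::-1], axis=1)[:, ::-1]
        ll = (eta - np.log(risk)).sum(axis=1)
        best = grid[np.argmax(ll)]
        assert res.table.loc["tertile_low", "coef"] == pytest.approx(best, abs=1e-4 + 1e-4)

    def test_time_rescaling_invariance(self):
        df = _survival(n=300, seed=4)
        res_years = fit_cox(df)
        df_months = df.assign(time=df["time"] * 12.0)
        res_months = fit_cox(df_months)
        assert res_years.hr("tertile_low") == pytest.approx(
            res_months.hr("tertile_low"), rel=1e-6
        )

    def test_education_lrt_null(self):
        """Education independent of hazard: adding it changes the tertile
        HR by less than 1 SE and the LRT is unremarkable."""
        df = _survival(n=400, seed=5)
        m1 = fit_cox(df, include_education=False)
        m2 = fit_cox(df, include_education=True)
        se = m1.table.loc["tertile_low", "se"]
        assert abs(
            m1.table.loc["tertile_low", "coef"] - m2.table.loc["tertile_low", "coef"]
        ) < se
        chi2, dfree, p = compare_cox_education(df)
        assert dfree == 1 and p > 0.001

    def test_no_events_rejected(self):
        df = _survival(n=50, seed=6)
        df["event"] = False
        with pytest.raises(ValueError, match="event"):
            fit_cox(df)
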