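import numpy as np
import pandas as pd
import pytest
from scipy import stats

from stilquant.survival import (
    ConvergenceError,
    adjusted_snp_analysis,
    cox_fit,
    cox_partial_loglik,
    derive_dfs,
    design_matrix,
    genotype_coding,
    kaplan_meier,
    log_rank,
    stratified_univariable,
)


class TestDeriveDFS:
    def test_earliest_event_rule(self):
        assert derive_dfs(0, recurrence=100, death=400, last_followup=500) == (100, 1)

    def test_censoring_at_last_followup(self):
        assert derive_dfs(0, last_followup=851) == (851, 0)

    def test_same_day_event_beats_censoring(self):
        assert derive_dfs(0, death=300, last_followup=300) == (300, 1)

    def test_dates_accepted(self):
        from datetime import date

        t, e = derive_dfs(date(2010, 1, 1), death=date(2010, 4, 11))
        assert (t, e) == (100, 1)

    def test_event_before_diagnosis_errors(self):
        with pytest.raises(ValueError):
            derive_dfs(10, death=5)


def km_oracle(time, event):
    """Brute-force product over distinct event times."""
    s = 1.0
    out = {}
    for t in sorted(set(time[event == 1])):
        at_risk = (time >= t).sum()
        d = ((time == t) & (event == 1)).sum()
        s *= 1 - d / at_risk
        out[t] = s
    return out


class TestKaplanMeier:
    def test_hand_product_limit(self):
        """Times {1 censored, 2 event, 3 censored}: two at risk at t=2, so
        S(2) = 0.5 and the median is 2."""
        est = kaplan_meier([1, 2, 3], [0, 1, 0])
        s_at_2 = est.survival[est.times == 2][0]
        assert s_at_2 == pytest.approx(0.5)
        assert est.median == 2

    def test_all_censored_median_undefined(self):
        est = kaplan_meier([5, 6, 7], [0, 0, 0])
        assert (est.survival == 1.0).all()
        assert est.median is None

    def test_matches_product_oracle_on_random_instances(self, rng):
        for _ in range(100):
            n = int(rng.integers(3, 30))
            time = rng.integers(1, 15, size=n).astype(float)
            event = rng.integers(0, 2, size=n)
            if event.sum() == 0:
                event[0] = 1
            est = kaplan_meier(time, event)
            oracle = km_oracle(time, event)
            for t, s in oracle.items():
                assert est.survival[est.times == t][0] == pytest.approx(s)


class TestLogRank:
    def test_identical_groups_near_zero(self):
        time = np.array([3, 5, 7, 9, 3, 5, 7, 9], dtype=float)
        event = np.array([1, 0, 1, 1, 1, 0, 1, 1])
        group = np.array(list("aaaabbbb"))
        stat, df, p = log_rank(time, event, group)
        assert stat == pytest.approx(0.0, abs=1e-9)
        assert df == 1

    def test_single_event_time_hand_calculation(self):
        """One event in group a at t=1 with 2 per group at risk:
        O - E = 1 - 0.5, hypergeometric variance = 0.25, statistic 1."""
        time = np.array([1.0, 5.0, 5.0, 5.0])
        event = np.array([1, 0, 0, 0])
        group = np.array(["a", "a", "b", "b"])
        stat, df, p = log_rank(time, event, group)
        assert stat == pytest.approx((1 - 0.5) ** 2 / 0.25)

    def test_zero_events_errors(self):
        with pytest.raises(ValueError):
            log_rank([1, 2], [0, 0], ["a", "b"])

    def test_null_p_uniform(self, rng):
        """Two equal exponential groups: the log-rank p-value is uniform
        (Kolmogorov-Smirnov distance < 0.05 over 2000 replicates)."""
        ps = []
        for _ in range(2000):
            t = rng.exponential(1.0, size=40)
            c = rng.exponential(2.0, size=40)
            time = np.minimum(t, c)
            event = (t <= c).astype(int)
            group = np.repeat(["a", "b"], 20)
            if event.sum() == 0:
                continue
            ps.append(log_rank(time, event, group)[2])
        d = stats.kstest(ps, "uniform").statistic
        assert d < 0.05

    def test_two_group_logrank_matches_cox_score_direction(self, rng):
        """On tie-free data the two-group log-rank agrees with the score
        test of the single-covariate Cox fit (checked via the chi-square
        statistic to 3 significant figures)."""
        n = 60
        x = np.repeat([0.0, 1.0], n // 2)
        t = rng.exponential(np.exp(-0.7 * x))
        t += rng.uniform(0, 1e-9, size=n)  # break ties
        c = rng.exponential(2.0, size=n)
        time, event = np.minimum(t, c), (t <= c).astype(int)
        stat, _, _ = log_rank(time, event, x)
        beta0 = np.zeros(1)
        _, score, info = cox_partial_loglik(beta0, x[:, None], time, event, "efron")
        score_stat = score[0] ** 2 / info[0, 0]
        assert stat == pytest.approx(score_stat, rel=1e-3)


class TestCoxFit:
    def _sim(self, rng, n=500, beta=0.7):
        x = rng.normal(size=n)
        t = rng.exponential(np.exp(-beta * x) * 500.0)
        c = rng.uniform(100, 1500, size=n)
        return pd.DataFrame(
            {"dfs_time": np.minimum(t, c), "dfs_event": (t <= c).astype(int), "x": x}
        )

    def test_matches_lifelines(self, rng, cohort):
        from lifelines import CoxPHFitter

        df = pd.concat(
            [
                cohort.table[["dfs_time", "dfs_event", "stil", "age"]],
                design_matrix(cohort.table, ["sex", "treatment"]),
            ],
            axis=1,
        ).dropna()
        covs = [c for c in df.columns if c not in ("dfs_time", "dfs_event")]
        mine = cox_fit(df, covariates=covs)
        cph = CoxPHFitter().fit(df, "dfs_time", "dfs_event")
        assert np.allclose(mine.coef, cph.params_[mine.covariates].values, atol=1e-4)
        assert np.allclose(mine.se, cph.standard_errors_[mine.covariates].values, atol=1e-4)

    def test_efron_equals_breslow_without_ties(self, rng):
        df = self._sim(rng)
        df["dfs_time"] += rng.uniform(0, 1e-6, len(df))  # guarantee unique times
        X = df[["x"]].to_numpy()
        t, e = df["dfs_time"].to_numpy(), df["dfs_event"].to_numpy()
        beta = np.array([0.3])
        ll_e, _, _ = cox_partial_loglik(beta, X, t, e, "efron")
        ll_b, _, _ = cox_partial_loglik(beta, X, t, e, "breslow")
        assert ll_e == pytest.approx(ll_b, abs=1e-12 * abs(ll_b))

    def test_loglik_trace_monotone(self, rng):
        df = self._sim(rng)
        fit = cox_fit(df, covariates=["x"])
        assert fit.converged
        # re-derive the trace by evaluating the partial likelihood at 0 and at the optimum
        X = (df[["x"]] - df[["x"]].mean()).to_numpy()
        ll0, _, _ = cox_partial_loglik(np.zeros(1), X, df["dfs_time"].to_numpy(), df["dfs_event"].to_numpy())
        assert fit.loglik >= ll0

    def test_constant_covariate_dropped(self, rng):
        df = self._sim(rng)
        df["const"] = 1.0
        fit = cox_fit(df, covariates=["x", "const"])
        assert fit.dropped == ["const"]
        assert fit.covariates == ["x"]

    def test_no_events_errors(self):
        df = pd.DataFrame({"dfs_time": [1.0, 2.0], "dfs_event": [0, 0], "x": [0.0, 1.0]})
        with pytest.raises(ValueError):
            cox_fit(df, covariates=["x"])

    def test_hr_ci_consistency(self, rng):
        fit = cox_fit(self._sim(rng), covariates=["x"])
        assert fit.ci[0, 0] == pytest.approx(np.exp(fit.coef[0] - 1.96 * fit.se[0]))
        assert (fit.hr > 0).all()

    def test_complete_separation_raises_convergence_error(self):
        # the covariate perfectly orders the (tie-free) event times
        n = 30
        df = pd.DataFrame(
            {"dfs_time": np.arange(1, n + 1, dtype=float), "dfs_event": 1, "x": np.arange(n, dtype=float)}
        )
        with pytest.raises(ConvergenceError):
            cox_fit(df, covariates=["x"], max_iter=40)


class TestGenotypeCoding:
    def test_reference_coding_two_indicator_columns(self):
        g = pd.Series(["A/A", "A/C", "C/C", "A/A"], name="rs")
        out = genotype_coding(g, model="reference", reference="A/A")
        assert list(out.columns) == ["rs[A/C]", "rs[C/C]"]
        assert out["rs[A/C]"].tolist() == [0.0, 1.0, 0.0, 0.0]

    def test_dominant_pooling(self):
        g = pd.Series(["A/A", "G/A", "G/G"], name="rs")
        out = genotype_coding(g, model="dominant", combined=["A/A", "G/G"])
        assert out.shape[1] == 1
        assert out.iloc[:, 0].tolist() == [1.0, 0.0, 1.0]

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            genotype_coding(pd.Series(["A/A", "A/A"]), model="reference", reference="A/A")

    def test_unobserved_reference_errors(self):
        with pytest.raises(ValueError):
            genotype_coding(pd.Series(["A/C", "C/C"]), model="reference", reference="A/A")

    def test_missing_stays_missing(self):
        g = pd.Series(["A/A", None, "A/C"], name="rs")
        out = genotype_coding(g, model="reference", reference="A/A")
        assert out["rs[A/C]"].isna().tolist() == [False, True, False]


class TestAdjustedAndStratified:
    def test_empty_adjustment_equals_univariable(self, cohort):
        adj = adjusted_snp_analysis(cohort.table, "rs1801131", adjustment=())
        geno = genotype_coding(cohort.table["rs1801131"], "reference", "A/A")
        df = pd.concat([cohort.table[["dfs_time", "dfs_event"]], geno], axis=1)
        uni = cox_fit(df, covariates=list(geno.columns))
        assert np.allclose(adj.coef, uni.coef)

    def test_recovers_dominant_log_hr(self, cohort):
        """The generator gives rs1801131 a dominant log-HR of 0.35; the
        adjusted fit recovers it within 3 SE."""
        fit = adjusted_snp_analysis(
            cohort.table, "rs1801131", model="dominant", combined=["A/C", "C/C"]
        )
        i = fit.covariates.index("rs1801131[A/C+C/C]")
        assert abs(fit.coef[i] - 0.35) <= 3 * fit.se[i]

    def test_stratified_single_stratum_equals_plain(self, cohort):
        df = cohort.table.copy()
        df["one"] = "all"
        strata = stratified_univariable(df, "rs1801131", stratum_col="one", reference="A/A")
        assert len(strata) == 1
        plain = adjusted_snp_analysis(cohort.table, "rs1801131", adjustment=(), reference="A/A")
        assert np.allclose(strata[0].fit.coef, plain.coef)

    def test_zero_event_stratum_flagged(self, cohort):
        df = cohort.table.copy()
        df.loc[df["treatment"] == "untreated", "dfs_event"] = 0
        strata = stratified_univariable(df, "rs1801131", reference="A/A")
        by_name = {s.stratum: s for s in strata}
        assert by_name["untreated"].fit is None
        assert by_name["untreated"].reason == "no events"
        assert by_name["surgery"].fit is not None
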