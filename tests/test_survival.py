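"""Cox fitting, KM/log-rank, risk scores, and IPCW time-dependent AUC."""

import numpy as np
import pandas as pd
import pytest

from epilnc import survival as sv


def sim_cox(rng, n=500, beta=0.7, censor=0.2):
    x = rng.normal(size=n)
    t = rng.exponential(1.0 / (0.001 * np.exp(beta * x)))
    e = np.ones(n, dtype=int)
    if censor > 0:
        c = rng.exponential(np.quantile(t, 1 - censor) / 0.7, size=n)
        e = (t <= c).astype(int)
        t = np.minimum(t, c)
    return t, e, x


class TestCoxFit:
    def test_parameter_recovery_single_replicate(self, rng):
        t, e, x = sim_cox(rng, n=2000, beta=0.7)
        fit = sv.cox_fit(t, e, x)
        assert fit.beta[0] == pytest.approx(0.7, abs=0.1)
        assert fit.p_value[0] < 1e-10

    def test_null_covariate_small_beta(self, rng):
        t = rng.exponential(1000, size=500)
        e = np.ones(500, dtype=int)
        x = rng.normal(size=500)
        fit = sv.cox_fit(t, e, x)
        assert abs(fit.beta[0]) < 0.2

    def test_matches_lifelines_breslow_free_data(self, rng):
        # continuous times: no ties, so Breslow == Efron == lifelines default
        t, e, x = sim_cox(rng, n=300, beta=0.5)
        fit = sv.cox_fit(t, e, x)
        from lifelines import CoxPHFitter
        df = pd.DataFrame({"t": t, "e": e, "x": x})
        cph = CoxPHFitter().fit(df, duration_col="t", event_col="e")
        assert fit.beta[0] == pytest.approx(cph.params_["x"], abs=1e-4)
        assert fit.se[0] == pytest.approx(cph.standard_errors_["x"], abs=1e-4)

    def test_rescaling_covariate_rescales_beta(self, rng):
        t, e, x = sim_cox(rng, n=300, beta=0.5)
        a = sv.cox_fit(t, e, x)
        b = sv.cox_fit(t, e, 10.0 * x)
        assert b.beta[0] == pytest.approx(a.beta[0] / 10.0, abs=1e-8)

    def test_too_few_events_rejected(self):
        with pytest.raises(ValueError, match="2 events"):
            sv.cox_fit([1.0, 2.0, 3.0], [1, 0, 0], [0.1, 0.2, 0.3])

    def test_constant_covariate_rejected(self, rng):
        t = rng.exponential(100, 10)
        with pytest.raises(ValueError, match="constant"):
            sv.cox_fit(t, np.ones(10, int), np.ones(10))

    def test_perfect_separation_reported(self):
        # covariate perfectly ordered with event time -> monotone likelihood
        t = np.arange(1.0, 41.0)
        e = np.ones(40, int)
        x = -t
        with pytest.raises(RuntimeError):
            sv.cox_fit(t, e, x)


class TestUnivariateScreen:
    def make_cohort(self, rng, n=400, true_betas=(0.8,) * 4, n_null=4):
        genes = [f"g{i}" for i in range(len(true_betas) + n_null)]
        expr = rng.lognormal(3, 0.5, size=(len(genes), n))
        cols = [f"s{i}" for i in range(n)]
        tpm = pd.DataFrame(expr, index=genes, columns=cols)
        z = (np.log2(expr + 1) - np.log2(expr + 1).mean(axis=1, keepdims=True))
        z /= z.std(axis=1, keepdims=True)
        lp = np.zeros(n)
        for i, b in enumerate(true_betas):
            lp += b * z[i]
        t = rng.exponential(1.0 / (0.001 * np.exp(lp)))
        clinical = pd.DataFrame({"sample_id": cols, "time_days": t,
                                 "event": np.ones(n, int)})
        return tpm, clinical, genes

    def test_planted_prognostic_genes_recovered(self, rng):
        tpm, clinical, genes = self.make_cohort(rng)
        out = sv.univariate_screen(tpm, clinical, genes)
        assert out["selected"].iloc[:4].all()

    def test_null_false_positive_rate(self, rng):
        n_sel = 0
        for _ in range(5):
            tpm, clinical, genes = self.make_cohort(rng, true_betas=(), n_null=20)
            out = sv.univariate_screen(tpm, clinical, genes)
            n_sel += out["selected"].sum()
        assert n_sel <= 10  # ~alpha * 100 candidates, generous bound

    def test_alpha_zero_selects_nothing(self, rng):
        tpm, clinical, genes = self.make_cohort(rng)
        out = sv.univariate_screen(tpm, clinical, genes, alpha=0.0)
        assert not out["selected"].any()

    def test_missing_candidate_rejected(self, rng):
        tpm, clinical, _ = self.make_cohort(rng)
        with pytest.raises(ValueError, match="absent"):
            sv.univariate_screen(tpm, clinical, ["nope"])


class TestKmLogrank:
    def test_km_no_censoring_steps(self):
        curve = sv.km_estimate([1, 2, 3, 4], [1, 1, 1, 1])
        assert np.allclose(curve["survival"], [0.75, 0.5, 0.25, 0.0])

    def test_km_equals_empirical_without_censoring(self, rng):
        t = rng.exponential(100, size=50)
        curve = sv.km_estimate(t, np.ones(50, int))
        for _, row in curve.iterrows():
            assert row["survival"] == pytest.approx((t > row["time"]).mean())

    def test_km_nonincreasing_from_one(self, rng):
        t = rng.exponential(100, size=60)
        e = rng.integers(0, 2, size=60)
        e[0] = 1
        curve = sv.km_estimate(t, e)
        s = curve["survival"].to_numpy()
        assert (np.diff(s) <= 1e-12).all() and s[0] <= 1.0

    def test_logrank_identical_groups_zero(self):
        t = [1, 2, 3, 4, 1, 2, 3, 4]
        e = [1] * 8
        g = ["a"] * 4 + ["b"] * 4
        chi2, p = sv.logrank(t, e, g)
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_logrank_textbook_toy_oracle(self):
        # groups A={1,3,5}, B={2,4,6}, all events.  Hand computation:
        # O_A = 3, E_A = 1/2+2/5+1/2+1/3+1/2 = 67/30,
        # V = 1/4+6/25+1/4+2/9+1/4 = 1091/900  ->  chi2 = 529/1091.
        t = [1, 3, 5, 2, 4, 6]
        e = [1] * 6
        g = ["A"] * 3 + ["B"] * 3
        chi2, p = sv.logrank(t, e, g)
        assert chi2 == pytest.approx(529 / 1091, abs=1e-12)

    def test_logrank_is_squared_standardized_oe(self):
        # chi-square(1) form: statistic equals (O-E)^2 / V for two groups
        t = [5, 8, 12, 20, 3, 9, 14, 25]
        e = [1, 1, 0, 1, 1, 1, 1, 0]
        g = ["a"] * 4 + ["b"] * 4
        chi2, _ = sv.logrank(t, e, g)
        assert chi2 >= 0

    def test_logrank_matches_lifelines(self, rng):
        t = rng.exponential(100, size=80)
        e = rng.integers(0, 2, size=80)
        e[:5] = 1
        g = np.array(["a", "b"])[rng.integers(0, 2, size=80)]
        chi2, p = sv.logrank(t, e, g)
        from lifelines.statistics import logrank_test
        ref = logrank_test(t[g == "a"], t[g == "b"], e[g == "a"], e[g == "b"])
        assert chi2 == pytest.approx(ref.test_statistic, rel=1e-6)
        assert p == pytest.approx(ref.p_value, rel=1e-6)


class TestRiskModel:
    def test_zero_beta_scores_all_low(self):
        model = sv.RiskModel(["g1"], np.array([0.0]), np.array([5.0]),
                             np.array([1.0]), 0.0)
        tpm = pd.DataFrame({"s1": [10.0], "s2": [99.0]}, index=["g1"])
        rs = sv.risk_score(model, tpm)
        assert np.allclose(rs["score"], 0.0)
        assert (rs["group"] == "low").all()

    def test_score_linear_in_beta(self):
        m1 = sv.RiskModel(["g1"], np.array([0.5]), np.array([0.0]), np.array([1.0]), 0.0)
        m2 = sv.RiskModel(["g1"], np.array([1.0]), np.array([0.0]), np.array([1.0]), 0.0)
        tpm = pd.DataFrame({"s1": [10.0], "s2": [100.0]}, index=["g1"])
        r1 = sv.risk_score(m1, tpm)["score"]
        r2 = sv.risk_score(m2, tpm)["score"]
        assert np.allclose(r2, 2.0 * r1)

    def test_model_json_round_trip(self):
        m = sv.RiskModel(["a", "b"], np.array([0.1, -0.2]), np.array([1.0, 2.0]),
                         np.array([0.5, 0.6]), 0.33)
        back = sv.RiskModel.from_dict(m.to_dict())
        assert back.panel == m.panel
        assert np.allclose(back.beta, m.beta)
        assert back.median_score == m.median_score

    def test_planted_signal_stratifies_survival(self, rng):
        # end-to-end: strong single-gene effect -> high-risk group dies earlier
        n = 300
        cols = [f"s{i}" for i in range(n)]
        expr = rng.lognormal(3, 0.5, size=(1, n))
        tpm = pd.DataFrame(expr, index=["g1"], columns=cols)
        x = np.log2(expr[0] + 1)
        z = (x - x.mean()) / x.std()
        t = rng.exponential(1.0 / (0.001 * np.exp(1.0 * z)))
        clinical = pd.DataFrame({"sample_id": cols, "time_days": t,
                                 "event": np.ones(n, int)})
        model, fit = sv.fit_risk_model(tpm, clinical, ["g1"])
        rs = sv.risk_score(model, tpm, clinical["sample_id"])
        chi2, p = sv.logrank(t, clinical["event"], rs["group"].to_numpy())
        assert p < 0.05
        high = rs["group"] == "high"
        assert t[high.to_numpy()].mean() < t[(~high).to_numpy()].mean()


def auc_oracle(scores, time, event, h):
    """Explicit double-loop IPCW concordance at horizon h."""
    g_curve = sv.censoring_km(time, event)

    def G(t, left=False):
        if g_curve.empty:
            return 1.0
        return sv.km_survival_at(g_curve, t, left=left)

    num = den = 0.0
    for i in range(len(time)):
        if not (time[i] <= h and event[i] == 1):
            continue
        wi = 1.0 / max(G(time[i], left=True), 1e-12)
        for j in range(len(time)):
            if not time[j] > h:
                continue
            wj = 1.0 / max(G(h), 1e-12)
            if scores[i] > scores[j]:
                c = 1.0
            elif scores[i] == scores[j]:
                c = 0.5
            else:
                c = 0.0
            num += wi * wj * c
            den += wi * wj
    return num / den if den else np.nan


class TestTimeDependentAuc:
    def test_constant_score_half(self, rng):
        t = rng.exponential(500, 100)
        e = np.ones(100, int)
        auc = sv.time_dependent_auc(np.zeros(100), t, e, [np.median(t)])
        assert auc.iloc[0] == 0.5

    def test_perfect_score_one(self, rng):
        t = np.sort(rng.exponential(500, 100))
        auc = sv.time_dependent_auc(-t, t, np.ones(100, int), [np.median(t)])
        assert auc.iloc[0] == 1.0

    def test_sign_flip_complements(self, rng):
        t = rng.exponential(500, 120)
        e = rng.integers(0, 2, 120)
        e[:10] = 1
        s = rng.normal(size=120)
        h = float(np.median(t))
        a = sv.time_dependent_auc(s, t, e, [h]).iloc[0]
        b = sv.time_dependent_auc(-s, t, e, [h]).iloc[0]
        assert a == pytest.approx(1.0 - b, abs=1e-12)

    def test_matches_pairwise_oracle_with_censoring(self, rng):
        t = rng.exponential(500, 150)
        c = rng.exponential(800, 150)
        e = (t <= c).astype(int)
        obs = np.minimum(t, c)
        s = rng.normal(size=150)
        for h in [200.0, 500.0]:
            fast = sv.time_dependent_auc(s, obs, e, [h]).iloc[0]
            slow = auc_oracle(s, obs, e, h)
            assert fast == pytest.approx(slow, abs=1e-10)

    def test_horizon_beyond_followup_is_nan(self, rng):
        t = rng.exponential(100, 50)
        auc = sv.time_dependent_auc(rng.normal(size=50), t, np.ones(50, int),
                                    [t.max() + 1])
        assert np.isnan(auc.iloc[0])

    def test_auc_in_unit_interval(self, rng):
        t = rng.exponential(500, 100)
        e = rng.integers(0, 2, 100)
        e[:5] = 1
        auc = sv.time_dependent_auc(rng.normal(size=100), t, e,
                                    [float(np.quantile(t, 0.5))])
        assert 0.0 <= auc.iloc[0] <= 1.0
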