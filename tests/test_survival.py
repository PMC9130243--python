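import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from snrppfs import survival as sv
from snrppfs.survival import DegenerateFitError


def efron_negloglik(beta, X, time, event):
    """Independent Efron partial likelihood (direct summation oracle)."""
    beta = np.atleast_1d(beta)
    eta = X @ beta
    ll = 0.0
    for t in np.unique(time[event == 1]):
        D = (time == t) & (event == 1)
        R = time >= t
        d = D.sum()
        sum_D = np.exp(eta[D]).sum()
        sum_R = np.exp(eta[R]).sum()
        ll += eta[D].sum()
        for ell in range(d):
            ll -= np.log(sum_R - (ell / d) * sum_D)
    return -ll


def km_hand_table(time, event):
    """Product-limit estimates by explicit risk-table recursion."""
    order = np.argsort(time)
    time, event = np.asarray(time)[order], np.asarray(event)[order]
    surv = 1.0
    out = {}
    for t in np.unique(time):
        at_risk = (time >= t).sum()
        deaths = ((time == t) & (event == 1)).sum()
        surv *= 1.0 - deaths / at_risk
        out[t] = surv
    return out


class TestStageCorrelation:
    def test_gene_equal_to_stage_perfect(self):
        stage = np.array([1.0, 2, 3, 4, 1, 2, 3, 4])
        X = pd.DataFrame([stage], index=["g"])
        tab = sv.stage_correlation(X, stage)
        assert tab.loc[0, "pearson_r"] == pytest.approx(1.0)
        assert tab.loc[0, "stage_positive"]

    def test_missing_stage_dropped(self):
        stage = np.array([1.0, 2, np.nan, 4, 3, np.nan, 2, 1])
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(size=(2, 8)), index=["g1", "g2"])
        tab = sv.stage_correlation(X, stage)
        assert len(tab) == 2 and tab["pearson_r"].notna().all()

    def test_constant_gene_warns_and_reports_missing(self):
        stage = np.array([1.0, 2, 3, 4, 2, 3])
        X = pd.DataFrame([[5.0] * 6], index=["flat"])
        with pytest.warns(UserWarning, match="constant"):
            tab = sv.stage_correlation(X, stage)
        assert np.isnan(tab.loc[0, "pearson_r"])
        assert not tab.loc[0, "stage_positive"]

    def test_planted_stage_gene_power(self):
        # slope 0.8, noise sd 1, n=200: detection should be near-certain
        rng = np.random.default_rng(1)
        hits = 0
        for rep in range(30):
            stage = rng.integers(1, 5, size=200).astype(float)
            gene = 0.8 * stage + rng.normal(0, 1, size=200)
            tab = sv.stage_correlation(pd.DataFrame([gene], index=["g"]), stage)
            hits += int(tab.loc[0, "stage_positive"])
        assert hits >= 29

    def test_null_type_one_error(self):
        rng = np.random.default_rng(2)
        false_pos = 0
        reps = 400
        for _ in range(reps):
            stage = rng.integers(1, 5, size=80).astype(float)
            gene = rng.normal(size=80)
            tab = sv.stage_correlation(pd.DataFrame([gene], index=["g"]), stage)
            false_pos += int(tab.loc[0, "p_value"] < 0.05)
        se = np.sqrt(0.05 * 0.95 / reps)
        assert false_pos / reps <= 0.05 + 2 * se


class TestCoxFit:
    def test_matches_efron_oracle_small_instances(self):
        rng = np.random.default_rng(3)
        for rep in range(10):
            n = rng.integers(8, 20)
            x = rng.normal(size=(n, 1))
            time = rng.exponential(10, size=n).round(0) + 1  # ties likely
            event = rng.integers(0, 2, size=n).astype(float)
            if event.sum() < 2:
                continue
            fit = sv.cox_fit(pd.DataFrame({"x": x[:, 0]}), time, event)
            oracle = minimize(
                efron_negloglik, [0.0], args=(x, time, event), method="BFGS",
                options={"gtol": 1e-12},
            )
            assert fit.loc[0, "coef"] == pytest.approx(oracle.x[0], abs=1e-6)

    def test_null_covariate_ci_covers_one(self):
        rng = np.random.default_rng(4)
        covered = 0
        reps = 60
        for _ in range(reps):
            n = 150
            x = rng.normal(size=n)
            time = rng.exponential(100, size=n)
            event = (rng.random(n) < 0.7).astype(float)
            fit = sv.cox_fit(pd.DataFrame({"x": x}), time, event)
            covered += int(fit.loc[0, "ci_low"] <= 1.0 <= fit.loc[0, "ci_high"])
        assert covered / reps >= 0.88  # ~95% nominal, binomial slack at 60 reps

    def test_time_rescaling_invariance(self):
        rng = np.random.default_rng(5)
        n = 120
        x = rng.normal(size=n)
        time = rng.exponential(300, size=n) * np.exp(0.5 * x)
        event = (rng.random(n) < 0.75).astype(float)
        days = sv.cox_fit(pd.DataFrame({"x": x}), time, event)
        months = sv.cox_fit(pd.DataFrame({"x": x}), time / 30.44, event)
        assert days.loc[0, "hazard_ratio"] == pytest.approx(months.loc[0, "hazard_ratio"], rel=1e-6)
        assert days.loc[0, "p_value"] == pytest.approx(months.loc[0, "p_value"], rel=1e-6)

    def test_univariate_loops_terms(self):
        rng = np.random.default_rng(6)
        n = 100
        cov = pd.DataFrame(rng.normal(size=(n, 3)), columns=["a", "b", "c"])
        time = rng.exponential(50, size=n)
        event = np.ones(n)
        uni = sv.cox_fit(cov, time, event, model="univariate")
        assert list(uni["term"]) == ["a", "b", "c"]
        assert (uni["model"] == "univariate").all()
        assert ((uni["ci_low"] <= uni["hazard_ratio"]) & (uni["hazard_ratio"] <= uni["ci_high"])).all()

    def test_no_events_degenerate(self):
        with pytest.raises(DegenerateFitError):
            sv.cox_fit(
                pd.DataFrame({"x": [1.0, 2, 3, 4]}), np.array([1.0, 2, 3, 4]), np.zeros(4)
            )

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            sv.cox_fit(
                pd.DataFrame({"x": [2.0, 2, 2, 2]}), np.array([1.0, 2, 3, 4]), np.ones(4)
            )


class TestKaplanMeier:
    def test_product_limit_matches_hand_table(self):
        time = np.array([3.0, 5, 7, 2, 9, 4, 6, 8])
        event = np.array([1, 0, 1, 1, 0, 1, 1, 0])
        hand = km_hand_table(time, event)
        from lifelines import KaplanMeierFitter

        kmf = KaplanMeierFitter().fit(time, event)
        for t, s in hand.items():
            assert kmf.survival_function_at_times(t).iloc[0] == pytest.approx(s)

    def test_no_events_curves_constant_one(self):
        score = np.array([1.0, 2, 3, 10, 11, 12])
        time = np.array([5.0, 6, 7, 8, 9, 10])
        event = np.zeros(6)
        hi, lo = sv.km_and_logrank(score, time, event, cutpoint_method="median")
        assert (hi.survival == 1.0).all() and (lo.survival == 1.0).all()

    def test_logrank_label_swap_invariance(self):
        rng = np.random.default_rng(7)
        n = 80
        score = rng.normal(size=n)
        time = rng.exponential(40, size=n)
        event = (rng.random(n) < 0.6).astype(float)
        hi, lo = sv.km_and_logrank(score, time, event, cutpoint_method="median")
        hi2, lo2 = sv.km_and_logrank(-score, time, event, cutpoint_method="median")
        # negating the marker swaps high/low groups but not the log-rank p
        assert hi.logrank_p == pytest.approx(hi2.logrank_p, rel=1e-9)

    def test_planted_hazard_gene_direction(self):
        rng = np.random.default_rng(8)
        n = 300
        gene = rng.normal(size=n)
        time = rng.exponential(1000 * np.exp(-0.7 * gene))
        event = np.ones(n)
        hi, lo = sv.km_and_logrank(gene, time, event)
        assert hi.logrank_p < 0.01
        # high-expression group has worse survival: lower curve at median time
        t_mid = np.median(time)
        s_hi = hi.survival[np.searchsorted(hi.times, t_mid, side="right") - 1]
        s_lo = lo.survival[np.searchsorted(lo.times, t_mid, side="right") - 1]
        assert s_hi < s_lo

    def test_curves_start_at_one_and_non_increasing(self):
        rng = np.random.default_rng(9)
        score = rng.normal(size=50)
        time = rng.exponential(10, size=50)
        event = (rng.random(50) < 0.5).astype(float)
        hi, lo = sv.km_and_logrank(score, time, event, cutpoint_method="maxstat")
        for c in (hi, lo):
            assert c.survival[0] <= 1.0 + 1e-12
            assert (np.diff(c.survival) <= 1e-12).all()

    def test_degenerate_split_rejected(self):
        with pytest.raises(ValueError):
            sv.km_and_logrank([1.0, 1, 1, 1], [1.0, 2, 3, 4], [1, 1, 0, 1], cutpoint_method="median")


class TestSurvivalScreen:
    def test_empty_gene_list(self, small_cohort):
        uni, multi = sv.survival_screen([], small_cohort.expression, small_cohort.annotation)
        assert uni.empty and multi is None

    def test_two_tier_flags(self):
        rng = np.random.default_rng(10)
        n = 280
        ids = [f"s{i}" for i in range(n)]
        hazard_gene = rng.normal(size=n)
        null_genes = rng.normal(size=(9, n))
        X = pd.DataFrame(np.vstack([hazard_gene, null_genes]), index=[f"g{i}" for i in range(10)], columns=ids)
        time = rng.exponential(1000 * np.exp(-0.8 * hazard_gene))
        cens = rng.exponential(3000, size=n)
        clinical = pd.DataFrame(
            {
                "sample_id": ids,
                "os_time_days": np.minimum(time, cens),
                "os_status": (time <= cens).astype(float),
            }
        )
        uni, multi = sv.survival_screen(list(X.index), X, clinical)
        assert uni.loc[uni.term == "g0", "flag"].iloc[0] == "significant"
        assert multi is not None and "g0" in set(multi["term"])

    def test_null_flag_rate(self):
        rng = np.random.default_rng(11)
        flagged = total = 0
        for rep in range(25):
            n = 120
            ids = [f"s{i}" for i in range(n)]
            X = pd.DataFrame(rng.normal(size=(8, n)), index=[f"g{i}" for i in range(8)], columns=ids)
            clinical = pd.DataFrame(
                {
                    "sample_id": ids,
                    "os_time_days": rng.exponential(500, size=n),
                    "os_status": (rng.random(n) < 0.5).astype(float),
                }
            )
            uni, _ = sv.survival_screen(list(X.index), X, clinical)
            flagged += (uni["flag"] != "none").sum()
            total += len(uni)
        rate = flagged / total
        se = np.sqrt(0.1 * 0.9 / total)
        assert rate <= 0.1 + 3 * se
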