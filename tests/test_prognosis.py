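"""Penalized-Cox risk models, cross-validated discrimination and
reclassification metrics."""

import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter
from scipy.stats import spearmanr

from cmrperf import prognosis as pg
from cmrperf import synthetic as sy


def cohort_frame(n, coefficients, seed, **kw):
    c = sy.generate_cohort(
        sy.CohortSpec(n_patients=n, coefficients=coefficients, rng_seed=seed, **kw)
    )
    return c.rename(
        columns={
            "age_years": "age",
            "visual_burden_fraction": "visual_burden",
            "mpr_burden_fraction": "mpr_burden",
        }
    )


def km_oracle(time, event, at):
    """Direct risk-set counting product-limit estimator at time `at`."""
    s = 1.0
    for t in sorted(set(time[event == 1])):
        if t > at:
            break
        d = np.sum((time == t) & (event == 1))
        n = np.sum(time >= t)
        s *= 1.0 - d / n
    return s


class TestLinearPredictor:
    def test_zero_covariates(self):
        assert pg.linear_predictor(pg.PRINTED_MODELS["baseline"],
                                   {"age": 0, "sex": 0, "lge": 0}) == 0.0

    def test_baseline_model_example(self):
        lp = pg.linear_predictor(
            pg.PRINTED_MODELS["baseline"], {"age": 60, "sex": 1, "lge": 1}
        )
        assert lp == pytest.approx(0.025 * 60 + 2.993 + 0.616)
        assert lp == pytest.approx(5.109)

    def test_mpr_model_example(self):
        lp = pg.linear_predictor(
            pg.PRINTED_MODELS["mpr"],
            {"age": 63, "sex": 1, "lge": 1, "mpr_burden": 0.234},
        )
        assert lp == pytest.approx(0.02 * 63 + 2.722 + 0.678 + 2.490 * 0.234)
        assert lp == pytest.approx(5.243, abs=5e-4)

    def test_missing_covariate_rejected(self):
        with pytest.raises(ValueError):
            pg.linear_predictor(pg.PRINTED_MODELS["baseline"], {"age": 60})


class TestFitPenalizedCox:
    def test_infinite_penalty_reduces_to_unpenalized_fit(self):
        data = cohort_frame(800, sy.DEFAULT_COEFFICIENTS, seed=3)
        spec = pg.CoxModelSpec(penalized=("mpr_burden",), name="mpr")
        fitted = pg.fit_penalized_cox(data, spec, alpha=1e6)
        assert fitted.coefficients["mpr_burden"] == 0.0
        plain = CoxPHFitter().fit(
            data[["age", "sex", "lge", "time_days", "event"]],
            duration_col="time_days", event_col="event",
        )
        for cov in ("age", "sex", "lge"):
            assert fitted.coefficients[cov] == pytest.approx(
                plain.params_[cov], rel=0.01, abs=1e-3
            )

    def test_coefficient_recovery_small_penalty(self):
        gen = {"age": 0.03, "sex": 1.0, "lge": 0.5, "burden": 0.0}
        data = cohort_frame(
            5000, gen, seed=17, baseline_hazard_rate=0.10, censoring_rate=0.05
        )
        fitted = pg.fit_penalized_cox(data, pg.CoxModelSpec())
        assert fitted.coefficients["age"] == pytest.approx(0.03, rel=0.10)
        assert fitted.coefficients["sex"] == pytest.approx(1.0, rel=0.10)
        assert fitted.coefficients["lge"] == pytest.approx(0.5, rel=0.10)

    def test_pure_noise_covariate_selected_out(self):
        """The lasso drops an uninformative covariate in nearly all replicates."""
        dropped = 0
        n_rep = 20
        for rep in range(n_rep):
            data = cohort_frame(2000, sy.DEFAULT_COEFFICIENTS, seed=100 + rep)
            data["noise"] = np.random.default_rng(500 + rep).normal(size=len(data))
            spec = pg.CoxModelSpec(penalized=("noise",), name="noisy")
            fitted = pg.fit_penalized_cox(
                data, spec, n_alphas=20, inner_folds=3,
                rng=np.random.default_rng(rep),
            )
            if fitted.coefficients["noise"] == 0.0:
                dropped += 1
        assert dropped >= 0.9 * n_rep

    def test_selected_set_drops_zero_coefficients(self):
        data = cohort_frame(800, sy.DEFAULT_COEFFICIENTS, seed=3)
        data["noise"] = np.random.default_rng(1).normal(size=len(data))
        spec = pg.CoxModelSpec(penalized=("noise",))
        fitted = pg.fit_penalized_cox(data, spec, alpha=1e6)
        assert "noise" not in fitted.selected
        assert set(fitted.selected) == {"age", "sex", "lge"}

    def test_too_few_events_rejected(self):
        data = cohort_frame(50, {}, seed=1, baseline_hazard_rate=0.0)
        with pytest.raises(ValueError):
            pg.fit_penalized_cox(data, pg.CoxModelSpec())


class TestCvSurvivalProbabilities:
    def test_null_model_matches_kaplan_meier(self):
        data = cohort_frame(600, {}, seed=21, baseline_hazard_rate=0.12)
        data["noise"] = np.random.default_rng(2).normal(size=len(data))
        spec = pg.CoxModelSpec(unpenalized=(), penalized=("noise",), name="null")
        probs, _ = pg.cv_survival_probabilities(
            data, spec, k_folds=5, restarts=1, seed=4, n_alphas=10, inner_folds=3
        )
        km_event = 1.0 - km_oracle(
            data["time_days"].to_numpy(), data["event"].to_numpy(), pg.HORIZON_DAYS
        )
        assert np.mean(probs) == pytest.approx(km_event, abs=0.05)
        assert np.std(probs) < 0.05  # uninformative model: near-constant risk

    def test_deterministic_under_seed(self):
        data = cohort_frame(300, sy.DEFAULT_COEFFICIENTS, seed=5)
        spec = pg.CoxModelSpec.for_perfusion("mpr")
        a, _ = pg.cv_survival_probabilities(
            data, spec, k_folds=4, restarts=1, seed=9, n_alphas=8, inner_folds=3
        )
        b, _ = pg.cv_survival_probabilities(
            data, spec, k_folds=4, restarts=1, seed=9, n_alphas=8, inner_folds=3
        )
        np.testing.assert_array_equal(a, b)

    def test_strong_effect_monotone_predictions(self):
        rng = np.random.default_rng(13)
        n = 500
        x = rng.normal(size=n)  # hazard ratio 5 per unit
        t_event = rng.exponential(1.0, n) / (0.05 * np.exp(np.log(5.0) * x))
        t_cens = rng.exponential(2.0, n)
        data = pd.DataFrame(
            {
                "x": x,
                "time_days": np.maximum(np.minimum(t_event, t_cens) * 365.25, 1.0),
                "event": (t_event <= t_cens).astype(int),
            }
        )
        spec = pg.CoxModelSpec(unpenalized=("x",), penalized=(), name="single")
        probs, _ = pg.cv_survival_probabilities(
            data, spec, k_folds=4, restarts=2, seed=3, n_alphas=8, inner_folds=3
        )
        rho, _ = spearmanr(x, probs)
        assert rho > 0.9


class TestCvRocAuc:
    def test_null_discrimination(self):
        data = cohort_frame(5000, {}, seed=31, baseline_hazard_rate=0.15)
        scores = np.random.default_rng(7).random(len(data))
        auc, _ = pg.cv_roc_auc(
            scores, data["time_days"], data["event"], pg.HORIZON_DAYS
        )
        assert auc == pytest.approx(0.5, abs=0.02)

    def test_perfect_separation(self):
        time = np.r_[np.full(50, 300.0), np.full(150, 1000.0)]
        event = np.r_[np.ones(50, int), np.zeros(150, int)]
        scores = np.r_[np.ones(50), np.zeros(150)]
        auc, _ = pg.cv_roc_auc(scores, time, event, 730.0)
        assert auc == pytest.approx(1.0)

    def test_uncensored_equals_pairwise_oracle(self):
        rng = np.random.default_rng(11)
        n = 300
        event_first = rng.random(n) < 0.3
        time = np.where(event_first, rng.uniform(50, 700, n), rng.uniform(731, 1500, n))
        event = event_first.astype(int)
        scores = rng.normal(size=n) + event  # informative, continuous
        auc, _ = pg.cv_roc_auc(scores, time, event, 730.0)
        cases = scores[event_first]
        controls = scores[~event_first]
        diff = cases[:, None] - controls[None, :]
        mw = (np.sum(diff > 0) + 0.5 * np.sum(diff == 0)) / diff.size
        assert auc == pytest.approx(mw, abs=1e-9)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(12)
        data = cohort_frame(800, sy.DEFAULT_COEFFICIENTS, seed=41)
        scores = rng.random(len(data))
        auc1, _ = pg.cv_roc_auc(scores, data["time_days"], data["event"])
        auc2, _ = pg.cv_roc_auc(
            np.exp(3 * scores), data["time_days"], data["event"]
        )
        assert auc1 == pytest.approx(auc2, abs=1e-12)

    def test_undefined_without_cases(self):
        time = np.full(100, 1000.0)
        event = np.zeros(100, int)
        with pytest.raises(ValueError):
            pg.cv_roc_auc(np.random.default_rng(0).random(100), time, event, 730.0)


class TestRiskCategorize:
    @pytest.mark.parametrize(
        "p,expected",
        [
            (0.005, "low"),
            (0.01, "intermediate"),  # both boundaries are intermediate
            (0.02, "intermediate"),
            (0.03, "intermediate"),
            (0.031, "high"),
        ],
    )
    def test_categories(self, p, expected):
        assert pg.risk_categorize(p)[0] == expected

    def test_invalid_probability(self):
        with pytest.raises(ValueError):
            pg.risk_categorize(1.5)


class TestCategoricalNri:
    @staticmethod
    def toy_outcomes(n_events, n_nonevents):
        time = np.r_[np.full(n_events, 100.0), np.full(n_nonevents, 1000.0)]
        event = np.r_[np.ones(n_events, int), np.zeros(n_nonevents, int)]
        return time, event

    def test_identical_classifications_zero(self):
        time, event = self.toy_outcomes(10, 20)
        p = np.random.default_rng(3).uniform(0, 0.06, 30)
        res = pg.categorical_nri(p, p, time, event)
        assert res.nri == 0.0
        assert res.idi == 0.0

    def test_extremal_reclassification(self):
        time, event = self.toy_outcomes(10, 20)
        base = np.r_[np.full(10, 0.02), np.full(20, 0.02)]  # all intermediate
        new = np.r_[np.full(10, 0.05), np.full(20, 0.005)]  # events up, rest down
        res = pg.categorical_nri(base, new, time, event)
        assert res.nri == pytest.approx(2.0)

    def test_toy_counting_oracle(self):
        """10 events (6 up, 1 down), 20 nonevents (2 up, 5 down):
        NRI = (0.6 - 0.1) + (0.25 - 0.1) = 0.65."""
        time, event = self.toy_outcomes(10, 20)
        LOW, INT, HIGH = 0.005, 0.02, 0.05
        # events: 6 up (low->int), 1 down (int->low), 3 unchanged
        base_ev = np.array([LOW] * 6 + [INT] * 1 + [INT] * 3)
        new_ev = np.array([INT] * 6 + [LOW] * 1 + [INT] * 3)
        base_ne = np.array([INT] * 2 + [INT] * 5 + [LOW] * 13)
        new_ne = np.array([HIGH] * 2 + [LOW] * 5 + [LOW] * 13)
        base_p = np.r_[base_ev, base_ne]
        new_p = np.r_[new_ev, new_ne]
        res = pg.categorical_nri(base_p, new_p, time, event)
        assert res.nri == pytest.approx(0.65)
        assert res.nri_events == pytest.approx(0.5)
        assert res.nri_nonevents == pytest.approx(0.15)
        assert res.table_events.sum() == 10
        assert res.table_nonevents.sum() == 20

    def test_idi_matches_mean_difference(self):
        time, event = self.toy_outcomes(10, 20)
        rng = np.random.default_rng(5)
        base = rng.uniform(0, 0.05, 30)
        new = rng.uniform(0, 0.05, 30)
        res = pg.categorical_nri(base, new, time, event)
        expect = (new - base)[:10].mean() - (new - base)[10:].mean()
        assert res.idi == pytest.approx(expect, abs=1e-12)


class TestKaplanMeierStrata:
    def test_no_events_flat_curve(self):
        df = pd.DataFrame(
            {"time_days": [100.0, 200, 300], "event": 0, "grp": [0, 0, 0]}
        )
        curves = pg.kaplan_meier_strata(df, ["grp"])
        assert np.all(curves[(0,)]["survival"] == 1.0)

    def test_simultaneous_events_drop_to_zero(self):
        df = pd.DataFrame(
            {"time_days": [100.0] * 10, "event": 1, "grp": [1] * 10}
        )
        sf = curves = pg.kaplan_meier_strata(df, ["grp"])[(1,)]
        assert sf[sf.time_days >= 100]["survival"].iloc[0] == pytest.approx(0.0)

    def test_matches_risk_set_counting_oracle(self):
        rng = np.random.default_rng(23)
        time = np.ceil(rng.exponential(300, 60))
        event = (rng.random(60) < 0.6).astype(int)
        df = pd.DataFrame({"time_days": time, "event": event, "grp": 0})
        curve = pg.kaplan_meier_strata(df, ["grp"])[(0,)]
        for at in (50.0, 200.0, 500.0):
            km_at = curve[curve.time_days <= at]["survival"].iloc[-1]
            assert km_at == pytest.approx(km_oracle(time, event, at), abs=1e-12)


class TestModelComparison:
    def test_burden_model_outranks_baseline(self):
        """With outcomes generated from the quantitative-burden model, adding
        the burden covariate improves cross-validated discrimination."""
        data = cohort_frame(2000, sy.DEFAULT_COEFFICIENTS, seed=77)
        data["mpr_positive"] = (data["mpr_burden"] >= 0.10).astype(int)
        res = pg.compare_prognostic_models(
            data, models=("baseline", "mpr"), k_folds=5, restarts=2,
            seed=19, n_alphas=10, inner_folds=3,
        )
        assert res["mpr"]["cv_auc_2y"] > res["baseline"]["cv_auc_2y"]
        assert "nri_vs_baseline" in res["mpr"]

    def test_noise_covariate_barely_moves_auc(self):
        """Penalization keeps an uninformative covariate from inflating the
        cross-validated AUC."""
        data = cohort_frame(2000, sy.DEFAULT_COEFFICIENTS, seed=88)
        data["noise"] = np.random.default_rng(6).normal(size=len(data))
        base_spec = pg.CoxModelSpec()
        noisy_spec = pg.CoxModelSpec(penalized=("noise",), name="noisy")
        kw = dict(k_folds=5, restarts=2, seed=44, n_alphas=10, inner_folds=3)
        p0, _ = pg.cv_survival_probabilities(data, base_spec, **kw)
        p1, _ = pg.cv_survival_probabilities(data, noisy_spec, **kw)
        a0, _ = pg.cv_roc_auc(p0, data["time_days"], data["event"])
        a1, _ = pg.cv_roc_auc(p1, data["time_days"], data["event"])
        assert abs(a1 - a0) < 0.02
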