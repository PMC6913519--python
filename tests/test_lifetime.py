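import warnings

import numpy as np
import pandas as pd
import pytest

import nonhdlrisk as nr
from nonhdlrisk.hazards import CoxFit, DesignSpec
from nonhdlrisk.lifetime import (
    CauseSpecificModel,
    average_cells,
    fit_cause_specific_models,
    fit_weibull_baseline,
    predict_cif_at_age,
    predict_cvd_by_75,
    risk_factor_burden,
)


def _null_cox() -> CoxFit:
    """A Cox fit with no covariates (linear predictor identically zero)."""
    spec = DesignSpec(exposure="none", adjustment=())
    return CoxFit(params=pd.Series(dtype=float), cov=pd.DataFrame(), design=spec)


def _profile_frame(n=1, age=50.0):
    return pd.DataFrame(
        {
            "subject_id": np.arange(n),
            "cohort_id": np.zeros(n, dtype=int),
            "sex": ["female"] * n,
            "age_baseline": np.full(n, age),
        }
    )


def _toy_model(baselines, death=True):
    return CauseSpecificModel(
        cox_cvd=_null_cox(),
        cox_death=_null_cox() if death else None,
        baselines=baselines,
    )


class TestPredictClosedForms:
    def test_constant_hazards(self):
        """Weibull shape 1 = constant hazards: F1(75|a0) has the closed form
        h1/(h1+h2) (1 - exp(-(h1+h2)(75-a0)))."""
        h1, h2 = 0.02, 0.03  # per year; shape-1 Weibull scale = 1/h
        model = _toy_model({("female", 0, 1): (1.0, 1 / h1),
                            ("female", 0, 2): (1.0, 1 / h2)})
        for a0 in (35.0, 50.0, 70.0):
            f1 = predict_cvd_by_75(_profile_frame(age=a0), model)[0]
            closed = h1 / (h1 + h2) * (1 - np.exp(-(h1 + h2) * (75 - a0)))
            assert f1 == pytest.approx(closed, abs=1e-4)

    def test_single_cause_weibull(self):
        """Without competing mortality F1 = 1 - exp(-[(75/l)^k - (a0/l)^k])."""
        k, lam = 5.0, 100.0
        model = _toy_model({("female", 0, 1): (k, lam)}, death=False)
        for a0 in (40.0, 60.0):
            f1 = predict_cvd_by_75(_profile_frame(age=a0), model)[0]
            closed = 1 - np.exp(-((75 / lam) ** k - (a0 / lam) ** k))
            assert f1 == pytest.approx(closed, abs=1e-4)

    def test_grid_refinement(self):
        model = _toy_model({("female", 0, 1): (6.0, 105.0),
                            ("female", 0, 2): (9.0, 95.0)})
        df = _profile_frame(age=42.0)
        coarse = predict_cvd_by_75(df, model, grid_points=801)[0]
        fine = predict_cvd_by_75(df, model, grid_points=1601)[0]
        assert abs(coarse - fine) < 1e-5

    def test_total_probability_sums_to_one(self):
        model = _toy_model({("female", 0, 1): (6.0, 105.0),
                            ("female", 0, 2): (9.0, 95.0)})
        df = _profile_frame(n=3)
        df["age_baseline"] = [35.0, 50.0, 70.0]
        f1, f2, s = predict_cif_at_age(df, model, 75.0, return_all=True)
        assert np.allclose(f1 + f2 + s, 1.0, atol=1e-6)

    def test_f1_decreasing_in_entry_age_for_increasing_hazards(self):
        """With age-increasing hazards (shape > 1), later entry leaves less
        lifetime risk before 75."""
        model = _toy_model({("female", 0, 1): (6.0, 105.0),
                            ("female", 0, 2): (9.0, 95.0)})
        ages = np.linspace(35, 70, 8)
        preds = [predict_cvd_by_75(_profile_frame(age=a), model)[0] for a in ages]
        assert np.all(np.diff(preds) < 0)

    def test_age_outside_window_rejected(self):
        model = _toy_model({("female", 0, 1): (6.0, 105.0)}, death=False)
        with pytest.raises(ValueError, match="eligibility"):
            predict_cvd_by_75(_profile_frame(age=72.0), model)

    def test_matches_independent_competing_simulation(self):
        """Monte-Carlo oracle: draw cause-specific Weibull event ages by
        closed-form inversion (no numerical integration) and take the min."""
        k1, l1, k2, l2 = 5.5, 102.0, 8.0, 96.0
        lp1, lp2 = 0.3, -0.2
        rng = np.random.default_rng(5)
        n = 1_000_000
        for a0 in (40.0, 60.0):
            e = rng.exponential(size=(2, n))
            t1 = l1 * ((a0 / l1) ** k1 + e[0] / np.exp(lp1)) ** (1 / k1)
            t2 = l2 * ((a0 / l2) ** k2 + e[1] / np.exp(lp2)) ** (1 / k2)
            mc = np.mean((t1 < t2) & (t1 <= 75.0))
            spec = DesignSpec(exposure="none", adjustment=("smoking",))
            fit1 = CoxFit(params=pd.Series({"smoking": lp1}),
                          cov=pd.DataFrame([[0.0]], index=["smoking"],
                                           columns=["smoking"]),
                          design=spec)
            fit2 = CoxFit(params=pd.Series({"smoking": lp2}),
                          cov=pd.DataFrame([[0.0]], index=["smoking"],
                                           columns=["smoking"]),
                          design=spec)
            model = CauseSpecificModel(fit1, fit2,
                                       {("female", 0, 1): (k1, l1),
                                        ("female", 0, 2): (k2, l2)})
            df = _profile_frame(age=a0)
            df["smoking"] = 1.0
            f1 = predict_cvd_by_75(df, model)[0]
            se = np.sqrt(f1 * (1 - f1) / n)
            assert abs(f1 - mc) < 4 * se + 1e-4


class TestWeibullBaseline:
    def test_parameter_recovery_from_generator(self):
        """Cause-specific Weibull MLE recovers the generating (k, lambda)
        within 5% at n=100 000 when covariate effects are zero."""
        cfg = nr.default_config(n_subjects=100_000, seed=55)
        cfg.cohort_frailty_sd = 0.0
        for hz in (cfg.cvd_hazard, cfg.death_hazard):
            hz.loghr = {k: 0.0 for k in hz.loghr}
        df = nr.generate_cohort(cfg)
        entry = df["age_baseline"].to_numpy()
        exit_ = entry + df["followup_years"].to_numpy()
        for cause, hz in ((1, cfg.cvd_hazard), (2, cfg.death_hazard)):
            k, lam = fit_weibull_baseline(entry, exit_, (df["event_cause"] == cause))
            assert k == pytest.approx(hz.shape, rel=0.05)
            assert lam == pytest.approx(hz.scale, rel=0.05)

    def test_needs_events(self):
        with pytest.raises(ValueError, match="event"):
            fit_weibull_baseline([50.0, 55.0], [60.0, 62.0], [0, 0])

    def test_offset_shifts_scale_consistently(self):
        """Doubling every hazard via the offset is equivalent to rescaling
        lambda by 2^(-1/k) in the fitted model."""
        rng = np.random.default_rng(8)
        n = 30_000
        a0 = rng.uniform(40, 60, n)
        k_true, lam_true = 5.0, 100.0
        e = rng.exponential(size=n)
        t = lam_true * ((a0 / lam_true) ** k_true + e) ** (1 / k_true)
        cens = a0 + rng.uniform(5, 25, n)
        exit_ = np.minimum(t, cens)
        ev = (t <= cens).astype(float)
        k0, lam0 = fit_weibull_baseline(a0, exit_, ev)
        off = np.full(n, np.log(2.0))
        k1, lam1 = fit_weibull_baseline(a0, exit_, ev, offset=off)
        assert k1 == pytest.approx(k0, rel=0.02)
        assert lam1 == pytest.approx(lam0 * 2 ** (1 / k0), rel=0.02)


class TestCauseSpecificModelFit:
    def test_converges_and_signs_match_generator(self, midsize_cohort):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = fit_cause_specific_models(midsize_cohort)
        assert not model.death_degenerate
        for fit in (model.cox_cvd, model.cox_death):
            for term in ("smoking", "diabetes", "antihypertensive_med"):
                assert fit.params[term] > 0, term  # generator effects positive
        for (sex, coh, cause), (k, lam) in model.baselines.items():
            assert k > 1 and lam > 0

    def test_no_deaths_flagged_degenerate(self, small_cohort):
        df = small_cohort[small_cohort["event_cause"] != 2].reset_index(drop=True)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = fit_cause_specific_models(df)
        assert model.death_degenerate
        assert model.cox_death is None
        pred = predict_cvd_by_75(
            df[df["age_baseline"].between(35, 70)], model
        )
        assert np.all((pred >= 0) & (pred <= 1))


class TestAverageCells:
    def test_risk_factor_burden(self):
        df = pd.DataFrame(
            {"smoking": [1, 0, 1], "hypertension": [1, 0, 0],
             "diabetes": [0, 0, 0], "bmi": [25.0, 31.0, 31.0]}
        )
        assert list(risk_factor_burden(df)) == [">=2", "0-1", ">=2"]

    def test_identical_members_mean_equals_individual(self):
        df = _profile_frame(n=40, age=40.0)
        df["non_hdl_cat"] = 3
        df["smoking"] = 1
        df["hypertension"] = 1
        df["diabetes"] = 0
        df["bmi"] = 25.0
        pred = np.full(40, 0.156)
        cells = average_cells(pred, df, n_bootstrap=50, seed=1)
        row = cells[(cells["sex"] == "female") & (cells["age_group"] == "<45")
                    & (cells["non_hdl_cat"] == 3) & (cells["rf_burden"] == ">=2")]
        assert row["p0"].iloc[0] == pytest.approx(15.6)
        assert row["ci_low"].iloc[0] == pytest.approx(15.6)
        assert row["ci_high"].iloc[0] == pytest.approx(15.6)
        assert row["n_members"].iloc[0] == 40
        assert len(cells) == 60

    def test_weighted_average_consistency(self, small_cohort):
        """Pooled cell means equal the membership-weighted combination of the
        same cells computed on two halves."""
        df = small_cohort[small_cohort["age_baseline"].between(35, 70)]
        df = df.reset_index(drop=True)
        rng = np.random.default_rng(3)
        pred = rng.uniform(0, 0.5, len(df))
        half = np.arange(len(df)) % 2 == 0
        keys = ["sex", "age_group", "non_hdl_cat", "rf_burden"]
        all_cells = average_cells(pred, df, n_bootstrap=0).set_index(keys)
        a = average_cells(pred[half], df[half], n_bootstrap=0).set_index(keys)
        b = average_cells(pred[~half], df[~half], n_bootstrap=0).set_index(keys)
        n = a["n_members"] + b["n_members"]
        combo = (a["p0"].fillna(0) * a["n_members"]
                 + b["p0"].fillna(0) * b["n_members"]) / n
        mask = n > 0
        assert np.allclose(all_cells.loc[mask, "p0"], combo[mask], atol=1e-9)
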