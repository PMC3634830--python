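"""Kaplan-Meier, log-rank, Cox fits and the per-age curves."""

import math

import numpy as np
import pandas as pd
import pytest

from gendereffect import (ConvergenceError, RegistrySimSpec, cox_fit,
                          hr_by_age, km_fit, logrank, simulate_registry,
                          survdiff_by_age, planted_truth)
from gendereffect._coxph import efron_loglik, fit_coxph

from conftest import registry_frame, grid_max_efron, logrank_oracle


def surv_frame(times, events, sexes=None):
    rows = []
    for i, (t, e) in enumerate(zip(times, events)):
        r = {"time_months": float(t), "event": int(e)}
        if sexes is not None:
            r["sex"] = sexes[i]
        rows.append(r)
    return registry_frame(rows)


class TestKaplanMeier:
    def test_hand_computed_product_limit(self):
        # events at months 1 and 2, censored at 3,3,3:
        # S(1) = 4/5 = 0.8, S(2) = 0.8 * 3/4 = 0.6
        km = km_fit(surv_frame([1, 2, 3, 3, 3], [1, 1, 0, 0, 0]))
        assert km.survival_at(1) == pytest.approx(0.8)
        assert km.survival_at(2) == pytest.approx(0.6)
        assert km.survival_at(0.5) == 1.0

    def test_all_censored_survival_is_one(self):
        km = km_fit(surv_frame([5, 8, 9], [0, 0, 0]))
        assert km.survival_at(100) == 1.0

    def test_single_subject_event_drops_to_zero(self):
        km = km_fit(surv_frame([7], [1]))
        assert km.survival_at(7) == 0.0 and km.survival_at(6.9) == 1.0

    def test_matches_closed_form_product_over_risk_sets(self):
        rng = np.random.default_rng(4)
        t = rng.integers(1, 20, 30)
        e = rng.integers(0, 2, 30)
        e[0] = 1
        km = km_fit(surv_frame(t, e))
        prod = np.prod(1 - km.events / km.at_risk)
        assert km.survival_at(km.grid[-1]) == pytest.approx(prod)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            km_fit(surv_frame([], []))


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        g = surv_frame([1, 2, 3, 4], [1, 1, 0, 1])
        stat, p = logrank(g, g)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_label_symmetry(self):
        a = surv_frame([1, 3, 5], [1, 0, 1])
        b = surv_frame([2, 4, 6], [1, 1, 0])
        assert logrank(a, b)[0] == pytest.approx(logrank(b, a)[0])

    def test_six_subject_toy_matches_risk_set_summation(self):
        t = [1, 2, 3, 4, 5, 6]
        e = [1, 1, 0, 1, 1, 0]
        g = [1, 0, 1, 0, 1, 0]
        a = surv_frame([t[i] for i in range(6) if g[i]],
                       [e[i] for i in range(6) if g[i]])
        b = surv_frame([t[i] for i in range(6) if not g[i]],
                       [e[i] for i in range(6) if not g[i]])
        stat, _ = logrank(a, b)
        assert stat == pytest.approx(logrank_oracle(t, e, g), rel=1e-9)

    def test_empty_group_rejected(self):
        g = surv_frame([1], [1])
        with pytest.raises(ValueError):
            logrank(g, surv_frame([], []))


class TestCoxFit:
    def test_matches_brute_force_grid_search_with_ties(self):
        rng = np.random.default_rng(17)
        for _ in range(5):
            n = int(rng.integers(5, 11))
            x = rng.integers(0, 2, n).astype(float)
            t = rng.integers(1, 5, n).astype(float)  # heavy ties
            e = rng.integers(0, 2, n)
            e[rng.integers(0, n)] = 1
            if x[e == 1].std() == 0 or x.std() == 0:
                continue
            try:
                beta, *_ = fit_coxph(x[:, None], t, e)
            except ConvergenceError:
                continue
            assert beta[0] == pytest.approx(
                grid_max_efron(x, t, e), abs=1e-6)

    def test_loglik_matches_oracle_at_arbitrary_beta(self, oracles):
        x = np.array([1, 0, 1, 1, 0, 0], float)
        t = np.array([2, 2, 3, 1, 3, 4], float)
        e = np.array([1, 1, 0, 1, 1, 0])
        for b in (-1.0, 0.0, 0.7, 2.3):
            assert efron_loglik(x, t, e, [b]) == pytest.approx(
                oracles["efron_loglik"](b, x, t, e), rel=1e-12)

    def test_agrees_with_lifelines_on_simulated_cohort(self):
        from lifelines import CoxPHFitter
        from gendereffect.survival import DEFAULT_TERMS, build_design
        df = simulate_registry(RegistrySimSpec(
            n_patients=3000, seed=21,
            log_hr_by_age={a: 0.3 for a in range(1, 85)}))
        fit = cox_fit(df)
        X, names, _ = build_design(df, DEFAULT_TERMS)
        dd = pd.DataFrame(X, columns=names)
        dd["T"], dd["E"] = df["time_months"].values, df["event"].values
        ll = CoxPHFitter().fit(dd, "T", "E")
        assert np.abs(ll.params_.values - fit.params.values).max() < 1e-5
        assert np.abs(ll.standard_errors_.values - fit.se.values).max() < 1e-6

    def test_null_difference_ci_covers_one(self):
        df = simulate_registry(RegistrySimSpec(n_patients=8000, seed=22))
        ci = cox_fit(df).conf_int.loc["sex[male]"]
        assert ci["lo95"] <= 1.0 <= ci["hi95"]

    def test_single_level_factor_dropped_with_warning(self):
        df = simulate_registry(RegistrySimSpec(n_patients=500, seed=23))
        df["race"] = "caucasian"
        with pytest.warns(UserWarning, match="race"):
            fit = cox_fit(df)
        assert "race[caucasian]" not in fit.params.index
        assert "race" in fit.dropped

    def test_too_few_event_times_rejected(self):
        df = surv_frame([3, 3, 5], [1, 1, 0],
                        sexes=["male", "female", "male"])
        with pytest.raises(ValueError, match="event times"):
            cox_fit(df, ("sex",))

    def test_complete_separation_flagged(self):
        # all events in the male group, before every female time
        df = surv_frame([1, 2, 3, 10, 11, 12], [1, 1, 1, 0, 0, 0],
                        sexes=["male"] * 3 + ["female"] * 3)
        with pytest.raises(ConvergenceError):
            cox_fit(df, ("sex",))


@pytest.fixture(scope="module")
def hump_cohort():
    spec = RegistrySimSpec(
        n_patients=60_000, seed=31,
        log_hr_by_age={a: (math.log(2.2) if 18 <= a <= 45 else 0.0)
                       for a in range(1, 85)})
    return spec, simulate_registry(spec)


class TestHRByAge:
    def test_planted_band_recovered(self, hump_cohort):
        from scipy.stats import spearmanr
        spec, df = hump_cohort
        curve = hr_by_age(df)
        truth = planted_truth(spec)
        m = curve.defined
        rho = spearmanr(curve.hr[m], truth.hr[np.isin(truth.ages,
                                                      curve.ages[m])]).statistic
        assert rho > 0.6
        inside = curve.frame[(curve.frame.age >= 25) & (curve.frame.age <= 40)]
        outside = curve.frame[curve.frame.age >= 65]
        assert inside["hr"].median() > 1.5 > outside["hr"].median()

    def test_pooled_hr_between_min_and_max_of_per_age(self, hump_cohort):
        _, df = hump_cohort
        curve = hr_by_age(df)
        pooled = cox_fit(df).hazard_ratios["sex[male]"]
        m = curve.defined
        assert curve.hr[m].min() < pooled < curve.hr[m].max()

    def test_single_sex_stratum_is_undefined(self, make_registry):
        rows = [{"age_at_dx": 30, "sex": "male", "time_months": t,
                 "event": ev} for t, ev in [(1, 1), (2, 1), (3, 0)]]
        rows += [{"age_at_dx": 31, "sex": s, "time_months": t, "event": ev}
                 for s, t, ev in [("male", 1, 1), ("female", 2, 1),
                                  ("male", 3, 0), ("female", 4, 1),
                                  ("male", 5, 1), ("female", 6, 0)]]
        curve = hr_by_age(make_registry(rows), terms=("sex",))
        s = pd.Series(curve.defined, index=curve.ages)
        assert not s.loc[30] and s.loc[31]

    def test_interaction_method_tracks_stratified_trend(self, hump_cohort):
        _, df = hump_cohort
        inter = hr_by_age(df, method="interaction")
        assert inter.defined.all()
        # a linear-in-age log HR cannot match the band exactly, but the male
        # excess must appear somewhere and the curve must vary with age
        assert inter.hr.max() > 1.1 and inter.hr.min() < inter.hr.max()


class TestSurvDiffByAge:
    def test_identical_hazards_delta_near_zero(self):
        df = simulate_registry(RegistrySimSpec(n_patients=40_000, seed=33))
        sd = survdiff_by_age(df)
        d = sd.frame["delta"].dropna()
        assert abs(d.mean()) < 1.0
        assert sd.frame["significant"].mean() <= 0.12

    def test_planted_band_positive_delta_confined(self, hump_cohort):
        _, df = hump_cohort
        sd = survdiff_by_age(df)
        f = sd.frame.set_index("age")
        sig = f[f["significant"]]
        in_band = sig.loc[(sig.index >= 18) & (sig.index <= 45), "delta"]
        assert (in_band > 0).mean() > 0.95
        # closed form for the expected gap at the plateau: exponential times
        assert f.loc[25:40, "delta"].median() > 5.0

    def test_single_sex_curve_undefined(self, make_registry):
        rows = [{"age_at_dx": a, "sex": "male", "time_months": 5.0, "event": 1}
                for a in (30, 30, 31, 31)]
        sd = survdiff_by_age(make_registry(rows))
        assert sd.frame["delta"].isna().all()
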