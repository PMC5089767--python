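import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hipce.families import available_families, get_family, simulate_event_times
from hipce.survival import (
    AnnualRevisionSchedule,
    ConvergenceError,
    SurvivalFit,
    annual_transition_probs,
    fit_parametric,
    fit_royston_parmar,
    kaplan_meier,
    predict_cumulative_revision,
)

from conftest import make_weibull_data


class TestKaplanMeier:
    def test_no_censoring_equals_empirical_survival(self):
        km = kaplan_meier([1.0, 2.0, 3.0], [1, 1, 1])
        np.testing.assert_allclose(km.survival, [2 / 3, 1 / 3, 0.0])

    def test_hand_product_limit_with_censoring(self):
        # at t=1: 2/3 survive; censored at 2; last subject fails at 3
        km = kaplan_meier([1.0, 2.0, 3.0], [1, 0, 1])
        assert km.survival_at(1.0) == pytest.approx(2 / 3)
        assert km.survival_at(3.0) == pytest.approx(1 / 3 * 1.0 * 0.0 + 2 / 3 * 0.0, abs=1e-12)
        assert km.survival_at(2.5) == pytest.approx(2 / 3)

    def test_s_at_zero_is_one(self):
        km = kaplan_meier([1.0, 2.0], [1, 1])
        assert km.survival_at(0.0) == 1.0

    def test_all_censored_warns(self):
        with pytest.warns(UserWarning, match="censored"):
            km = kaplan_meier([1.0, 2.0], [0, 0])
        assert km.survival_at(5.0) == 1.0
        assert km.n_events == 0

    def test_monotone_and_bounded(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(5.0, 500)
        e = rng.integers(0, 2, 500)
        km = kaplan_meier(t, e)
        assert (np.diff(km.survival) <= 1e-12).all()
        assert ((km.survival >= 0) & (km.survival <= 1)).all()
        assert (km.ci_lower <= km.survival + 1e-12).all()
        assert (km.survival <= km.ci_upper + 1e-12).all()

    def test_matches_lifelines(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(1)
        t = rng.weibull(1.3, 400) * 8
        e = (rng.uniform(size=400) < 0.7).astype(int)
        km = kaplan_meier(t, e)
        kmf = lifelines.KaplanMeierFitter().fit(t, e)
        ours = [km.survival_at(x) for x in km.times]
        theirs = [float(kmf.predict(x)) for x in km.times]
        np.testing.assert_allclose(ours, theirs, atol=1e-10)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            kaplan_meier([0.0, 1.0], [1, 1])
        with pytest.raises(ValueError):
            kaplan_meier([1.0, 2.0], [1, 2])


class TestRoystonParmar:
    def test_df1_recovers_weibull_shape(self, weibull_data):
        fit = fit_royston_parmar(weibull_data, df=1)
        # df=1: log H = gamma0 + gamma1 log t -> shape = gamma1
        shape = fit.gammas[1]
        se = fit.params_se.get("gamma1", 0.05)
        assert abs(shape - 1.4) < 3 * se

    def test_df1_equals_direct_weibull_loglik(self, weibull_data):
        rp = fit_royston_parmar(weibull_data, df=1)
        wb = fit_parametric(weibull_data, "weibull")
        assert abs(rp.log_likelihood - wb.log_likelihood) < 1e-4

    def test_df1_equivalence_on_registry_fixture(self, small_registry):
        rs = small_registry[small_registry["device_class"] == "RS"]
        rp = fit_royston_parmar(rs, df=1)
        wb = fit_parametric(rs, "weibull")
        assert abs(rp.log_likelihood - wb.log_likelihood) < 1e-4

    def test_null_covariate_effect_recovered(self):
        rng = np.random.default_rng(4)
        df = make_weibull_data(n=3000, seed=4)
        df["noise"] = rng.normal(size=len(df))
        fit = fit_royston_parmar(df, df=2, covariates=("noise",))
        assert abs(fit.beta["noise"]) < 3 * fit.beta_se["noise"]

    def test_higher_df_improves_loglik(self, weibull_data):
        ll = [
            fit_royston_parmar(weibull_data, df=d).log_likelihood for d in (1, 2, 3)
        ]
        assert ll[0] <= ll[1] + 1e-6 and ll[1] <= ll[2] + 1e-6

    def test_refuses_without_events(self):
        df = pd.DataFrame({"followup_time": [1.0, 2.0], "revised": [0, 0]})
        with pytest.raises(ValueError, match="events"):
            fit_royston_parmar(df, df=1)

    def test_extrapolated_survival_valid_to_65_years(self, weibull_data):
        for d in (1, 2, 3):
            fit = fit_royston_parmar(weibull_data, df=d)
            t = np.linspace(0.0, 65.0, 300)
            S = fit.predict_survival(t)
            assert S[0] == pytest.approx(1.0)
            assert ((S > 0) & (S <= 1)).all()
            assert (np.diff(S) <= 1e-12).all()


class TestParametricFits:
    def test_exponential_recovered_as_weibull(self):
        df = make_weibull_data(n=5000, shape=1.0, scale=10.0, seed=6)
        fit = fit_parametric(df, "weibull")
        assert abs(fit.params["shape"] - 1.0) < 3 * fit.params_se["shape"]

    def test_bathtub_component_dominance(self):
        true = {
            "shape_early": 0.5,
            "scale_early": 60.0,
            "shape_late": 3.0,
            "scale_late": 15.0,
        }
        rng = np.random.default_rng(8)
        t_event = simulate_event_times("bathtub", true, n=4000, rng=rng)
        censor = rng.uniform(0, 25, size=4000)
        df = pd.DataFrame(
            {
                "followup_time": np.maximum(np.minimum(t_event, censor), 1e-9),
                "revised": (t_event <= censor).astype(int),
            }
        )
        fit = fit_parametric(df, "bathtub")
        assert fit.converged
        fam = get_family("bathtub")
        early1, late1 = fam.hazard_components(0.5, fit.params)
        early8, late8 = fam.hazard_components(10.0, fit.params)
        assert early1 > late1  # early component dominates before year 1
        assert late8 > early8  # late component dominates well after year 8

    def test_all_censored_refused(self):
        df = pd.DataFrame({"followup_time": [1.0, 2.0, 3.0], "revised": [0, 0, 0]})
        with pytest.raises(ValueError, match="events"):
            fit_parametric(df, "weibull")

    def test_unknown_family_rejected(self, weibull_data):
        with pytest.raises(ValueError, match="unknown hazard family"):
            fit_parametric(weibull_data, "frechet")

    @pytest.mark.parametrize("family", available_families())
    def test_extrapolation_bounded_all_families(self, family, weibull_data):
        fit = fit_parametric(weibull_data, family)
        if not fit.converged:
            pytest.skip(f"{family} did not converge on Weibull data")
        t = np.linspace(0.0, 65.0, 200)
        S = fit.predict_survival(t)
        assert ((S > 0) & (S <= 1)).all()
        assert (np.diff(S) <= 1e-12).all()

    def test_json_round_trip(self, weibull_data, tmp_path):
        fit = fit_parametric(weibull_data, "weibull")
        path = tmp_path / "fit.json"
        fit.to_json(path)
        import json

        back = SurvivalFit.from_dict(json.loads(path.read_text()))
        np.testing.assert_allclose(
            back.predict_survival([1.0, 5.0, 10.0]),
            fit.predict_survival([1.0, 5.0, 10.0]),
        )


_RECOVERY_TRUTH = {
    "weibull": {"shape": 1.4, "scale": 12.0},
    "gompertz": {"rate": 0.04, "shape": 0.12},
    "loglogistic": {"scale": 9.0, "shape": 1.6},
    "gengamma": {"a": 1.5, "c": 1.2, "scale": 8.0},
    "bathtub": {
        "shape_early": 0.5,
        "scale_early": 60.0,
        "shape_late": 3.0,
        "scale_late": 15.0,
    },
}


@pytest.mark.parametrize("family", sorted(_RECOVERY_TRUTH))
def test_parameter_recovery_50_replicates(family):
    """Fitting data simulated from each family recovers the truth within
    3 SE in at least 90% of seeded replicates (~30% censoring)."""
    true = _RECOVERY_TRUTH[family]
    n = 2000
    hits = 0
    total = 0
    for seed in range(50):
        rng = np.random.default_rng(1000 + seed)
        t_event = simulate_event_times(family, true, n=n, rng=rng)
        horizon = np.quantile(t_event[np.isfinite(t_event)], 0.85)
        censor = rng.uniform(0, 2 * horizon, size=n)
        df = pd.DataFrame(
            {
                "followup_time": np.maximum(np.minimum(t_event, censor), 1e-9),
                "revised": (t_event <= censor).astype(int),
            }
        )
        fit = fit_parametric(df, family)
        if not fit.converged:
            total += 1
            continue
        ok = True
        for name, truth in true.items():
            se = fit.params_se.get(name)
            if se is None or not np.isfinite(se) or se == 0:
                ok = False
                break
            if abs(fit.params[name] - truth) > 3 * se:
                ok = False
                break
        hits += ok
        total += 1
    assert hits / total >= 0.90, f"{family}: {hits}/{total} replicates recovered"


class TestPrediction:
    def test_zero_at_time_zero(self, weibull_data):
        fit = fit_parametric(weibull_data, "weibull")
        assert predict_cumulative_revision(fit, 0.0) == pytest.approx(0.0)

    def test_weibull_closed_form(self):
        fit = SurvivalFit(family="weibull", params={"shape": 1.5, "scale": 20.0})
        for t in (0.5, 2.0, 10.0, 30.0):
            expected = 1.0 - np.exp(-((t / 20.0) ** 1.5))
            assert predict_cumulative_revision(fit, t) == pytest.approx(
                expected, abs=1e-10
            )

    def test_monotone_in_t(self, weibull_data):
        fit = fit_parametric(weibull_data, "weibull")
        assert predict_cumulative_revision(fit, 10.0) >= predict_cumulative_revision(
            fit, 5.0
        )

    def test_negative_t_rejected(self, weibull_data):
        fit = fit_parametric(weibull_data, "weibull")
        with pytest.raises(ValueError):
            predict_cumulative_revision(fit, -1.0)

    def test_nonconverged_fit_refuses_prediction(self):
        fit = SurvivalFit(
            family="weibull", params={"shape": 1.0, "scale": 1.0}, converged=False
        )
        with pytest.raises(ConvergenceError):
            fit.predict_survival(1.0)

    def test_missing_covariate_value_rejected(self, small_registry):
        rs = small_registry[small_registry["device_class"] == "RS"]
        fit = fit_parametric(rs, "weibull", covariates=("age_at_primary",))
        with pytest.raises(ValueError, match="age_at_primary"):
            fit.predict_survival(5.0, {})


class TestAnnualSchedule:
    def test_constant_hazard_closed_form(self):
        # S(t) = exp(-0.1 t): every annual probability is 1 - exp(-0.1)
        fit = SurvivalFit(family="weibull", params={"shape": 1.0, "scale": 10.0})
        sched = annual_transition_probs(fit, horizon=10)
        np.testing.assert_allclose(sched.probs, 1.0 - np.exp(-0.1), atol=1e-12)

    def test_telescoping_identity(self, weibull_data):
        fit = fit_parametric(weibull_data, "weibull")
        sched = annual_transition_probs(fit, horizon=10)
        assert sched.survival() == pytest.approx(
            float(fit.predict_survival(10.0)), abs=1e-12
        )

    def test_zero_hazard_schedule(self):
        sched = AnnualRevisionSchedule.zero(10)
        assert (sched.probs == 0).all()
        assert sched.survival() == 1.0

    def test_bad_horizon_rejected(self, weibull_data):
        fit = fit_parametric(weibull_data, "weibull")
        with pytest.raises(ValueError):
            annual_transition_probs(fit, horizon=0)

    @given(
        shape=st.floats(0.5, 3.0),
        scale=st.floats(5.0, 50.0),
        horizon=st.integers(1, 30),
    )
    @settings(max_examples=25, deadline=None)
    def test_product_identity_property(self, shape, scale, horizon):
        fit = SurvivalFit(family="weibull", params={"shape": shape, "scale": scale})
        sched = annual_transition_probs(fit, horizon=horizon)
        assert ((sched.probs >= 0) & (sched.probs <= 1)).all()
        assert sched.survival() == pytest.approx(
            float(fit.predict_survival(float(horizon))), abs=1e-12
        )
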