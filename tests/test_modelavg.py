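"""All-subsets enumeration, AIC weighting and full model averaging."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crowflock.modelavg import (
    FLOCK_TERMS,
    SUBGROUP_TERMS,
    FitResult,
    ModelSpec,
    akaike_weights,
    all_subsets_average,
    enumerate_models,
    fit_model,
    full_average,
    prepare_model_data,
)


def _flock_table(n_days=40, seed=0):
    rng = np.random.default_rng(seed)
    dates = pd.date_range("2014-01-08", periods=n_days, freq="3D")
    rows = []
    for d in dates:
        for sess in ("Morning", "Afternoon"):
            rows.append(
                {
                    "date": d,
                    "session": sess,
                    "FS_e_t": float(rng.integers(20, 90)),
                    "weather": rng.choice(["rain", "clouds", "sun"]),
                    "temperature": rng.choice(["cold", "warm", "hot"]),
                    "visitors": rng.choice(["few", "some", "many"]),
                }
            )
    return pd.DataFrame(rows)


class TestPrepare:
    def test_subgroup_response_is_size_minus_one(self):
        table = pd.DataFrame(
            {
                "date": pd.to_datetime(["2014-05-01"] * 3),
                "session": "Morning",
                "subgroup_size": [1, 2, 5],
                "weather": "sun",
                "temperature": "warm",
                "visitors": "few",
                "n_crows_present": [3.0, 3.0, 3.0],
                "age_class": "juvenile",
                "forested_area": "in_forest",
                "food": "grass",
                "on_building": "on",
            }
        )
        data = prepare_model_data(table, response="subgroup")
        assert data.response.tolist() == [0, 1, 4]
        assert data.candidate_terms == SUBGROUP_TERMS

    def test_flock_response_rounding(self):
        table = _flock_table(n_days=5)
        table.loc[0, "FS_e_t"] = 16.4
        table.loc[1, "FS_e_t"] = 16.6
        data = prepare_model_data(table, response="flock")
        assert data.response[0] == 16 and data.response[1] == 17

    def test_unknown_level_rejected(self):
        table = _flock_table(n_days=5)
        table.loc[2, "weather"] = "snow"
        with pytest.raises(ValueError, match="snow"):
            prepare_model_data(table, response="flock")

    def test_missing_covariate_rejected(self):
        table = _flock_table(n_days=5)
        table.loc[3, "weather"] = np.nan
        with pytest.raises(ValueError, match="weather"):
            prepare_model_data(table, response="flock")

    def test_reference_levels_absorbed_into_intercept(self):
        table = _flock_table(n_days=10)
        data = prepare_model_data(table, response="flock")
        cols = list(data.design.columns)
        for ref in ("rain", "cold", "Morning", "nonbreeder", "few"):
            assert not any(f"[{ref}]" in c for c in cols)


class TestEnumerate:
    @pytest.mark.parametrize("terms, count", [(FLOCK_TERMS, 32), (SUBGROUP_TERMS, 1024), ((), 1)])
    def test_all_subsets(self, terms, count):
        specs = enumerate_models(terms)
        assert len(specs) == count
        assert specs[0].terms == ()  # intercept-only first
        assert len({s.terms for s in specs}) == count

    def test_deterministic_order(self):
        assert enumerate_models(("a", "b")) == enumerate_models(("a", "b"))


class TestFit:
    def test_intercept_only_closed_form(self):
        table = _flock_table(n_days=8)
        table["FS_e_t"] = 3.0
        data = prepare_model_data(table, response="flock")
        fit = fit_model(ModelSpec(terms=(), random_intercept=False), data)
        assert fit.converged
        assert fit.estimates["(Intercept)"] == pytest.approx(np.log(3.0), abs=1e-6)

    def test_poisson_effect_recovery_without_random_intercept(self):
        rng = np.random.default_rng(4)
        n = 2000
        dates = pd.to_datetime("2014-01-08") + pd.to_timedelta(rng.integers(0, 100, n), unit="D")
        x = rng.integers(0, 2, n)
        y = rng.poisson(np.exp(1.0 + 0.5 * x))
        table = pd.DataFrame(
            {
                "date": dates,
                "session": "Morning",
                "FS_e_t": y.astype(float),
                "weather": np.where(x == 1, "sun", "rain"),
                "temperature": "cold",
                "visitors": "few",
            }
        )
        data = prepare_model_data(table, response="flock", candidate_terms=("weather",))
        fit = fit_model(ModelSpec(terms=("weather",), random_intercept=False), data)
        est, se = fit.estimates["weather[sun]"], fit.ses["weather[sun]"]
        assert abs(est - 0.5) < 3 * se

    def test_noise_term_never_decreases_loglik(self):
        table = _flock_table(n_days=30, seed=9)
        data = prepare_model_data(table, response="flock", candidate_terms=("weather", "visitors"))
        base = fit_model(ModelSpec(terms=("weather",), random_intercept=False), data)
        bigger = fit_model(ModelSpec(terms=("weather", "visitors"), random_intercept=False), data)
        assert bigger.llf >= base.llf - 1e-6

    def test_singular_design_flagged_not_raised(self):
        table = _flock_table(n_days=6)
        table["weather"] = "sun"  # dummy column constant -> singular with itself duplicated
        table["visitors"] = "many"
        data = prepare_model_data(table, response="flock", candidate_terms=("weather", "visitors"))
        fit = fit_model(ModelSpec(terms=("weather", "visitors"), random_intercept=False), data)
        assert isinstance(fit.converged, bool)  # no crash; flag carries the verdict


class TestWeights:
    def test_two_model_closed_form(self):
        w = akaike_weights([100.0, 102.0])
        assert w == pytest.approx([1 / (1 + np.exp(-1)), 1 - 1 / (1 + np.exp(-1))], abs=1e-4)
        assert w[0] == pytest.approx(0.7311, abs=1e-4)

    def test_equal_aics(self):
        assert akaike_weights([5.0] * 4) == pytest.approx([0.25] * 4)

    @given(st.lists(st.floats(-1e4, 1e4), min_size=1, max_size=40), st.floats(-1e5, 1e5))
    @settings(max_examples=100, deadline=None)
    def test_normalization_and_shift_invariance(self, aics, shift):
        w = akaike_weights(aics)
        assert abs(w.sum() - 1.0) < 1e-12
        assert (w >= 0).all()
        w2 = akaike_weights([a + shift for a in aics])
        assert np.allclose(w, w2, atol=1e-9)


def _fr(terms, estimates, ses, aic=0.0):
    return FitResult(
        spec=ModelSpec(terms=terms), estimates=estimates, ses=ses, llf=0.0, aic=aic, converged=True
    )


class TestFullAverage:
    def test_identical_estimates_pass_through(self):
        fits = [
            _fr(("a",), {"(Intercept)": 0.2, "a": 1.3}, {"(Intercept)": 0.1, "a": 0.4}),
            _fr(("a", "b"), {"(Intercept)": 0.2, "a": 1.3, "b": 0.0}, {"(Intercept)": 0.1, "a": 0.4, "b": 0.2}),
        ]
        out = full_average(fits, weights=[0.5, 0.5])
        assert out.loc["a", "estimate"] == pytest.approx(1.3)
        assert out.loc["a", "se"] == pytest.approx(0.4)

    def test_zero_substitution_hand_example(self):
        """Two models, equal weight; term present once with estimate 1 and
        SE 0 -> average 0.5 with unconditional SE 0.5."""
        fits = [
            _fr(("a",), {"a": 1.0}, {"a": 0.0}),
            _fr((), {}, {}),
        ]
        out = full_average(fits, weights=[0.5, 0.5])
        assert out.loc["a", "estimate"] == pytest.approx(0.5)
        assert out.loc["a", "se"] == pytest.approx(0.5)

    def test_concentrated_weight_limit(self):
        fits = [
            _fr(("a",), {"a": 2.0}, {"a": 0.3}),
            _fr((), {}, {}),
        ]
        out = full_average(fits, weights=[1.0 - 1e-12, 1e-12])
        assert out.loc["a", "estimate"] == pytest.approx(2.0, abs=1e-9)
        assert out.loc["a", "se"] == pytest.approx(0.3, abs=1e-6)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            full_average([])


def test_all_subsets_average_smoke():
    """32-model flock averaging end to end, no random intercept."""
    table = _flock_table(n_days=40, seed=2)
    data = prepare_model_data(table, response="flock")
    res = all_subsets_average(data, family="poisson", random_intercept=False)
    assert len(res["fits"]) == 32
    assert res["weights"].sum() == pytest.approx(1.0, abs=1e-12)
    avg = res["average"]
    assert "(Intercept)" in avg.index
    # every non-reference level of every candidate term appears
    assert {"weather[clouds]", "temperature[hot]", "visitors[many]"} <= set(avg.index)
    assert (avg["se"] >= 0).all()
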