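import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq

from nanobmd import bmd, synth
from nanobmd.bmd import (
    ResponseTable,
    ced_closed_form,
    fit_bmd,
    fit_exponential_family,
    model_mean,
    profile_interval,
    select_model,
)

from conftest import make_table


class TestModelMean:
    def test_m2_closed_form(self):
        assert model_mean(2, {"a": 1.0, "b": math.log(1.2)}, 1.0) == pytest.approx(1.2)

    def test_m4_asymptote(self):
        assert model_mean(4, {"a": 1.0, "b": 1e9, "c": 2.0}, 5.0) == pytest.approx(2.0)

    def test_m5_hand_value(self):
        expected = 2.0 * (3.0 - 2.0 * math.exp(-0.5))
        assert model_mean(
            5, {"a": 2.0, "b": 0.5, "c": 3.0, "d": 2.0}, 1.0
        ) == pytest.approx(expected)

    @pytest.mark.parametrize("model_id, params", [
        (1, {"a": 3.0}),
        (2, {"a": 3.0, "b": 0.5}),
        (3, {"a": 3.0, "b": 0.5, "d": 2.0}),
        (4, {"a": 3.0, "b": 0.5, "c": 2.0}),
        (5, {"a": 3.0, "b": 0.5, "c": 2.0, "d": 2.0}),
    ])
    def test_background_at_zero_and_monotone(self, model_id, params):
        assert model_mean(model_id, params, 0.0) == pytest.approx(params["a"])
        doses = np.linspace(0, 20, 50)
        values = model_mean(model_id, params, doses)
        assert np.all(np.diff(values) >= -1e-12)

    @pytest.mark.parametrize("model_id, params", [
        (2, {"a": 1.0, "b": -0.1}),
        (4, {"a": 1.0, "b": 0.1, "c": 0.9}),
        (3, {"a": 1.0, "b": 0.1, "d": 0.5}),
        (7, {"a": 1.0}),
        (2, {"a": -1.0, "b": 0.1}),
    ])
    def test_invalid_params_rejected(self, model_id, params):
        with pytest.raises(ValueError):
            model_mean(model_id, params, 1.0)


param_strategy = st.fixed_dictionaries(
    {
        "model_id": st.sampled_from([2, 3, 4, 5]),
        "b": st.floats(min_value=1e-3, max_value=10.0),
        "c": st.floats(min_value=1.35, max_value=50.0),
        "d": st.floats(min_value=1.0, max_value=4.0),
        "ces": st.floats(min_value=0.05, max_value=1.0),
    }
)


class TestCedClosedForm:
    def test_m2_unit(self):
        assert ced_closed_form(2, {"a": 1, "b": math.log(1.2)}, 0.2) == pytest.approx(1.0)

    def test_m3_unit(self):
        assert ced_closed_form(
            3, {"a": 1, "b": math.log(1.2), "d": 2.0}, 0.2
        ) == pytest.approx(1.0)

    def test_m4_unreachable_asymptote(self):
        assert ced_closed_form(4, {"a": 1, "b": 1.0, "c": 1.2}, 0.2) is None

    def test_constant_model_has_no_ced(self):
        assert ced_closed_form(1, {"a": 1.0}, 0.2) is None

    @given(draw=param_strategy)
    @settings(max_examples=100, deadline=None)
    def test_agrees_with_bisection(self, draw):
        """Exact inversion matches numerically inverting the mean curve."""
        model_id, ces = draw["model_id"], draw["ces"]
        params = {"a": 2.0, "b": draw["b"]}
        if model_id in (4, 5):
            params["c"] = 1.0 + ces + draw["c"]  # keep the level reachable
        if model_id in (3, 5):
            params["d"] = draw["d"]
        ced = ced_closed_form(model_id, params, ces)
        assert ced is not None and ced > 0
        # the mean at the CED hits the benchmark response exactly
        assert model_mean(model_id, params, ced) == pytest.approx(
            (1 + ces) * params["a"], rel=1e-10
        )
        target = (1 + ces) * params["a"]
        f = lambda x: model_mean(model_id, params, x) - target
        lo, hi = ced * 1e-6, ced * 1e6
        if f(lo) < 0 < f(hi):
            assert brentq(f, lo, hi, xtol=1e-14, rtol=1e-12) == pytest.approx(
                ced, rel=1e-8
            )


class TestFitting:
    def test_noise_free_m2_recovery(self):
        doses = np.repeat([0.0, 1.0, 3.0, 10.0], 6)
        table = make_table(doses, 1.0 * np.exp(0.1 * doses))
        fit = fit_exponential_family(table, models=(2,))[0]
        assert fit.b == pytest.approx(0.1, abs=1e-6)
        assert fit.a == pytest.approx(1.0, rel=1e-6)

    def test_constant_data_boundary_equivalence(self):
        """On constant data every model collapses to the constant fit."""
        doses = np.repeat([0.0, 1.0, 10.0], 4)
        table = make_table(doses, np.full(doses.size, 5.0))
        fits = {f.model_id: f for f in fit_exponential_family(table)}
        for model_id in (2, 3, 4, 5):
            assert fits[model_id].loglik == pytest.approx(fits[1].loglik, abs=1e-4)

    def test_likelihood_nesting(self, m2_table):
        """A nested extra parameter never decreases the maximised
        log-likelihood.  Only strictly nested pairs are compared: the
        unbounded models (m2, m3) are c -> infinity limits of the
        saturating ones (m4, m5), not members of them."""
        fits = {f.model_id: f for f in fit_exponential_family(m2_table)}
        tol = 1e-5
        assert fits[2].loglik >= fits[1].loglik - tol
        assert fits[3].loglik >= fits[2].loglik - tol
        assert fits[4].loglik >= fits[1].loglik - tol
        assert fits[5].loglik >= fits[4].loglik - tol

    def test_rejects_tables_without_control(self):
        with pytest.raises(ValueError, match="control"):
            make_table([1.0, 1.0, 3.0, 3.0], [1, 2, 3, 4])

    def test_rejects_nonpositive_responses(self):
        with pytest.raises(ValueError, match="> 0"):
            make_table([0.0, 0.0, 3.0, 3.0], [1.0, -2.0, 3.0, 4.0])


class TestSelection:
    def test_single_fit_returned_as_is(self, m2_table):
        fits = fit_exponential_family(m2_table, models=(3,))
        assert select_model(fits) is fits[0]

    def test_null_data_rarely_promotes_beyond_constant(self):
        """Type-I of the m1->m2 ladder step stays near alpha = 0.05."""
        truth = synth.EndpointTruth(model_id=1, a=50.0, sigma=0.25)
        promoted = 0
        n_sim = 120
        for s in range(n_sim):
            table = synth.generate_dose_response(
                truth, [0, 1, 3, 10], 6, np.random.default_rng(1000 + s)
            )
            promoted += select_model(fit_exponential_family(table)).model_id != 1
        assert promoted / n_sim < 0.12  # ~alpha plus binomial noise

    def test_strong_slope_selects_responding_model(self, m2_table):
        selected = select_model(fit_exponential_family(m2_table))
        assert selected.model_id in (2, 3, 4, 5)
        ced = ced_closed_form(selected.model_id, selected.params(), 0.2)
        assert 2.5 <= ced <= 10.0  # within 2x of the true CED of 5

    def test_aic_rule(self, m2_table):
        fits = fit_exponential_family(m2_table)
        best = select_model(fits, rule="aic")
        assert best.aic == min(f.aic for f in fits if f.converged)


class TestProfile:
    def test_noise_free_interval_collapses_on_ced(self):
        doses = np.repeat([0.0, 1.0, 3.0, 10.0], 6)
        table = make_table(doses, np.exp(0.05 * doses))
        result = fit_bmd(table, models=(2,))
        assert result.status == "ok"
        assert result.bmdl == pytest.approx(result.ced, rel=1e-3)
        assert result.bmdu == pytest.approx(result.ced, rel=1e-3)

    def test_interval_brackets_ced(self, m2_table):
        result = fit_bmd(m2_table)
        assert result.status in ("ok", "unbounded_upper")
        assert result.bmdl <= result.ced
        if result.bmdu is not None:
            assert result.ced <= result.bmdu

    def test_higher_confidence_never_narrows(self, m2_table):
        fits = fit_exponential_family(m2_table)
        selected = select_model(fits)
        l90, u90, _ = profile_interval(m2_table, selected, confidence=0.90)
        l95, u95, _ = profile_interval(m2_table, selected, confidence=0.95)
        assert l95 <= l90 * (1 + 1e-6)
        if u90 is not None and u95 is not None:
            assert u95 >= u90 * (1 - 1e-6)

    def test_constant_model_cannot_be_profiled(self, flat_table):
        fits = fit_exponential_family(flat_table, models=(1,))
        with pytest.raises(ValueError):
            profile_interval(flat_table, fits[0])


class TestFitBmd:
    def test_median_ced_recovery(self):
        """Median fitted CED over replicate draws stays within 20% of truth."""
        truth = synth.EndpointTruth.from_ced(2, 100.0, 5.0, 0.2, 0.25)
        ceds = []
        for s in range(60):
            table = synth.generate_dose_response(
                truth, [0, 1, 3, 10], 6, np.random.default_rng(2000 + s)
            )
            result = fit_bmd(table)
            if result.defined:
                ceds.append(result.ced)
        assert len(ceds) > 30
        assert abs(np.median(ceds) - 5.0) / 5.0 < 0.20

    def test_flat_truth_mostly_no_response(self):
        truth = synth.EndpointTruth(model_id=1, a=50.0, sigma=0.25)
        nd = 0
        for s in range(25):
            table = synth.generate_dose_response(
                truth, [0, 1, 3, 10], 6, np.random.default_rng(3000 + s)
            )
            nd += fit_bmd(table).status == "no_response"
        assert nd / 25 > 0.6

    def test_deterministic_given_table_and_seed(self, m2_table):
        r1 = fit_bmd(m2_table, seed=11)
        r2 = fit_bmd(m2_table, seed=11)
        assert (r1.ced, r1.bmdl, r1.bmdu) == (r2.ced, r2.bmdl, r2.bmdu)

    def test_dose_scale_equivariance_exact_binary(self, m2_table):
        """Rescaling doses by a power of two rescales CED/BMDL/BMDU exactly."""
        base = fit_bmd(m2_table)
        for k in (0.125, 8.0):
            scaled_table = ResponseTable(
                m2_table.material_id, m2_table.context_id, m2_table.endpoint,
                m2_table.metric, m2_table.doses * k, m2_table.responses,
            )
            scaled = fit_bmd(scaled_table)
            assert scaled.ced == pytest.approx(k * base.ced, rel=1e-13)
            assert scaled.bmdl == pytest.approx(k * base.bmdl, rel=1e-13)
            assert scaled.bmdu == pytest.approx(k * base.bmdu, rel=1e-13)

    def test_response_scale_leaves_ced_unchanged(self, m2_table):
        base = fit_bmd(m2_table)
        scaled_table = ResponseTable(
            m2_table.material_id, m2_table.context_id, m2_table.endpoint,
            m2_table.metric, m2_table.doses, m2_table.responses * 50.0,
        )
        scaled = fit_bmd(scaled_table)
        assert scaled.ced == pytest.approx(base.ced, rel=1e-6)
        assert scaled.selected_model.a == pytest.approx(
            50.0 * base.selected_model.a, rel=1e-6
        )
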