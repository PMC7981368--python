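"""Sigmoid packing models: evaluation, limits, inflection, fitting, bootstrap."""

import numpy as np
import pytest

from porescale.models import (MODELS, ModelError, asymptote_onset,
                              bootstrap_ci, eval_model, fit_model,
                              inflection_point, richards_d, select_model)
from porescale.synthetic import make_packing_trace

RICHARDS_REGIME = {"A": 1.05, "t": 0.2, "s": 18.02, "q_tilde": 0.54}


def numeric_inflection(model, params, lo, hi):
    """Oracle: root of the finite-difference second derivative, bracketed
    around the maximum of the first derivative (the RDF peak)."""
    from scipy.optimize import brentq

    grid = np.linspace(lo, hi, 4001)
    n = eval_model(model, params, grid)
    d1 = np.gradient(n, grid)
    i = int(np.argmax(d1))
    assert 0 < i < len(grid) - 1
    h = (hi - lo) * 1e-5

    def d2(x):
        f = lambda y: float(eval_model(model, params, np.array([y]))[0])
        return (f(x + h) - 2.0 * f(x) + f(x - h)) / h**2

    a, b = grid[max(i - 3, 0)], grid[min(i + 3, len(grid) - 1)]
    assert d2(a) * d2(b) < 0
    return brentq(d2, a, b, xtol=1e-10)


class TestEvalModel:
    def test_logistic_half_asymptote_at_inflection(self):
        p = {"A": 1.0, "t": 0.25, "s": 10.0}
        xi = p["s"] + p["A"] / (2 * p["t"])
        assert eval_model("logistic", p, [xi])[0] == pytest.approx(0.5)

    def test_gompertz_value_a_over_e_at_inflection(self):
        p = {"A": 1.0, "t": 0.25, "s": 10.0}
        xi = p["s"] + p["A"] / (np.e * p["t"])
        assert eval_model("gompertz", p, [xi])[0] == pytest.approx(1 / np.e)

    def test_richards_special_cases(self):
        l = np.linspace(0, 40, 50)
        base = {"A": 1.0, "t": 0.25, "s": 10.0}
        logi = eval_model("logistic", base, l)
        gomp = eval_model("gompertz", base, l)
        ric1 = eval_model("richards", {**base, "q_tilde": 1.0}, l)
        np.testing.assert_allclose(ric1, logi, atol=1e-9)
        ric0 = eval_model("richards", {**base, "q_tilde": 1e-8}, l)
        np.testing.assert_allclose(ric0, gomp, atol=1e-5)
        # continuity across the small-q_tilde switch
        ric_eps = eval_model("richards", {**base, "q_tilde": 1e-5}, l)
        np.testing.assert_allclose(ric_eps, gomp, atol=1e-4)

    def test_overflow_safe_far_from_the_rise(self):
        p = {"A": 1.0, "t": 5.0, "s": 500.0, "q_tilde": 2.0}
        vals = eval_model("richards", p, [0.0, 1e6])
        assert np.all(np.isfinite(vals))

    def test_invalid_params_rejected(self):
        with pytest.raises(ModelError):
            eval_model("logistic", {"A": -1.0, "t": 0.1, "s": 1.0}, [1.0])
        with pytest.raises(ModelError):
            eval_model("richards",
                       {"A": 1.0, "t": 0.1, "s": 1.0, "q_tilde": -1.5}, [1.0])

    def test_monotone_non_decreasing_for_plain_sigmoids(self):
        l = np.linspace(0, 60, 500)
        for model in ("logistic", "gompertz", "richards"):
            p = {"A": 1.0, "t": 0.2, "s": 15.0}
            if model == "richards":
                p["q_tilde"] = 0.54
            assert np.all(np.diff(eval_model(model, p, l)) >= -1e-12)


class TestInflectionPoint:
    def test_logistic_closed_form(self):
        xi = inflection_point("logistic", {"A": 1.0, "t": 0.25, "s": 10.0})
        assert xi == pytest.approx(12.0)

    @pytest.mark.parametrize("model,params", [
        ("logistic", {"A": 1.0, "t": 0.25, "s": 10.0}),
        ("gompertz", {"A": 1.2, "t": 0.15, "s": 12.0}),
        ("richards", RICHARDS_REGIME),
        ("richards", {"A": 0.9, "t": 0.3, "s": 8.0, "q_tilde": -0.4}),
    ])
    def test_closed_form_matches_numeric_root(self, model, params):
        xi = inflection_point(model, params)
        oracle = numeric_inflection(model, params, 0.0,
                                    params["s"] + 4 * params["A"] / params["t"])
        assert xi == pytest.approx(oracle, abs=1e-6)

    def test_rdf_maximized_at_inflection(self):
        params = RICHARDS_REGIME
        xi = inflection_point("richards", params)
        grid = np.linspace(5, 35, 30001)
        rdf = np.gradient(eval_model("richards", params, grid), grid)
        assert grid[np.argmax(rdf)] == pytest.approx(xi, abs=2e-3)

    def test_modified_gompertz_numeric_root(self):
        params = {"A": 1.0, "t": 0.2, "s": 10.0, "w": 0.01, "l_shift": 60.0}
        xi = inflection_point("modified_gompertz", params, (0.0, 40.0))
        base = inflection_point("gompertz",
                                {k: params[k] for k in ("A", "t", "s")})
        assert xi == pytest.approx(base, abs=0.1)  # weak second rise

    def test_tangent_onset_identity(self):
        # o - s == A/t exactly for the three reparametrised sigmoids
        for model in ("logistic", "gompertz", "richards"):
            p = {"A": 1.05, "t": 0.2, "s": 18.02}
            if model == "richards":
                p["q_tilde"] = 0.54
            o = asymptote_onset(model, p)
            assert o - p["s"] == pytest.approx(p["A"] / p["t"], rel=1e-12)

    def test_threshold_onset_reaches_99_percent(self):
        p = dict(RICHARDS_REGIME)
        o = asymptote_onset("richards", p, o_mode="threshold")
        val = eval_model("richards", p, [o])[0]
        assert val == pytest.approx(0.99 * p["A"], rel=1e-6)


class TestFitModel:
    def test_noiseless_logistic_recovery(self):
        true = {"A": 1.0, "t": 0.25, "s": 10.0}
        l, n = make_packing_trace("logistic", true, noise_sd=0.0, K_alpha=120)
        fit = fit_model(l, n, "logistic", normalize=False)
        assert fit.converged
        for k, v in true.items():
            assert fit.params[k] == pytest.approx(v, rel=1e-6)
        assert fit.mafe < 1e-8

    def test_fit_invariants_hold_for_converged_richards(self):
        l, n = make_packing_trace("richards", RICHARDS_REGIME,
                                  noise_sd=0.005, K_alpha=150, seed=5)
        fit = fit_model(l, n, "richards", normalize=False)
        assert fit.converged
        assert fit.s < fit.xi < fit.o
        assert fit.t == pytest.approx(fit.A / fit.os_, rel=0.02)
        assert fit.q == pytest.approx(1.0 - fit.q_tilde)

    def test_degenerate_constant_trace_flagged(self):
        fit = fit_model(np.linspace(1, 10, 20), np.ones(20), "logistic")
        assert not fit.converged
        assert "degenerate" in fit.message

    def test_too_few_points_rejected(self):
        with pytest.raises(ModelError, match="8 points"):
            fit_model(np.arange(4), np.arange(4), "logistic")


class TestSelectModel:
    def test_logistic_data_selects_logistic_family(self):
        true = {"A": 1.0, "t": 0.25, "s": 10.0}
        l, n = make_packing_trace("logistic", true, noise_sd=0.0, K_alpha=120)
        best = select_model(l, n, normalize=False)
        assert best.model == "logistic" or (
            best.model == "richards"
            and best.q_tilde == pytest.approx(1.0, abs=0.05))
        np.testing.assert_allclose(
            eval_model(best.model, best.params, l),
            eval_model("logistic", true, l), atol=1e-3)

    def test_gompertz_data_drives_q_tilde_to_zero(self):
        true = {"A": 1.0, "t": 0.25, "s": 10.0}
        l, n = make_packing_trace("gompertz", true, noise_sd=0.0, K_alpha=120)
        best = select_model(l, n, normalize=False)
        assert best.model == "gompertz" or (
            best.model == "richards" and abs(best.q_tilde) < 0.05)

    def test_four_point_trace_rejected(self):
        with pytest.raises(ModelError):
            select_model(np.arange(4), np.arange(4.0))


class TestBootstrap:
    def test_zero_noise_intervals_collapse(self):
        true = {"A": 1.0, "t": 0.25, "s": 10.0}
        l, n = make_packing_trace("logistic", true, noise_sd=0.0, K_alpha=80)
        fit = fit_model(l, n, "logistic", normalize=False)
        ci = bootstrap_ci(l, n, fit, n_boot=40, seed=1, normalize=False)
        for lo, hi in ci.values():
            assert hi - lo < 1e-4

    def test_fixed_seed_reproducible(self):
        l, n = make_packing_trace("richards", RICHARDS_REGIME,
                                  noise_sd=0.01, K_alpha=80, seed=2)
        fit = fit_model(l, n, "richards", normalize=False)
        ci1 = bootstrap_ci(l, n, fit, n_boot=30, seed=7, normalize=False)
        ci2 = bootstrap_ci(l, n, fit, n_boot=30, seed=7, normalize=False)
        assert ci1 == ci2
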