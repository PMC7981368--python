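"""Scale-invariance analysis: power-law fits, regions, composite model."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from porescale.models import eval_model, fit_model
from porescale.sampling import RadialTraces
from porescale.scaling import (ScalingError, aggregate_traces,
                               composite_chdf_model, coupling_energy,
                               crossover_correlation,
                               detect_scale_invariance, domain_composition,
                               fit_biphasic, loglog_powerlaw_fit)
from porescale.synthetic import make_powerlaw_hiis

from conftest import build_structure
from porescale.geometry import PorePoint


def _traces(l, N, h_z=None, z=0.0):
    N = np.asarray(N, dtype=float)
    h_z = np.zeros_like(N) if h_z is None else np.asarray(h_z, dtype=float)
    I = np.where(N > 0, np.abs(h_z) / np.maximum(N, 1), np.nan)
    return RadialTraces(
        p=PorePoint(p=np.array([0.0, 0.0, z]), R=1.0, D=float(l[0]) - 0.1,
                    L=float(l[-1])),
        l=np.asarray(l, dtype=float), N=N, h_z=h_z,
        h_xy_mag=np.zeros_like(N), I=I, AE=np.abs(h_z) / l)


class TestLogLogFit:
    def test_exact_power_law_recovered(self):
        x, I = make_powerlaw_hiis(1.41, -8.4, (1, 100))
        gamma, beta, pc = loglog_powerlaw_fit(x, I)
        assert gamma == pytest.approx(1.41, abs=1e-9)
        assert beta == pytest.approx(-8.4, abs=1e-9)
        assert pc == pytest.approx(1.0, abs=1e-12)

    def test_constant_trace_has_zero_slope(self):
        x = np.linspace(1, 10, 30)
        gamma, _, _ = loglog_powerlaw_fit(x, np.full(30, 2.0))
        assert gamma == pytest.approx(0.0, abs=1e-12)

    def test_nonpositive_values_masked_with_warning(self):
        x = np.linspace(1, 10, 30)
        I = 2.0 * x**1.5
        I[5] = 0.0
        with pytest.warns(UserWarning, match="masked"):
            gamma, _, _ = loglog_powerlaw_fit(x, I)
        assert gamma == pytest.approx(1.5, abs=1e-9)

    def test_too_few_points_rejected(self):
        with pytest.raises(ScalingError):
            loglog_powerlaw_fit(np.array([1.0, 2.0]), np.array([1.0, 2.0]))

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(scale=hst.floats(1e-3, 1e3), seed=hst.integers(0, 1000))
    def test_uniform_rescaling_changes_only_intercept(self, scale, seed):
        x, I = make_powerlaw_hiis(0.8, -2.0, (1, 50), noise_sd=0.1, seed=seed)
        g1, b1, pc1 = loglog_powerlaw_fit(x, I)
        g2, b2, pc2 = loglog_powerlaw_fit(x, scale * I)
        assert g2 == pytest.approx(g1, rel=1e-9, abs=1e-12)
        assert pc2 == pytest.approx(pc1, rel=1e-9)
        assert b2 == pytest.approx(b1 + np.log(scale), rel=1e-6, abs=1e-9)


class TestBiphasic:
    def test_exact_piecewise_slopes_recovered(self):
        xi = 20.0
        x = np.geomspace(5, 60, 200)
        I = np.where(x <= xi, x**1.41, xi**(1.41 + 2.76) * x**-2.76)
        sf = fit_biphasic(x, I, s=6.0, xi=xi)
        assert sf.gamma_pre == pytest.approx(1.41, abs=1e-6)
        assert sf.gamma_post == pytest.approx(-2.76, abs=1e-6)
        assert abs(sf.pc_pre) == pytest.approx(1.0, abs=1e-9)

    def test_pure_power_law_gives_equal_slopes(self):
        x, I = make_powerlaw_hiis(0.7, 0.0, (2, 80), n_points=300)
        sf = fit_biphasic(x, I, s=3.0, xi=20.0)
        assert sf.gamma_pre == pytest.approx(sf.gamma_post, abs=1e-9)

    def test_requires_ordered_boundaries(self):
        x, I = make_powerlaw_hiis(1.0, 0.0, (1, 10))
        with pytest.raises(ScalingError):
            fit_biphasic(x, I, s=5.0, xi=5.0)


class TestDetectScaleInvariance:
    def _fits(self, z, good_window, noise_seed=0):
        fits = []
        for i, zi in enumerate(z):
            if good_window[0] <= zi <= good_window[1]:
                x, I = make_powerlaw_hiis(1.4, 0.0, (5, 50), n_points=80)
            else:
                x, I = make_powerlaw_hiis(1.4, 0.0, (5, 50), noise_sd=0.8,
                                          seed=noise_seed + i, n_points=80)
            fits.append(fit_biphasic(x, I, s=6.0, xi=20.0))
        return fits

    def test_planted_window_localized_exactly(self):
        z = np.arange(-20.0, -14.0, 0.5)
        fits = self._fits(z, (-18.0, -16.5))
        regions = detect_scale_invariance(z, fits, pc_threshold=0.97)
        assert regions == [(-18.0, -16.5)]

    def test_all_noise_gives_empty_list(self):
        z = np.arange(-20.0, -14.0, 0.5)
        fits = self._fits(z, (1.0, 0.0))   # empty planted window
        assert detect_scale_invariance(z, fits, pc_threshold=0.97) == []

    def test_failed_fits_never_qualify(self):
        z = np.array([0.0, 1.0])
        x, I = make_powerlaw_hiis(1.4, 0.0, (5, 50))
        good = fit_biphasic(x, I, s=6.0, xi=20.0)
        assert detect_scale_invariance(z, [None, good], 0.97) == [(1.0, 1.0)]


class TestAggregate:
    def test_identical_traces_have_zero_width(self):
        l = np.linspace(1, 10, 20)
        trs = [_traces(l, np.arange(1, 21)) for _ in range(5)]
        agg = aggregate_traces(trs, "N")
        np.testing.assert_allclose(agg.mean, np.arange(1, 21) / 20.0)
        np.testing.assert_allclose(agg.hi95 - agg.lo95, 0.0, atol=1e-12)

    def test_mean_of_mirrored_traces_is_flat(self):
        l = np.array([1.0, 2.0, 3.0])
        trs = [_traces(l, [1, 2, 3]), _traces(l, [3, 2, 1])]
        agg = aggregate_traces(trs, "N")
        np.testing.assert_allclose(agg.mean, [2 / 3, 2 / 3, 2 / 3])

    def test_boundary_indices_match_brute_force_average(self):
        rng = np.random.default_rng(1)
        l = np.linspace(5, 30, 50)
        trs, xis = [], []
        for _ in range(50):
            trs.append(_traces(l, np.arange(1, 51)))
            xis.append(rng.uniform(8, 25))
        agg = aggregate_traces(trs, "N",
                               {i: {"xi": xi} for i, xi in enumerate(xis)})
        oracle = np.mean([1 + np.argmin(np.abs(l - xi)) for xi in xis])
        assert agg.alpha_xi == pytest.approx(oracle)

    def test_empty_set_rejected(self):
        with pytest.raises(ScalingError):
            aggregate_traces([], "N")


class TestCompositeModel:
    def _richards_fit(self, l):
        params = {"A": 1.05, "t": 0.2, "s": 18.02, "q_tilde": 0.54}
        n = eval_model("richards", params, l)
        return fit_model(l, n, "richards", normalize=False), n

    def test_exactly_composite_input_has_zero_error(self):
        l = np.linspace(6, 40, 300)
        fit, n = self._richards_fit(l)
        xi = fit.xi
        gamma = np.where(l <= xi, 2.27, -4.36)
        amp = np.where(l <= xi, 1.0, xi**(2.27 + 4.36))
        h_z = -amp * n * l**gamma
        I = np.abs(h_z) / n          # == l**gamma exactly, per construction
        sf = fit_biphasic(l, I, fit.s, xi)
        comp = composite_chdf_model(fit, sf, l, h_z)
        assert comp["mafe_pre"] == pytest.approx(0.0, abs=1e-6)
        assert comp["mafe_post"] == pytest.approx(0.0, abs=1e-6)
        assert comp["orientation"] == "out"
        assert np.all(comp["model_h_mag"][np.isfinite(comp["model_h_mag"])]
                      >= 0)

    def test_zero_exponent_degenerates_to_scaled_sigmoid(self):
        l = np.linspace(6, 40, 300)
        fit, n = self._richards_fit(l)
        h_z = -3.0 * n
        sf = fit_biphasic(l, np.full_like(l, 2.0), fit.s, fit.xi)
        # constant imbalance -> gamma == 0 in both phases
        assert sf.gamma_pre == pytest.approx(0.0, abs=1e-10)
        comp = composite_chdf_model(fit, sf, l, h_z)
        mask = np.isfinite(comp["model_h_mag"])
        np.testing.assert_allclose(comp["model_h_mag"][mask], 3.0 * n[mask],
                                   rtol=1e-9)


class TestCouplingEnergy:
    def test_peak_inside_window_returned(self):
        l = np.linspace(1, 30, 100)
        AE = np.exp(-((l - 15) ** 2) / 8)
        out = coupling_energy(l, AE, nu=10.0, xi=20.0)
        assert out["max_in_window"] == pytest.approx(AE.max(), rel=1e-6)
        assert out["first_scale"] == pytest.approx(AE[0])
        assert out["last_scale"] == pytest.approx(AE[-1])

    def test_window_excluding_peak_is_restricted(self):
        l = np.linspace(1, 30, 100)
        AE = np.exp(-((l - 15) ** 2) / 8)
        out = coupling_energy(l, AE, nu=20.0, xi=28.0)
        assert out["max_in_window"] < AE.max()

    def test_empty_window_rejected(self):
        with pytest.raises(ScalingError):
            coupling_energy(np.array([1.0, 2.0]), np.array([1.0, 1.0]),
                            nu=5.0, xi=6.0)


class TestCrossoverCorrelation:
    def test_identical_traces(self):
        z = np.linspace(-5, 5, 11)
        xi = np.linspace(18, 25, 11)
        out = crossover_correlation(z, xi, xi)
        assert out["mean_abs_distance"] == pytest.approx(0.0)
        assert out["spearman_pos_z"] == pytest.approx(1.0)
        assert out["spearman_neg_z"] == pytest.approx(1.0)

    def test_constant_shift(self):
        z = np.linspace(-5, 5, 11)
        xi = np.linspace(18, 25, 11)
        out = crossover_correlation(z, xi, xi + 2.0)
        assert out["mean_abs_distance"] == pytest.approx(2.0)
        assert out["sd_abs_distance"] == pytest.approx(0.0, abs=1e-12)
        assert out["spearman_pos_z"] == pytest.approx(1.0)

    def test_small_subset_reports_nan(self):
        z = np.array([1.0, 2.0, -1.0, -2.0, -3.0])
        xi = np.array([20.0, 21.0, 20.0, 21.0, 22.0])
        out = crossover_correlation(z, xi, xi + 1.0)
        assert np.isnan(out["spearman_pos_z"])   # only 2 points with z > 0


class TestDomainComposition:
    def test_uniform_label_fills_lag_domain(self):
        st = build_structure([[3, 0, 0], [4, 0, 0], [12, 0, 0]],
                             segment=["S5", "S5", "S1"])
        comp = domain_composition(st, (0, 0, 0), s=5.0, o=10.0)
        assert comp["lag"] == {"S5": 1.0}
        assert comp["asymptote"] == {"S1": 1.0}
        assert comp["inflection"] == {}

    def test_fractions_sum_to_one_and_match_hand_count(self):
        coords = [[2, 0, 0], [3, 0, 0], [7, 0, 0], [8, 0, 0], [9, 0, 0],
                  [15, 0, 0]]
        segs = ["S5", "S6", "S5", "S1", "S1", "S1"]
        st = build_structure(coords, segment=segs)
        comp = domain_composition(st, (0, 0, 0), s=5.0, o=10.0)
        assert sum(comp["lag"].values()) == pytest.approx(1.0)
        assert comp["lag"] == {"S5": 0.5, "S6": 0.5}
        assert comp["inflection"] == pytest.approx(
            {"S5": 1 / 3, "S1": 2 / 3})
        assert comp["asymptote"] == {"S1": 1.0}
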