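"""Photophysics equation suite: sigmoids, rates, two-step scheme, screen."""

import numpy as np
import pytest
from scipy import stats

from flimmux import simulate_anisotropy_trace, simulate_titration
from flimmux.kinetics import (
    KineticTrace,
    ScreenWell,
    bleach_normalize,
    delta_I,
    fit_extinction,
    fit_monoexp_kapp,
    fit_sigmoid_d50,
    fit_two_step,
    gaussian_fwhm,
    molecular_brightness,
    monte_carlo_ci,
    screen_select,
    two_step_monte_carlo,
    _gauss_profile,
    _sigmoid,
)


class TestSigmoidD50:
    def test_noiseless_recovery_is_exact(self):
        x = np.linspace(0, 100, 11)
        y = _sigmoid(x, 1.0, 0.3, 40.0)
        fit = fit_sigmoid_d50(x, y)
        assert fit.x_c == pytest.approx(40.0, abs=1e-6)
        assert fit.a == pytest.approx(1.0, abs=1e-6)

    def test_reflection_flips_inflection_and_steepness(self):
        x = np.linspace(-60, 60, 13)
        y = _sigmoid(x, 1.0, 0.3, 20.0)
        fit = fit_sigmoid_d50(-x, y)
        assert fit.x_c == pytest.approx(-20.0, abs=1e-6)
        assert fit.k == pytest.approx(-0.3, abs=1e-6)

    def test_noisy_eleven_point_titration_recovers_d50(self):
        """The 0-100% water-dioxane design (11 mixtures), noise SD 0.02:
        inflection recovered within 2 dielectric units across seeds."""
        x = np.linspace(0, 100, 11)
        for seed in range(20):
            df = simulate_titration(1.0, 0.3, 40.0, x, noise_sd=0.02,
                                    seed=seed)
            fit = fit_sigmoid_d50(df["dielectric"], df["value"])
            assert abs(fit.x_c - 40.0) < 2.0

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_sigmoid_d50([1, 2, 3], [0.1, 0.5, 0.9])


class TestMonoExpKapp:
    def test_assay_scale_arithmetic(self):
        """tau = 125 s at [P]0 = 80 nM gives k_app = 1e5 /M/s."""
        t = np.linspace(0, 600, 50)
        y = 0.1 + 0.2 * np.exp(-t / 125.0)
        fit = fit_monoexp_kapp(t, y, conc_protein=80e-9)
        assert fit.tau == pytest.approx(125.0, rel=1e-6)
        assert fit.k_app == pytest.approx(1.0e5, rel=1e-6)

    def test_doubling_protein_halves_kapp(self):
        t = np.linspace(0, 600, 50)
        y = 0.1 + 0.2 * np.exp(-t / 125.0)
        k1 = fit_monoexp_kapp(t, y, conc_protein=80e-9).k_app
        k2 = fit_monoexp_kapp(t, y, conc_protein=160e-9).k_app
        assert k1 == pytest.approx(2 * k2, rel=1e-9)


class TestTwoStep:
    TRUTH = dict(k1=1e6, k_minus1=10.0, k2=5.0)

    def _traces(self, noise_sd, seed, n_rep=1):
        times = np.unique(np.geomspace(0.002, 10.0, 300))
        traces = []
        for i, s0 in enumerate((0.125e-6, 0.25e-6, 0.5e-6)):
            reps = [simulate_anisotropy_trace(
                **self.TRUTH, conc_protein=s0, conc_substrate=s0,
                dead_time=0.002, noise_sd=noise_sd, r_free=0.05,
                r_bound=0.25, times=times, seed=1000 * seed + 10 * i + r).values
                for r in range(n_rep)]
            tr = simulate_anisotropy_trace(
                **self.TRUTH, conc_protein=s0, conc_substrate=s0,
                dead_time=0.002, noise_sd=0.0, r_free=0.05, r_bound=0.25,
                times=times)
            tr.values = np.mean(reps, axis=0)
            traces.append(tr)
        return traces

    def test_noiseless_global_fit_recovers_rates_and_derived_constants(self):
        fit = fit_two_step(self._traces(0.0, 0))
        assert fit.converged
        assert fit.k1 == pytest.approx(1e6, rel=0.01)
        assert fit.k_minus1 == pytest.approx(10.0, rel=0.01)
        assert fit.k2 == pytest.approx(5.0, rel=0.01)
        # dissociation constant and apparent rate identities
        assert fit.K_D == pytest.approx(1e-5, rel=0.02)
        assert fit.k_app == pytest.approx(1e6 * 5 / 15, rel=0.02)

    def test_derived_constants_recomputed_not_stored(self):
        fit = fit_two_step(self._traces(0.0, 0))
        fit.k_minus1 *= 2
        assert fit.K_D == pytest.approx(fit.k_minus1 / fit.k1, rel=1e-12)
        assert fit.k_app == pytest.approx(
            fit.k1 * fit.k2 / (fit.k2 + fit.k_minus1), rel=1e-12)

    def test_fast_commitment_limit_kapp_approaches_k1(self):
        """k2 >> k_minus1: every encounter commits and k_app -> k1."""
        fit = fit_two_step(self._traces(0.0, 0))
        fit.k2 = 1e6 * fit.k_minus1
        assert fit.k_app == pytest.approx(fit.k1, rel=1e-5)


class TestMonteCarlo:
    def _sigmoid_refit(self, x):
        def refit(y):
            f = fit_sigmoid_d50(x, y)
            resid = y - _sigmoid(x, f.a, f.k, f.x_c)
            return [f.a, f.k, f.x_c], float(np.sum(resid ** 2))
        return refit

    def test_zero_noise_intervals_collapse(self):
        x = np.linspace(0, 100, 11)
        y = _sigmoid(x, 1.0, 0.3, 40.0)
        fit = fit_sigmoid_d50(x, y)
        mc = monte_carlo_ci(self._sigmoid_refit(x), y, y - y,
                            ["a", "k", "x_c"], n_draws=50, seed=1)
        lo, hi = mc.intervals["x_c"]
        assert hi - lo < 1e-6

    def test_discard_never_widens_intervals_on_one_run(self):
        x = np.repeat(np.linspace(0, 100, 11), 3)
        rng = np.random.default_rng(5)
        y = _sigmoid(x, 1.0, 0.2, 40.0) + rng.normal(0, 0.02, x.size)
        fit = fit_sigmoid_d50(x, y)
        fitted = _sigmoid(x, fit.a, fit.k, fit.x_c)
        kw = dict(param_names=["a", "k", "x_c"], n_draws=400, seed=9)
        mc0 = monte_carlo_ci(self._sigmoid_refit(x), fitted, y - fitted,
                             discard_frac=0.0, **kw)
        mc5 = monte_carlo_ci(self._sigmoid_refit(x), fitted, y - fitted,
                             discard_frac=0.05, **kw)
        # discarding the worst fits must not widen the intervals beyond
        # percentile-estimation jitter
        for p in ("a", "k", "x_c"):
            w0 = mc0.intervals[p][1] - mc0.intervals[p][0]
            w5 = mc5.intervals[p][1] - mc5.intervals[p][0]
            assert w5 <= 1.02 * w0
        assert mc5.n_kept < mc0.n_kept

    def test_excessive_refit_failures_raise(self):
        def refit(y):
            raise RuntimeError("no fit")
        with pytest.raises(RuntimeError, match="20%"):
            monte_carlo_ci(refit, np.ones(5), np.ones(5) * 0.1, ["p"],
                           n_draws=20, seed=0)

    def test_two_step_single_concentration_flagged_unidentifiable(self):
        """One low concentration cannot pin down k1 vs k_minus1: the
        Monte-Carlo interval spans orders of magnitude and the fit is
        flagged."""
        times = np.unique(np.geomspace(0.005, 5.0, 80))
        tr = simulate_anisotropy_trace(
            k1=1e6, k_minus1=10.0, k2=5.0, conc_protein=0.125e-6,
            conc_substrate=0.125e-6, dead_time=0.005, noise_sd=0.003,
            r_free=0.05, r_bound=0.25, times=times, seed=3)
        fit = fit_two_step([tr])
        fit = two_step_monte_carlo(fit, n_draws=40, seed=3)
        assert fit.identifiable is False


class TestExtinction:
    def test_exact_line_slope_conversion(self):
        conc_uM = np.array([0.5, 1.0, 1.5, 2.0, 3.0])
        absorb = 0.1 * conc_uM  # 0.1 OD per uM -> 1e5 /M/cm
        fit = fit_extinction(conc_uM * 1e-6, absorb)
        assert fit.epsilon == pytest.approx(1e5, rel=1e-9)

    def test_zero_variance_concentrations_rejected(self):
        with pytest.raises(ValueError):
            fit_extinction([1e-6] * 5, [0.1] * 5)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_extinction([1e-6, 2e-6], [0.1, 0.2])

    def test_noisy_five_point_design_recovers_epsilon(self):
        conc = np.array([0.5, 1.0, 1.5, 2.0, 3.0]) * 1e-6
        errs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            absorb = 1e5 * conc + rng.normal(0, 0.005, conc.size)
            fit = fit_extinction(conc, absorb)
            errs.append(fit.epsilon / 1e5 - 1)
        assert np.sqrt(np.mean(np.square(errs))) < 0.05


class TestBrightnessAndFwhm:
    def test_molecular_brightness_arithmetic(self):
        assert molecular_brightness(0.01, 100_000.0) == pytest.approx(1000.0)
        assert molecular_brightness(0.01, 0.0) == 0.0
        r = molecular_brightness(0.02, 50_000.0) / molecular_brightness(
            0.01, 100_000.0)
        assert r == pytest.approx(1.0)

    def test_fwhm_closed_form_for_unit_width(self):
        x = np.linspace(-3, 3, 41)
        y = _gauss_profile(x, 0.0, 1.0, 1.0, 0.0)
        fit = gaussian_fwhm(x, y)
        assert fit.w == pytest.approx(1.0, abs=1e-9)
        assert fit.fwhm == pytest.approx(1.17741, abs=1e-5)

    def test_sted_profile_fwhm_within_ten_percent(self):
        """40-nm microtubule profile sampled at the 25-nm STED pixel size
        with 5% noise: FWHM recovered within 10% over seeds."""
        w = 40.0 / np.sqrt(2 * np.log(2))
        x = np.arange(-100, 101, 25.0)
        clean = _gauss_profile(x, 0.02, 10.0, w, 0.0)
        errs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            y = clean + rng.normal(0, 0.05 * clean.max(), x.size)
            fit = gaussian_fwhm(x, y)
            errs.append(fit.fwhm / 40.0 - 1)
        assert np.sqrt(np.mean(np.square(errs))) < 0.10


class TestDeltaI:
    def test_published_variant_arithmetic(self):
        """Means 1.199 vs 1.000 reproduce the brightest-variant 19.9%."""
        d, _ = delta_I([1.198, 1.199, 1.200], [0.999, 1.000, 1.001])
        assert d * 100 == pytest.approx(19.9, abs=0.01)

    def test_identical_samples_give_zero_and_half_p(self):
        d, p = delta_I([1.0, 1.1, 0.9], [1.0, 1.1, 0.9])
        assert d == pytest.approx(0.0)
        assert p == pytest.approx(0.5)

    def test_p_value_uses_pooled_df4_for_triplicates(self):
        v = np.array([1.30, 1.25, 1.35])
        p = np.array([1.00, 1.05, 0.95])
        _, pval = delta_I(v, p)
        df = 4
        sp2 = (v.var(ddof=1) * 2 + p.var(ddof=1) * 2) / df
        t = (v.mean() - p.mean()) / np.sqrt(sp2 * (2 / 3))
        assert pval == pytest.approx(float(stats.t.sf(abs(t), df)), rel=1e-9)

    def test_zero_parent_mean_rejected(self):
        with pytest.raises(ValueError):
            delta_I([1.0, 1.1], [0.0, 0.0])


class TestScreenSelect:
    def _wells(self):
        controls = [ScreenWell(f"c{i}", 100.0, v, True)
                    for i, v in enumerate((95.0, 100.0, 105.0, 100.0, 100.0))]
        return controls

    def test_first_round_three_sigma_rule(self):
        wells = self._wells()
        sd = np.std([95, 100, 105, 100, 100], ddof=1)
        hi = 100 + 3 * sd
        wells += [ScreenWell("bright", 100.0, hi + 1),
                  ScreenWell("meh", 100.0, hi - 1)]
        selected, report = screen_select(wells, round="1")
        assert [w.well for w in selected] == ["bright"]
        assert report.loc[report.well == "bright", "direction"].item() == "brighter"

    def test_low_gfp_discarded_regardless_of_sir(self):
        wells = self._wells() + [ScreenWell("dark_gfp", 8.0, 1e4)]
        selected, report = screen_select(wells, round="1")
        assert selected == []
        assert not report.loc[report.well == "dark_gfp", "gfp_ok"].item()

    def test_round_switch_tightens_threshold(self):
        wells = self._wells()
        sd = np.std([95, 100, 105, 100, 100], ddof=1)
        borderline = 100 + 2.5 * sd
        wells.append(ScreenWell("mid", 100.0, borderline))
        sel1, _ = screen_select(wells, round="1")
        sel2, _ = screen_select(wells, round="2_3")
        assert sel1 == []
        assert [w.well for w in sel2] == ["mid"]

    def test_no_controls_rejected(self):
        with pytest.raises(ValueError):
            screen_select([ScreenWell("a", 1.0, 1.0)], round="1")


class TestBleachNormalize:
    def test_constant_series_becomes_ones(self):
        out = bleach_normalize(np.array([[5.0, 5.0, 5.0]]))
        assert np.allclose(out, 1.0)

    def test_simple_halving(self):
        out = bleach_normalize(np.array([10.0, 5.0]))
        assert out.tolist() == [1.0, 0.5]

    def test_scale_invariance(self):
        series = np.array([[10.0, 8.0, 6.0], [20.0, 10.0, 5.0]])
        assert np.allclose(bleach_normalize(series),
                           bleach_normalize(3.7 * series))

    def test_zero_t0_rejected(self):
        with pytest.raises(ValueError, match="0"):
            bleach_normalize(np.array([[0.0, 1.0]]))
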