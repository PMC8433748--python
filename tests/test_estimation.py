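"""Model fitting: initial guesses, single/global fits, classical estimators."""

import numpy as np
import pytest

import cmcfit as cf
from cmcfit import (
    BoltzmannSigmoid,
    CmcCurveFit,
    DerivativeEstimator,
    EstimatorError,
    GlobalCmcFit,
    ParameterSpec,
    TwoLineIntersection,
)
from cmcfit.fitting import FitError, global_fit
from cmcfit.models import MODELS, initial_guess
from cmcfit.synthetic import (
    GridSpec,
    NoiseSpec,
    ScenarioSeries,
    simulate_curve,
    simulate_temperature_series,
)

from conftest import SDS, TX100_FLUOR

ZERO_NOISE_CASES = {
    "conductivity": (SDS | {"kappa_s": 0.5}, GridSpec(0.0, 16.2, 60)),
    "molar_conductivity": ({"cmc": 8.099, "r": 0.112, "a": 66.74, "b": 26.43}, GridSpec(0.2, 16.2, 60)),
    "carpena": ({"cmc": 8.099, "delta": 0.52, "a": 66.74, "b": 26.43, "kappa_s": 0.5}, GridSpec(0.0, 16.2, 60)),
    "surface_tension": ({"cmc": 1.0, "r": 0.1, "gamma0": 72.0, "st_coeff": 10.0, "k_ad": 50.0}, GridSpec(0.001, 5.0, 60, kind="log")),
    "nmr": ({"cmc": 8.0, "r": 0.1, "delta_free": 1.2, "delta_mic": 0.8}, GridSpec(0.5, 40.0, 60, kind="log")),
    "fluorescence": ({"cmc": 0.27, "r": 0.15, "k_per_s": 50.0, "f_free": 1.0, "f_bound": 10.0}, GridSpec(0.01, 2.7, 40, kind="log")),
    "pyrene_ratio": ({"cmc": 0.27, "r": 0.16, "c": 50.0, "sr_free": 0.45, "sr_bound": 0.98}, GridSpec(0.01, 2.7, 40, kind="log")),
    "absorbance": ({"cmc": 0.27, "r": 0.108, "eps1": 1.0, "epsm": 2.5}, GridSpec(0.0, 1.0, 50)),
    "absorbance_ratio": ({"cmc": 0.27, "r": 0.108, "q1": 1.0, "qm": 1.8, "qa": 1.3}, GridSpec(0.01, 1.0, 50, kind="log")),
    "fcs_diffusion": ({"cmc": 0.27, "r": 0.15, "k_per_s": 50.0, "d_free": 400.0, "d_bound": 60.0}, GridSpec(0.01, 2.7, 40, kind="log")),
    "aggregation": ({"cac": 90.0, "r": 0.36}, GridSpec(5.0, 900.0, 40, kind="log")),
}


class TestInitialGuess:
    def test_conductivity_cmc_guess_close(self):
        c = simulate_curve("conductivity", SDS | {"r": 0.05}, GridSpec(0.0, 16.2, 100))
        specs = {s.name: s for s in initial_guess(c)}
        assert abs(specs["cmc"].init - 8.099) / 8.099 < 0.05
        assert specs["r"].init == 0.1

    def test_featureless_line_still_yields_interior_guess(self):
        flat = dict(SDS, a=50.0, b=50.0)
        c = simulate_curve(
            "conductivity", flat, GridSpec(0.1, 16.2, 50), NoiseSpec(sd=0.02, mode="absolute", seed=5)
        )
        specs = {s.name: s for s in initial_guess(c)}
        assert c.x[0] <= specs["cmc"].init <= c.x[-1]
        result = cf.fit_curve(c)  # must terminate and report, not crash
        assert result.n_points == 50

    def test_sigmoid_plateau_guesses(self):
        c = simulate_curve("fluorescence", TX100_FLUOR, GridSpec(0.005, 5.4, 80, kind="log"))
        specs = {s.name: s for s in initial_guess(c)}
        assert abs(specs["f_free"].init - 1.0) < 0.05
        assert abs(specs["f_bound"].init - 10.0) < 0.5

    def test_too_short_curve_rejected(self):
        with pytest.raises(ValueError):
            cf.TitrationCurve(kind="nmr", x=[1, 2, 3], y=[1, 2, 3])


class TestFitCurve:
    @pytest.mark.parametrize("kind", sorted(ZERO_NOISE_CASES))
    def test_zero_noise_identifiability(self, kind):
        """Noiseless forward output returns the generating parameters to 6+ digits."""
        true, grid = ZERO_NOISE_CASES[kind]
        c = simulate_curve(kind, true, grid)
        est = CmcCurveFit(kind=kind).fit(c.x, c.y)
        assert est.converged_
        for name, v in true.items():
            assert abs(est.params_[name] - v) <= 1e-6 * max(abs(v), 1e-30), name

    def test_noisy_estimates_within_three_se(self):
        true = SDS | {"kappa_s": 0.5}
        c = simulate_curve(
            "conductivity", true, GridSpec(0.5, 16.2, 30), NoiseSpec(sd=0.005, mode="relative", seed=0)
        )
        est = CmcCurveFit(kind="conductivity").fit(c.x, c.y, c.y_err)
        assert est.converged_
        for name, v in true.items():
            assert abs(est.params_[name] - v) <= 3 * est.std_errors_[name], name

    def test_weighted_reduced_chi2_band(self):
        """With weights equal to the true noise sd, red chi^2 follows its
        chi-square reference distribution (95% empirical band within [0.5, 1.6])."""
        chi2s = []
        for seed in range(100):
            c = simulate_curve(
                "conductivity", SDS, GridSpec(0.5, 16.2, 30), NoiseSpec(sd=0.005, mode="relative", seed=seed)
            )
            est = CmcCurveFit(kind="conductivity").fit(c.x, c.y, c.y_err)
            chi2s.append(est.red_chi2_)
        lo, hi = np.percentile(chi2s, [2.5, 97.5])
        assert 0.5 <= lo and hi <= 1.6

    def test_fixed_parameter_has_no_std_error(self):
        c = simulate_curve("conductivity", SDS, GridSpec(0.0, 16.2, 40))
        est = CmcCurveFit(kind="conductivity", fixed={"r": 0.1}).fit(c.x, c.y)
        assert est.params_["r"] == 0.1
        assert "r" not in est.std_errors_

    def test_unknown_parameter_rejected(self):
        c = simulate_curve("conductivity", SDS, GridSpec(0.0, 16.2, 40))
        with pytest.raises(FitError):
            CmcCurveFit(kind="conductivity", fixed={"bogus": 1.0}).fit(c.x, c.y)

    def test_sklearn_contract(self):
        est = CmcCurveFit(kind="nmr")
        assert est.get_params()["kind"] == "nmr"
        est.set_params(kind="conductivity")
        c = simulate_curve("conductivity", SDS, GridSpec(0.0, 16.2, 40))
        est.fit(c.x, c.y)
        pred = est.predict(c.x)
        assert np.allclose(pred, c.y, rtol=1e-8)
        assert est.score(c.x.reshape(-1, 1), c.y) > 0.999

    def test_independent_optimizer_cross_check(self):
        """Same model fitted through lmfit reproduces estimates and errors."""
        lmfit = pytest.importorskip("lmfit")
        from scipy.special import erfc

        c = simulate_curve(
            "conductivity", SDS, GridSpec(0.5, 16.2, 50), NoiseSpec(sd=0.01, mode="relative", seed=3)
        )

        def kappa(x, cmc, r, a, b, kappa_s):
            sigma = r * cmc
            amp = 2.0 / (
                1.0
                + np.sqrt(2 / np.pi) * r * np.exp(-1.0 / (2 * r**2))
                + (1.0 - erfc(1.0 / (np.sqrt(2) * r)))
            )
            u = (x - cmc) / (np.sqrt(2) * sigma)
            s1 = cmc - 0.5 * amp * (np.sqrt(2 / np.pi) * sigma * np.exp(-(u**2)) - (x - cmc) * erfc(u))
            return a * s1 + b * (x - s1) + kappa_s

        model = lmfit.Model(kappa)
        pars = model.make_params(cmc=7.0, r=0.2, a=60.0, b=30.0, kappa_s=0.1)
        pars["cmc"].min = 0
        pars["r"].min = 0
        ref = model.fit(c.y, pars, x=c.x)  # unweighted, covar scaled: same convention
        mine = CmcCurveFit(kind="conductivity").fit(c.x, c.y)
        for name in ("cmc", "r", "a", "b", "kappa_s"):
            assert mine.params_[name] == pytest.approx(ref.params[name].value, rel=5e-4)
            assert mine.std_errors_[name] == pytest.approx(ref.params[name].stderr, rel=1e-2)


class TestGlobalFit:
    def _series(self, n_t=5, noise_seed=3):
        series = ScenarioSeries(
            temperatures=tuple(np.linspace(283, 313, n_t)),
            cmc_poly=(200.0, -1.4, 0.0028),
            r=0.5,
            a_poly=(120.0, -0.2),
            b_poly=(-40.0, 0.3),
            kappa_s=0.1,
        )
        return simulate_temperature_series(
            series, GridSpec(1.0, 80.0, 19), NoiseSpec(sd=0.005, mode="relative", seed=noise_seed)
        )

    def test_no_sharing_reproduces_individual_fits(self):
        curves = self._series()[:3]
        g = GlobalCmcFit(kind="conductivity", share=()).fit(curves)
        for curve, joint in zip(curves, g.results_):
            single = cf.fit_curve(curve)
            for name, v in single.estimates.items():
                assert joint.estimates[name] == pytest.approx(v, rel=1e-6, abs=1e-6)

    def test_shared_width_recovery_and_pooling(self):
        curves = self._series()
        g = GlobalCmcFit(kind="conductivity", share=("r",)).fit(curves)
        r_hat, r_se = g.shared_["r"]
        assert abs(r_hat - 0.5) <= 2 * r_se
        individual_ses = [cf.fit_curve(c).std_errors["r"] for c in curves]
        assert r_se <= min(individual_ses)  # information pooling
        assert r_se < np.median(individual_ses)

    def test_fixing_at_the_free_estimate_changes_nothing(self):
        curves = self._series()[:3]
        g = GlobalCmcFit(kind="conductivity", share=("r",)).fit(curves)
        cmc0 = g.results_[0].estimates["cmc"]
        fixed = [{"cmc": cmc0}, None, None]
        g2 = GlobalCmcFit(kind="conductivity", share=("r",), fixed=fixed).fit(curves)
        for r1, r2 in zip(g.results_[1:], g2.results_[1:]):
            for name in r1.estimates:
                assert r2.estimates[name] == pytest.approx(r1.estimates[name], rel=1e-6, abs=1e-6)

    def test_inconsistent_share_group_rejected(self):
        curves = self._series()[:2]
        lists = []
        for i, c in enumerate(curves):
            specs = initial_guess(c)
            # tie 'r' on one curve to 'a' on the other: invalid
            name = "r" if i == 0 else "a"
            lists.append(
                [
                    ParameterSpec(s.name, s.init, s.bounds, s.fixed, "g" if s.name == name else None, s.scale)
                    for s in specs
                ]
            )
        with pytest.raises(FitError):
            global_fit(curves, lists)


class TestTwoLineIntersection:
    def test_exact_on_piecewise_linear_data(self):
        c = simulate_curve("conductivity", SDS | {"r": 1e-9}, GridSpec(0.0, 16.2, 80))
        est = TwoLineIntersection(low_frac=0.3, high_frac=0.3).fit(c.x, c.y)
        assert est.cmc_ == pytest.approx(8.099, abs=1e-9)

    def test_offset_invariance(self):
        c = simulate_curve("conductivity", SDS, GridSpec(0.0, 16.2, 80))
        a = TwoLineIntersection().fit(c.x, c.y).cmc_
        b = TwoLineIntersection().fit(c.x, c.y + 123.4).cmc_
        assert a == pytest.approx(b, rel=1e-10)

    def test_graphical_estimate_depends_on_binding_constant(self):
        """The two-line cmc moves with K although the true cmc is constant."""
        estimates = []
        for k in (20.0, 200.0, 2000.0):
            p = dict(TX100_FLUOR, k_per_s=k)
            c = simulate_curve("fluorescence", p, GridSpec(0.001, 1.35, 60))
            estimates.append(TwoLineIntersection().fit(c.x, c.y).cmc_)
        assert (max(estimates) - min(estimates)) / min(estimates) > 0.10

    def test_parallel_lines_rejected(self):
        x = np.linspace(0, 10, 30)
        with pytest.raises(EstimatorError):
            TwoLineIntersection().fit(x, 2.0 * x + 1.0)


class TestDerivativeEstimator:
    def test_conductivity_break_located(self):
        c = simulate_curve("conductivity", SDS, GridSpec(0.0, 16.2, 120))
        est = DerivativeEstimator(order=2).fit(c.x, c.y)
        assert abs(est.cmc_ - 8.099) / 8.099 < 0.02

    def test_window_insensitivity_on_noiseless_data(self):
        c = simulate_curve("conductivity", SDS, GridSpec(0.0, 16.2, 120))
        vals = [
            DerivativeEstimator(order=2, window_frac=w).fit(c.x, c.y).cmc_
            for w in (0.15, 0.2, 0.25, 0.3)
        ]
        assert (max(vals) - min(vals)) / min(vals) < 0.01

    def test_nonlinear_property_gives_offset_extremum(self):
        """Derivative criteria miss the cmc when the dye binding equilibrium
        shapes the curve."""
        p = dict(TX100_FLUOR, k_per_s=20.0)
        c = simulate_curve("fluorescence", p, GridSpec(0.001, 1.35, 120))
        est = DerivativeEstimator(order=1).fit(c.x, c.y)
        assert abs(est.cmc_ - 0.27) / 0.27 > 0.05

    def test_flat_curve_rejected(self):
        c = simulate_curve("conductivity", dict(SDS, a=50.0, b=50.0), GridSpec(0.0, 16.2, 60))
        with pytest.raises(EstimatorError):
            DerivativeEstimator(order=2).fit(c.x, c.y)


class TestBoltzmannSigmoid:
    def test_exact_recovery_of_logistic_data(self):
        x = np.linspace(0, 10, 80)
        y = 3.0 + (8.0 - 3.0) / (1 + np.exp((x - 4.2) / 0.7))
        est = BoltzmannSigmoid().fit(x, y)
        assert est.x0_ == pytest.approx(4.2, abs=1e-8)
        assert est.dx_ == pytest.approx(0.7, abs=1e-8)
        assert est.plateaus_ == pytest.approx((8.0, 3.0), abs=1e-8)
        assert est.dx_ > 0

    def test_midpoint_is_not_the_cmc_for_pyrene_data(self):
        p = {"cmc": 0.27, "r": 0.16, "c": 50.0, "sr_free": 0.45, "sr_bound": 0.98}
        c = simulate_curve("pyrene_ratio", p, GridSpec(0.005, 2.7, 80, kind="log"))
        est = BoltzmannSigmoid().fit(c.x, c.y)
        assert abs(est.x0_ - 0.27) > 0.005

    def test_width_positive_by_construction(self):
        x = np.linspace(0, 10, 50)
        y = 1.0 - 1.0 / (1 + np.exp(-(x - 5.0) / 0.9))  # rising sigmoid
        est = BoltzmannSigmoid().fit(x, y)
        assert est.dx_ > 0


class TestCarpenaComparison:
    def test_the_two_models_agree_on_noisy_data(self, sds_noisy):
        cmp_ = cf.compare_carpena(sds_noisy)
        assert abs(cmp_.cmc_model - cmp_.cmc_carpena) / cmp_.cmc_model < 0.001
        assert 1.5 <= cmp_.sigma_delta_ratio <= 1.8
        rel = abs(cmp_.red_chi2_model - cmp_.red_chi2_carpena) / cmp_.red_chi2_model
        assert rel < 0.05

    def test_requires_conductivity_kind(self):
        c = simulate_curve("nmr", {"cmc": 8.0, "r": 0.1, "delta_free": 1.2, "delta_mic": 0.8}, GridSpec(0.5, 40, 30, kind="log"))
        with pytest.raises(ValueError):
            cf.compare_carpena(c)


class TestBestFitWidthRatio:
    def test_scale_invariance(self):
        g1 = np.linspace(0, 16.2, 200)
        r1 = cf.best_fit_width_ratio(8.099, 0.112, g1)
        r2 = cf.best_fit_width_ratio(80.99, 0.112, 10 * g1)
        assert r1 == pytest.approx(r2, rel=1e-6)

    @pytest.mark.parametrize("r", [0.05, 0.1, 0.2, 0.3])
    def test_ratio_band_across_widths(self, r):
        grid = np.linspace(0, 2 * 8.099, 200)
        ratio = cf.best_fit_width_ratio(8.099, r, grid)
        assert 1.5 <= ratio <= 1.8

    def test_grid_must_cover_transition(self):
        with pytest.raises(ValueError):
            cf.best_fit_width_ratio(8.099, 0.1, np.linspace(0, 8.0, 50))


class TestSparseProtocol:
    def test_degenerate_subsample_matches_full_fit(self, sds_noisy):
        full = cf.fit_curve(sds_noisy)
        sparse = cf.sparse_fit_protocol(sds_noisy, k=len(sds_noisy))
        for name, v in full.estimates.items():
            assert sparse.estimates[name] == pytest.approx(v, rel=1e-9)

    def test_fixed_width_values_agree(self):
        c = simulate_curve(
            "conductivity", SDS, GridSpec(0.05, 16.2, 332), NoiseSpec(sd=0.005, mode="relative", seed=7)
        )
        r01 = cf.sparse_fit_protocol(c, k=10, r_fixed=0.1)
        r001 = cf.sparse_fit_protocol(c, k=10, r_fixed=0.001)
        se = max(r01.std_errors["cmc"], r001.std_errors["cmc"])
        assert abs(r01.estimates["cmc"] - r001.estimates["cmc"]) <= se
        assert r01.subsample_indices is not None and len(r01.subsample_indices) == 10

    def test_too_few_points_rejected(self, sds_noisy):
        with pytest.raises(ValueError):
            cf.sparse_fit_protocol(sds_noisy, k=5, r_fixed=0.1)
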