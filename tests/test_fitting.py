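"""Region deconvolution: recovery, identities, and uncertainty oracles."""

import numpy as np
import pytest

from napxps import synth
from napxps.fitting import (
    FitWarning,
    RegionFitModel,
    estimate_uncertainties,
)
from napxps.lineshapes import voigt_profile
from napxps.peakmodel import PeakComponent, RegionModel
from napxps.spectra import Spectrum


class TestNoiselessRecovery:
    @pytest.mark.parametrize("region", ["C1s", "N1s", "O1s", "P2p"])
    def test_recovers_generating_areas_and_centers(
        self, region, region_models, noiseless_series
    ):
        series, truth = noiseless_series
        s = series.get(region, 0.0)
        fr = RegionFitModel(s, region_models[region], weighting="none").fit()
        assert fr.converged
        scale = truth.scales[region]
        for c in fr.model.components:
            a_true = truth.noiseless_areas[region][c.label][0] * scale
            a_fit, _ = fr.component_areas[c.label]
            if a_true > 0:
                assert a_fit == pytest.approx(a_true, rel=1e-3)
                assert abs(c.center - truth.centers[c.label]) < 0.01

    def test_identity_model_plus_background_plus_residuals(
        self, region_models, noiseless_series
    ):
        series, _ = noiseless_series
        s = series.get("C1s", 0.0)
        fr = RegionFitModel(s, region_models["C1s"]).fit()
        # exact in the stored arithmetic: residuals are counts minus
        # background minus model, bit for bit
        np.testing.assert_array_equal(
            fr.residuals, s.counts - fr.background_curve - fr.model_curve
        )
        recon = fr.model_curve + fr.background_curve + fr.residuals
        np.testing.assert_allclose(recon, s.counts, rtol=1e-14, atol=1e-9)


class TestFitContracts:
    def _flat_spectrum(self):
        x = np.arange(280.0, 294.05, 0.1)
        rng = np.random.default_rng(5)
        return Spectrum("C1s", x, rng.poisson(50, x.size).astype(float))

    def test_fixed_zero_area_leaves_residuals_as_net_signal(self):
        s = self._flat_spectrum()
        m = RegionModel("C1s", [PeakComponent("only", 286.0, area=0.0)])
        fm = RegionFitModel(s, m, vary_areas=False, vary_centers=False,
                            vary_widths=False, vary_lorentzian_widths=False,
                            reiterate_background=False)
        fr = fm.fit()
        np.testing.assert_allclose(
            fr.residuals, s.counts - fr.background_curve, atol=1e-12
        )

    def test_component_outside_window_rejected(self, region_models):
        x = np.arange(280.0, 294.05, 0.1)
        s = Spectrum("O1s", x, np.ones_like(x))
        with pytest.raises(ValueError, match="outside the spectrum window"):
            RegionFitModel(s, region_models["O1s"])

    def test_too_many_free_parameters_rejected(self, region_models):
        x = np.arange(284.0, 288.2, 0.1)[:30]
        s = Spectrum("C1s", x, np.ones_like(x))
        with pytest.raises(ValueError, match="free parameters"):
            RegionFitModel(s, region_models["C1s"])

    def test_warm_start_reproduces_cold_start_solution(
        self, region_models, noiseless_series
    ):
        series, _ = noiseless_series
        s0 = series.get("C1s", 0.0)
        s1 = series.get("C1s", series.timepoints("C1s")[1])
        cold = RegionFitModel(s1, region_models["C1s"], weighting="none").fit()
        warm = RegionFitModel(s1, region_models["C1s"], weighting="none").fit(
            start_from=RegionFitModel(s0, region_models["C1s"],
                                      weighting="none").fit()
        )
        for lab in cold.component_areas:
            assert warm.component_areas[lab][0] == pytest.approx(
                cold.component_areas[lab][0], rel=1e-4
            )

    def test_parameter_at_bound_is_warned_and_noted(self):
        x = np.arange(280.0, 292.05, 0.05)
        # generate a peak wider than the allowed Gaussian bounds
        y = voigt_profile(x, 286.0, 5000.0, 3.5, 0.0) + 50.0
        s = Spectrum("C1s", x, y)
        comp = PeakComponent("wide", 286.0)
        m = RegionModel("C1s", [comp])
        with pytest.warns(FitWarning, match="bound"):
            fr = RegionFitModel(s, m).fit()
        assert any("bound" in n for n in fr.notes)

    def test_doublet_link_enforced(self, region_models, noiseless_series):
        series, _ = noiseless_series
        s = series.get("P2p", 0.0)
        fr = RegionFitModel(s, region_models["P2p"]).fit()
        a32 = fr.model["P2p_32"]
        a12 = fr.model["P2p_12"]
        assert a12.area == pytest.approx(0.5 * a32.area, rel=1e-12)
        assert a12.center - a32.center == pytest.approx(1.0, abs=1e-12)

    def test_summary_mentions_components_and_chi2(
        self, region_models, noiseless_series
    ):
        series, _ = noiseless_series
        fr = RegionFitModel(series.get("C1s", 0.0), region_models["C1s"]).fit()
        text = fr.summary()
        for lab in ("C1s_285", "C1s_286", "C1s_288", "C1s_289"):
            assert lab in text
        assert "chi2" in text

    def test_plot_runs_headless(self, region_models, noiseless_series):
        series, _ = noiseless_series
        fr = RegionFitModel(series.get("P2p", 0.0), region_models["P2p"]).fit()
        ax = fr.plot()
        assert ax.get_xlabel() == "binding energy / eV"


class TestUncertainties:
    def _linear_fixture(self):
        """Two well-separated components with fixed shapes: linear model."""
        x = np.arange(280.0, 294.05, 0.05)
        rng = np.random.default_rng(42)
        truth = (voigt_profile(x, 284.5, 8000.0, 1.3, 0.2)
                 + voigt_profile(x, 289.5, 4000.0, 1.3, 0.2) + 200.0)
        y = rng.poisson(truth).astype(float)
        s = Spectrum("C1s", x, y)
        m = RegionModel("C1s", [
            PeakComponent("a", 284.5, area=5000.0),
            PeakComponent("b", 289.5, area=5000.0),
        ])
        return s, m

    def test_linear_amplitude_sigmas_match_closed_form(self):
        s, m = self._linear_fixture()
        fm = RegionFitModel(s, m, vary_centers=False, vary_widths=False,
                            vary_lorentzian_widths=False, weighting="poisson",
                            reiterate_background=False)
        fr = fm.fit()
        # closed-form weighted linear least squares on the two profiles
        x, y = s.binding_energy, s.counts
        w = 1.0 / np.sqrt(np.clip(y, 1.0, None))
        bg = fr.background_curve
        X = np.column_stack([
            voigt_profile(x, 284.5, 1.0, 1.3, 0.2),
            voigt_profile(x, 289.5, 1.0, 1.3, 0.2),
        ])
        Xw = X * w[:, None]
        rw = (y - bg) * w
        beta, *_ = np.linalg.lstsq(Xw, rw, rcond=None)
        resid = rw - Xw @ beta
        dof = y.size - 2
        s2 = resid @ resid / dof
        cov = s2 * np.linalg.inv(Xw.T @ Xw)
        expected = np.sqrt(np.diag(cov))
        sig = estimate_uncertainties(fr)
        assert sig["a"] == pytest.approx(expected[0], rel=1e-6)
        assert sig["b"] == pytest.approx(expected[1], rel=1e-6)
        assert beta[0] == pytest.approx(fr.component_areas["a"][0], rel=1e-8)

    def test_doubling_noise_doubles_area_sigmas(self):
        # average reported sigma over replicates at two noise scales
        x = np.arange(280.0, 294.05, 0.1)
        shape = voigt_profile(x, 287.0, 1.0, 1.3, 0.2)
        m = RegionModel("C1s", [PeakComponent("p", 287.0, area=1000.0)])
        rng = np.random.default_rng(7)

        def mean_sigma(noise_sd, nrep=40):
            out = []
            for _ in range(nrep):
                y = 1000.0 * shape + 100.0 + rng.normal(0, noise_sd, x.size)
                y = np.clip(y, 0, None)
                s = Spectrum("C1s", x, y)
                fr = RegionFitModel(s, m, weighting="none",
                                    vary_centers=False, vary_widths=False,
                                    vary_lorentzian_widths=False,
                                    reiterate_background=False).fit()
                out.append(fr.component_areas["p"][1])
            return np.mean(out)

        ratio = mean_sigma(8.0) / mean_sigma(4.0)
        assert ratio == pytest.approx(2.0, rel=0.15)

    def test_zero_residual_fit_has_zero_sigmas(self):
        x = np.arange(280.0, 294.05, 0.05)
        # pure Gaussian: no Lorentzian tails at the window edges, so the
        # data-derived background is exact and the best fit has residual 0
        y = voigt_profile(x, 287.0, 1000.0, 1.3, 0.0) + 100.0
        s = Spectrum("C1s", x, y)
        m = RegionModel("C1s", [PeakComponent("p", 287.0, area=1000.0,
                                              lorentzian_width=0.0)])
        fr = RegionFitModel(s, m, weighting="none", vary_centers=False,
                            vary_widths=False, vary_lorentzian_widths=False,
                            reiterate_background=False).fit()
        assert fr.component_areas["p"][1] == pytest.approx(0.0, abs=1e-6)

    def test_covariance_symmetric_positive_semidefinite(
        self, region_models, c1s_only_scenario
    ):
        series, _ = synth.generate_series(c1s_only_scenario, seed=99)
        fr = RegionFitModel(series.get("C1s", 0.0), region_models["C1s"]).fit()
        cov = fr.covariance
        np.testing.assert_array_equal(cov, cov.T)
        eig = np.linalg.eigvalsh(cov)
        assert eig.min() >= -1e-10 * eig.max()
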