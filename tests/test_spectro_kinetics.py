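import itertools

from hypothesis import given, settings
from hypothesis import strategies as st

import numpy as np
import pytest

from asymfold.errors import (
    DegenerateCalibrationError,
    DomainError,
    LowAmplitudeError,
    NoTransitionError,
)
from asymfold.spectro_kinetics import (
    KineticTrace,
    Spectrum,
    deconvolute_spectrum,
    fit_folding_kinetics,
    fit_urea_titration,
    folded_fraction,
    gp_value,
    linear_calibration,
    melting_midpoint,
)
from asymfold.synthetic_data import gen_curves, reference_spectra


class TestDeconvolution:
    def test_exact_basis_member(self):
        refs = reference_spectra()
        raw = Spectrum(refs["liposome"].wavelengths, 2.0 * refs["liposome"].values)
        res = deconvolute_spectrum(raw, refs)
        assert res.component_concentrations["liposome"] == pytest.approx(2.0, abs=1e-8)
        assert res.component_concentrations["fluorophore"] == pytest.approx(0.0, abs=1e-8)
        assert res.residual_ss == pytest.approx(0.0, abs=1e-12)

    def test_noisy_mixture_within_one_percent(self):
        df, _ = gen_curves("spectrum", truth={"liposome": 1.5, "fluorophore": 0.3},
                           noise=1e-4, seed=0)
        refs = reference_spectra()
        raw = Spectrum(df["wavelength_nm"].to_numpy(), df["absorbance"].to_numpy())
        res = deconvolute_spectrum(raw, refs)
        assert res.component_concentrations["liposome"] == pytest.approx(1.5, rel=0.01)
        assert res.component_concentrations["fluorophore"] == pytest.approx(0.3, rel=0.01)

    def test_zero_spectrum(self):
        refs = reference_spectra()
        raw = Spectrum(refs["liposome"].wavelengths,
                       np.zeros_like(refs["liposome"].values))
        res = deconvolute_spectrum(raw, refs)
        assert all(v == 0 for v in res.component_concentrations.values())
        assert res.residual_ss == 0.0

    def test_beats_grid_search_oracle(self):
        # NNLS residual can never exceed the best residual on a coarse grid
        refs = reference_spectra()
        df, _ = gen_curves("spectrum", truth={"liposome": 0.8, "fluorophore": 0.6},
                           noise=5e-3, seed=3)
        raw = Spectrum(df["wavelength_nm"].to_numpy(), df["absorbance"].to_numpy())
        res = deconvolute_spectrum(raw, refs)
        A = np.column_stack([refs[n].values for n in refs])
        best_grid = min(
            float(((A @ [s1, s2] - raw.values) ** 2).sum())
            for s1, s2 in itertools.product(np.linspace(0, 2, 41), repeat=2)
        )
        assert res.residual_ss <= best_grid + 1e-12

    def test_dependent_references_flagged(self):
        wl = np.arange(300.0, 601.0)
        base = np.exp(-0.5 * ((wl - 450) / 30) ** 2)
        refs = {"a": Spectrum(wl, base), "b": Spectrum(wl, 2 * base)}
        res = deconvolute_spectrum(Spectrum(wl, base), refs)
        assert res.ill_conditioned


class TestLinearCalibration:
    def test_exact_line(self):
        x = np.arange(0, 201, 25, dtype=float)
        slope, intercept, _ = linear_calibration(x, 0.002 * x)
        assert slope == pytest.approx(0.002)
        assert intercept == pytest.approx(0.0, abs=1e-12)

    def test_inverse_prediction_with_noise(self):
        rng = np.random.default_rng(1)
        x = np.arange(0, 201, 25, dtype=float)
        y = 0.002 * x + 0.01 + rng.normal(0, 1e-4, x.size)
        _, _, inverse = linear_calibration(x, y)
        assert inverse(0.21) == pytest.approx(100.0, abs=2.0)

    def test_repeated_x_errors(self):
        with pytest.raises(DegenerateCalibrationError):
            linear_calibration([5.0, 5.0, 5.0], [1.0, 2.0, 3.0])


class TestGP:
    @pytest.mark.parametrize("i440,i490,expected", [
        (0.5, 0.5, 0.0),
        (1.0, 0.0, 1.0),
        (0.6, 0.4, pytest.approx(0.2)),
    ])
    def test_values(self, i440, i490, expected):
        assert gp_value(i440, i490) == expected

    @settings(derandomize=True, max_examples=200)
    @given(a=st.floats(1e-3, 1e4), b=st.floats(1e-3, 1e4))
    def test_bounds_and_antisymmetry(self, a, b):
        g = gp_value(a, b)
        assert -1.0 <= g <= 1.0
        assert gp_value(b, a) == pytest.approx(-g)

    def test_zero_total_is_domain_error(self):
        with pytest.raises(DomainError):
            gp_value(0.0, 0.0)


class TestMeltingMidpoint:
    def test_noiseless_logistic(self):
        df, _ = gen_curves("laurdan", truth={"Tm": 24.0}, noise=0.0)
        tm = melting_midpoint(df["temp_C"].to_numpy(), df["gp"].to_numpy())
        assert tm == pytest.approx(24.0, abs=0.05)

    @pytest.mark.parametrize("seed", range(10))
    def test_noisy_logistic_within_quarter_degree(self, seed):
        df, _ = gen_curves("laurdan", truth={"Tm": 24.0}, noise=0.002, seed=seed)
        tm = melting_midpoint(df["temp_C"].to_numpy(), df["gp"].to_numpy())
        assert tm == pytest.approx(24.0, abs=0.25)

    def test_linear_curve_has_no_transition(self):
        t = np.arange(14, 34, 0.25)
        with pytest.raises(NoTransitionError):
            melting_midpoint(t, np.linspace(0.4, -0.2, t.size))


class TestFoldedFraction:
    def test_gel_monomer(self):
        assert folded_fraction("gel_monomer", folded=30, unfolded=10) == pytest.approx(0.75)

    def test_trp_ratio_endpoints_and_midpoint(self):
        kw = {"folded_ref": 1.4, "unfolded_ref": 0.8}
        assert folded_fraction("trp_ratio", sample_ratio=1.4, **kw) == pytest.approx(1.0)
        assert folded_fraction("trp_ratio", sample_ratio=1.1, **kw) == pytest.approx(0.5)

    def test_identical_references_degenerate(self):
        with pytest.raises(DegenerateCalibrationError):
            folded_fraction("trp_ratio", sample_ratio=1.0, folded_ref=1.0,
                            unfolded_ref=1.0)


class TestFoldingKinetics:
    def test_noiseless_slow_phase_recovery(self):
        t = np.linspace(0, 15 * 3600, 400)
        y = 1.0 + 1.0 * (1 - np.exp(-5e-4 * t))
        fit = fit_folding_kinetics(KineticTrace(t, y))
        assert fit.n_phases == 1
        assert fit.k_obs[0] == pytest.approx(5e-4, abs=1e-6)
        assert fit.accepted

    def test_truncated_trace_rejected(self):
        # 0.5/k of signal -> completion 1 - e^-0.5 = 0.393 < 0.75
        t = np.linspace(0, 0.5 / 5e-4, 60)
        y = 1.0 + (1 - np.exp(-5e-4 * t))
        fit = fit_folding_kinetics(KineticTrace(t, y))
        assert not fit.accepted
        assert fit.completion_fraction == pytest.approx(1 - np.exp(-0.5), abs=0.02)

    def test_two_phase_detection(self):
        rng = np.random.default_rng(2)
        t = np.linspace(0, 8 / 5e-4, 800)
        y = (1.0 + 0.5 * (1 - np.exp(-1e-2 * t)) + 0.5 * (1 - np.exp(-5e-4 * t))
             + rng.normal(0, 0.005, t.size))
        fit = fit_folding_kinetics(KineticTrace(t, y))
        assert fit.n_phases == 2
        assert fit.k_obs[0] == pytest.approx(1e-2, rel=0.1)
        assert fit.k_obs[1] == pytest.approx(5e-4, rel=0.1)

    def test_time_rescaling_equivariance(self):
        df, _ = gen_curves("kinetics", truth={"k_obs": 2e-3}, noise=0.005, seed=4)
        t, y = df["time_s"].to_numpy(), df["signal"].to_numpy()
        k1 = fit_folding_kinetics(KineticTrace(t, y)).k_obs[0]
        k10 = fit_folding_kinetics(KineticTrace(t * 10, y)).k_obs[0]
        assert k10 == pytest.approx(k1 / 10, rel=1e-6)

    def test_parameter_recovery_suite(self):
        # median relative error < 5% over 200 traces, k log-uniform, 1% noise
        rng = np.random.default_rng(99)
        rel_errors = []
        for _ in range(200):
            k = 10 ** rng.uniform(-4, -1)
            seed = int(rng.integers(0, 2**31))
            df, _ = gen_curves("kinetics", truth={"k_obs": k}, noise=0.01, seed=seed)
            fit = fit_folding_kinetics(
                KineticTrace(df["time_s"].to_numpy(), df["signal"].to_numpy()),
                max_phases=1,
            )
            rel_errors.append(abs(fit.k_obs[0] - k) / k)
        assert np.median(rel_errors) < 0.05


class TestUreaTitration:
    def test_noiseless_midpoint(self):
        df, _ = gen_curves("titration", truth={"Pm": 4.5, "slope": 0.3}, noise=0.0)
        fit = fit_urea_titration(df["urea_M"].to_numpy(), df["fraction_folded"].to_numpy())
        assert fit.Pm == pytest.approx(4.5, abs=0.01)

    def test_flat_curve_low_amplitude(self):
        u = np.arange(0, 8.1, 0.5)
        with pytest.raises(LowAmplitudeError):
            fit_urea_titration(u, np.full(u.size, 0.9))

    @pytest.mark.parametrize("seed", range(5))
    def test_noisy_midpoint(self, seed):
        df, _ = gen_curves("titration", truth={"Pm": 2.3, "slope": 0.3},
                           noise=0.03, seed=seed)
        fit = fit_urea_titration(df["urea_M"].to_numpy(), df["fraction_folded"].to_numpy())
        assert fit.Pm == pytest.approx(2.3, abs=0.15)

    def test_recovery_unbiased(self):
        # mean fitted Pm over 200 titrations within +-0.05 M of truth
        rng = np.random.default_rng(5)
        pms = []
        for _ in range(200):
            seed = int(rng.integers(0, 2**31))
            df, _ = gen_curves("titration", truth={"Pm": 4.5, "slope": 0.3},
                               noise=0.03, seed=seed)
            pms.append(fit_urea_titration(df["urea_M"].to_numpy(),
                                          df["fraction_folded"].to_numpy()).Pm)
        assert np.mean(pms) == pytest.approx(4.5, abs=0.05)

    def test_pm_sd_reported(self):
        df, _ = gen_curves("titration", truth={"Pm": 4.5}, noise=0.03, seed=0)
        fit = fit_urea_titration(df["urea_M"].to_numpy(), df["fraction_folded"].to_numpy())
        assert np.isfinite(fit.Pm_sd) and fit.Pm_sd > 0
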