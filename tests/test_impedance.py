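"""Impedance spectrum estimation and constant-phase identification."""

import numpy as np
import pytest

from hystereon.errors import DegenerateInputError, FitFailureError, InvalidArgumentError
from hystereon.impedance import (
    BANDS,
    ConstantPhaseParams,
    ImpedanceSpectrum,
    alpha_from_eta,
    compute_eta,
    constant_phase_impedance,
    estimate_spectrum,
    fit_constant_phase,
)
from hystereon.synthdata import generate_fot_signals

TRUE = ConstantPhaseParams(R=2.3, L=0.012, D=14.0, alpha=0.62)


def _synth_spectrum(params, band="high", noise_sd_rel=0.0, seed=0):
    grid = np.asarray(BANDS[band]["grid"], float)
    z = params.impedance(grid)
    if noise_sd_rel > 0:
        rng = np.random.default_rng(seed)
        scale = noise_sd_rel * np.abs(z)
        z = z + scale * (rng.standard_normal(z.size)
                         + 1j * rng.standard_normal(z.size)) / np.sqrt(2)
    return ImpedanceSpectrum(grid, z, band=band)


class TestComputeEta:
    def test_alpha_half_gives_unity(self):
        assert compute_eta(ConstantPhaseParams(1.0, 0.0, 3.7, 0.5)) == pytest.approx(
            1.0, abs=1e-12
        )

    def test_alpha_06_closed_form(self):
        # cot(0.3*pi), evaluated independently beforehand
        assert compute_eta(ConstantPhaseParams(0.0, 0.0, 1.0, 0.6)) == pytest.approx(
            0.7265425280053609, abs=1e-12
        )

    def test_degenerate_tissue_term_rejected(self):
        # G = H = 0 requires D = 0, which the parameter invariants forbid
        with pytest.raises(InvalidArgumentError):
            ConstantPhaseParams(1.0, 0.0, 0.0, 0.5)

    def test_alpha_eta_inverse_pair(self):
        for eta in (0.2, 0.5, 1.0, 2.0, 5.0):
            a = alpha_from_eta(eta)
            assert compute_eta(ConstantPhaseParams(0, 0, 1.0, a)) == pytest.approx(
                eta, rel=1e-12
            )

    def test_eta_strictly_decreasing_in_alpha(self):
        alphas = np.linspace(0.01, 0.99, 100)
        etas = [compute_eta(ConstantPhaseParams(0, 0, 1.0, a)) for a in alphas]
        assert np.all(np.diff(etas) < 0)


class TestParameterization:
    def test_g_h_consistency(self):
        for a in np.linspace(0.05, 0.95, 19):
            p = ConstantPhaseParams(1.0, 0.01, 7.3, float(a))
            assert abs(p.G - p.D * np.cos(a * np.pi / 2)) < 1e-9 * p.D
            assert abs(p.H - p.D * np.sin(a * np.pi / 2)) < 1e-9 * p.D
            assert abs(p.G**2 + p.H**2 - p.D**2) < 1e-9 * p.D**2

    @pytest.mark.parametrize("kwargs", [
        {"R": -1.0}, {"L": -0.1}, {"D": 0.0}, {"alpha": 0.0}, {"alpha": 1.0},
    ])
    def test_invariant_violations_rejected(self, kwargs):
        base = dict(R=1.0, L=0.01, D=5.0, alpha=0.5)
        with pytest.raises(InvalidArgumentError):
            ConstantPhaseParams(**{**base, **kwargs})


class TestEstimateSpectrum:
    def test_pure_resistance(self):
        fs, r = 50.0, 3.0
        t = np.arange(int(120 * fs)) / fs
        grid = np.asarray(BANDS["low"]["grid"])
        pressure = sum(np.cos(2 * np.pi * f * t + 0.3 * k)
                       for k, f in enumerate(grid))
        spec = estimate_spectrum(pressure, pressure / r, grid, fs)
        assert np.allclose(spec.z_values, r + 0j, atol=1e-10)

    def test_roundtrip_from_generator(self):
        """Noiseless synthetic records reproduce the generating model."""
        for band in ("low", "high"):
            rec = generate_fot_signals(TRUE, band, noise_sd=0.0,
                                       breathing_rel_amp=0.0, seed=4)
            spec = estimate_spectrum(rec.pressure, rec.flow, rec.grid, rec.fs,
                                     band=band)
            z_true = TRUE.impedance(rec.grid)
            assert np.max(np.abs(spec.z_values - z_true) / np.abs(z_true)) < 1e-6

    def test_empty_series_rejected(self):
        with pytest.raises(InvalidArgumentError):
            estimate_spectrum([], [], BANDS["low"]["grid"], 50.0)

    def test_vanishing_flow_coefficient_flagged(self):
        fs = 50.0
        t = np.arange(int(120 * fs)) / fs
        grid = np.asarray(BANDS["low"]["grid"])
        pressure = sum(np.cos(2 * np.pi * f * t) for f in grid)
        flow = np.cos(2 * np.pi * grid[0] * t)  # no energy at other lines
        with pytest.raises(DegenerateInputError):
            estimate_spectrum(pressure, flow, grid, fs)

    def test_unresolvable_grid_rejected(self):
        grid = BANDS["low"]["grid"]
        with pytest.raises(InvalidArgumentError):
            estimate_spectrum(np.ones(50), np.ones(50), grid, 50.0)

    def test_nyquist_precondition(self):
        with pytest.raises(InvalidArgumentError):
            estimate_spectrum(np.ones(1000), np.ones(1000),
                              BANDS["high"]["grid"], 60.0)


class TestFitConstantPhase:
    @pytest.mark.parametrize("band", ["low", "high"])
    def test_noiseless_roundtrip_recovery(self, band):
        fit = fit_constant_phase(_synth_spectrum(TRUE, band))
        assert fit.R == pytest.approx(TRUE.R, rel=1e-6)
        assert fit.L == pytest.approx(TRUE.L, rel=1e-6)
        assert fit.D == pytest.approx(TRUE.D, rel=1e-6)
        assert fit.alpha == pytest.approx(TRUE.alpha, rel=1e-6)
        assert fit.eta == pytest.approx(TRUE.eta, abs=1e-6)
        assert fit.fit_residual < 1e-10

    def test_alpha_half_recovers_unit_eta(self):
        p = ConstantPhaseParams(1.8, 0.008, 11.0, 0.5)
        fit = fit_constant_phase(_synth_spectrum(p, "low"))
        assert fit.eta == pytest.approx(1.0, abs=1e-6)

    def test_band_independence_of_eta(self):
        etas = [fit_constant_phase(_synth_spectrum(TRUE, band)).eta
                for band in ("low", "high")]
        assert abs(etas[0] - etas[1]) < 1e-6

    def test_noisy_eta_median_error_below_5pct(self):
        """1% complex noise per bin: median relative eta error < 5%."""
        errors = []
        for rep in range(100):
            spec = _synth_spectrum(TRUE, "high", noise_sd_rel=0.01, seed=rep)
            fit = fit_constant_phase(spec, n_d_starts=4, alpha_starts=(0.4, 0.7))
            errors.append(abs(fit.eta - TRUE.eta) / TRUE.eta)
        assert np.median(errors) < 0.05

    def test_nls_matches_grid_search_oracle(self):
        """Exhaustive (D, alpha) search at 1e4 nodes confirms the optimum."""
        rng = np.random.default_rng(42)
        grid_hz = np.asarray(BANDS["high"]["grid"])
        w = 2 * np.pi * grid_hz
        for _ in range(10):
            true = ConstantPhaseParams(
                R=rng.uniform(1.5, 3.5), L=rng.uniform(0.005, 0.02),
                D=rng.uniform(8.0, 20.0), alpha=rng.uniform(0.4, 0.8),
            )
            spec = _synth_spectrum(true, "high", noise_sd_rel=0.01,
                                   seed=int(rng.integers(1 << 30)))
            fit = fit_constant_phase(spec)
            # profile the objective over (D, alpha) at the fitted (R, L)
            d_grid = np.geomspace(fit.D / 3, fit.D * 3, 100)
            a_grid = np.linspace(0.05, 0.95, 100)
            dd, aa = np.meshgrid(d_grid, a_grid, indexing="ij")
            z_mod = (fit.R + 1j * w * fit.L
                     + dd[..., None] * np.exp(-1j * aa[..., None] * np.pi / 2)
                     * w ** (-aa[..., None]))
            sse = np.sum(np.abs(z_mod - spec.z_values) ** 2, axis=-1)
            i, j = np.unravel_index(np.argmin(sse), sse.shape)
            # within one grid cell of the exhaustive optimum
            assert abs(np.log(fit.D) - np.log(d_grid[i])) <= np.log(d_grid[1] / d_grid[0]) * 1.5
            assert abs(fit.alpha - a_grid[j]) <= (a_grid[1] - a_grid[0]) * 1.5

    def test_too_few_frequencies_rejected(self):
        with pytest.raises(InvalidArgumentError):
            ImpedanceSpectrum(np.array([1.0, 2.0, 3.0]),
                              np.array([1 + 0j, 1 + 0j, 1 + 0j]))

    def test_all_starts_failing_reports_diagnostics(self):
        spec = _synth_spectrum(TRUE, "high")
        with pytest.raises(FitFailureError) as exc_info:
            fit_constant_phase(spec, max_nfev=1, n_d_starts=2,
                               alpha_starts=(0.5,))
        assert exc_info.value.diagnostics


class TestSpectrumContainer:
    def test_csv_roundtrip(self, tmp_path):
        spec = _synth_spectrum(TRUE, "high")
        path = tmp_path / "spec.csv"
        spec.to_csv(path)
        loaded = ImpedanceSpectrum.from_csv(path)
        assert loaded.band == "high"
        assert np.allclose(loaded.z_values, spec.z_values)

    def test_band_range_enforced(self):
        freqs = np.array([0.2, 0.5, 1.0, 3.0])
        with pytest.raises(InvalidArgumentError):
            ImpedanceSpectrum(freqs, np.ones(4, complex), band="low")

    def test_nan_rejected(self):
        z = np.ones(4, complex)
        z[1] = np.nan
        with pytest.raises(InvalidArgumentError):
            ImpedanceSpectrum(np.array([5.0, 11.0, 17.0, 23.0]), z, band="high")
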