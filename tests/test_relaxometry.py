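"""Water relaxometry: complex PCA extraction, mono-exponential and NNLS fits."""

import numpy as np
import pytest

from myorelax import (
    DecayCurve,
    cpca_extract,
    default_t2_grid,
    fit_monoexp,
    fit_nnls,
    simulate_steam_decay,
    spectrum_summary,
    study,
)

TE29 = np.asarray(study.STEAM_TE_MS, dtype=float)


def _rank1_matrix(te, t2, profile, phase=0.0):
    decay = np.exp(-te / t2)
    return np.outer(profile, decay) * np.exp(1j * phase)


class TestCpcaExtract:
    def test_rank1_identity(self):
        profile = np.array([0.5 + 0.1j, 1.0 - 0.3j, 0.2 + 0.9j])
        m = _rank1_matrix(TE29, 31.0, profile)
        curve = cpca_extract(m, TE29)
        truth = np.exp(-TE29 / 31.0)
        scale = curve.signal[0] / truth[0]
        np.testing.assert_allclose(curve.signal, scale * truth, rtol=1e-9)
        assert curve.signal[0] > 0

    def test_global_phase_invariance(self):
        profile = np.array([1.0, 0.7, 0.4, 0.2])
        a = cpca_extract(_rank1_matrix(TE29, 25.0, profile), TE29)
        b = cpca_extract(
            _rank1_matrix(TE29, 25.0, profile, phase=1.234), TE29
        )
        np.testing.assert_allclose(a.signal, b.signal, rtol=1e-9)

    def test_first_component_dominates_at_high_snr(self):
        rng = np.random.default_rng(0)
        profile = rng.normal(size=8) + 1j * rng.normal(size=8)
        m = _rank1_matrix(TE29, 40.0, profile)
        noise = 1e-3 * (
            rng.normal(size=m.shape) + 1j * rng.normal(size=m.shape)
        )
        s = np.linalg.svd(m + noise, compute_uv=False)
        assert s[0] ** 2 / np.sum(s**2) > 0.99

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            cpca_extract(np.zeros((3, 29), dtype=complex), TE29)
        with pytest.raises(ValueError, match="2 samples"):
            cpca_extract(np.ones((1, 29), dtype=complex), TE29)

    def test_cpca_then_monoexp_equals_fit_on_true_decay(self):
        profile = np.array([2.0, 1.0 + 1.0j, 0.5 - 0.2j])
        m = _rank1_matrix(TE29, 28.0, profile)
        fit_extracted = fit_monoexp(cpca_extract(m, TE29))
        fit_truth = fit_monoexp(
            DecayCurve(te=TE29, signal=np.exp(-TE29 / 28.0))
        )
        assert fit_extracted.t2 == pytest.approx(fit_truth.t2, abs=1e-6)


class TestFitMonoexp:
    def test_noise_free_recovery_on_the_29_te_schedule(self):
        curve = simulate_steam_decay([(1.0, 31.0)], study.STEAM_ACQ)
        fit = fit_monoexp(DecayCurve(te=TE29, signal=curve.signal.real))
        assert fit.t2 == pytest.approx(31.0, abs=1e-6)
        assert fit.converged
        assert fit.rss == pytest.approx(0.0, abs=1e-12)

    def test_two_points_reproduce_the_closed_form(self):
        curve = DecayCurve(te=np.array([14.0, 40.0]), signal=np.array([200.0, 100.0]))
        fit = fit_monoexp(curve)
        assert fit.t2 == pytest.approx(26.0 / np.log(2.0), abs=1e-4)

    def test_constant_signal_flagged_not_raised(self):
        curve = DecayCurve(te=TE29, signal=np.ones(29))
        fit = fit_monoexp(curve)
        assert not fit.converged

    def test_scale_equivariance(self):
        base = DecayCurve(te=TE29, signal=3.0 * np.exp(-TE29 / 45.0))
        scaled = DecayCurve(te=TE29, signal=30.0 * np.exp(-TE29 / 45.0))
        fa, fb = fit_monoexp(base), fit_monoexp(scaled)
        assert fb.t2 == pytest.approx(fa.t2, rel=1e-6)
        assert fb.s0 == pytest.approx(10 * fa.s0, rel=1e-6)

    def test_noisy_parameter_recovery(self):
        """Median relative T2 error under 1% amplitude noise stays < 2%."""
        errors = []
        for seed in range(200):
            curve = simulate_steam_decay(
                [(1.0, 31.0)], study.STEAM_ACQ, noise_sd=0.01, seed=seed
            )
            fit = fit_monoexp(DecayCurve(te=TE29, signal=curve.magnitude))
            errors.append(abs(fit.t2 - 31.0) / 31.0)
        assert np.median(errors) < 0.02


class TestFitNnls:
    def test_on_grid_component_concentrates_all_mass(self):
        grid = default_t2_grid(10.0, 100.0, 13)
        t2 = grid[5]
        curve = DecayCurve(te=TE29, signal=np.exp(-TE29 / t2))
        spec = fit_nnls(curve, grid)
        assert spec.rss <= 1e-12
        assert spec.amplitude[5] == pytest.approx(1.0, rel=1e-6)
        others = np.delete(spec.amplitude, 5)
        np.testing.assert_allclose(others, 0.0, atol=1e-8)

    def test_zero_signal_gives_zero_spectrum(self):
        spec = fit_nnls(DecayCurve(te=TE29, signal=np.zeros(29)))
        np.testing.assert_array_equal(spec.amplitude, 0.0)

    def test_two_component_resolution(self):
        """0.7/0.3 mixture of 20 and 80 ms resolved on the default grid."""
        curve = simulate_steam_decay([(0.7, 20.0), (0.3, 80.0)], study.STEAM_ACQ)
        spec = fit_nnls(
            DecayCurve(te=TE29, signal=curve.signal.real), default_t2_grid()
        )
        summ = spectrum_summary(spec)
        assert summ.n_components == 2
        # amplitude-weighted mean T2 per contiguous run
        pos = spec.amplitude > 1e-12 * spec.amplitude.max()
        runs = np.split(np.flatnonzero(pos), np.where(np.diff(np.flatnonzero(pos)) > 1)[0] + 1)
        means = [
            float(np.sum(spec.amplitude[r] * spec.grid[r]) / np.sum(spec.amplitude[r]))
            for r in runs
        ]
        assert means[0] == pytest.approx(20.0, rel=0.05)
        assert means[1] == pytest.approx(80.0, rel=0.05)
        assert summ.fractions[0] == pytest.approx(0.7, abs=0.035)
        assert summ.fractions[1] == pytest.approx(0.3, abs=0.035)

    def test_nnls_never_beaten_by_monoexp(self):
        """The spectrum nests the single exponential, so its rss is <=."""
        for seed in range(10):
            curve = simulate_steam_decay(
                [(0.6, 18.0), (0.4, 70.0)], study.STEAM_ACQ,
                noise_sd=0.01, seed=seed,
            )
            mag = DecayCurve(te=TE29, signal=curve.magnitude)
            mono = fit_monoexp(mag)
            spec = fit_nnls(mag)
            assert spec.rss <= mono.rss + 1e-12

    def test_regularization_trades_norm_for_residual(self):
        curve = DecayCurve(te=TE29, signal=np.exp(-TE29 / 30.0))
        plain = fit_nnls(curve, mu=0.0)
        smooth = fit_nnls(curve, mu=0.5)
        # ridge minimizer has smaller L2 norm and larger plain residual
        assert np.linalg.norm(smooth.amplitude) <= np.linalg.norm(
            plain.amplitude
        ) + 1e-9
        assert smooth.rss >= plain.rss


class TestSpectrumSummary:
    def test_single_node(self):
        from myorelax import T2Spectrum

        grid = default_t2_grid(5, 500, 10)
        amp = np.zeros(10)
        amp[3] = 2.0
        summ = spectrum_summary(T2Spectrum(grid=grid, amplitude=amp, rss=0.0))
        assert summ.geometric_mean_t2 == pytest.approx(grid[3])
        assert summ.n_components == 1
        assert summ.fractions == [1.0]

    def test_equal_mass_at_10_and_1000_gives_gm_100(self):
        from myorelax import T2Spectrum

        spec = T2Spectrum(
            grid=np.array([10.0, 1000.0]), amplitude=np.array([1.0, 1.0]), rss=0.0
        )
        assert spectrum_summary(spec).geometric_mean_t2 == pytest.approx(100.0)

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(1)
        from myorelax import T2Spectrum

        amp = rng.uniform(0, 1, 40)
        amp[10:15] = 0.0
        spec = T2Spectrum(grid=default_t2_grid(), amplitude=amp, rss=0.0)
        assert sum(spectrum_summary(spec).fractions) == pytest.approx(1.0)

    def test_all_zero_spectrum_rejected(self):
        from myorelax import T2Spectrum

        spec = T2Spectrum(grid=default_t2_grid(), amplitude=np.zeros(40), rss=0.0)
        with pytest.raises(ValueError, match="zero"):
            spectrum_summary(spec)
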