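import numpy as np
import pytest

from trabs import kinetics as kin
from trabs.core import SpectralSeries, WavelengthGrid, make_logtime_grid


def _series(data, lam=None, times=None):
    n_l, n_t = data.shape
    lam = lam if lam is not None else np.arange(400.0, 400.0 + n_l)
    times = times if times is not None else make_logtime_grid(1e-5, 1.0, n_t)
    return SpectralSeries(WavelengthGrid(lam), times, data, "difference_absorbance")


def _exp_matrix(times, tau, amps, offsets, spectra):
    """Forward model: spectra (n_l x m) times exponential kinetics (m x n_t)."""
    T = np.array([a * np.exp(-times / t) for t, a in zip(tau, amps)])
    return spectra @ T + offsets[:, None]


class TestWindow:
    def test_counting_rows(self):
        lam = np.arange(400.0, 676.0)
        s = _series(np.zeros((lam.size, 4)), lam=lam)
        out = kin.window(s, 410.0, 530.0)
        assert len(out.grid) == 121

    def test_full_range_is_identity(self):
        s = _series(np.arange(12.0).reshape(3, 4), lam=np.array([410.0, 420.0, 430.0]))
        out = kin.window(s, 400.0, 500.0)
        np.testing.assert_array_equal(out.data, s.data)

    def test_empty_overlap_rejected(self):
        s = _series(np.zeros((3, 4)), lam=np.array([410.0, 420.0, 430.0]))
        with pytest.raises(ValueError, match="overlap"):
            kin.window(s, 600.0, 700.0)


class TestSvd:
    def test_rank_one_outer_product(self):
        u = np.array([1.0, 2.0, 3.0])
        v = np.array([4.0, 5.0, 6.0, 7.0])
        svd = kin.svd_decompose(_series(np.outer(u, v)))
        s = svd.singular_values
        assert s[0] > 0 and np.all(s[1:] < 1e-12 * s[0])
        recon = svd.lsv @ np.diag(s) @ svd.rsv.T
        np.testing.assert_allclose(recon, np.outer(u, v), rtol=1e-12)

    def test_reconstruction_and_orthonormality_random(self):
        rng = np.random.default_rng(0)
        data = rng.normal(size=(40, 12))
        svd = kin.svd_decompose(_series(data))
        recon = svd.lsv @ np.diag(svd.singular_values) @ svd.rsv.T
        assert np.linalg.norm(recon - data) < 1e-10 * np.linalg.norm(data)
        np.testing.assert_allclose(svd.lsv.T @ svd.lsv, np.eye(12), atol=1e-10)
        np.testing.assert_allclose(svd.rsv.T @ svd.rsv, np.eye(12), atol=1e-10)
        assert np.all(np.diff(svd.singular_values) <= 0)

    def test_sign_convention(self):
        rng = np.random.default_rng(1)
        svd = kin.svd_decompose(_series(rng.normal(size=(20, 6))))
        for j in range(svd.lsv.shape[1]):
            i = np.argmax(np.abs(svd.lsv[:, j]))
            assert svd.lsv[i, j] > 0


class TestSelectSignificant:
    def test_pure_noise_has_no_significant_components(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            svd = kin.svd_decompose(_series(rng.normal(size=(60, 30))))
            j, _ = kin.select_significant(svd)
            hits += j
        assert hits == 0

    def test_scale_invariance(self, solution_sim_noise_free):
        res = solution_sim_noise_free
        s1 = kin.svd_decompose(_series(res.truth["difference"][:121],
                                       lam=res.raw.grid.values[:121],
                                       times=res.raw.times))
        s2 = kin.svd_decompose(_series(1e6 * res.truth["difference"][:121],
                                       lam=res.raw.grid.values[:121],
                                       times=res.raw.times))
        assert kin.select_significant(s1)[0] == kin.select_significant(s2)[0]


class TestGlobalFit:
    @pytest.mark.parametrize("n_exp", [1, 2, 3])
    def test_noise_free_parameter_recovery(self, n_exp):
        # oracle: the generation parameters
        rng = np.random.default_rng(n_exp)
        times = make_logtime_grid(1e-5, 5.0, 40)
        lam = np.arange(400.0, 430.0)
        tau_true = np.sort(10 ** rng.uniform(-4, 0, n_exp))
        # smooth band-like spectral profiles, as real species spectra are
        centers = rng.uniform(405.0, 425.0, size=n_exp)
        signs = rng.choice([-1.0, 1.0], size=n_exp)
        spectra = np.column_stack(
            [s * np.exp(-0.5 * ((lam - c) / 6.0) ** 2) for c, s in zip(centers, signs)]
        )
        offsets = 0.01 * np.exp(-0.5 * ((lam - 415.0) / 10.0) ** 2)
        data = _exp_matrix(times, tau_true, np.ones(n_exp), offsets, spectra)
        svd = kin.svd_decompose(_series(data, lam=lam, times=times))
        j, mask = kin.select_significant(svd)
        assert j >= 1
        fit = kin.global_fit(svd, n_exp=n_exp, mask=mask, seed=0)
        np.testing.assert_allclose(fit.tau, tau_true, rtol=1e-3)

    def test_single_exponential_exact_zero_residual(self):
        times = make_logtime_grid(1e-4, 1.0, 25)
        rsv = 0.7 * np.exp(-times / 0.02)
        data = np.outer(np.ones(5), rsv)
        svd = kin.svd_decompose(_series(data, lam=np.arange(400.0, 405.0), times=times))
        fit = kin.global_fit(svd, n_exp=1, mask=np.array([True] + [False] * 4), seed=0)
        assert fit.tau[0] == pytest.approx(0.02, rel=1e-6)
        assert fit.residual_norm < 1e-10

    def test_rate_time_product_is_exact(self, solution_noise_free_report):
        tau = np.array(solution_noise_free_report["fit"]["tau_s"])
        rates = np.array(solution_noise_free_report["fit"]["rates_per_s"])
        # reciprocal pairs agree to the last ulp
        assert np.all(np.abs(rates * tau - 1.0) < 1e-15)

    def test_residual_non_increasing_in_starts(self):
        rng = np.random.default_rng(9)
        times = make_logtime_grid(1e-5, 2.0, 15)
        data = _exp_matrix(
            times, np.array([3e-4, 0.3]), np.array([1.0, -0.5]),
            np.zeros(8), rng.normal(size=(8, 2)),
        ) + rng.normal(scale=0.05, size=(8, 15))
        svd = kin.svd_decompose(_series(data, lam=np.arange(400.0, 408.0), times=times))
        mask = np.zeros(svd.singular_values.size, dtype=bool)
        mask[:2] = True
        norms = [
            kin.global_fit(svd, n_exp=2, mask=mask, n_starts=n, seed=4).residual_norm
            for n in (1, 4, 16)
        ]
        assert norms[0] >= norms[1] - 1e-12 and norms[1] >= norms[2] - 1e-12

    def test_weighted_equals_unweighted_for_equal_singular_values(self):
        times = make_logtime_grid(1e-4, 1.0, 20)
        y1 = np.exp(-times / 1e-2)
        y2 = np.exp(-times / 0.3)
        q, _ = np.linalg.qr(np.column_stack([y1, y2]))
        svd = kin.SvdResult(
            singular_values=np.array([2.0, 2.0]),
            lsv=np.eye(2),
            rsv=q,
            wavelengths=np.array([440.0, 450.0]),
            times=times,
        )
        mask = np.array([True, True])
        fw = kin.global_fit(svd, n_exp=2, mask=mask, weighted=True, seed=0)
        fu = kin.global_fit(svd, n_exp=2, mask=mask, weighted=False, seed=0)
        np.testing.assert_allclose(fw.tau, fu.tau, rtol=1e-8)

    def test_overparameterization_rejected(self):
        times = make_logtime_grid(1e-4, 1.0, 6)
        data = np.outer(np.ones(4), np.exp(-times / 0.01))
        svd = kin.svd_decompose(_series(data, lam=np.arange(400.0, 404.0), times=times))
        with pytest.raises(ValueError, match="time points"):
            kin.global_fit(svd, n_exp=3, mask=np.array([True, False, False, False]), seed=0)


class TestSingleWavelength:
    def test_analytic_two_exponential_trace(self):
        times = make_logtime_grid(1e-5, 2.0, 30)
        trace = 0.3 * np.exp(-times / 2e-4) - 0.8 * np.exp(-times / 0.4) + 0.05
        data = np.vstack([trace, trace * 0.5])
        s = _series(data, lam=np.array([485.0, 490.0]), times=times)
        fit = kin.single_wavelength_fit(s, 485.0, n_exp=2, seed=0)
        np.testing.assert_allclose(fit.tau, [2e-4, 0.4], rtol=1e-6)
        assert fit.offsets[0] == pytest.approx(0.05, abs=1e-8)

    def test_off_grid_wavelength_warns_and_uses_nearest(self):
        times = make_logtime_grid(1e-5, 2.0, 12)
        data = np.vstack([np.exp(-times / 0.01), 2 * np.exp(-times / 0.01)])
        s = _series(data, lam=np.array([480.0, 490.0]), times=times)
        with pytest.warns(RuntimeWarning, match="nearest"):
            fit = kin.single_wavelength_fit(s, 483.0, n_exp=1, seed=0)
        assert fit.tau[0] == pytest.approx(0.01, rel=1e-6)


class TestTauRateConversion:
    @pytest.mark.parametrize(
        "tau_s,rate_2sf",
        [(0.29e-3, 3.4e3), (40e-3, 25.0), (1.0, 1.0)],
    )
    def test_reciprocal_with_report_rounding(self, tau_s, rate_2sf):
        assert kin.round_sig(kin.tau_rate_convert(tau_s), 2) == pytest.approx(rate_2sf)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            kin.tau_rate_convert(0.0)


class TestReconstruction:
    def test_noise_free_fit_residual_tiny(self, solution_sim_noise_free):
        res = solution_sim_noise_free
        lam = res.raw.grid.values
        sel = (lam >= 410) & (lam <= 530)
        s = _series(res.truth["difference"][sel], lam=lam[sel], times=res.raw.times)
        svd = kin.svd_decompose(s)
        j, mask = kin.select_significant(svd)
        fit = kin.global_fit(svd, mask=mask, seed=0)
        fitted, residual = kin.reconstruct_fit(svd, fit, mask)
        assert np.linalg.norm(residual) < 1e-8
        np.testing.assert_allclose(fitted, s.data, atol=1e-8)

    def test_residual_never_exceeds_input_norm(self):
        rng = np.random.default_rng(3)
        data = rng.normal(size=(30, 18))
        svd = kin.svd_decompose(_series(data))
        mask = np.zeros(18, dtype=bool)
        mask[:2] = True
        fit = kin.global_fit(svd, n_exp=2, mask=mask, seed=0)
        _, residual = kin.reconstruct_fit(svd, fit, mask)
        assert np.linalg.norm(residual) <= np.linalg.norm(data) * (1 + 1e-12)
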