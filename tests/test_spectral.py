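"""Frequency-domain estimation machinery: segmentation, DFT, cross-spectra,
complex Gaussian / Wishart densities, Gaussianity testing, band averaging."""

import numpy as np
import pytest
from scipy import stats

from cesi import (
    CrossSpectrum,
    FourierInstances,
    SpectralGrid,
    band_average,
    complex_gaussian_logdensity,
    complex_wishart_loglik,
    discrete_fourier_transform,
    fourier_instances,
    gaussianity_test,
    sample_cross_spectrum,
    segment_time_series,
)
from cesi.synthetic import (
    ar2_spectral_density,
    make_oscillator_series,
    sample_fourier_instances,
)


def make_grid(n=101, fs=100.0, m=5, fmin=0.0, fmax=None):
    return SpectralGrid.from_band(n, fs, m, fmin=fmin, fmax=fmax)


def direct_dft(segment, grid):
    """Brute-force O(T^2) evaluation of the centered DFT definition."""
    seg = np.atleast_2d(segment)
    T = (seg.shape[1] - 1) // 2
    t = np.arange(-T, T + 1)
    out = np.empty((seg.shape[0], grid.num_frequencies), dtype=complex)
    for fi, freq in enumerate(grid.frequencies):
        out[:, fi] = seg @ np.exp(-2j * np.pi * freq * t * grid.sampling_period)
    return out


class TestSegmentation:
    @pytest.mark.parametrize(
        "total,length,overlap,expected",
        [(100, 50, 0, 2), (100, 60, 30, 2), (100, 100, 0, 1), (101, 50, 25, 3)],
    )
    def test_segment_count_matches_floor_formula(self, total, length, overlap, expected):
        segs = segment_time_series(np.zeros((2, total)), length, overlap)
        assert len(segs) == expected
        assert all(s.shape == (2, length) for s in segs)

    def test_segment_starts_match_index_arithmetic(self, rng):
        data = rng.standard_normal((3, 500))
        segs = segment_time_series(data, 100, 50)
        for m, seg in enumerate(segs):
            np.testing.assert_array_equal(seg, data[:, 50 * m : 50 * m + 100])

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            segment_time_series(np.zeros((1, 10)), 20, 0)
        with pytest.raises(ValueError):
            segment_time_series(np.zeros((1, 10)), 5, 5)


class TestDFT:
    def test_constant_series_concentrates_at_zero_frequency(self):
        grid = make_grid(n=51, fs=50.0, m=1)
        coeffs = discrete_fourier_transform(np.full(51, 2.5), grid)
        assert coeffs[0] == pytest.approx(51 * 2.5)
        assert np.abs(coeffs[1:]).max() < 1e-10

    def test_linearity(self, rng):
        grid = make_grid(n=51, fs=50.0, m=1)
        x, y = rng.standard_normal((2, 51))
        lhs = discrete_fourier_transform(2.0 * x - 3.0 * y, grid)
        rhs = 2.0 * discrete_fourier_transform(x, grid) - 3.0 * discrete_fourier_transform(y, grid)
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)

    def test_matches_direct_summation_oracle(self, rng):
        grid = make_grid(n=101, fs=100.0, m=1, fmin=0.0)
        seg = rng.standard_normal((2, 101))
        np.testing.assert_allclose(
            discrete_fourier_transform(seg, grid), direct_dft(seg, grid), atol=1e-10
        )

    def test_length_mismatch_rejected(self):
        grid = make_grid(n=51, fs=50.0, m=1)
        with pytest.raises(ValueError):
            discrete_fourier_transform(np.zeros(50), grid)


class TestSampleCrossSpectrum:
    def test_zero_instances_give_zero_matrix(self):
        grid = make_grid(n=51, fs=50.0, m=4)
        inst = FourierInstances(np.zeros((4, 3, grid.num_frequencies)), grid)
        cs = sample_cross_spectrum(inst)
        assert np.abs(cs.matrices).max() == 0

    def test_single_instance_rank_one_outer_product(self):
        grid = SpectralGrid(51, 0.02, np.array([1.0]), 1)
        inst = FourierInstances(np.array([1.0, 1j]).reshape(1, 2, 1), grid)
        cs = sample_cross_spectrum(inst)
        np.testing.assert_allclose(
            cs.matrices[0], np.array([[1, -1j], [1j, 1]]), atol=1e-15
        )

    def test_converges_to_population_covariance(self):
        # Monte-Carlo bound calibrated from independent replicate draws
        sigma = np.diag([2.0, 1.0]).astype(complex)
        grid = SpectralGrid(51, 0.02, np.array([1.0]), 1000)
        target = CrossSpectrum(sigma[None], 1000, grid)
        errs = []
        for rep in range(5):
            inst = sample_fourier_instances(target, 1000, seed=100 + rep)
            cs = sample_cross_spectrum(inst)
            errs.append(np.linalg.norm(cs.matrices[0] - sigma))
        inst = sample_fourier_instances(target, 1000, seed=7)
        err = np.linalg.norm(sample_cross_spectrum(inst).matrices[0] - sigma)
        assert err < 4.0 * np.median(errs) + 1e-12

    def test_output_always_hermitian_psd(self, rng):
        grid = make_grid(n=51, fs=50.0, m=6)
        for _ in range(20):
            vals = rng.standard_normal((6, 4, grid.num_frequencies)) + 1j * rng.standard_normal(
                (6, 4, grid.num_frequencies)
            )
            cs = sample_cross_spectrum(FourierInstances(vals, grid))
            cs.validate()  # raises on violation


class TestComplexGaussian:
    def test_scalar_standard_density_at_zero(self):
        assert complex_gaussian_logdensity(np.array([0.0]), np.eye(1)) == pytest.approx(
            -np.log(np.pi)
        )

    def test_unitary_invariance(self, rng):
        r = 3
        a = rng.standard_normal((r, r)) + 1j * rng.standard_normal((r, r))
        sigma = a @ a.conj().T + r * np.eye(r)
        q, _ = np.linalg.qr(rng.standard_normal((r, r)) + 1j * rng.standard_normal((r, r)))
        x = rng.standard_normal(r) + 1j * rng.standard_normal(r)
        assert complex_gaussian_logdensity(q @ x, q @ sigma @ q.conj().T) == pytest.approx(
            complex_gaussian_logdensity(x, sigma), rel=1e-10
        )

    def test_scalar_density_integrates_to_one(self):
        # quadrature over the complex plane on a grid
        sigma = np.array([[0.7]])
        grid = np.linspace(-5, 5, 301)
        h = grid[1] - grid[0]
        re, im = np.meshgrid(grid, grid)
        dens = np.exp(
            [
                complex_gaussian_logdensity(np.array([a + 1j * b]), sigma)
                for a, b in zip(re.ravel(), im.ravel())
            ]
        ).sum() * h * h
        assert dens == pytest.approx(1.0, abs=1e-3)


class TestComplexWishart:
    @staticmethod
    def _cs(mat, m):
        grid = SpectralGrid(51, 0.02, np.array([1.0]), max(m, 1))
        return CrossSpectrum(np.asarray(mat, dtype=complex)[None], max(m, 1), grid)

    def test_scalar_loglik_maximized_at_sample_value(self):
        sbar = 2.3
        m = 10
        sigmas = np.linspace(0.5, 6.0, 200)
        vals = [
            complex_wishart_loglik(self._cs([[sbar]], m), self._cs([[s]], m), m)[0]
            for s in sigmas
        ]
        assert sigmas[int(np.argmax(vals))] == pytest.approx(sbar, abs=0.05)

    def test_unitary_invariance(self, rng):
        r, m = 3, 8
        a = rng.standard_normal((r, r)) + 1j * rng.standard_normal((r, r))
        sbar = a @ a.conj().T
        b = rng.standard_normal((r, r)) + 1j * rng.standard_normal((r, r))
        sigma = b @ b.conj().T + r * np.eye(r)
        q, _ = np.linalg.qr(rng.standard_normal((r, r)) + 1j * rng.standard_normal((r, r)))
        lhs = complex_wishart_loglik(
            self._cs(q @ sbar @ q.conj().T, m), self._cs(q @ sigma @ q.conj().T, m), m
        )
        rhs = complex_wishart_loglik(self._cs(sbar, m), self._cs(sigma, m), m)
        np.testing.assert_allclose(lhs, rhs, rtol=1e-9)

    def test_scalar_estimator_distribution_is_gamma(self):
        # M * sbar / sigma ~ Gamma(M, 1) for complex Gaussian data
        m, sigma, n_rep = 8, 1.7, 400
        rng = np.random.default_rng(5)
        stats_vals = []
        for _ in range(n_rep):
            z = np.sqrt(sigma / 2) * (rng.standard_normal(m) + 1j * rng.standard_normal(m))
            stats_vals.append(m * np.mean(np.abs(z) ** 2) / sigma)
        _, pval = stats.kstest(stats_vals, "gamma", args=(m, 0, 1))
        assert pval > 0.01

    def test_dof_below_dimension_rejected(self):
        with pytest.raises(ValueError):
            complex_wishart_loglik(self._cs(np.eye(2), 1), self._cs(np.eye(2), 1), 1)

    def test_agrees_with_gaussian_logdensity_for_single_draw(self):
        # M = 1, R = 1: difference is the constant -log(pi)
        diffs = []
        for sigma in (0.5, 1.0, 2.0, 5.0):
            x = np.array([1.2 + 0.3j])
            sbar = np.abs(x[0]) ** 2
            gauss = complex_gaussian_logdensity(x, np.array([[sigma]]))
            wish = complex_wishart_loglik(self._cs([[sbar]], 1), self._cs([[sigma]], 1), 1)[0]
            diffs.append(gauss - wish)
        np.testing.assert_allclose(diffs, -np.log(np.pi), atol=1e-12)


class TestGaussianityTest:
    @staticmethod
    def _gaussian_instances(m=200, r=2, nf=13, seed=0):
        rng = np.random.default_rng(seed)
        grid = SpectralGrid.from_band(101, 100.0, m, fmin=1.0, fmax=13.0)
        nf = grid.num_frequencies
        vals = (rng.standard_normal((m, r, nf)) + 1j * rng.standard_normal((m, r, nf))) / np.sqrt(2)
        return FourierInstances(vals, grid)

    def test_calibrated_at_nominal_level_for_gaussian_draws(self):
        res = gaussianity_test(self._gaussian_instances(), alpha=0.05)
        n = res.num_tests
        se = np.sqrt(0.05 * 0.95 / n)
        assert abs(res.uncorrected_rejection_fraction - 0.05) < 3 * se + 0.01
        assert res.rejection_fraction <= res.uncorrected_rejection_fraction + 1e-12

    def test_heavy_tailed_coefficients_rejected_more_often(self):
        gauss = gaussianity_test(self._gaussian_instances(seed=1), alpha=0.05)
        inst = self._gaussian_instances(seed=1)
        heavy = FourierInstances(np.sign(inst.values.real) * inst.values.real**4
                                 + 1j * np.sign(inst.values.imag) * inst.values.imag**4,
                                 inst.grid)
        res = gaussianity_test(heavy, alpha=0.05)
        assert res.rejection_fraction > gauss.rejection_fraction
        assert res.rejection_fraction > 0.5

    def test_constant_coefficients_flagged_degenerate(self):
        grid = SpectralGrid.from_band(101, 100.0, 30, fmin=1.0, fmax=3.0)
        inst = FourierInstances(
            np.ones((30, 2, grid.num_frequencies), dtype=complex), grid
        )
        res = gaussianity_test(inst)
        assert res.num_tests == 0
        assert res.num_degenerate == res.table.shape[0]


class TestBandAverage:
    def test_constant_matrices_unchanged_and_single_bin_identity(self, rng):
        grid = SpectralGrid.from_band(101, 100.0, 3, fmin=1.0, fmax=10.0)
        mat = np.eye(2, dtype=complex) * 3.0
        cs = CrossSpectrum(np.repeat(mat[None], grid.num_frequencies, 0), 3, grid)
        out = band_average(cs, {"low": (1.0, 5.0), "high": (5.0, 10.0)})
        for k in range(2):
            np.testing.assert_allclose(out.matrices[k], mat)
        single = band_average(cs, {"one": (grid.frequencies[2], grid.frequencies[2] + 0.5)})
        np.testing.assert_allclose(single.matrices[0], cs.matrices[2])

    def test_matches_enumeration_oracle(self, rng):
        grid = SpectralGrid.from_band(101, 100.0, 4, fmin=1.0, fmax=20.0)
        nf = grid.num_frequencies
        raw = rng.standard_normal((nf, 3, 3)) + 1j * rng.standard_normal((nf, 3, 3))
        mats = np.einsum("fij,fkj->fik", raw, raw.conj())
        cs = CrossSpectrum(mats, 4, grid)
        out = band_average(cs, {"b": (4.0, 12.0)})
        mask = (grid.frequencies >= 4.0) & (grid.frequencies < 12.0)
        np.testing.assert_allclose(out.matrices[0], mats[mask].mean(axis=0))

    def test_empty_band_rejected(self):
        grid = SpectralGrid.from_band(101, 100.0, 2, fmin=1.0, fmax=10.0)
        cs = CrossSpectrum(
            np.repeat(np.eye(2, dtype=complex)[None], grid.num_frequencies, 0), 2, grid
        )
        with pytest.raises(ValueError):
            band_average(cs, {"void": (60.0, 70.0)})


class TestBrillingerConsistency:
    def test_ar2_sample_spectrum_error_halves_when_segments_quadruple(self):
        a1, a2, fs, n = 1.4, -0.72, 100.0, 101
        grid_small = SpectralGrid.from_band(n, fs, 50, fmin=2.0, fmax=40.0)

        def mean_err(m, seed):
            series = make_oscillator_series(1, (a1, a2), m * n, seed=seed)
            segs = segment_time_series(series, n, 0)
            grid = SpectralGrid.from_band(n, fs, m, fmin=2.0, fmax=40.0)
            cs = sample_cross_spectrum(fourier_instances(segs, grid))
            est = cs.diagonal()[:, 0] / n
            truth = ar2_spectral_density(a1, a2, grid.frequencies, fs)
            return np.mean(np.abs(est - truth) / truth)

        errs_small = [mean_err(50, s) for s in range(4)]
        errs_large = [mean_err(200, 100 + s) for s in range(4)]
        assert np.mean(errs_large) < 0.75 * np.mean(errs_small)
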