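"""Estimation: peak filtering, library size, peak means, sparsity, dispersion."""

import numpy as np
import pytest
import scipy.optimize as opt
import scipy.stats as st

from picsim import (
    correct_dispersion,
    estimate_caqtl_effect_params,
    estimate_dispersion,
    estimate_library_size,
    estimate_peak_means,
    estimate_population,
    estimate_sparsity,
    filter_peaks,
)
from picsim.estimation import EPS_PHI, fit_peak_mean_family, normalized_peak_means

from conftest import make_counts


# ---------------------------------------------------------------------------
# filter_peaks


class TestFilterPeaks:
    def test_at_least_boundary_is_inclusive(self, rng):
        # 100 cells; one peak nonzero in exactly 1 cell survives the 1% filter
        mat = np.zeros((2, 100), dtype=int)
        mat[0, 0] = 1
        mat[1, :] = 1
        out = filter_peaks(make_counts(mat), min_cell_frac=0.01)
        assert out.n_peaks == 2

    def test_all_zero_peak_removed(self):
        mat = np.array([[0, 0, 0], [1, 2, 0]])
        out = filter_peaks(make_counts(mat), min_cell_frac=0.01)
        assert out.n_peaks == 1

    def test_threshold_counts_nonzero_cells_brute_force(self):
        # 3 informative peaks nonzero in {0, 1, 5} cells of 10
        mat = np.zeros((3, 10), dtype=int)
        mat[1, 0] = 3
        mat[2, :5] = 1
        counts = make_counts(mat)
        detected = (mat > 0).sum(axis=1)  # brute-force oracle
        expected = int((detected >= np.ceil(0.2 * 10)).sum())
        assert expected == 1
        out = filter_peaks(counts, min_cell_frac=0.2)
        assert out.n_peaks == expected

    def test_idempotent(self, small_sim):
        once = filter_peaks(small_sim.data, 0.05)
        twice = filter_peaks(once, 0.05)
        assert once.n_peaks == twice.n_peaks
        assert (once.counts != twice.counts).nnz == 0

    def test_errors(self):
        with pytest.raises(ValueError, match="empty"):
            filter_peaks(make_counts(np.empty((0, 0))))
        with pytest.raises(ValueError, match="min_cell_frac=0.9"):
            filter_peaks(make_counts(np.eye(3, dtype=int)), min_cell_frac=0.9)


# ---------------------------------------------------------------------------
# library size


class TestLibrarySize:
    def test_degenerate_identical_totals(self):
        t = int(round(np.exp(5)))
        mat = np.full((1, 10), t)
        p = estimate_library_size(make_counts(mat))
        assert p.sigma == 0
        assert p.mu == pytest.approx(np.log(t))

    def test_lognormal_recovery_matches_log_moment_oracle(self, rng):
        totals = np.maximum(1, np.round(np.exp(rng.normal(8.5, 0.35, 2000)))).astype(int)
        p = estimate_library_size(make_counts(totals[None, :]))
        logs = np.log(totals)  # oracle: sample moments of the drawn logs
        assert p.mu == pytest.approx(logs.mean(), abs=1e-12)
        assert p.sigma == pytest.approx(logs.std(), abs=1e-12)
        assert abs(p.mu - 8.5) < 0.03
        assert abs(p.sigma - 0.35) < 0.03

    def test_zero_total_cell_dropped(self):
        mat = np.array([[2, 0, 2], [3, 0, 3]])
        p = estimate_library_size(make_counts(mat))
        assert p.mu == pytest.approx(np.log(5))
        assert p.sigma == 0

    def test_too_few_cells_error(self):
        with pytest.raises(ValueError):
            estimate_library_size(make_counts(np.array([[3]])))


# ---------------------------------------------------------------------------
# peak means


def _weibull_mle_oracle(x):
    """Independent Weibull MLE: solve the profile score equation for the
    shape, then the closed-form scale."""
    logx = np.log(x)

    def score(k):
        xk = x**k
        return (xk * logx).sum() / xk.sum() - 1.0 / k - logx.mean()

    k = opt.brentq(score, 1e-3, 50)
    lam = (np.mean(x**k)) ** (1.0 / k)
    return k, lam


class TestPeakMeans:
    def test_weibull_fit_recovers_truth_and_matches_oracle(self, rng):
        x = 0.3 * rng.weibull(0.8, 10_000)
        p = fit_peak_mean_family(x, family="weibull")
        k_or, lam_or = _weibull_mle_oracle(x)
        assert p.shape == pytest.approx(k_or, rel=1e-3)
        assert p.scale == pytest.approx(lam_or, rel=1e-3)
        assert p.shape == pytest.approx(0.8, rel=0.05)
        assert p.scale == pytest.approx(0.3, rel=0.05)

    def test_gamma_fit(self, rng):
        x = rng.gamma(2.0, 0.5, 10_000)
        p = fit_peak_mean_family(x, family="gamma")
        assert p.shape == pytest.approx(2.0, rel=0.06)
        assert p.scale == pytest.approx(0.5, rel=0.06)

    def test_all_zero_peak_excluded(self):
        mat = np.array([[0, 0, 0], [2, 2, 2], [1, 3, 2], [4, 1, 1], [2, 5, 1]])
        means = normalized_peak_means(make_counts(mat))
        assert means[0] == 0
        p = estimate_peak_means(make_counts(mat), family="gamma")
        assert p.shape > 0

    def test_constant_matrix_degenerate(self):
        with pytest.raises(ValueError, match="degenerate|identical"):
            estimate_peak_means(make_counts(np.ones((5, 5), dtype=int)))

    def test_unknown_family(self, rng):
        with pytest.raises(ValueError, match="family"):
            fit_peak_mean_family(rng.gamma(2, 1, 100), family="zipf")

    def test_normalization_invariance_scaling_one_cell(self, small_sim):
        # scaling the deepest cell leaves the lower-median total, and hence
        # all normalized peak means, unchanged
        base = small_sim.data
        means0 = normalized_peak_means(base)
        dense = base.to_dense()
        j = int(np.argmax(dense.sum(axis=0)))
        dense[:, j] *= 7
        means1 = normalized_peak_means(make_counts(dense))
        np.testing.assert_allclose(means0, means1, rtol=1e-12)

    def test_lognormal_gamma_mixture_fit_runs(self, rng):
        ln = np.exp(rng.normal(-2.0, 0.4, 4000))
        gm = rng.gamma(3.0, 0.4, 6000)
        p = fit_peak_mean_family(np.concatenate([ln, gm]), family="lognormal-gamma-mixture")
        assert 0.2 < p.extra["weight"] < 0.6
        assert p.extra["lognorm_mu"] == pytest.approx(-2.0, abs=0.5)


# ---------------------------------------------------------------------------
# sparsity


class TestSparsity:
    def test_boundaries_and_hand_example(self):
        # 5 peaks x 3 cells; cell 1 holds (0,0,1,0,2) down its column
        mat = np.array([[0, 1, 0], [0, 1, 0], [1, 1, 1], [0, 1, 0], [2, 1, 2]])
        counts = make_counts(mat)
        pi = estimate_sparsity(counts).pi
        # cell 1: (0,0,1,0,2) -> 3/5 zeros
        assert pi[0] == pytest.approx(0.6)
        assert pi[1] == pytest.approx(0.0)  # fully dense cell

    def test_all_zero_cell_dropped_like_library_size(self):
        mat = np.array([[1, 0], [2, 0]])
        pi = estimate_sparsity(make_counts(mat)).pi
        assert pi.size == 1 and pi[0] == 0.0

    def test_equals_brute_force_zero_count(self, small_sim):
        dense = small_sim.data.to_dense()
        oracle = (dense == 0).sum(axis=0) / dense.shape[0]
        np.testing.assert_allclose(estimate_sparsity(small_sim.data).pi, oracle)


# ---------------------------------------------------------------------------
# dispersion


class TestDispersion:
    def test_linear_correction_printed_values(self):
        assert correct_dispersion(2.0) == EPS_PHI  # -0.3 + 0.15*2 = 0 -> clamp
        assert correct_dispersion(4.0) == pytest.approx(0.3)
        assert correct_dispersion(1.0, clamp=False) - correct_dispersion(
            0.0, clamp=False
        ) == pytest.approx(0.15)

    def test_raw_estimator_matches_mom_oracle(self, rng):
        # gamma-Poisson counts with dispersion (BCV^2) = 0.4
        phi2 = 0.4
        n_peaks, n_cells = 400, 500
        m = rng.gamma(3.0, 2.0, n_peaks) + 0.5
        lam = rng.gamma(1 / phi2, (m * phi2)[:, None], (n_peaks, n_cells))
        counts = rng.poisson(lam)
        ds = make_counts(counts)
        est = estimate_dispersion(ds)
        # oracle: pooled (var - mean) / mean^2 on the same matrix
        mean = counts.mean(axis=1)
        var = counts.var(axis=1, ddof=1)
        oracle = np.median((var - mean) / mean**2)
        assert est.phi_raw == pytest.approx(oracle, rel=0.2)
        assert est.phi_raw == pytest.approx(phi2, rel=0.25)
        assert est.df0 > 0

    def test_degenerate_counts_error(self):
        with pytest.raises(ValueError, match="dispersion signal"):
            estimate_dispersion(make_counts(np.ones((4, 6), dtype=int)))

    def test_groupwise_estimation_ignores_group_shift(self, rng):
        base = rng.poisson(5.0, (200, 100))
        shifted = rng.poisson(15.0, (200, 100))
        counts = np.hstack([base, shifted])
        groups = np.array([0] * 100 + [1] * 100)
        with_groups = estimate_dispersion(make_counts(counts), groups=groups)
        # Poisson data: within-group dispersion near zero -> clamped phi
        assert with_groups.phi <= 0.05


# ---------------------------------------------------------------------------
# population-level


class TestPopulation:
    def _matrix_with_cvs(self, rng, cvs, n_ind=500, mean=100.0):
        sds = cvs * mean
        return mean + rng.normal(size=(cvs.size, n_ind)) * sds[:, None]

    def test_bins_of_50(self, rng):
        mat = np.abs(self._matrix_with_cvs(rng, np.full(250, 0.2), n_ind=5))
        pop = estimate_population(mat, n_bins_size=50)
        assert len(pop.cv_bins) == 5
        assert all(b.n_peaks == 50 for b in pop.cv_bins)

    def test_identical_individuals_degenerate_sentinel(self, rng):
        col = rng.gamma(2, 5, 60) + 1
        mat = np.tile(col[:, None], (1, 4))
        pop = estimate_population(mat, n_bins_size=50)
        assert all(b.beta_v >= 1e5 for b in pop.cv_bins)

    def test_cv_gamma_recovery_against_mle_oracle(self, rng):
        cvs = rng.gamma(2.0, 1 / 10.0, 50)
        mat = np.abs(self._matrix_with_cvs(rng, cvs, n_ind=500))
        pop = estimate_population(mat, n_bins_size=50)
        assert len(pop.cv_bins) == 1
        a_or, _, sc_or = st.gamma.fit(cvs, floc=0)  # oracle: MLE on the draws
        assert pop.cv_bins[0].alpha_v == pytest.approx(a_or, rel=0.15)
        assert pop.cv_bins[0].beta_v == pytest.approx(1 / sc_or, rel=0.15)

    def test_trailing_small_bin_merges(self, rng):
        mat = np.abs(self._matrix_with_cvs(rng, np.full(102, 0.2), n_ind=5))
        pop = estimate_population(mat, n_bins_size=50)
        assert len(pop.cv_bins) == 2
        assert pop.cv_bins[-1].n_peaks == 52

    def test_per_individual_fits_present(self, rng):
        mat = np.abs(self._matrix_with_cvs(rng, np.full(60, 0.3), n_ind=4))
        pop = estimate_population(mat)
        assert len(pop.sample_fits) == 4

    def test_too_few_individuals(self, rng):
        with pytest.raises(ValueError, match="3 individuals"):
            estimate_population(np.ones((10, 2)))


class TestCaQTLEffectParams:
    def test_gamma_recovery(self, rng):
        draws = rng.gamma(1.5, 1 / 3.0, 5000)
        a, b = estimate_caqtl_effect_params(draws)
        assert a == pytest.approx(1.5, rel=0.05)
        assert b == pytest.approx(3.0, rel=0.05)

    def test_constant_vector_error(self):
        with pytest.raises(ValueError, match="zero-variance"):
            estimate_caqtl_effect_params(np.full(100, 0.5))

    def test_negative_values_abs_with_warning(self, rng, caplog):
        draws = rng.gamma(2.0, 0.5, 1000)
        signs = np.where(rng.random(1000) < 0.5, -1, 1)
        a1, b1 = estimate_caqtl_effect_params(draws * signs)
        a2, b2 = estimate_caqtl_effect_params(draws)
        assert (a1, b1) == (a2, b2)

    def test_small_sample_mom_fallback(self, rng):
        x = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        a, b = estimate_caqtl_effect_params(x)
        m, v = x.mean(), x.var(ddof=1)
        assert a == pytest.approx(m**2 / v)
        assert b == pytest.approx(m / v)
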