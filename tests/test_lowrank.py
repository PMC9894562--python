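"""Rank-one approximation: perturbation vectors, statistics, truncation."""

import numpy as np
import pytest

import eilowrank as ei
from eilowrank.populations import POPS


class TestMeanVectors:
    def test_outer_product_reconstructs_mean(self, pop_small):
        mv = ei.mean_vectors(pop_small, 2.0, 0.6)
        Jbar = ei.make_mean_matrix(pop_small, 2.0, 0.6)
        assert np.allclose(np.outer(mv.mbar, mv.nbar) / pop_small.N, Jbar)
        assert mv.nbar @ mv.mbar / pop_small.N == pytest.approx(1.4)

    def test_biorthogonal_eigenvectors(self, pop_small):
        mv = ei.mean_vectors(pop_small, 2.0, 0.6)
        assert mv.Lbar @ mv.Rbar == pytest.approx(1.0)
        Jbar = ei.make_mean_matrix(pop_small, 2.0, 0.6)
        assert np.allclose(Jbar @ mv.Rbar, mv.lambda0 * mv.Rbar)


class TestPerturbedVectors:
    def test_zero_fluctuation(self, pop_small):
        stats = ei.GaussianLocalStats.homogeneous(2.0, 0.6, g=0.0)
        real = ei.sample_gaussian(pop_small, stats, seed=0)
        mv = ei.mean_vectors(pop_small, 2.0, 0.6)
        pv = ei.perturbed_vectors(real, mv, 1.4)
        assert np.allclose(pv.m, mv.mbar)
        assert np.allclose(pv.n, mv.nbar)

    def test_ensemble_mean_is_mean_vectors(self, pop_small):
        stats = ei.GaussianLocalStats.homogeneous(2.0, 0.6, g=0.5)
        mv = ei.mean_vectors(pop_small, 2.0, 0.6)
        ms = np.mean(
            [
                ei.perturbed_vectors(
                    ei.sample_gaussian(pop_small, stats, s), mv, 1.4
                ).m
                for s in range(100)
            ],
            axis=0,
        )
        sem = (0.5 / 1.4) / np.sqrt(100)  # sigma_m / sqrt(seeds)
        assert np.all(np.abs(ms - 1.0) < 5 * sem)

    def test_zero_lambda0_rejected(self, pop_small):
        stats = ei.GaussianLocalStats.homogeneous(2.0, 0.6, g=0.5)
        real = ei.sample_gaussian(pop_small, stats, seed=0)
        mv = ei.mean_vectors(pop_small, 2.0, 0.6)
        with pytest.raises(ValueError):
            ei.perturbed_vectors(real, mv, 0.0)

    def test_gaussian_mixture_moments(self, pop_sparse):
        # pooled entries per population pass Gaussianity moment checks
        import scipy.stats

        stats = ei.SparseLocalStats(c=0.3, A_E=0.025, A_I=-0.075, rho=0.3)
        g = ei.sparse_to_gaussian_moments(stats, pop_sparse)
        mv = ei.mean_vectors(pop_sparse, g.J_E, g.J_I)
        lam0 = g.J_E - g.J_I
        dm = {p: [] for p in POPS}
        dn = {p: [] for p in POPS}
        for s in range(30):
            real = ei.sample_sparse(pop_sparse, stats, s)
            pv = ei.perturbed_vectors(real, mv, lam0)
            for p in POPS:
                sl = pop_sparse.block_slice(p)
                dm[p].append(pv.dm[sl])
                dn[p].append(pv.dn[sl])
        for p in POPS:
            for pool in (np.concatenate(dm[p]), np.concatenate(dn[p])):
                assert abs(scipy.stats.skew(pool)) < 0.2
                assert abs(scipy.stats.kurtosis(pool)) < 0.5


class TestPredictedVectorStats:
    def test_homogeneous_independent_collapse(self, pop_dense):
        stats = ei.GaussianLocalStats.homogeneous(2.0, 0.6, g=0.3)
        rs = ei.predicted_vector_stats(stats, pop_dense)
        for p in POPS:
            assert rs.sigma2_m[p] == pytest.approx(0.09 / 1.96)
            assert rs.sigma_nm[p] == 0.0

    def test_reference_covariance(self, pop_dense):
        # homogeneous g = 0.3, eta = 1, lambda0 = 0.8: sigma_nm uses the
        # dominant cubic root 0.8907 in the denominator
        stats = ei.GaussianLocalStats.homogeneous(2.0, 1.2, g=0.3, eta=1.0)
        rs = ei.predicted_vector_stats(stats, pop_dense)
        lam = 0.89074552
        for p in POPS:
            assert rs.sigma_nm[p] == pytest.approx(0.8 * 0.09 / lam**2, rel=1e-5)

    def test_sparse_variance_ratio(self, pop_sparse):
        stats = ei.SparseLocalStats(c=0.3, A_E=0.025, A_I=-0.075, rho=0.3)
        rs = ei.predicted_vector_stats(stats, pop_sparse)
        assert rs.sigma2_n["E"] / rs.sigma2_n["I"] == pytest.approx(
            0.025**2 / 0.075**2
        )
        assert rs.sigma2_m["E"] == rs.sigma2_m["I"]

    def test_implied_eigenvalue_consistency(self, pop_dense):
        stats = ei.GaussianLocalStats.homogeneous(2.0, 1.2, g=0.3, eta=1.0)
        rs = ei.predicted_vector_stats(stats, pop_dense)
        # lambda = sum_p alpha_p (mbar nbar + sigma_nm) = lambda0 + sigma_nm
        assert rs.implied_eigenvalue == pytest.approx(
            0.8 + rs.sigma_nm_overall, rel=1e-12
        )

    def test_independent_vectors_uncorrelated(self, pop_dense):
        stats = ei.GaussianLocalStats.homogeneous(2.0, 0.6, g=0.3)
        mv = ei.mean_vectors(pop_dense, 2.0, 0.6)
        real = ei.sample_gaussian(pop_dense, stats, seed=0)
        pv = ei.perturbed_vectors(real, mv, 1.4)
        for p in POPS:
            sl = pop_dense.block_slice(p)
            corr = np.corrcoef(pv.m[sl], pv.n[sl])[0, 1]
            assert abs(corr) < 3 / np.sqrt(pop_dense.sizes[p])


class TestNumericalDominantPair:
    def test_pure_mean(self, pop_small):
        Jbar = ei.make_mean_matrix(pop_small, 2.0, 0.6)
        lam, R, L = ei.numerical_dominant_pair(Jbar)
        assert np.real(lam) == pytest.approx(1.4)
        Rr = np.real(R)
        assert np.allclose(Rr / Rr[0], np.ones(pop_small.N))
        assert np.real(L @ R) == pytest.approx(1.0)

    def test_exact_rank_one_recovery(self, pop_small):
        rng = np.random.default_rng(5)
        m = 1 + 0.3 * rng.standard_normal(pop_small.N)
        n = 2 + 0.5 * rng.standard_normal(pop_small.N)
        J = np.outer(m, n) / pop_small.N
        lam, R, L = ei.numerical_dominant_pair(J)
        assert np.real(lam) == pytest.approx(n @ m / pop_small.N, rel=1e-10)

    def test_arpack_matches_dense(self, pop_dense, het_g):
        stats = ei.GaussianLocalStats(2.0, 0.6, g=het_g)
        real = ei.sample_gaussian(pop_dense, stats, seed=1)
        lam_a, _, _ = ei.numerical_dominant_pair(real.J, method="arpack")
        lam_d, _, _ = ei.numerical_dominant_pair(real.J, method="dense")
        assert np.real(lam_a) == pytest.approx(np.real(lam_d), rel=1e-8)

    def test_outlier_absent_signal(self, pop_small):
        stats = ei.GaussianLocalStats.homogeneous(1.0, 0.99, g=0.5)
        pred = ei.predict_outliers(stats, pop_small)
        real = ei.sample_gaussian(pop_small, stats, seed=2)
        with pytest.raises(ValueError, match="no visible outlier"):
            ei.numerical_dominant_pair(real.J, pred)


class TestNormalizeForComparison:
    def test_identity_on_mean_vectors(self, pop_small):
        mv = ei.mean_vectors(pop_small, 2.0, 0.6)
        R, L = ei.normalize_for_comparison(mv.Rbar, mv.Lbar, mv.Rbar, mv.Lbar)
        assert np.allclose(R, mv.Rbar)
        assert np.allclose(L, mv.Lbar)

    def test_idempotent(self, pop_dense, het_g):
        stats = ei.GaussianLocalStats(2.0, 0.6, g=het_g)
        real = ei.sample_gaussian(pop_dense, stats, seed=0)
        pred = ei.predict_outliers(stats, pop_dense)
        _, Rh, Lh = ei.numerical_dominant_pair(real.J, pred, method="arpack")
        mv = ei.mean_vectors(pop_dense, 2.0, 0.6)
        R1, L1 = ei.normalize_for_comparison(
            np.real(Rh), np.real(Lh), mv.Rbar, mv.Lbar
        )
        R2, L2 = ei.normalize_for_comparison(R1, L1, mv.Rbar, mv.Lbar)
        assert np.allclose(R1, R2, atol=1e-12)
        assert np.allclose(L1, L2, atol=1e-12)

    def test_entrywise_agreement_at_small_g(self, pop_dense):
        # weak fluctuations: numerical and perturbative entries agree
        # entry-by-entry (identity-line scatter)
        stats = ei.GaussianLocalStats.homogeneous(2.0, 0.6, g=0.1)
        pred = ei.predict_outliers(stats, pop_dense)
        real = ei.sample_gaussian(pop_dense, stats, seed=1)
        lam, Rh, Lh = ei.numerical_dominant_pair(real.J, pred, method="arpack")
        mv = ei.mean_vectors(pop_dense, 2.0, 0.6)
        R, L = ei.normalize_for_comparison(
            np.real(Rh), np.real(Lh), mv.Rbar, mv.Lbar
        )
        m_num = np.sqrt(pop_dense.N) * R
        n_num = np.sqrt(pop_dense.N) * np.real(lam) * L
        pv = ei.perturbed_vectors(real, mv, pred.lambda0)
        assert np.corrcoef(m_num, pv.m)[0, 1] > 0.99
        assert np.corrcoef(n_num, pv.n)[0, 1] > 0.99
        slope_m = np.polyfit(pv.m - 1, m_num - 1, 1)[0]
        assert slope_m == pytest.approx(1.0, abs=0.05)


class TestTruncatedRankApprox:
    def test_full_rank_reconstruction(self):
        rng = np.random.default_rng(0)
        J = rng.standard_normal((40, 40)) / 7 + 0.2
        J_R, _ = ei.truncated_rank_approx(J, 40)
        assert np.allclose(J_R, J, atol=1e-8)

    def test_rank_one_preserves_top_eigenvalue_svd_does_not(self, pop_small):
        stats = ei.GaussianLocalStats.homogeneous(2.0, 0.6, g=0.5)
        real = ei.sample_gaussian(pop_small, stats, seed=3)
        J = real.J
        top = np.linalg.eigvals(J)
        top = top[np.argmax(np.abs(top))]
        J_1, vecs = ei.truncated_rank_approx(J, 1)
        lam1, m1, n1 = vecs[0]
        assert lam1 == pytest.approx(top, rel=1e-10)
        assert np.allclose(J_1, np.outer(m1, n1) / pop_small.N, atol=1e-10)
        ev1 = np.linalg.eigvals(J_1)
        assert ev1[np.argmax(np.abs(ev1))] == pytest.approx(top, rel=1e-8)
        # SVD rank-one truncation misses the top eigenvalue
        U, s, Vt = np.linalg.svd(J)
        J_svd = s[0] * np.outer(U[:, 0], Vt[0])
        ev_svd = np.linalg.eigvals(J_svd)
        top_svd = ev_svd[np.argmax(np.abs(ev_svd))]
        assert abs(top_svd - top) > 1e-3

    def test_rank_one_on_mean_matrix(self, pop_small):
        Jbar = ei.make_mean_matrix(pop_small, 2.0, 0.6)
        J_1, _ = ei.truncated_rank_approx(Jbar, 1)
        assert np.allclose(J_1, Jbar, atol=1e-10)

    def test_complex_dominant_pair_rejected_at_rank_one(self):
        J = np.array([[0.0, -2.0], [2.0, 0.0]])  # eigenvalues +/- 2i
        with pytest.raises(ValueError, match="complex pair"):
            ei.truncated_rank_approx(J, 1)


class TestLowrankToLocalStats:
    def _stats(self, pop, **kw):
        base = dict(
            mbar={"E": 1.0, "I": 1.0},
            nbar={"E": 2.5, "I": -6.0},
            sigma2_m={"E": 0.0, "I": 0.0},
            sigma2_n={"E": 0.0, "I": 0.0},
            sigma_nm={"E": 0.0, "I": 0.0},
            alpha=pop.fractions,
        )
        base.update(kw)
        return ei.RankOneStats(**base)

    def test_zero_variance_recovers_mean_blocks(self, pop_dense):
        rs = self._stats(pop_dense)
        with pytest.raises(ValueError, match="zero block variance"):
            ei.lowrank_to_local_stats(rs, pop_dense)
        # means still recoverable with small variances
        rs = self._stats(
            pop_dense, sigma2_m={"E": 1e-4, "I": 1e-4}, sigma2_n={"E": 1e-4, "I": 1e-4}
        )
        Jbar, _, eta = ei.lowrank_to_local_stats(rs, pop_dense)
        assert Jbar[0, 0] == pytest.approx(2.5 / pop_dense.N)
        assert Jbar[0, 1] == pytest.approx(-6.0 / pop_dense.N)
        assert np.allclose(eta, 0.0)

    def test_roundtrip_from_predicted_stats(self, pop_dense, het_g):
        stats = ei.GaussianLocalStats(2.0, 0.6, g=het_g)
        rs = ei.predicted_vector_stats(stats, pop_dense)
        Jbar, _, eta = ei.lowrank_to_local_stats(rs, pop_dense)
        assert Jbar[0, 0] == pytest.approx(2.0 / pop_dense.N_E)
        assert Jbar[1, 1] == pytest.approx(-0.6 / pop_dense.N_I)
        assert np.allclose(eta, 0.0)

    def test_nonzero_covariance_matches_monte_carlo(self, pop_dense):
        # sample (m_i, n_i) from the mixture, build m n^T / N and measure the
        # reciprocal correlation directly on the matrix
        rng = np.random.default_rng(7)
        rs = self._stats(
            pop_dense,
            sigma2_m={"E": 0.2, "I": 0.2},
            sigma2_n={"E": 1.5, "I": 1.5},
            sigma_nm={"E": 0.3, "I": 0.3},
        )
        _, _, eta_pred = ei.lowrank_to_local_stats(rs, pop_dense)
        N = pop_dense.N
        m = np.empty(N)
        n = np.empty(N)
        for p in ("E", "I"):
            sl = pop_dense.block_slice(p)
            cov = [[rs.sigma2_m[p], rs.sigma_nm[p]], [rs.sigma_nm[p], rs.sigma2_n[p]]]
            draws = rng.multivariate_normal([rs.mbar[p], rs.nbar[p]], cov, sl.stop - sl.start)
            m[sl], n[sl] = draws[:, 0], draws[:, 1]
        J = np.outer(m, n) / N
        eta_emp = ei.local_reciprocal_correlation(J, pop_dense)
        assert np.all(np.abs(eta_emp - eta_pred) < 0.05)
        assert np.all(eta_pred != 0)


class TestVarianceFloor:
    def test_numerical_variance_bounded_below_by_theory(self, pop_dense):
        # perturbation theory is a lower bound, tight as g -> 0
        gaps = {}
        for g in (0.1, 0.5):
            stats = ei.GaussianLocalStats.homogeneous(2.0, 0.6, g=g)
            pred = ei.predict_outliers(stats, pop_dense)
            rs = ei.predicted_vector_stats(stats, pop_dense)
            mv = ei.mean_vectors(pop_dense, 2.0, 0.6)
            vals = []
            for seed in range(5):
                real = ei.sample_gaussian(pop_dense, stats, seed)
                lam, Rh, Lh = ei.numerical_dominant_pair(
                    real.J, pred, method="arpack"
                )
                R, L = ei.normalize_for_comparison(
                    np.real(Rh), np.real(Lh), mv.Rbar, mv.Lbar
                )
                emp = ei.empirical_vector_stats(
                    (np.sqrt(pop_dense.N) * R, np.sqrt(pop_dense.N) * np.real(lam) * L),
                    pop_dense,
                )
                vals.append(emp.sigma2_m["E"])
            ratio = np.mean(vals) / rs.sigma2_m["E"]
            assert ratio > 0.95  # floor (5 seeds of sampling slack)
            gaps[g] = ratio - 1.0
        assert gaps[0.1] < gaps[0.5]
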