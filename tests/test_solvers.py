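"""Proximal operators and the PCA / PCP / SPCP solvers."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from imsrpca import (
    Method,
    SolverSettings,
    gen_lowrank_sparse,
    load_decomposition,
    numerical_rank,
    pca_fit,
    pcp_fit,
    save_decomposition,
    soft_threshold,
    spcp_fit,
    svt,
)


def rel(a, b):
    return np.linalg.norm(a - b) / max(np.linalg.norm(b), 1e-300)


class TestSoftThreshold:
    @pytest.mark.parametrize(
        "x,tau,expected",
        [(1.5, 1.0, 0.5), (-2.0, 0.5, -1.5), (0.3, 0.5, 0.0)],
    )
    def test_scalar_cases(self, x, tau, expected):
        assert soft_threshold(x, tau) == pytest.approx(expected)

    @settings(deadline=None, derandomize=True)
    @given(
        x=arrays(np.float64, (3, 4), elements=st.floats(-100, 100)),
        tau=st.floats(0, 50),
    )
    def test_shrinks_toward_zero_within_tau(self, x, tau):
        y = soft_threshold(x, tau)
        assert np.all(np.abs(y) <= np.abs(x) + 1e-12)
        assert np.all(np.abs(x - y) <= tau + 1e-12)
        assert np.all(np.sign(y) * np.sign(x) >= 0)

    def test_negative_tau_rejected(self):
        with pytest.raises(ValueError):
            soft_threshold(1.0, -0.1)


class TestSVT:
    def test_diagonal_case(self):
        M = np.diag([3.0, 1.0])
        out, kept = svt(M, 2.0)
        np.testing.assert_allclose(out, np.diag([1.0, 0.0]), atol=1e-12)
        assert len(kept) == 1

    def test_tau_zero_is_identity(self, rng):
        M = rng.standard_normal((5, 4))
        out, _ = svt(M, 0.0)
        np.testing.assert_allclose(out, M, atol=1e-10)

    def test_threshold_at_singular_value_drops_it(self):
        M = np.diag([3.0, 2.0, 1.0])
        _, kept = svt(M, 2.0)  # value == tau must threshold to zero
        assert len(kept) == 1

    def test_matches_dense_svd_oracle(self, rng):
        M = rng.standard_normal((6, 4))
        S = np.linalg.svd(M, compute_uv=False)
        tau = S[2] + 1e-6
        out, kept = svt(M, tau)
        assert len(kept) == 2
        # oracle: distance to M from full SVD tail
        expected_dist = np.sqrt(
            np.sum(np.minimum(S, tau) ** 2)
        )
        assert np.linalg.norm(out - M) == pytest.approx(expected_dist, rel=1e-8)

    def test_rank_non_increasing_in_tau(self, rng):
        M = rng.standard_normal((8, 8))
        ranks = [len(svt(M, t)[1]) for t in np.linspace(0, 10, 15)]
        assert all(a >= b for a, b in zip(ranks, ranks[1:]))


class TestNumericalRank:
    @pytest.mark.parametrize(
        "S,thr,expected",
        [([10, 5, 1e-12], 1e-6, 2), ([0.0], 1e-6, 0), ([], 1e-6, 0)],
    )
    def test_cases(self, S, thr, expected):
        assert numerical_rank(np.array(S, dtype=float), thr) == expected

    def test_constructed_rank_four(self, rng):
        G = rng.standard_normal((9, 4))
        H = rng.standard_normal((7, 4))
        S = np.linalg.svd(G @ H.T, compute_uv=False)
        assert numerical_rank(S, 1e-9) == 4


class TestPCA:
    def test_exact_rank_matrix_recovered(self, rng):
        A = rng.standard_normal((20, 3)) @ rng.standard_normal((3, 15))
        d = pca_fit(A, 2 + 1)
        assert rel(d.B, A) < 1e-8
        assert np.linalg.norm(d.D) < 1e-8 * np.linalg.norm(A)

    def test_full_rank_reproduces_input(self, rng):
        A = rng.standard_normal((6, 9))
        d = pca_fit(A, 6)
        np.testing.assert_allclose(d.B, A, atol=1e-10)

    def test_eckart_young_oracle(self, rng):
        A = rng.standard_normal((50, 30))
        d = pca_fit(A, 5)
        S = np.linalg.svd(A, compute_uv=False)
        expected = np.sqrt(np.sum(S[5:] ** 2))
        assert np.linalg.norm(A - d.B) == pytest.approx(expected, rel=1e-8)

    def test_conservation_exact(self, rng):
        A = rng.standard_normal((12, 8))
        d = pca_fit(A, 3)
        np.testing.assert_allclose(d.B + d.D, A, atol=1e-12)
        assert d.C is None

    def test_factors_reconstruct_b(self, rng):
        A = rng.standard_normal((12, 8))
        d = pca_fit(A, 3)
        assert rel((d.U * d.S) @ d.V.T, d.B) < 1e-8

    def test_rank_out_of_range(self, rng):
        with pytest.raises(ValueError):
            pca_fit(rng.standard_normal((4, 4)), 5)


class TestPCP:
    def test_zero_input(self):
        d = pcp_fit(np.zeros((5, 5)), 0.2)
        assert np.all(d.B == 0) and np.all(d.C == 0)
        assert d.rank_r == 0 and d.diagnostics["converged"]

    def test_recovers_planted_low_rank_plus_sparse(self):
        t = gen_lowrank_sparse(120, 120, 4, 0.05, amp=5.0, seed=7)
        d = pcp_fit(t.A, 1 / np.sqrt(120))
        assert rel(d.B, t.L0) <= 1e-4
        assert np.abs(d.C[~t.support]).max() <= 1e-6

    def test_large_lam_gives_pure_low_rank(self, rng):
        A = rng.standard_normal((15, 4)) @ rng.standard_normal((4, 12))
        d = pcp_fit(A, 10.0)
        assert np.linalg.norm(d.C) <= 1e-6 * np.linalg.norm(A)
        oracle = pca_fit(A, min(A.shape))
        assert rel(d.B, oracle.B) < 1e-5

    def test_conservation_within_tol(self):
        t = gen_lowrank_sparse(40, 30, 2, 0.05, seed=1)
        s = SolverSettings(tol=1e-7)
        d = pcp_fit(t.A, 1 / np.sqrt(40), s)
        assert rel(d.B + d.C, t.A) <= s.tol * 10
        assert d.D is None

    def test_homogeneity_under_scaling(self):
        t = gen_lowrank_sparse(40, 40, 3, 0.05, seed=3)
        lam = 1 / np.sqrt(40)
        d1 = pcp_fit(t.A, lam)
        d2 = pcp_fit(7.0 * t.A, lam)
        assert rel(d2.B, 7.0 * d1.B) < 1e-4
        assert rel(d2.C, 7.0 * d1.C) < 1e-4

    def test_limits_in_lam(self):
        t = gen_lowrank_sparse(50, 50, 3, 0.05, seed=5)
        A = t.A
        big = pcp_fit(A, 1e3)
        assert np.linalg.norm(big.C) <= 1e-6 * np.linalg.norm(A)
        tiny = pcp_fit(A, 1e-6)
        assert np.linalg.norm(tiny.B) <= 1e-3 * np.linalg.norm(A)

    def test_non_finite_input_rejected(self):
        A = np.ones((3, 3))
        A[0, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            pcp_fit(A, 0.5)

    def test_deterministic_reruns(self):
        t = gen_lowrank_sparse(30, 25, 2, 0.05, seed=9)
        d1 = pcp_fit(t.A, 1 / np.sqrt(30))
        d2 = pcp_fit(t.A, 1 / np.sqrt(30))
        np.testing.assert_array_equal(d1.B, d2.B)
        np.testing.assert_array_equal(d1.C, d2.C)
        assert d1.diagnostics == d2.diagnostics


class TestSPCP:
    def test_delta_zero_reduces_to_pcp(self):
        for seed in range(3):
            t = gen_lowrank_sparse(40, 35, 3, 0.05, seed=seed)
            lam = 1 / np.sqrt(40)
            dp = pcp_fit(t.A, lam)
            ds = spcp_fit(t.A, lam, 0.0)
            assert rel(ds.B, dp.B) <= 1e-4
            assert rel(ds.C, dp.C) <= 1e-4

    def test_huge_delta_returns_zero_terms(self, rng):
        A = rng.uniform(0, 1, size=(10, 8))
        d = spcp_fit(A, 0.3, np.linalg.norm(A) * 1.5)
        assert np.all(d.B == 0) and np.all(d.C == 0)
        np.testing.assert_array_equal(d.D, A)

    def test_feasibility_at_convergence(self):
        rng = np.random.default_rng(11)
        t = gen_lowrank_sparse(60, 50, 3, 0.05, seed=11)
        N = rng.normal(0, 0.01 * np.linalg.norm(t.L0) / np.sqrt(60 * 50),
                       (60, 50))
        A = t.L0 + t.S0 + N
        delta = np.linalg.norm(N)
        d = spcp_fit(A, 1 / np.sqrt(60), delta)
        assert d.diagnostics["converged"]
        assert np.linalg.norm(A - d.B - d.C) <= delta * (1 + 1e-6)
        # D is the remainder, identically
        np.testing.assert_array_equal(d.D, A - d.B - d.C)

    def test_beats_pca_under_dense_noise(self):
        rng = np.random.default_rng(13)
        t = gen_lowrank_sparse(80, 60, 4, 0.05, seed=13)
        sigma = 0.01 * np.linalg.norm(t.L0) / np.sqrt(80 * 60)
        N = rng.normal(0, sigma, (80, 60))
        A = t.L0 + t.S0 + N
        ds = spcp_fit(A, 1 / np.sqrt(80), np.linalg.norm(N))
        dp = pca_fit(A, max(ds.rank_r, 1))
        assert rel(ds.B, t.L0) < rel(dp.B, t.L0)

    def test_invalid_parameters_rejected(self, rng):
        A = rng.uniform(size=(4, 4))
        with pytest.raises(ValueError):
            spcp_fit(A, -1.0, 0.1)
        with pytest.raises(ValueError):
            spcp_fit(A, 1.0, -0.1)


class TestSettingsValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"tol": 0},
            {"rho": 1.0},
            {"rank_threshold": 0},
            {"rank_threshold": 1.5},
            {"max_iter": 0},
            {"svd_strategy": "bogus"},
        ],
    )
    def test_bad_settings(self, kwargs):
        with pytest.raises(ValueError):
            SolverSettings(**kwargs)


class TestPersistence:
    def test_round_trip(self, tmp_path):
        t = gen_lowrank_sparse(25, 20, 2, 0.1, seed=2)
        d = pcp_fit(t.A, 1 / np.sqrt(25))
        path = tmp_path / "dec.h5"
        save_decomposition(d, path)
        d2 = load_decomposition(path)
        assert d2.method is Method.PCP
        assert rel(d2.B, d.B) < 1e-10
        np.testing.assert_array_equal(d2.C, d.C)
        assert d2.D is None
        assert d2.rank_r == d.rank_r
        assert d2.params == d.params
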