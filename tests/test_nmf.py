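"""Unit and property tests for the multiplicative-update NMF core."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from nmfpeaks import nmf
from nmfpeaks.nmf import (
    DegenerateInputError,
    factorize,
    normalize_factors,
    preprocess,
    select_components,
    update_step,
)


def _divergence(Y, A, X):
    return float(np.sum((Y - A @ X) ** 2))


class TestPreprocess:
    def test_three_four_five_norm(self):
        Yn, scale = preprocess(np.array([[3.0, 4.0], [0.0, 0.0]]))
        assert scale == pytest.approx(5.0)
        np.testing.assert_allclose(Yn, [[0.6, 0.8], [0.0, 0.0]])

    def test_negative_entries_clipped(self):
        Yn, _ = preprocess(np.array([[1.0, -1.0], [2.0, -3.0]]))
        assert np.all(Yn >= 0)
        assert Yn[0, 1] == 0.0 and Yn[1, 1] == 0.0

    def test_idempotent_on_normalized_input(self, rng):
        Y = rng.random((5, 7))
        Yn, _ = preprocess(Y)
        _, scale2 = preprocess(Yn)
        assert scale2 == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("bad", [np.zeros((3, 3)), -np.ones((2, 2))])
    def test_degenerate_input_raises(self, bad):
        with pytest.raises(DegenerateInputError):
            preprocess(bad)

    def test_nonfinite_raises(self):
        with pytest.raises(DegenerateInputError):
            preprocess(np.array([[1.0, np.nan]]))


class TestUpdateStep:
    def test_exact_factorization_is_fixed_point(self, rng):
        A = rng.uniform(0.5, 1.0, (6, 2))
        X = rng.uniform(0.5, 1.0, (2, 8))
        Y = A @ X
        A2, X2 = update_step(Y, A, X)
        np.testing.assert_allclose(A2 @ X2, Y, atol=1e-8)

    def test_zero_rows_stay_zero(self, rng):
        A = rng.uniform(0.5, 1.0, (6, 2))
        X = rng.uniform(0.5, 1.0, (2, 8))
        A[3, :] = 0.0
        X[:, 5] = 0.0
        Y = rng.random((6, 8))
        A2, X2 = update_step(Y, A, X)
        assert np.all(A2[3, :] == 0.0)
        assert np.all(X2[:, 5] == 0.0)

    def test_single_step_never_increases_divergence(self, rng):
        for _ in range(20):
            Y = rng.random((6, 8))
            A = rng.uniform(0.1, 1.1, (6, 2))
            X = rng.uniform(0.1, 1.1, (2, 8))
            before = _divergence(Y, A, X)
            A2, X2 = update_step(Y, A, X)
            assert _divergence(Y, A2, X2) <= before + 1e-10

    def test_shape_mismatch_raises(self, rng):
        with pytest.raises(ValueError, match="shape"):
            update_step(rng.random((4, 4)), rng.random((4, 2)),
                        rng.random((3, 4)))


@settings(deadline=None, max_examples=40, derandomize=True)
@given(
    Y=hnp.arrays(float, (5, 6), elements=st.floats(0, 10)),
    seed=st.integers(0, 2**16),
)
def test_updates_preserve_nonnegativity_and_descend(Y, seed):
    """For arbitrary non-negative input, every iterate stays non-negative
    and the divergence never increases beyond numerical slack."""
    rng = np.random.default_rng(seed)
    A = rng.uniform(0.1, 1.1, (5, 2))
    X = rng.uniform(0.1, 1.1, (2, 6))
    prev = _divergence(Y, A, X)
    for _ in range(20):
        A, X = update_step(Y, A, X)
        assert np.all(A >= 0) and np.all(X >= 0)
        d = _divergence(Y, A, X)
        assert d <= prev * (1 + 1e-9) + 1e-12
        prev = d


class TestFactorize:
    def test_rank_one_exact_recovery(self, rng):
        u = rng.uniform(0.5, 1.5, 6)
        v = rng.uniform(0.5, 1.5, 9)
        Y = np.outer(u, v)
        pair, trace = factorize(Y, 1, seed=0)
        assert trace.final_residual < 1e-8
        # recovered factors proportional to u and v
        cos_u = np.dot(pair.A[:, 0], u) / (np.linalg.norm(pair.A) * np.linalg.norm(u))
        cos_v = np.dot(pair.X[0], v) / (np.linalg.norm(pair.X) * np.linalg.norm(v))
        assert cos_u > 0.99999 and cos_v > 0.99999

    def test_identity_recovered_at_rank_two(self):
        Y = np.eye(2)
        pair, trace = factorize(Y, 2, seed=1)
        assert trace.final_residual < 1e-6
        np.testing.assert_allclose(pair.A @ pair.X, Y, atol=1e-3)

    def test_deterministic_under_seed(self, rng):
        Y = rng.random((8, 8))
        pair1, _ = factorize(Y, 3, seed=42)
        pair2, _ = factorize(Y, 3, seed=42)
        np.testing.assert_array_equal(pair1.A, pair2.A)
        np.testing.assert_array_equal(pair1.X, pair2.X)

    def test_overcomplete_rank_warns_but_runs(self, rng):
        Y = rng.random((3, 3))
        with pytest.warns(UserWarning, match="over-complete"):
            pair, _ = factorize(Y, 5, seed=0)
        assert pair.rank == 5

    def test_residual_trace_monotone(self, rng):
        Y = rng.random((10, 12))
        _, trace = factorize(Y, 3, seed=7, restarts=1)
        diffs = np.diff(trace.residuals)
        assert np.all(diffs <= trace.residuals[:-1] * 1e-9 + 1e-12)

    def test_scale_identity(self, rng):
        """scale * (A X) reconstructs the clipped input to residual level."""
        Y = rng.random((10, 10))
        Yn, scale = preprocess(Y)
        pair, trace = factorize(Yn, 6, seed=3, scale=scale)
        err = np.linalg.norm(Y - pair.reconstruct()) ** 2 / scale**2
        assert err == pytest.approx(trace.final_residual, rel=1e-6, abs=1e-9)


class TestNormalizeFactors:
    def test_scale_transfer(self):
        pair = normalize_factors(np.array([[2.0], [2.0]]), np.array([[3.0]]))
        np.testing.assert_allclose(pair.A, [[0.5], [0.5]])
        np.testing.assert_allclose(pair.X, [[12.0]])

    def test_idempotent(self, rng):
        A = rng.random((5, 3))
        X = rng.random((3, 4))
        p1 = normalize_factors(A, X)
        p2 = normalize_factors(p1.A, p1.X)
        np.testing.assert_allclose(p1.A, p2.A, atol=1e-14)
        np.testing.assert_allclose(p1.X, p2.X, atol=1e-14)

    def test_product_unchanged(self, rng):
        A = rng.random((6, 4))
        X = rng.random((4, 5))
        pair = normalize_factors(A, X)
        assert np.max(np.abs(A @ X - pair.A @ pair.X)) < 1e-12

    def test_zero_column_left_alone(self):
        A = np.array([[1.0, 0.0], [1.0, 0.0]])
        X = np.ones((2, 3))
        pair = normalize_factors(A, X)
        assert np.all(pair.A[:, 1] == 0.0)
        np.testing.assert_allclose(pair.A[:, 0], [0.5, 0.5])


class TestSelectComponents:
    def _separable(self, rng, rank, m=24, t=24, width=1.5):
        from conftest import gauss
        centers = np.linspace(4, m - 5, rank)
        Y = np.zeros((m, t))
        for k, c in enumerate(centers):
            Y += (1.0 - 0.15 * k) * np.outer(gauss(m, c, width),
                                             gauss(t, m - 1 - c, width))
        return Y

    def test_recovers_rank_three(self, rng):
        Y = self._separable(rng, 3)
        Yn, _ = preprocess(Y)
        res = select_components(Yn, [2, 3, 4, 5], seed=0)
        assert res.chosen_r == 3
        assert res.final_residuals[3] < 1e-6
        assert res.final_residuals[2] > 10 * max(res.final_residuals[3], 1e-9)

    def test_rank_one_tie_break_to_smallest(self, rng):
        u = rng.uniform(0.5, 1.5, 10)
        v = rng.uniform(0.5, 1.5, 10)
        Yn, _ = preprocess(np.outer(u, v))
        res = select_components(Yn, [1, 2, 3], seed=0)
        assert res.chosen_r == 1

    def test_residuals_nested_in_rank(self, rng):
        """More components never fit worse (within solver tolerance)."""
        Y = rng.random((12, 12))
        Yn, _ = preprocess(Y)
        res = select_components(Yn, [2, 3, 4, 5], seed=1)
        rs = res.candidate_r
        for lo, hi in zip(rs, rs[1:]):
            assert (res.final_residuals[hi]
                    <= res.final_residuals[lo] + 1e-5)

    def test_empty_candidates_rejected(self, rng):
        with pytest.raises(ValueError):
            select_components(rng.random((4, 4)), [])


def test_agrees_with_reference_nmf_implementation(rng):
    """Cross-check: final divergence comparable to scikit-learn's
    multiplicative-update NMF on the same problem."""
    sklearn = pytest.importorskip("sklearn.decomposition")
    Y = rng.random((15, 12))
    Yn, _ = preprocess(Y)
    pair, trace = factorize(Yn, 3, seed=0)
    ref = sklearn.NMF(n_components=3, solver="mu", beta_loss="frobenius",
                      init="nndsvda", max_iter=2000, tol=1e-10,
                      random_state=0)
    W = ref.fit_transform(Yn)
    ref_div = float(np.sum((Yn - W @ ref.components_) ** 2))
    assert trace.final_residual <= ref_div * 1.05 + 1e-8
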