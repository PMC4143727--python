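"""Liability thresholds, conditional means, correlation and decorrelation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import norm

from latentgwas.io import DataError
from latentgwas.latent import (conditional_liability, decorrelate,
                               hwe_category_probs, latent_block,
                               liability_thresholds, sample_correlation,
                               truncated_normal_mean)


@pytest.mark.parametrize("q, expected", [
    (0.5, (0.25, 0.5, 0.25)),
    (1e-9, (1.0, 0.0, 0.0)),           # degenerate limit, within fp tolerance
    (0.16, (0.7056, 0.2688, 0.0256)),
])
def test_hwe_probs(q, expected):
    assert hwe_category_probs(q) == pytest.approx(expected, abs=1e-7)


def test_hwe_rejects_out_of_range():
    for q in (0.0, -0.1, 0.6):
        with pytest.raises(ValueError):
            hwe_category_probs(q)


def test_thresholds_match_normal_quantiles():
    th = liability_thresholds((0.25, 0.5, 0.25))
    assert th.t2 == pytest.approx(norm.ppf(0.75))
    assert th.t1 == pytest.approx(-th.t2)
    th2 = liability_thresholds((0.7056, 0.2688, 0.0256))
    assert th2.t1 == pytest.approx(norm.ppf(0.7056))
    assert th2.t2 == pytest.approx(norm.ppf(0.9744))
    # boundary categories map to infinite cut points
    assert liability_thresholds((0.0, 0.5, 0.5)).t1 == -np.inf
    assert liability_thresholds((0.5, 0.5, 0.0)).t2 == np.inf


class TestTruncatedNormalMean:
    def test_closed_forms(self):
        assert truncated_normal_mean(-np.inf, np.inf) == 0.0
        assert truncated_normal_mean(0.0, np.inf) == pytest.approx(np.sqrt(2 / np.pi))
        assert truncated_normal_mean(-0.6745, 0.6745) == pytest.approx(0.0, abs=1e-15)

    def test_value_lies_inside_interval(self):
        m = truncated_normal_mean(1.0, 2.5)
        assert 1.0 < m < 2.5

    def test_zero_mass_interval_raises(self):
        with pytest.raises(FloatingPointError):
            truncated_normal_mean(40.0, 41.0)

    @settings(deadline=None, max_examples=30)
    @given(st.floats(0.01, 0.98), st.floats(0.01, 0.98))
    def test_law_of_total_expectation(self, p0, p1):
        # category means weighted by category probabilities average to zero
        total = p0 + p1
        if total >= 0.999:
            p0, p1 = p0 / (total + 0.01), p1 / (total + 0.01)
        p2 = 1.0 - p0 - p1
        th = liability_thresholds((p0, p1, p2))
        acc = sum(pk * truncated_normal_mean(*th.interval(k))
                  for k, pk in enumerate((p0, p1, p2)) if pk > 1e-12)
        assert acc == pytest.approx(0.0, abs=1e-10)

    def test_agrees_with_rejection_sampling(self):
        rng = np.random.default_rng(7)
        draws = rng.standard_normal(400_000)
        for _ in range(5):
            a = rng.uniform(-2.0, 0.5)
            b = a + rng.uniform(0.3, 2.0)
            kept = draws[(draws > a) & (draws <= b)]
            se = kept.std(ddof=1) / np.sqrt(kept.size)
            assert truncated_normal_mean(a, b) == pytest.approx(kept.mean(), abs=3 * se)


class TestConditionalLiability:
    def test_symmetric_category_maps_to_zero(self):
        th = [liability_thresholds(hwe_category_probs(0.5))]
        U = conditional_liability(np.array([[1], [1]]), th)
        np.testing.assert_allclose(U, 0.0, atol=1e-15)

    def test_monotone_in_genotype_and_category_constant(self):
        for q in (0.1, 0.3, 0.5):
            th = [liability_thresholds(hwe_category_probs(q))]
            U = conditional_liability(np.array([[0], [1], [2], [1]]), th)
            assert U[0, 0] < U[1, 0] < U[2, 0]
            assert U[1, 0] == U[3, 0]

    def test_homozygote_minor_mean_positive(self):
        th = [liability_thresholds(hwe_category_probs(0.5))]
        U = conditional_liability(np.array([[2]]), th)
        assert U[0, 0] == pytest.approx(norm.pdf(0.6745) / 0.25, rel=1e-3)


class TestSampleCorrelation:
    def test_identical_columns_correlate_fully(self):
        x = np.arange(10.0)
        C = sample_correlation(np.column_stack([x, x]))
        assert C[0, 1] == pytest.approx(1.0)

    def test_full_shrinkage_gives_identity(self):
        rng = np.random.default_rng(0)
        C = sample_correlation(rng.standard_normal((30, 4)), shrinkage=1.0)
        np.testing.assert_allclose(C, np.eye(4))

    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(1)
        M = rng.standard_normal((10_000, 2))
        C = sample_correlation(M)
        assert abs(C[0, 1]) < 3 / np.sqrt(10_000)

    def test_zero_variance_column_rejected(self):
        with pytest.raises(DataError):
            sample_correlation(np.column_stack([np.ones(5), np.arange(5.0)]))


class TestDecorrelate:
    def test_identity_correlation_is_noop(self):
        rng = np.random.default_rng(2)
        U = rng.standard_normal((6, 3))
        for mode in ("inverse", "inv_sqrt"):
            np.testing.assert_allclose(decorrelate(U, np.eye(3), mode), U, atol=1e-12)

    def test_two_by_two_closed_form(self):
        rho = 0.6
        C = np.array([[1.0, rho], [rho, 1.0]])
        U = np.array([[1.0, 2.0], [0.5, -1.0]])
        Z = decorrelate(U, C, "inverse")
        expected = np.column_stack([
            (U[:, 0] - rho * U[:, 1]) / (1 - rho**2),
            (U[:, 1] - rho * U[:, 0]) / (1 - rho**2),
        ])
        np.testing.assert_allclose(Z, expected, atol=1e-12)

    def test_inverse_mode_round_trips_through_C(self):
        rng = np.random.default_rng(3)
        C = sample_correlation(rng.standard_normal((50, 5)), shrinkage=0.2)
        U = rng.standard_normal((8, 5))
        Z = decorrelate(U, C, "inverse")
        np.testing.assert_allclose(Z @ C, U, atol=1e-8)

    def test_inv_sqrt_whitens_correlated_draws(self):
        rng = np.random.default_rng(4)
        rho = 0.7
        C = np.array([[1.0, rho], [rho, 1.0]])
        U = rng.standard_normal((20_000, 2)) @ np.linalg.cholesky(C).T
        Z = decorrelate(U, C, "inv_sqrt")
        R = np.corrcoef(Z, rowvar=False)
        assert abs(R[0, 1]) < 3 / np.sqrt(20_000)

    def test_singular_matrix_advises_shrinkage(self):
        C = np.ones((2, 2))
        with pytest.raises(np.linalg.LinAlgError, match="shrinkage"):
            decorrelate(np.ones((3, 2)), C, "inverse")


def test_latent_block_end_to_end_shapes_and_u_columns():
    rng = np.random.default_rng(5)
    X = rng.integers(0, 3, size=(40, 6)).astype(np.int8)
    maf = np.clip(X.mean(axis=0) / 2, 0.05, 0.5)
    lat = latent_block(X, maf, shrinkage=0.1, probs="empirical")
    assert lat.U_hat.shape == lat.Z_hat.shape == (40, 6)
    np.testing.assert_allclose(np.diag(lat.C), 1.0)
    np.testing.assert_allclose(lat.C, lat.C.T)
    assert np.linalg.eigvalsh(lat.C).min() > 0
    for j in range(6):
        assert len(np.unique(lat.U_hat[:, j])) <= 3
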