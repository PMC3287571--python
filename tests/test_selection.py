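"""BIC and PCA hidden-dimension selection."""
import numpy as np
import pytest

from ssmgrn import (EMConfig, ExpressionDataset, SSMParameters, compute_bic,
                    count_parameters, em_fit, pca_eigenvalues, pca_init,
                    select_m_bic, select_m_pca, simulate_ssm)
from ssmgrn.ssm import m_step
from ssmgrn.kalman import kalman_filter_smoother

from helpers import spectrum_dataset


class TestComputeBic:
    def test_zero_parameters_is_plain_loglik(self):
        assert compute_bic(-10.0, 0, 57) == -10.0

    def test_known_penalty(self):
        # ln(e^2) = 2, so the penalty is (1/2) * 4 * 2 = 4
        assert compute_bic(-10.0, 4, np.e ** 2) == pytest.approx(-14.0)

    def test_fewer_parameters_wins_at_equal_loglik(self):
        assert compute_bic(-5.0, 3, 10) > compute_bic(-5.0, 7, 10)

    def test_penalty_strictly_decreasing_in_n_params(self):
        vals = [compute_bic(0.0, k, 50) for k in range(6)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_invalid_n_data_rejected(self):
        with pytest.raises(ValueError):
            compute_bic(0.0, 1, 0)


class TestCountParameters:
    @pytest.mark.parametrize("m,l,expected", [(1, 1, 5), (2, 30, 99)])
    def test_direct_counts(self, m, l, expected):
        assert count_parameters(m, l) == expected

    def test_matches_free_scalars_updated_by_m_step(self, rng):
        """The count equals the scalars the M-step can actually move:
        all of F and H, the upper triangle of (symmetric) Q, the diagonal of
        (diagonal) R, and mu0 — with Sigma0 held fixed."""
        m, l, T = 2, 4, 12
        d = ExpressionDataset(rng.standard_normal((l, T)))
        init = pca_init(d, m)
        sm = kalman_filter_smoother(init, d.centered())
        upd = m_step(d.centered().values, init, sm)
        assert np.allclose(upd.Q, upd.Q.T)  # symmetric: m(m+1)/2 free
        assert np.allclose(upd.R, np.diag(np.diag(upd.R)))  # diagonal: l free
        assert np.array_equal(upd.Sigma0, init.Sigma0)  # fixed: 0 free
        free = upd.F.size + upd.H.size + m * (m + 1) // 2 + l + m
        assert count_parameters(m, l) == free


class TestPcaEigenvalues:
    def test_rank_one_data(self):
        pattern = np.array([1.0, -2.0, 0.5, 3.0, -1.0])
        Y = np.outer([1.0, 0.3, -2.0], pattern)
        lam = pca_eigenvalues(ExpressionDataset(Y))
        assert (lam > 0).sum() == 1

    def test_matches_dense_eigendecomposition(self, rng):
        Y = rng.standard_normal((6, 5))
        lam = pca_eigenvalues(ExpressionDataset(Y))
        cov = np.cov(Y)  # explicit l x l gene-covariance matrix
        dense = np.sort(np.linalg.eigvalsh(cov))[::-1]
        assert np.allclose(lam[: len(dense)], np.maximum(dense[: len(lam)], 0),
                           atol=1e-8)

    def test_duplicated_row_preserves_nonzero_count(self, rng):
        Y = rng.standard_normal((4, 8))
        lam1 = pca_eigenvalues(ExpressionDataset(Y))
        lam2 = pca_eigenvalues(ExpressionDataset(np.vstack([Y, Y[:1]])))
        assert (lam1 > 0).sum() == (lam2 > 0).sum()

    def test_sum_equals_total_centered_variance(self, rng):
        Y = rng.standard_normal((5, 9))
        d = ExpressionDataset(Y)
        lam = pca_eigenvalues(d)
        Yc = d.centered().values
        total = (Yc ** 2).sum() / (Y.shape[1] - 1)
        assert lam.sum() == pytest.approx(total, abs=1e-8)

    def test_descending_nonnegative(self, rng):
        lam = pca_eigenvalues(ExpressionDataset(rng.standard_normal((7, 5))))
        assert np.all(np.diff(lam) <= 1e-12)
        assert np.all(lam >= 0)


class TestSelectMPca:
    @pytest.mark.parametrize("spectrum,expected_m", [
        ((8.0, 1.0, 1.0), 1),  # residual 2/10 = 20% passes at the 20% cutoff
        ((5.0, 4.0, 1.0), 2),  # m=1 residual 50% fails, m=2 residual 10% passes
    ])
    def test_constructed_spectra(self, spectrum, expected_m):
        d = spectrum_dataset(spectrum, T=6)
        assert select_m_pca(d, fraction=0.2).chosen_m == expected_m

    def test_minimality_by_linear_scan(self, rng):
        d = ExpressionDataset(rng.standard_normal((6, 10)))
        rep = select_m_pca(d, fraction=0.3)
        lam = pca_eigenvalues(d)
        total = lam.sum()
        feasible = [m for m in range(1, len(lam) + 1)
                    if lam[m:].sum() / total <= 0.3]
        assert rep.chosen_m == min(feasible)

    @pytest.mark.parametrize("dataset_seed", [0, 1, 2])
    def test_monotone_in_fraction(self, dataset_seed):
        rng = np.random.default_rng(dataset_seed)
        d = ExpressionDataset(rng.standard_normal((6, 12)))
        ms = [select_m_pca(d, fraction=f).chosen_m
              for f in (0.05, 0.1, 0.2, 0.4, 0.8)]
        assert all(a >= b for a, b in zip(ms, ms[1:]))

    def test_constant_data_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            select_m_pca(ExpressionDataset(np.ones((3, 5))))

    def test_recovers_low_rank_signal(self, rng):
        r, l, T = 3, 10, 30
        signal = rng.standard_normal((l, r)) @ rng.standard_normal((r, T))
        Y = signal + 0.01 * rng.standard_normal((l, T))
        assert select_m_pca(ExpressionDataset(Y), fraction=0.01).chosen_m == r


class TestSelectMBic:
    def test_single_candidate(self, small_dataset):
        rep = select_m_bic(small_dataset, [3], EMConfig(max_iter=5))
        assert rep.chosen_m == 3

    def test_chosen_is_argmax_of_reported_criterion(self, small_dataset):
        rep = select_m_bic(small_dataset, [1, 2, 3], EMConfig(max_iter=20))
        vals = np.asarray(rep.criterion_values)
        assert rep.chosen_m == rep.candidate_ms[int(np.nanargmax(vals))]

    def test_recovers_true_dimension_on_identified_data(self):
        """BIC prefers the generating m=2 on long strongly-identified series."""
        rng = np.random.default_rng(7)
        p = SSMParameters(F=np.array([[0.9, 0.3], [-0.2, 0.7]]),
                          H=rng.standard_normal((8, 2)),
                          Q=0.3 * np.eye(2), R=0.1 * np.eye(8),
                          mu0=np.zeros(2), Sigma0=np.eye(2))
        hits = 0
        for s in range(3):
            _, d = simulate_ssm(p, 200, seed=s)
            rep = select_m_bic(d, [1, 2, 3], EMConfig(max_iter=100, seed=s))
            hits += rep.chosen_m == 2
        assert hits >= 2

    def test_all_failures_raise(self, small_dataset):
        with pytest.raises(RuntimeError, match="failed"):
            # candidates all above min(l, T) fail their precondition
            select_m_bic(small_dataset, [40, 50], EMConfig(max_iter=5))
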