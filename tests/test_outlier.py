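"""Windowed mean-distance statistic, Beta null, and marker calling."""

import numpy as np
import pandas as pd
import pytest

from rarecnv.data import LogratioMatrix
from rarecnv.outlier import (
    MarkerSet,
    WindowSpec,
    call_markers,
    fit_null_beta,
    fit_null_beta_rows,
    make_windows,
    marker_pvalues,
    mu_limit_k1,
    mu_matrix,
    mu_statistic,
    simulate_independence_null,
)
from rarecnv.ranks import PseudoRankMatrix, pseudo_rank
from rarecnv.synth import make_probe_index


def _rank_matrix(values):
    values = np.asarray(values, float)
    pi = make_probe_index((("chr1", values.shape[1]),))
    ids = [f"S{i}" for i in range(values.shape[0])]
    return PseudoRankMatrix(values, ids, pi)


class TestWindows:
    def test_window_count_is_p_minus_k_plus_one(self):
        pi = make_probe_index((("chr1", 10),))
        ws = make_windows(pi, k=7)
        assert list(ws.starts) == [0, 1, 2, 3]

    def test_short_chromosome_yields_no_window(self):
        pi = make_probe_index((("chr1", 6),))
        assert len(make_windows(pi, k=7)) == 0

    def test_windows_never_span_chromosome_boundary(self):
        pi = make_probe_index((("chr1", 8), ("chr2", 8)))
        ws = make_windows(pi, k=7)
        assert list(ws.starts) == [0, 1, 8, 9]

    def test_k_below_two_rejected(self):
        pi = make_probe_index((("chr1", 10),))
        with pytest.raises(ValueError):
            make_windows(pi, k=1)


class TestMuStatistic:
    def test_two_samples_one_probe(self):
        R = _rank_matrix([[1 / 3], [2 / 3]])
        np.testing.assert_allclose(mu_statistic(R, (0, 1)), [1 / 6, 1 / 6])

    def test_three_samples_one_probe(self):
        R = _rank_matrix([[0.25], [0.5], [0.75]])
        np.testing.assert_allclose(mu_statistic(R, (0, 1)), [0.25, 1 / 6, 0.25])

    def test_matches_naive_double_loop(self, rng):
        """Vectorised mu equals the brute-force pairwise definition."""

        def naive(W, d):
            n, k = W.shape
            out = np.zeros(n)
            for s in range(n):
                acc = 0.0
                for j in range(n):
                    dist = sum(abs(W[s, l] - W[j, l]) ** d for l in range(k)) ** (1 / d)
                    acc += dist
                out[s] = acc / n
            return out

        for _ in range(20):
            W = rng.uniform(0.01, 0.99, size=(20, 7))
            R = _rank_matrix(W)
            for d in (1.0, 2.0):
                np.testing.assert_allclose(
                    mu_statistic(R, (0, 7), d=d), naive(W, d), atol=1e-10
                )

    def test_fast_path_matches_per_window_path(self, rng):
        X = rng.normal(size=(30, 40))
        R = pseudo_rank(
            LogratioMatrix(X, [f"S{i}" for i in range(30)], make_probe_index((("chr1", 40),)))
        )
        ws = make_windows(R.probe_index, k=7)
        fast = mu_matrix(R, ws, d=1.0).values
        direct = np.vstack([mu_statistic(R, (q, 7)) for q in ws.starts])
        np.testing.assert_allclose(fast, direct, atol=1e-10)

    def test_range_and_zero_iff_identical_rows(self):
        k = 5
        same = _rank_matrix(np.tile(np.linspace(0.2, 0.8, k), (4, 1)))
        mu = mu_statistic(same, (0, k))
        np.testing.assert_allclose(mu, 0.0, atol=1e-15)
        extremes = _rank_matrix(
            np.vstack([np.full(k, 0.01), np.full(k, 0.99)])
        )
        mu2 = mu_statistic(extremes, (0, k))
        assert np.all(mu2 >= 0) and np.all(mu2 <= k)

    def test_sample_with_missing_cell_excluded(self):
        W = np.array([[0.2, 0.3], [0.4, np.nan], [0.6, 0.7], [0.8, 0.9]])
        mu = mu_statistic(_rank_matrix(W), (0, 2))
        assert np.isnan(mu[1])
        # remaining samples: mean over the 3 included samples only
        sub = W[[0, 2, 3]]
        expected = np.abs(sub[:, None, :] - sub[None, :, :]).sum(-1).mean(1)
        np.testing.assert_allclose(mu[[0, 2, 3]], expected)

    def test_relabeling_equivariance(self, rng):
        W = rng.uniform(size=(12, 7))
        perm = rng.permutation(12)
        mu = mu_statistic(_rank_matrix(W), (0, 7))
        mu_p = mu_statistic(_rank_matrix(W[perm]), (0, 7))
        np.testing.assert_allclose(mu[perm], mu_p, atol=1e-12)


class TestLimit:
    def test_limit_values(self):
        assert mu_limit_k1(0.5) == pytest.approx(0.25)
        assert mu_limit_k1(0.0) == pytest.approx(0.5)
        assert mu_limit_k1(1.0) == pytest.approx(0.5)
        assert mu_limit_k1(0.25) == pytest.approx(0.3125)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            mu_limit_k1(1.5)

    def test_mu_converges_to_limit_at_large_n(self):
        """At k=1 with a large uniform cohort, mu at pseudo-rank z approaches
        the mean absolute deviation of U(0,1) from z."""
        n = 5000
        ranks = (np.arange(1, n + 1) / (n + 1))[:, None]
        mu = mu_statistic(_rank_matrix(ranks), (0, 1))
        for z in np.arange(0.1, 0.95, 0.1):
            s = int(round(z * (n + 1))) - 1
            assert mu[s] == pytest.approx(mu_limit_k1(ranks[s, 0]), abs=0.01)


class TestIndependenceNull:
    def test_k1_support_and_mean(self):
        n = 1000
        draws = simulate_independence_null(1, n, 20000, seed=11)
        assert draws.min() >= 0.25 - 1.0 / n
        assert draws.max() <= 0.5
        # E[mu] -> integral of (z^2+(1-z)^2)/2 = 1/3
        assert draws.mean() == pytest.approx(1 / 3, abs=0.01)

    def test_k7_mean_is_seven_times_k1(self):
        draws = simulate_independence_null(7, 1000, 20000, seed=12)
        assert draws.mean() == pytest.approx(7 / 3, rel=0.02)

    def test_general_d_path_agrees_with_fast_path_at_d1(self):
        fast = simulate_independence_null(3, 200, 4000, d=1.0, seed=5)
        # d close to 1 exercises the full-permutation path, same distribution
        slow = simulate_independence_null(3, 200, 4000, d=1.0 + 1e-12, seed=5)
        assert slow.mean() == pytest.approx(fast.mean(), rel=0.03)
        assert np.std(slow) == pytest.approx(np.std(fast), rel=0.15)

    def test_reproducible_under_seed(self):
        a = simulate_independence_null(2, 50, 100, seed=3)
        b = simulate_independence_null(2, 50, 100, seed=3)
        np.testing.assert_array_equal(a, b)


class TestBetaNull:
    def test_degenerate_input_gives_no_fit_and_unit_pvalues(self):
        fit = fit_null_beta(np.full(20, 0.7))
        assert not fit.ok
        np.testing.assert_array_equal(marker_pvalues(np.full(20, 0.7), fit), 1.0)

    def test_parameter_recovery_on_known_interval(self, rng):
        draws = 3.0 + 2.0 * rng.beta(2.0, 5.0, size=10_000)
        fit = fit_null_beta(draws, lo=3.0, hi=5.0)
        assert fit.alpha == pytest.approx(2.0, abs=0.2)
        assert fit.beta == pytest.approx(5.0, abs=0.5)

    def test_symmetric_sample_gives_symmetric_fit(self, rng):
        fit = fit_null_beta(rng.normal(size=10_000))
        assert fit.ok
        assert abs(fit.alpha - fit.beta) / max(fit.alpha, fit.beta) < 0.15

    def test_boundary_pvalues(self, rng):
        mu = rng.uniform(2.0, 4.0, size=50)
        fit = fit_null_beta(mu)
        p = marker_pvalues(mu, fit)
        assert p[np.argmin(mu)] == pytest.approx(1.0)
        assert p[np.argmax(mu)] == pytest.approx(0.0)

    def test_uniform_null_is_identity_tail(self):
        fit = fit_null_beta(np.linspace(0, 1, 100), lo=0.0, hi=1.0)
        # 90th percentile of [lo, hi] under Beta(1,1) has p = 0.1
        fit.alpha = fit.beta = 1.0
        p = marker_pvalues(np.array([0.9]), fit)
        assert p[0] == pytest.approx(0.1, abs=1e-9)

    def test_requires_minimum_sample(self):
        with pytest.raises(ValueError, match="at least 8"):
            fit_null_beta(np.arange(5.0))

    def test_row_vectorised_fit_matches_scalar_fit(self, rng):
        M = rng.uniform(1.0, 3.0, size=(15, 60))
        M[2, 5] = np.nan
        fits, P = fit_null_beta_rows(M)
        for w in (0, 2, 7):
            ref = fit_null_beta(M[w], window=w)
            assert fits[w].alpha == pytest.approx(ref.alpha, rel=1e-12)
            assert fits[w].beta == pytest.approx(ref.beta, rel=1e-12)
            np.testing.assert_allclose(
                P[w], marker_pvalues(M[w], ref), atol=1e-12
            )


class TestCallMarkers:
    def _windows(self, starts, k=7):
        return WindowSpec(k=k, step=1, starts=np.asarray(starts))

    def test_strict_threshold(self):
        P = np.array([[0.005, 0.5, 0.01]])
        ms = call_markers(P, self._windows([0]), ["A", "B", "C"], threshold=0.01)
        assert ms.pairs() == {("A", 0)}

    def test_all_unit_pvalues_give_empty_set(self):
        P = np.ones((3, 4))
        ms = call_markers(P, self._windows([0, 1, 2]), list("ABCD"))
        assert len(ms) == 0

    def test_marker_set_rejects_pvalues_at_threshold(self):
        df = pd.DataFrame({"sample": ["A"], "window": [0], "pvalue": [0.01]})
        with pytest.raises(ValueError):
            MarkerSet(df, p_threshold=0.01)

    def test_nan_pvalues_never_flagged(self):
        P = np.array([[np.nan, 0.001]])
        ms = call_markers(P, self._windows([3]), ["A", "B"])
        assert ms.pairs() == {("B", 3)}
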