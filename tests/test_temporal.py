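"""Autocovariance, autocorrelation time, and transition machinery."""

import numpy as np
import pytest

from sleepmem import (
    STAGES,
    TransitionMatrix,
    autocorrelation_time,
    autocovariance,
    estimate_transition_matrix,
    group_average_autocov,
    indicator_series,
    initial_distribution,
    normalize_autocov,
    simulate_hypnogram,
    transition_vector,
)
from sleepmem.errors import (
    DegenerateSignalError,
    InsufficientDataError,
    InvalidInputError,
)


class TestIndicatorSeries:
    def test_basic_indicator_and_mean(self):
        s = indicator_series(["W", "N1", "W"], "W", delta_t=30)
        assert s.values.tolist() == [1, 0, 1]
        assert s.mean == pytest.approx(2 / 3)

    def test_absent_and_ubiquitous_stage(self):
        assert indicator_series(["N2"] * 5, "REM").mean == 0.0
        assert indicator_series(["N2"] * 5, "N2").mean == 1.0

    def test_empty_labels_rejected(self):
        with pytest.raises(InvalidInputError):
            indicator_series([], "W")


class TestAutocovariance:
    def test_constant_indicator_has_zero_autocovariance(self):
        gamma = autocovariance(indicator_series(["W"] * 50, "W"), max_lag=5)
        assert np.allclose(gamma, 0.0)

    def test_alternating_sequence_hand_expansion(self):
        # I = 1,0,1,0,... length 1000: mean 1/2, deviations +/- 1/2.
        # 1/n convention: gamma(0) = 0.25, gamma(1) = -0.25 * 999/1000.
        labels = ["W", "N1"] * 500
        gamma = autocovariance(indicator_series(labels, "W"), max_lag=2)
        assert gamma[0] == pytest.approx(0.25)
        assert gamma[1] == pytest.approx(-0.25 * 999 / 1000)
        assert gamma[2] == pytest.approx(0.25 * 998 / 1000)

    def test_iid_bernoulli_lags_within_clt_bound(self):
        rng = np.random.default_rng(8)
        n = 10_000
        labels = ["W" if b else "N1" for b in rng.random(n) < 0.5]
        gamma = autocovariance(indicator_series(labels, "W"), max_lag=10)
        bound = 3 * 0.25 / np.sqrt(n)
        assert np.all(np.abs(gamma[1:]) < bound)

    def test_single_epoch_rejected(self):
        with pytest.raises(InsufficientDataError):
            autocovariance(indicator_series(["W"], "W"), max_lag=1)


class TestNormalizeAndCorrelationTime:
    def test_normalization_division(self):
        rho = normalize_autocov(np.array([2.0, 1.0, -0.5]))
        assert rho.tolist() == [1.0, 0.5, -0.25]

    def test_scale_invariance(self):
        g = np.array([0.3, 0.1, -0.05])
        assert np.allclose(normalize_autocov(g), normalize_autocov(10 * g))

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateSignalError):
            normalize_autocov(np.zeros(5))

    def test_immediate_zero_crossing(self):
        t_c, tau_max = autocorrelation_time(np.array([1.0, -0.2, 0.1]), delta_t=30)
        assert tau_max == 0
        assert t_c == pytest.approx(30.0)

    def test_geometric_profile_sum(self):
        rho = 0.5 ** np.arange(21)
        t_c, tau_max = autocorrelation_time(rho, delta_t=30)
        assert tau_max == 20
        assert t_c == pytest.approx(30 * (2 - 0.5**20))

    def test_truncation_stops_before_first_nonpositive(self):
        rho = np.array([1.0, 0.5, 0.2, 0.0, 0.4])
        t_c, tau_max = autocorrelation_time(rho, delta_t=10)
        assert tau_max == 2
        assert t_c == pytest.approx(10 * 1.7)


def two_state_labels(p_stay, n, seed):
    """Symmetric 2-state chain with stay-probability p, as W/N1 labels."""
    T = TransitionMatrix(
        np.array([
            [p_stay, 1 - p_stay, 0, 0, 0],
            [1 - p_stay, p_stay, 0, 0, 0],
            [0, 0, 1, 0, 0],
            [0, 0, 0, 1, 0],
            [0, 0, 0, 0, 1],
        ])
    )
    return simulate_hypnogram(T, n, initial_stage="W", rng_seed=seed)


class TestTwoStateChainTheory:
    def test_rho_matches_eigenvalue_decay(self):
        # For a symmetric 2-state chain, rho(tau) = (2p - 1)^tau.
        p, n = 0.9, 100_000
        labels = two_state_labels(p, n, seed=13)
        rho = normalize_autocov(autocovariance(indicator_series(labels, "W"), 10))
        lam = 2 * p - 1
        # Bartlett large-sample SE for an AR(1)-like correlogram
        se = np.sqrt((1 + 2 * lam**2 / (1 - lam**2)) / n)
        for tau in range(1, 11):
            assert abs(rho[tau] - lam**tau) < 3 * se

    def test_correlation_time_monotone_in_stickiness(self):
        tcs = []
        for p in (0.6, 0.8, 0.9, 0.95):
            labels = two_state_labels(p, 50_000, seed=29)
            rho = normalize_autocov(
                autocovariance(indicator_series(labels, "W"), 120))
            t_c, _ = autocorrelation_time(rho, delta_t=30)
            tcs.append(t_c)
        assert tcs == sorted(tcs)

    def test_iid_indicator_correlation_time_near_delta_t(self):
        # Memoryless indicator: t_c should estimate ~Delta t; allow the
        # sampling noise of finite chains but require 95/100 replicates
        # inside [Delta t, 2 Delta t].
        hits = 0
        for rep in range(100):
            rng = np.random.default_rng(1000 + rep)
            labels = ["W" if b else "N2" for b in rng.random(2000) < 0.5]
            rho = normalize_autocov(
                autocovariance(indicator_series(labels, "W"), 120))
            t_c, _ = autocorrelation_time(rho, delta_t=30)
            if 30.0 <= t_c <= 60.0:
                hits += 1
        assert hits >= 95


class TestGroupAverage:
    def test_identical_profiles_pass_through(self):
        g = np.array([1.0, 0.5, 0.2])
        rho, se = group_average_autocov([g, g, g])
        assert np.allclose(rho, g / g[0])
        assert np.allclose(se, 0.0)
        assert rho[0] == 1.0

    def test_mean_then_normalize_not_mean_of_rhos(self):
        rho, _ = group_average_autocov([np.array([1.0, 0.5]), np.array([3.0, 0.5])])
        # group gamma = [2, 0.5] -> rho = [1, 0.25]; averaging individual
        # rhos would instead give [1, (0.5 + 1/6)/2].
        assert np.allclose(rho, [1.0, 0.25])

    def test_zero_variance_subject_skipped(self):
        good = np.array([1.0, 0.4])
        rho, _ = group_average_autocov([good, np.zeros(2), good])
        assert np.allclose(rho, [1.0, 0.4])


class TestTransitionMatrixEstimation:
    def test_manual_count_single_hypnogram(self):
        T = estimate_transition_matrix([["W", "W", "W", "N1"]], smoothing=0.0)
        assert np.allclose(T.row("W"), [2 / 3, 1 / 3, 0, 0, 0])

    def test_unseen_predecessor_rows_uniform(self):
        T = estimate_transition_matrix([["N2", "N2", "N2"]], smoothing=0.0)
        assert np.allclose(T.row("N2"), [0, 0, 1, 0, 0])
        for stage in ("W", "N1", "N3", "REM"):
            assert np.allclose(T.row(stage), 0.2)

    def test_rows_always_stochastic(self):
        rng = np.random.default_rng(3)
        hyps = [[STAGES[i] for i in rng.integers(0, 5, size=50)] for _ in range(4)]
        T = estimate_transition_matrix(hyps, smoothing=0.5)
        assert np.allclose(T.probs.sum(axis=1), 1.0)

    def test_counting_never_crosses_subject_boundaries(self):
        # ...N3] + [W... must not contribute an N3->W transition.
        T = estimate_transition_matrix([["N3", "N3"], ["W", "W"]])
        assert T.row("N3")[0] == 0.0

    def test_non_stochastic_matrix_rejected(self):
        with pytest.raises(InvalidInputError):
            TransitionMatrix(np.full((5, 5), 0.3))


class TestTransitionVector:
    def test_one_hot_extracts_matrix_row(self):
        rng = np.random.default_rng(11)
        probs = rng.random((5, 5))
        T = TransitionMatrix(probs / probs.sum(axis=1, keepdims=True))
        for i in range(5):
            onehot = np.zeros(5)
            onehot[i] = 1.0
            assert np.allclose(transition_vector(onehot, T), T.probs[i])

    def test_uniform_input_doubly_stochastic_matrix(self):
        T = TransitionMatrix(np.full((5, 5), 0.2))
        v = transition_vector(np.full(5, 0.2), T)
        assert np.allclose(v, 0.2)

    def test_matches_dot_product_oracle_and_simplex(self):
        rng = np.random.default_rng(17)
        probs = rng.random((5, 5))
        T = TransitionMatrix(probs / probs.sum(axis=1, keepdims=True))
        p = np.array([0.5, 0.5, 0, 0, 0])
        oracle = np.array([sum(p[i] * T.probs[i, j] for i in range(5))
                           for j in range(5)])
        v = transition_vector(p, T)
        assert np.allclose(v, oracle, atol=1e-12)
        assert v.sum() == pytest.approx(1.0)

    def test_dimension_mismatch_rejected(self):
        T = TransitionMatrix(np.eye(5))
        with pytest.raises(InvalidInputError):
            transition_vector(np.array([1.0, 0.0]), T)


class TestInitialDistribution:
    def test_one_hot_at_wake_any_order(self):
        p0 = initial_distribution()
        assert p0.tolist() == [1, 0, 0, 0, 0]
        p0 = initial_distribution(("N2", "REM", "W"))
        assert p0.tolist() == [0, 0, 1]
        assert p0.sum() == 1.0

    def test_missing_wake_rejected(self):
        with pytest.raises(InvalidInputError):
            initial_distribution(("N1", "N2"))
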