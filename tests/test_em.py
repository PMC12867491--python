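"""Post-hoc EM refinement: formula oracles, ascent property, entropy filter."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import norm

from raremix.em import (FILTERED, AbundantClusterParams, EmState,
                        assign_final_labels, default_entropy_threshold,
                        e_step, entropy_filter, initialize_em, m_step,
                        observed_loglik, responsibility_entropy, run_em)
from raremix.gibbs import Chain, MultiSubjectMatrix


def _data(X, subject=None, D=1):
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if subject is None:
        subject = np.zeros(X.shape[0], dtype=int)
    return MultiSubjectMatrix(X, np.asarray(subject), [f"s{d}" for d in range(D)])


def _chain(pi, mu, sigma2):
    """Single-draw chain whose posterior means are the given arrays."""
    pi = np.atleast_2d(np.asarray(pi, float))[None]
    mu = np.atleast_2d(np.asarray(mu, float))[None]
    sigma2 = np.atleast_2d(np.asarray(sigma2, float))[None]
    K = pi.shape[2]
    return Chain(np.ones((1, K), int), pi, mu, sigma2, np.empty(0, int), 0, 1, 0)


def _abundant(G=1, K_a=2, loc=100.0):
    means = np.full((G, K_a), loc) + np.arange(K_a)[None, :]
    return AbundantClusterParams(means, np.ones((G, K_a)))


class TestInitialize:
    @pytest.mark.parametrize("K_a", [1, 2, 3, 5])
    def test_abundant_mass_totals_one_tenth(self, K_a):
        chain = _chain([[0.6, 0.4]], [[0.0, 5.0]], [[0.1, 0.2]])
        state = initialize_em(chain, np.array([0, 1]), _abundant(K_a=K_a))
        ab_mass = state.pi[:, state.K_rare:].sum(axis=1)
        np.testing.assert_allclose(ab_mass, 0.1, atol=1e-12)
        # equal split over abundant components
        np.testing.assert_allclose(state.pi[:, state.K_rare:], 0.1 / K_a,
                                   atol=1e-12)

    def test_rare_mass_proportional_to_posterior_mixing(self):
        chain = _chain([[0.6, 0.2, 0.2]], [[0.0, 5.0, 9.0]],
                       [[0.1, 0.1, 0.1]])
        state = initialize_em(chain, np.array([0, 1]), _abundant())
        # rare clusters 0,1 had posterior mixing 0.6 / 0.2 -> ratio 3:1
        assert state.pi[0, 0] / state.pi[0, 1] == pytest.approx(3.0)
        assert state.pi[0, :2].sum() == pytest.approx(0.9)

    def test_no_rare_clusters_is_an_error(self):
        chain = _chain([[1.0]], [[0.0]], [[1.0]])
        with pytest.raises(ValueError, match="no rare clusters"):
            initialize_em(chain, np.array([], dtype=int), _abundant())


class TestEStep:
    def test_symmetric_cell_is_half_half(self):
        state = EmState(np.array([[0.5, 0.5]]), np.array([[-1.0, 1.0]]),
                        np.array([[1.0, 1.0]]), K_rare=1)
        omega = e_step(_data([[0.0]]), state)
        np.testing.assert_allclose(omega, [[0.5, 0.5]], atol=1e-12)

    def test_far_abundant_component_gets_no_mass(self):
        state = EmState(np.array([[0.5, 0.5]]), np.array([[0.0, 100.0]]),
                        np.array([[1.0, 1.0]]), K_rare=1)
        omega = e_step(_data([[0.0]]), state)
        assert omega[0, 0] == pytest.approx(1.0, abs=1e-12)

    def test_matches_hand_normalized_densities(self, rng):
        # 3 components, G=1: compare against the direct formula
        pi = np.array([[0.5, 0.3, 0.2]])
        mu = np.array([[-1.0, 0.5, 2.0]])
        s2 = np.array([[0.5, 1.0, 2.0]])
        state = EmState(pi, mu, s2, K_rare=1)
        X = rng.normal(size=(7, 1))
        omega = e_step(_data(X), state)
        dens = pi * norm.pdf(X, mu, np.sqrt(s2))
        np.testing.assert_allclose(omega, dens / dens.sum(axis=1, keepdims=True),
                                   atol=1e-12)


class TestMStep:
    def test_single_cell_single_component(self):
        state = EmState(np.array([[1.0]]), np.array([[0.0]]),
                        np.array([[1.0]]), K_rare=1)
        new = m_step(_data([[3.0]]), np.array([[1.0]]), state)
        assert new.pi[0, 0] == 1.0
        assert new.mu[0, 0] == 3.0
        assert new.sigma2[0, 0] == pytest.approx(1e-8)  # floored

    def test_hard_responsibilities_give_sample_means(self, rng):
        X = rng.normal(size=(10, 2))
        omega = np.zeros((10, 2))
        omega[:6, 0] = 1.0
        omega[6:, 1] = 1.0
        state = EmState(np.array([[0.5, 0.5]]), np.zeros((2, 2)),
                        np.ones((2, 2)), K_rare=2)
        new = m_step(_data(X), omega, state)
        np.testing.assert_allclose(new.mu[:, 0], X[:6].mean(axis=0), atol=1e-12)
        np.testing.assert_allclose(new.mu[:, 1], X[6:].mean(axis=0), atol=1e-12)

    def test_matches_brute_force_formulas(self, rng):
        # random responsibilities, 2 subjects: evaluate the three update
        # formulas directly and compare to 1e-12
        X = rng.normal(size=(9, 2))
        subject = np.array([0] * 4 + [1] * 5)
        data = _data(X, subject, D=2)
        omega = rng.dirichlet(np.ones(3), size=9)
        state = EmState(np.tile([0.4, 0.4, 0.2], (2, 1)), rng.normal(size=(2, 3)),
                        np.ones((2, 3)), K_rare=2)
        new = m_step(data, omega, state)
        for d in range(2):
            rows = subject == d
            np.testing.assert_allclose(
                new.pi[d], omega[rows].sum(axis=0) / rows.sum(), atol=1e-12)
        for k in range(2):  # rare components only
            w = omega[:, k]
            mu_k = (w[:, None] * X).sum(axis=0) / w.sum()
            var_k = (w[:, None] * (X - mu_k) ** 2).sum(axis=0) / w.sum()
            np.testing.assert_allclose(new.mu[:, k], mu_k, atol=1e-12)
            np.testing.assert_allclose(new.sigma2[:, k], var_k, atol=1e-12)
        # abundant column untouched
        np.testing.assert_array_equal(new.mu[:, 2], state.mu[:, 2])
        np.testing.assert_array_equal(new.sigma2[:, 2], state.sigma2[:, 2])

    def test_zero_responsibility_component_is_frozen_with_warning(self):
        state = EmState(np.array([[0.5, 0.25, 0.25]]),
                        np.array([[0.0, 5.0, 9.0]]),
                        np.array([[1.0, 1.0, 1.0]]), K_rare=2)
        omega = np.array([[1.0, 0.0, 0.0], [1.0, 0.0, 0.0]])
        with pytest.warns(RuntimeWarning, match="zero responsibility"):
            new = m_step(_data([[0.1], [-0.1]]), omega, state)
        assert new.mu[0, 1] == 5.0 and new.sigma2[0, 1] == 1.0


class TestRunEm:
    def test_loglik_non_decreasing(self, rng):
        X = np.vstack([rng.normal(-2, 0.5, size=(20, 1)),
                       rng.normal(2, 0.5, size=(20, 1))])
        state = EmState(np.array([[0.5, 0.5]]), np.array([[-1.0, 1.0]]),
                        np.array([[1.0, 1.0]]), K_rare=2)
        final, _ = run_em(_data(X), state, max_iter=100, tol=1e-10)
        ll = np.array(final.loglik)
        assert (np.diff(ll) >= -1e-8 * np.maximum(1.0, np.abs(ll[:-1]))).all()

    def test_already_converged_input_stops_immediately(self, rng):
        X = rng.normal(size=(15, 1))
        state = EmState(np.array([[1.0]]), np.array([[X.mean()]]),
                        np.array([[X.var()]]), K_rare=1)
        final, _ = run_em(_data(X), state, max_iter=50, tol=1e-6)
        assert len(final.loglik) <= 3

    def test_recovers_well_separated_planted_components(self, rng):
        n = 300
        X = np.vstack([rng.normal(-4, 0.7, size=(n, 1)),
                       rng.normal(4, 0.7, size=(n, 1))])
        state = EmState(np.array([[0.5, 0.5]]), np.array([[-1.0, 1.0]]),
                        np.array([[2.0, 2.0]]), K_rare=2)
        final, _ = run_em(_data(X), state, max_iter=200, tol=1e-9)
        se = 0.7 / np.sqrt(n)
        assert abs(final.mu[0, 0] - (-4.0)) < 3 * se
        assert abs(final.mu[0, 1] - 4.0) < 3 * se

    def test_one_pass_reproduces_classical_gmm_updates(self, rng):
        # with no abundant components and hard init, a single E+M pass is
        # the textbook Gaussian-mixture update
        X = rng.normal(size=(12, 1))
        state = EmState(np.array([[0.5, 0.5]]), np.array([[-0.5, 0.5]]),
                        np.array([[1.0, 1.0]]), K_rare=2)
        data = _data(X)
        omega = e_step(data, state)
        new = m_step(data, omega, state)
        w = omega
        np.testing.assert_allclose(new.pi[0], w.mean(axis=0), atol=1e-12)
        mu = (w * X).sum(axis=0) / w.sum(axis=0)
        var = (w * (X - mu) ** 2).sum(axis=0) / w.sum(axis=0)
        np.testing.assert_allclose(new.mu[0], mu, atol=1e-12)
        np.testing.assert_allclose(new.sigma2[0], var, atol=1e-12)


class TestEntropyFilter:
    def test_one_hot_retained_uniform_removed(self):
        for K in (2, 5, 10):
            one_hot = np.eye(K)[:1]
            uniform = np.full((1, K), 1.0 / K)
            assert entropy_filter(one_hot, K)[0]
            assert not entropy_filter(uniform, K)[0]

    def test_nearly_one_hot_is_still_removed(self):
        # entropy of (0.999, 0.001) ~ 0.00791 > log(2)/1000 ~ 0.000693
        omega = np.array([[0.999, 0.001]])
        assert responsibility_entropy(omega)[0] == pytest.approx(0.00791, abs=5e-5)
        assert not entropy_filter(omega, 2)[0]

    def test_threshold_value(self):
        assert default_entropy_threshold(10) == pytest.approx(np.log(10) / 1000)

    def test_monotone_in_threshold(self, rng):
        omega = rng.dirichlet(np.full(4, 0.05), size=50)
        low = entropy_filter(omega, 4, threshold=1e-4)
        high = entropy_filter(omega, 4, threshold=1e-2)
        assert (high | ~low).all()  # raising threshold never removes a kept cell

    @settings(derandomize=True, max_examples=30)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_entropy_invariant_to_component_permutation(self, seed):
        r = np.random.default_rng(seed)
        omega = r.dirichlet(np.ones(5), size=8)
        perm = r.permutation(5)
        np.testing.assert_allclose(responsibility_entropy(omega),
                                   responsibility_entropy(omega[:, perm]),
                                   atol=1e-12)


class TestFinalLabels:
    def test_rare_peak_abundant_peak_and_tie(self):
        omega = np.array([
            [0.05, 0.90, 0.05],   # peaked on rare component 1
            [0.10, 0.10, 0.80],   # abundant argmax -> filtered
            [0.45, 0.45, 0.10],   # tie -> lowest index
        ])
        labels = assign_final_labels(omega, np.array([True, True, True]),
                                     K_rare=2)
        assert labels.tolist() == [1, FILTERED, 0]

    def test_entropy_mask_overrides(self):
        omega = np.array([[0.9, 0.1]])
        labels = assign_final_labels(omega, np.array([False]), K_rare=2)
        assert labels[0] == FILTERED


def test_observed_loglik_matches_direct_sum(rng):
    pi = np.array([[0.3, 0.7]])
    mu = np.array([[0.0, 2.0]])
    s2 = np.array([[1.0, 0.5]])
    state = EmState(pi, mu, s2, K_rare=1)
    X = rng.normal(size=(5, 1))
    direct = np.log((pi * norm.pdf(X, mu, np.sqrt(s2))).sum(axis=1)).sum()
    assert observed_loglik(_data(X), state) == pytest.approx(direct, abs=1e-10)
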