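import itertools

import numpy as np
import pytest

from symptomnet import (
    IsingNetwork,
    conditional_prob,
    enumerate_distribution,
    log_score,
    sample_exact,
    sample_gibbs,
)


def _logistic(x):
    return 1.0 / (1.0 + np.exp(-x))


class TestNetworkInvariants:
    def test_asymmetric_weights_rejected(self):
        W = np.array([[0.0, 1.0], [0.5, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            IsingNetwork(weights=W, thresholds=np.zeros(2))

    def test_nonzero_diagonal_rejected(self):
        W = np.eye(2)
        with pytest.raises(ValueError, match="diagonal"):
            IsingNetwork(weights=W, thresholds=np.zeros(2))

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            IsingNetwork(
                weights=np.zeros((2, 2)),
                thresholds=np.zeros(2),
                labels=("a", "a"),
            )


class TestLogScore:
    def test_all_zero_state_scores_zero(self, random_net5):
        assert log_score(random_net5, np.zeros(5)) == 0.0

    def test_pair_interaction(self, pair_net):
        assert log_score(pair_net, np.array([1, 1])) == pytest.approx(
            np.log(2.0)
        )

    def test_matches_term_by_term_summation(self, random_net5):
        rng = np.random.default_rng(0)
        for _ in range(10):
            x = rng.integers(0, 2, 5)
            expected = sum(
                random_net5.thresholds[i] * x[i] for i in range(5)
            ) + sum(
                random_net5.weights[i, j] * x[i] * x[j]
                for i in range(5)
                for j in range(i + 1, 5)
            )
            assert log_score(random_net5, x) == pytest.approx(expected)

    def test_dimension_mismatch_rejected(self, pair_net):
        with pytest.raises(ValueError):
            log_score(pair_net, np.array([1, 0, 1]))


class TestEnumeration:
    def test_independence_is_uniform(self):
        net = IsingNetwork(weights=np.zeros((2, 2)), thresholds=np.zeros(2))
        _, probs = enumerate_distribution(net)
        assert np.allclose(probs, 0.25)

    def test_pair_coupling_probabilities(self, pair_net):
        states, probs = enumerate_distribution(pair_net)
        table = {tuple(s): p for s, p in zip(states.tolist(), probs)}
        # weights exp(score) are (1, 1, 1, 2), normalized by 5
        assert table[(0, 0)] == pytest.approx(0.2)
        assert table[(1, 0)] == pytest.approx(0.2)
        assert table[(0, 1)] == pytest.approx(0.2)
        assert table[(1, 1)] == pytest.approx(0.4)

    def test_probabilities_normalized(self, random_net5):
        _, probs = enumerate_distribution(random_net5)
        assert probs.sum() == pytest.approx(1.0, abs=1e-12)

    def test_large_p_refused(self):
        p = 21
        net = IsingNetwork(weights=np.zeros((p, p)), thresholds=np.zeros(p))
        with pytest.raises(ValueError, match="gibbs"):
            enumerate_distribution(net)

    def test_relabeling_permutes_distribution(self):
        rng = np.random.default_rng(7)
        p = 4
        W = np.zeros((p, p))
        for i in range(p):
            for j in range(i + 1, p):
                W[i, j] = W[j, i] = rng.normal()
        tau = rng.normal(size=p)
        net = IsingNetwork(weights=W, thresholds=tau)
        perm = np.array([2, 0, 3, 1])
        net_p = IsingNetwork(
            weights=W[np.ix_(perm, perm)], thresholds=tau[perm]
        )
        states, probs = enumerate_distribution(net)
        states_p, probs_p = enumerate_distribution(net_p)
        lookup = {tuple(s): pr for s, pr in zip(states_p.tolist(), probs_p)}
        for s, pr in zip(states.tolist(), probs):
            assert lookup[tuple(np.asarray(s)[perm])] == pytest.approx(pr)


class TestConditionalProb:
    def test_isolated_node_at_zero_threshold(self):
        net = IsingNetwork(weights=np.zeros((3, 3)), thresholds=np.zeros(3))
        assert conditional_prob(net, 0, np.zeros(3)) == pytest.approx(0.5)

    def test_single_active_neighbor(self):
        W = np.zeros((2, 2))
        W[0, 1] = W[1, 0] = np.log(3.0)
        net = IsingNetwork(weights=W, thresholds=np.zeros(2))
        assert conditional_prob(net, 0, np.array([0, 1])) == pytest.approx(
            0.75
        )

    def test_bayes_identity_against_enumeration(self, random_net5):
        states, probs = enumerate_distribution(random_net5)
        lookup = {tuple(s): pr for s, pr in zip(states.tolist(), probs)}
        for rest in itertools.product((0, 1), repeat=4):
            x1 = (1,) + rest
            x0 = (0,) + rest
            expected = lookup[x1] / (lookup[x1] + lookup[x0])
            got = conditional_prob(random_net5, 0, np.array(x1))
            assert got == pytest.approx(expected, abs=1e-12)

    def test_index_out_of_range(self, pair_net):
        with pytest.raises(IndexError):
            conditional_prob(pair_net, 5, np.zeros(2))


class TestSampleExact:
    def test_deterministic_under_seed(self, random_net5):
        a = sample_exact(random_net5, 100, seed=9)
        b = sample_exact(random_net5, 100, seed=9)
        assert np.array_equal(a, b)

    def test_independent_marginals_are_logistic(self):
        tau = np.array([-1.0, 0.0, 1.0])
        net = IsingNetwork(weights=np.zeros((3, 3)), thresholds=tau)
        X = sample_exact(net, 50_000, seed=1)
        assert np.all(np.abs(X.mean(axis=0) - _logistic(tau)) < 0.01)

    def test_pair_cooccurrence_frequency(self, pair_net):
        X = sample_exact(pair_net, 100_000, seed=2)
        both = np.mean((X[:, 0] == 1) & (X[:, 1] == 1))
        assert both == pytest.approx(0.4, abs=0.005)


class TestSampleGibbs:
    def test_free_nodes_are_fair_coins(self):
        net = IsingNetwork(weights=np.zeros((3, 3)), thresholds=np.zeros(3))
        X = sample_gibbs(net, 20_000, burn_in=100, thin=1, seed=3)
        assert np.all(np.abs(X.mean(axis=0) - 0.5) < 0.02)

    def test_independent_marginals_are_logistic(self):
        tau = np.array([-0.5, 0.8])
        net = IsingNetwork(weights=np.zeros((2, 2)), thresholds=tau)
        X = sample_gibbs(net, 50_000, burn_in=200, thin=1, seed=4)
        assert np.all(np.abs(X.mean(axis=0) - _logistic(tau)) < 0.02)

    def test_deterministic_under_seed(self, random_net5):
        a = sample_gibbs(random_net5, 500, burn_in=50, thin=2, seed=5)
        b = sample_gibbs(random_net5, 500, burn_in=50, thin=2, seed=5)
        assert np.array_equal(a, b)

    def test_matches_enumeration_in_total_variation(self, random_net5):
        # oracle equivalence: empirical Gibbs distribution vs exact table
        X = sample_gibbs(random_net5, 200_000, burn_in=500, thin=2, seed=6)
        _, probs = enumerate_distribution(random_net5)
        codes = X.astype(np.int64) @ (1 << np.arange(5, dtype=np.int64))
        emp = np.bincount(codes, minlength=32) / len(codes)
        tv = 0.5 * np.abs(emp - probs).sum()
        assert tv < 0.01
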