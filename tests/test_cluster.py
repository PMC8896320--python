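"""Affinity propagation: message updates, convergence, and fidelity
against independent references (sklearn and brute-force exemplar search)."""

import itertools

import numpy as np
import pytest

from pwmclust import (APParams, ConvergenceError, PWMCollection, cluster,
                      net_similarity, set_preference, similarity_matrix,
                      update_availability, update_responsibility)
from pwmclust.similarity import SimilarityMatrix

from conftest import random_pwm


def random_similarity(n: int, rng: np.random.Generator) -> SimilarityMatrix:
    v = rng.uniform(0, 1, size=(n, n))
    v = (v + v.T) / 2
    np.fill_diagonal(v, np.nan)
    return SimilarityMatrix(v, [f"p{i}" for i in range(n)])


def brute_force_best_partition(S: np.ndarray) -> float:
    """Optimal net similarity over every nonempty exemplar subset; each
    point assigned to its most similar exemplar."""
    n = S.shape[0]
    best = -np.inf
    for r in range(1, n + 1):
        for subset in itertools.combinations(range(n), r):
            ex = np.array(subset)
            labels = ex[S[:, ex].argmax(axis=1)]
            labels[ex] = ex
            best = max(best, S[np.arange(n), labels].sum())
    return best


class TestPreference:
    def test_uniform_offdiag_median(self):
        v = np.full((3, 3), 0.6)
        np.fill_diagonal(v, np.nan)
        S = set_preference(SimilarityMatrix(v, list("abc")), "median")
        np.testing.assert_allclose(np.diag(S.values), 0.6)
        assert S.diagonal_policy == "preference"

    def test_min_mode(self, rng):
        S = random_similarity(5, rng)
        out = set_preference(S, "min")
        off = S.values[~np.eye(5, dtype=bool)]
        np.testing.assert_allclose(np.diag(out.values), off.min())

    def test_hand_median_4x4(self):
        v = np.full((4, 4), np.nan)
        vals = [0.1, 0.3, 0.5, 0.7, 0.8, 0.9]
        k = 0
        for i in range(4):
            for j in range(i + 1, 4):
                v[i, j] = v[j, i] = vals[k]
                k += 1
        S = set_preference(SimilarityMatrix(v, list("abcd")), "median")
        np.testing.assert_allclose(np.diag(S.values), 0.6)

    def test_value_mode_requires_value(self, rng):
        with pytest.raises(ValueError):
            set_preference(random_similarity(3, rng), "value")


class TestMessageUpdates:
    def test_first_iteration_n2_responsibility(self):
        p, s = 0.4, 0.7
        S = np.array([[p, s], [s, p]])
        R = update_responsibility(S, np.zeros((2, 2)))
        assert R[0, 1] == pytest.approx(s - p)
        assert R[1, 0] == pytest.approx(s - p)

    def test_equal_similarities_symmetric_responsibilities(self):
        S = np.full((4, 4), 0.5)
        R = update_responsibility(S, np.zeros((4, 4)))
        off = R[~np.eye(4, dtype=bool)]
        np.testing.assert_allclose(off, off[0])

    def test_availability_zero_when_no_positive_responsibility(self):
        R = -np.abs(np.random.default_rng(0).normal(size=(5, 5)))
        A = update_availability(R)
        np.testing.assert_allclose(np.diag(A), 0.0)

    def test_availability_offdiagonal_never_positive(self, rng):
        R = rng.normal(size=(6, 6))
        A = update_availability(R)
        off = A[~np.eye(6, dtype=bool)]
        assert np.all(off <= 1e-12)
        assert np.all(np.diag(A) >= -1e-12)

    def test_availability_hand_3x3(self):
        R = np.array([[0.2, -0.1, 0.3],
                      [0.4, -0.5, -0.2],
                      [-0.3, 0.6, 0.1]])
        A = update_availability(R)
        # diagonal: sum of positive off-diagonal responsibilities per column
        np.testing.assert_allclose(np.diag(A), [0.4, 0.6, 0.3])
        # off-diagonal: min(0, R(k,k) + sum_{i' not in {i,k}} max(0, R(i',k)))
        assert A[0, 1] == pytest.approx(min(0, -0.5 + 0.6))
        assert A[1, 0] == pytest.approx(min(0, 0.2 + 0.0))
        assert A[2, 0] == pytest.approx(min(0, 0.2 + 0.4))
        assert A[0, 2] == pytest.approx(min(0, 0.1 + (-0.0)))
        assert A[2, 1] == pytest.approx(-0.5)   # -0.5 + max(0, -0.1)

    def test_criterion_is_sum_of_messages(self, rng):
        S = set_preference(random_similarity(6, rng))
        res = cluster(S)
        np.testing.assert_allclose(res.state.C,
                                   res.state.R + res.state.A, atol=1e-12)


class TestCluster:
    def test_two_identical_pwms_merge(self, rng):
        p = random_pwm("x", 6, rng)
        coll = PWMCollection([p.with_name("a"), p.with_name("b")])
        S = set_preference(similarity_matrix(coll), "median")
        res = cluster(S)
        assert res.n_clusters == 1
        assert res.labels[0] == res.labels[1]

    def test_no_affinity_gives_singletons(self):
        v = np.zeros((4, 4))
        np.fill_diagonal(v, np.nan)
        S = set_preference(SimilarityMatrix(v, list("abcd")), "value", 0.9)
        res = cluster(S)
        assert res.n_clusters == 4
        np.testing.assert_array_equal(res.labels, np.arange(4))

    def test_exemplars_self_assigned(self, rng):
        S = set_preference(random_similarity(8, rng))
        res = cluster(S)
        for ex in res.exemplars:
            assert res.labels[ex] == ex
        assert set(res.labels) <= set(res.exemplars)

    def test_deterministic(self, rng):
        S = set_preference(random_similarity(9, rng))
        r1, r2 = cluster(S), cluster(S)
        assert r1.exemplars == r2.exemplars
        np.testing.assert_array_equal(r1.labels, r2.labels)

    def test_zero_iterations_cannot_produce_exemplars(self, rng):
        S = set_preference(random_similarity(4, rng))
        with pytest.raises(ConvergenceError):
            cluster(S, APParams(max_iter=0))

    def test_matches_sklearn_reference(self):
        """Exemplar sets agree with sklearn's affinity propagation (the
        independent Frey-Dueck reference) on >= 95% of seeded instances."""
        from sklearn.cluster import AffinityPropagation
        agree = 0
        trials = 40
        for seed in range(trials):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(5, 11))
            S = set_preference(random_similarity(n, rng), "median")
            res = cluster(S)
            pref = float(S.values[0, 0])
            ref = AffinityPropagation(
                affinity="precomputed", damping=0.9, max_iter=1000,
                convergence_iter=50, preference=pref, random_state=0,
            ).fit(S.values)
            if set(ref.cluster_centers_indices_) == set(res.exemplars):
                agree += 1
        assert agree >= 0.95 * trials

    def test_net_similarity_near_brute_force_optimum(self):
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            n = int(rng.integers(4, 9))
            S = set_preference(random_similarity(n, rng), "median")
            res = cluster(S)
            achieved = net_similarity(S.values, res.labels)
            optimal = brute_force_best_partition(S.values)
            assert achieved >= 0.9 * optimal

    def test_raising_preference_rarely_reduces_cluster_count(self):
        violations = 0
        trials = 20
        for seed in range(trials):
            rng = np.random.default_rng(200 + seed)
            S = random_similarity(8, rng)
            lo = cluster(set_preference(S, "value", 0.1))
            hi = cluster(set_preference(S, "value", 0.9))
            if hi.n_clusters < lo.n_clusters:
                violations += 1
        assert violations <= 0.05 * trials + 1

    def test_damping_bounds_enforced(self):
        with pytest.raises(ValueError):
            APParams(damping=0.3)
        with pytest.raises(ValueError):
            APParams(damping=1.0)
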