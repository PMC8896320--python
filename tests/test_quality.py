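"""Cluster quality assessment, Z-score outlier filtering and
representative motif construction."""

import numpy as np
import pytest

from pwmclust import (PWM, PWMCollection, QualityParams, assess_cluster,
                      generate_family, label_distribution,
                      representative_motif, similarity_matrix,
                      z_score_matrix)
from pwmclust.synthetic import FamilySpec, random_outlier_pwm
from pwmclust.similarity import SimilarityMatrix

from conftest import one_hot_pwm, random_pwm


def sim_from_dense(values, names):
    v = np.array(values, dtype=float)
    np.fill_diagonal(v, np.nan)
    return SimilarityMatrix(v, names)


def planted_outlier_matrix(seed: int):
    """10 similar members + 1 planted dissimilar PWM, via the similarity
    module on a synthetic family."""
    fam, _ = generate_family(
        FamilySpec("CACGTGCA", n_members=10, concentration=50, name="FAM"),
        seed=seed)
    rng = np.random.default_rng(seed + 10_000)
    out = random_outlier_pwm("ZOUT", 8, rng)
    coll = PWMCollection(list(fam) + [out])
    return similarity_matrix(coll), coll


class TestZScoreMatrix:
    def test_identical_members_all_zero(self):
        S = np.full((4, 4), 1.0)
        Z = z_score_matrix(S)
        off = ~np.eye(4, dtype=bool)
        np.testing.assert_allclose(Z[off], 0.0)

    def test_hand_row_arithmetic(self):
        # row 0 off-diagonal scores (0.9, 0.9, 0.3): mean 0.7,
        # population sd sqrt(0.08); z of the 0.3 entry = -0.4/sd < -1
        S = np.array([
            [1.0, 0.9, 0.9, 0.3],
            [0.9, 1.0, 0.9, 0.3],
            [0.9, 0.9, 1.0, 0.3],
            [0.3, 0.3, 0.3, 1.0],
        ])
        Z = z_score_matrix(S)
        sd = np.sqrt(0.08)
        assert Z[0, 3] == pytest.approx((0.3 - 0.7) / sd)
        assert Z[0, 3] < -1
        assert Z[0, 1] == pytest.approx((0.9 - 0.7) / sd)

    def test_rows_standardized_to_zero_mean(self, rng):
        v = rng.uniform(0, 1, (6, 6))
        S = (v + v.T) / 2
        Z = z_score_matrix(S)
        for i in range(6):
            row = np.delete(Z[i], i)
            assert abs(row.mean()) < 1e-9

    def test_too_small_cluster_rejected(self):
        with pytest.raises(ValueError):
            z_score_matrix(np.ones((2, 2)))


class TestAssessCluster:
    def test_planted_outlier_flagged_and_removed(self):
        S, _ = planted_outlier_matrix(seed=0)
        rep = assess_cluster(S, "c0")
        counts = rep.low_z_counts
        assert counts["ZOUT"] == max(counts.values())
        assert "ZOUT" in rep.candidates
        assert rep.removed == ["ZOUT"]

    def test_removal_increases_mean_score(self):
        S, _ = planted_outlier_matrix(seed=1)
        rep = assess_cluster(S, "c0")
        keep = [m for m in rep.members if m not in rep.removed]
        rep2 = assess_cluster(S.submatrix(keep), "c0b")
        assert rep2.mean_score > rep.mean_score

    def test_pure_cluster_untouched_and_good(self, rng):
        p = random_pwm("m", 8, rng)
        coll = PWMCollection([p.with_name(f"m{i}") for i in range(8)])
        rep = assess_cluster(similarity_matrix(coll), "pure")
        assert rep.removed == [] and rep.label == "good"
        assert rep.mean_score == pytest.approx(1.0)

    def test_mean_threshold_is_inclusive(self):
        v = np.full((4, 4), 0.8)
        rep = assess_cluster(sim_from_dense(v, list("abcd")), "t")
        assert rep.mean_score == pytest.approx(0.8)
        assert rep.label == "good"

    def test_singleton_and_pair_never_filtered(self, rng):
        one = sim_from_dense([[np.nan]], ["a"])
        rep = assess_cluster(one, "s")
        assert rep.label == "singleton" and rep.removed == []
        v = np.full((2, 2), 0.3)
        rep2 = assess_cluster(sim_from_dense(v, ["a", "b"]), "p")
        assert rep2.removed == [] and rep2.label == "bad"

    def test_member_order_invariance(self):
        S, coll = planted_outlier_matrix(seed=3)
        rep = assess_cluster(S, "c")
        perm = list(reversed(S.names))
        rep_perm = assess_cluster(S.submatrix(perm), "c")
        assert set(rep.removed) == set(rep_perm.removed)
        assert rep.mean_score == pytest.approx(rep_perm.mean_score)

    def test_sensitivity_and_specificity_over_trials(self, rng):
        """Planted outliers are caught, pure clusters left intact."""
        trials = 15
        caught = 0
        false_any = 0
        for t in range(trials):
            S, _ = planted_outlier_matrix(seed=500 + t)
            if assess_cluster(S, "c").removed == ["ZOUT"]:
                caught += 1
            fam, _ = generate_family(
                FamilySpec("TGACTCAT", n_members=10, concentration=50,
                           name="PURE"), seed=900 + t)
            if assess_cluster(similarity_matrix(fam), "p").removed:
                false_any += 1
        assert caught >= 0.9 * trials
        assert false_any <= 0.1 * trials


class TestLabelDistribution:
    def _pure_report(self, n, cid):
        v = np.full((n, n), 0.95)
        return assess_cluster(sim_from_dense(v, [f"{cid}m{i}"
                                                 for i in range(n)]), cid)

    def _bad_report(self, cid):
        v = np.full((2, 2), 0.2)
        return assess_cluster(sim_from_dense(v, [f"{cid}a", f"{cid}b"]), cid)

    def test_all_pure_is_all_good(self):
        reports = [self._pure_report(4, f"c{i}") for i in range(5)]
        dist = label_distribution(reports)
        assert dist["good"] == pytest.approx(100.0)

    def test_one_bad_among_nine_pure(self):
        reports = [self._pure_report(4, f"c{i}") for i in range(9)]
        reports.append(self._bad_report("x"))
        dist = label_distribution(reports)
        assert dist["good"] == pytest.approx(90.0)
        assert dist["bad"] == pytest.approx(10.0)
        assert sum(dist.values()) == pytest.approx(100.0)

    def test_matches_hand_recount_on_synthetic_mix(self):
        reports = ([self._pure_report(3, f"g{i}") for i in range(3)]
                   + [self._bad_report("b0")]
                   + [assess_cluster(sim_from_dense([[np.nan]], ["solo"]),
                                     "s0")])
        dist = label_distribution(reports)
        assert dist["good"] == pytest.approx(100 * 3 / 5)
        assert dist["bad"] == pytest.approx(100 * 1 / 5)
        assert dist["singleton"] == pytest.approx(100 * 1 / 5)


class TestRepresentativeMotif:
    def test_identical_members_reproduce_member(self, rng):
        p = random_pwm("m0", 6, rng)
        coll = PWMCollection([p.with_name(f"m{i}") for i in range(3)])
        rep = representative_motif(coll, "m0")
        np.testing.assert_allclose(rep.pwm.matrix, p.matrix, atol=1e-9)
        assert list(rep.support) == [3] * 6

    def test_equal_length_offset_zero_is_elementwise_mean(self, rng):
        a = random_pwm("a", 5, rng)
        # same motif with mild perturbation so offset 0 stays optimal
        noisy = 0.9 * a.matrix + 0.1 * np.full((5, 4), 0.25)
        b = PWM("b", noisy)
        rep = representative_motif(PWMCollection([a, b]), "a")
        expected = (a.matrix + b.matrix) / 2
        expected /= expected.sum(axis=1, keepdims=True)
        np.testing.assert_allclose(rep.pwm.matrix, expected, atol=1e-9)

    def test_shifted_member_projection_hand_table(self):
        # anchor ACGT; member CGTA aligns at offset 1 (overlap CGT),
        # flanks are copied from their single covering member:
        # representative consensus ACGTA
        anchor = one_hot_pwm("anchor", "ACGT")
        member = one_hot_pwm("member", "CGTA")
        rep = representative_motif(PWMCollection([anchor, member]), "anchor",
                                   min_overlap=3, use_revcomp=False)
        np.testing.assert_allclose(rep.pwm.matrix,
                                   one_hot_pwm("exp", "ACGTA").matrix,
                                   atol=1e-9)
        assert list(rep.support) == [1, 2, 2, 2, 1]

    def test_empty_cluster_rejected(self):
        with pytest.raises(ValueError):
            representative_motif(PWMCollection(), "x")
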