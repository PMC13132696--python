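"""Joint trajectory k-means and the model-selection rule set."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm
from sklearn.metrics import adjusted_rand_score

from agetraj.clustering import (
    AVEPP_THRESHOLD,
    CH_CAP,
    AmbiguousLabelingError,
    ClusterSolution,
    TrajectoryMatrix,
    assignments_frame,
    avepp,
    build_trajectories,
    ch_index,
    evaluate_candidates,
    information_criteria,
    kmeans_joint,
    label_classes,
    recompute_wcss,
    select_k,
)

#: Fig-1-like shapes with per-measurement class gaps of >= 3 within-SDs:
#: (kdm level, kdm slope, hd level) per class; within-noise SD is 1.
SEPARATED_SHAPES = {
    "A": (0.0, 0.0, 0.0),
    "B": (6.0, 0.0, 3.0),
    "C": (0.0, -3.0, 6.0),
    "D": (6.0, 3.0, 9.0),
}


def separated_scores(n=800, seed=0, props=(0.27, 0.35, 0.31, 0.07), sd=1.0):
    """Score table for a well-separated 4-class cohort (T=3 visits)."""
    rng = np.random.default_rng(seed)
    letters = np.array(list(SEPARATED_SHAPES))
    cls = rng.choice(4, size=n, p=props)
    rows = []
    for sid in range(n):
        kdm0, slope, hd0 = SEPARATED_SHAPES[letters[cls[sid]]]
        for t in range(3):
            rows.append(
                {
                    "subject_id": sid,
                    "visit_index": t,
                    "kdm_advance": kdm0 + slope * t + sd * rng.normal(),
                    "hd_log": hd0 + sd * rng.normal(),
                }
            )
    return pd.DataFrame(rows), letters[cls]


def _traj_from_array(values):
    values = np.asarray(values, dtype=float)
    return TrajectoryMatrix(
        subjects=np.arange(values.shape[0]), values=values,
        variables=["kdm_advance", "hd_log"][: values.shape[2]],
        standardized=False, center=None, scale=None,
    )


class TestBuildTrajectories:
    def test_shape_contract(self):
        scores, _ = separated_scores(n=100, seed=1)
        traj = build_trajectories(scores)
        assert traj.values.shape == (100, 3, 2)

    def test_baseline_standardization(self):
        scores, _ = separated_scores(n=500, seed=2)
        traj = build_trajectories(scores, standardize=True)
        np.testing.assert_allclose(traj.values[:, 0, :].mean(axis=0), 0.0, atol=1e-8)
        np.testing.assert_allclose(traj.values[:, 0, :].std(axis=0), 1.0, atol=1e-8)

    def test_incomplete_trajectories_dropped(self):
        scores, _ = separated_scores(n=50, seed=3)
        scores = scores[~((scores["subject_id"] == 7) & (scores["visit_index"] == 2))]
        traj = build_trajectories(scores)
        assert traj.n == 49 and traj.n_dropped == 1
        assert 7 not in traj.subjects

    def test_constant_variable_named_in_error(self):
        scores, _ = separated_scores(n=40, seed=4)
        scores["hd_log"] = 1.0
        with pytest.raises(ValueError, match="hd_log"):
            build_trajectories(scores, standardize=True)

    def test_single_visit_rejected(self):
        scores, _ = separated_scores(n=40, seed=5)
        with pytest.raises(ValueError, match="2 visits"):
            build_trajectories(scores[scores["visit_index"] == 0])


class TestKMeans:
    def test_k1_degenerate(self):
        traj = _traj_from_array(np.random.default_rng(0).normal(size=(20, 3, 2)))
        sol = kmeans_joint(traj, 1, seed=0)
        np.testing.assert_allclose(sol.centroids[0], traj.values.mean(axis=0))
        total_ss = np.sum((traj.flat - traj.flat.mean(axis=0)) ** 2)
        assert sol.wcss == pytest.approx(total_ss)

    def test_exact_recovery_of_duplicated_trajectories(self):
        a = np.tile([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]], (4, 1, 1))
        b = np.tile([[5.0, 5.0], [6.0, 5.0], [7.0, 5.0]], (4, 1, 1))
        traj = _traj_from_array(np.concatenate([a, b]))
        sol = kmeans_joint(traj, 2, seed=1)
        assert sol.wcss == pytest.approx(0.0, abs=1e-20)
        assert len(set(sol.assignment[:4])) == 1 and len(set(sol.assignment[4:])) == 1

    def test_brute_force_partition_oracle(self):
        # n=6, T=2, V=1: solution wcss equals the exhaustive 2-partition minimum
        rng = np.random.default_rng(42)
        X = rng.normal(size=(6, 2, 1))
        traj = _traj_from_array(X)
        sol = kmeans_joint(traj, 2, n_starts=30, seed=7)
        flat = traj.flat
        best = np.inf
        for mask_bits in range(1, 2**5):  # fix subject 0 in group 0 (symmetry)
            mask = np.array([0] + [int(b) for b in f"{mask_bits:05b}"])
            w = 0.0
            for g in (0, 1):
                pts = flat[mask == g]
                if len(pts):
                    w += np.sum((pts - pts.mean(axis=0)) ** 2)
            best = min(best, w)
        assert sol.wcss == pytest.approx(best, rel=1e-10)

    def test_too_many_clusters_rejected(self):
        traj = _traj_from_array(np.zeros((3, 2, 1)))
        with pytest.raises(ValueError, match="cannot support"):
            kmeans_joint(traj, 4, seed=0)

    def test_wcss_consistency_with_assignment(self):
        scores, _ = separated_scores(n=300, seed=6)
        traj = build_trajectories(scores)
        sol = kmeans_joint(traj, 4, seed=2)
        assert recompute_wcss(traj, sol) == pytest.approx(sol.wcss, rel=1e-10)


class TestCHIndex:
    def test_two_blobs_favored_over_three(self):
        # splitting a tight blob cuts W by a scale-free ~10% while halving
        # B/(k-1), so CH at the true k=2 beats k=3 by a bounded margin
        rng = np.random.default_rng(8)
        blob = lambda c: c + 0.05 * rng.normal(size=(50, 3, 2))
        traj = _traj_from_array(np.concatenate([blob(0.0), blob(10.0)]))
        ch2 = ch_index(traj, kmeans_joint(traj, 2, seed=0))
        ch3 = ch_index(traj, kmeans_joint(traj, 3, seed=0))
        assert ch2 >= 1.5 * ch3

    def test_zero_within_ss_capped(self):
        # 1-D points {0,0,10,10}, k=2: B=100, W=0 -> capped, not a blow-up
        traj = _traj_from_array(np.array([0.0, 0.0, 10.0, 10.0]).reshape(4, 1, 1))
        sol = kmeans_joint(traj, 2, seed=0)
        assert sol.wcss == pytest.approx(0.0)
        assert ch_index(traj, sol) == CH_CAP

    def test_k1_undefined(self):
        traj = _traj_from_array(np.random.default_rng(1).normal(size=(10, 2, 1)))
        with pytest.raises(ValueError):
            ch_index(traj, kmeans_joint(traj, 1, seed=0))


class TestInformationCriteria:
    def test_parameter_count_formula(self):
        scores, _ = separated_scores(n=60, seed=9)
        traj = build_trajectories(scores)  # d = 3*2 = 6
        ic = information_criteria(traj, kmeans_joint(traj, 4, seed=0))
        assert ic.n_params == 4 * 6 + 1 == 25

    def test_degenerate_zero_wcss(self):
        traj = _traj_from_array(np.array([0.0, 0.0, 10.0, 10.0]).reshape(4, 1, 1))
        ic = information_criteria(traj, kmeans_joint(traj, 2, seed=0))
        assert ic.degenerate and ic.aic == -np.inf and ic.bic == -np.inf

    def test_loglik_nondecreasing_in_k(self):
        rng = np.random.default_rng(10)
        traj = _traj_from_array(rng.normal(size=(200, 3, 2)))
        logliks = [
            information_criteria(traj, kmeans_joint(traj, k, n_starts=30, seed=3)).loglik
            for k in range(2, 6)
        ]
        assert all(b >= a - 1e-6 for a, b in zip(logliks, logliks[1:]))

    def test_bic_favors_four_over_underfit(self):
        # on separated 4-class data, merging true classes (k=2, 3) costs far
        # more likelihood than the parameter penalty saves: BIC(4) << BIC(3) << BIC(2)
        scores, _ = separated_scores(n=100, seed=11, sd=0.5)
        traj = build_trajectories(scores)
        bics = {
            k: information_criteria(traj, kmeans_joint(traj, k, n_starts=30, seed=4)).bic
            for k in range(2, 5)
        }
        assert bics[4] < bics[3] < bics[2]


class TestAvePP:
    def test_separated_classes_confident(self):
        scores, _ = separated_scores(n=600, seed=12)
        traj = build_trajectories(scores)
        pp = avepp(traj, kmeans_joint(traj, 4, seed=5))
        assert pp.min() >= 0.99

    def test_identical_centroids_half(self):
        rng = np.random.default_rng(13)
        traj = _traj_from_array(rng.normal(size=(100, 2, 1)))
        c = traj.flat.mean(axis=0)
        sol = ClusterSolution(
            k=2, assignment=np.arange(100) % 2,
            centroids=np.tile(c.reshape(1, 2, 1), (2, 1, 1)),
            wcss=float(np.sum((traj.flat - c) ** 2)), iterations=1, converged=True, seed=0,
        )
        np.testing.assert_allclose(avepp(traj, sol), 0.5, atol=1e-12)

    def test_hand_density_oracle(self):
        # 3 subjects, stated centroids and variance: posteriors recomputed
        # from the spherical-Gaussian density formula directly
        values = np.array([[0.0], [1.0], [4.0]]).reshape(3, 1, 1)
        traj = _traj_from_array(values)
        centroids = np.array([[0.5], [4.0]]).reshape(2, 1, 1)
        assignment = np.array([0, 0, 1])
        wcss = 0.25 + 0.25 + 0.0
        sol = ClusterSolution(k=2, assignment=assignment, centroids=centroids,
                              wcss=wcss, iterations=1, converged=True, seed=0)
        sigma2 = wcss / 3.0
        w = np.array([2 / 3, 1 / 3])
        flat = values.reshape(3, 1)
        dens = np.array(
            [w[c] * norm.pdf(flat[:, 0], loc=centroids[c, 0, 0], scale=np.sqrt(sigma2))
             for c in range(2)]
        ).T
        post = dens / dens.sum(axis=1, keepdims=True)
        expected = np.array([post[assignment == c, c].mean() for c in range(2)])
        np.testing.assert_allclose(avepp(traj, sol), expected, atol=1e-9)


def _per_k_frame(rows):
    return pd.DataFrame(rows)


class TestSelectK:
    def test_recovery_on_separated_cohort(self):
        scores, letters = separated_scores(n=1200, seed=14)
        traj = build_trajectories(scores)
        sols, per_k = evaluate_candidates(traj, seed=6)
        report = select_k(per_k)
        assert report.chosen_k == 4

    def test_small_class_fails_share_gate(self):
        rows = [
            {"k": 2, "ch": 10.0, "bic": 100.0, "min_avepp": 0.9, "min_proportion": 0.4, "avepp": [], "proportions": []},
            {"k": 3, "ch": 50.0, "bic": 90.0, "min_avepp": 0.9, "min_proportion": 0.03, "avepp": [], "proportions": []},
        ]
        report = select_k(_per_k_frame(rows))
        assert report.chosen_k == 2
        assert any("< 5%" in r for r in report.reasons)

    def test_no_candidate_passes(self):
        rows = [{"k": 2, "ch": 1.0, "bic": 1.0, "min_avepp": 0.5, "min_proportion": 0.4,
                 "avepp": [], "proportions": []}]
        report = select_k(_per_k_frame(rows))
        assert report.chosen_k is None
        assert any("no candidate" in r for r in report.reasons)

    def test_override_recorded_never_silent(self):
        rows = [
            {"k": 3, "ch": 90.0, "bic": 80.0, "min_avepp": 0.9, "min_proportion": 0.2, "avepp": [], "proportions": []},
            {"k": 4, "ch": 50.0, "bic": 95.0, "min_avepp": 0.9, "min_proportion": 0.2, "avepp": [], "proportions": []},
        ]
        report = select_k(_per_k_frame(rows), override_k=4)
        assert report.chosen_k == 4
        assert any("override" in r for r in report.reasons)

    def test_bic_rule_ties_to_smaller_k(self):
        rows = [
            {"k": 3, "ch": 1.0, "bic": 50.0, "min_avepp": 0.9, "min_proportion": 0.2, "avepp": [], "proportions": []},
            {"k": 4, "ch": 2.0, "bic": 50.0, "min_avepp": 0.9, "min_proportion": 0.2, "avepp": [], "proportions": []},
        ]
        assert select_k(_per_k_frame(rows), rule="bic").chosen_k == 3


class TestLabeling:
    def test_generator_roundtrip_labels(self):
        scores, letters = separated_scores(n=1000, seed=15)
        traj = build_trajectories(scores)
        sol = kmeans_joint(traj, 4, seed=7)
        labeling = label_classes(sol)
        ass = assignments_frame(traj, sol, labeling)
        true = pd.Series(letters, index=np.arange(len(letters)))
        ass["true"] = ass["subject_id"].map(true)
        assert adjusted_rand_score(ass["true"], ass["class_label"]) == 1.0
        assert (ass["true"] == ass["class_label"]).all()

    def test_tied_features_ambiguous(self):
        centroids = np.zeros((4, 3, 2))  # all HD levels identical
        sol = ClusterSolution(k=4, assignment=np.arange(8) % 4, centroids=centroids,
                              wcss=1.0, iterations=1, converged=True, seed=0)
        with pytest.raises(AmbiguousLabelingError):
            label_classes(sol)

    def test_k3_withholds_labels(self):
        centroids = np.random.default_rng(16).normal(size=(3, 3, 2))
        sol = ClusterSolution(k=3, assignment=np.arange(9) % 3, centroids=centroids,
                              wcss=1.0, iterations=1, converged=True, seed=0)
        labeling = label_classes(sol)
        assert labeling.mapping is None and len(labeling.features) == 3


class TestInvariances:
    def test_label_permutation_invariance(self):
        scores, _ = separated_scores(n=400, seed=17)
        traj = build_trajectories(scores)
        sol = kmeans_joint(traj, 4, seed=8)
        perm = np.array([2, 0, 3, 1])
        inv = np.argsort(perm)
        sol_p = ClusterSolution(
            k=4, assignment=perm[sol.assignment], centroids=sol.centroids[inv],
            wcss=sol.wcss, iterations=sol.iterations, converged=True, seed=0,
        )
        assert ch_index(traj, sol_p) == pytest.approx(ch_index(traj, sol), rel=1e-12)
        assert information_criteria(traj, sol_p).bic == pytest.approx(
            information_criteria(traj, sol).bic
        )
        np.testing.assert_allclose(
            np.sort(avepp(traj, sol_p)), np.sort(avepp(traj, sol)), atol=1e-12
        )

    def test_ari_one_at_three_sd_separation(self):
        scores, letters = separated_scores(n=2000, seed=18)
        traj = build_trajectories(scores)
        sol = kmeans_joint(traj, 4, seed=9)
        assert adjusted_rand_score(letters, sol.assignment) == 1.0
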