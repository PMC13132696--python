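"""KDM biological age and homeostatic dysregulation: equation-level oracles."""

import numpy as np
import pandas as pd
import pytest

from agetraj.bioage import (
    MARKERS,
    DegenerateAgeError,
    DegenerateMarkerError,
    ReferenceModel,
    hd_scores,
    kdm_scores,
    score_cohort,
    train_reference,
)
from agetraj.synthetic import generate_reference_population

from conftest import toy_reference_frame


def _single_marker_model(k=1.0, q=0.0, s=1.0, sigma2=100.0) -> ReferenceModel:
    one = np.array([1.0])
    return ReferenceModel(
        markers=["x"], k=np.array([k]), q=np.array([q]), s=np.array([s]),
        sigma2=sigma2, mu=np.array([q + k * 50.0]), S=np.array([[1.0]]),
        S_inv=np.array([[1.0]]), ref_sd=one, S_z=np.array([[1.0]]),
        S_z_inv=np.array([[1.0]]), n_ref=100,
    )


class TestTrainReference:
    def test_hand_ols_five_points(self):
        # closed-form OLS on (30,62),(40,79),(50,102),(60,121),(70,138):
        # slope 1.94, intercept 3.4, n-denominator RMSE sqrt(1.92)
        df = pd.DataFrame({"age": [30, 40, 50, 60, 70], "x": [62, 79, 102, 121, 138]})
        model = train_reference(df, markers=["x"])
        assert model.k[0] == pytest.approx(1.94, abs=1e-9)
        assert model.q[0] == pytest.approx(3.4, abs=1e-9)
        assert model.s[0] == pytest.approx(np.sqrt(1.92), abs=1e-9)

    def test_age_variance_uses_n_minus_1(self):
        df = pd.DataFrame({"age": [40.0, 50.0, 60.0], "x": [1.0, 2.5, 3.1]})
        model = train_reference(df, markers=["x"])
        assert model.sigma2 == pytest.approx(100.0)

    def test_exact_linear_marker_rejected(self):
        df = pd.DataFrame({"age": [40.0, 50.0, 60.0]})
        df["x"] = 2.0 * df["age"]
        with pytest.raises(DegenerateMarkerError):
            train_reference(df, markers=["x"])

    def test_constant_age_rejected(self):
        df = pd.DataFrame({"age": [50.0] * 10, "x": np.arange(10.0)})
        with pytest.raises(DegenerateAgeError):
            train_reference(df, markers=["x"])

    def test_full_panel_roundtrip(self):
        model = train_reference(toy_reference_frame())
        assert model.m == len(MARKERS)
        assert np.all(model.s > 0)
        # covariance inverse really inverts
        assert np.allclose(model.S_inv @ model.S, np.eye(model.m), atol=1e-8)
        assert not model.pinv_fallback


class TestKDM:
    def test_hand_evaluation_single_marker(self):
        # BA = (60*1/1 + 50/100) / (1 + 1/100) = 59.9010
        model = _single_marker_model()
        ba, adv = kdm_scores(np.array([60.0]), 50.0, model)
        assert ba == pytest.approx(59.9009900990099, abs=1e-10)
        assert adv == pytest.approx(9.9009900990099, abs=1e-10)

    def test_fixed_point_at_age_expected_panel(self, reference_model):
        # x_j = q_j + k_j * CA for all j -> BA_KDM == CA
        for ca in (30.0, 47.5, 68.0):
            panel = reference_model.q + reference_model.k * ca
            ba, adv = kdm_scores(panel, ca, reference_model)
            assert ba == pytest.approx(ca, abs=1e-10)
            assert adv == pytest.approx(0.0, abs=1e-10)

    def test_large_age_variance_limit_inverts_biomarker(self):
        model = _single_marker_model(k=2.0, q=5.0, s=1.0, sigma2=1e12)
        ba, _ = kdm_scores(np.array([65.0]), 40.0, model)
        assert ba == pytest.approx((65.0 - 5.0) / 2.0, rel=1e-6)

    def test_weighted_average_bounds(self, reference_model):
        # BA lies between min and max of per-marker implied ages and CA when all k>0
        rng = np.random.default_rng(11)
        model = reference_model
        pos = np.abs(model.k) + 0.01
        model_pos = ReferenceModel(
            markers=model.markers, k=pos, q=model.q, s=model.s, sigma2=model.sigma2,
            mu=model.mu, S=model.S, S_inv=model.S_inv, ref_sd=model.ref_sd,
            S_z=model.S_z, S_z_inv=model.S_z_inv,
        )
        for _ in range(50):
            ca = rng.uniform(30, 70)
            panel = model_pos.q + pos * ca + rng.normal(0, model.s)
            implied = (panel - model_pos.q) / pos
            ba, _ = kdm_scores(panel, ca, model_pos)
            lo, hi = min(implied.min(), ca), max(implied.max(), ca)
            assert lo - 1e-9 <= ba <= hi + 1e-9

    def test_monotone_in_marker_with_positive_slope(self):
        model = _single_marker_model(k=1.5, q=0.0)
        ba1, _ = kdm_scores(np.array([70.0]), 50.0, model)
        ba2, _ = kdm_scores(np.array([70.1]), 50.0, model)
        assert ba2 > ba1

    def test_nonfinite_panel_rejected(self, reference_model):
        panel = reference_model.q + reference_model.k * 50.0
        panel[0] = np.nan
        with pytest.raises(ValueError):
            kdm_scores(panel, 50.0, reference_model)


def _model_2d(S):
    S = np.asarray(S, dtype=float)
    sd = np.sqrt(np.diag(S))
    return ReferenceModel(
        markers=["a", "b"], k=np.array([1.0, 1.0]), q=np.zeros(2), s=np.ones(2),
        sigma2=100.0, mu=np.zeros(2), S=S, S_inv=np.linalg.inv(S), ref_sd=sd,
        S_z=S / np.outer(sd, sd), S_z_inv=np.linalg.inv(S / np.outer(sd, sd)),
    )


class TestHD:
    def test_identity_covariance_hand_value(self):
        model = _model_2d(np.eye(2))
        hd, hd_log = hd_scores(np.array([3.0, 4.0]), model, standardize=False)
        assert hd == pytest.approx(25.0, abs=1e-12)
        assert hd_log == pytest.approx(np.log(25.0), abs=1e-12)

    def test_correlated_covariance_hand_value(self):
        model = _model_2d([[1.0, 0.5], [0.5, 1.0]])
        hd, _ = hd_scores(np.array([1.0, 1.0]), model, standardize=False)
        assert hd == pytest.approx(4.0 / 3.0, abs=1e-12)

    def test_centroid_flagged_not_neg_inf(self):
        model = _model_2d(np.eye(2))
        hd, hd_log = hd_scores(np.zeros(2), model, standardize=False)
        assert hd == 0.0
        assert np.isnan(hd_log)

    def test_sqrt_variant(self):
        model = _model_2d(np.eye(2))
        hd, _ = hd_scores(np.array([3.0, 4.0]), model, standardize=False, sqrt_form=True)
        assert hd == pytest.approx(5.0)

    def test_cofactor_inverse_oracle_m3(self):
        # explicit adjugate inversion as the independent route
        rng = np.random.default_rng(3)
        for _ in range(20):
            A = rng.normal(size=(3, 3))
            S = A @ A.T + 3 * np.eye(3)
            mu = rng.normal(size=3)
            x = rng.normal(size=3)
            cof = np.empty((3, 3))
            for i in range(3):
                for j in range(3):
                    minor = np.delete(np.delete(S, i, axis=0), j, axis=1)
                    cof[i, j] = (-1) ** (i + j) * np.linalg.det(minor)
            S_inv_oracle = cof.T / np.linalg.det(S)
            hd_oracle = (x - mu) @ S_inv_oracle @ (x - mu)
            sd = np.sqrt(np.diag(S))
            model = ReferenceModel(
                markers=list("abc"), k=np.ones(3), q=np.zeros(3), s=np.ones(3),
                sigma2=1.0, mu=mu, S=S, S_inv=np.linalg.inv(S), ref_sd=sd,
                S_z=S / np.outer(sd, sd), S_z_inv=np.linalg.inv(S / np.outer(sd, sd)),
            )
            hd, _ = hd_scores(x, model, standardize=False)
            assert hd == pytest.approx(hd_oracle, abs=1e-10)

    def test_affine_invariance(self):
        # HD is invariant under invertible affine maps of the marker space
        # when the centroid/covariance are recomputed on the transformed data
        rng = np.random.default_rng(5)
        ref = toy_reference_frame()
        model = train_reference(ref)
        X = ref[MARKERS].to_numpy()
        points = X[:5]
        hd0, _ = hd_scores(points, model, standardize=False)
        for _ in range(10):
            A = rng.normal(size=(len(MARKERS), len(MARKERS))) + 2 * np.eye(len(MARKERS))
            b = rng.normal(size=len(MARKERS))
            ref_t = ref.copy()
            ref_t[MARKERS] = X @ A.T + b
            model_t = train_reference(ref_t)
            hd1, _ = hd_scores(points @ A.T + b, model_t, standardize=False)
            np.testing.assert_allclose(hd1, hd0, atol=1e-8, rtol=1e-8)


class TestScoreCohort:
    @staticmethod
    def _cohort(n=10, visits=3, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for sid in range(n):
            age0 = rng.uniform(35, 65)
            for t in range(visits):
                row = {"subject_id": sid, "visit_index": t, "age": age0 + t}
                for j, m in enumerate(MARKERS):
                    row[m] = 10 + j + 0.1 * (j + 1) * (age0 + t) + rng.normal()
                rows.append(row)
        return pd.DataFrame(rows)

    def test_row_count_complete(self, reference_model):
        scores, n_excl = score_cohort(self._cohort(), reference_model)
        assert len(scores) == 30 and n_excl == 0

    def test_missing_marker_dropped_and_counted(self, reference_model):
        cohort = self._cohort()
        cohort.loc[5, "wbc"] = np.nan
        scores, n_excl = score_cohort(cohort, reference_model)
        assert len(scores) == 29 and n_excl == 1

    def test_reference_self_scoring_centers_advance(self, small_config, reference_model):
        ref = generate_reference_population(small_config, 6000, seed=101)
        ref["subject_id"] = np.arange(len(ref))
        ref["visit_index"] = 0
        scores, _ = score_cohort(ref, reference_model)
        se = scores["kdm_advance"].std() / np.sqrt(len(scores))
        assert abs(scores["kdm_advance"].mean()) < 4 * se
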