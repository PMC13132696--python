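"""Biological-age metrics: Klemera-Doubal biological age and homeostatic dysregulation.

Two complementary summaries of physiological state are computed from a panel of
eight routine blood biomarkers (albumin, creatinine, fasting glucose, BUN,
lymphocyte %, MCV, RDW, WBC):

* **KDM biological age** — a precision-weighted combination of the per-biomarker
  age predictions ``(x_j - q_j) / k_j`` obtained from regressions of each
  biomarker on chronological age in a healthy reference population, shrunk
  toward chronological age by the reference age variance ``sigma2``::

      BA_KDM = ( sum_j (x_j - q_j) * k_j / s_j**2  +  CA / sigma2 )
               / ( sum_j k_j**2 / s_j**2  +  1 / sigma2 )

  ``KDM_advance = BA_KDM - CA`` is the biological-age acceleration; positive
  values indicate aging faster than the calendar.

* **Homeostatic dysregulation (HD)** — the Mahalanobis statistic of the
  biomarker vector relative to the reference centroid,
  ``HD = (x - mu)^T S^{-1} (x - mu)`` in its squared form (the conventional
  square-root variant is available via a flag), and ``HD_log = ln(HD)``.

The reference model is trained on any table of (age, biomarker panel) rows;
it is deliberately agnostic about where that reference comes from.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

#: Canonical biomarker column names, in panel order.
MARKERS = ["alb", "creatinine", "glucose", "bun", "lymph_pct", "mcv", "rdw", "wbc"]

#: Condition-number threshold above which the covariance inverse falls back to
#: a symmetric pseudo-inverse (flagged in the model).
_COND_LIMIT = 1e10


class DegenerateMarkerError(ValueError):
    """A biomarker regression has zero residual scatter (s_j = 0)."""


class DegenerateAgeError(ValueError):
    """The reference ages are constant, so age regressions are undefined."""


@dataclass
class ReferenceModel:
    """Trained reference-population parameters for KDM and HD scoring.

    Attributes
    ----------
    markers : list of str
        Biomarker column names, fixing the panel order.
    k, q, s : ndarray, shape (m,)
        Per-marker slope (units/year), intercept and root-mean-square residual
        of the regression of the marker on chronological age.  ``s`` uses the
        n-denominator RMSE convention.
    sigma2 : float
        Variance of chronological age in the reference (years^2, ddof=1).
    mu : ndarray, shape (m,)
        Reference centroid of the raw biomarker panel.
    S, S_inv : ndarray, shape (m, m)
        Raw-scale covariance and its (possibly pseudo-) inverse.
    ref_sd : ndarray, shape (m,)
        Reference standard deviations, used when scoring on the standardized
        (z-scored) scale.
    S_z, S_z_inv : ndarray, shape (m, m)
        Correlation matrix of the panel and its inverse — the covariance of the
        z-scored markers, used when ``standardize=True``.
    pinv_fallback : bool
        True when the covariance was ill-conditioned and a pseudo-inverse was
        used.
    """

    markers: list[str]
    k: np.ndarray
    q: np.ndarray
    s: np.ndarray
    sigma2: float
    mu: np.ndarray
    S: np.ndarray
    S_inv: np.ndarray
    ref_sd: np.ndarray
    S_z: np.ndarray
    S_z_inv: np.ndarray
    n_ref: int = 0
    pinv_fallback: bool = False
    conventions: dict = field(
        default_factory=lambda: {"s_denominator": "n", "sigma2_denominator": "n-1"}
    )

    @property
    def m(self) -> int:
        return len(self.markers)

    # -- serialization -----------------------------------------------------
    def to_json(self, path) -> None:
        payload = {}
        for key, val in asdict(self).items():
            payload[key] = val.tolist() if isinstance(val, np.ndarray) else val
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "ReferenceModel":
        with open(path) as fh:
            payload = json.load(fh)
        arrays = {"k", "q", "s", "mu", "S", "S_inv", "ref_sd", "S_z", "S_z_inv"}
        for key in arrays:
            payload[key] = np.asarray(payload[key], dtype=float)
        return cls(**payload)


def _sym_inverse(S: np.ndarray) -> tuple[np.ndarray, bool]:
    """Invert a symmetric covariance, falling back to pinvh when ill-conditioned."""
    cond = np.linalg.cond(S)
    if not np.isfinite(cond) or cond > _COND_LIMIT:
        from scipy.linalg import pinvh

        return pinvh(S), True
    S_inv = np.linalg.inv(S)
    return 0.5 * (S_inv + S_inv.T), False


def train_reference(
    ref: pd.DataFrame, markers: list[str] | None = None, age_col: str = "age"
) -> ReferenceModel:
    """Fit per-marker age regressions and the panel centroid/covariance.

    Parameters
    ----------
    ref : DataFrame
        One row per reference individual with an ``age`` column and one column
        per biomarker.
    markers : list of str, optional
        Panel columns; defaults to :data:`MARKERS`.

    Raises
    ------
    DegenerateAgeError
        If the reference ages are constant.
    DegenerateMarkerError
        If any marker lies exactly on its age regression line (s_j = 0) or is
        constant — either breaks the KDM precision weights.
    """
    markers = list(markers) if markers is not None else list(MARKERS)
    if len(ref) < len(markers) + 2:
        raise ValueError(
            f"reference needs at least m+2={len(markers) + 2} rows, got {len(ref)}"
        )
    age = np.asarray(ref[age_col], dtype=float)
    if np.ptp(age) == 0:
        raise DegenerateAgeError("reference ages are constant; age regressions undefined")

    X = np.asarray(ref[markers], dtype=float)
    if not np.all(np.isfinite(X)) or not np.all(np.isfinite(age)):
        raise ValueError("reference table contains non-finite values")

    n, m = X.shape
    age_c = age - age.mean()
    denom = np.sum(age_c**2)
    k = age_c @ (X - X.mean(axis=0)) / denom
    q = X.mean(axis=0) - k * age.mean()
    resid = X - (q + np.outer(age, k))
    s = np.sqrt(np.mean(resid**2, axis=0))  # RMSE with n denominator
    bad = np.flatnonzero(s <= 0)
    if bad.size:
        names = ", ".join(markers[j] for j in bad)
        raise DegenerateMarkerError(f"zero residual scatter for marker(s): {names}")

    sigma2 = float(np.var(age, ddof=1))
    mu = X.mean(axis=0)
    S = np.atleast_2d(np.cov(X, rowvar=False, ddof=1))
    S_inv, fallback = _sym_inverse(S)
    ref_sd = np.sqrt(np.diag(S))
    S_z = S / np.outer(ref_sd, ref_sd)
    S_z_inv, fallback_z = _sym_inverse(S_z)

    return ReferenceModel(
        markers=markers,
        k=k,
        q=q,
        s=s,
        sigma2=sigma2,
        mu=mu,
        S=S,
        S_inv=S_inv,
        ref_sd=ref_sd,
        S_z=S_z,
        S_z_inv=S_z_inv,
        n_ref=n,
        pinv_fallback=bool(fallback or fallback_z),
    )


def _as_panel_matrix(panel, model: ReferenceModel) -> np.ndarray:
    """Coerce a panel (dict/Series/array/DataFrame) to an (n, m) float matrix."""
    if isinstance(panel, pd.DataFrame):
        X = np.asarray(panel[model.markers], dtype=float)
    elif isinstance(panel, (dict, pd.Series)):
        X = np.asarray([panel[name] for name in model.markers], dtype=float)[None, :]
    else:
        X = np.atleast_2d(np.asarray(panel, dtype=float))
    if X.shape[1] != model.m:
        raise ValueError(f"panel has {X.shape[1]} markers, model expects {model.m}")
    return X


def kdm_scores(panel, ca, model: ReferenceModel):
    """Klemera-Doubal biological age and its acceleration.

    Parameters
    ----------
    panel : array-like, dict or DataFrame
        Biomarker values; a single panel or an (n, m) batch.
    ca : float or array-like
        Chronological age(s) in years.

    Returns
    -------
    (BA_KDM, KDM_advance)
        Arrays (or scalars for scalar input).  ``KDM_advance = BA_KDM - CA``.
    """
    X = _as_panel_matrix(panel, model)
    ca_arr = np.atleast_1d(np.asarray(ca, dtype=float))
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite biomarker value in panel")
    w = model.k / model.s**2  # precision weights k_j / s_j^2
    num = (X - model.q) @ w + ca_arr / model.sigma2
    den = np.sum(model.k**2 / model.s**2) + 1.0 / model.sigma2
    ba = num / den
    adv = ba - ca_arr
    if np.isscalar(ca) or np.asarray(ca).ndim == 0:
        return float(ba[0]), float(adv[0])
    return ba, adv


def hd_scores(panel, model: ReferenceModel, standardize: bool = True, sqrt_form: bool = False):
    """Homeostatic dysregulation: Mahalanobis statistic from the reference centroid.

    Parameters
    ----------
    standardize : bool
        Z-score markers by the reference mean/SD before scoring (the centroid
        and covariance are transformed consistently, so this only changes HD
        when combined with numerical regularization; it is the default
        convention of this package).
    sqrt_form : bool
        Return the classical (square-root) Mahalanobis distance instead of the
        squared form.  Default False: the squared quadratic form.

    Returns
    -------
    (HD, HD_log)
        ``HD_log`` is NaN wherever HD == 0 (panel exactly at the centroid):
        the logarithm is undefined there and flagged rather than returned as
        ``-inf``.
    """
    X = _as_panel_matrix(panel, model)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite biomarker value in panel")
    if standardize:
        d = (X - model.mu) / model.ref_sd
        S_inv = model.S_z_inv
    else:
        d = X - model.mu
        S_inv = model.S_inv
    hd = np.einsum("ij,jk,ik->i", d, S_inv, d)
    hd = np.maximum(hd, 0.0)  # guard tiny negative round-off
    if sqrt_form:
        hd = np.sqrt(hd)
    with np.errstate(divide="ignore"):
        hd_log = np.where(hd > 0, np.log(np.where(hd > 0, hd, 1.0)), np.nan)
    if X.shape[0] == 1 and not isinstance(panel, pd.DataFrame):
        return float(hd[0]), float(hd_log[0])
    return hd, hd_log


def score_cohort(
    cohort: pd.DataFrame,
    model: ReferenceModel,
    standardize_hd: bool = True,
    sqrt_form: bool = False,
) -> tuple[pd.DataFrame, int]:
    """Score every subject-visit of a long-format cohort table.

    Rows with any missing biomarker are dropped and counted, mirroring the
    complete-case handling of the screening data.

    Parameters
    ----------
    cohort : DataFrame
        Long format with columns ``subject_id``, ``visit_index``, ``age`` and
        the marker columns of the model.

    Returns
    -------
    (scores, n_excluded)
        ``scores`` has one row per retained subject-visit with columns
        ``subject_id, visit_index, age, ba_kdm, kdm_advance, hd, hd_log``.
    """
    required = ["subject_id", "visit_index", "age"] + list(model.markers)
    missing_cols = [c for c in required if c not in cohort.columns]
    if missing_cols:
        raise KeyError(f"cohort table missing columns: {missing_cols}")
    complete = cohort[required].notna().all(axis=1)
    n_excluded = int((~complete).sum())
    kept = cohort.loc[complete]

    ba, adv = kdm_scores(kept[model.markers], np.asarray(kept["age"], float), model)
    hd, hd_log = hd_scores(kept[model.markers], model, standardize=standardize_hd, sqrt_form=sqrt_form)
    scores = pd.DataFrame(
        {
            "subject_id": kept["subject_id"].to_numpy(),
            "visit_index": kept["visit_index"].to_numpy(),
            "age": np.asarray(kept["age"], float),
            "ba_kdm": np.atleast_1d(ba),
            "kdm_advance": np.atleast_1d(adv),
            "hd": np.atleast_1d(hd),
            "hd_log": np.atleast_1d(hd_log),
        }
    ).reset_index(drop=True)
    return scores, n_excluded
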