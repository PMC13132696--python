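"""Joint k-means clustering of (KDM-advance, HD-log) longitudinal trajectories.

Subjects are clustered on their full multivariate trajectory: the T-visit,
2-variable array is flattened to a T*V vector and clustered with Lloyd's
k-means under the joint Euclidean distance (the kml3d-style 3-D metric over
time and variables).  Model selection over k follows the study's rule set:
Calinski-Harabasz index, AIC/BIC under a spherical Gaussian working
likelihood, average posterior probability (AvePP) > 0.70, and a smallest-class
share of at least 5%; among candidates passing the constraints the lowest BIC
wins, with an explicit (never silent) clinical override.

k-means has no native posteriors, so AvePP uses the standard surrogate: a
Gaussian mixture with the k-means centroids, mixing weights equal to the class
proportions and a shared spherical variance ``wcss / (n*d)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from scipy.special import logsumexp

TRAJECTORY_VARIABLES = ["kdm_advance", "hd_log"]

#: Calinski-Harabasz value reported when the within-cluster SS is (near) zero.
CH_CAP = 1e12

#: Semantic names for the four-class solution.
CLASS_NAMES = {
    "A": "Stable Low-Risk",
    "B": "Stable Moderate-Risk",
    "C": "Remissive High-Risk",
    "D": "Progressive High-Risk",
}


class AmbiguousLabelingError(ValueError):
    """Centroid features tie, so A/B/C/D labels cannot be assigned."""


@dataclass
class TrajectoryMatrix:
    subjects: np.ndarray  # (n,) subject ids
    values: np.ndarray  # (n, T, V)
    variables: list[str]
    standardized: bool
    center: np.ndarray | None  # per-variable baseline mean actually applied
    scale: np.ndarray | None  # per-variable baseline SD actually applied
    n_dropped: int = 0

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def n_visits(self) -> int:
        return self.values.shape[1]

    @property
    def flat(self) -> np.ndarray:
        return self.values.reshape(self.n, -1)


@dataclass
class ClusterSolution:
    k: int
    assignment: np.ndarray  # (n,) class indices
    centroids: np.ndarray  # (k, T, V)
    wcss: float
    iterations: int
    converged: bool
    seed: int


@dataclass
class ModelSelectionReport:
    per_k: pd.DataFrame  # one row per candidate k with all criteria
    chosen_k: int | None
    reasons: list[str]
    override_k: int | None = None

    def to_json(self, path) -> None:
        payload = {
            "chosen_k": self.chosen_k,
            "override_k": self.override_k,
            "reasons": self.reasons,
            "per_k": self.per_k.to_dict(orient="records"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, default=float)


# ---------------------------------------------------------------------------


def build_trajectories(
    scores: pd.DataFrame, standardize: bool = True, variables: list[str] | None = None
) -> TrajectoryMatrix:
    """Assemble complete per-subject trajectories from a per-visit score table.

    Subjects missing any visit (or any score value) are dropped and counted.
    Standardization is anchored at the baseline visit: each variable is
    centered and scaled by its visit-0 mean/SD, and that same transform is
    applied to every visit (so 0 means "the cohort baseline mean").
    """
    variables = list(variables) if variables is not None else list(TRAJECTORY_VARIABLES)
    T = int(scores["visit_index"].max()) + 1
    if T < 2:
        raise ValueError("trajectories require at least 2 visits")
    wide = scores.pivot_table(
        index="subject_id", columns="visit_index", values=variables, sort=True
    )
    complete = wide.notna().all(axis=1)
    n_dropped = int((~complete).sum())
    wide = wide.loc[complete]
    n = len(wide)
    values = np.empty((n, T, len(variables)))
    for vi, var in enumerate(variables):
        for t in range(T):
            values[:, t, vi] = wide[(var, t)].to_numpy()

    center = scale = None
    if standardize:
        center = values[:, 0, :].mean(axis=0)
        scale = values[:, 0, :].std(axis=0, ddof=0)
        zero = np.flatnonzero(scale == 0)
        if zero.size:
            names = ", ".join(variables[i] for i in zero)
            raise ValueError(f"cannot standardize: zero baseline SD for variable(s) {names}")
        values = (values - center) / scale
    return TrajectoryMatrix(
        subjects=wide.index.to_numpy(),
        values=values,
        variables=variables,
        standardized=standardize,
        center=center,
        scale=scale,
        n_dropped=n_dropped,
    )


def kmeans_joint(
    traj: TrajectoryMatrix,
    k: int,
    n_starts: int = 20,
    max_iter: int = 200,
    seed: int = 0,
) -> ClusterSolution:
    """Lloyd's k-means on the flattened trajectories, best of ``n_starts``."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if traj.n < k:
        raise ValueError(f"n={traj.n} subjects cannot support k={k} clusters")
    X = traj.flat
    if k == 1:
        centroid = X.mean(axis=0)
        wcss = float(np.sum((X - centroid) ** 2))
        return ClusterSolution(
            k=1,
            assignment=np.zeros(traj.n, dtype=int),
            centroids=centroid.reshape(1, traj.n_visits, -1),
            wcss=wcss,
            iterations=1,
            converged=True,
            seed=seed,
        )
    km = KMeans(
        n_clusters=k,
        n_init=n_starts,
        max_iter=max_iter,
        random_state=seed,
        algorithm="lloyd",
    ).fit(X)
    return ClusterSolution(
        k=k,
        assignment=km.labels_.astype(int),
        centroids=km.cluster_centers_.reshape(k, traj.n_visits, -1),
        wcss=float(km.inertia_),
        iterations=int(km.n_iter_),
        converged=bool(km.n_iter_ < max_iter),
        seed=seed,
    )


def recompute_wcss(traj: TrajectoryMatrix, solution: ClusterSolution) -> float:
    """Within-cluster sum of squares recomputed from scratch (consistency check)."""
    X = traj.flat
    C = solution.centroids.reshape(solution.k, -1)
    return float(np.sum((X - C[solution.assignment]) ** 2))


def ch_index(traj: TrajectoryMatrix, solution: ClusterSolution) -> float:
    """Calinski-Harabasz: [B/(k-1)] / [W/(n-k)] under the joint distance.

    When W is (numerically) zero the ratio is reported as :data:`CH_CAP`
    rather than a division blow-up.
    """
    k, n = solution.k, traj.n
    if k < 2 or k > n - 1:
        raise ValueError("CH index requires 2 <= k <= n-1")
    X = traj.flat
    grand = X.mean(axis=0)
    C = solution.centroids.reshape(k, -1)
    counts = np.bincount(solution.assignment, minlength=k)
    B = float(np.sum(counts[:, None] * (C - grand) ** 2))
    W = solution.wcss
    if W <= 1e-12 * max(B, 1.0):
        return CH_CAP
    return (B / (k - 1)) / (W / (n - k))


@dataclass
class InformationCriteria:
    aic: float
    bic: float
    loglik: float
    n_params: int
    degenerate: bool = False


def information_criteria(traj: TrajectoryMatrix, solution: ClusterSolution) -> InformationCriteria:
    """AIC/BIC under a spherical Gaussian working model.

    ``logL = -(n d / 2) ln(2 pi sigma^2) - n d / 2`` with ``d = T*V`` and
    ``sigma^2 = wcss / (n d)``; parameter count ``p = k d + 1`` (centroids
    plus the shared variance).  A zero wcss makes the likelihood degenerate;
    both criteria are then ``-inf`` with the degenerate flag set.
    """
    n, d = traj.n, traj.flat.shape[1]
    p = solution.k * d + 1
    sigma2 = solution.wcss / (n * d)
    if sigma2 <= 0:
        return InformationCriteria(-np.inf, -np.inf, np.inf, p, degenerate=True)
    loglik = -(n * d / 2.0) * np.log(2.0 * np.pi * sigma2) - n * d / 2.0
    return InformationCriteria(
        aic=float(-2.0 * loglik + 2.0 * p),
        bic=float(-2.0 * loglik + p * np.log(n)),
        loglik=float(loglik),
        n_params=p,
    )


def avepp(traj: TrajectoryMatrix, solution: ClusterSolution) -> np.ndarray:
    """Average posterior probability per class, from the spherical-mixture surrogate.

    Posterior responsibilities come from a Gaussian mixture with the k-means
    centroids, mixing weights equal to the class proportions and shared
    spherical variance ``wcss/(n d)``.  AvePP of class c is the mean posterior
    of c over the subjects assigned to c.  A zero variance degenerates every
    posterior to 1.
    """
    if solution.k < 2:
        raise ValueError("AvePP requires k >= 2")
    n, d = traj.n, traj.flat.shape[1]
    sigma2 = solution.wcss / (n * d)
    if sigma2 <= 0:
        return np.ones(solution.k)
    X = traj.flat
    C = solution.centroids.reshape(solution.k, -1)
    counts = np.bincount(solution.assignment, minlength=solution.k)
    logw = np.log(counts / n)
    d2 = ((X[:, None, :] - C[None, :, :]) ** 2).sum(axis=2)
    logpost = logw - d2 / (2.0 * sigma2)
    logpost -= logsumexp(logpost, axis=1, keepdims=True)
    post = np.exp(logpost)
    out = np.empty(solution.k)
    for c in range(solution.k):
        out[c] = post[solution.assignment == c, c].mean()
    return out


def evaluate_candidates(
    traj: TrajectoryMatrix,
    k_range=range(2, 7),
    n_starts: int = 20,
    max_iter: int = 200,
    seed: int = 0,
) -> tuple[dict[int, ClusterSolution], pd.DataFrame]:
    """Fit every candidate k and tabulate all model-selection criteria."""
    solutions, rows = {}, []
    for k in k_range:
        sol = kmeans_joint(traj, k, n_starts=n_starts, max_iter=max_iter, seed=seed)
        ic = information_criteria(traj, sol)
        pp = avepp(traj, sol)
        props = np.bincount(sol.assignment, minlength=k) / traj.n
        solutions[k] = sol
        rows.append(
            {
                "k": k,
                "ch": ch_index(traj, sol),
                "aic": ic.aic,
                "bic": ic.bic,
                "avepp": pp.tolist(),
                "min_avepp": float(pp.min()),
                "proportions": props.tolist(),
                "min_proportion": float(props.min()),
                "wcss": sol.wcss,
                "converged": sol.converged,
            }
        )
    return solutions, pd.DataFrame(rows)


AVEPP_THRESHOLD = 0.70
MIN_CLASS_SHARE = 0.05


def select_k(
    per_k: pd.DataFrame, override_k: int | None = None, rule: str = "ch"
) -> ModelSelectionReport:
    """Deterministic k selection with machine-checkable constraint reporting.

    Candidates must satisfy min AvePP > 0.70 and smallest class share >= 5%.
    Among the survivors the winner is picked by ``rule``:

    * ``"ch"`` (default) — highest Calinski-Harabasz index, the canonical
      quality criterion of kml-family trajectory clustering.  The spherical
      k-means BIC decreases essentially monotonically in k at large n (each
      extra centroid cuts wcss by a scale-free few percent while the penalty
      grows only logarithmically), so BIC alone cannot recover a true k at
      cohort scale; CH can.
    * ``"bic"`` — lowest BIC, ties to the smaller k.

    ``override_k`` forces a candidate regardless of the rule (the "clinical
    interpretability" escape hatch); the override is always recorded in the
    reasons, never silent.
    """
    if rule not in ("ch", "bic"):
        raise ValueError("rule must be 'ch' or 'bic'")
    per_k = per_k.copy()
    per_k["pass_avepp"] = per_k["min_avepp"] > AVEPP_THRESHOLD
    per_k["pass_share"] = per_k["min_proportion"] >= MIN_CLASS_SHARE
    eligible = per_k[per_k["pass_avepp"] & per_k["pass_share"]]
    reasons = []
    for _, row in per_k.iterrows():
        if not row["pass_avepp"]:
            reasons.append(f"k={int(row['k'])}: min AvePP {row['min_avepp']:.3f} <= {AVEPP_THRESHOLD}")
        if not row["pass_share"]:
            reasons.append(
                f"k={int(row['k'])}: smallest class {row['min_proportion']:.3%} < {MIN_CLASS_SHARE:.0%}"
            )
    chosen = None
    if len(eligible):
        if rule == "bic":
            best = eligible.sort_values(["bic", "k"]).iloc[0]
        else:
            best = eligible.sort_values(["ch", "k"], ascending=[False, True]).iloc[0]
        chosen = int(best["k"])
        crit = "lowest BIC" if rule == "bic" else "highest CH index"
        reasons.append(f"k={chosen} chosen: {crit} among constraint-passing candidates")
    else:
        reasons.append("no candidate k passes the AvePP/class-share constraints")
    if override_k is not None:
        if override_k not in set(per_k["k"].astype(int)):
            raise ValueError(f"override_k={override_k} was not among the fitted candidates")
        reasons.append(f"override: k={override_k} forced over rule-selected k={chosen}")
        chosen = int(override_k)
    return ModelSelectionReport(per_k=per_k, chosen_k=chosen, reasons=reasons, override_k=override_k)


# ---------------------------------------------------------------------------
# semantic labels for the 4-class solution
# ---------------------------------------------------------------------------


@dataclass
class ClassLabeling:
    mapping: dict | None  # class index -> letter, or None when k != 4
    names: dict | None  # class index -> semantic name
    features: pd.DataFrame  # per-class HD-log level and KDM-advance slope


def _centroid_features(solution: ClusterSolution, variables: list[str]) -> pd.DataFrame:
    vi_hd = variables.index("hd_log")
    vi_kdm = variables.index("kdm_advance")
    T = solution.centroids.shape[1]
    t = np.arange(T)
    rows = []
    for c in range(solution.k):
        hd_level = float(solution.centroids[c, :, vi_hd].mean())
        kdm_slope = float(np.polyfit(t, solution.centroids[c, :, vi_kdm], 1)[0])
        rows.append({"class_index": c, "hd_level": hd_level, "kdm_slope": kdm_slope})
    return pd.DataFrame(rows)


def label_classes(
    solution: ClusterSolution, variables: list[str] | None = None
) -> ClassLabeling:
    """Map a 4-class solution's indices to the A-D semantic labels.

    The rule works off centroid features: mean HD-log level and fitted linear
    KDM-advance slope across visits.  D is the highest-dysregulation class
    (its rising acceleration is audited via the emitted feature table), A the
    lowest; of the remaining two, C is the one with the more negative
    KDM-advance slope (remissive), B the other.  Exact feature ties raise
    :class:`AmbiguousLabelingError` instead of an arbitrary assignment.
    For k != 4 the semantic labels are withheld (mapping None, indices only).
    """
    variables = list(variables) if variables is not None else list(TRAJECTORY_VARIABLES)
    feats = _centroid_features(solution, variables)
    if solution.k != 4:
        return ClassLabeling(mapping=None, names=None, features=feats)
    hd = feats["hd_level"].to_numpy()
    slope = feats["kdm_slope"].to_numpy()
    if len(np.unique(hd)) < 4:
        raise AmbiguousLabelingError("tied HD-log levels between class centroids")
    order = np.argsort(hd)
    a_idx, d_idx = int(order[0]), int(order[-1])
    rest = [int(i) for i in order[1:-1]]
    if slope[rest[0]] == slope[rest[1]]:
        raise AmbiguousLabelingError("tied KDM-advance slopes between candidate B/C centroids")
    c_idx = rest[0] if slope[rest[0]] < slope[rest[1]] else rest[1]
    b_idx = rest[1] if c_idx == rest[0] else rest[0]
    mapping = {a_idx: "A", b_idx: "B", c_idx: "C", d_idx: "D"}
    names = {i: CLASS_NAMES[letter] for i, letter in mapping.items()}
    return ClassLabeling(mapping=mapping, names=names, features=feats)


def assignments_frame(
    traj: TrajectoryMatrix, solution: ClusterSolution, labeling: ClassLabeling | None = None
) -> pd.DataFrame:
    """Per-subject assignment table (subject_id, class_index[, class_label])."""
    out = pd.DataFrame({"subject_id": traj.subjects, "class_index": solution.assignment})
    if labeling is not None and labeling.mapping is not None:
        out["class_label"] = out["class_index"].map(labeling.mapping)
    return out
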