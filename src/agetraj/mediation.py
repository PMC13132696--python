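"""Counterfactual mediation: how much of the class-D stone risk flows through metabolism.

The treatment is the Progressive High-Risk vs Stable Low-Risk contrast
(Class D vs A; subjects in B/C are excluded).  For a mediator M (BMI,
hypertension or diabetes) two models are fitted:

* mediator model  M ~ treatment + covariates   (linear for continuous M,
  logistic for binary M),
* outcome model   Y ~ treatment + M + covariates (logistic; Y is the binary
  incidence flag).

Potential outcomes are then simulated: for every subject, mediator values
M(0) and M(1) are drawn from the fitted mediator model under each treatment
arm (common random numbers across arms), and the outcome-model risk is
evaluated at the four treatment/mediator combinations.  On the
risk-difference scale::

    ACME(t) = mean[ Y(t, M(1)) - Y(t, M(0)) ]      (indirect, through M)
    ADE(t)  = mean[ Y(1, M(t)) - Y(0, M(t)) ]      (direct)
    total   = mean[ Y(1, M(1)) - Y(0, M(0)) ]

reported averaged over t in {0, 1}; with shared draws the decomposition
ACME + ADE = total holds exactly.  Confidence intervals and p-values come
from a bias-corrected (BC) percentile bootstrap over subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

QUANTITIES = ["acme", "ade", "total", "prop_mediated"]


@dataclass
class MediationSpec:
    mediator: str
    family: str  # "continuous" or "binary"
    covariates: list = field(default_factory=list)
    treatment_col: str = "treatment"
    outcome_col: str = "event"
    n_sim: int = 1000
    n_boot: int = 1000
    alpha: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.family not in ("continuous", "binary"):
            raise ValueError("family must be 'continuous' or 'binary'")
        if self.n_boot < 200:
            raise ValueError("n_boot must be >= 200")
        if self.n_sim < 100:
            raise ValueError("n_sim must be >= 100")


@dataclass
class MediationResult:
    mediator: str
    point: dict  # quantity -> point estimate (risk-difference scale)
    ci: dict  # quantity -> (low, high) BC bootstrap interval
    p: dict  # quantity -> BC two-sided p
    prop_mediated_alt: float  # ACME / (ACME + ADE)
    mc_se: float  # Monte-Carlo SE of the ACME simulation
    n: int
    n_boot: int
    n_boot_failed: int
    prop_unstable: bool  # total-effect CI includes 0 -> proportion unreliable
    boot_summary: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# small fast fitting engine (bootstrap refits thousands of models)
# ---------------------------------------------------------------------------


def _draw_noise(n: int, spec: "MediationSpec", rng: np.random.Generator) -> np.ndarray:
    """The (n, n_sim) simulation-noise matrix for the mediator draws."""
    if spec.family == "binary":
        return rng.random(size=(n, spec.n_sim), dtype=np.float32)
    return rng.standard_normal((n, spec.n_sim), dtype=np.float32)


def _ols(X: np.ndarray, y: np.ndarray):
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = max(len(y) - X.shape[1], 1)
    return beta, float(np.sqrt(resid @ resid / dof))


def _logit(X: np.ndarray, y: np.ndarray, max_iter: int = 50, tol: float = 1e-10):
    """Newton-Raphson logistic regression with a tiny ridge for stability."""
    n, p = X.shape
    beta = np.zeros(p)
    ridge = 1e-8
    for _ in range(max_iter):
        eta = X @ beta
        mu = expit(eta)
        w = mu * (1.0 - mu)
        grad = X.T @ (y - mu) - ridge * beta
        H = (X * w[:, None]).T @ X + ridge * np.eye(p)
        step = np.linalg.solve(H, grad)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            return beta, True
    return beta, False


# ---------------------------------------------------------------------------


def mediation_table(
    baseline: pd.DataFrame,
    treatment_class: str = "D",
    reference_class: str = "A",
    class_col: str = "class_label",
) -> pd.DataFrame:
    """Restrict a baseline table to the treated/reference classes, adding a 0/1 treatment."""
    lab = baseline[class_col].astype(str)
    keep = lab.isin([treatment_class, reference_class])
    out = baseline.loc[keep].copy()
    out["treatment"] = (lab.loc[keep] == treatment_class).astype(int)
    return out


def _matrices(data: pd.DataFrame, spec: MediationSpec):
    t = data[spec.treatment_col].to_numpy(dtype=float)
    m = data[spec.mediator].to_numpy(dtype=float)
    y = data[spec.outcome_col].to_numpy(dtype=float)
    Z = data[list(spec.covariates)].to_numpy(dtype=float) if spec.covariates else np.empty((len(data), 0))
    uniq = np.unique(m)
    if spec.family == "continuous" and uniq.size <= 2:
        raise ValueError(
            f"mediator {spec.mediator!r} looks binary ({uniq.size} distinct values) "
            "but was declared continuous"
        )
    if spec.family == "binary" and not np.all(np.isin(uniq, [0.0, 1.0])):
        raise ValueError(f"mediator {spec.mediator!r} declared binary but is not 0/1")
    return t, m, y, Z


def _estimate(t, m, y, Z, spec: MediationSpec, rng: np.random.Generator, draws=None):
    """One full mediation estimate; returns (acme, ade, total, prop, mc_se, ok).

    ``draws`` optionally carries pre-drawn simulation noise (an (n, n_sim)
    standard-normal or uniform matrix); the bootstrap reuses one set of draws
    across replicates (common random numbers — the simulation noise, ~1e-6
    here, is negligible against the ~1e-3 sampling noise being bootstrapped).
    """
    n = len(t)
    ones = np.ones(n)
    Xm = np.column_stack([ones, t, Z])
    Xy = np.column_stack([ones, t, m, Z])

    ok = True
    if spec.family == "continuous":
        bm, sigma = _ols(Xm, m)
    else:
        bm, conv = _logit(Xm, m)
        ok &= conv
    by, conv = _logit(Xy, y)
    ok &= conv

    # mediator model linear predictors under each arm (treatment is column 1)
    base_m = Xm @ bm
    mhat = {0: base_m - bm[1] * t, 1: base_m - bm[1] * t + bm[1]}

    # outcome linear predictor pieces: intercept+covariates, treatment, mediator
    w = by[0] + (Z @ by[3:] if Z.shape[1] else 0.0)
    bt, bmed = by[1], by[2]
    n_batch = 10
    batches = np.array_split(np.arange(spec.n_sim), n_batch)

    if spec.family == "binary":
        # a 0/1 mediator makes the risk two-valued per subject/arm, so every
        # mean reduces to per-subject draw frequencies — no (n, n_sim) expits
        u = draws if draws is not None else _draw_noise(n, spec, rng)
        ind = {arm: (u < expit(mhat[arm]).astype(np.float32)[:, None]) for arm in (0, 1)}
        draw_mean = {arm: ind[arm].mean(axis=1) for arm in (0, 1)}
        r0, r0m = expit(w), expit(w + bmed)
        r1, r1m = expit(w + bt), expit(w + bt + bmed)
        delta = {0: r0m - r0, 1: r1m - r1}

        def mean_r(a, mm):
            base = r0 if a == 0 else r1
            return float(np.mean(base + delta[a] * draw_mean[mm]))

        acme_t = {a: mean_r(a, 1) - mean_r(a, 0) for a in (0, 1)}
        ade_t = {mm: mean_r(1, mm) - mean_r(0, mm) for mm in (0, 1)}
        total = mean_r(1, 1) - mean_r(0, 0)
        half_delta = 0.5 * (delta[0] + delta[1])
        bm_means = np.array(
            [
                float(np.mean(half_delta * (ind[1][:, idx].mean(axis=1) - ind[0][:, idx].mean(axis=1))))
                for idx in batches
            ]
        )
    else:
        # common draws across arms: M(1) = M(0) + mediator treatment effect,
        # so the four risk surfaces differ by additive constants only
        eps = draws if draws is not None else _draw_noise(n, spec, rng)
        # simulation means need ~1e-6 accuracy, not 1e-16
        A = (w + bmed * mhat[0]).astype(np.float32)[:, None] + np.float32(bmed * sigma) * eps
        dm, dt = np.float32(bmed * bm[1]), np.float32(bt)
        # every reported quantity is a difference of the four risk-surface
        # means, so only per-batch means of each surface are materialized
        edges = np.linspace(0, spec.n_sim, n_batch + 1).astype(int)
        buf = np.empty_like(A)
        bmeans = {}
        for key, shift in [((0, 0), None), ((0, 1), dm), ((1, 0), dt), ((1, 1), dt + dm)]:
            if shift is None:
                np.negative(A, out=buf)
            else:
                np.subtract(np.float32(-shift), A, out=buf)
            with np.errstate(over="ignore"):
                np.exp(buf, out=buf)
            buf += np.float32(1.0)
            np.reciprocal(buf, out=buf)
            bmeans[key] = np.array(
                [buf[:, lo:hi].mean(dtype=np.float64) for lo, hi in zip(edges[:-1], edges[1:])]
            )
        weights = np.diff(edges) / spec.n_sim
        mean = {key: float(vals @ weights) for key, vals in bmeans.items()}
        acme_t = {a: mean[(a, 1)] - mean[(a, 0)] for a in (0, 1)}
        ade_t = {mm: mean[(1, mm)] - mean[(0, mm)] for mm in (0, 1)}
        total = mean[(1, 1)] - mean[(0, 0)]
        bm_means = 0.5 * ((bmeans[(0, 1)] - bmeans[(0, 0)]) + (bmeans[(1, 1)] - bmeans[(1, 0)]))

    acme = 0.5 * (acme_t[0] + acme_t[1])
    ade = 0.5 * (ade_t[0] + ade_t[1])
    prop = acme / total if total != 0 else np.nan
    mc_se = float(bm_means.std(ddof=1) / np.sqrt(n_batch))
    return acme, ade, float(total), prop, mc_se, ok


def estimate_effects(data: pd.DataFrame, spec: MediationSpec) -> MediationResult:
    """Point estimates only (no bootstrap); deterministic under ``spec.seed``."""
    spec.validate()
    t, m, y, Z = _matrices(data, spec)
    rng = np.random.default_rng(spec.seed)
    acme, ade, total, prop, mc_se, ok = _estimate(t, m, y, Z, spec, rng)
    return MediationResult(
        mediator=spec.mediator,
        point={"acme": acme, "ade": ade, "total": total, "prop_mediated": prop},
        ci={},
        p={},
        prop_mediated_alt=acme / (acme + ade) if (acme + ade) != 0 else np.nan,
        mc_se=mc_se,
        n=len(data),
        n_boot=0,
        n_boot_failed=0,
        prop_unstable=False,
    )


def _bc_interval(boot: np.ndarray, point: float, alpha: float):
    """Bias-corrected percentile interval (Efron's BC, no acceleration)."""
    B = len(boot)
    frac = np.clip(np.mean(boot <= point), 1.0 / (B + 1), B / (B + 1.0))
    z0 = stats.norm.ppf(frac)
    zq = stats.norm.ppf(1.0 - alpha / 2.0)
    q_lo = stats.norm.cdf(2.0 * z0 - zq)
    q_hi = stats.norm.cdf(2.0 * z0 + zq)
    return float(np.quantile(boot, q_lo)), float(np.quantile(boot, q_hi)), float(z0)


def _bc_pvalue(boot: np.ndarray, point: float) -> float:
    """Smallest alpha at which the BC interval excludes 0 (two-sided).

    The interval narrows as alpha grows, so exclusion is monotone in alpha;
    the threshold is found by bisection.
    """
    lo, hi = 1e-8, 1.0 - 1e-8
    if _excludes_zero(boot, point, lo):
        return float(lo)
    if not _excludes_zero(boot, point, hi):
        return 1.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if _excludes_zero(boot, point, mid):
            hi = mid
        else:
            lo = mid
    return float(hi)


def _excludes_zero(boot, point, alpha):
    low, high, _ = _bc_interval(boot, point, alpha)
    return low > 0.0 or high < 0.0


def bc_bootstrap(data: pd.DataFrame, spec: MediationSpec) -> MediationResult:
    """Full mediation analysis with BC bootstrap CIs and p-values.

    Subjects are resampled with replacement ``n_boot`` times and every
    quantity re-estimated; if more than 10% of resamples fail to converge the
    result is flagged via ``n_boot_failed``.  The proportion mediated is
    flagged unstable when the total effect's CI includes 0.
    """
    spec.validate()
    t, m, y, Z = _matrices(data, spec)
    rng = np.random.default_rng(spec.seed)
    n = len(t)
    draws = _draw_noise(n, spec, rng)
    acme, ade, total, prop, mc_se, ok = _estimate(t, m, y, Z, spec, rng, draws=draws)
    point = {"acme": acme, "ade": ade, "total": total, "prop_mediated": prop}

    boot = {qq: [] for qq in QUANTITIES}
    n_failed = 0
    for _ in range(spec.n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            a, d, tot, pr, _, conv = _estimate(
                t[idx], m[idx], y[idx], Z[idx] if Z.shape[1] else Z, spec, rng, draws=draws
            )
            if not conv:
                n_failed += 1
                continue
        except np.linalg.LinAlgError:
            n_failed += 1
            continue
        for qq, val in zip(QUANTITIES, (a, d, tot, pr)):
            boot[qq].append(val)

    ci, pvals, rows = {}, {}, []
    for qq in QUANTITIES:
        arr = np.asarray(boot[qq], dtype=float)
        arr = arr[np.isfinite(arr)]
        if arr.size < spec.n_boot // 2:
            ci[qq], pvals[qq] = (np.nan, np.nan), np.nan
            continue
        lo, hi, z0 = _bc_interval(arr, point[qq], spec.alpha)
        ci[qq] = (lo, hi)
        pvals[qq] = _bc_pvalue(arr, point[qq])
        rows.append(
            {"quantity": qq, "boot_mean": arr.mean(), "boot_sd": arr.std(ddof=1), "z0": z0}
        )
    prop_unstable = not (ci["total"][0] > 0.0 or ci["total"][1] < 0.0)
    return MediationResult(
        mediator=spec.mediator,
        point=point,
        ci=ci,
        p=pvals,
        prop_mediated_alt=acme / (acme + ade) if (acme + ade) != 0 else np.nan,
        mc_se=mc_se,
        n=n,
        n_boot=spec.n_boot,
        n_boot_failed=n_failed,
        prop_unstable=prop_unstable,
        boot_summary=pd.DataFrame(rows),
    )


MEDIATOR_FAMILIES = {"bmi": "continuous", "hypertension": "binary", "diabetes": "binary"}


def multi_mediator_report(
    data: pd.DataFrame,
    mediators: list[str] | None = None,
    covariates: list[str] | None = None,
    n_sim: int = 1000,
    n_boot: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """One single-mediator analysis per metabolic mediator, plus a headline summary.

    Returns the per-mediator table (ACME/ADE/total/proportion with BC CIs and
    p-values) and a path-summary dict whose ``combined_significant_pct`` is
    the sum of the significantly mediated proportions, in percent.
    """
    mediators = list(mediators) if mediators is not None else list(MEDIATOR_FAMILIES)
    covariates = list(covariates) if covariates is not None else ["age", "gender"]
    rows, paths = [], {}
    combined = 0.0
    for i, med in enumerate(mediators):
        spec = MediationSpec(
            mediator=med,
            family=MEDIATOR_FAMILIES.get(med, "continuous"),
            covariates=[c for c in covariates if c != med],
            n_sim=n_sim,
            n_boot=n_boot,
            alpha=alpha,
            seed=seed + 1000 * (i + 1),
        )
        res = bc_bootstrap(data, spec)
        significant = bool(np.isfinite(res.p.get("acme", np.nan)) and res.p["acme"] < alpha)
        pct = 100.0 * res.point["prop_mediated"]
        if significant:
            combined += pct
        rows.append(
            {
                "mediator": med,
                "acme": res.point["acme"],
                "acme_ci_low": res.ci["acme"][0],
                "acme_ci_high": res.ci["acme"][1],
                "acme_p": res.p["acme"],
                "ade": res.point["ade"],
                "ade_p": res.p["ade"],
                "total": res.point["total"],
                "total_p": res.p["total"],
                "prop_mediated_pct": pct,
                "prop_ci_low_pct": 100.0 * res.ci["prop_mediated"][0],
                "prop_ci_high_pct": 100.0 * res.ci["prop_mediated"][1],
                "prop_mediated_alt_pct": 100.0 * res.prop_mediated_alt,
                "prop_unstable": res.prop_unstable,
                "significant": significant,
            }
        )
        paths[med] = {"significant": significant, "prop_mediated_pct": pct}
    summary = {"paths": paths, "combined_significant_pct": combined}
    return pd.DataFrame(rows), summary
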