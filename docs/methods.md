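# Methods

`agetraj` implements a longitudinal biological-aging analysis for incident
urolithiasis: two aging scores computed from an 8-marker blood panel, joint
k-means clustering of their 3-visit trajectories, Cox modelling of incident
stones by trajectory class, a multinomial model of class membership, and a
counterfactual mediation decomposition of the Progressive-class risk through
metabolic mediators. A synthetic-cohort generator with known ground truth
drives every stage, so the whole chain is testable end to end.

## Aging scores

**KDM biological age.** Each biomarker is regressed on chronological age in a
healthy reference population, giving slope `k_j`, intercept `q_j` and RMSE
`s_j` (n-denominator convention; the age variance `sigma2` uses n−1 — both
conventions are stored in the serialized model). The estimator is the
precision-weighted combination

```
BA_KDM = ( Σ_j (x_j − q_j) k_j / s_j² + CA/σ² ) / ( Σ_j k_j²/s_j² + 1/σ² )
```

and `KDM_advance = BA_KDM − CA`. The estimator is linear in the panel, lies
between the per-marker implied ages and CA when all slopes are positive, and
returns exactly CA for a panel at its age-expected values — both properties
are tested.

**Homeostatic dysregulation.** `HD = (x − μ)ᵀ S⁻¹ (x − μ)` with the reference
centroid and covariance, in the *squared* quadratic form; a `sqrt_form` flag
exposes the classical Mahalanobis distance. `HD_log = ln(HD)`, undefined
(NaN, never −∞) at the centroid. Markers are z-scored by the reference
mean/SD by default (`standardize=True`); with a full, well-conditioned
covariance this is an affine reparameterization and does not change HD — the
flag matters only under the pseudo-inverse fallback, which engages when the
covariance condition number exceeds 1e10 and is flagged on the model. Whether
the original analysis standardized, and whether its reference was external or
cohort-internal, is not determinable from the published values; both choices
are exposed, neither is asserted.

## Trajectory clustering

Subjects with all `T` visits scored are clustered on the flattened `T×2`
vector (KDM-advance, HD-log) under the joint Euclidean metric — the
kml3d-style distance over time and variables. Standardization anchors at the
baseline visit: each variable is centered/scaled by its visit-0 mean/SD so 0
reads "cohort baseline mean". Lloyd's k-means runs with 20 restarts
(best-of by wcss), max 200 iterations, deterministic under the stage seed.

Model selection over k = 2…6 computes:

* **CH index** `[B/(k−1)]/[W/(n−k)]`; a numerically zero W reports a capped
  value (1e12) instead of a division blow-up.
* **AIC/BIC** under a spherical Gaussian working likelihood with
  `σ̂² = wcss/(nd)`, `d = T·V`, and `p = kd + 1` parameters.
* **AvePP** from a Gaussian-mixture surrogate (k-means has no posteriors):
  responsibilities from spherical components at the k-means centroids with
  mixing weights equal to class shares; AvePP of a class is the mean
  posterior over its assigned subjects.

Constraint gates follow the study design: min AvePP > 0.70 and smallest class
≥ 5%. Among gate-passers the default winner is the **highest CH index**.
BIC is reported and available as an alternative rule, but it cannot select a
true k at cohort scale: splitting any cluster removes a scale-free
~`π_c·0.64/d` fraction of wcss, so `−2Δlogℓ ≈ nd·ln(W_k/W_{k+1})` outgrows
the `d·ln n` penalty for n beyond a few hundred, and the spherical BIC
decreases essentially monotonically in k — on real and synthetic data alike
BIC "prefers" ever-finer solutions while CH peaks at the generative k on
separated data. An explicit `override_k` (default 4 in the pipeline)
reproduces the clinically interpreted four-class choice; the override is
always recorded in the selection report, never applied silently.

The four-class labels are assigned from centroid features: A = lowest mean
HD-log, D = highest; of the remaining two, C = more negative fitted
KDM-advance slope (remissive), B = the other. Exact feature ties raise an
error rather than an arbitrary assignment; for k ≠ 4 only indices are
returned.

## Survival models

Cox partial likelihood with Efron tie handling (annual screening data is
heavily tied), fitted by lifelines with tightened convergence (`precision
1e-9`, matching a brute-force partial-likelihood oracle to 1e-6 on toys).
Model 1: class indicators (vs Stable Low-Risk A) only; Model 2 adds age,
gender, BMI; Model 3 adds SBP, DBP, hypertension, diabetes. Wald 95% CIs
(`exp(β ± 1.959964·SE)`). A monotone likelihood (complete separation) raises
an error. Diagnostics: scaled Schoenfeld residuals correlated with event-time
rank per term; the global statistic sums the per-term chi-squares on the
summed df — an omnibus approximation, with the per-term tests primary; VIFs
from auxiliary regressions among model terms, `inf` under exact collinearity.
The sensitivity analysis drops subjects with baseline hypertension or
diabetes. Subgroup analyses stratify by gender, comorbidity flags, or median
splits of age/BMI (the original groupings are unstated; the median is the
symmetric default, configurable); interaction tests use the likelihood ratio
between pooled models with and without class×stratum products, preferred over
Wald for small strata.

## Membership model

Multinomial logit (statsmodels MNLogit, Newton) of class membership on
baseline age, gender, BMI, hypertension, diabetes, with class A as reference.
Odds ratios are reported per 5 years of age and per 5 kg/m² of BMI (CI
endpoints transformed identically), per level for binary predictors. A ridge
(1e-8) regularized fallback engages under separation and is flagged.

## Mediation

Treatment is the Class-D-vs-Class-A contrast (B/C excluded). Mediator model:
linear (BMI) or logistic (hypertension, diabetes) on treatment + covariates.
Outcome model: logistic on treatment + mediator + covariates — the binary
3-year incidence flag is the outcome; a proportional-hazards outcome has no
closed potential-outcome risk and the counterfactual machinery used here is
defined for parametric outcome models, so effects are reported on the
risk-difference scale. For every subject, mediator potential values M(0),
M(1) are simulated from the fitted mediator model (n_sim draws, common random
numbers across arms) and the outcome risk is evaluated at the four
treatment×mediator combinations; ACME, ADE and the total effect are the
averaged contrasts, reported averaged over both treatment arms. With shared
draws ACME + ADE = total holds exactly; the Monte-Carlo SE of the ACME is
estimated by batching the draws (10 batches) and reported.

Each mediator is analyzed separately (matching the per-mediator proportions
that are then summed); a joint-mediator mode is out of scope. The proportion
mediated is ACME/total, with ACME/(ACME+ADE) also reported (they coincide
here by the exact decomposition); it is flagged unstable whenever the total
effect's CI includes 0.

**Bias-corrected bootstrap.** Subjects are resampled with replacement
(default 1000 resamples; the bootstrap reuses one simulation-noise matrix
across replicates — the ~1e-6 simulation noise is negligible against the
~1e-3 sampling noise being bootstrapped). For each quantity,
`z0 = Φ⁻¹(fraction of bootstrap estimates ≤ point estimate)` and the interval
endpoints sit at percentiles `Φ(2z0 ± z_{α/2})` (linear-interpolated
quantiles). The two-sided p-value is the smallest α at which the BC interval
excludes 0, found by bisection. Degenerate fractions are clipped to
`[1/(B+1), B/(B+1)]`.

## Synthetic cohort

The generator emulates a 3-visit annual screening cohort of 27,948 adults
with four latent aging-trajectory classes. Defaults are calibrated to the
published baseline table: class shares 27.3/34.7/30.8/7.2%, per-class
KDM-advance and HD-log means, cross-sectional SDs (~1.9 y and ~0.25), marker
means/SDs at age 50, hypertension/diabetes/gender rates, and the qualitative
trajectory shapes (A/B stable, C remissive with negative slopes, D
progressive with positive slopes and the highest dysregulation).

Latent signals are per-class linear-in-visit targets plus subject-level
random intercepts (SD 1.2 y for KDM-advance, 0.12 for HD-log); visit-level
biomarker noise is 24% of the reference residual SD, reflecting that
within-person variability is much smaller than cross-sectional spread. The
split was chosen so that the recomputed trajectories cluster with the high
classification certainty (AvePP > 0.9 at k=4) the study reports; a
consequence is that raw marker cross-sectional SDs in the cohort are smaller
than the reference SDs — the aging-score dispersions, which drive every
downstream stage, are the calibrated quantities.

Signals enter the panel through two fixed directions. The KDM direction is
the age-slope vector `k` scaled by `(W + 1/σ²)/W` with `W = Σ k_j²/s_j²`, so
the *expected recomputed* KDM-advance equals the latent signal exactly (the
estimator is linear). The HD direction `v` has unit Mahalanobis length
(`vᵀS⁻¹v = 1`) and is orthogonal to the KDM precision weights (`wᵀv = 0`),
with magnitude `sqrt(exp(g))` for latent HD-log `g`: a deviation `b·v` adds
`b²` to the expected HD without moving KDM-advance. Because HD is quadratic,
the recomputed HD-log is a monotone, compressed transform of the latent
signal (floor terms from age spread and marker noise), not an affine match —
class ordering and slopes survive; absolute HD-log levels do not, and no test
asserts they should.

Mediators: BMI = 24.58 + class shift + N(0, 3.3²); hypertension Bernoulli
with class-shifted log-odds around 36.5%; diabetes class-independent at 9.2%.
Outcome: a logistic model on class (direct), BMI, hypertension (diabetes null
by default), with a binary event over a fixed 3-year window — uniform event
times for cases, censoring at the window otherwise; the original time-origin
construction is not recoverable from the publication, and this is the
simplest structure supporting both Cox and logistic-outcome mediation. The
default direct/indirect coefficients reproduce the published effect pattern:
crude class risk ratios ≈ {B 1.09, C 0.83, D 1.20} and a true BMI-mediated
share of ~23% with a positive secondary hypertension path and a null diabetes
path. (The published baseline table actually shows the Progressive class with
*lower* diagnosed hypertension than the reference class; the generator
follows the mediation structure, which is the quantity under test.)
Ground truth (class labels, exact potential-outcome ACME/ADE/total by
200k-draw Monte Carlo on the true models, marginal class risk ratios) is
emitted alongside every cohort.

What the generator does **not** emulate: real marker distributions (all
Gaussian), missing data (complete-case only, mirroring the source design),
informative censoring, competing risks, secular trends, or measurement-device
effects. Passing tests therefore demonstrate correctness of the estimators
under the stated generative model, not robustness to those features.

## Problem sizes and numerical choices

Simulation-based tests use: 200 replicates at n=2000 for Cox null coverage;
100 replicates at n=800 for Schoenfeld calibration; n=5000 for HR recovery;
n=4000 for clustering recovery; 50 replicates at n=8000 with 200 resamples
for mediation-coverage checks; the end-to-end run uses the full default
cohort (n=27,948) with a 400-resample bootstrap in the test and the full
1000-resample default in the acceptance script. Mediation simulation draws
default to 1000 (pipeline runs use 300; the batched MC-SE, ~1e-6, is reported
so the simulation error is always visible against the ~1e-3 sampling error).
One global seed hashes into per-stage seeds; identical configurations
reproduce byte-identical artifacts.

## Known limitations

* AvePP is a surrogate definition (k-means has no posteriors); its absolute
  level is population-specific and is used only as a gate, not a fidelity
  target.
* The proportion mediated is a ratio; when the total effect is weakly
  identified its interval is wide and flagged unstable — single-number
  summaries of mediation in that regime are not trustworthy, by construction.
* The global Schoenfeld test sums per-term chi-squares (independence
  approximation); use the per-term tests for decisions.
* Estimated-class mediation attenuates direct effects relative to true-class
  analyses (misclassified treatment); the reported proportions on clustered
  labels are therefore larger than the generator truth, as the end-to-end run
  shows.
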