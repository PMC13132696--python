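# agetraj

Longitudinal biological-aging trajectories and incident kidney-stone risk:
a complete, tested analysis pipeline for cohort studies that screen adults
annually with a routine blood panel and abdominal ultrasound.

Cross-sectional "biological age" misses the dynamics of aging. This package
scores each subject-visit with two complementary metrics computed from eight
routine biomarkers (albumin, creatinine, fasting glucose, BUN, lymphocyte %,
MCV, RDW, WBC):

* **KDM biological age** — the Klemera–Doubal precision-weighted estimator

  `BA_KDM = (Σ_j (x_j − q_j)·k_j/s_j² + CA/σ²) / (Σ_j k_j²/s_j² + 1/σ²)`,

  with `KDM-advance = BA_KDM − CA` as the acceleration;
* **Homeostatic dysregulation** — the Mahalanobis statistic
  `HD = (x − μ)ᵀ S⁻¹ (x − μ)` from a reference centroid, log-transformed.

Joint k-means over the multivariate (KDM-advance, HD-log) trajectories —
kml3d-style, Euclidean over time points and variables — identifies latent
aging classes (stable-low, stable-moderate, remissive, progressive), selected
by Calinski–Harabasz / AIC / BIC with AvePP > 0.70 and ≥ 5% smallest-class
gates. Class membership is modelled by multinomial logit (ORs per 5 years /
5 kg/m²), incident urolithiasis by Cox proportional hazards under three
adjustment sets with Schoenfeld and VIF diagnostics, and the progressive
class's excess risk is decomposed into direct and mediated components (ACME /
ADE on the risk-difference scale, bias-corrected bootstrap CIs) through BMI,
hypertension and diabetes.

Because screening cohorts are rarely shareable, a first-class synthetic
generator emulates the study structure — 3 annual visits, four trajectory
classes with published-table means and spreads, and a stone outcome whose
class effect flows partly through BMI and hypertension — with exact ground
truth (class labels, potential-outcome mediation effects, marginal risk
ratios) for every cohort it draws.

## Worked example

```python
from agetraj import (SyntheticConfig, generate_reference_population,
                     generate_cohort_frame, train_reference, score_cohort,
                     build_trajectories, evaluate_candidates, select_k,
                     label_classes, kdm_scores)

cfg = SyntheticConfig(n_subjects=12_000, seed=3)
ref = generate_reference_population(cfg, 10_000, seed=99)
model = train_reference(ref)

cohort, truth = generate_cohort_frame(cfg)
scores, n_excluded = score_cohort(cohort, model)
traj = build_trajectories(scores, standardize=True)
solutions, per_k = evaluate_candidates(traj, seed=11)
report = select_k(per_k, override_k=4)
print(label_classes(solutions[4]).mapping)
```

prints `{2: 'A', 1: 'B', 0: 'C', 3: 'D'}`: the four clusters, named by their
centroid features (A = lowest dysregulation, D = highest with rising
acceleration, C = remissive with the most negative KDM-advance slope). The
scored classes track the generator's targets — e.g. baseline per-class
KDM-advance means of 2.1 / 4.6 / −1.1 / −3.2 years (targets 2.41 / 4.91 /
−0.74 / −2.84) with SDs ≈ 1.9 years.

A single-marker sanity check of the KDM formula (slope 1, intercept 0,
RMSE 1, σ² = 100, marker value 60 at age 50):

```python
ba, advance = kdm_scores([60.0], 50.0, single_marker_model)
# ba = 59.9010, advance = 9.9010
```

The full pipeline is one call (or `agetraj all --config cfg.yaml`):

```python
from agetraj import PipelineConfig, run_pipeline
result = run_pipeline(PipelineConfig(out_dir="out", seed=1))
```

At the default emulated cohort (n = 27,948) this writes the cohort, scores,
assignments, selection report, baseline table, membership ORs, Cox table,
and mediation results; with seed 1 it selects k = 4 (clinical override
recorded; the CH rule alone favors coarser solutions, as the diagnostics
table shows), recovers the generating classes at ARI 0.63 with every cluster
majority-matching its true class, and reports a crude Progressive-class
hazard ratio of 1.10, a significant BMI-mediated share (p < 1e-4) and a null
diabetes share (p ≈ 0.49).

The CLI exposes each stage separately: `agetraj simulate | score | cluster |
cox | membership | mediate | report | all`, each taking `--config`, `--seed`,
`--out`.

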