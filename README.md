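# otva — site-of-origin analysis for outflow-tract ventricular arrhythmias

Outflow-tract ventricular arrhythmias (OTVA) are treated by radiofrequency
ablation, and the procedure's success hinges on knowing the site of origin
(SOO) — left or right ventricular outflow tract (LVOT / RVOT) — before the
catheter goes in. The 12-lead ECG of the patient's premature ventricular
contraction (PVC) encodes that origin, most visibly in the **precordial R/S
transition**: the first chest lead V1..V6 whose R wave dominates the S wave
(R/S ratio ≥ 1). Early transitions point left, late transitions point right.

This package is a tested, reusable implementation of that analysis chain
for researchers in ECG-based arrhythmia localization:

* **QRS morphology features** — each delineated QRS complex is reduced to
  120 values (mean voltage of each 10% section of the QRS, per lead), plus
  per-lead R/S measurements and the automatic precordial transition with
  all of its encodings (scalar lead index, one-hot vector, PVC−sinus
  standardized forms, raw R/S ratio vectors).
* **Experiment scenarios** — feature tables combining clinical covariates
  (age, sex, hypertension, V3 amplitude) with transition encodings (B.1–B.7),
  pure QRS morphology (A.1/A.2), and stacked combinations that feed the
  QRS model's prediction into the clinical model (C.1–C.5).
* **Supervised models** — nu-SVC, multilayer perceptron, random forest,
  extra trees and XGBoost, tuned by exhaustive 5-fold grid-search CV and
  scored with accuracy and the macro-average sensitivity

  MA = ½ · ( TP/(TP+FN) + TN/(TN+FP) ),

  with RVOT as the positive class — MA weighs both classes equally, so a
  degenerate always-RVOT classifier scores exactly 0.5 regardless of the
  class imbalance.
* **Interpretability** — Gini importances and exact tree-path Shapley
  attributions (positive values push toward RVOT), aggregated per lead and
  per 10% QRS section.
* **Unsupervised SOO structure** — Ward hierarchical clustering of the
  seven consolidated origin labels (RCC, LCC, RCC/LCC commissure, LVOT
  sub-valvular, LV summit, RVOT septum, RVOT free wall), with the
  dendrogram cut selected by silhouette grid search and results summarized
  as a cluster-by-origin frequency table.
* **Synthetic cohorts** — hospital OTVA data are rarely shareable, so the
  package ships a phenomenological 12-lead generator (Gaussian-bump QRS
  complexes driven by per-origin templates) whose cohorts carry the class
  structure the analysis relies on: earlier transitions and higher V1–V4
  voltage for LVOT, older/male/hypertensive LVOT covariates, and a
  clinician-transition noise model.

## Worked example

`examples/` contains one narrative script per capability. For instance,
`python examples/03_train_scenarios.py` trains four clinical-feature
scenarios on a 400-patient synthetic cohort and prints:

```
B.1: accuracy  96.2%  macro sensitivity  94.9%  (best family: xgboost)
B.2: accuracy 100.0%  macro sensitivity 100.0%  (best family: random_forest)
B.4: accuracy 100.0%  macro sensitivity 100.0%  (best family: svm)
B.5: accuracy 100.0%  macro sensitivity 100.0%  (best family: svm)
```

B.1 is the classical baseline (binarized age/V3 plus the clinician-read
transition); B.4 replaces thresholds with continuous values and the
clinician label with the computed transition vector. On synthetic cohorts
the computed transition is essentially noise-free while the simulated
clinician labels carry reading variability, so B.4 ≥ B.1 is the expected
ordering. `python examples/02_transition_detection.py` quantifies that
disagreement directly:

```
median transition lead  LVOT: V2, RVOT: V5
exact agreement with clinician labels: 28.3%
mean |shift|: 0.88 leads, median: 1, IQR: 1.0
```

i.e. the automatic and clinician transitions rarely name the same lead
but typically differ by a single position.

The same chain is available from a shell:

```
otva simulate --n 200 --seed 1 --out cohort/
otva train --scenario B.4 --cohort cohort/ --family xgboost --seed 1 --out report.json
otva explain --cohort cohort/ --out relevance/
otva cluster --cohort cohort/ --out clusters/
```

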