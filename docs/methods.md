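# Methods

## Problem and scope

The package classifies the binary site of origin (SOO) of outflow-tract
ventricular arrhythmias — left vs right ventricular outflow tract — from
the 12-lead ECG morphology of a premature ventricular contraction (PVC)
and basic clinical covariates, and explores the seven-way specific SOO
with unsupervised clustering. ECG delineation is out of scope: beats
arrive as fiducials (QRS onset / R peak / offset, 0-based sample indices,
half-open windows), produced upstream by any delineator or by the
synthetic generator.

## Feature definitions

**Decile morphology.** Each lead's QRS (onset→offset window, baseline
corrected by subtracting the lead's onset value so every lead starts at
exactly 0 mV) is summarized by the mean voltage of each 10% section,
giving 12 × 10 = 120 features in the fixed lead order I, II, III, aVR,
aVL, aVF, V1–V6. Section boundaries sit at the fractional sample
positions *i·n/10* and samples straddling a boundary contribute to both
sections in proportion to overlap. This duration-weighted definition is
exactly invariant to integer upsampling of the segment (so features do
not depend on sampling rate) and reduces to plain window means whenever
the segment length is a multiple of 10.

**R/S measurements and the precordial transition.** Per lead, R is the
maximum positive deflection and S the magnitude of the maximum negative
deflection of the baseline-corrected QRS (the S search is not restricted
to a post-R window; this is the simplest reading consistent with the
ratio's definition). The ratio is R/S with an epsilon rule: S below
ε = 1e-6 mV gives ratio 0 when R is also below ε, else the cap 1e6. The
transition index is the smallest k in 1..6 with ratio(Vk) ≥ 1 — ties
count as dominant, and later leads are not required to stay dominant
(first-crossing rule). When no chest lead qualifies, the sentinel index 7
is used and its one-hot encoding is the zero vector; this preserves the
length-6 vector semantics for the rare no-transition patients. The
PVC−sinus standardization subtracts the same patient's sinus-rhythm
transition, as a scalar difference and as the elementwise difference of
one-hot vectors.

**Clinical encodings.** Age is either divided by 100 (NormAge) or
binarized at a strict > 50 years (BinAge); V3 amplitude is the raw R peak
in mV or binarized at > 1 mV; sex is male = 1, hypertension yes = 1
(encodings chosen here; the convention is arbitrary but fixed).

## Models and evaluation

Five families are tuned by exhaustive grid search under stratified 5-fold
CV: NuSVC (nu ∈ {0.4, 0.5, 0.6}; rbf/linear/poly kernels with degree and
coef0 expanded only for poly), MLP (lbfgs/adam, alpha 1e-4..1e-6, single
hidden layer of 10/50/100 units, four activations), random forest and
extra trees (100–500 trees, fractional split/leaf minima 0.1–1), and
XGBoost (depth 1–10, min child weight 1–6 in halves, gamma 0–0.5,
sub-/column-sampling 0.6–1 in hundredths, L1 alpha 1e-5..100). That full
grid is enumerable but large (the XGBoost grid alone has 5,547,300
combinations), so the runnable default is a "fast" preset with at most a
handful of values per parameter; the full grid remains a config option.

The CV selection score is macro-average sensitivity — the unweighted mean
of the two class recalls, with RVOT fixed as the positive class — with
mean CV accuracy as tie-break and grid order as the final tie-break.
Selection never sees test rows. Held-out evaluation uses a per-database
stratified 80/20 split: per class, round(0.2·n) samples go to test, so a
79/35 cohort yields a 16 + 7 test set. Multi-database cohorts are split
per database and concatenated. Configurations whose fit fails (an
infeasible nu, for instance) are skipped rather than aborting the search.

Experiment C stacks the fitted QRS-morphology model's output onto the
best clinical block: its binary prediction (C.1), its RVOT probability as
a single column (C.2, the second class's probability being redundant in a
binary task), and/or its k most relevant decile features (C.3–C.5,
default k = 5 — the count is a free choice and configurable). Feature
ranking uses Gini importance with mean |Shapley| and name order as
deterministic tie-breaks. A redundancy ablation quantifies the overlap
between the transition vector and the stacked prediction by evaluating
the four add/remove combinations on a common split.

## Shapley attributions

Tree-ensemble attributions are computed exactly by the polynomial-time
tree-path algorithm implemented in `otva._treeshap`: the value function
is the tree's cover-weighted conditional expectation, and per-sample
attributions plus the base value reconstruct the model output (class-1
probability for forests; log-odds margin for XGBoost, which uses its
built-in tree-path attribution). The test suite checks both the
additivity identity (residual < 1e-4) and exact agreement with
brute-force coalition enumeration on trees with ≤ 3 features. Positive
attributions push toward RVOT. Kernel-style attributions for non-tree
models are deliberately not provided; Gini-based analyses require a tree
model and fall back to the best tree family when another family wins a
scenario.

## Clustering

The unsupervised experiment consolidates clinician SOO labels to seven
sites (the raw→consolidated map is user-supplied; hospitals use dozens of
free-text labels) grouped into three macro structures: RCC, LCC and the
RCC/LCC commissure form the aortic cusp group (anatomically part of the
LVOT but electrocardiographically distinct), LVOT sub-valvular and LV
summit form the LVOT group, and the two RVOT sites form the RVOT group.
The feature space is the B.4 clinical block plus the 120 decile features,
z-scored per column (constant columns left at zero) so clinical and
voltage features contribute on comparable scales — the standardization is
a design choice of this package. Ward linkage (SciPy) is cut at the
threshold maximizing the mean Euclidean silhouette over 50 candidates
evenly spaced between the smallest and largest merge heights; ties go to
the larger threshold (fewer clusters). Clusters are reported in
dendrogram leaf order and banded into thirds (top/mid/bottom, the middle
band absorbing the remainder, so 25 clusters band as 8/9/8).

## The synthetic cohort generator

Real OTVA cohorts are private, so every stage is exercised on synthetic
data designed to carry — and only to carry — the class structure the
analysis relies on:

* each PVC QRS is a per-lead sum of three Gaussian bumps (Q at 18%, R at
  45%, S at 75% of the QRS duration) plus white noise (default sd
  0.05 mV, 500 Hz sampling, amplitudes in mV, durations in ms);
* seven origin templates set the precordial R/S ramp so LVOT-side origins
  (including the aortic cusps) nominally transition by V3 with higher
  V1–V4 voltage, RVOT origins at V4–V5 with lower voltage; LVOT templates
  add a small early positive V2 deflection; the RCC template is
  deliberately the LVOT-side origin closest in amplitude space to the
  RVOT septum, so cusp/septum proximity is reproducible in clustering;
* the sinus beat uses one class-independent template (typical V3/V4
  transition) — all class signal rides on the PVC;
* covariates are class-conditional: LVOT age ~ N(62, 10), P(male) = 0.7,
  P(hypertension) = 0.6; RVOT age ~ N(45, 12), 0.4, 0.3; the RVOT class
  prior defaults to 0.69, the imbalance typical of clinical OTVA cohorts.
  These effect sizes are plausible in direction and magnitude but are
  configuration, not clinical truth;
* the clinician-reported transition is the nominal lead plus a −2..+2
  shift with probabilities (0.10, 0.25, 0.30, 0.25, 0.10), clipped to
  1..6 — a simple inter-observer noise model.

What passing tests show, and what they do not: the pipeline provably
recovers a planted, low-dimensional class signal under Gaussian noise and
reproduces all analytic contracts exactly. Synthetic cohorts contain no
P/T waves, no rhythm context beyond one sinus + one PVC beat, no
electrode-placement or axis-rotation variability, no delineation error
and no biophysical torso projection, so absolute performance figures on
synthetic cohorts (which approach 100% at default noise) say nothing
about accuracy on real patients — only the relative orderings (computed
transition ≥ noisy clinician transition; V1–V4 dominating the relevance
map; macro groups separating in the dendrogram) are the meaningful
read-outs.

## Problem sizes and numerical choices

Default study sizes are 600 patients for the supervised recovery
experiments (5 seeds), 280 (~40 per origin) for clustering, and 1,000 for
distributional checks of the generator — sizes at which the binomial and
law-of-large-numbers checks in the test suite have comfortable margins.
Grid-search ties are broken at 1e-12 tolerance; silhouette ties at 1e-12
toward fewer clusters; Ward merge ties follow SciPy's index order.
Degenerate inputs fail loudly: cohorts need ≥ 2 patients and both classes
per database for splitting, CV requires the rarer class to fill every
fold, segments need ≥ 10 samples, and an all-zero lead yields R = S = 0
with ratio 0.

## Known limitations

The generator is phenomenological; its waveforms are carriers for a
controlled signal, not electrophysiology. The no-transition sentinel (7)
and its zero one-hot are a convention for a case the underlying
definition leaves open. Gini-vs-Shapley rank disagreements are expected
(they measure different things on different data slices); the package
resolves them by fixed tie-break rules rather than judgment. Specific-SOO
classification is deliberately unsupervised — with realistic per-site
counts a supervised 7-way model would overfit.
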