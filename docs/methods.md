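# Methods

This note documents the models and procedures `sofatraj` implements, the
choices made where the design was genuinely open, and what the synthetic
study conditions do and do not establish.

## SOFA scoring

Total SOFA is the sum of six organ subscores (respiration, coagulation,
liver, cardiovascular, CNS, renal), each 0–4, evaluated on twelve
left-closed half-open windows [6(k−1), 6k) hours, k = 1..12, partitioning
the first 72 h of the ICU stay. A measurement at exactly hour 6 belongs to
window 2; records at or beyond hour 72 are dropped.

Within a window, the **worst** value per variable is the one that
maximises the resulting subscore: minimum for PaO2/FiO2, platelets, MAP,
GCS and urine; maximum for bilirubin, creatinine and vasopressor doses.
Daily urine output (mL/day) is divided by 4 to the 6-hour scale before
banding, so the oliguria thresholds are <125 and <50 mL/6 h. The lowest
GCS in a window is used irrespective of sedation.

Scoring bands follow the standard SOFA definition. Conventions worth
stating explicitly:

* respiration subscores 3–4 additionally require the patient-level
  respiratory-support flag; without it the subscore is capped at 2;
* the cardiovascular subscore is the maximum of the MAP band and the
  dose bands; an absent dose record means the drug was not administered
  (dose = 0), and the subscore is missing only when MAP *and* all doses
  are unrecorded;
* the renal subscore is max(creatinine band, urine band) ("or" semantics).

### Missing data

Two imputation layers, both strictly within the information available to
the scorer:

1. **Variable level**: a lab or vital missing in some windows is imputed
   per patient by last observation carried forward (LOCF), with next
   observation carried backward (NOCB) for leading gaps, *before*
   scoring. Vasopressor doses are exempt — an absent dose row is a
   structural zero (drug not given), not a missing value, and carrying a
   single-window dose forward would fabricate persistent vasopressor
   dependence.
2. **Subscore level**: an organ with no usable observation in any of the
   12 windows is zero-filled (assumed normal). `impute_trajectory`
   implements the generic LOCF→NOCB→zero rule on a subscore matrix and is
   idempotent.

A measured consequence, documented because it is easy to miss: zero-filled
organs produce trajectories that are *persistently* offset from the
patient's true curve. Window-level gaps at 10–30% are benign after
variable-level imputation, but even a 1–2% rate of fully-missing variables
creates enough persistent outliers to destabilise average-linkage
clustering at k = 4 on cohorts of a few hundred patients (outlier
singletons absorb cluster slots). Analyses that rely on cluster recovery
should either keep full-variable missingness low or treat zero-filled
organs with care.

## Trajectory distance

Dynamic time warping with squared local cost, full alignment and a final
square root:

    D(i,j) = (x_i − y_j)² + min(D(i−1,j), D(i,j−1), D(i−1,j−1)),
    dtw(x,y) = sqrt(D(n,m)).

No Sakoe–Chiba band: sequences are length 12, so each pair costs a 12×12
dynamic program and the full n×n matrix is vectorised one-row-vs-all.
DTW distances are symmetric, nonnegative, zero for identical sequences and
bounded above by the Euclidean distance for equal lengths; they do not
satisfy the triangle inequality. Distances are computed on the total-SOFA
trajectories only (not the 6-dimensional subscore curves).

## Hierarchical clustering and archetype naming

Agglomerative clustering runs directly on the precomputed DTW matrix via
Lance–Williams updates (average linkage default; complete and single
available). Ward linkage is deliberately not offered: it presumes squared
Euclidean geometry DTW does not have. Exact ties merge the
lexicographically smallest index pair, making the tree deterministic.
Cutting at k removes the k−1 highest merges; cluster ids 1..k are assigned
by descending size, ties by the smallest member index.

The cluster count is chosen by a majority vote of three
distance-compatible indices over k ∈ 2..8: mean silhouette (max), Dunn
index (max) and C-index (min), ties resolved toward the smallest k. On the
default archetype geometry this ensemble prefers k = 2: the Rapidly
Worsening archetype sits roughly three times farther from the other three
(pairwise DTW separations ≈ 6–8 SOFA points) than those three sit from
each other (≈ 2–3), so the coarse RW-vs-rest bipartition scores best on
all three indices at every noise level — even when the four generating
clusters are recovered at ARI ≈ 0.99. This is a known behaviour of
internal validity indices on hierarchically imbalanced data, not a
property of the noise; the per-k index table the module returns makes the
sharp within-dispersion elbow at k = 4 visible, and k can always be fixed
explicitly (as the pipeline default does).

At k = 4, clusters are named from their mean curve m: Δ_early =
m(window 8) − m(window 1) (first 48 h), Δ_late = m(window 12) − m(window 8)
(last 24 h). Sign pattern with tolerance ε = 0.1 SOFA points (suppressing
noise-level flips): (+,+)→RW, (−,−)→RI, (−,+)→DW, (+,−)→DI. If two
clusters collide on a label, the larger |m(12) − m(1)| keeps the Rapid
label of its family and the other takes the Delayed one; a Hungarian
match on normalised slope signs is the last-resort fallback for degenerate
shapes.

## Group-based trajectory modeling

The sensitivity arm re-derives groups under a parametric model: a G-class
mixture of polynomial growth curves, y_it | g ~ N(Σ_j β_gj t^j, σ²), with
time rescaled to [0,1] over the 12 windows (numerical conditioning),
shared residual variance across classes and time (the canonical minimal
form; both degree — default 2 — and G are configurable). Fitting is EM
with responsibilities initialised from seeded k-means partitions, 10
restarts, convergence when the log-likelihood improves by < 1e-6, σ²
floored at 1e-12 for degenerate noiseless fits. The log-likelihood is
monotone non-decreasing across iterations (standard EM guarantee, asserted
in tests). A restart that empties a class is discarded; an error is raised
only if all restarts collapse. Class count is selected by BIC
(−2·loglik + p·ln n, p = G(degree+1) + (G−1) + 1). Agreement between GBTM
hard assignments and the DTW+HAC partition is the adjusted Rand index.

## Group characterization

Categorical covariates: R×C chi-square without continuity correction,
switching to Fisher's exact test for 2×2 tables with any expected cell
below 5. Continuous covariates: a per-group Shapiro–Wilk screen at
α = 0.05 decides between mean (SD) with t-test/ANOVA and median [IQR] with
Mann–Whitney/Kruskal–Wallis; groups smaller than 12 skip the screen and go
nonparametric (the screen is uninformative at such sizes). All tests are
two-tailed omnibus tests across the groups at α = 0.05.

Survival uses the Kaplan–Meier product-limit estimator and the
multivariate log-rank test (df = groups − 1), both via lifelines, with
administrative censoring at 28 days applied upstream by the generator.

## Early prediction

Feature snapshots at cutoff t ∈ {6, 24, 36, 48, 60} h use only
measurements with hour < t: demographics (age, sex), comorbidity index,
ventilation and septic-shock flags, each organ's latest and worst-so-far
subscore (computed by re-running the scoring pipeline on the truncated
stream, so NOCB never sees past the cutoff), and each variable's worst raw
value, median-imputed with paired missingness indicators. Leakage-freedom
is tested by corrupting all data at hours ≥ t and asserting the snapshot
is unchanged.

The classifier is a 500-tree random forest with sqrt-feature subsampling
on a stratified 70/30 split; all cutoffs share one split so accuracies are
comparable. Accuracy CIs are percentile bootstrap (default 1000 resamples
of the held-out set). Attribution uses Monte-Carlo permutation Shapley
values: for each explained observation, marginal contributions are
averaged over random feature orderings (default 200), absent features
drawn from a background sample; per permutation the contributions
telescope, so attributions sum exactly to f(x) minus the mean output over
the drawn background rows. For multi-class models the explained output is
the predicted class's probability.

## Synthetic cohort generator

The generator defines the study conditions for all tests. Four archetypes
with 12-point mean total-SOFA curves anchored at the endpoint/inflection
values of the cohort it emulates, linear in between: RW 4.5→7.2; DW 5.2
falling to 3.7 at window 8 then rising to 4.8; RI 5.5→2.8; DI 4.0 rising
to 5.2 at window 6 then falling to 3.5. Default prevalences
13.1/20.5/41.3/25.1% and in-hospital mortality 28.3/10.6/5.5/10.7%
(RW/DW/RI/DI).

Per patient and window, each organ's latent is mean_curve·w_o plus
Gaussian noise with sd = noise_sd·w_o, where w is the archetype's organ
weight vector (RW skewed to liver/coagulation/respiration, RI to
cardiovascular/CNS/renal, DW to resp/coag/CNS/renal, DI to
resp/coag/cardiovascular — the qualitative organ-dysfunction patterns
associated with each archetype). The latent total is therefore a noisy
copy of the mean curve with per-window sd = noise_sd·sqrt(Σw²) ≈
0.45·noise_sd; it is rounded, clipped to [0,24], and decomposed back into
integer subscores by largest-remainder rounding of the noisy organ shares
(sum-preserving, capped at 4 with overflow pushed to the organs with
headroom). With noise_sd = 0 the decomposition is exact, giving the
noiseless round-trip property: the SOFA engine reproduces every generated
subscore bit for bit.

Raw measurements are back-generated by emitting, per subscore, a value in
the interior of the corresponding band (e.g. platelets 120 for
coagulation 1; norepinephrine 0.05 plus MAP 63 for cardiovascular 3), one
record per variable per window at a uniformly jittered timestamp, plus
normal urine, and two severity-tracking auxiliary measurements (lactate,
heart rate). The ventilation flag is set for patients whose respiration
subscore ever reaches 3, keeping rubric and generator consistent.

Missingness is MCAR at two levels (defaults: 10% per variable-window, 2%
per patient-variable for the whole 72 h), dose records exempt. Outcomes:
death ~ Bernoulli(archetype mortality), death times uniform on (0, 28]
days, survivors censored at 28 days; length of stay log-normal around the
archetype median. The missingness mechanism of the emulated cohorts is
unreported; MCAR is a choice, not a claim.

**What passing tests show — and don't.** The generator produces
rubric-consistent, archetype-shaped data with realistic marginal rates; it
does not model inter-variable physiology beyond the subscore structure,
treatment feedback, informative missingness, competing risks, or
measurement error inside a band. Recovery results (ARI ≈ 0.8–1.0,
prediction accuracy ≈ 0.95) therefore certify the pipeline's correctness
under its stated conditions, not expected performance on real EHR data,
where trajectory overlap is larger and accuracy substantially lower.

## Problem sizes

Tests and the acceptance script run at sizes chosen to make the checks
sharp while keeping the suite quick: clustering-recovery sweeps use
n = 400 patients × 20 seeds at noise 0.5 and 1.0 (without missingness, to
probe the distance/clustering stage in isolation); GBTM selection n = 300;
prediction sweeps n = 2000 × 10 seeds; the end-to-end determinism check
n = 400 with 10% window-level missingness; the acceptance script n = 2000
for cohort-level quantities and n = 400 for the recovery arm.

## Known limitations

* Average-linkage HAC is outlier-sensitive at small n; below ~200 patients
  the k = 4 cut frequently yields singleton clusters even on clean data.
* The cluster-count index ensemble prefers the coarse bipartition on this
  archetype geometry (see above); k must be fixed to 4 to reproduce the
  four-group analysis.
* GBTM assumes shared residual variance and polynomial class means; the
  piecewise-linear DW/DI archetypes are approximated, not matched, by
  quadratics.
* FiO2 estimation from oxygen-delivery devices, sedation adjustment of
  GCS, Cox models, competing risks and cross-cohort replication are out of
  scope.
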