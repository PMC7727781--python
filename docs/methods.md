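# Methods

`ventphen` re-implements a latent-profile phenotyping pipeline for
mechanically ventilated ICU patients: a finite Gaussian-mixture model over
22 first-24-hour clinical variables, fitted by EM, with phenotype-number
selection, population-stability validation between a training and a
held-out cohort, and phenotype-stratified 28-day mortality reporting. This
note records the model, the synthetic cohort generator the tests run
against, the numerical choices, and the known limits of what the synthetic
results demonstrate.

## The latent profile model

Each patient contributes a vector x ∈ R^D of z-scaled features. The
mixture density is

    p(x) = Σ_{l=1..K} p_l · N(x; μ_l, Σ_l),

with diagonal Σ_l in one of two constraint modes:

* **model_1** — equal variance: one variance per dimension shared by all
  classes (Σ_l = diag(σ²_1..σ²_D) for every l);
* **model_2** — varying variance: class-specific diagonal variances.

Patients are assigned to the phenotype with maximal posterior membership
p(z = l | x) ∝ p_l · N(x; μ_l, Σ_l), computed in log space with
log-sum-exp normalization.

EM alternates responsibilities (E) and weighted parameter updates (M); the
observed-data log-likelihood is non-decreasing across iterations, which the
test suite asserts on every fit. Fits restart from k-means++-seeded means
(uniform weights, pooled per-dimension variance start) and stop when the
relative log-likelihood gain falls below `tol` or `max_iter` is reached.

**Degenerate restarts.** A diagonal-Gaussian likelihood is unbounded
whenever many identical values exist in a column: a component can center on
the tie and crush its variance to the floor, gaining arbitrary likelihood.
The cohort data have exactly such an atom — SpO2 is capped at 100% and
roughly a fifth of patients sit on the cap — and varying-variance fits
reliably find these spurious maxima (a component's SpO2 variance lands on
the floor while BIC improves by thousands). A restart is therefore flagged
degenerate when any class weight drops below 1/(10n) **or** any fitted
variance lies at the variance floor; the best non-degenerate restart wins,
and the model-selection sweep refuses to choose a K for which no
non-degenerate restart exists. This is the usual spurious-maximizer
safeguard in mixture modelling; the pooled-variance mode is structurally
immune (a shared variance cannot collapse onto one class's atom), which is
a practical argument for that mode on bounded clinical variables.

### Defaults and why

| parameter | default | rationale |
|---|---|---|
| covariance mode | model_1 (pipeline) | the mode the source analysis adopted; immune to atom collapse |
| restarts | 10 | k-means++ seeding converges fast; 10 restarts make the winning optimum stable across seeds |
| tol | 1e-6 (relative loglik) | parameter movement at convergence ≈ 1e-3–1e-4, well below reporting precision |
| max_iter | 500 | typical convergence is 25–60 iterations on n ≈ 4000 |
| variance floor | 1e-6 (z-scale) | numerical guard only; a variance *at* the floor marks a degenerate restart |
| class labels | sorted by descending weight; optional re-map to phenotypes I..V by nearest published reference profile (Hungarian matching, Euclidean on the z scale) | the published label order is not size-ordered |

### Fit criteria

* **BIC** = −2·loglik + q·ln n with q = (K−1) + K·D + D (model_1) or
  (K−1) + 2·K·D (model_2); lower is better.
* **Relative entropy** E = 1 − [−Σ_i Σ_k p_ik ln p_ik]/(n ln K); 1 means
  perfectly crisp assignment.
* **Selection rule** (`sweep_k`): minimize BIC among fits with
  (a) smallest estimated mixing proportion ≥ 4% ("adequate size" — read as
  the latent class proportion, the standard usage), (b) median max
  posterior ≥ 0.7, and (c) a non-degenerate winning restart. If nothing is
  admissible the pure BIC minimum is returned, flagged. The floors
  quantify the qualitative criteria ("adequate size, high median
  membership probabilities") and are configurable.

## Preprocessing

* **24-h aggregation**: arithmetic mean per patient-feature over
  observations in [0, 24) h; absent observations leave the cell missing.
* **Imputation**: chained equations with predictive mean matching. Missing
  cells start at column means; each incomplete column is then cycled
  (default 10 cycles), regressing it by OLS on all other columns over its
  originally observed rows and redrawing missing entries from the 5
  donors with nearest predicted values. Multiple imputations (default 1,
  as a single completed table feeds the mixture fit) are averaged
  cell-wise. Observed cells are never altered. The fitted column models
  and donor pools are retained so a validation cohort is imputed with
  training information only (split first, impute within split — no
  leakage).
* **Screening**: pairwise Spearman |ρ| ≥ 0.75 drops the member of a pair
  with more original missingness (tie: later panel order), strongest pair
  first. Off by default — it is a sensitivity analysis, and the primary
  panel keeps all 22 variables.
* **Scaling**: per-feature z-score with the training mean and sample SD
  (ddof = 1); validation data always use the training scaler. Fitting on
  the z scale makes a pooled-variance model meaningful across variables
  with incommensurate units; profile tables are reported back on the
  original scale through the stored scaler.

## The synthetic cohort generator

The generator emulates the published training cohort so every stage is
testable without hospital data:

* five latent phenotypes with mixing weights (54.2, 12.0, 6.01, 9.18,
  18.6)% — renormalized to an exact simplex, as printed they sum to
  99.99%;
* per-phenotype feature distributions: independent Normals per variable
  within class, means/SDs from the published per-phenotype table (22
  variables: demographics, APACHE II/SOFA, ventilator settings and gas
  exchange, circulation/perfusion, 24-h fluid balance);
* MCAR missingness at the published marginal ratios (APACHE II 12.45%,
  SOFA 10.03%, CVP 43.18%, Pv-aCO2 45.02%, Pv-aCO2/Ca-vO2 ratio 47.09%;
  all others complete);
* 28-day mortality per phenotype (1.23, 18.1, 1.40, 27.4, 1.59)%, death
  day uniform on 1..28 (no hazard shape is published), survivors censored
  at day 28;
* support constraints: age clipped at 18 (adult cohort), SpO2 capped at
  100%; fluid balance may be negative.

**What the generator does not carry.** Within-class independence is a
deliberate simplification (zero covariance matches the fitted model
family), and it has consequences the tests make visible:

* *Class overlap.* Under independent Gaussians at the published means/SDs,
  phenotypes I, III and V overlap substantially. The Bayes-optimal
  classifier — the true generative model applied to uncorrupted data —
  reaches an adjusted Rand index of only ≈ 0.82–0.84 against the latent
  labels, so no fitted model can do better; fitted varying-variance
  mixtures reach ≈ 0.55–0.78 and pooled-variance fits ≈ 0.66–0.70. The
  crisp real-data classes the source reports (median posterior, entropy)
  evidently rest on structure — within-class correlation, non-Gaussian
  shape — that this emulation does not reproduce. Synthetic recovery
  results therefore demonstrate pipeline correctness and the achievable
  accuracy *under this generator*, not the clinical separability of the
  phenotypes.
* *Imputation ceiling.* Because features are independent within class, the
  best possible imputer of CVP given all other variables has residual
  variance equal to the pooled within-class variance: with the published
  CVP parameters the maximal RMSE improvement over mean imputation is
  1 − √(2.905/3.845) ≈ 13%. Chained-equation PMM with averaged draws
  approaches but cannot exceed this bound (single-draw PMM is *worse* than
  mean fill in RMSE, by design — it preserves the predictive
  distribution, trading a √2 RMSE penalty for calibrated spread).
* *Model selection.* The generator is a varying-variance mixture, so the
  phenotype-number study fits model_2 — BIC consistency requires the
  fitted family to contain the truth. On 20 synthetic cohorts of n = 4000
  the sweep selects K = 5 in 20/20 runs. The pooled-variance mode, fitted
  to data it is misspecified for, compensates for unmodelled
  heteroscedasticity with extra components and does not recover K = 5;
  on real data the source adopted it, which is consistent with real
  phenotypes being more separated than this emulation.

## Stability and outcomes

* **PSI** = Σ_bins (actual% − expected%)·ln(actual%/expected%) between two
  phenotype count distributions; symmetric, non-negative, zero iff equal.
  A bin empty in either vector receives 0.5-count additive smoothing in
  both (flagged); < 0.1 is the conventional "no shift" band. On the
  published training/validation phenotype counts the package computes
  0.0045.
* **SOFA segments**: [0,4], (4,6], (6,9], (9,22] exactly as printed (first
  bin closed, then left-open); out-of-range scores are clamped into the
  boundary bins and flagged (the synthetic Gaussian SOFA occasionally
  exceeds 22). Cells display only when segment mortality exceeds 2%,
  reproducing the chord-plot exclusion of uniformly low-mortality
  phenotypes. Chord/alluvial figures are emitted as tidy tables, not
  graphics.
* **Survival**: per-phenotype Kaplan–Meier (lifelines) with administrative
  censoring at day 28; with no earlier censoring the day-28 cumulative
  mortality equals crude deaths/n, asserted to 1e-12.
* **Profiles**: per-phenotype mean ± sd on the original scale, z-scale
  means for profile plots, and a descriptive one-way ANOVA p per feature
  (no multiplicity correction, mirroring the source's per-row p values).

## Pipeline and determinism

One global seed fans out to per-stage child seeds by fixed offsets
(simulate +0, split +1, impute +2, EM +3), so stages can be rerun in
isolation. The train/validation split assigns exactly round(ratio·n)
patients to training via a seeded permutation. Reruns with an identical
config reproduce every numeric artifact bit for bit; the manifest records
config, row counts, warnings (variance-floor hits, PSI smoothing, collapsed
restarts) and a SHA-256 checksum of every written file.

Problem sizes used in the shipped studies: synthetic cohorts of n = 4000
(matching the published training cohort scale), 20 seeds for the
phenotype-number study, 10 seeds for parameter recovery, 3 for the
imputation hide-and-recover experiment.

## Known limitations

* The generator's within-class independence understates real-data class
  separability (see above); conclusions about clinical phenotypes must
  come from real cohorts.
* PMM imputation assumes approximately linear relations between variables;
  nonlinear imputation models are out of scope.
* No bootstrap uncertainty on PSI, no cross-validated likelihood for K
  selection, no full-covariance mixtures, no regression adjustment or
  competing risks in the outcome analysis.
* The mortality-PSI variant reported alongside the population PSI in the
  source is not emitted as a default report: its binning is not
  reconstructible from the published counts; the generic `psi()` covers
  any user-supplied count pair.
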