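# ventphen

Latent-profile phenotyping of mechanically ventilated ICU patients.

Critically ill patients on mechanical ventilation are clinically
heterogeneous: identical ventilator strategies can help one subgroup and
harm another. `ventphen` implements the statistical pipeline used to
discover such subgroups from routine first-24-hour data: a finite
Gaussian-mixture (latent profile) model over 22 clinical variables —
demographics, APACHE II and SOFA severity scores, ventilator and gas
exchange parameters, circulation/perfusion markers and fluid balance —
fitted by EM under two constraint modes (shared or class-specific diagonal
variances), with

* phenotype-number selection by BIC plus adequacy rules (class size,
  median membership certainty, relative entropy, non-degeneracy),
* maximum-posterior patient assignment,
* population-stability validation between training and held-out cohorts
  via the population stability index
  PSI = Σ (actual% − expected%)·ln(actual%/expected%),
* phenotype-stratified outcomes: feature profiles, SOFA-segment mortality
  tables with a >2% display filter, and 28-day Kaplan–Meier cumulative
  mortality.

The model: p(x) = Σ_{l=1..K} p_l · N(x; μ_l, Σ_l) with diagonal Σ_l, and
patient assignment by the posterior p(z = l | x) ∝ p_l · N(x; μ_l, Σ_l).

Because the hospital cohort is not public, the package ships a synthetic
cohort generator that emulates the published five-phenotype structure
(mixing weights 54.2/12.0/6.01/9.18/18.6%, per-phenotype feature
distributions, per-variable missingness up to 47%, phenotype-linked 28-day
mortality of 1.23/18.1/1.40/27.4/1.59%). Every stage of the pipeline is
exercised and tested against it; `docs/methods.md` spells out what the
generator does and does not emulate.

## Worked example

The `analysis/` scripts run the study end to end on a synthetic cohort
(each also accepts `--seed`/`--outdir`):

```sh
python analysis/01_simulate_cohort.py     # 5013 patients, 4:1 split
python analysis/02_preprocess.py          # chained-equation imputation + scaling
python analysis/03_select_phenotype_number.py
python analysis/04_fit_and_validate.py
python analysis/05_outcomes.py
```

The selection sweep prints the per-K rule trace and recovers the five-class
structure:

```
 K           bic  entropy  min_class_prop  median_max_posterior  admissible
 2 227794.364039 0.960279        0.225206              0.999991        True
 3 224524.597411 0.963718        0.107576              0.999903        True
 4 222889.618285 0.891818        0.102906              0.994145        True
 5 222475.726158 0.887179        0.050111              0.990520        True
 6 222634.078221 0.872996        0.025735              0.982586       False
 ...
chosen K = 5
```

K = 5 minimizes BIC among fits whose smallest class keeps at least 4% of
the cohort and whose median max-posterior stays above 0.7 — larger K fits
shave off sub-scale classes and are excluded. Fitting and validating that
model:

```
fitted K=5 (model_2), loglik -110308.7, converged True in 32 iters
phenotype counts (train):      [2189, 539, 152, 396, 734]
phenotype proportions (train): [54.6, 13.4, 3.8, 9.9, 18.3]
phenotype counts (validation): [580, 139, 48, 84, 152]
population stability index = 0.0127 (no meaningful shift)
```

The fitted proportions track the generating weights (54.2/12.0/6.0/9.2/
18.6%), and the PSI between the training and validation phenotype
distributions sits far below the conventional 0.1 "no shift" band. The
outcome stage then stratifies 28-day mortality:

```
28-day cumulative mortality by phenotype:
  phenotype 1: 1.0%  (n=2189)
  phenotype 2: 16.1%  (n=539)
  phenotype 3: 3.9%  (n=152)
  phenotype 4: 25.3%  (n=396)
  phenotype 5: 1.0%  (n=734)
```

— mortality concentrates in phenotypes II and IV (generated at 18.1% and
27.4%), while I, III and V stay near 1–2%, and the SOFA-segment table
shows which severity segments carry those deaths.

The same pipeline is available as a CLI (`ventphen run`, plus per-stage
subcommands `simulate`, `preprocess`, `select`, `fit`, `assign`,
`validate`, `outcomes`) and as a library:

```python
import ventphen as vp

res = vp.psi([2174, 480, 241, 368, 746], [542, 124, 52, 81, 205])
print(round(res.total, 4))   # 0.0045
```

## Layout

```
src/ventphen/        library: panel, simulate, preprocess, mixture,
                     selection, outcomes, pipeline, cli
analysis/            numbered end-to-end study drivers
scripts/acceptance.py
tests/               pytest suite (unit, property and end-to-end checks)
docs/methods.md      model, generator, numerical choices, limitations
```
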