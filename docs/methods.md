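# Methods

## The prediction problem

Primary TKA with the PFC Sigma system uses a femoral component in eight
side-specific sizes: 1.5, 2, 2.5, 3, 4 Narrow, 4, 5, 6. "4 Narrow" is a
size-4 implant with reduced mediolateral width housed on its own 0.5 DIN
tray; for modeling it is merged into size 4 (its instrumentation choice is
made intraoperatively, not predicted), leaving seven modeled sizes.

Femoral size is modeled with a multinomial logistic regression on five
preoperative predictors: sex (female = 1), height (cm), weight (kg), BMI
(kg/m²), and prosthesis side (right = 1), all on their natural units, with
size 3 — the modal size — as the reference category:

    log P(size = k | x) / P(size = 3 | x) = α_k + β_k' x .

`exp(β_kj)` is the odds ratio of size *k* versus size 3 per unit of
predictor *j*. Probabilities are the softmax of the linear predictors with
the reference fixed at zero.

### Fitting

BMI is a near-deterministic function of height and weight, so the design
is strongly collinear (condition number ≈ 50 after centering), and the
rarest size (1.5; 2 of 4,980 cases in the reference cohort) is
quasi-separated in realistic samples. The estimator therefore maximizes a
ridge-penalized likelihood, with penalty λ/2·‖slopes‖² (intercepts
unpenalized) and default λ = 1e-6 — numerically negligible for
well-populated sizes but keeping separated classes bounded. Predictors are
centered internally for conditioning; reported coefficients are on the
natural scale (slopes are unaffected by centering).

The default solver is Newton–Raphson with step halving; the observed
information at the optimum doubles as the Wald covariance for odds-ratio
confidence intervals, `exp(β ± 1.96·SE)`. Convergence requires either a
mean absolute score below 1e-7 or a relative objective decrease below
`tol` (default 1e-9); non-convergence sets `converged_ = False` with a
warning rather than raising, because quasi-separated replicates still
yield usable predicted probabilities. An L-BFGS fallback solver is
available. The fitter is cross-checked against `statsmodels.MNLogit`
(coefficients to 1e-5, slope SEs to 1e-6) on a well-conditioned fixture in
the test suite.

Classes absent from a training split are dropped from that replicate's
model and can never be predicted by it; if such a size occurs in the test
split it counts as a misprediction. Exact probability ties in `predict`
resolve to the smaller size.

## Synthetic cohort generator

The registry extract is not redistributable; the generator emulates its
published summary so the pipeline is testable end to end. The defaults are
the study conditions and are not tuning knobs.

* **Sex**: Bernoulli(3154/4980 female).
* **Height**: sex-conditional Gaussian. The male–female mean gap is fixed
  at 15 cm (typical adult sexual dimorphism); the sex means and the common
  within-sex SD are solved so the pooled mean/SD equal 168.6/9.7 cm
  exactly (female 163.1, male 178.1, within-SD 6.47).
* **Weight**: linear in height at 0.8 kg/cm (a realistic adult
  weight-height gradient) plus a Gaussian residual solved so the pooled
  mean/SD equal 85.3/15.6 kg.
* **BMI**: computed exactly as weight/(height/100)², never drawn.
  Implausible triples (height outside 100–230 cm, weight outside
  30–250 kg, BMI outside 12–70) are redrawn.
* **Size**: drawn from the multinomial logit above with slopes equal to
  the log odds ratios of the registry-fitted model
  (`REFERENCE_ODDS_RATIOS`). The published model reports no intercepts, so
  they are calibrated by fixed-point iteration
  (α_k ← α_k + log(target_k / implied_k), size 3 anchored at 0) against a
  200,000-draw Monte Carlo sample of the predictor distribution until the
  implied marginal size distribution matches the observed one to 1e-3 on
  the log scale. Size-4 draws are split into 4 Narrow with probability
  346/1476.
* **Side, femur type, insert thickness, patellar resurfacing**: drawn
  independently at the observed frequencies (right 52%, PS 68%,
  resurfacing 78%).

What the generator does *not* emulate: any dependence of femur type,
insert thickness, or resurfacing on patient anthropometrics; secular
trends over the accrual decade; within-surgeon clustering; and the true
joint covariate distribution beyond the sex/height/weight structure above.
Passing tests therefore demonstrate that the pipeline recovers its own
generating process and reproduces the published accounting identities, not
that the model attains any particular accuracy on real registry data —
observed cross-validated accuracies on synthetic cohorts run ~1–6 points
below the published real-data values depending on the scenario.

### Identifiability of the recovery check

Parameter recovery (refit at n = 100,000) is assessed over the sizes with
at least 500 expected cases. Size 1.5 (~40 expected cases) is
quasi-completely separated and its ML slopes are not consistent at this
n — no estimator recovers them. Moreover, estimation error concentrates
along the height/weight/BMI collinearity null direction, so individual
collinear slopes wander (±2σ excursions of ~0.05–0.18 on the log scale)
while the aggregate slope matrix and the predictive distribution are
tightly identified. Recovery is therefore asserted as (i) aggregate
Frobenius relative slope error ≤ 10%, (ii) every well-populated slope
within 3 Wald SEs of truth, and (iii) mean absolute probability error
< 0.01 against the generating model on a fresh draw.

## Tray scenarios and counting rules

Twelve catalogued scenarios (A–L) group the seven sizes into 1–3 sets; a
set of up to three sizes occupies one surgical tray, larger sets two.
Assignment is anchored on the most probable size: it identifies the
candidate set(s); if it lies in two sets (an overlapping size), the set
with the larger summed member-size probability is prepared (ties: lower
set index). An alternative rule that always takes the highest-sum set is
available via `rule="sum"` but is not the default. A prediction is
*correct* when the implanted size is in the prepared set. Tray count per
patient is the prepared set's trays, plus — on a miss — the trays of the
cheapest set containing the implanted size. 4 Narrow maps to size 4
throughout the scenario logic.

Cross-validation repeats an unstratified 80/20 split (default 500×); one
model fit per replication serves all scenarios, so scenario contrasts are
paired. A training split with fewer than two size classes is redrawn (up
to a cap). The accuracy interval is the 2.5–97.5 percentile range of
replication accuracies: the procedure averages performance across runs,
and the percentile band is the natural summary of that replication
distribution.

Note one structural consequence of these rules: in scenarios whose two
main ranges share the modal size 3 (D, I), patients predicted size 3 are
assigned to a single range by the probability-sum tie-break, and a
patient whose implanted size falls in the *other* range counts as a miss.
Crediting such patients with the union of both ranges would raise D and I
by several accuracy points; the implemented definition deliberately counts
membership in the single prepared set only.

## DIN accounting

Tray usage is accumulated in exact half-DIN integer arithmetic. The
standard setup charges 7 DIN per case plus add-ons: size 1.5 (+1, a
request-only tray), size 4 Narrow (+0.5), size 6 (+1), and PS femur type
(+1, box sawing guides). The optimized setup — built around the adopted
two-range scenario with further reshuffling — charges 6 DIN plus the same
size add-ons, +0.5 for a 15 mm trial insert, +1 for patellar resurfacing
(both moved off the standard trays), and +1 per wrongly predicted case;
PS instruments fit the reorganized tray at no extra charge. Outlier-size
trays are charged per femoral size only (the shared size-6 tray is not
triggered by tibial size), and insert thicknesses above 15 mm were never
on the standard tray and trigger nothing.

Rate-based lines charge a whole number of cases, `round(rate × n)`: trays
are opened for whole patients, and this reproduces the published line
(129 wrong-size DIN at rate 0.026, n = 4,980; the unrounded product would
be 129.48) and total (34,212.5 DIN vs 38,529 standard, a 11.2%
reduction). The accuracy interval propagates monotonically: the lower
accuracy bound yields the upper tray bound.

## Sustainability conversion

Carbon scales with tray footprint: kgCO₂eq saved =
DIN saved × 2.14 × (1 − 0.52), where 2.14 kgCO₂eq/DIN is a Dutch-hospital
sterilization footprint and 52% is the emission reduction already achieved
by reusable rigid containers relative to single-use wrap (so eliminating a
tray that would have been sterilized in a rigid container saves
≈ 1.03 kgCO₂eq per DIN). Cost scales with tray count at €29.6 per tray (a
size-agnostic UK decontamination figure). Arithmetic is unrounded
internally; display rounds carbon to 2 decimals and euros to 1. Both
factors are overridable for hospital-specific energy mixes and prices.

## Problem sizes used in the test suite

Marginal-convergence checks use a 50,000-case draw (tolerances ±0.02 on
proportions, ±0.5 on pooled moments); parameter recovery uses 100,000
cases; scenario evaluation uses a 4,980-case cohort with 100 replications,
which estimates the paired scenario contrasts to well under a percentage
point. These sizes make the full suite run in well under a minute while
keeping Monte Carlo error far below every asserted margin.

## Known limitations

* Odds-ratio CIs are Wald intervals from the penalized observed
  information; for separated classes they are meaningless (as are the
  published degenerate CIs for size 1.5) and should be read only for
  well-populated sizes.
* The scenario search space is the fixed catalog (plus user-supplied JSON
  catalogs); the package does not enumerate all partitions of the size
  range.
* Tibial size prediction is out of scope; tibial counts are carried only
  as summary metadata.
* The DIN rules encode one hospital's tray composition; other sites should
  encode their own setups via `TraySetupRule`.
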