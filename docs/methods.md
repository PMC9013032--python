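# Methods

## Outcome and features

The unit of analysis is one adult (age ≥ 18) inpatient encounter with its
list of coded ICD-10-CM diagnoses, each carrying a present-on-admission
(POA) flag and a principal/secondary position. The 4-level APR-DRG-style
severity of illness is collapsed to a binary outcome: levels 1–2
(minor/moderate) are *low*, levels 3–4 (major/extreme) are *high*. All
models predict the probability of high severity.

Two feature families are constructed per encounter and phase:

* **Body-system CC/MCC indicators** (18 ordinal variables). Every
  diagnosis code maps to at most one of 18 body systems; a system scores
  2 if any of its codes is designated CC or MCC, 1 if it has codes but
  none CC/MCC, 0 otherwise. The principal diagnosis participates (see
  Design choices).
* **Elixhauser comorbidity flags** (30 binary variables), set when any
  *secondary* diagnosis maps to the category. The 30-name registry
  follows the classic Elixhauser set (with a single combined hypertension
  category); it is configurable because category definitions drift across
  releases of the comorbidity software.

Phases differ only in code selection: *discharge* uses every diagnosis,
*admission* uses diagnoses with POA flag in {Y, W} plus POA-exempt codes
regardless of flag. Admission features are therefore an elementwise lower
bound of discharge features — an invariant the tests enforce.

## Regression model

Each ordinal indicator enters through orthogonal polynomial contrasts
over equally spaced scores (the `contr.poly` construction: for three
levels, a linear column ∝ (−1, 0, 1)/√2 and a quadratic ∝ (1, −2, 1)/√6),
each binary flag through the two-level contrast ∝ (−1, 1)/√2. The
contrasts are an orthonormal basis change of the factor's dummy encoding:
they leave the model space, fitted probabilities and deviance untouched
(verified to 1e−8 against a one-hot encoding), while making the linear
and curvature components of each ordinal effect separately readable.

Three fixed variants are compared: *full* (18 ordinals + 30 flags = 48
variables, 66 columns), *comorbidity* (30), *body system* (18 variables,
36 columns). No interaction terms are included. The outcome model is a
binomial GLM with logit link; "probability of high severity" demands a
link with range (0, 1), and the logit is the standard choice for this
kind of administrative-data severity model. The fitted probabilities of
the body-system variant are the reported scores (J_Score from discharge
features, J_Score_POA from admission features); admission and discharge
models are fitted independently with the same algorithm.

### Estimation

Maximum likelihood via iteratively reweighted least squares. Starting
from β = 0, each step solves the weighted normal equations
(XᵀWX + λI)β = XᵀWz with W = diag(μ(1−μ)) and working response
z = η + (y − μ)/W. Numerical choices:

* convergence when the relative deviance change drops below 1e−8, at most
  100 iterations; non-convergence is reported in the results object, not
  silently ignored;
* rank-deficient designs (a factor level never observed) fall back to the
  minimum-norm least-squares step instead of failing;
* the optional ridge penalty λ (never applied to the intercept; default
  0) is the documented escape hatch for separated data. Under the
  unpenalized default, a perfectly classified fit with vanishing deviance
  — or a diverging linear predictor that fails to converge — raises a
  `SeparationError` advising the ridge option. Quasi-separation is a real
  phenomenon in small cohorts with 66 columns and rare comorbidity
  columns, not just a fixture artifact.
* standard errors come from the inverse observed information at the
  optimum (pseudo-inverse when singular). The IRLS fitter is cross-checked
  in the test suite against a direct numerical maximization of the
  log-likelihood and against an independent GLM implementation.

## Validation protocol

Encounters are split 3:1 (simple random; stratification by outcome is
available but off by default, since at realistic cohort sizes the
marginal distributions of the two halves agree closely anyway). For each
variant and phase the model is fitted on the training set, the ROC curve
swept over all distinct fitted scores (ties grouped), and the
classification cutoff chosen to minimize √(FPR² + (1−TPR)²) — the
Euclidean distance to the ideal corner — with ties broken toward the
larger threshold (the more conservative high-severity call). The rule
"predict high iff score ≥ cutoff" is then applied unchanged to the test
set to obtain accuracy, FPR = FP/(FP+TN) and FNR = FN/(FN+TP).

ROC AUC uses the trapezoidal rule, which equals the Mann–Whitney pairwise
concordance probability (asserted exactly against a brute-force pairwise
oracle, including ties). PR area uses the average-precision step sum
rather than trapezoidal interpolation, which is known to be optimistic
for PR curves. Cohort comparison tables report mean/SD with a Welch
two-sample test for age and counts/proportions with an uncorrected
Pearson chi-square test for categorical variables.

## Scoring analytics

Scored encounters are written as one delimited row per encounter, and
every downstream report (score histograms, monthly trend, CDI group
comparison, per-facility high-severity proportions) consumes only that
file, so reports are bit-reproducible from the scored output alone.
Because a logistic probability never equals 1 exactly, "scores of 1" are
counted as scores ≥ 0.995, i.e. values that display as 1.00 at
two-decimal rounding (threshold configurable). Trends are aggregated by
calendar discharge month. The CDI comparison reports group means only; no
significance testing is attached.

## Synthetic data: what it emulates and what it does not

The generator stands in for a licensed code-mapping release plus a
multi-facility clinical database. Its defaults define the study
conditions:

* 18 × 40 synthetic codes, each with one body system; 20% CC and 10% MCC;
  per-category Elixhauser attachment probabilities declining from 3% to
  0.3% (encounter-level prevalences ≈ 25% down to ≈ 3%, the order seen in
  adult inpatient cohorts); 5% POA-exempt codes.
* Encounters draw 1 + Poisson(8) distinct codes; routine codes are POA
  with probability 0.90, CC/MCC codes with probability 0.97 (severe
  complications acquired during the stay are mostly surfaced by the CDI
  process below, while routine coding is predominantly POA).
* Labels follow a known logistic model on the *constructed* discharge
  features — by default the body-system variant with linear coefficients
  rising 0.5→1.5 across systems, quadratic 0.15, and (when the variant
  includes them) Elixhauser coefficients declining 0.5→0.05, so the
  body-system signal genuinely dominates the comorbidity signal. The
  intercept is calibrated on the generated cohort so the mean true
  probability of high severity is 40%, a typical high-severity rate for
  large academic centers. The drawn binary label is cosmetically refined
  to a 4-level SOI (high → 3 or 4, low → 1 or 2, uniformly) because the
  method consumes only the binarized outcome.
* The CDI process reviews encounters whose latent admission probability
  exceeds 0.5, queries half of those, and documents Poisson(3) extra
  non-POA, non-exempt CC/MCC codes on reviewed encounters. Since the
  severity level of record is assigned from the final coded record, the
  discharge SOI of augmented encounters is redrawn from the
  post-augmentation true probability (the truth table is updated
  accordingly).

Everything is deterministic under the configured seed (child generators
are spawned per stage, so maps, encounters and the CDI process are
independently reproducible).

What the generator does **not** emulate: real ICD-10-CM semantics,
correlated comorbidity structure, demographic case-mix (age, sex and race
are independent decoration), inter-facility differences beyond the label,
coder behaviour, or the proprietary grouper logic (age/procedure-based
severity adjustments are out of scope throughout). Passing tests
therefore demonstrate the *mechanics* of the scoring system — feature
construction, estimation, cutoff selection, score analytics — and
parameter recovery under a correctly specified model, not clinical
validity on real claims data.

## Problem sizes

The test suite works on cohorts of 500–20,000 encounters; coefficient
recovery uses 50,000 (where ≥ 95% of true coefficients fall within 3
estimated standard errors) and the feature-dominance sweep 10,000. The
reproduction script (`scripts/acceptance.py`) uses a 40,000-encounter
study cohort split 30,000/10,000. These sizes give stable estimates for
a 36-column model while keeping a full run around a minute.

## Known limitations

* CC/MCC status is treated as a property of the code alone; the MS-DRG
  exclusion logic (CC status conditional on the principal diagnosis) is
  not applied, matching a flat final-rule code list.
* Codes mapped to multiple body systems by upstream software must be
  reduced to a single (first-listed) system in the canonical input file.
* Unpenalized ML can fail on small or sparse cohorts (separation); the
  ridge option trades a small bias for existence of the estimate.
* Optimal cutoffs are data-dependent quantities of the training cohort;
  they must be re-derived, and the mapping tables refreshed, whenever the
  underlying code standards are updated.
* No confidence intervals on AUC and no calibration analysis are
  provided; model comparison is by AUC, accuracy and variable count.
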