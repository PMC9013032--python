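# jscore

Grouper-independent severity-of-illness (SOI) scoring for adult inpatient
encounters, built entirely from coded ICD-10-CM diagnoses.

Hospitals usually measure inpatient severity through the APR-DRG grouper's
four-level SOI subclass, a proprietary, annually updated black box. `jscore`
implements an open alternative: it maps an encounter's diagnosis codes onto
transparent, publicly documented categorizations — 18 body systems, CMS
CC/MCC complication designations, and the 30 Elixhauser comorbidities — and
converts them into a probability that the case is high severity. Two scores
are produced per encounter:

* **J_Score** — probability of high severity at discharge, from *all* coded
  diagnoses;
* **J_Score_POA** — probability of high severity on admission, from only
  the diagnoses present on admission (POA flag Y/W) plus POA-exempt codes.

The scores support benchmarking across facilities and quantify the impact
of Clinical Documentation Improvement (CDI) programs: the per-encounter gap
`J_Score − J_Score_POA` measures severity captured after admission.

## Model

For encounter $i$, each body system $s \in \{1,\dots,18\}$ gets an ordinal
indicator $B_{is} \in \{0,1,2\}$ (0: no diagnosis in the system; 1: at
least one diagnosis, none CC/MCC; 2: at least one CC or MCC diagnosis),
and each Elixhauser category $c \in \{1,\dots,30\}$ a binary flag $E_{ic}$
from secondary diagnoses. The binary outcome is high severity,
$y_i = \mathbf{1}[\mathrm{SOI}_i \ge 3]$. The full model is the logistic
regression

$$\operatorname{logit} P(y_i = 1) = \beta_0
  + \sum_{s=1}^{18} \big[\beta_{s}^{L}\, \ell(B_{is}) + \beta_{s}^{Q}\, q(B_{is})\big]
  + \sum_{c=1}^{30} \gamma_c\, b(E_{ic}),$$

where $\ell(\cdot), q(\cdot)$ are the linear and quadratic orthogonal
polynomial contrasts over the three ordinal levels (as in R's
`contr.poly`) and $b(\cdot)$ the two-level contrast — 48 predictor
variables, 66 design columns. The *comorbidity* variant drops the body
systems (30 variables) and the *body-system* variant drops the
comorbidities (18 variables, 36 columns); the body-system variant is the
one whose fitted probabilities are reported as J_Scores. Estimation is
maximum likelihood via iteratively reweighted least squares.

Validation follows the standard protocol: a random 3:1 train/test split,
ROC and precision–recall analysis on the training set, a classification
cutoff chosen as the threshold minimizing the Euclidean distance from the
training ROC curve to the ideal corner $(0,1)$, and accuracy / FPR / FNR
measured on the held-out test set at that cutoff.

No licensed table contents are shipped: the four reference mappings
(body system, CC/MCC, Elixhauser, POA-exempt) are pluggable CSV files,
and a synthetic-data module generates a complete code universe and
encounter cohort with known ground truth for development and testing.

## Worked example

```python
from jscore import SimulationConfig, SplitSpec, split_train_test, evaluate_variant
from jscore.synthetic import generate_reference_maps, generate_encounters
from jscore.scoring import score_encounters

cfg = SimulationConfig(seed=11, n_encounters=8000)
maps = generate_reference_maps(cfg)
encounters, truth = generate_encounters(cfg, maps)

train, test = split_train_test(encounters, SplitSpec(seed=11))
reports = {}
for phase in ("admission", "discharge"):
    report, results = evaluate_variant(train, test, maps, "body_system", phase)
    reports[phase] = (report, results)
    print(f"{phase:>9}: ROC AUC {report.roc_auc:.3f}  PR AUC {report.pr_auc:.3f}  "
          f"cutoff {report.optimal_cutoff:.3f}  test accuracy {report.accuracy:.3f}")

records = score_encounters(
    reports["admission"][1], reports["discharge"][1], maps, test,
    cutoff_poa=reports["admission"][0].optimal_cutoff,
    cutoff=reports["discharge"][0].optimal_cutoff,
)
r = records[0]
print(f"{r.encounter_id}: J_Score_POA={r.j_score_poa:.3f} ({r.predicted_class_poa}), "
      f"J_Score={r.j_score:.3f} ({r.predicted_class})")
```

prints

```
admission: ROC AUC 0.877  PR AUC 0.814  cutoff 0.354  test accuracy 0.784
discharge: ROC AUC 0.880  PR AUC 0.844  cutoff 0.402  test accuracy 0.798
E0000000: J_Score_POA=0.229 (low), J_Score=0.206 (low)
```

The body-system model separates high from low severity well on both
phases (training ROC AUC ≈ 0.88); the first test encounter scores below
both cutoffs and is classified low severity on admission and at
discharge.

The same pipeline is available from the shell:

```sh
jscore simulate --seed 11 --out run --n-encounters 8000
jscore build-features --out run
jscore evaluate --seed 11 --out run --plots
jscore score --seed 11 --out run
jscore report --out run --plots
```

## Layout

| Module | Contents |
| --- | --- |
| `jscore.codes` | ICD-10-CM normalization, the four reference mapping tables |
| `jscore.features` | phase-specific code selection, ordinal/binary feature construction |
| `jscore.contrasts` | orthogonal polynomial contrasts, design matrices |
| `jscore.model` | `SeverityModel` / `SeverityResults` (IRLS logistic fit, prediction, serialization) |
| `jscore.evaluation` | split, ROC/PR, cutoff selection, cohort comparison reports |
| `jscore.scoring` | per-encounter J_Scores, distribution/trend/CDI/facility analytics |
| `jscore.synthetic` | synthetic code universe, encounter cohorts, CDI process |
| `jscore.cli` | `jscore` command-line pipeline |

See `docs/methods.md` for the modelling details and design choices.
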