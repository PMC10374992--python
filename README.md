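# strokecohort

Etiological subtyping, probabilistic reclassification and prognosis estimation
for ischemic stroke (IS) cohorts, exercised end to end on a calibrated
synthetic cohort generator.

Large population cohorts ascertain tens of thousands of incident IS cases, but
many cases lack the brain imaging, cardiac testing (echocardiography or ECG)
or vascular imaging needed to assign an etiological subtype — cardioaortic
embolism (CE), large artery atherosclerosis (LAA) or small artery occlusion
(SAO) — with a rule-based algorithm. This package implements, as a tested and
reusable pipeline, the full analysis such a study runs:

1. **Rule engine** (`strokecohort.ccs`): a modified Causative Classification
   System decision table assigns each case a subtype with a confidence tier
   (evident / probable / possible / undetermined), driven by the cardioaortic
   source, ipsilateral ≥50% stenosis, the infarct pattern and the lacunar
   (LACI) syndrome, with findings masked to *unknown* whenever the
   corresponding investigation was not done. Cases classified evident or
   probable form the "truth set".
2. **Probabilistic reclassifier** (`strokecohort.classifier`): a multiclass
   logistic regression with an L1 penalty, minimizing
   `-log L(W, b) + α‖W‖₁`, trained on an 85:15 split of the truth set with α
   tuned by stratified five-fold cross-validation maximizing macro one-vs-rest
   AUC, then applied to incompletely investigated cases of undetermined
   etiology.
3. **Prognosis** (`strokecohort.prognosis`): cumulative all-cause mortality as
   `1 − Ŝ(t)` from the Kaplan–Meier estimator with exponential Greenwood
   (log(−log S)-scale) 95% intervals, and cumulative incidence of subsequent
   stroke (>28 days after the index event) from the Aalen–Johansen estimator
   `F_k(t) = Σ_{t_i≤t} Ŝ(t_i⁻) d_ki/n_i` treating death as a competing risk.
4. **Synthetic cohort generator** (`strokecohort.generator`): draws case
   records — latent subtype, baseline covariates, investigation availability,
   diagnostic findings, competing-risks outcomes with constant hazards — from
   a fully declarative `GeneratorConfig` whose defaults encode the cohort
   structure the pipeline is designed for (2% CE / 32% LAA / 66% SAO; 91% /
   87% / 51% availability of brain / cardiac / vascular investigations;
   cardioaortic-source prevalence 100.0% / 4.1% / 0.3%; 5-year readouts of
   43.5/43.2/38.1% subsequent stroke and 40.7/17.4/11.1% mortality for
   CE/LAA/SAO).

## Worked example

```python
import numpy as np
import strokecohort as sc
from strokecohort.classifier import build_feature_frame

cfg = sc.default_config()
cohort = sc.generate_cohort(cfg, 6000, seed=1)
assignments, summary = sc.classify_cohort(cohort)
print("evident+probable:", summary["evident_or_probable"],
      "undetermined:", summary["undetermined"])

merged = cohort.merge(assignments, on="case_id")
truth = merged[merged["confidence"].isin(["EVIDENT", "PROBABLE"])]
train, test, y_train, y_test = sc.split_cohort(truth, truth["subtype"].to_numpy(), seed=2)

model = sc.SubtypeClassifier(alpha_grid=[0.1, 1.0, 10.0, 100.0], cv=5, random_state=3)
model.fit(build_feature_frame(train), y_train)
report = sc.evaluate(model, build_feature_frame(test), y_test, n_bootstrap=200, seed=4)
for cls, m in report.per_class.items():
    print(f"{cls}: AUC {m.auc:.3f} ({m.auc_ci[0]:.3f}-{m.auc_ci[1]:.3f})")
print(f"accuracy {report.accuracy:.3f}")

pred = sc.apply_to_undetermined(model, cohort, assignments)
print("reclassified:", len(pred))
```

Output:

```
evident+probable: 4160 undetermined: {'total': 1377, 'incomplete_investigation': 1265, 'cryptogenic': 112}
CE: AUC 0.999 (0.998-1.000)
LAA: AUC 0.678 (0.628-0.722)
SAO: AUC 0.712 (0.669-0.755)
accuracy 0.787
reclassified: 1265
```

Reading: of 6,000 simulated cases, 4,160 receive an evident or probable
etiology; 1,265 are undetermined because of missing investigations and are
reclassified by the model. The cardioaortic-source screening indicator makes
CE almost perfectly separable (AUC ≈ 1), while LAA and SAO are only modestly
separable from baseline risk factors (region, sex, urban residence, blood
pressure) — exactly the regime the rule-plus-model design targets. Prognosis
by group then comes from `sc.compare_groups(merged, groups)`, which returns
the 5-year subsequent-stroke and mortality rates with 95% intervals; on the
truth set the mortality ordering is CE > LAA > SAO.

The same flow is available from the shell:

```bash
strokecohort run-all -n 20000 --seed 1 -o run_output/
strokecohort generate -n 20000 --seed 1 -o cohort.csv
strokecohort classify-ccs --cohort cohort.csv -o assignments.csv --summary summary.json
```

## Layout

- `src/strokecohort/config.py` — generator configuration, default calibration,
  hazard inversion from 5-year readouts.
- `src/strokecohort/generator.py` — cohort sampling, competing-risks outcome
  simulation, CSV round trip.
- `src/strokecohort/ccs.py` — declarative decision table and rule engine.
- `src/strokecohort/classifier.py` — L1 multinomial model, tuning, evaluation,
  reclassification; JSON model artifact.
- `src/strokecohort/prognosis.py` — Kaplan–Meier and Aalen–Johansen estimators
  with pointwise intervals, group comparison.
- `src/strokecohort/pipeline.py`, `cli.py` — orchestration and the
  `strokecohort` command.
- `docs/methods.md` — models, assumptions, calibration and design choices.
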