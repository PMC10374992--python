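# Methods

This note documents the models behind `strokecohort`, the calibration of the
synthetic cohort generator, the numerical choices, and the limits of what the
synthetic validation demonstrates.

## The problem setting

An incident ischemic stroke (IS) case can be assigned an etiological subtype —
cardioaortic embolism (CE), large artery atherosclerosis (LAA), small artery
occlusion (SAO) — only when the relevant investigations were done: brain
imaging establishes the infarct pattern, vascular imaging establishes whether
an ipsilateral ≥50% stenosis is present, and cardiac testing (echocardiography
or ECG; a cardioaortic source may also surface during stroke-record review)
establishes whether a cardioaortic embolic source exists. In community
cohorts a large fraction of cases lack one or more of these tests, so a
rule-based classification leaves them undetermined. The package couples a
deterministic rule engine with a probabilistic model trained on the
well-characterized cases, and compares prognosis across subtypes however they
were obtained.

## Rule engine

Classification is a fixed, ordered decision table over four findings:
`cardioaortic_source` (none / low_risk / high_risk / unknown),
`ipsilateral_stenosis_ge50` (yes / no / unknown), `infarct_pattern`
(lacunar <20 mm / territorial / multi-territory / none visible / unknown) and
the clinical lacunar syndrome `laci_syndrome` (yes / no, always observed).
The hierarchy follows published causative-classification logic:

| rule | assigns | condition (first match wins) |
|---|---|---|
| CE-1 | CE, evident | high-risk source, stenosis excluded, territorial or multi-territory infarct |
| CE-2 | CE, probable | high-risk source, no contradicting positive finding, corroboration incomplete |
| LAA-1 | LAA, evident | stenosis, no source, territorial infarct |
| LAA-2 | LAA, probable | stenosis, no high-risk source, no lacunar infarct, at most one corroborating item missing |
| SAO-1 | SAO, evident | lacunar infarct, stenosis and source excluded |
| SAO-2 | SAO, probable | lacunar infarct with lacunar syndrome, exclusion incomplete |
| CE-3 | CE, possible | low-risk source only |
| LAA-3 | LAA, possible | stenosis with both source and pattern unknown |
| SAO-3 | SAO, possible | lacunar syndrome without a non-lacunar infarct on imaging |
| — | undetermined | otherwise; *incomplete_investigation* if any test missing, else *cryptogenic* |

Design choices worth spelling out:

- **Conflicts are not adjudicated.** A case with conflicting positive
  mechanisms (e.g. high-risk source *and* demonstrated stenosis) falls
  through to undetermined/cryptogenic rather than being forced into one
  subtype.
- **Neutral findings do not block probable tiers.** "None visible" imaging
  and multi-territory patterns are treated as non-contradicting levels in
  CE-2/LAA-2/SAO-3. Without this, a complete negative workup would score
  *below* a partially missing one, breaking the intended monotonicity of
  confidence in evidence.
- **Monotonicity and its domain.** On profiles without conflicting positive
  mechanism markers, masking any single finding to unknown never raises the
  confidence tier a subtype receives (verified by exhaustive enumeration).
  The restriction is necessary: masking the *conflicting* finding of a
  conflicted profile can legitimately unlock a probable rule, since the
  engine can no longer see the conflict. No rule system with
  unknown-tolerant probable tiers and a conflict-to-undetermined rule can be
  monotone on the full domain.
- The table is data (`DECISION_TABLE`), so alternative rule sets — e.g. a
  site-specific mapping of record fields to criteria — can be swapped in
  without touching the engine.
- "Other determined etiology" is not representable, matching adjudication
  forms that only capture the three subtypes.

## Probabilistic reclassifier

A multinomial logistic regression minimizing `-log L(W,b) + α‖W‖₁`
(intercepts unpenalized), fitted with scikit-learn's saga solver
(`C = 1/α`). Predictors are the baseline covariates (age, systolic and
diastolic blood pressure, BMI standardized on the training split; region,
sex, urban residence, medical history, smoking, drinking, family history of
stroke, health-insurance access one-hot encoded) plus a cardioaortic-source
screening indicator with *unknown* as an explicit level — missingness itself
is informative and is never imputed.

- The truth set (evident + probable cases) is split 85:15, stratified by
  class because CE is rare (~2%); the training size is `round(0.85 n)` via
  largest-remainder allocation across classes.
- α is tuned on a grid (default 20 points, log-spaced 10⁻³–10³) by stratified
  five-fold cross-validation maximizing macro one-vs-rest AUC; ties break
  toward the weakest penalty. Fold fits are iteration-capped (the ranking is
  insensitive to the last digits of convergence); the final refit on all
  training data must converge to tolerance or an error carrying the
  iteration trace is raised. `alpha = inf` is honored exactly: zero
  coefficients, class-frequency predictions.
- Evaluation on the held-out 15%: one-vs-rest AUC (rank statistic, ties
  counted ½), PPV, sensitivity, F1 (harmonic mean of PPV and sensitivity)
  and accuracy from the arg-max confusion matrix, with 95% percentile
  intervals from a class-stratified bootstrap (2,000 replicates by default).
  A class absent from the test set has its metrics flagged undefined, not
  zeroed. Arg-max ties resolve in the fixed order CE, LAA, SAO.
- The model artifact is plain JSON (encoder statistics, coefficient matrix,
  intercepts, tuned α, CV trace, seeds); predictions round-trip exactly.

Two identifiability caveats, both verified in tests: softmax intercepts are
identified only up to a common shift, and a full set of one-hot indicators
plus an intercept leaves the L1 optimum non-unique along the collinear
direction whenever the optimal within-block signs differ — predicted
probabilities and the continuous-feature coefficients are identified, raw
one-hot coefficients are not. The fit is cross-checked against an
independent generic convex optimizer (L-BFGS-B on the smooth positive/negative
split reformulation) on a small instance.

## Prognosis estimators

- **Mortality**: `1 − Ŝ(t)` with Ŝ the Kaplan–Meier product-limit estimator
  (via lifelines). Pointwise 95% intervals use the exponential Greenwood
  construction: on the log(−log Ŝ) scale,
  `v(t) = [Σ dᵢ/(nᵢ(nᵢ−dᵢ))] / log²Ŝ(t)` and bounds `Ŝ^exp(±1.96√v)`,
  guaranteed inside [0, 1]. Follow-up for death is not terminated by a
  non-fatal subsequent stroke.
- **Subsequent stroke**: the Aalen–Johansen cumulative incidence
  `F_k(t) = Σ_{tᵢ≤t} Ŝ(tᵢ⁻) d_{ki}/nᵢ`, with death a competing risk,
  implemented in-package so that the conservation identity
  `Σ_k F_k(t) = 1 − Ŝ_all(t)` holds to machine precision at every event
  time; the point estimates are tested to agree with lifelines'
  AalenJohansenFitter to 10⁻¹⁰. The variance is the standard delta-method
  (Marubini–Valsecchi) estimator, evaluated in O(m) via cumulative sums, and
  the 95% interval is built on the log F_k scale.
- Ties: events are processed before censorings. Horizon readouts use the
  right-continuous step convention; a horizon before the first event returns
  a flagged zero. Groups under 10 cases are reported with a small-sample
  flag. Formal between-curve testing (Gray-type tests) is out of scope; only
  interval overlap is reported.

## Synthetic cohort generator

The generator emulates the cohort structure the pipeline targets; its
defaults are the study conditions, not tuning knobs.

- **Mixture**: 2% CE / 32% LAA / 66% SAO. Ten regions (five urban, five
  rural) carry SAO:LAA ratios spanning four-fold, scaled so the
  uniform-over-regions mixture reproduces the overall shares; a case's urban
  flag comes from its region, so urban-by-subtype differences emerge from
  geography.
- **Covariates**: per-subtype marginals — age 61.9 (9.4) / 59.9 (8.9) /
  58.7 (9.5) years, female 46.9/46.3/59.1%, SBP 141.9 (25.6) / 144.7 (23.8) /
  139.9 (23.1) mmHg, and so on for DBP, BMI, diabetes, coronary heart
  disease, hypertension, blood-pressure drugs, sex-specific smoking and
  drinking. Continuous covariates are truncated normals (age 30–79 by the
  enrolment range; SBP 60–260, DBP 30–160, BMI 12–60 mmHg/kg·m⁻² as
  physiological bounds); at these distances the truncation shifts means by
  <0.02 units. Family history of stroke (17/20/16%) and health-insurance
  access (97/95/98%) are not tabulated anywhere and were chosen once as
  plausible values that give the LAA-vs-SAO discrimination its documented
  secondary signals. Covariates are independent within subtype (only
  marginals are available to calibrate against).
- **Findings emission**: per-subtype probabilities chosen so (i) the
  cardioaortic-source prevalence is exactly 100.0/4.1/0.3% for CE/LAA/SAO
  and (ii) the rule engine's evident+probable capture rate is nearly equal
  across subtypes (≈0.88–0.93 under full investigation), so the recovered
  mixture is an unbiased image of the latent one. Under full investigation
  the assigned subtype agrees with the latent label in >99% of
  evident+probable cases.
- **Investigation availability**: independent Bernoulli draws at 0.91 /
  0.87 / 0.51 (brain / cardiac / vascular), giving an incompletely
  investigated fraction of 1 − 0.91·0.87·0.51 ≈ 0.60. Real missingness is
  correlated across tests; independence is a documented simplification and
  the config is the extension point. A source can be recorded from
  stroke-record review without a cardiac test (probability 0.5).
- **Outcomes**: competing constant hazards. The death hazard is inverted
  from the 5-year marginal mortality, `λ_D = −log(1−F_D(5))/5`, because
  mortality is estimated by 1−KM with death observed regardless of an
  intervening stroke; the stroke hazard then solves the competing-risks
  closed form `F_S(t) = λ_S/(λ_S+λ_D)·(1−e^{−(λ_S+λ_D)t})` for the 5-year
  stroke cumulative incidence, which is estimated with death competing.
  Defaults (per person-year): CE λ_S 0.1555, λ_D 0.1045; LAA 0.1269,
  0.0382; SAO 0.1028, 0.0235. Subsequent strokes within 28 days of the
  index event do not count; by memorylessness this left-truncation is a
  28/365.25-year shift. Stroke times are recorded only when they precede
  death. Administrative censoring at 9 years; independent loss to follow-up
  at 0.0002/year (loss is rare in registry-linked cohorts). Silent
  (imaging-only) infarcts are flagged at rate 0.15 independent of subtype
  and only interact with the pipeline's inclusion toggle.

### What the synthetic validation does and does not show

Passing tests demonstrate that the estimators are correct (oracle agreement,
conservation, closed-form recovery at n = 20,000 with bias < 0.005), that the
rule engine is total, deterministic and evidence-monotone on its stated
domain, and that the pipeline is reproducible end to end. They do *not*
demonstrate performance on real cohorts: the generator has independent
covariates, independent test availability, constant hazards, and emission
probabilities that make subtypes cleanly separable given complete findings.
Classifier metrics on synthetic data (CE AUC ≈ 1, LAA/SAO AUC ≈ 0.7) mirror
the regime the design targets but are properties of the generator, not of
any real population.

## Numerical choices and degenerate inputs

- Simulation sizes: n = 20,000 for calibration-recovery checks (Monte-Carlo
  SE ≈ 0.3–0.4 percentage points on 5-year rates), printed group sizes where
  a quantity is tied to one (e.g. n = 2,395 for the LAA SBP mean).
- saga: tol 10⁻⁵, max 20,000 iterations by default; the convex-oracle test
  tightens to 10⁻¹⁰. Weak penalties on quasi-separable data converge slowly;
  the iteration cap plus error-on-nonconvergence makes this loud rather than
  silent.
- Kaplan–Meier with an exhausted risk set truncates the curve and sets a
  flag. Empty inputs, non-positive times, unknown event codes (named by
  row), inconsistent findings (a known stenosis without vascular imaging)
  and invalid configurations (named field) all raise immediately.
- Determinism: every random stream is seeded and recorded in the run
  manifest; identical configuration yields byte-identical outputs.

## Known limitations

- Joint covariate structure, correlated missingness and non-constant hazards
  are not modelled; all three are config-level extension points.
- The decision table is one concretization of causative-classification
  logic; site-specific variants should replace `DECISION_TABLE` rather than
  assume this one.
- Confidence intervals for the cumulative incidence use the log-scale delta
  method; other variants (log(−log), simulation-based) are not offered.
- The possible-etiology tier is produced and counted but not used for
  training; applying the trained model to it is left to the caller.
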