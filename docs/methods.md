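# Methods

## The question and the design

Nine widely used cardiovascular risk prediction models are applied to the
same primary-prevention cohort, each with its own guideline-mapped treatment
threshold, and the resulting *binary statin-eligibility decisions* are
compared pairwise and under k-of-9 consensus rules. This is deliberately a
decision-level comparison of complete frameworks (equation + outcome +
horizon + calibration + threshold), not a comparison of interchangeable risk
numbers and not an outcome-based validation: no C-statistics, calibration
slopes or observed event rates are computed anywhere in the package.

## Cohort model and inclusion

Records carry SI clinical units (lipids and glucose mmol/L, creatinine
µmol/L, CRP mg/L). Inclusion requires age 40–65 and NCEP ATP III metabolic
syndrome: at least three of

| criterion | rule |
|---|---|
| blood pressure | SBP ≥ 130 or DBP ≥ 85 mmHg, or hypertension diagnosis |
| central adiposity | waist ≥ 88 cm (women) / ≥ 102 cm (men) |
| HDL-C | **strictly** < 1.29 (women) / < 1.03 (men) mmol/L |
| triglycerides | ≥ 1.7 mmol/L or TG-lowering pharmacotherapy |
| glycemia | fasting glucose ≥ 5.6 mmol/L or diagnosed diabetes |

Boundary directions follow the printed criteria exactly (≥ everywhere except
the strict < for HDL); the classifier is pure and order-independent.
TG-lowering pharmacotherapy is approximated by the generic lipid-treatment
flag — registry-style data do not distinguish fibrates from statins — and a
single diabetes flag feeds the glycemia criterion. Validation returns a full
issue list (age range, strict positivity, HDL ≤ TC, presence of every field
any engine needs) rather than failing fast.

## Synthetic cohort generator

The generator emulates the *study conditions*: sex-stratified marginal means,
SDs and prevalences equal to the published baseline table of an 11,174-person
cohort (58.41% female; female/male mean ages 57.62/47.69 y; male current
smoking 31.5% vs female 12.9%; and so on for BMI, blood pressure, lipids,
glucose, renal markers and CRP), ages 40–65, and 100% metabolic syndrome.

Design choices:

* **Dependence.** Only marginals are public, so the joint is explicitly
  synthetic: a Gaussian copula over configurable pairwise Spearman
  correlations (defaults: TC–LDL 0.88, HDL–TG −0.40, SBP–DBP 0.70, age–SBP
  0.20, BMI–CRP 0.30, creatinine–eGFR −0.80, …), converted to the copula
  scale via 2·sin(πρ/6). The specification is validated for positive
  semi-definiteness.
* **Marginals.** Truncated normals within clinical plausibility bounds;
  triglycerides and CRP use moment-matched log-normals because their
  published SDs are of the order of their means (right skew).
* **Waist** is absent from the source table and is synthesized from BMI by a
  documented linear map (women 25 + 2.3·BMI, men 28 + 2.4·BMI, ±5 cm noise),
  chosen so central adiposity is commonly met at the table's mean BMI. This
  is an invention and is flagged as such.
* **MetS enforcement** is by rejection sampling against the real classifier,
  never by distorting marginals. Under the default configuration roughly
  70–80% of draws pass, and conditioning shifts the criterion-linked
  marginals upward/downward a few percent (measured at n = 20,000):

  | field | drift (female / male) |
  |---|---|
  | HDL | −4.0% / −6.0% |
  | TG | +9.7% / +16.5% |
  | glucose | +4.2% / +4.5% |
  | BMI | +3.4% / +3.7% |
  | SBP | +1.5% / +1.4% |
  | age, TC, LDL, eGFR, creatinine | within ±1% |

  Parameter-recovery checks therefore compare realized moments against the
  configured **pre-rejection** targets with a class-based allowance on top of
  3 standard errors: 3% of the mean for fields outside the MetS criteria, 8%
  for criterion-linked fields (`synthetic.METS_LINKED_FIELDS`), and TG is
  excluded from mean recovery because a criterion thresholds it directly at
  1.7 mmol/L. Prevalence recovery uses 3 binomial SE + 3 percentage points
  (treatment and diabetes flags drift ≤ ~2 pp under rejection).
* Family-history prevalence (0.25) and the untreated-hypertension-diagnosis
  rate (0.15) are not in the source table; both are configurable, documented
  defaults. Smoking is drawn as current/ex/never with the two published
  prevalences and never as the remainder.
* Determinism: one `numpy` generator seeded from the config; identical
  config (including seed) gives byte-identical cohorts. A rejection cap
  (50× the requested count per sex by default) turns an over-constrained
  configuration into a clear error.

What passing tests on this cohort do **not** show: the generator does not fit
the registry's true joint distribution, so cohort-level results (per-model
eligibility percentages, the κ median, consensus coverages) are not expected
to reproduce published cohort values numerically — only the arithmetic of
every stage, the metric definitions and the qualitative structure (large
spread, NPA ≫ PPA, half-coverage near k = 3) carry over.

## Risk engines

Each engine evaluates its published equation — a linear predictor on
transformed covariates through the model's baseline-survival or logistic
form — from a YAML coefficient registry with per-entry citations, so
transcription is auditable and never buried in logic. Unit conversions use
×38.67 (cholesterol) and ×88.57 (triglycerides) mmol/L → mg/dL. Risks are
carried at full precision and only rounded for presentation (2 dp).

Per-model conventions, with the omissions a registry-style dataset forces
(each omission is logged in the estimate's `omitted_inputs`):

* **SCORE2** — sex-specific log-HRs on centered age, SBP, TC, HDL and
  smoking with age interactions; the uncalibrated risk is mapped through the
  published region recalibration, defaulting to the very-high-risk European
  scales (the cohort's region); all four region scale pairs ship in the
  registry.
* **PREVENT** — base-model logistic equation for 10-year total CVD with
  non-HDL, HDL, piecewise SBP and eGFR terms, treatment flags and age
  interactions; the optional ZIP-linked social-deprivation add-on is not
  applicable and omitted.
* **PCE** — race/sex-specific Cox coefficients; the non-Hispanic White
  branch is the default for a European cohort (configurable; the African
  American branch ships in the registry but is outside the fixture surface).
* **MESA** — the published risk-factors-only (no-CAC) equation; an imputed
  calcium score is never used; ethnicity at the non-Hispanic White reference.
* **QRISK3** — fractional-polynomial age and BMI terms, TC/HDL ratio, SBP,
  smoking categories and condition flags, centered at the published cohort
  means; ethnicity, Townsend deprivation and SBP variability are held at
  reference/center. Transcription caveat: the open-source release could not
  be re-verified offline, so the registry is a best-effort transcription and
  the full algorithm's age-interaction terms are omitted (main effects
  only) — at the older, high-burden end of this cohort QRISK3 therefore
  runs high relative to the official calculator. Current smokers are scored
  in the moderate (10–19/day) category because the data record status only.
* **ASSIGN** — log hazard ratios derived from the published HRs
  (self-consistent to 4 decimals); baseline survivals and the SHHEC
  centering means are flagged approximate in the registry. Deprivation
  (SIMD) is not applicable and sits at the cohort mean (zero contribution
  after centering); current smokers are entered as 15 cigarettes/day
  (configurable in the registry).
* **AusCVDRisk** — the PREDICT-derived 5-year equation with postcode/SEIFA
  and ethnicity terms at reference (the Australian recalibration constants
  are not publicly printed in transcribable form); atrial fibrillation is
  structurally present but always false here because the cohort definition
  excludes arrhythmias. The 5-year horizon is preserved — by construction
  this model flags far fewer people at a ≥10% threshold than any 10-year
  model.
* **FRS-hCHD** — the ATP III point tables (age, age-dependent TC and smoking
  points, HDL, treated/untreated SBP) with the discrete point-to-risk map;
  "<1%" is carried as 0.5 and "≥30%" as 30. The model has **no diabetes
  input**; diabetic participants are scored with the same tables, matching
  how the points instrument is used in practice.
* **RRS** — women's (2007) and men's (2008) equations with hsCRP and family
  history; for diabetic women the HbA1c term uses a documented default of
  7.0% because the dataset carries no HbA1c.

Structural guarantees tested for every engine: risk in [0, 100] with no NaN
on valid input; smoking strictly increases risk; risk non-decreasing in age
on 40–65 and in SBP on [110, 200] (below 110 mmHg PREVENT's published
low-SBP term makes risk rise as pressure falls — the one documented
exception); sex-specific branches actually switch. Five engines (SCORE2,
PCE, PREVENT, MESA, RRS) are additionally checked against independent
straight-line re-implementations with re-typed constants. The frozen fixture
file is synthetic — it pins the package's own outputs against accidental
change and is not a recording of the official web calculators, which were
not reachable when this package was built.

## Eligibility

decision = risk ≥ cut-point, uniformly ("meets or exceeds"). Policies are
constant or age-banded; bands must partition the age range and are selected
by age in whole truncated years (calculators take whole years). Shipped
defaults (every entry carries its source): SCORE2 ≥7.5% at 40–49 / ≥10% at
50–69 (very-high-risk region thresholds); PCE, PREVENT and MESA ≥7.5%;
QRISK3 ≥10%; ASSIGN ≥20%; FRS-hCHD ≥10%; RRS ≥10%; AusCVDRisk ≥10% 5-year.
The active policy set is printed in every report and hashed into a
fingerprint so results are never silently policy-dependent. Flagged scoring
failures (NaN cells) classify as ineligible rather than crashing the run.

## Agreement panel

All metrics are recomputable from the stored 2×2 counts. Conventions that
matter:

* **PPA/NPA use the Dice (specific-agreement) form** 2a/(2a+b+c) and
  2d/(2d+b+c), not a/(a+b+c): this is the convention consistent with the
  exact identity PPA = 2J/(1+J), which the test suite enforces throughout.
* **McNemar** switches to the exact two-sided binomial test below 25
  discordant pairs (configurable); with zero discordant pairs the test is
  flagged undefined.
* **Degenerate margins yield flagged `None`** (JSON null), never a silent 0:
  κ when expected agreement is 1, Jaccard/PPA when no positives exist, NPA
  when no negatives exist.
* Summaries across the 36 pairs use the median and linearly interpolated
  quartiles, computed over defined values only (with the defined count
  reported). Presentation rounding: κ/AC1/PPA/NPA to 2 dp; Jaccard to 3 dp
  below 0.1, else 2 dp.
* No confidence intervals for κ/AC1 and no weighted kappa — out of scope by
  design.

The extreme-imbalance exemplar used in tests and the acceptance script —
(a, b, c, d) = (339, 7191, 0, 3644) — is *forced* by two marginal positive
counts (7530, 339 of 11,174) and their Jaccard overlap 0.045, via
a = J(p₁+p₂)/(1+J); the reconstruction is verified by recovering all five
metrics at their printed rounding (κ 0.03, AC1 −0.18, PPA 0.09, NPA 0.50,
J 0.045).

## Consensus

Per-participant tallies (row sums) feed coverage(k) = % of the stratum with
tally ≥ k, k = 1..9; denominators are full stratum sizes (eligible or not),
k = 0 is excluded as trivially 100%. Endpoints are identities: coverage(1) is
the union of the nine eligible sets, coverage(9) the intersection. Curve
features: steepest adjacent drop with its interval, the k nearest 50%
coverage, and the k of maximal male-minus-female gap; ties break toward
smaller k for deterministic reporting. All nine k values are always emitted.

## Pipeline and determinism

`run_pipeline` chains simulate/load → score → eligibility → agreement →
consensus; any failure aborts with a stage-named diagnostic. Every CSV's
first line carries the run fingerprint (SHA-256 over cohort configuration,
policy set, coefficient registries, seed and package version); the manifest
records the fingerprint, config hashes, row counts and a timestamp that is
deliberately excluded from the fingerprint, so identical seed + configs give
byte-identical CSVs and report. A sex stratum with fewer than two
participants is skipped in the agreement stage with a logged warning (a 2×2
panel is undefined there). The report is validated against a shipped schema
document; the cohort CSV schema is likewise shipped as JSON and enforced on
every read by the package's validator. Default problem sizes — n = 5000 for
end-to-end runs and parameter recovery, 200–250 random tables for metric
oracle suites — keep a full run in seconds while leaving Monte Carlo noise
well below the tested tolerances.

## Known limitations

* Engine coefficient registries are transcriptions; QRISK3, ASSIGN and
  AusCVDRisk carry documented transcription caveats (above), and no fixture
  against the official web calculators exists in this build. Decision-level
  *structure* is robust to this; individual risk values for those three
  engines should not be quoted against the official tools without
  re-verification.
* The synthetic joint distribution is a modelling choice; only marginals are
  anchored to published values.
* Binary sex only, as in the source data model; PCE race branches other than
  non-Hispanic White ship untested; no risk-enhancer or clinician-discretion
  pathways — absolute-risk thresholds only.
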