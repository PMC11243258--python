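# Methods

## Scope and model

The package reimplements a screening-epidemiology analysis pipeline: five
formula-defined MAFLD risk scores are computed per subject, each subject is
classified into risk tiers and into high/normal adiposity states, and four
adiposity measures (BMI, waist circumference, bioimpedance body-fat %,
visceral-fat rating) are evaluated as predictors of high-risk score status
via ROC analysis. Correlation (Pearson) and concordance (Cohen's kappa)
matrices summarize agreement between measures and between scales. No liver
outcome is modelled; the "outcomes" are always the score-defined high-risk
states, which is exactly the construct the analysis quantifies.

## Score formulas and conventions

- **FLI.** The published expression is a logistic transform of the linear
  predictor L = 0.953·ln TG + 0.139·BMI + 0.718·ln GGT + 0.053·WC − 15.745
  scaled to 0–100. We implement 100·e^L/(1+e^L), computed as
  100/(1+e^−L) for numerical stability on both tails. TG enters in mg/dL
  and GGT in U/L, the scale's canonical units.
- **Units.** Subject records store analytes in mg/dL. ZJU, FLD and LAP
  convert TG (÷ 88.57) and fasting glucose (÷ 18.016) to mmol/L
  internally; the constants are module-level and documented.
- **Threshold inclusivity.** Every "high risk from x" boundary is read as
  score ≥ x. Lower-tier boundaries (low vs moderate) are not published for
  these scales; the shipped defaults (FLI 30, HSI 30, ZJU 32, FLD 27) are
  conventional rule-out values, configurable, and echoed into run metadata.
  LAP is two-tier (normal/high at 42.7).
- **Hyperglycemia (FLD term).** Not defined by the source scale's users in
  any consistent way; default is fasting glucose ≥ 100 mg/dL (the standard
  impaired-fasting-glucose floor) or a diabetes diagnosis flag.
  Configurable.
- **Diabetes (HSI term).** Default rule is diagnosis flag OR fasting
  glucose ≥ 126 mg/dL, because screening datasets often lack reliable
  diagnosis flags; `flag_only` is available.
- **Negative LAP.** A waist below the sex offset (65 cm men / 58 cm women)
  produces a negative product. The value is returned as-is with a warning:
  clamping would create ties and degrade ROC ranking.
- **Friedewald LDL** (TC − HDL − TG/5) is applied only for TG ≤ 400 mg/dL;
  above that the measured LDL field is used or left missing.
- **Adiposity cut-offs.** High visceral fat is a rating ≥ 10. High body
  fat is age- and sex-dependent; the shipped table (men 25/28/30%, women
  39/40/42% across bands 18–39/40–59/60–69) follows bioimpedance
  healthy-range charts and is fully configurable — analyses that matter
  should treat it as a study parameter, not a constant of nature.

## ROC machinery

The empirical curve sweeps unique predictor values descending with
"positive" = value ≥ threshold; ties are grouped so the curve has one
vertex per distinct value. The AUC is the Mann–Whitney statistic computed
from midranks, which equals the trapezoidal integral of the curve exactly
(asserted to 1e−12 in tests). Confidence intervals use DeLong structural
components in the midrank (O(n log n)) formulation, normal approximation,
truncated to [0, 1]; a stratified bootstrap is available as a sensitivity
check. The paper-of-record for a given analysis rarely names its CI
method, so the method name is always recorded in output metadata rather
than asserted to match.

Youden-optimal cut-points maximize J = sensitivity + specificity − 1 over
midpoints between adjacent distinct values plus the two infinite extremes
(observed-value candidates behind a flag). Ties in J break toward higher
specificity, then the smaller cut-point. Predictors are assumed positively
associated with the outcome; `auto_orient=True` flips a predictor whose
AUC is below 0.5 and records the flip.

## Agreement statistics

Student's t is pooled-variance by default ("Student's t-test" taken
literally), Welch behind a flag; two zero-variance groups with equal means
return t = 0, p = 1 by convention. Chi-square is Pearson's without
continuity correction. Kappa uses marginal-product expected agreement and
is undefined (reported as missing, with the reason) when either vector is
single-class. Scale concordance dichotomizes at high vs not-high
(moderate and low merged) — the only reading under which a binary kappa
between three-tier scales is possible. For BMI and waist the kappa
dichotomization is not canonical: the default uses each measure's
Youden-optimal cut-point against the high-FLD outcome (the scale with the
strongest separation), and fixed clinical cut-offs (BMI 30 kg/m²; waist
102/88 cm) are available; the choice and resulting cut-offs are part of
the report metadata.

In the fat-by-risk-tier table the k-group p-value is a one-way ANOVA,
which reduces to the pooled two-sample t for the two-tier LAP.

## Synthetic cohort generator

The generator emulates an occupational-health screening cohort (default
4,104 men and 4,486 women, the published sex split) through a Gaussian
copula:

- **Marginals.** Height, weight, waist, hip and blood pressure are
  truncated normals at the published sex-stratified means/SDs. Glucose,
  LDL, TG, GGT, AST and ALT — whose published SDs approach or exceed half
  their means, indicating right skew — are lognormals moment-matched on
  the natural scale. Truncation is implemented by clipping draws at
  physiologic bounds kept ≥ 2.6 SD from the mean (< 1% of mass, warned
  above that), which preserves both the copula correlation structure and
  the marginal moments to well within sampling error at n = 50,000.
- **Latent correlations.** Only the adiposity inter-correlations are
  calibrated to published values; the remaining cells are
  literature-plausible moderate values (0.2–0.4 among metabolic analytes)
  that shape realism, not correctness, and are freely editable. The
  default matrix is positive definite as shipped; arbitrary user matrices
  are repaired by eigenvalue-clipping projection with a warning.
- **Derived body composition.** Body-fat % is a linear blend
  a·z(BMI) + b·z(waist) + c·ε with (a, b) solved at generation time from
  the realized BMI–waist correlation so the sampled Pearson correlations
  hit the published targets (0.875/0.803 vs BMI for women/men); the
  visceral-fat rating passes the analogous blend through a moment-matched
  lognormal and integer rounding to mimic a Tanita-style scale, which
  attenuates its realized correlations a few hundredths below target —
  accepted, since no exact device mapping exists.
- **Flags.** Diabetes is glucose ≥ 126 mg/dL plus a 1% labeled-diagnosis
  fraction; smoking, social class and physical activity follow the
  published prevalences; ages are drawn by published band weights, uniform
  within band.

What the generator does **not** emulate: the real joint distribution
beyond printed moments and correlations, device-specific measurement
error, intra-company clustering, or any diabetes prevalence (none is
published). Consequently, pipeline results on synthetic cohorts reproduce
the *qualitative* published pattern — fat measures separate high-risk
status with AUCs around 0.85–0.95, fat means rise strictly across risk
tiers, ZJU and FLD correlate near-perfectly — but the published AUCs and
empirical cut-offs themselves are properties of the unavailable real
cohort and are not reproduction targets.

`inject_outcome_structure` is test scaffolding: it shifts an adiposity
predictor for outcome-positive subjects by the binormal increment
δ = √2·(Φ⁻¹(AUC_target) − Φ⁻¹(AUC_current)) to set a requested separation,
so ROC calibration tests can dial separation levels deliberately.

## Numerical choices and degenerate inputs

- Scores are carried at full precision; report tables round to 1–3 dp.
- FLI uses the stable logistic form; ±∞ thresholds represent the
  all-positive/all-negative classifications in the Youden scan.
- A constant predictor yields the diagonal ROC (AUC 0.5) and an undefined
  Pearson/kappa cell, reported as missing with the reason — never a crash
  of the cohort run.
- Per-subject formula errors (e.g. AST = 0) are logged and skipped; the
  cohort run continues. Input validation rejects rows by named rule and
  hard-fails only when > 50% of rows are rejected (probable column
  mis-mapping).
- End-to-end determinism: (config, seed) fixes every table; the report
  hash in metadata makes this checkable.

## Problem sizes

Default analyses run at the published cohort size (8,590 subjects,
< 2 s end-to-end). Parameter-recovery checks use 50,000 per sex, chosen so
the 4·SE acceptance band on means is a few tenths of each SD; oracle
equivalence checks use 1,000 random instances of n ≤ 200, where brute
force is exact and fast.

## Known limitations

- The five scales' coefficients are taken as published; no refitting.
- No partial AUC, covariate-adjusted ROC, correlated-AUC comparison test,
  weighted kappa, or multiple-testing correction (the analysis this
  mirrors used none).
- The body-fat cut-off table and the low/moderate tier boundaries are
  conventions, and the kappa values for BMI/waist depend visibly on the
  dichotomization chosen — both are surfaced in metadata rather than
  hidden.
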