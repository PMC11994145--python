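# Methods

## Problem and model

`lacerisk` implements a 30-day unplanned-readmission risk pipeline for
surgical admission registries whose comorbidity information lives only in
free text. The pipeline has five stages:

1. **Comorbidity extraction.** A weighted keyword dictionary maps condition
   surface forms (full names and clinical abbreviations) to Charlson
   Comorbidity Index (CCI) weights in {1, 2, 3, 6}. The CCI for an admission
   is the sum of the weights of the *distinct* conditions found in the
   history text plus an age adjustment.
2. **LACE scoring.** LACE = L + A + C + E with L = length-of-stay points
   (0–7), A = acuity of admission (emergency 3, elective 0), C = comorbidity
   points from the CCI (0–5), E = emergency-department visits in the prior
   six months (binary: any visit 4; graded option: min(count, 4)). The total
   ranges 0–19; totals ≥ 10 flag high readmission risk (threshold
   configurable).
3. **Screening evaluation.** The high-risk flag against the unplanned
   readmission outcome as a 2×2 problem: sensitivity, specificity, PPV, NPV,
   accuracy with an exact Clopper–Pearson 95% CI, prevalence, flagged rate,
   and the no-information rate (majority-class proportion). Group
   comparisons (unplanned vs all other patients) use Welch t-tests for
   continuous variables and Yates-corrected Pearson χ² for 2×2 tables.
4. **Logistic readmission models.** Unplanned readmission (1) on the LACE
   total plus one covariate — sex (female = 0, male = 1) for the trauma
   cohort, age in years for general surgery — fitted by Newton maximum
   likelihood (score-norm tolerance 1e−8, ≤ 50 iterations; statsmodels
   `Logit` underneath). Odds ratios are exp(β) with 95% Wald intervals
   exponentiated from the log-odds scale.
5. **Synthetic cohorts.** Because the source registry is not public, a
   seeded generator produces admission records — including free text with
   planted dictionary terms — that reproduce the published cohort structure
   and carry exact ground truth for every stage.

## Extraction details

Normalisation lower-cases the text, maps unicode dashes to `-`, replaces
all punctuation except intra-token `/` and `-` with whitespace, and splits
("CA w/o mets" → `ca`, `w/o`, `mets`). Matching is greedy
longest-phrase-first with token consumption: occurrences are ranked by
(length desc, weight desc, position) and a phrase is accepted only if none
of its tokens was consumed by an earlier-accepted phrase, so "metastatic
solid CA" blocks an inner "CA" match. Abbreviations match whole tokens only
("DM" never fires inside "admission"). Synonyms of one clinical concept
(the diabetes cluster, the stroke/CVA/TIA cluster, the CHF/CCF cluster, the
malignancy cluster, the liver cluster) share a canonical condition and
score once; within a severity group (liver 1 vs 3, malignancy 2 vs 6) only
the highest-weight matched entry is retained. The "+2" malignancy row of
the dictionary is deliberately collapsed onto one concept: mentions such as
"carcinoma", "CA", "mass" and "CA w/o mets" are one Charlson category, and
scoring them cumulatively would inflate cohort comorbidity means far above
the published values (0.2 trauma, 1.56 general). Bare "nephropathy" /
"retinopathy" / "neuropathy" are not standalone surface forms — only the
"diabetes with …" phrases — to avoid scoring non-diabetic organ disease.

There is no negation, family-history or hedging detection by default
("no DM" scores DM): the baseline procedure is pure keyword weighting, and
machine-vs-expert discordance in this design is attributed to expert
interpretation, not machine-side filtering. A `negation=True` option drops
matches whose two preceding tokens contain a simple cue (no, not, without,
denies, denied, negative); it is off everywhere unless requested.

**Age adjustment.** One CCI point per *completed* decade past 40
(50–59 → 1, 60–69 → 2, 70–79 → 3, …; ≤ 49 → 0), the standard Charlson
age convention, implemented as `floor((age − 40)/10)` clamped at 0. The
alternative "started decade" (ceiling) reading was rejected: under it the
expected age points of a trauma-profile cohort (mean age ≈ 34, SD ≈ 12)
alone already exceed the published trauma comorbidity mean of 0.2, so the
published cohort structure would be unreachable.

**Concordance.** `concordance(a, b)` is the fraction of records with
exactly equal integer scores — the statistic used to compare machine
extraction against expert or gold scores.

## LACE lookup tables

The L and C point bands are the standard published LACE bands
(L: <1 day 0, 1 → 1, 2 → 2, 3 → 3, 4–6 → 4, 7–13 → 5, ≥14 → 7;
C: 0–3 map through, ≥4 caps at 5); they reproduce the documented component
ranges (L max 7, total max 19 = 7+3+5+4) and are override-able arguments
for registries that use different bands. E is binary by default ("0 or 4")
with the standard graded variant as an explicit mode. The high-risk
threshold (default 10, inclusive) is a parameter to support threshold
sweeps under class imbalance.

## Statistical choices

- **Welch rather than pooled t.** Recomputing the published LACE and age
  t statistics from their (n, M, SD) summary cells matches the printed
  values (19.38, 5.81) under the unequal-variance test but not under the
  pooled-variance test; `welch_t_from_summary` therefore implements Welch
  with Welch–Satterthwaite df.
- **Yates correction on by default.** The published 2×2 sex statistic
  (17.01) is recovered with continuity correction (17.43 without).
- **Accuracy CI.** Exact binomial (Clopper–Pearson); conservative, and on
  cohort-sized n it reproduces published interval widths to within a few
  hundredths of a percentage point.
- **Undefined metrics** (zero denominators, e.g. PPV when nothing is
  flagged) are reported as `None` with a warning, never coerced to 0, so
  degenerate synthetic runs stay visible.
- **2×2 reconstruction.** `reconstruct_confusion(n_pos, n_neg, sens, spec)`
  rebuilds integer counts by rounding `sens·n_pos` and `spec·n_neg`;
  printed two-decimal proportions leave a ±1 count ambiguity that moves
  derived metrics by well under 0.02 percentage points at cohort sizes.

## Synthetic cohort generator

The generator emulates the two published cohort structures:

| parameter | trauma | general |
|---|---|---|
| n | 12,590 | 19,120 |
| unplanned prevalence | 804/12,590 ≈ 6.39% | 2,192/19,120 ≈ 11.46% |
| age mean (SD), years | 33.91 (12.26) | 49.33 (17.44) |
| male | 85% | 47% |
| emergency admission | 95% | 49% |
| LOS mean (SD), days | 1.76 (2.18) | 3.04 (2.08) |
| ED-visit Poisson mean | 0.35 | 0.75 |
| comorbidity-score mean | 0.2 | 1.56 |
| true LACE log-odds slope | 0.11 | 0.15 |
| covariate (slope) | sex (+0.52) | age (−0.004) |

Distributional choices: ages are truncated normal on [18, 100] with the
location calibrated by root-finding so the *truncated* mean equals the
target (plain truncation would inflate young cohorts' means); length of
stay is negative binomial with the size parameter solved from the printed
mean and SD (both cohorts are over-dispersed, variance > mean); ED visits
are Poisson. The ED rates are not published; 0.35/0.75 were fixed once so
the expected LACE totals line up with the published cohort means (5.91
trauma, 7.75 general).

Comorbid conditions are planted per record as a Poisson number of distinct
canonical conditions drawn uniformly from the dictionary. The planting
rate is derived, not tuned: expected CCI = expected age points under the
cohort age law (computed analytically from the truncated normal) plus
rate × mean dictionary weight, solved so the total matches the published
comorbidity-score mean. Each planted condition is embedded in the history
text as one randomly chosen surface form inside neutral clinical filler;
the filler vocabulary is frozen in the source and screened at generation
time (including across phrase boundaries) so it can never fire the
matcher. `gold_cci` is the planted weights — run through the same
dedup/dominance rule as the matcher — plus age points, which makes
planted-term recovery an exact oracle for the whole extraction chain
(asserted at 100% over 1,000 random histories).

The outcome is Bernoulli with logit α + β·LACE + γ·covariate, where LACE
is computed by the real scoring chain on the gold CCI (identical to the
extracted CCI by the recovery property) and α is found by bisection so the
expected prevalence matches the target to 1e−9. Because the fitted
downstream model is therefore correctly specified, parameter-recovery
checks (mean fitted OR ≈ exp(true slope)) and null-slope type-I
calibration (95% CI coverage of OR = 1) are meaningful end-to-end tests.

An `obfuscation_rate` option replaces a planted surface form with an
unmatchable paraphrase while keeping it in the gold score, emulating
phrasing an expert reader catches but the keyword matcher cannot; default
0, used only to demonstrate machine-vs-expert discordance.

What the generator does *not* emulate: realistic clinical language
(templated text only), misspellings, correlated comorbidity patterns
(conditions are drawn uniformly and independently), within-patient repeat
admissions, or separate planned-readmission dynamics ("other" pools
planned readmissions and non-readmitted patients). Passing tests therefore
demonstrate correctness of the scoring and inference machinery under the
published cohort structure, not extraction performance on real clinical
notes.

## Problem sizes and numerics

The test suite runs its simulation checks at the sizes the properties
need: full-size cohorts (n = 19,120) for parameter recovery over 20 seeds,
n = 2,000 over 100 seeds for null-slope CI calibration (coverage is
n-free), and n = 400 fixtures for structural checks. Logistic fits are
Newton with tolerance 1e−8 and raise a separation error instead of
returning diverged coefficients (detected via non-convergence or
|β| > 30). Bisection tolerances: 1e−9 on calibrated prevalence, 1e−10 on
the truncated-normal location. All randomness flows through
`numpy.random.default_rng` seeded per call; identical profile + seed gives
byte-identical cohorts.

## Known limitations

- The dictionary covers exactly the published term list; it is not a
  general clinical NER system and does no spelling correction or
  UMLS/SNOMED coding.
- The published registry tables contain internal inconsistencies (totals
  that do not sum, several mutually incompatible prevalence figures, a
  no-information rate not derivable from any printed count set); the
  package takes counts as given per file and does not attempt to
  reconcile them.
- The C component caps the CCI contribution at 5 to keep the documented
  0–19 total; registries feeding raw CCI (0–6) into LACE would need a
  custom C band, which the API allows.
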