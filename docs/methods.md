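# Methods

## The index

The obstetric comorbidity index is an additive integer score over weighted
maternal comorbidities and pregnancy risk factors recorded at admission
for delivery. Weights live in a versioned JSON table shipped with the
package (`obcmi/data/weights.json`); the two built-ins are the
prospectively validated system and a modified system that appends
2 points each for spontaneous rupture of membranes > 48 h and unbooked
pregnancy. Users can define further systems by editing or supplying a
table — for example, the variant that weights placental complications at
2 rather than 4 points is a one-line config change.

Three exclusion rules apply on top of plain summation:

* **Age**: one band only — 35–39 years → 1, 40–44 → 2, ≥ 45 → 3. Bands are
  inclusive on integer years (35 scores 1, 45 scores 3).
* **BMI**: highest band only, strict thresholds — > 40 kg/m² → 2,
  > 50 kg/m² → 3 (a BMI of exactly 40 scores 0).
* **Hypertensive disorders**: scored once. Severe preeclampsia/eclampsia
  (5 points) supersedes the entire 2-point non-severe category
  (mild/unspecified preeclampsia, gestational hypertension, chronic
  hypertension); any combination of non-severe flags contributes a single
  2. The narrower published rule — gestational hypertension is scored only
  in the absence of the other hypertensive diagnoses — is arithmetically
  equivalent because all three non-severe items carry the same weight; the
  score-once-highest formulation mirrors the stated age/BMI logic and
  generalises to user tables with unequal weights.

`max_score` computes the attainable maximum from the weight table under
these rules rather than hard-coding it: 51 for the validated system and 55
for the modified one. A stated range of 0–46 circulates for this table; it
is not reproducible from the printed weights under any reading of the
exclusion rules we could construct, so the package always reports the
computed maximum.

Missing scoring fields are a validation error with the offending row and
column, not an imputation target: the intended data source is complete-case
chart extraction.

## Outcomes

Severe maternal morbidity (SMM) and cumulative fetal morbidity (CFM) are
plain any-of composites over ten maternal and five fetal indicator flags
respectively, recomputed from the indicators on every load. No
indicator-level adjudication (e.g. transfusion thresholds for postpartum
hemorrhage) is modelled; the definitions are narrative, not algorithmic,
and the observation window (delivery to 72 h) is a property of data
collection, not enforced in code.

## Synthetic cohort generator

The generator exists so that every downstream statistic can be exercised
and calibrated without access to medical records. Its defaults are the
study conditions: n = 999 deliveries; age-band probabilities
0.397/0.356/0.185/0.058/0.003 (< 30 through ≥ 45, shortfall folded into
the reference band); P(BMI > 40) = 0.047 and P(BMI > 50) = 0.002 with
continuous BMI drawn uniformly within the implied intervals; marginal
prevalences 0.272 (previous cesarean/myomectomy), 0.049 (diabetes on
insulin), 0.034 (unbooked), 0.028 (multiple gestation), 0.022 (placental
complications), 0.019 (SROM > 48 h), 0.004 (IUFD); a 0.034/0.014 split
between non-severe hypertension and severe preeclampsia drawn as one
three-way categorical so the two are mutually exclusive by construction;
and a pooled 3.5% "prior medical comorbidity" block divided uniformly
across its seven constituent flags (autoimmune/lupus, hematological,
neurological, congenital/valvular heart disease, ischemic heart
disease/arrhythmia, asthma, chronic renal disease) because per-item
prevalences are unpublished. HIV, substance abuse, alcohol abuse,
congestive heart failure and pulmonary hypertension default to prevalence
0 (none observed in the emulated population).

Outcomes follow a single-index logistic model in the score itself — the
same model the evaluation fits — with per-unit odds ratios 1.44 (SMM) and
1.28 (CFM) under the modified system. The intercept is calibrated on the
realised score distribution by bracketed root finding
(`mean(expit(beta0 + beta1 s)) = target`, residual < 1e-10), targeting
incidences of 13.1% and 11.3%. Given a positive composite, individual
indicators are drawn independently at their published conditional
frequencies, with all-zero rows redrawn; the draw probabilities are
pre-scaled by the factor t solving `t = 1 − Π(1 − t·rᵢ)` so the
post-rejection conditional frequencies match the targets in expectation.
How indicators co-occur within a case is not identified by marginal
frequencies alone, so this independence-plus-rejection scheme is a
modelling choice.

One root seed is split into per-stage child streams (profiles, maternal
outcomes, fetal outcomes, indicator allocation); adding a stage never
perturbs earlier draws, and identical config + seed reproduce the cohort
CSV byte for byte.

**What passing tests on synthetic cohorts do and do not show.** Risk
factors are sampled independently, whereas real comorbidities cluster
(e.g. chronic hypertension with BMI and age); synthetic cohorts therefore
have slightly more women with exactly one factor and fewer with
correlated multi-factor profiles, which depresses score dispersion and
AUC relative to a real cohort with the same marginals (single-cohort AUCs
near 0.56–0.60 at these settings versus ~0.61–0.66 reported for real
data). Tests on these cohorts validate the statistical machinery —
calibration, CI coverage, determinism — not the clinical performance of
the index in any particular population.

## Evaluation statistics

* **Per-unit logistic OR** — binomial GLM fit by IRLS (statsmodels),
  Newton-polished in-package to gradient norm < 1e-9; OR = exp(β₁) with
  95% Wald CI and Wald p. Complete separation is reported via
  `converged=False` rather than an exception. A nested-grid likelihood
  maximiser in the test suite confirms the MLE to 1e-6 on small fixtures.
* **Rank-sum comparison** — exhaustive permutation enumeration of the
  rank-sum statistic (midranks; two-sided p = twice the smaller inclusive
  tail, capped at 1) when both groups have ≤ 7 observations, where heavy
  ties make the normal approximation weakest; otherwise the tie-corrected
  normal approximation with continuity correction.
* **ROC/AUC** — one point per rule "positive ⇔ score ≥ t" at every
  distinct observed score, with sentinel thresholds above the maximum and
  below the minimum pinning the curve to (0,0) and (1,1); AUC by
  trapezoidal integration (equal to the Mann–Whitney probability with ties
  counted ½); CI and the paired two-system comparison by the DeLong
  covariance method, the standard for correlated ROC statistics on the
  same subjects.
* **2×2 effect measures** — RD in percentage points; RR with a log-scale
  Wald interval (asymptotically identical to binomial-GLM inference,
  without refitting a model per table row); NNH = 100/RD, flagged
  undefined when RD ≤ 0, reported both at one decimal and rounded up to a
  whole person. RR is flagged undefined when the below-cutoff group has
  zero events.
* **Power** — classical two-sided normal-approximation power for a
  difference of two independent proportions (pooled variance under the
  null, unpooled under the alternative); returns α when p₁ = p₂.
* **Rounding** — percentages retain full precision internally;
  `round_percent` rounds half away from zero to one decimal for report
  tables.

## Numerical and design choices

* Intercept calibration brackets the root at ±(60 + |β₁|·max score); the
  mean logistic response is strictly monotone in β₀, so the root is unique.
* Cutoff tables default to every observed score; at the minimal cutoff the
  below group is empty, so sensitivity is 100%, specificity 0%, and the
  2×2 effect measures are undefined (`None`), not NaN.
* The pipeline computes every table before writing any file; a failing
  stage leaves no partial outputs. The default NNH-table cutoffs {3, 4, 5}
  bracket the recommended high-risk flag (score ≥ 4); the recommendation
  is a labelled default, not hard-coded logic.
* Report-scale simulations in the test suite use 200 replicates of
  n = 999 for coverage checks and 2×10⁴–6×10⁴ draws for
  prevalence/calibration checks — sizes at which binomial error bands are
  a few tenths of a percentage point.

## Known limitations

* No correlation structure among risk factors, and no simulation of
  descriptive-only variables (gestational age, birthweight, anesthesia,
  mode of delivery).
* Indicator co-occurrence within a composite-positive case is a modelling
  choice (independent draws with rejection), not an identified quantity.
* Weight re-estimation from data is out of scope; the package scores and
  validates existing tables.
* ICD-code-based flag extraction is out of scope; inputs are explicit 0/1
  flags as produced by chart review.
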