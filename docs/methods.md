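# Methods

This note documents the statistical procedures the package implements, the
design choices made where the underlying instrument documentation is
silent, the synthetic-data model and its calibration, and the limits of
what the test suite demonstrates.

## Instrument and scoring

The catalogue carries 103 scored items partitioned over five domains
(PHWB 13, SC 26, EM 30, LC 26, CGK 8) plus informational items that are
collected but never scored.  Instruments in this family are often described
as "104-item"; the extra item(s) are informational, so only the 103-item
scored partition is enforced (strict mode) and informational items are
unconstrained in number.  Items carry two coordinates — a letter-prefixed
section id (canonical, used to join roster columns) and a running sequence
number.  The published domain definitions give overlapping ranges in the
two numbering systems whose exact bijection cannot be recovered, so the
packaged default adopts one self-consistent mapping (e.g. PHWB = A2–A13
plus C58, sequence 17–28 and 126).  Item wordings in the packaged registry
are placeholders: all computation depends only on ids, domains,
sub-domains, response kinds and polarity, and the registry is an editable
YAML file for deployments holding the licensed item text.

Raw responses map linearly onto the ten-point scale: yes/no → {0, 10},
three-point Likert → {0, 5, 10}.  This is the only linear map of 2- and
3-category items onto a closed [0, 10] range.  Reverse-worded items
(problem behaviours such as "is shy"; polarity −1 in the registry, the
default elsewhere is +1) have the mapping flipped so 10 always means
better development.  A pupil's domain score is the unweighted mean of the
answered items of that domain — no imputation.  Because exclusion
guarantees at least 70% of items answered, the mean-over-answered rule
changes denominators by at most a few items; it is the simplest rule
consistent with that guarantee, and it is a visible policy choice
(`ExclusionPolicy`, scoring behaviour) rather than a hidden constant.
Nothing is rounded inside the pipeline; serialization rounds scores to 2
decimals and percentages to 1.

## Exclusion rules

Pupils are excluded, in fixed precedence, for: (1) parental opt-out;
(2) less than one month in class, or time-in-class unrecorded;
(3) special needs; (4) heavy missingness — ≥ 30% of the 103 scored items
unanswered, or more than one domain with no answered item.  Precedence
makes the audit log deterministic and counts each pupil exactly once; the
order follows the narrative order in which such exclusions are usually
reported.  The log conserves the roster (included + excluded = input) and
exclusion is idempotent.  Pupils with a missing deprivation quintile stay
in the analysed cohort and all non-quintile analyses; they drop out of
quintile-stratified outputs only.

Ages are computed on a 365.25-day year from date of birth to assessment
date; ages outside [3.5, 8.5) are flagged as parse issues, not excluded.

## Cutoffs and banding

Cutoffs are nearest-rank empirical quantiles over the analysed cohort:
`c_p` is the smallest observed score with cumulative proportion ≥ p%.
This guarantees every cutoff is an attainable score, which is how ceiling
behaviour becomes visible: when at least half a domain's scores equal the
observed maximum, c50 *is* that maximum, and the above-median band is
structurally empty.  The short 8-item communication scale ceilings this
way in realistic cohorts.

The banding convention is: vulnerable strictly below c10; at-risk
[c10, c25); on-track-1 [c25, c50]; on-track-2 above c50.  Strict-below at
c10 paired with right-closed c50 is the only convention that both keeps
the vulnerable fraction at or under the nominal 10% and zeroes the
above-median band under a ceiling.  An at-or-below-c10 variant is exposed
as a configuration switch.  On tie-free (continuous) scores the vulnerable
count is exactly ⌈n/10⌉ − 1, hence the fraction lies in [10% − 1/n, 10%];
on real item-mean scores ties at the cutoff push the fraction further
below 10% — most visibly in coarse scales (the 8-item domain supports only
multiples of 1.25 before missingness).  This tie effect is a property of
cohort-relative banding on discrete scores, not an implementation
artefact.

Cutoffs are computed on the full analysed cohort (including
quintile-missing pupils), never within strata; externally supplied cutoff
sets (e.g. national norms) can be loaded instead and their provenance is
echoed in every report.

## Inference

All analyses delete missing data pairwise (per analysis), so usable n —
and ANOVA degrees of freedom — legitimately differ between domains.

* **Reliability.** Cronbach's α = k/(k−1) · (1 − Σ var_i / var_total) on
  complete cases with unbiased variances.  Item-total correlations are
  *corrected* (item vs sum of the remaining items of its scale), since
  uncorrected values are inflated by self-inclusion; items below 0.2 are
  flagged for monitoring, not dropped.
* **ANOVA.** Classical one-way fixed-effects decomposition;
  F = MS_between/MS_within with p from the F distribution.
* **Odds ratios.** Maximum-likelihood binomial logistic regression; one
  model per analysis with the exposure dummy-coded against its stated
  reference (girls; most-affluent quintile; adequate first-language
  communication) and age in decimal years as a continuous covariate
  (gender added for quintile and language contrasts).  Quintile contrasts
  come from a single five-level model rather than four pairwise models.
  Wald 95% intervals are reported; perfect separation is flagged and the
  estimate marked non-estimable rather than raised.
* **Chi-square.** Pearson statistic without continuity correction
  (switchable at the call site via the table passed), expected counts from
  the margin product.
* p-values are carried at machine precision; display-level "p = .000" is
  a formatting artefact, never a computational target.

## Synthetic cohorts

The generator draws, per pupil: deprivation quintile (default probabilities
(0.04, 0.21, 0.25, 0.25, 0.25) — a small most-deprived group, as in a
district that lacks the most deprived areas), gender (51.65% boys, 0.275%
unrecorded), ESL status (2.4%), inadequate first-language communication
(0.8%), and age uniform on [4.5, 6.5) years.  Five latent domain abilities
are equicorrelated standard normals (ρ = 0.5) shifted additively by
quintile (monotone, (−0.62 … 0) latent SD units), gender (boys −0.45),
ESL (−0.30) and language (−1.30).  Each scored item adds N(0, 1.1²) noise
to its domain latent and thresholds the sum into the item's categories;
reverse-polarity items emit the reversed token so the conversion recovers
the same score.  Missingness (1% per cell) and exclusion scenarios
(opt-out 1.53%, short enrolment 2.54%, special needs 3.56%) are overlaid.

Thresholds and shifts were calibrated once, by simulation at n = 60,000
over two seeds, to the study conditions the pipeline is meant to emulate:
domain means in the mid-8s with SDs ≈ 1.8–1.9, a ceiling confined to the
CGK scale, an implied boys-vs-girls vulnerability odds ratio of ≈ 2.4 and
a most-vs-least-deprived odds ratio of ≈ 3.  A binary-threshold item model
cannot simultaneously reproduce a domain mean near 8.9 with SD 1.3 and a
minimum above 2 (as the physical-wellbeing scale shows empirically)
without per-item threshold heterogeneity; the single-threshold-per-domain
simplification was kept deliberately, so generator SDs run somewhat higher
than real scales.  Latent shifts have no closed-form mapping to
vulnerability odds ratios (vulnerability depends on cohort-relative
cutoffs over five correlated ordinal scales), so the "implied" odds ratio
of a configuration is measured on a 150,000-pupil reference cohort from
the same model; recovery tests compare desk-scale estimates against that
large-sample value.

What the generator does *not* emulate: school/teacher clustering and rater
effects, item-level difficulty heterogeneity within a domain,
non-monotone deprivation effects, and informative missingness.  Passing
recovery tests therefore shows the pipeline is consistent for data
satisfying the generator's assumptions, not that real checklist data
satisfy them.

The deterministic reference roster (1,180 pupils) is built backwards from
fixed marginals: 18 opt-outs, 30 short-enrolment and 42 special-needs
exclusions (one short-enrolment pupil also has two fully missing domains,
so the missingness rule alone never fires); 1,090 analysed pupils
(563 boys / 524 girls / 3 unrecorded, 7 missing a quintile); 193 boys,
104 girls and 1 unrecorded-gender pupil vulnerable in ≥ 1 domain (298,
27.3%) and 111 / 56 / 1 in ≥ 2 (168, 15.4%).  Note the subset constraint:
with gendered ≥1 counts of 193 + 104 and a ≥2 total of 168 > 111 + 56, the
≥1 total must be 298 — these are the only counts jointly consistent with
all six percentages at printed precision.  Per-pupil vulnerable domains
are dealt round-robin; per-domain score levels are item-count multiples
placed so the nearest-rank cutoffs land exactly between engineered blocks
(with the CGK median pinned at the maximum to reproduce the ceiling); the
constructor re-runs the full pipeline and raises if any count deviates.

## Reporting

Reports aggregate only.  Strata below a minimum cell size (default 5) are
suppressed with a reason code — the instrument's community-level ethos
makes individual-level readout a design error, not just a privacy risk.
Band percentage rows sum to 100% of pupils with a non-missing band;
≥1/≥2-domain percentages use the stratum's analysed count as denominator.
Stratum means are exact weighted decompositions of the overall mean
(checked to 1e-9).  Serialized reports are byte-deterministic for fixed
inputs and run id.

The cost model is arithmetic on a labelled currency: cohort per wave =
population × crude birth rate; wave cost = cohort × per-child cost;
annualized = wave cost / wave interval (default worked example: 150,000 ×
1% × 20 → 30,000 per triennial wave, 10,000 a year).

## Problem sizes and numerical choices

The test suite runs at desk scale by design: property suites use 100–120
random cohorts of 30–400 pupils; Monte-Carlo checks of quantile and null
behaviour use 20,000–50,000 pupils; ANOVA type-I calibration uses 500
replicates of 1,000 pupils; parameter recovery uses 20,000 pupils against
a 150,000-pupil implied-truth reference.  Closed-form oracles are checked
to 1e-10 (sums of squares, chi-square), 1e-6 (logistic vs cross-product
ratio on 2×2 tables) and 1e-12 (α against the direct formula).  The 30%
missingness boundary is compared with a 1e-12 guard so 31/103 counts as
at-least-30% despite floating-point division.

## Known limitations

* Sub-domain scores are used for reliability screening only, not reported
  as primary outputs.
* No multilevel (teacher-clustered) models and no multiple-testing
  correction — estimates mirror the single-level analysis the report
  tables assume.
* External cutoffs are accepted but not validated against the cohort's
  score support; provenance is recorded instead.
* The CLI subcommands beyond `simulate` and `all` are aliases of the full
  run (each stage's artefacts are always written); staged execution with
  caching was judged not worth the state management.
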