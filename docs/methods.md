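# Methods

## The switching phenotype

`rxswitch` operationalises early antidepressant switching from prescription
issue dates alone. No treatment durations are inferred from dosage or
quantity — in UK primary-care extracts these fields are too unreliable to
estimate exposure windows, so the phenotype is defined purely on the dates
of issues of different drugs.

For each SSRI a participant ever received, the candidate window is anchored
on the **first** issue of that SSRI (`anchor="first"`, the default, matching
the index-date definition: first prescription date of the index SSRI). An
alternative anchor on the most recent pre-switch issue (`anchor="last_before"`)
is implemented for sensitivity analyses. A candidate event is the earliest
issue of any *other* antidepressant 5–95 days after the anchor. Four
criteria gate the event (window membership; index SSRI issued ≤3 times in
total, ≤2 times strictly before, ≤2 times strictly after the switch date).
Considering only the earliest in-window candidate per index SSRI loses no
switchers: with the ≤3-total cap, a later candidate can only have *more*
pre-switch issues, and a post-switch-count failure implies a total-count
failure (the index issue always precedes the switch). The property-based
tests confirm equivalence with an exhaustive oracle over all (SSRI, other
prescription) pairs on randomized histories.

Deterministic tie-breaks: among valid events, earliest switch date, then
smallest gap, then alphabetical post-switch drug, then alphabetical index
SSRI. A same-day index-SSRI issue on the switch date counts as "after"
(strict inequalities), read as a cross-tapering allowance. A participant
whose only candidate events are invalid (e.g. an augmentation pattern) but
who holds ≥3 issues of some SSRI is a nonswitcher — they did not switch —
and carries a `had_invalid_candidate` flag for sensitivity analyses.
"≥3 prescriptions" for nonswitchers means 3 distinct issue dates of the
same canonical drug; no maximum inter-issue gap is imposed by default
(`max_refill_gap_days` makes "consecutive" strict when wanted).

Same-day duplicate (participant, date, canonical drug) rows are collapsed
on read, because duplicated EHR issue rows would otherwise inflate the
counts the criteria depend on. Drug strings resolve through a
case-insensitive dictionary with longest-canonical-substring fallback, so
brand/strength-qualified text maps to its generic. Unmapped strings become
`NON_AD` with a warning — lookup is total. Diagnosis code lists are flat
lookup tables; the shipped defaults are illustrative placeholders, not
validated codelists.

## Cohort and strata

Exclusion (any bipolar / psychosis / substance-abuse code) applies at any
date, before or after the index prescription, and empties all strata.
Depression records are likewise counted at any date; a separate check
reports the fraction of classified participants whose earliest depression
record is on or before the index date (the generator's default plants 75%).
Two same-day depression records count separately when the codes differ.
Strata are nested: ≥2 records ⊆ ≥1 record ⊆ all.

## Statistical analyses

Group descriptives follow standard cohort-table practice: Pearson
chi-square without continuity correction for binaries (large-sample usage;
correction is switchable), Kruskal–Wallis on integer scores in display
order for multi-level categoricals, Wilcoxon rank-sum for continuous
variables, medians with linear-interpolation (type-7) quantiles. Missing
levels are reported as "Unknown" rows and excluded from tests. Temporal
trends bin participants by calendar year of index date (bin width is a
convention; years are the natural granularity for multi-decade prescribing
data), drop bins under 20 participants, and report Pearson correlations of
per-bin switch rate and median time-to-switch against year. A constant
series has no defined correlation; the convention here is r = 0, p = 1.

Association models are maximum-likelihood logistic regressions fitted per
exposure: switcher (1) vs nonswitcher (0) on the exposure plus sex (female
reference), index date and assessment centre. Index date enters as a
continuous covariate in years since 1995-01-01 — the coding is a design
choice; years rather than days only rescales the coefficient. Polygenic
scores are standardised to mean 0, SD 1 within the analysis sample (effects
are per SD) and additionally adjusted for 10 principal components. Missing
categorical levels are excluded from fitting rather than modelled, so
reference levels stay interpretable. Inference is a likelihood-ratio test
of the full against the adjustment-only model; intervals are 95% Wald.
Complete or quasi-complete separation is flagged (`estimable=False`) rather
than silently penalised — small strata legitimately return non-estimable
rows. Multiplicity control is Bonferroni over 7 tests (4 sociodemographic
exposures + 3 polygenic scores), threshold 0.05/7 ≈ 0.00714.

Relatedness pruning treats kinship ≥ 0.044 as related (the conventional
third-degree cut-off; the threshold is configurable) and greedily deletes
the individual covering the most remaining related pairs, preferring to
delete nonswitchers at every tie, with id order as the final tie-break.
Greedy vertex cover is not guaranteed optimal; tests audit that the
retained set is within one individual of the exhaustive optimum on small
graphs.

## The synthetic cohort

The generator emulates what the analysis needs from biobank-linked primary
care data, as a pure function of (config, seed) with one RNG stream per
output table (adding a table never perturbs existing ones).

Defaults encode the published study conditions: 67% female; index-SSRI mix
from the nonswitcher column of the baseline table (nonswitchers dominate);
marginal switch prevalence 0.13, achieved by solving the liability
intercept against the sampled covariates; log-odds effects of −0.31 for a
university degree, −0.42 for income >£100k, +0.068 per SD of the
nonremission polygenic score, +0.02 per calendar year; 22 assessment
centres with N(0, 0.3) log-odds offsets (giving roughly a 9–19% prevalence
range); post-switch mix 46% SSRI / 31% TCA with the remainder split across
SNRI/SARI/NRI/MAOI/other; refill intervals N(28, 5) days floored at 7 (a
convention — UK monthly scripts — since no inter-issue distribution is
published); nonswitcher issue counts log-normal with median 18 (IQR 7–47),
capped at 60 to bound table sizes; 58% / 38% of participants with ≥1 / ≥2
depression records; 75% of first depression records preceding the index
date; 1% excluded by diagnosis; 1% of participants in kinship pairs; a
1995–2018 calendar span.

**Time to switch.** The published summary is median 28, IQR 17–49 days.
These quartiles are not log-symmetric (28/17 ≠ 49/28), so no two-parameter
log-normal reproduces all three. `derive_ttswitch_params` provides the
conventional symmetric fit (μ = ln median, σ = log-IQR/1.349), which
matches the median exactly but log-symmetrises the IQR to about (16.5,
47.6). The generator therefore samples a **shifted** log-normal whose three
parameters are solved in closed form to hit all three quartiles exactly
(σ = ln r / z₀.₇₅ with r the ratio of upper to lower quartile spread;
shift = median − exp μ), falling back to the symmetric form when r ≤ 1.
Gaps are truncated to the 5–95-day window by rejection and rounded to whole
days. Truncation trims ~8% of upper-tail mass, so the *cohort-level* upper
quartile sits near 41 days even though the pre-truncation distribution has
q75 = 49; tests compare cohort quantiles against the truncated
distribution's closed-form integer-day quantiles.

Switcher histories honour the four criteria by construction (1–2 pre-switch
issues, the switch drug at the sampled gap, optional cross-taper issue,
post-switch continuation refills); nonswitcher histories are same-drug
refill streams. Optional contaminant patterns — augmentation overlap
(second antidepressant within 5 days, index SSRI continued), single-issue
participants, non-antidepressant-only streams — exercise the unclassified
path and individual criterion failures; each is recorded in the truth
table so misclassification is attributable row by row. The default is
contamination-free, which is what makes exact recovery a meaningful test.

What the generator does **not** emulate: genotypes (polygenic scores are
standard normals with configured effects), informative missingness,
correlated covariates (education/income/deprivation are drawn
independently), dosage/quantity fields, multi-episode relapse structure,
and code-system dialect beyond cosmetic strength suffixes. Passing recovery
tests therefore demonstrate algorithmic correctness under the assumed
record structure, not robustness to real-world coding noise.

## Numerical and testing choices

Problem sizes: the replicate study runs 100 seeds of the default 20,000-
participant cohort; the acceptance script uses a single 40,000-participant
cohort for association estimates and 10⁵ draws for the time-to-switch
calibration. Oracle suites compare scipy/statsmodels-backed statistics
against hand-written formula implementations to 10⁻⁶ relative accuracy on
small instances; the coverage check uses 1000 replicates against a ≥93%
coverage bound so that binomial noise at nominal 95% coverage rarely
triggers a false failure. Logistic fits flag non-convergence, exploding
exposure coefficients (|β| > 15) or non-finite standard errors as
non-estimable. All file outputs are deterministic: sorted keys, no
timestamps, mergesort (stable) ordering throughout.

## Known limitations

* The phenotype cannot distinguish the reason for switching (inefficacy,
  side effects, noncompliance); early switches are enriched for
  tolerability problems.
* Kinship pruning is near-optimal, not optimal; with very dense relatedness
  graphs the retained set may be one below the maximum.
* The default drug dictionary and codesets are small illustrative lists;
  production use requires curated codelists for the source code systems.
* The generator's depression-record counts are independent of switcher
  status, whereas real cohorts show slightly higher record counts among
  switchers (60% vs 58% with ≥1 record); the difference is immaterial for
  the recovery properties tested here.
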