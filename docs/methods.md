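# Methods

This note documents the models, parameter choices and numerical
conventions behind shiftjem, and what the synthetic-data tests do and do
not establish about real data.

## Exposure assessment

**Shift-worker definition.** A labour-survey respondent is a shift worker
iff their schedule is regular evening, regular night, or rotating *and*
weekly hours exceed 20 (strict inequality, read literally from the
definition's wording "more than 20 hours/week"). The three shift
schedules are never distinguished downstream, so the survey generator
assigns them uniformly among respondents drawn "shift".

**Tabulation.** Counts are per sex and occupation code at two hierarchy
levels: specific (4-character) and broad (2-character). Broad codes are
the leading two characters of the specific code, matching how the
four-tier national occupation classification nests unit groups inside
major groups. Tabulation is unweighted — one respondent, one count; the
source tool's weighting is undocumented, and unweighted counts are the
reproducible choice.

**Suppression.** A cell's proportion is concealed iff n_total < 25, or
(n_shift < 5 and n_total < 100); all comparisons strict, mirroring the
release rule's wording ("fewer than 25", "fewer than five", "less than
100"). Suppressed cells expose no proportion through the API (`p_shift`
is None) and serialise with an empty field, emulating a released table.

**Linkage.** Current workers are looked up at the specific level first;
under the `fallback` strategy a suppressed *or absent* specific cell
falls through to the broad level (from the consumer's side the two are
indistinguishable). 2-character codes — standing in for occupation
reports too vague to code specifically — go straight to the broad
lookup. The `four_digit_only` strategy (sensitivity analysis) accepts
specific hits only. Former and never workers are pooled into a single
`not_working` comparison category; the employment-status column retains
the distinction for reporting.

**Categories.** Cut-points 0.015, 0.10, 0.45 on the proportion scale,
lower bound inclusive ("1.5% to <10%", "45%+"). Boundary behaviour is
unit-tested from both sides at ±1e-9.

## Outcomes

BMI = weight/height² (kg/m²). The outermost 0.2% of weight and of height
responses are removed per variable before classification; the total
fraction is split 0.1% per tail (the symmetric reading; the fraction is a
parameter, so an asymmetric variant is testable). The cut is an
order-statistic rule: with k = floor(n·fraction/2), values strictly below
the (k+1)-th smallest or strictly above the (k+1)-th largest are flagged,
which leaves ties at the cut intact, flags nobody in a degenerate
constant sample, and never flags more than ceil(n·fraction) ids per
variable. A participant trimmed on either variable is excluded from
classification. WHO classes: normal/under < 25 ≤ overweight < 30 ≤ obese.

## Regression

Baseline-category multinomial logit, reference outcome normal/under,
reference exposure near nil, with dummies for low, medium, high,
missing-probability and not-working. Estimation is full Newton on the
stacked coefficient vector with step-halving (the log-likelihood is
non-decreasing across iterations by construction), converging when the
gradient max-norm is ≤ 1e-8, capped at 100 iterations; fits stopping at
the cap are flagged non-converged and refused by the Wald summariser.
The covariance is the inverse observed information at the optimum (which
for this model equals the expected information); no robust correction,
matching conventional Wald reporting. CIs use the customary 1.96
multiplier; p-values are two-tailed normal. A likelihood-ratio test is
available as a secondary statistic. Rank-deficient designs raise an
error naming the collinear columns (QR with pivoting); exposure groups
with an empty outcome cell are excluded from estimation with a logged
note, since their odds ratio is not estimable — mirroring removal of
low-cell-count groups in published tables.

The implementation is validated against closed-form cross-product ratios
on saturated tables (to 1e-6), against an independent multinomial
implementation (statsmodels MNLogit, machine precision), and against
ordinary logistic regression after collapsing overweight+obese into one
level (to 1e-8).

## Confounder selection

Forward selection by the change-in-estimate criterion: each round refits
the model once per remaining candidate and admits the one with the
largest relative change of the exposure estimates if it reaches 10.0%.
The monitored parameter set is the low/medium/high odds ratios on both
outcome contrasts, aggregated by maximum — this protects every reported
exposure contrast; per-contrast monitoring and a log-odds scale are
config options, since the aggregation convention is genuinely open. The
change is measured on the OR scale by default (|OR_with − OR_without| /
OR_without × 100), the standard epidemiologic convention, which also
avoids dividing by near-zero log-odds. Ties break by candidate-list
order; candidates that make the design singular or fail to converge are
skipped for the round with a logged warning. Age is *not* force-entered;
it competes like any candidate. With threshold → ∞ the base model is
returned unchanged; with threshold 0 every usable candidate is admitted
in order of change magnitude.

## Synthetic data

**What the survey generator emulates.** A 12,500-respondent female
extract with 22 occupation codes across 10 broad groups whose shift
propensities span all four exposure categories. Weekly hours are normal
(mean 37.5, SD 9, clipped at 0), so ~2.5% of would-be shift workers fall
at or below the 20-hour threshold and the tabulated proportion sits
slightly below the configured propensity — deliberate, since category
pools are derived from the *realised* JEM. Small-weight codes (~15–70
workers) trigger both suppression branches naturally, and every category
contains suppressed specific codes with a releasable broad parent, so the
fallback path is always exercised.

**What the study generator emulates.** Default n = 3,377 (1,611 current
workers + 1,766 non-workers) with the category mix, covariate marginals,
near-nil-group intercepts (log 60/90, log 31/90) and per-category
four-digit linkage shares (high 100%, near nil 83%, others 55%) of the
population-based sample the pipeline is modelled on; exposure log-odds
default to the log of that sample's adjusted odds ratios (obese, high:
ln 1.88). Occupation codes are drawn from the realised JEM's category
pools, so fallback linkage reproduces the generated category exactly.
Heights are normal (1.63 m, SD 0.07); BMI is drawn uniformly within the
drawn class interval (normal/under 17–25, overweight 25–30, obese 30–45)
and weight back-solved as BMI·height², guaranteeing the emitted
anthropometry reclassifies to the drawn class for every untrimmed record.
0.5% of participants have missing anthropometry, reproducing the small
group-n versus class-count shortfalls seen in published tables. A
true-exposure variant draws an individual Bernoulli(p) shift indicator
per participant and drives the outcome from it (default individual
obesity OR 3.0), enabling the attenuation experiment.

**What it does not emulate.** Panel structure and survey weights of the
source labour survey; free-text occupation coding; self-report bias in
height and weight; covariate-exposure correlation (absent by default, so
default runs contain no genuine confounding — selection tests construct
it explicitly); male workers (the API carries sex, fixtures are female).
Passing tests therefore demonstrate correctness of the *procedures* under
the stated generating model, not reproduction of any real cohort's
adjusted estimates, which would require the original individual data.

## Reporting conventions

Display percentages are rounded half-up: one decimal in descriptive
tables, integers in the per-category regression table. Weight-class
percentages use the sum of the three non-missing class counts as
denominator (this is the convention that reproduces the printed
69/28/3 row from counts 46/19/2); exposure-category percentages use all
current workers including the unattainable group. Underlying CSVs keep
full precision. All artifacts are plain text (CSV/JSON), each stage is
re-runnable from the persisted output of the stage before, and a fixed
master seed makes the whole pipeline byte-identical (nested seeds are
derived from it).

## Problem sizes

Simulation-based checks use 200 replicates at n = 5,000 for parameter
recovery (mean log-OR within ±0.05 of ln 1.88; Wald coverage 92–98%),
100 replicates at n = 3,377 for attenuation, 100 replicates at n = 4,000
for the null-calibration check (mean ORs in [0.8, 1.25], KS-uniform
p-values), and 20 random datasets for the binary-collapse oracle —
sizes chosen so each check's Monte-Carlo error is well inside its
tolerance band while the whole suite stays fast on one CPU. A
per-replicate OR bound at these sizes would be tighter than the
sampling distribution allows; the null check therefore bounds the
replicate *mean*.
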