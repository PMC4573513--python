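# shiftjem

Probability-of-shift-work exposure assessment and obesity analysis for
occupational epidemiology.

## The problem

Many questionnaire studies never ask about shift work directly, yet shift
work is a suspected risk factor for obesity and the chronic diseases it
mediates. When only a free-text occupation is available, exposure can be
assessed through a **job-exposure matrix (JEM)**: a labour survey in which
respondents report both occupation and work schedule is tabulated, per sex
and occupation code, into the proportion of workers who are shift workers
(*P*<sub>shift work</sub>). Study participants are then linked to that
proportion through their occupation code and banded into exposure
categories.

Two real-world complications drive the design:

* **Confidentiality suppression.** The releasing agency conceals a cell's
  proportion when it holds fewer than 25 workers, or fewer than 5 shift
  workers with fewer than 100 total. Suppressed 4-digit codes force a
  *fallback* to the broader 2-digit code's proportion.
* **Group-level exposure.** Assigning every nurse the nursing profession's
  shift probability misclassifies individuals, attenuating effect
  estimates toward the null — a bias this package quantifies by
  simulation.

shiftjem implements the full workflow as a tested library: synthetic
survey/study generators with known ground truth (the confidential source
data cannot be shipped), JEM tabulation and suppression, specific-first /
broad-fallback linkage, BMI outcomes (0.2% outlier trimming, WHO classes
at 25 and 30 kg/m²), change-in-estimate (≥10%) forward confounder
selection, and baseline-category multinomial logistic regression.

## The model

A shift worker holds regular evening, night, or rotating shifts for
strictly more than 20 h/week. Linked probabilities are banded as
near nil (*p* < 1.5%), low (1.5% ≤ *p* < 10%), medium (10% ≤ *p* < 45%)
and high (*p* ≥ 45%), with missing-probability and not-working comparison
categories. With weight class *Y* ∈ {normal/under, overweight, obese}
(reference: normal/under) and design row *x*,

  log [ P(Y = j) / P(Y = normal) ] = xᵀβⱼ,  j ∈ {overweight, obese},

fitted by Newton iterations with step-halving to gradient max-norm ≤ 1e-8.
Odds ratios are exp(β) with Wald 95% intervals exp(β ± 1.96·se) and
two-tailed p-values; covariates enter after forward selection admits any
candidate that moves a low/medium/high exposure OR by ≥ 10%.

## Worked example

`python examples/fit_obesity_model.py` simulates a cohort of 8,000
participants in which the generating obese log-odds for the high category
is ln(1.88), links them through a JEM built from 12,500 synthetic survey
records, and prints:

```
confounders admitted (>=10% change in an exposure OR): none

fit on n=7944 (converged=True); odds ratios vs near-nil reference:

  contrast                  term  odds_ratio  ci_low  ci_high  p_value
overweight         category[low]       0.911   0.728    1.140    0.415
...
     obese        category[high]       1.661   1.089    2.534    0.018
```

The high-category obesity OR (1.66, 95% CI 1.09–2.53) estimates the
generating value 1.88 within sampling error; no candidate covariate is
admitted because the default generator gives covariates no association
with exposure. `examples/misclassification_attenuation.py` shows the
flip side: with a true *individual*-level OR of 3.0, the category-level
analysis averages an OR of about 2.0 — attenuation from group-level
exposure assignment.

Other entry points: `examples/build_jem.py`, `examples/link_exposures.py`,
`examples/run_full_pipeline.py`, and a thin CLI
(`shiftjem all --seed 5 --out run/`, with per-stage subcommands
`simulate`, `build-jem`, `link`, `outcomes`, `select`, `fit`, `report`).

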