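"""Adjusted polytomous regression of weight class on shift-work exposure.

Runs the full analysis on one synthetic cohort: BMI trimming and WHO
classification, forward change-in-estimate confounder selection (>=10%
movement of any low/medium/high exposure odds ratio), and the final
baseline-category multinomial fit with Wald 95% intervals.
"""

import shiftjem as sj
from shiftjem.model import ModelSpec
from shiftjem.pipeline import build_analysis_table, covariates_from_study_config

survey = sj.generate_survey(sj.SurveyConfig(seed=1))
specific, broad = sj.build_jem_pair(survey)
cfg = sj.StudyConfig(n_participants=8000, seed=3)
study = sj.generate_study(cfg, specific, broad)

assignments = sj.link_exposures(study, specific, broad)
bmi = sj.assess_bmi(study)
analysis = build_analysis_table(study, assignments, bmi)

base = ModelSpec(exposure="category", exposure_levels=sj.ALL_CATEGORIES)
candidates = covariates_from_study_config(cfg, ["age", "education", "race"])
trace = sj.select_confounders(base, candidates, analysis, threshold=10.0)
print("confounders admitted (>=10% change in an exposure OR):",
      list(trace.final_covariates) or "none")

final = [c for c in candidates if c.name in trace.final_covariates]
fit = sj.fit_multinomial(base.with_covariates(final), analysis)
table = sj.wald_summary(fit)
exposure_rows = table[table["term"].str.startswith("category[")]
print(f"\nfit on n={fit.n_used} (converged={fit.converged}); "
      "odds ratios vs near-nil reference:\n")
print(exposure_rows[["contrast", "term", "odds_ratio", "ci_low", "ci_high", "p_value"]]
      .to_string(index=False, float_format=lambda x: f"{x:.3f}"))
print("\nThe generating obese log-OR for the high category is ln(1.88);")
print("its fitted odds ratio should sit near 1.88 up to sampling error.")
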