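"""Attenuation of an individual-level effect under group-level exposure.

Each participant's outcome is driven by a personal shift-work indicator
drawn Bernoulli(p) from their occupation's probability (true individual
obesity OR = 3.0), but the analysis only sees the probability *category*.
Averaged over replicates, the estimated high-vs-near-nil category OR falls
strictly between 1.0 and 3.0: the bias toward the null that group-level
exposure assignment buys in exchange for not measuring individual exposure.
"""

import numpy as np

import shiftjem as sj
from shiftjem.model import Covariate, ModelSpec, fit_multinomial
from shiftjem.pipeline import build_analysis_table

survey = sj.generate_survey(sj.SurveyConfig(seed=1))
specific, broad = sj.build_jem_pair(survey)
spec = ModelSpec(
    exposure="category",
    exposure_levels=sj.ALL_CATEGORIES,
    covariates=(
        Covariate("age", "continuous"),
        Covariate("education", "categorical",
                  ("secondary_or_less", "post_secondary", "graduate")),
    ),
)

ors = []
for seed in range(20):
    cfg = sj.StudyConfig(n_participants=3377, seed=seed)
    study = sj.generate_true_exposure_variant(cfg, specific, broad)
    assignments = sj.link_exposures(study, specific, broad)
    analysis = build_analysis_table(study, assignments, sj.assess_bmi(study))
    fit = fit_multinomial(spec, analysis)
    ors.append(fit.odds_ratio("obese", "category[high]"))

print(f"true individual-level obesity OR:      3.00")
print(f"mean category-level OR ({len(ors)} replicates): {np.mean(ors):.2f}")
print("\nThe category estimate is attenuated because the high category mixes")
print("truly exposed and unexposed workers (p_shift ~0.5-0.6, not 1.0).")
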