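"""Baseline-category multinomial logit: oracles, invariance, inference."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import shiftjem as sj
from shiftjem.errors import DataError, NotConvergedError, SingularDesignError
from shiftjem.model import (
    Covariate,
    FitResult,
    ModelSpec,
    fit_multinomial,
    lr_test,
    wald_summary,
)

CLASSES = ("normal_under", "overweight", "obese")


def table_to_frame(cells: dict[str, tuple[int, int, int]]) -> pd.DataFrame:
    """Expand {exposure: (n_normal, n_over, n_obese)} into individual rows."""
    rows = []
    for group, counts in cells.items():
        for cls, n in zip(CLASSES, counts):
            rows += [{"category": group, "weight_class": cls}] * n
    return pd.DataFrame(rows)


def exposure_only_spec(levels):
    return ModelSpec(exposure="category", exposure_levels=tuple(levels))


def test_saturated_fit_equals_cross_product_ratios():
    """Crude ORs from a 2x3 table are closed-form cross-product ratios."""
    data = table_to_frame({"near_nil": (90, 60, 31), "high": (48, 34, 28)})
    fit = fit_multinomial(exposure_only_spec(["near_nil", "high"]), data)
    assert fit.converged
    obese_or = fit.odds_ratio("obese", "category[high]")
    over_or = fit.odds_ratio("overweight", "category[high]")
    assert obese_or == pytest.approx((28 * 90) / (48 * 31), abs=1e-6)
    assert over_or == pytest.approx((34 * 90) / (48 * 60), abs=1e-6)


def test_saturated_equivalence_over_random_tables():
    rng = np.random.default_rng(202)
    for _ in range(30):
        cells = {
            "ref": tuple(rng.integers(1, 60, 3)),
            "exp": tuple(rng.integers(1, 60, 3)),
        }
        fit = fit_multinomial(exposure_only_spec(["ref", "exp"]), table_to_frame(cells))
        for j, contrast in enumerate(("overweight", "obese"), start=1):
            oracle = (cells["exp"][j] * cells["ref"][0]) / (
                cells["exp"][0] * cells["ref"][j]
            )
            assert fit.odds_ratio(contrast, "category[exp]") == pytest.approx(
                oracle, abs=1e-6
            )


def simulate_three_class(seed, n=1500):
    rng = np.random.default_rng(seed)
    age = rng.normal(46, 8, n)
    cat = rng.choice(["near_nil", "low", "high"], n, p=[0.4, 0.4, 0.2])
    lp_o = -0.4 + 0.2 * (cat == "low") + 0.5 * (cat == "high") + 0.01 * (age - 46)
    lp_b = -1.0 + 0.1 * (cat == "low") + 0.7 * (cat == "high") + 0.02 * (age - 46)
    eo, eb = np.exp(lp_o), np.exp(lp_b)
    den = 1 + eo + eb
    u = rng.random(n)
    y = np.where(u < 1 / den, "normal_under",
                 np.where(u < (1 + eo) / den, "overweight", "obese"))
    return pd.DataFrame({"weight_class": y, "category": cat, "age": age})


def test_agrees_with_statsmodels_mnlogit():
    data = simulate_three_class(5, n=2000)
    spec = ModelSpec(
        exposure="category",
        exposure_levels=("near_nil", "low", "high"),
        covariates=(Covariate("age", "continuous"),),
    )
    fit = fit_multinomial(spec, data, tol=1e-10)
    ycode = pd.Categorical(data["weight_class"], categories=CLASSES).codes
    X = np.column_stack(
        [
            np.ones(len(data)),
            (data["category"] == "low").astype(float),
            (data["category"] == "high").astype(float),
            data["age"],
        ]
    )
    oracle = sm.MNLogit(ycode, X).fit(method="newton", tol=1e-10, disp=0)
    assert np.abs(oracle.params - fit.params.to_numpy()).max() < 1e-8
    assert np.abs(np.asarray(oracle.bse) - fit.bse.to_numpy()).max() < 1e-6
    assert fit.llf == pytest.approx(oracle.llf, abs=1e-8)


def test_binary_collapse_matches_ordinary_logistic_regression():
    """Merging overweight+obese reduces the model to a binary logit."""
    rng = np.random.default_rng(77)
    for seed in rng.integers(0, 2**31 - 1, 20):
        data = simulate_three_class(int(seed), n=400)
        data["weight_class"] = np.where(
            data["weight_class"] == "normal_under", "normal_under", "above_normal"
        )
        spec = ModelSpec(
            exposure="category",
            exposure_levels=("near_nil", "low", "high"),
            outcome_levels=("normal_under", "above_normal"),
            covariates=(Covariate("age", "continuous"),),
        )
        fit = fit_multinomial(spec, data, tol=1e-12)
        X = np.column_stack(
            [
                np.ones(len(data)),
                (data["category"] == "low").astype(float),
                (data["category"] == "high").astype(float),
                data["age"],
            ]
        )
        y = (data["weight_class"] == "above_normal").astype(float)
        oracle = sm.Logit(y, X).fit(method="newton", tol=1e-12, maxiter=200, disp=0)
        assert np.abs(oracle.params.to_numpy() - fit.params["above_normal"].to_numpy()).max() < 1e-8


def test_reference_recoding_transforms_coefficients_exactly():
    data = table_to_frame(
        {"near_nil": (90, 60, 31), "low": (70, 50, 30), "high": (48, 34, 28)}
    )
    fit_a = fit_multinomial(exposure_only_spec(["near_nil", "low", "high"]), data)
    fit_b = fit_multinomial(exposure_only_spec(["high", "near_nil", "low"]), data)
    for contrast in ("overweight", "obese"):
        b_high = fit_a.coef(contrast, "category[high]")
        b_low = fit_a.coef(contrast, "category[low]")
        assert fit_b.coef(contrast, "category[low]") == pytest.approx(
            b_low - b_high, abs=1e-6
        )
        assert fit_b.coef(contrast, "category[near_nil]") == pytest.approx(
            -b_high, abs=1e-6
        )


def test_likelihood_never_decreases_across_iterations():
    data = simulate_three_class(9, n=800)
    spec = ModelSpec(
        exposure="category",
        exposure_levels=("near_nil", "low", "high"),
        covariates=(Covariate("age", "continuous"),),
    )
    fit = fit_multinomial(spec, data)
    diffs = np.diff(fit.ll_path)
    assert (diffs >= -1e-10).all()
    assert fit.converged and fit.max_grad <= 1e-8


def test_null_exposure_estimates_unbiased_and_p_values_uniform(jem_pair):
    """With all exposure effects zero the fitted ORs centre on 1 and
    Wald p-values are uniform."""
    from scipy import stats

    specific, broad = jem_pair
    zero = {c: 0.0 for c in ("low", "medium", "high", "missing_p", "not_working")}
    base = sj.StudyConfig(
        n_participants=4000,
        true_log_odds={"overweight": dict(zero), "obese": dict(zero)},
    )
    spec = exposure_only_spec(sj.ALL_CATEGORIES)
    rng = np.random.default_rng(314)
    ors, pvals = [], []
    for seed in rng.integers(0, 2**31 - 1, 100):
        cfg = base.model_copy(update={"seed": int(seed)})
        study = sj.generate_study(cfg, specific, broad)
        study["category"] = study["true_exposure_category"]
        study["weight_class"] = study["drawn_class"]
        fit = fit_multinomial(spec, study)
        table = fit.or_table()
        row = table[(table["contrast"] == "obese") & (table["term"] == "category[high]")]
        ors.append(
            [fit.odds_ratio(c, f"category[{l}]")
             for c in ("overweight", "obese") for l in ("low", "medium", "high")]
        )
        pvals.append(float(row["p_value"].iloc[0]))
    mean_ors = np.mean(ors, axis=0)
    assert np.all(mean_ors > 0.8) and np.all(mean_ors < 1.25)
    assert stats.kstest(pvals, "uniform").pvalue > 0.01


def test_rank_deficient_design_names_collinear_terms():
    data = simulate_three_class(13, n=300)
    data["age_copy"] = data["age"]
    spec = ModelSpec(
        exposure="category",
        exposure_levels=("near_nil", "low", "high"),
        covariates=(Covariate("age", "continuous"), Covariate("age_copy", "continuous")),
    )
    with pytest.raises(SingularDesignError) as err:
        fit_multinomial(spec, data)
    assert "age_copy" in err.value.collinear_terms


def test_missing_outcome_level_raises():
    data = table_to_frame({"near_nil": (90, 60, 0), "high": (48, 34, 0)})
    with pytest.raises(DataError):
        fit_multinomial(exposure_only_spec(["near_nil", "high"]), data)


def test_groups_with_empty_outcome_cell_are_excluded():
    data = table_to_frame(
        {"near_nil": (90, 60, 31), "high": (48, 34, 28), "missing_p": (17, 10, 0)}
    )
    fit = fit_multinomial(exposure_only_spec(["near_nil", "high", "missing_p"]), data)
    assert fit.dropped_groups == ["missing_p"]
    assert "category[missing_p]" not in fit.params.index
    # remaining estimates are untouched by the removed group
    assert fit.odds_ratio("obese", "category[high]") == pytest.approx(
        (28 * 90) / (48 * 31), abs=1e-6
    )


def _toy_fit(coef, se, converged=True):
    spec = ModelSpec(exposure="x", exposure_levels=("a", "b"))
    params = pd.DataFrame(
        {"overweight": [0.0, coef], "obese": [0.0, coef]}, index=["intercept", "x[b]"]
    )
    bse = pd.DataFrame(
        {"overweight": [1.0, se], "obese": [1.0, se]}, index=["intercept", "x[b]"]
    )
    return FitResult(
        spec=spec, params=params, bse=bse, cov=pd.DataFrame(),
        llf=0.0, converged=converged, n_used=10, n_iter=1,
    )


def test_wald_summary_null_coefficient():
    table = wald_summary(_toy_fit(0.0, 1.0))
    row = table[(table["term"] == "x[b]") & (table["contrast"] == "obese")].iloc[0]
    assert row["p_value"] == pytest.approx(1.0)
    assert not row["significant"]


def test_wald_summary_at_significance_boundary():
    table = wald_summary(_toy_fit(1.96, 1.0))
    row = table[(table["term"] == "x[b]") & (table["contrast"] == "obese")].iloc[0]
    assert row["p_value"] == pytest.approx(0.05, abs=1e-3)
    assert row["ci_low"] == pytest.approx(1.0, abs=1e-6)  # exp(1.96 - 1.96*1)


def test_ci_excluding_one_iff_significant():
    """A 95% CI lower bound above 1 coincides with p < 0.05."""
    for coef in (0.3, 0.631, 1.0):
        for se in (0.2, 0.32, 0.5):
            table = wald_summary(_toy_fit(coef, se))
            row = table[(table["term"] == "x[b]") & (table["contrast"] == "obese")].iloc[0]
            assert (row["ci_low"] > 1.0) == row["significant"]


def test_wald_summary_refuses_non_converged_fit():
    with pytest.raises(NotConvergedError):
        wald_summary(_toy_fit(1.0, 1.0, converged=False))


def test_lr_test_secondary_statistic():
    data = simulate_three_class(21, n=1200)
    spec0 = exposure_only_spec(["near_nil", "low", "high"])
    spec1 = ModelSpec(
        exposure="category",
        exposure_levels=("near_nil", "low", "high"),
        covariates=(Covariate("age", "continuous"),),
    )
    reduced = fit_multinomial(spec0, data)
    full = fit_multinomial(spec1, data)
    stat, df, p = lr_test(full, reduced)
    assert stat > 0 and df == 2 and 0 <= p <= 1
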