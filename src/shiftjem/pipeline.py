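"""End-to-end orchestration: simulate, build JEM, link, classify, select, fit.

The pipeline persists every intermediate artifact as plain text (CSV/JSON)
so any stage can be re-run from the stage before it, and produces three
report structures mirroring how such analyses are conventionally
published: a descriptive distribution table, a top-occupations-per-category
table, and a per-category odds-ratio table, plus sample-size flow counts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from ._util import percentages, round_half_up, spawn_seeds
from .bmi import DEFAULT_TRIM_FRACTION, WEIGHT_CLASSES, assess_bmi
from .errors import DataError
from .jem import JEMTable, build_jem_pair
from .linkage import (
    ALL_CATEGORIES,
    EXPOSURE_CATEGORIES,
    FlowCounts,
    flow_accounting,
    link_exposures,
)
from .model import Covariate, FitResult, ModelSpec, fit_multinomial, term_name
from .selection import DEFAULT_THRESHOLD, SelectionTrace, select_confounders
from .synthetic import (
    CategoricalConfounder,
    StudyConfig,
    SurveyConfig,
    generate_study,
    generate_survey,
    write_provenance,
)

logger = logging.getLogger(__name__)


class PipelineStageError(DataError):
    """A pipeline stage failed; carries the stage name, chains the cause."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")


#: Covariates assessed for confounding (the questionnaire variable list).
DEFAULT_CANDIDATES = (
    "age",
    "education",
    "race",
    "marital",
    "parity",
    "smoking_pack_years",
    "calories",
    "alcohol",
    "physical_activity",
)


class SelectionConfig(BaseModel):
    threshold: float = DEFAULT_THRESHOLD
    scale: Literal["or", "log"] = "or"
    contrast: str | None = None
    candidates: list[str] = Field(default_factory=lambda: list(DEFAULT_CANDIDATES))


class RunConfig(BaseModel):
    """Configuration of a full synthetic-data pipeline run.

    ``seed`` drives every stage; the nested survey/study seeds are derived
    from it, so two runs with equal configs are byte-identical.
    """

    survey: SurveyConfig = Field(default_factory=SurveyConfig)
    study: StudyConfig = Field(default_factory=StudyConfig)
    strategy: Literal["fallback", "four_digit_only"] = "fallback"
    trim_fraction: float = Field(default=DEFAULT_TRIM_FRACTION, ge=0.0, lt=0.5)
    selection: SelectionConfig = Field(default_factory=SelectionConfig)
    seed: int = 0


@dataclass
class ReportBundle:
    """All artifacts of one pipeline run."""

    survey: pd.DataFrame
    jem_specific: JEMTable
    jem_broad: JEMTable
    study: pd.DataFrame
    assignments: pd.DataFrame
    flow: FlowCounts
    bmi: pd.DataFrame
    analysis: pd.DataFrame
    trace: SelectionTrace
    fit: FitResult
    table2: pd.DataFrame
    table3: pd.DataFrame
    table4: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.survey.to_csv(out / "survey.csv", index=False)
        self.jem_specific.to_csv(out / "jem_specific.csv")
        self.jem_broad.to_csv(out / "jem_broad.csv")
        self.study.to_csv(out / "study.csv", index=False)
        self.assignments.to_csv(out / "assignments.csv", index=False)
        self.flow.to_json(out / "flow.json")
        self.bmi.to_csv(out / "bmi.csv", index=False)
        self.analysis.to_csv(out / "analysis.csv", index=False)
        self.trace.to_json(out / "selection.json")
        (out / "fit.json").write_text(json.dumps(self.fit.to_dict(), indent=2) + "\n")
        self.table2.to_csv(out / "table2.csv", index=False)
        self.table3.to_csv(out / "table3.csv", index=False)
        self.table4.to_csv(out / "table4.csv", index=False)
        (out / "provenance.json").write_text(json.dumps(self.provenance, indent=2) + "\n")


def covariates_from_study_config(
    study: StudyConfig, names: Sequence[str]
) -> list[Covariate]:
    """Model covariates (kind + level coding) for the named study variables."""
    by_name = {c.name: c for c in study.confounders}
    out = []
    for name in names:
        conf = by_name.get(name)
        if conf is None:
            raise DataError(f"unknown candidate covariate {name!r}")
        if isinstance(conf, CategoricalConfounder):
            out.append(Covariate(name=name, kind="categorical", levels=tuple(conf.levels)))
        else:
            out.append(Covariate(name=name, kind="continuous"))
    return out


def build_analysis_table(
    study: pd.DataFrame, assignments: pd.DataFrame, bmi: pd.DataFrame
) -> pd.DataFrame:
    """Merge study records, exposure assignments and BMI results."""
    merged = (
        study.assign(participant_id=study["participant_id"].astype(str))
        .merge(assignments, on="participant_id", validate="one_to_one")
        .merge(bmi, on="participant_id", validate="one_to_one")
    )
    return merged


def descriptive_table(
    study: pd.DataFrame, assignments: pd.DataFrame, bmi: pd.DataFrame
) -> pd.DataFrame:
    """Descriptive distributions amongst current workers.

    Weight-class percentages are computed over the sum of the three class
    counts (excluding missing/trimmed BMI); exposure-category percentages
    over all current workers including the unattainable (missing-p) group.
    Percentages are rounded to one decimal, half-up.
    """
    d = build_analysis_table(study, assignments, bmi)
    cur = d[d["employment_status"] == "current"]
    rows: list[dict] = []

    def add_continuous(variable, series):
        series = series.dropna()
        rows.append(
            {
                "variable": variable,
                "level": "mean_sd",
                "n": int(series.size),
                "pct": np.nan,
                "mean": float(series.mean()),
                "sd": float(series.std(ddof=1)),
            }
        )

    def add_categorical(variable, series, order):
        counts = [int((series == lvl).sum()) for lvl in order]
        pcts = percentages(counts, 1)
        for lvl, n, pct in zip(order, counts, pcts or [np.nan] * len(order)):
            rows.append(
                {"variable": variable, "level": lvl, "n": n, "pct": pct,
                 "mean": np.nan, "sd": np.nan}
            )

    add_continuous("bmi", cur.loc[~cur["trimmed"], "bmi"])
    add_categorical("weight_class", cur["weight_class"].dropna(), WEIGHT_CLASSES)
    # exposure categories over all current workers, unattainable included
    cat_order = list(EXPOSURE_CATEGORIES) + ["missing_p"]
    counts = [int((cur["category"] == lvl).sum()) for lvl in cat_order]
    pcts = percentages(counts, 1)
    for lvl, n, pct in zip(cat_order, counts, pcts or [np.nan] * len(cat_order)):
        label = "unattainable" if lvl == "missing_p" else lvl
        rows.append(
            {"variable": "p_shift_work", "level": label, "n": n, "pct": pct,
             "mean": np.nan, "sd": np.nan}
        )

    for col in ("age", "calories"):
        if col in cur.columns:
            add_continuous(col, cur[col])
    for col in (
        "education", "race", "marital", "parity",
        "smoking_pack_years", "alcohol", "physical_activity",
    ):
        if col in cur.columns:
            levels = list(pd.unique(study[col].dropna()))
            add_categorical(col, cur[col], levels)
    return pd.DataFrame(rows)


def top_occupations(
    assignments: pd.DataFrame,
    records: pd.DataFrame,
    k: int = 3,
) -> pd.DataFrame:
    """The ``k`` most frequent occupation codes within each exposure category.

    Percentages are within-category, over participants with a linked code;
    ties are broken by code order.
    """
    d = records.assign(participant_id=records["participant_id"].astype(str)).merge(
        assignments, on="participant_id", validate="one_to_one"
    )
    cur = d[(d["employment_status"] == "current") & d["occupation_code"].notna()]
    rows = []
    for cat in EXPOSURE_CATEGORIES:
        grp = cur[cur["category"] == cat]
        if grp.empty:
            continue
        counts = (
            grp.groupby("occupation_code").size().reset_index(name="n")
            .sort_values(["n", "occupation_code"], ascending=[False, True])
        )
        total = counts["n"].sum()
        for rank, row in enumerate(counts.head(k).itertuples(index=False), start=1):
            rows.append(
                {
                    "category": cat,
                    "rank": rank,
                    "occupation_code": row.occupation_code,
                    "n": int(row.n),
                    "pct": round_half_up(100.0 * row.n / total, 1),
                }
            )
    return pd.DataFrame(rows, columns=["category", "rank", "occupation_code", "n", "pct"])


def regression_table(analysis: pd.DataFrame, fit: FitResult) -> pd.DataFrame:
    """Per-category class counts (row %) and adjusted ORs/CIs/p-values.

    Row percentages use the sum of the three non-missing class counts as
    denominator and are rounded to integers, half-up; group n counts every
    participant assigned to the category (missing BMI included).
    """
    or_table = fit.or_table()
    rows = []
    for cat in ALL_CATEGORIES:
        grp = analysis[analysis["category"] == cat]
        counts = [int((grp["weight_class"] == c).sum()) for c in WEIGHT_CLASSES]
        pcts = percentages(counts, 0) or [np.nan] * 3
        row = {
            "category": cat,
            "n_group": int(len(grp)),
            "mean_bmi": round_half_up(grp["bmi"].mean(), 1) if grp["bmi"].notna().any() else np.nan,
        }
        for cls, n, pct in zip(WEIGHT_CLASSES, counts, pcts):
            row[f"n_{cls}"] = n
            row[f"pct_{cls}"] = pct
        term = term_name(fit.spec.exposure, cat)
        for contrast in fit.contrasts:
            hit = or_table[(or_table["contrast"] == contrast) & (or_table["term"] == term)]
            if cat == ALL_CATEGORIES[0]:
                row[f"{contrast}_or"], row[f"{contrast}_ci_low"] = 1.0, np.nan
                row[f"{contrast}_ci_high"], row[f"{contrast}_p"] = np.nan, np.nan
            elif hit.empty:
                row[f"{contrast}_or"] = np.nan
                row[f"{contrast}_ci_low"] = np.nan
                row[f"{contrast}_ci_high"] = np.nan
                row[f"{contrast}_p"] = np.nan
            else:
                r = hit.iloc[0]
                row[f"{contrast}_or"] = r["odds_ratio"]
                row[f"{contrast}_ci_low"] = r["ci_low"]
                row[f"{contrast}_ci_high"] = r["ci_high"]
                row[f"{contrast}_p"] = r["p_value"]
        row["note"] = (
            "removed (empty outcome cell)" if cat in fit.dropped_groups else ""
        )
        rows.append(row)
    return pd.DataFrame(rows)


def subgroup_analysis(
    analysis: pd.DataFrame,
    codes: Sequence[str],
    category: str = "high",
    covariates: Sequence[Covariate] = (),
    reference: str = "near_nil",
) -> FitResult:
    """Refit the model on an occupation-defined stratum versus the reference.

    ``codes`` selects occupation codes within ``category``; the stratum is
    compared with the full reference category. Strata with an empty outcome
    cell are refused with a diagnostic, mirroring removal of groups with
    low cell counts.
    """
    in_stratum = (analysis["category"] == category) & analysis[
        "occupation_code"
    ].isin(list(codes))
    in_ref = analysis["category"] == reference
    subset = analysis[in_stratum | in_ref].copy()
    subset["stratum"] = np.where(in_stratum[in_stratum | in_ref], "stratum", "reference")

    counts = pd.crosstab(subset["stratum"], subset["weight_class"])
    for grp in ("reference", "stratum"):
        for cls in WEIGHT_CLASSES:
            n = int(counts.loc[grp, cls]) if grp in counts.index and cls in counts.columns else 0
            if n == 0:
                raise DataError(
                    f"subgroup analysis refused: {grp!r} has no {cls!r} participants "
                    f"(stratum codes {sorted(set(codes))}, category {category!r})"
                )
    spec = ModelSpec(
        exposure="stratum",
        exposure_levels=("reference", "stratum"),
        covariates=tuple(covariates),
    )
    return fit_multinomial(spec, subset)


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Execute every stage in order; deterministic for a fixed seed."""
    survey_seed, study_seed = spawn_seeds(config.seed, 2)
    survey_cfg = config.survey.model_copy(update={"seed": survey_seed})
    study_cfg = config.study.model_copy(update={"seed": study_seed})

    stage = "simulate-survey"
    try:
        survey = generate_survey(survey_cfg)
        logger.info("stage %s: %d survey records", stage, len(survey))

        stage = "build-jem"
        jem_specific, jem_broad = build_jem_pair(survey)
        logger.info(
            "stage %s: %d specific cells, %d broad cells",
            stage, len(jem_specific), len(jem_broad),
        )

        stage = "simulate-study"
        study = generate_study(study_cfg, jem_specific, jem_broad)
        logger.info("stage %s: %d participants", stage, len(study))

        stage = "link"
        assignments = link_exposures(study, jem_specific, jem_broad, config.strategy)
        flow = flow_accounting(assignments, study)
        logger.info(
            "stage %s: %d current workers, %d linked 4-digit, %d linked 2-digit, %d missing",
            stage, flow.n_current_workers, flow.n_linked_four_digit,
            flow.n_linked_two_digit, flow.n_missing_p,
        )

        stage = "outcomes"
        bmi = assess_bmi(study, config.trim_fraction)
        analysis = build_analysis_table(study, assignments, bmi)
        logger.info(
            "stage %s: %d classified, %d trimmed", stage,
            int(analysis["weight_class"].notna().sum()), int(analysis["trimmed"].sum()),
        )

        stage = "select"
        base_spec = ModelSpec(exposure="category", exposure_levels=ALL_CATEGORIES)
        candidates = covariates_from_study_config(study_cfg, config.selection.candidates)
        trace = select_confounders(
            base_spec,
            candidates,
            analysis,
            threshold=config.selection.threshold,
            scale=config.selection.scale,
            contrast=config.selection.contrast,
        )
        logger.info("stage %s: admitted %s", stage, list(trace.final_covariates))

        stage = "fit"
        final_covs = [c for c in candidates if c.name in trace.final_covariates]
        fit = fit_multinomial(base_spec.with_covariates(final_covs), analysis)
        logger.info("stage %s: converged=%s n=%d", stage, fit.converged, fit.n_used)

        stage = "report"
        table2 = descriptive_table(study, assignments, bmi)
        table3 = top_occupations(assignments, study)
        table4 = regression_table(analysis, fit)
    except Exception as exc:  # annotate which stage died; original is chained
        raise PipelineStageError(stage, exc) from exc

    from . import __version__

    provenance = {
        "config": json.loads(config.model_dump_json()),
        "seed": config.seed,
        "derived_seeds": {"survey": survey_seed, "study": study_seed},
        "versions": {
            "shiftjem": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    return ReportBundle(
        survey=survey,
        jem_specific=jem_specific,
        jem_broad=jem_broad,
        study=study,
        assignments=assignments,
        flow=flow,
        bmi=bmi,
        analysis=analysis,
        trace=trace,
        fit=fit,
        table2=table2,
        table3=table3,
        table4=table4,
        provenance=provenance,
    )
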