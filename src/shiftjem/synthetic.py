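"""Synthetic labour-survey and study-cohort generators with known truth.

The real inputs — a confidential national labour survey used to tabulate
shift-work probabilities, and two questionnaire studies of Canadian women —
are not publicly available, so every downstream stage is exercised on
synthetic data whose generating parameters are known exactly.

Two generators are provided:

* :func:`generate_survey` emulates the labour-survey extract (default
  N = 12,500 female respondents). Each occupation code has a configured
  shift-work propensity; respondents drawn "shift" receive an evening,
  night or rotating schedule uniformly at random. Small-weight codes fall
  below the disclosure thresholds and exercise suppression naturally.

* :func:`generate_study` emulates a cross-sectional study sample. Each
  participant draws a true exposure category; an occupation code consistent
  with that category is picked from the supplied JEM pair (sometimes via a
  suppressed specific code or a truncated 2-character code, to exercise the
  fallback linkage); the weight class is drawn from a baseline-category
  multinomial logit with configurable exposure log-odds and covariate
  effects; height and weight are back-solved so the emitted anthropometry
  reproduces the drawn class exactly.

:func:`generate_true_exposure_variant` additionally draws an *individual*
shift-work indicator Bernoulli(p of the linked code) and drives the outcome
from that indicator instead of the category — the setting in which
analysing by probability category attenuates the individual-level effect
toward the null (group-level exposure misclassification).

Default parameter values mirror the published study conditions: the
category mix and regression-sample sizes of the population-based arm
(1,611 current workers + 1,766 non-workers), its reported covariate
marginals, intercepts from the near-nil group's class counts, and
per-category four-digit linkage shares (100% in the high category, 83%
near nil).
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Annotated, Literal, Union

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

from .errors import DataError
from .jem import JEMTable, broad_code
from .linkage import ALL_CATEGORIES, EXPOSURE_CATEGORIES, categorize

CONTRASTS = ("overweight", "obese")
SHIFT_SCHEDULE_CHOICES = ("regular_evening", "regular_night", "rotating")
NONSHIFT_SCHEDULE_CHOICES = ("regular_day", "other")


# ---------------------------------------------------------------------------
# survey side
# ---------------------------------------------------------------------------


class CodeProfile(BaseModel):
    """One occupation code's share of the workforce and shift propensity."""

    code: str = Field(min_length=4, max_length=4)
    weight: float = Field(gt=0)
    shift_propensity: float = Field(ge=0.0, le=1.0)


class SurveyConfig(BaseModel):
    """Parameters of the synthetic labour-survey extract."""

    n_respondents: int = Field(default=12500, ge=1)
    code_profiles: list[CodeProfile] = Field(default_factory=lambda: default_code_profiles())
    sex: str = "female"
    hours_mean: float = Field(default=37.5, gt=0)  # h/week
    hours_sd: float = Field(default=9.0, ge=0)
    other_schedule_share: float = Field(default=0.1, ge=0.0, le=1.0)
    seed: int = 0

    @field_validator("code_profiles")
    @classmethod
    def _nonempty(cls, v):
        if not v:
            raise ValueError("code_profiles must not be empty")
        if len({p.code for p in v}) != len(v):
            raise ValueError("code_profiles contains duplicate codes")
        return v


def default_code_profiles() -> list[CodeProfile]:
    """A NOC-S-flavoured occupation mix spanning all exposure categories.

    Weights are relative workforce shares. Each broad group purposely mixes
    large retained codes with tiny codes that trigger suppression, so the
    specific table always contains suppressed cells whose broad parent is
    releasable (the situation the hierarchical fallback exists for).
    """
    entries = [
        # near-nil broad groups (office/clerical, managers)
        ("B111", 6.0, 0.005),  # bookkeepers
        ("B112", 0.08, 0.010),  # tiny cell -> suppressed (<25 workers)
        ("B113", 3.0, 0.008),
        ("B211", 4.0, 0.004),  # accountants
        ("A311", 2.0, 0.010),  # managers
        # low
        ("E111", 5.0, 0.025),  # elementary teachers
        ("E112", 4.0, 0.030),  # secondary teachers
        ("E113", 0.3, 0.030),  # ~60 workers, <5 shift -> suppressed
        ("B511", 7.0, 0.040),  # general office clerks
        ("B513", 6.0, 0.060),  # secretaries
        ("B514", 0.06, 0.090),  # tiny cell -> suppressed
        # medium
        ("G211", 6.0, 0.150),  # retail salespersons
        ("G212", 3.0, 0.220),  # sales clerks
        ("G213", 0.08, 0.300),  # tiny cell -> suppressed
        ("D211", 2.0, 0.140),  # health technologists
        ("D212", 2.0, 0.280),  # lab technicians
        ("F011", 1.0, 0.250),  # arts and culture
        # high
        ("D112", 5.0, 0.620),  # registered nurses
        ("D111", 0.5, 0.550),  # head nurses (small but releasable)
        ("D113", 0.07, 0.500),  # tiny cell -> suppressed
        ("G961", 1.5, 0.550),  # cleaners and janitors
        ("G962", 0.07, 0.550),  # tiny cell -> suppressed
    ]
    return [CodeProfile(code=c, weight=w, shift_propensity=p) for c, w, p in entries]


def generate_survey(config: SurveyConfig) -> pd.DataFrame:
    """Draw one synthetic labour-survey extract; deterministic per seed."""
    rng = np.random.default_rng(config.seed)
    n = config.n_respondents
    profiles = config.code_profiles
    weights = np.array([p.weight for p in profiles])
    weights = weights / weights.sum()
    idx = rng.choice(len(profiles), size=n, p=weights)
    codes = np.array([p.code for p in profiles], dtype=object)[idx]
    propensity = np.array([p.shift_propensity for p in profiles])[idx]

    is_shift = rng.random(n) < propensity
    shift_sched = rng.choice(SHIFT_SCHEDULE_CHOICES, size=n)
    o = config.other_schedule_share
    nonshift_sched = rng.choice(NONSHIFT_SCHEDULE_CHOICES, size=n, p=[1.0 - o, o])
    schedule = np.where(is_shift, shift_sched, nonshift_sched)

    hours = np.clip(rng.normal(config.hours_mean, config.hours_sd, size=n), 0.0, None)

    return pd.DataFrame(
        {
            "person_id": [f"S{i:06d}" for i in range(n)],
            "sex": config.sex,
            "occupation_code": codes,
            "weekly_hours": hours,
            "schedule": schedule,
        }
    )


# ---------------------------------------------------------------------------
# study side
# ---------------------------------------------------------------------------


class ContinuousConfounder(BaseModel):
    kind: Literal["continuous"] = "continuous"
    name: str
    mean: float
    sd: float = Field(ge=0)
    lower: float | None = None
    upper: float | None = None
    #: per-contrast log-odds per unit above the mean
    effects: dict[str, float] = Field(default_factory=dict)
    #: optional per-exposure-category mean shift (creates confounding)
    category_mean_shift: dict[str, float] = Field(default_factory=dict)


class CategoricalConfounder(BaseModel):
    kind: Literal["categorical"] = "categorical"
    name: str
    levels: list[str] = Field(min_length=2)
    probs: list[float]
    #: per-contrast log-odds for levels[1:] (levels[0] is the reference)
    effects: dict[str, list[float]] = Field(default_factory=dict)
    #: optional per-exposure-category level probabilities (creates confounding)
    category_probs: dict[str, list[float]] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _check(self):
        if len(self.probs) != len(self.levels):
            raise ValueError(f"{self.name}: probs must match levels")
        if abs(sum(self.probs) - 1.0) > 1e-9:
            raise ValueError(f"{self.name}: probs must sum to 1")
        for contrast, eff in self.effects.items():
            if len(eff) != len(self.levels) - 1:
                raise ValueError(
                    f"{self.name}: effects[{contrast}] must have {len(self.levels) - 1} entries"
                )
        for cat, probs in self.category_probs.items():
            if len(probs) != len(self.levels) or abs(sum(probs) - 1.0) > 1e-9:
                raise ValueError(f"{self.name}: category_probs[{cat}] invalid")
        return self


Confounder = Annotated[
    Union[ContinuousConfounder, CategoricalConfounder], Field(discriminator="kind")
]


class AnthropometrySpec(BaseModel):
    """Height distribution and BMI back-solving intervals."""

    height_mean: float = Field(default=1.63, gt=0)  # m
    height_sd: float = Field(default=0.07, ge=0)
    bmi_ranges: dict[str, tuple[float, float]] = Field(
        default_factory=lambda: {
            "normal_under": (17.0, 25.0),
            "overweight": (25.0, 30.0),
            "obese": (30.0, 45.0),  # capped at 45 kg/m^2
        }
    )
    missing_rate: float = Field(default=0.005, ge=0.0, le=1.0)


def default_confounders() -> list[Confounder]:
    """Covariate distributions mirroring the population-based sample.

    Age and education carry modest outcome effects; everything else is
    prognostically null by default. No covariate is associated with the
    exposure category unless a config overrides its tilt fields, so the
    default data contain no confounding.
    """
    return [
        ContinuousConfounder(
            name="age", mean=46.4, sd=8.5, lower=21, upper=73,
            effects={"overweight": 0.005, "obese": 0.010},
        ),
        CategoricalConfounder(
            name="education",
            levels=["secondary_or_less", "post_secondary", "graduate"],
            probs=[0.326, 0.571, 0.103],
            effects={"overweight": [-0.05, -0.10], "obese": [-0.15, -0.30]},
        ),
        CategoricalConfounder(
            name="race", levels=["white", "non_white"], probs=[0.904, 0.096]
        ),
        CategoricalConfounder(
            name="marital",
            levels=["married_common_law", "never_married", "divorced_separated", "widowed"],
            probs=[0.771, 0.063, 0.137, 0.029],
        ),
        CategoricalConfounder(
            name="parity", levels=["0", "1", "2_3", "4_plus"],
            probs=[0.147, 0.560, 0.213, 0.080],
        ),
        CategoricalConfounder(
            name="smoking_pack_years", levels=["never", "lt15", "ge15"],
            probs=[0.494, 0.308, 0.198],
        ),
        ContinuousConfounder(name="calories", mean=1767.1, sd=646.2, lower=500),
        CategoricalConfounder(
            name="alcohol", levels=["never", "1_6", "7_plus"],
            probs=[0.464, 0.343, 0.193],
        ),
        CategoricalConfounder(
            name="physical_activity", levels=["lt1", "ge1"], probs=[0.283, 0.717]
        ),
    ]


def _default_category_mix() -> dict[str, float]:
    # Group sizes of the population-based regression sample.
    counts = {
        "near_nil": 182, "low": 660, "medium": 434, "high": 112,
        "missing_p": 223, "not_working": 1766,
    }
    total = sum(counts.values())
    return {k: v / total for k, v in counts.items()}


def _default_true_log_odds() -> dict[str, dict[str, float]]:
    # ln of the published adjusted odds ratios, population-based arm.
    return {
        "overweight": {
            "low": math.log(0.94), "medium": math.log(0.87), "high": math.log(1.15),
            "missing_p": math.log(0.75), "not_working": math.log(0.90),
        },
        "obese": {
            "low": math.log(1.16), "medium": math.log(1.27), "high": math.log(1.88),
            "missing_p": math.log(0.71), "not_working": math.log(1.30),
        },
    }


class StudyConfig(BaseModel):
    """Parameters of the synthetic study-cohort generator."""

    n_participants: int = Field(default=3377, ge=1)
    category_mix: dict[str, float] = Field(default_factory=_default_category_mix)
    #: per-contrast log-odds of each non-reference exposure category
    true_log_odds: dict[str, dict[str, float]] = Field(
        default_factory=_default_true_log_odds
    )
    #: per-contrast intercepts (near-nil reference group)
    baseline_intercepts: dict[str, float] = Field(
        default_factory=lambda: {
            "overweight": math.log(60 / 90), "obese": math.log(31 / 90),
        }
    )
    #: individual-level shift-work log-odds, used by the
    #: true-exposure variant only
    true_individual_log_odds: dict[str, float] = Field(
        default_factory=lambda: {"overweight": math.log(1.5), "obese": math.log(3.0)}
    )
    confounders: list[Confounder] = Field(default_factory=default_confounders)
    anthropometry: AnthropometrySpec = Field(default_factory=AnthropometrySpec)
    #: share of each exposure category linked at the specific 4-digit level
    four_digit_fraction: dict[str, float] = Field(
        default_factory=lambda: {"near_nil": 0.83, "low": 0.55, "medium": 0.55, "high": 1.0}
    )
    #: among broad-linked participants, share reporting a vague occupation
    #: (truncated 2-character code) rather than a suppressed 4-digit code
    truncated_share_of_broad: float = Field(default=0.5, ge=0.0, le=1.0)
    former_share_not_working: float = Field(default=0.8, ge=0.0, le=1.0)
    former_code_missing_rate: float = Field(default=0.27, ge=0.0, le=1.0)
    age_range: tuple[float, float] = (21.0, 73.0)
    seed: int = 0

    @model_validator(mode="after")
    def _check_mix(self):
        extra = set(self.category_mix) - set(ALL_CATEGORIES)
        if extra:
            raise ValueError(f"category_mix has unknown categories {sorted(extra)}")
        if any(not 0.0 <= v <= 1.0 for v in self.category_mix.values()):
            raise ValueError("category_mix probabilities must lie in [0, 1]")
        if abs(sum(self.category_mix.values()) - 1.0) > 1e-9:
            raise ValueError(
                f"category_mix must sum to 1 (got {sum(self.category_mix.values())!r})"
            )
        for contrast in CONTRASTS:
            if contrast not in self.baseline_intercepts:
                raise ValueError(f"baseline_intercepts missing contrast {contrast!r}")
        names = [c.name for c in self.confounders]
        if len(set(names)) != len(names):
            raise ValueError("confounders contain duplicate names")
        return self


def category_code_pools(
    jem_specific: JEMTable, jem_broad: JEMTable
) -> dict[str, dict[str, list]]:
    """Occupation codes available to each exposure category, by source.

    ``four_digit``: specific codes retained at the 4-digit level;
    ``fallback``: specific codes suppressed (or absent) at the 4-digit level
    whose broad parent is retained with a probability in the category;
    ``truncated``: retained 2-character broad codes themselves.
    """
    pools: dict[str, dict[str, list]] = {
        c: {"four_digit": [], "fallback": [], "truncated": []}
        for c in EXPOSURE_CATEGORIES
    }
    for code in sorted(jem_specific.cells):
        p = jem_specific.lookup(code)
        if p is not None:
            pools[categorize(p)]["four_digit"].append((code, p))
        else:
            bp = jem_broad.lookup(broad_code(code))
            if bp is not None:
                pools[categorize(bp)]["fallback"].append((code, bp))
    for code in sorted(jem_broad.cells):
        p = jem_broad.lookup(code)
        if p is not None:
            pools[categorize(p)]["truncated"].append((code, p))
    return pools


def _draw_codes(rng, cats, config, pools):
    """Occupation code + linked-p per participant, honouring source shares."""
    n = len(cats)
    codes = np.full(n, None, dtype=object)
    p_linked = np.full(n, np.nan)

    all_four_digit = sorted(
        {cp for c in EXPOSURE_CATEGORIES for cp in pools[c]["four_digit"]}
    )

    for cat in EXPOSURE_CATEGORIES:
        members = np.flatnonzero(cats == cat)
        if members.size == 0:
            continue
        pool = pools[cat]
        if not any(pool.values()) or not (
            pool["four_digit"] or pool["fallback"] or pool["truncated"]
        ):
            raise DataError(f"JEM pair provides no codes for category {cat!r}")
        frac4 = config.four_digit_fraction.get(cat, 1.0)
        u = rng.random(members.size)
        v = rng.random(members.size)
        for j, i in enumerate(members):
            if u[j] < frac4 and pool["four_digit"]:
                src = pool["four_digit"]
            elif v[j] < config.truncated_share_of_broad:
                src = pool["truncated"] or pool["fallback"] or pool["four_digit"]
            else:
                src = pool["fallback"] or pool["truncated"] or pool["four_digit"]
            code, p = src[rng.integers(len(src))]
            codes[i], p_linked[i] = code, p

    # not-working: a share report their former occupation
    members = np.flatnonzero(cats == "not_working")
    if members.size and all_four_digit:
        has_code = rng.random(members.size) >= config.former_code_missing_rate
        picks = rng.integers(len(all_four_digit), size=members.size)
        for j, i in enumerate(members):
            if has_code[j]:
                codes[i] = all_four_digit[picks[j]][0]
    return codes, p_linked


def _draw_confounders(rng, cats, config):
    """Draw covariate columns; per-category tilts create confounding."""
    n = len(cats)
    values: dict[str, np.ndarray] = {}
    for conf in config.confounders:
        if conf.kind == "continuous":
            shift = np.zeros(n)
            for cat, delta in conf.category_mean_shift.items():
                shift[cats == cat] = delta
            x = conf.mean + shift + rng.normal(0.0, conf.sd, size=n)
            if conf.lower is not None or conf.upper is not None:
                x = np.clip(x, conf.lower, conf.upper)
            values[conf.name] = x
        else:
            out = np.empty(n, dtype=object)
            for cat in ALL_CATEGORIES:
                members = np.flatnonzero(cats == cat)
                if members.size == 0:
                    continue
                probs = conf.category_probs.get(cat, conf.probs)
                out[members] = rng.choice(conf.levels, size=members.size, p=probs)
            values[conf.name] = out
    return values


def _confounder_lp(config, values, contrast):
    """Covariate contribution to the linear predictor of one contrast."""
    n = len(next(iter(values.values()))) if values else 0
    lp = np.zeros(n)
    for conf in config.confounders:
        x = values[conf.name]
        if conf.kind == "continuous":
            eff = conf.effects.get(contrast, 0.0)
            if eff:
                lp += eff * (np.asarray(x, dtype=float) - conf.mean)
        else:
            effs = conf.effects.get(contrast)
            if effs:
                for lvl, eff in zip(conf.levels[1:], effs):
                    lp += eff * (x == lvl)
    return lp


def _draw_classes(rng, lp_over, lp_obese):
    expo = np.exp(lp_over)
    expb = np.exp(lp_obese)
    denom = 1.0 + expo + expb
    probs = np.column_stack([1.0 / denom, expo / denom, expb / denom])
    u = rng.random(len(lp_over))
    cum = np.cumsum(probs, axis=1)
    draws = (u[:, None] > cum).sum(axis=1)
    classes = np.array(["normal_under", "overweight", "obese"], dtype=object)
    return classes[draws]


def _back_solve_anthropometry(rng, drawn_class, spec: AnthropometrySpec):
    n = len(drawn_class)
    height = rng.normal(spec.height_mean, spec.height_sd, size=n)
    height = np.clip(height, 1.30, 2.10)
    bmi = np.empty(n)
    for cls, (lo, hi) in spec.bmi_ranges.items():
        members = drawn_class == cls
        bmi[members] = rng.uniform(lo, hi, size=int(members.sum()))
    weight = bmi * height**2
    if spec.missing_rate > 0:
        missing = rng.random(n) < spec.missing_rate
        height[missing] = np.nan
        weight[missing] = np.nan
    return height, weight


def _generate_study_common(config, jem_specific, jem_broad, individual_exposure):
    rng = np.random.default_rng(config.seed)
    n = config.n_participants
    mix = [config.category_mix.get(c, 0.0) for c in ALL_CATEGORIES]
    cats = rng.choice(np.array(ALL_CATEGORIES, dtype=object), size=n, p=mix)

    pools = category_code_pools(jem_specific, jem_broad)
    codes, p_linked = _draw_codes(rng, cats, config, pools)

    employment = np.where(cats == "not_working", "former", "current").astype(object)
    former = np.flatnonzero(cats == "not_working")
    never = former[rng.random(former.size) >= config.former_share_not_working]
    employment[never] = "never"

    values = _draw_confounders(rng, cats, config)

    true_shift = None
    lps = {}
    for contrast in CONTRASTS:
        lp = np.full(n, config.baseline_intercepts[contrast])
        lp += _confounder_lp(config, values, contrast)
        lps[contrast] = lp
    if individual_exposure:
        p_ind = np.where(np.isfinite(p_linked), p_linked, 0.0)
        true_shift = rng.random(n) < p_ind
        for contrast in CONTRASTS:
            lps[contrast] = (
                lps[contrast]
                + config.true_individual_log_odds.get(contrast, 0.0) * true_shift
            )
    else:
        for contrast in CONTRASTS:
            effects = config.true_log_odds.get(contrast, {})
            add = np.zeros(n)
            for cat, coef in effects.items():
                add[cats == cat] = coef
            lps[contrast] = lps[contrast] + add

    drawn_class = _draw_classes(rng, lps["overweight"], lps["obese"])
    height, weight = _back_solve_anthropometry(rng, drawn_class, config.anthropometry)

    frame = {
        "participant_id": [f"P{i:06d}" for i in range(n)],
        "employment_status": employment,
        "occupation_code": codes,
        "height": height,
        "weight": weight,
    }
    frame.update(values)
    frame["true_exposure_category"] = cats
    frame["true_p_shift"] = p_linked
    frame["drawn_class"] = drawn_class
    if true_shift is not None:
        frame["true_shift"] = true_shift.astype(int)
    return pd.DataFrame(frame)


def generate_study(
    config: StudyConfig, jem_specific: JEMTable, jem_broad: JEMTable
) -> pd.DataFrame:
    """Draw one synthetic study cohort; deterministic per seed.

    The outcome is driven by the participant's exposure *category* through
    ``config.true_log_odds``. Bookkeeping columns (``true_exposure_category``,
    ``true_p_shift``, ``drawn_class``) carry the generator's ground truth
    and are never used by the analysis stages.
    """
    return _generate_study_common(config, jem_specific, jem_broad, False)


def generate_true_exposure_variant(
    config: StudyConfig, jem_specific: JEMTable, jem_broad: JEMTable
) -> pd.DataFrame:
    """Cohort whose outcome depends on *individual* shift-work status.

    Each participant draws a Bernoulli(p) true shift-work indicator from
    their linked code's probability; the outcome model uses
    ``config.true_individual_log_odds`` times that indicator (categories
    contribute nothing). Analysing these data by probability category
    measures the attenuation caused by group-level exposure assignment.
    """
    return _generate_study_common(config, jem_specific, jem_broad, True)


def write_provenance(path: str | Path, config: BaseModel, seed: int | None = None) -> None:
    """Record the generating configuration and library versions as JSON."""
    from . import __version__

    payload = {
        "config": json.loads(config.model_dump_json()),
        "seed": seed if seed is not None else getattr(config, "seed", None),
        "versions": {
            "shiftjem": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
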