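"""Forward change-in-estimate confounder selection.

A candidate covariate is a confounder when adding it to the current model
moves the parameter of interest — here the exposure odds ratios for the
low, medium and high probability-of-shift-work categories, on both outcome
contrasts — by at least a threshold percentage (10.0% by default). Each
round refits the model once per remaining candidate, computes the maximum
relative change across the monitored terms, and admits the candidate with
the largest change when it meets the threshold; selection stops when no
candidate qualifies. Ties are broken by candidate-list order.

The change is measured on the odds-ratio scale by default
(|OR_with - OR_without| / OR_without x 100), the usual epidemiologic
convention; a log-odds-scale option is available.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from .errors import SingularDesignError
from .model import Covariate, FitResult, ModelSpec, fit_multinomial, term_name

logger = logging.getLogger(__name__)

#: Exposure categories whose odds ratios constitute the parameter of
#: interest. The missing-probability and not-working comparison dummies are
#: deliberately excluded: they are nuisance contrasts, not the estimate the
#: analysis protects.
MONITORED_LEVELS = ("low", "medium", "high")

DEFAULT_THRESHOLD = 10.0


@dataclass(frozen=True)
class SelectionStep:
    candidate: str
    max_relative_change: float  # percent
    admitted: bool


@dataclass(frozen=True)
class SelectionTrace:
    """Full record of a forward-selection run."""

    steps: tuple[SelectionStep, ...]
    final_covariates: tuple[str, ...]
    base_estimates: pd.DataFrame  # exposure OR table before selection
    final_estimates: pd.DataFrame  # exposure OR table of the final model
    evaluations: tuple[dict, ...] = field(default_factory=tuple)  # per-round changes

    def to_dict(self) -> dict:
        return {
            "steps": [
                {
                    "candidate": s.candidate,
                    "max_relative_change": s.max_relative_change,
                    "admitted": s.admitted,
                }
                for s in self.steps
            ],
            "final_covariates": list(self.final_covariates),
            "base_estimates": self.base_estimates.to_dict("records"),
            "final_estimates": self.final_estimates.to_dict("records"),
            "evaluations": [dict(e) for e in self.evaluations],
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def _exposure_estimates(fit: FitResult, exposure: str) -> pd.DataFrame:
    table = fit.or_table()
    monitored = [term_name(exposure, lvl) for lvl in MONITORED_LEVELS]
    return table[table["term"].isin(monitored)].reset_index(drop=True)


def _max_change(
    fit_with: FitResult,
    fit_without: FitResult,
    exposure: str,
    scale: str,
    contrast: str | None,
) -> float:
    """Maximum percent change of the monitored exposure terms."""
    contrasts = fit_without.contrasts if contrast is None else (contrast,)
    change = 0.0
    for c in contrasts:
        for lvl in MONITORED_LEVELS:
            term = term_name(exposure, lvl)
            if term not in fit_without.params.index or term not in fit_with.params.index:
                continue
            if scale == "or":
                base = fit_without.odds_ratio(c, term)
                new = fit_with.odds_ratio(c, term)
                rel = abs(new - base) / base * 100.0
            else:  # log-odds scale
                base = fit_without.coef(c, term)
                new = fit_with.coef(c, term)
                denom = max(abs(base), 1e-12)
                rel = abs(new - base) / denom * 100.0
            change = max(change, rel)
    return change


def select_confounders(
    base_spec: ModelSpec,
    candidates: Sequence[Covariate],
    data: pd.DataFrame,
    threshold: float = DEFAULT_THRESHOLD,
    scale: str = "or",
    contrast: str | None = None,
) -> SelectionTrace:
    """Forward selection by the change-in-estimate criterion.

    ``base_spec`` should contain the exposure only; ``candidates`` are
    considered in list order (which also breaks ties). ``scale`` is
    ``"or"`` or ``"log"``; ``contrast`` restricts monitoring to one outcome
    contrast (default: both). ``threshold`` is in percent; ``math.inf``
    reproduces the unadjusted model, 0 admits every usable candidate.
    """
    if scale not in ("or", "log"):
        raise ValueError(f"scale must be 'or' or 'log', got {scale!r}")
    if base_spec.covariates:
        raise ValueError("base_spec must be exposure-only (no covariates)")

    base_fit = fit_multinomial(base_spec, data)
    current_fit = base_fit
    admitted: list[Covariate] = []
    steps: list[SelectionStep] = []
    evaluations: list[dict] = []
    remaining = list(candidates)

    while remaining:
        changes: dict[str, float] = {}
        trial_fits: dict[str, FitResult] = {}
        for cand in remaining:
            trial_spec = base_spec.with_covariates(admitted + [cand])
            try:
                trial = fit_multinomial(trial_spec, data)
            except SingularDesignError as exc:
                logger.warning("candidate %s skipped (rank deficiency): %s", cand.name, exc)
                continue
            if not trial.converged:
                logger.warning("candidate %s skipped this round (no convergence)", cand.name)
                continue
            changes[cand.name] = _max_change(trial, current_fit, base_spec.exposure, scale, contrast)
            trial_fits[cand.name] = trial
        if not changes:
            break
        evaluations.append(dict(changes))

        # best candidate; ties resolved by candidate-list order (strict >)
        best_name, best_change = None, -math.inf
        for cand in remaining:
            if cand.name in changes and changes[cand.name] > best_change:
                best_name, best_change = cand.name, changes[cand.name]

        if best_change >= threshold:
            steps.append(SelectionStep(best_name, best_change, True))
            admitted.append(next(c for c in remaining if c.name == best_name))
            remaining = [c for c in remaining if c.name != best_name]
            current_fit = trial_fits[best_name]
        else:
            steps.append(SelectionStep(best_name, best_change, False))
            break

    return SelectionTrace(
        steps=tuple(steps),
        final_covariates=tuple(c.name for c in admitted),
        base_estimates=_exposure_estimates(base_fit, base_spec.exposure),
        final_estimates=_exposure_estimates(current_fit, base_spec.exposure),
        evaluations=tuple(evaluations),
    )
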