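"""Body-mass-index outcomes: trimming, computation, WHO classification.

BMI = weight (kg) / height (m)^2. Self-reported anthropometry is screened by
removing the outermost 0.2% of weight and of height responses (0.1% per
tail, applied to each variable separately); a participant trimmed on either
variable is excluded from classification. Weight classes follow the WHO
cut-offs: normal/underweight below 25, overweight 25 to <30, obese 30+.
"""

from __future__ import annotations

import math
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import DomainError

#: Total fraction of responses removed per variable (both tails combined).
DEFAULT_TRIM_FRACTION = 0.002

#: WHO class boundaries (kg/m^2); lower bound inclusive.
BMI_OVERWEIGHT = 25.0
BMI_OBESE = 30.0

WEIGHT_CLASSES = ("normal_under", "overweight", "obese")


def compute_bmi(weight: float, height: float) -> float:
    """BMI in kg/m^2 from weight in kg and height in m."""
    w = np.asarray(weight, dtype=float)
    h = np.asarray(height, dtype=float)
    if np.any(w <= 0) or np.any(h <= 0):
        raise DomainError("weight and height must be strictly positive")
    out = w / h**2
    return float(out) if out.ndim == 0 else out


def classify_weight(bmi: float) -> str:
    """WHO weight class of a single BMI value."""
    if not math.isfinite(bmi) or bmi <= 0:
        raise DomainError(f"bmi must be positive and finite, got {bmi!r}")
    if bmi < BMI_OVERWEIGHT:
        return "normal_under"
    if bmi < BMI_OBESE:
        return "overweight"
    return "obese"


def classify_weight_series(bmi: pd.Series) -> pd.Series:
    """Vectorised :func:`classify_weight`; NaN maps to missing (None)."""
    valid = bmi.notna()
    if (bmi[valid] <= 0).any():
        raise DomainError("bmi values must be strictly positive")
    out = pd.Series(np.full(len(bmi), None, dtype=object), index=bmi.index)
    out[valid & (bmi < BMI_OVERWEIGHT)] = "normal_under"
    out[valid & (bmi >= BMI_OVERWEIGHT) & (bmi < BMI_OBESE)] = "overweight"
    out[valid & (bmi >= BMI_OBESE)] = "obese"
    return out


def trim_outliers(values, fraction: float = DEFAULT_TRIM_FRACTION) -> set:
    """Ids whose measurement falls in the outermost ``fraction`` of responses.

    ``values`` is a Series indexed by participant id, or an iterable of
    ``(id, value)`` pairs. The trim is symmetric: ``fraction/2`` per tail.
    The cut uses order statistics: with k = floor(n * fraction / 2), values
    strictly below the (k+1)-th smallest or strictly above the (k+1)-th
    largest are flagged, so ties at the cut survive and at most
    ceil(n * fraction) ids are flagged. Missing values are ignored.
    """
    if not 0.0 <= fraction < 0.5:
        raise DomainError(f"fraction must lie in [0, 0.5), got {fraction!r}")
    if not isinstance(values, pd.Series):
        values = pd.Series(dict(values))
    values = values.dropna()
    n = len(values)
    if n == 0 or fraction == 0.0:
        return set()
    k = int(math.floor(n * fraction / 2.0))
    srt = np.sort(values.to_numpy(dtype=float))
    lo, hi = srt[k], srt[n - 1 - k]
    flagged = values.index[(values < lo) | (values > hi)]
    return set(flagged)


def assess_bmi(
    records: pd.DataFrame, fraction: float = DEFAULT_TRIM_FRACTION
) -> pd.DataFrame:
    """Per-participant BMI results for a study table.

    ``records`` needs ``participant_id``, ``height`` (m) and ``weight`` (kg);
    either may be missing. Returns columns ``participant_id``, ``bmi``
    (NaN when anthropometry is missing), ``weight_class`` (None when the
    participant is trimmed or BMI is unavailable) and ``trimmed``.
    """
    pid = records["participant_id"].astype(str)
    weight = pd.Series(records["weight"].to_numpy(dtype=float), index=pid)
    height = pd.Series(records["height"].to_numpy(dtype=float), index=pid)
    if (weight.dropna() <= 0).any() or (height.dropna() <= 0).any():
        raise DomainError("weight and height must be strictly positive")

    trimmed_ids = trim_outliers(weight, fraction) | trim_outliers(height, fraction)
    bmi = weight / height**2
    trimmed = pid.isin(trimmed_ids).to_numpy()

    out = pd.DataFrame(
        {
            "participant_id": pid.to_numpy(),
            "bmi": bmi.to_numpy(),
            "trimmed": trimmed,
        }
    )
    weight_class = classify_weight_series(out["bmi"])
    weight_class[out["trimmed"]] = None
    out["weight_class"] = weight_class
    return out[["participant_id", "bmi", "weight_class", "trimmed"]]
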