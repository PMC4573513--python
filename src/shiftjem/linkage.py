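"""Linking study participants to probability-of-shift-work values.

Each currently working participant is looked up in the specific (4-digit)
JEM first; when that cell is suppressed or absent, the ``fallback`` strategy
tries the broad (2-digit) table before declaring the probability missing.
The ``four_digit_only`` strategy (a sensitivity analysis) accepts specific
hits only. Non-current workers are assigned the ``not_working`` comparison
category regardless of any reported (former) occupation.

The linked probability is then banded into four exposure categories:

=========  =====================
near_nil   p < 1.5%
low        1.5% <= p < 10%
medium     10% <= p < 45%
high       p >= 45%
=========  =====================
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataIntegrityError, DomainError, LinkageError
from .jem import JEMTable, broad_code

#: Exposure categories in increasing-probability order, then the two
#: extra comparison categories used in the regression.
EXPOSURE_CATEGORIES = ("near_nil", "low", "medium", "high")
EXTRA_CATEGORIES = ("missing_p", "not_working")
ALL_CATEGORIES = EXPOSURE_CATEGORIES + EXTRA_CATEGORIES

#: Category cut-points on the proportion scale; lower bound inclusive.
CUT_LOW = 0.015
CUT_MEDIUM = 0.10
CUT_HIGH = 0.45

STRATEGIES = ("fallback", "four_digit_only")


def categorize(p_value: float) -> str:
    """Band a probability-of-shift-work value into an exposure category."""
    if not math.isfinite(p_value) or not 0.0 <= p_value <= 1.0:
        raise DomainError(f"p_value must lie in [0, 1], got {p_value!r}")
    if p_value < CUT_LOW:
        return "near_nil"
    if p_value < CUT_MEDIUM:
        return "low"
    if p_value < CUT_HIGH:
        return "medium"
    return "high"


@dataclass(frozen=True)
class ExposureAssignment:
    """Outcome of linking one participant to the JEM."""

    participant_id: str
    p_value: float | None
    source_level: str  # "four_digit" | "two_digit" | "none"
    category: str


def _clean_code(code) -> str | None:
    if code is None:
        return None
    if isinstance(code, float) and math.isnan(code):
        return None
    code = str(code).strip()
    return code or None


def link_probability(
    record,
    jem_specific: JEMTable,
    jem_broad: JEMTable,
    strategy: str = "fallback",
) -> ExposureAssignment:
    """Assign one participant a probability value and exposure category.

    ``record`` needs ``participant_id``, ``employment_status`` and
    ``occupation_code`` fields (a mapping, Series or namedtuple). The JEM
    tables must be built for the participant's sex.
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"strategy must be one of {STRATEGIES}, got {strategy!r}")
    if jem_specific.sex != jem_broad.sex:
        raise LinkageError(
            f"JEM sex mismatch: specific={jem_specific.sex!r}, broad={jem_broad.sex!r}"
        )

    def get(name, default=None):
        try:
            if isinstance(record, pd.Series) or isinstance(record, dict):
                return record.get(name, default)
            return getattr(record, name, default)
        except AttributeError:
            return default

    rec_sex = get("sex")
    if rec_sex is not None and rec_sex != jem_specific.sex:
        raise LinkageError(
            f"record sex {rec_sex!r} does not match JEM sex {jem_specific.sex!r}"
        )

    pid = str(get("participant_id"))
    if get("employment_status") != "current":
        return ExposureAssignment(pid, None, "none", "not_working")

    code = _clean_code(get("occupation_code"))

    if code is not None and len(code) >= 4:
        p = jem_specific.lookup(code)
        if p is not None:
            return ExposureAssignment(pid, p, "four_digit", categorize(p))

    if strategy == "fallback" and code is not None and len(code) >= 2:
        p = jem_broad.lookup(broad_code(code))
        if p is not None:
            return ExposureAssignment(pid, p, "two_digit", categorize(p))

    return ExposureAssignment(pid, None, "none", "missing_p")


def link_exposures(
    records: pd.DataFrame,
    jem_specific: JEMTable,
    jem_broad: JEMTable,
    strategy: str = "fallback",
) -> pd.DataFrame:
    """Link every participant; returns one assignment row per record."""
    assignments = [
        link_probability(row, jem_specific, jem_broad, strategy)
        for row in records.to_dict("records")
    ]
    out = pd.DataFrame([asdict(a) for a in assignments])
    out["p_value"] = out["p_value"].astype(float)
    return out


@dataclass(frozen=True)
class FlowCounts:
    """Sample-size flow through exposure-variable creation (one study arm)."""

    n_current_workers: int
    n_vague_two_digit: int  # occupation too vague even for a broad code
    n_vague_four_digit: int  # broad-codable only (2-character code)
    n_suppressed_four_digit: int  # 4-digit code present but unlinkable at that level
    n_linked_four_digit: int
    n_linked_two_digit: int
    n_missing_p: int

    def __post_init__(self):
        parts = self.n_linked_four_digit + self.n_linked_two_digit + self.n_missing_p
        if parts != self.n_current_workers:
            raise DataIntegrityError(
                f"flow counts do not partition current workers: "
                f"{self.n_linked_four_digit}+{self.n_linked_two_digit}"
                f"+{self.n_missing_p} != {self.n_current_workers}"
            )
        if any(v < 0 for v in asdict(self).values()):
            raise DataIntegrityError("flow counts must be non-negative")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")


def flow_accounting(
    assignments: pd.DataFrame, records: pd.DataFrame
) -> FlowCounts:
    """Reconstruct the sample-size flow from assignments and raw records."""
    ids = records["participant_id"].astype(str)
    if ids.duplicated().any():
        dupes = ids[ids.duplicated()].unique()[:5]
        raise DataIntegrityError(f"duplicate participant ids: {list(dupes)}")
    if len(assignments) != len(records):
        raise DataIntegrityError("one assignment per record is required")

    merged = records.assign(participant_id=ids).merge(
        assignments.assign(participant_id=assignments["participant_id"].astype(str)),
        on="participant_id",
        validate="one_to_one",
    )
    cur = merged[merged["employment_status"] == "current"]
    codes = cur["occupation_code"].map(_clean_code)
    code_len = codes.map(lambda c: 0 if c is None else len(c))

    return FlowCounts(
        n_current_workers=int(len(cur)),
        n_vague_two_digit=int((code_len == 0).sum()),
        n_vague_four_digit=int(((code_len >= 2) & (code_len < 4)).sum()),
        n_suppressed_four_digit=int(
            ((code_len >= 4) & (cur["source_level"] != "four_digit")).sum()
        ),
        n_linked_four_digit=int((cur["source_level"] == "four_digit").sum()),
        n_linked_two_digit=int((cur["source_level"] == "two_digit").sum()),
        n_missing_p=int((cur["category"] == "missing_p").sum()),
    )
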