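"""Job-exposure matrix (JEM) construction for probability of shift work.

A JEM cell holds, for one sex and one occupation code, the number of workers
observed in a labour survey, how many of them are shift workers, and the
resulting proportion ``p_shift`` (the probability-of-shift-work value that
downstream linkage assigns to study participants holding that occupation).

Tables exist at two hierarchy levels mirroring the NOC-S structure:

* ``specific`` — 4-character unit-group codes (e.g. ``"D112"``);
* ``broad`` — 2-character major-group codes (e.g. ``"D1"``), obtained by
  prefix truncation and aggregation of the specific codes.

Statistical-disclosure suppression conceals the proportion of cells whose
counts are too small to release: fewer than 25 workers in total, or fewer
than 5 shift workers when the cell has fewer than 100 workers. Suppressed
cells never expose ``p_shift`` to consumers; linkage must fall back to the
broad level (or fail).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

from .errors import DataIntegrityError, LinkageError

logger = logging.getLogger(__name__)

SCHEDULES = ("regular_day", "regular_evening", "regular_night", "rotating", "other")
#: Schedules that count as shift work.
SHIFT_SCHEDULES = frozenset({"regular_evening", "regular_night", "rotating"})
#: Weekly-hours threshold; shift work requires strictly more than this.
SHIFT_HOURS_THRESHOLD = 20.0

#: Suppression thresholds (strict "<" throughout).
SUPPRESS_MIN_TOTAL = 25
SUPPRESS_MIN_SHIFT = 5
SUPPRESS_SMALL_CELL_TOTAL = 100


def _field(record, name: str):
    if isinstance(record, Mapping) or isinstance(record, pd.Series):
        return record[name]
    return getattr(record, name)


def classify_shift_worker(record) -> bool:
    """Whether a survey respondent is a shift worker.

    A shift worker holds a regular evening, regular night, or rotating
    schedule for strictly more than 20 hours per week. Accepts any record
    with ``schedule`` and ``weekly_hours`` fields (mapping, Series, object).
    """
    schedule = _field(record, "schedule")
    hours = float(_field(record, "weekly_hours"))
    return schedule in SHIFT_SCHEDULES and hours > SHIFT_HOURS_THRESHOLD


def shift_worker_mask(records: pd.DataFrame) -> pd.Series:
    """Vectorised :func:`classify_shift_worker` over a survey DataFrame."""
    return records["schedule"].isin(SHIFT_SCHEDULES) & (
        records["weekly_hours"] > SHIFT_HOURS_THRESHOLD
    )


def broad_code(code: str) -> str:
    """Map an occupation code to its 2-character broad (major-group) code."""
    if not isinstance(code, str) or len(code) < 2:
        raise LinkageError(f"cannot derive broad code from {code!r}")
    return code[:2]


@dataclass(frozen=True)
class JEMCell:
    """Counts and shift-work proportion for one sex x occupation-code cell."""

    code: str
    level: str  # "specific" | "broad"
    sex: str
    n_total: int
    n_shift: int
    suppressed: bool = False

    def __post_init__(self):
        if not 0 <= self.n_shift <= self.n_total:
            raise DataIntegrityError(
                f"cell {self.code}: n_shift {self.n_shift} outside [0, {self.n_total}]"
            )

    @property
    def p_shift(self) -> float | None:
        """Proportion of shift workers, or None when concealed/undefined."""
        if self.suppressed or self.n_total == 0:
            return None
        return self.n_shift / self.n_total


@dataclass
class JEMTable:
    """One sex-specific JEM at a single hierarchy level."""

    level: str
    sex: str
    cells: dict[str, JEMCell] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.cells)

    def __iter__(self) -> Iterator[JEMCell]:
        return iter(self.cells.values())

    def __contains__(self, code: str) -> bool:
        return code in self.cells

    @property
    def n_records(self) -> int:
        return sum(c.n_total for c in self.cells.values())

    def lookup(self, code: str) -> float | None:
        """p_shift for ``code``, or None if the cell is absent or suppressed."""
        cell = self.cells.get(code)
        if cell is None:
            return None
        return cell.p_shift

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for code in sorted(self.cells):
            c = self.cells[code]
            rows.append(
                {
                    "code": c.code,
                    "level": c.level,
                    "sex": c.sex,
                    "n_total": c.n_total,
                    "n_shift": c.n_shift,
                    # concealed cells emit an empty field, like a released table
                    "p_shift": np.nan if c.p_shift is None else c.p_shift,
                    "suppressed": c.suppressed,
                }
            )
        return pd.DataFrame(
            rows,
            columns=["code", "level", "sex", "n_total", "n_shift", "p_shift", "suppressed"],
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "JEMTable":
        if frame.empty:
            raise DataIntegrityError("cannot rebuild a JEM table from an empty frame")
        levels = set(frame["level"])
        sexes = set(frame["sex"])
        if len(levels) != 1 or len(sexes) != 1:
            raise DataIntegrityError("a JEM table holds exactly one level and one sex")
        table = cls(level=levels.pop(), sex=sexes.pop())
        for row in frame.itertuples(index=False):
            table.cells[row.code] = JEMCell(
                code=row.code,
                level=row.level,
                sex=row.sex,
                n_total=int(row.n_total),
                n_shift=int(row.n_shift),
                suppressed=bool(row.suppressed),
            )
        return table

    @classmethod
    def from_csv(cls, path: str | Path) -> "JEMTable":
        return cls.from_frame(pd.read_csv(path, dtype={"code": str}))


def tabulate_jem(
    records: pd.DataFrame, level: str, sex: str | None = None
) -> JEMTable:
    """Tabulate shift-worker counts per occupation code for one sex.

    ``records`` must carry columns ``sex``, ``occupation_code``,
    ``weekly_hours`` and ``schedule``, all for a single sex. At
    ``level="broad"`` codes are first truncated to their 2-character prefix,
    so a broad cell aggregates all of its specific children. Suppression is
    *not* applied here; see :func:`apply_suppression`.
    """
    if level not in ("specific", "broad"):
        raise ValueError(f"level must be 'specific' or 'broad', got {level!r}")
    if records.empty:
        logger.warning("tabulate_jem: empty record collection; returning empty table")
        return JEMTable(level=level, sex=sex or "unknown")

    sexes = set(records["sex"].unique())
    if len(sexes) > 1:
        raise DataIntegrityError(f"records mix sexes {sorted(sexes)}; tabulate one sex at a time")
    table_sex = sexes.pop()
    if sex is not None and sex != table_sex:
        raise DataIntegrityError(f"records carry sex {table_sex!r}, expected {sex!r}")

    codes = records["occupation_code"].astype(str)
    if (codes.str.len() < 2).any():
        raise LinkageError("survey records contain occupation codes shorter than 2 characters")
    if level == "broad":
        codes = codes.str[:2]

    is_shift = shift_worker_mask(records)
    grouped = pd.DataFrame({"code": codes, "shift": is_shift.astype(int)}).groupby("code")[
        "shift"
    ]
    table = JEMTable(level=level, sex=table_sex)
    for code, grp in grouped:
        table.cells[code] = JEMCell(
            code=code,
            level=level,
            sex=table_sex,
            n_total=int(grp.size),
            n_shift=int(grp.sum()),
        )
    return table


def suppression_rule(n_total: int, n_shift: int) -> bool:
    """Confidentiality rule: True means the cell's proportion is concealed.

    A cell is suppressed when it has fewer than 25 workers in total, or when
    it has fewer than 5 shift workers and fewer than 100 workers in total.
    All comparisons are strict, per the release rule's literal wording.
    """
    return n_total < SUPPRESS_MIN_TOTAL or (
        n_shift < SUPPRESS_MIN_SHIFT and n_total < SUPPRESS_SMALL_CELL_TOTAL
    )


def apply_suppression(table: JEMTable) -> JEMTable:
    """Return a copy of ``table`` with disclosure-control flags set."""
    out = JEMTable(level=table.level, sex=table.sex)
    for code, cell in table.cells.items():
        out.cells[code] = replace(
            cell, suppressed=suppression_rule(cell.n_total, cell.n_shift)
        )
    return out


def build_jem_pair(records: pd.DataFrame, sex: str | None = None) -> tuple[JEMTable, JEMTable]:
    """Tabulate and suppress both hierarchy levels in one call.

    Returns ``(specific, broad)`` tables, each already suppression-flagged.
    """
    specific = apply_suppression(tabulate_jem(records, "specific", sex=sex))
    broad = apply_suppression(tabulate_jem(records, "broad", sex=sex))
    return specific, broad
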