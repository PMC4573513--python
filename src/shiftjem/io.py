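"""CSV readers that preserve the dtypes the pipeline stages expect.

Occupation codes must stay strings (a code like ``"0012"`` would otherwise
be mangled into an integer) and empty fields must come back as missing.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd


def read_survey_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"occupation_code": str, "person_id": str})


def read_study_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"occupation_code": str, "participant_id": str})
    if "occupation_code" in df.columns:
        df["occupation_code"] = df["occupation_code"].where(
            df["occupation_code"].notna(), None
        )
    return df


def read_assignments_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"participant_id": str})


def read_bmi_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"participant_id": str})
    df["weight_class"] = df["weight_class"].where(df["weight_class"].notna(), None)
    return df
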