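import pandas as pd
import pytest

import shiftjem as sj


@pytest.fixture(scope="session")
def survey_df() -> pd.DataFrame:
    """One synthetic labour-survey extract shared across tests."""
    return sj.generate_survey(sj.SurveyConfig(seed=11))


@pytest.fixture(scope="session")
def jem_pair(survey_df):
    """Suppression-flagged (specific, broad) JEM tables for the fixture survey."""
    return sj.build_jem_pair(survey_df)


def make_survey_records(rows):
    """Survey DataFrame from (code, schedule, hours) tuples, single sex."""
    return pd.DataFrame(
        {
            "person_id": [f"S{i}" for i in range(len(rows))],
            "sex": "female",
            "occupation_code": [r[0] for r in rows],
            "schedule": [r[1] for r in rows],
            "weekly_hours": [r[2] for r in rows],
        }
    )
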