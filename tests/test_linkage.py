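"""Exposure linkage: categorisation, fallback strategy, flow accounting."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import shiftjem as sj
from shiftjem import JEMCell, JEMTable, categorize, flow_accounting, link_probability
from shiftjem.errors import DataIntegrityError, DomainError, LinkageError
from shiftjem.linkage import CUT_HIGH, CUT_LOW, CUT_MEDIUM, EXPOSURE_CATEGORIES


def small_jem():
    """Hand-built JEM pair: D112 retained high, B999 suppressed with broad B9 low."""
    specific = JEMTable(level="specific", sex="female")
    specific.cells["D112"] = JEMCell("D112", "specific", "female", 100, 72)
    specific.cells["B999"] = JEMCell("B999", "specific", "female", 24, 2, suppressed=True)
    broad = JEMTable(level="broad", sex="female")
    broad.cells["D1"] = JEMCell("D1", "broad", "female", 100, 72)
    broad.cells["B9"] = JEMCell("B9", "broad", "female", 200, 16)
    return specific, broad


def record(pid="P1", status="current", code="D112"):
    return {"participant_id": pid, "employment_status": status, "occupation_code": code}


@pytest.mark.parametrize(
    "p,expected",
    [
        (0.0, "near_nil"),
        (0.014, "near_nil"),
        (0.015, "low"),  # lower bound of 'low' is inclusive
        (0.0999, "low"),
        (0.10, "medium"),
        (0.4499, "medium"),
        (0.45, "high"),  # '45%+'
        (1.0, "high"),
    ],
)
def test_category_cut_points(p, expected):
    assert categorize(p) == expected


@pytest.mark.parametrize("cut,below,above", [
    (CUT_LOW, "near_nil", "low"),
    (CUT_MEDIUM, "low", "medium"),
    (CUT_HIGH, "medium", "high"),
])
def test_category_boundaries_from_both_sides(cut, below, above):
    eps = 1e-9
    assert categorize(cut - eps) == below
    assert categorize(cut) == above
    assert categorize(cut + eps) == above


@pytest.mark.parametrize("bad", [-0.1, 1.1, float("nan"), float("inf")])
def test_categorize_rejects_out_of_domain(bad):
    with pytest.raises(DomainError):
        categorize(bad)


@given(st.floats(0.0, 1.0), st.floats(0.0, 1.0))
def test_categorize_monotone(p, q):
    order = {c: i for i, c in enumerate(EXPOSURE_CATEGORIES)}
    if p <= q:
        assert order[categorize(p)] <= order[categorize(q)]


def test_four_digit_direct_hit():
    a = link_probability(record(), *small_jem())
    assert (a.p_value, a.source_level, a.category) == (0.72, "four_digit", "high")


def test_suppressed_specific_falls_back_to_broad():
    a = link_probability(record(code="B999"), *small_jem(), strategy="fallback")
    assert (a.p_value, a.source_level, a.category) == (0.08, "two_digit", "low")


def test_four_digit_only_strategy_rejects_fallback():
    a = link_probability(record(code="B999"), *small_jem(), strategy="four_digit_only")
    assert (a.p_value, a.source_level, a.category) == (None, "none", "missing_p")


def test_two_character_code_links_at_broad_level():
    a = link_probability(record(code="B9"), *small_jem())
    assert (a.source_level, a.category) == ("two_digit", "low")


def test_absent_code_is_missing_p():
    for code in (None, float("nan"), ""):
        a = link_probability(record(code=code), *small_jem())
        assert (a.p_value, a.source_level, a.category) == (None, "none", "missing_p")


def test_non_current_workers_are_not_working_regardless_of_code():
    for status in ("former", "never"):
        a = link_probability(record(status=status, code="D112"), *small_jem())
        assert a.category == "not_working" and a.p_value is None


def test_jem_sex_mismatch_raises():
    specific, broad = small_jem()
    broad.sex = "male"
    with pytest.raises(LinkageError):
        link_probability(record(), specific, broad)


def test_flow_accounting_hand_counted_fixture():
    """10 four-digit hits, 5 broad fallbacks, 3 missing."""
    specific, broad = small_jem()
    rows = (
        [record(f"A{i}", code="D112") for i in range(10)]
        + [record(f"B{i}", code="B999") for i in range(5)]
        + [record(f"C{i}", code=None) for i in range(3)]
        + [record("D0", status="former", code="D112")]
    )
    records = pd.DataFrame(rows)
    assignments = sj.link_exposures(records, specific, broad)
    flow = flow_accounting(assignments, records)
    assert flow.n_current_workers == 18
    assert flow.n_linked_four_digit == 10
    assert flow.n_linked_two_digit == 5
    assert flow.n_missing_p == 3
    assert flow.n_suppressed_four_digit == 5
    assert flow.n_vague_two_digit == 3
    assert flow.n_vague_four_digit == 0


def test_flow_accounting_rejects_duplicate_ids():
    specific, broad = small_jem()
    records = pd.DataFrame([record("P1"), record("P1")])
    assignments = sj.link_exposures(records, specific, broad)
    with pytest.raises(DataIntegrityError):
        flow_accounting(assignments, records)


def test_flow_all_linkable_and_all_missing():
    specific, broad = small_jem()
    linkable = pd.DataFrame([record(f"P{i}") for i in range(7)])
    a = sj.link_exposures(linkable, specific, broad)
    f = flow_accounting(a, linkable)
    assert (f.n_linked_two_digit, f.n_missing_p) == (0, 0)
    absent = pd.DataFrame([record(f"P{i}", code=None) for i in range(4)])
    a = sj.link_exposures(absent, specific, broad)
    f = flow_accounting(a, absent)
    assert f.n_missing_p == f.n_current_workers == 4


def test_four_digit_only_is_subset_of_fallback(jem_pair):
    """The sensitivity strategy agrees with fallback wherever both link."""
    specific, broad = jem_pair
    study = sj.generate_study(sj.StudyConfig(n_participants=800, seed=7), specific, broad)
    fb = sj.link_exposures(study, specific, broad, "fallback")
    fd = sj.link_exposures(study, specific, broad, "four_digit_only")
    four = fd[fd["source_level"] == "four_digit"]
    merged = four.merge(fb, on="participant_id", suffixes=("_fd", "_fb"))
    assert (merged["source_level_fb"] == "four_digit").all()
    assert np.allclose(merged["p_value_fd"], merged["p_value_fb"])
    # fallback links everyone whose broad code is retained
    retained_broad = fb[fb["source_level"] == "two_digit"]
    assert (retained_broad["category"] != "missing_p").all()
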