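"""Exclusion cascade: reasons, envelope arithmetic, flow conservation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from newborntypes import (
    FlowAccounting,
    PlausibilityLimits,
    apply_exclusions,
    build_envelope,
    flow_summary,
)
from conftest import make_records


def test_envelope_hand_arithmetic(rec):
    records = make_records(
        [
            {"ga_days": 280, "bw_grams": 3000},
            {"ga_days": 281, "bw_grams": 3200},
            {"ga_days": 282, "bw_grams": 3400},
        ]
    )
    env = build_envelope(records, multiplier=5, min_cell=3)
    row = env.loc[40]
    assert row["mean_g"] == 3200
    assert row["sd_g"] == pytest.approx(200)  # sample SD, n-1
    assert (row["lower_g"], row["upper_g"]) == (2200, 4200)


def test_envelope_sparse_cell_has_no_bounds(rec):
    records = make_records([{"ga_days": 280, "bw_grams": 3000}])
    env = build_envelope(records, min_cell=2)
    assert np.isnan(env.loc[40, "lower_g"]) and np.isnan(env.loc[40, "upper_g"])


def test_envelope_empty_input():
    env = build_envelope(make_records([]))
    assert len(env) == 0


@pytest.mark.parametrize(
    "row, reason",
    [
        ({"bw_grams": 200, "ga_days": 280, "sex": "male"}, "implausible_bw"),
        ({"bw_grams": 6500}, "implausible_bw"),  # >= 6500 g implausible
        ({"ga_days": 153, "bw_grams": 450}, "implausible_ga"),  # 21+6 weeks
        ({"ga_days": 315}, "implausible_ga"),  # above 44+6 weeks
        ({"ga_days": None, "bw_grams": None}, "missing_both"),
        ({"ga_days": None}, "missing_ga"),
        ({"bw_grams": None}, "missing_bw"),
        ({"sex": None}, "missing_sex"),
        ({"ga_days": None, "sex": None}, "missing_ga"),  # first rule wins
    ],
)
def test_cascade_attributes_single_reason(row, reason):
    records = make_records([row, {}])  # one bad record plus one clean one
    result = apply_exclusions(records)
    assert result.flow.counts[reason] == 1
    assert result.flow.n_included == 1
    assert result.excluded["exclusion_reason"].tolist() == [reason]


@pytest.mark.parametrize(
    "row", [{"bw_grams": 250}, {"bw_grams": 6499}, {"ga_days": 154}, {"ga_days": 314}]
)
def test_plausibility_boundaries_are_inclusive(row):
    result = apply_exclusions(make_records([row]))
    assert result.flow.n_included == 1


def test_combo_exclusion_against_self_referential_envelope():
    rows = [{"bw_grams": 3000} for _ in range(50)]
    rows += [{"bw_grams": 3200} for _ in range(50)]
    rows.append({"bw_grams": 6000})  # ~9 SD above the week-40 mean
    result = apply_exclusions(make_records(rows))
    assert result.flow.counts["implausible_combo"] == 1
    assert result.excluded["bw_grams"].tolist() == [6000]


def test_combo_skipped_where_envelope_undefined():
    # two records in the cell, min_cell 10: no bounds, no combo exclusions
    records = make_records(
        [{"bw_grams": 500}, {"bw_grams": 4500}]
    )
    result = apply_exclusions(records)
    assert result.flow.n_included == 2


def test_idempotence_with_fixed_envelope():
    rng = np.random.default_rng(5)
    rows = [
        {
            "ga_days": int(g),
            "bw_grams": int(b),
            "sex": "male" if rng.random() < 0.5 else "female",
        }
        for g, b in zip(
            rng.integers(154, 315, 500),
            rng.normal(3200, 450, 500).clip(300, 6400).astype(int),
        )
    ]
    rows += [{"bw_grams": None}, {"ga_days": None}, {"bw_grams": 100}]
    first = apply_exclusions(make_records(rows))
    second = apply_exclusions(first.included, envelope=first.envelope)
    assert second.flow.n_excluded == 0
    assert second.flow.n_included == first.flow.n_included


def test_included_set_is_rule_order_invariant():
    """Rules 1-6 are pure filters: survivors = records failing none of them."""
    rows = [
        {},
        {"bw_grams": None},
        {"ga_days": None, "sex": None},
        {"bw_grams": 200},
        {"ga_days": 340},
        {"sex": None},
        {"bw_grams": 7000, "ga_days": None},
    ]
    records = make_records(rows)
    result = apply_exclusions(records)
    ga = records["ga_days"].astype("float64")
    bw = records["bw_grams"].astype("float64")
    direct = (
        ga.notna()
        & bw.notna()
        & records["sex"].notna()
        & ga.between(154, 314)
        & (bw >= 250)
        & (bw < 6500)
    )
    assert set(result.included.index) <= set(records.index[direct])
    # no combo exclusions here (cells too sparse for an envelope)
    assert set(result.included.index) == set(records.index[direct])


@settings(max_examples=50, derandomize=True, deadline=None)
@given(st.data())
def test_conservation_identity_on_random_registries(data):
    n = data.draw(st.integers(1, 60))
    rows = []
    for i in range(n):
        rows.append(
            {
                "ga_days": data.draw(
                    st.one_of(st.none(), st.integers(100, 340)), label=f"ga{i}"
                ),
                "bw_grams": data.draw(
                    st.one_of(st.none(), st.integers(50, 8000)), label=f"bw{i}"
                ),
                "sex": data.draw(
                    st.sampled_from(["male", "female", None]), label=f"sex{i}"
                ),
            }
        )
    records = make_records(rows)
    result = apply_exclusions(records)
    flow = result.flow
    assert flow.n_input == flow.n_included + sum(flow.counts.values())
    assert len(result.included) + len(result.excluded) == n
    assert set(result.included.index).isdisjoint(result.excluded.index)
    assert (result.excluded["exclusion_reason"] != "").all()


class TestFlowSummary:
    def test_zero_exclusions(self):
        flow = FlowAccounting(n_input=100, counts={}, n_included=100)
        table = flow_summary(flow)
        assert table.loc[table["stage"] == "excluded_total", "pct_of_input"].item() == 0.0
        assert table.loc[table["stage"] == "included", "n"].item() == 100

    def test_zero_input_is_error(self):
        with pytest.raises(ValueError):
            flow_summary(FlowAccounting(n_input=0, counts={}, n_included=0))

    def test_broken_identity_is_error(self):
        with pytest.raises(AssertionError):
            flow_summary(FlowAccounting(n_input=10, counts={"missing_ga": 2}, n_included=9))

    def test_percentages_at_one_decimal(self):
        flow = FlowAccounting(n_input=3, counts={"missing_ga": 1}, n_included=2)
        table = flow_summary(flow).set_index("stage")
        assert table.loc["excluded", "pct_of_input"] == 33.3
        assert table.loc["included", "pct_of_input"] == 66.7
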