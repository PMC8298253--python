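"""Statistics stage: Shapiro-Wilk and one-tailed t-test oracles
(cross-checked against scipy), table validation and report purity."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from embryoflow.cohortstats import (CohortTable, StatsError,
                                    build_report, report_to_json,
                                    report_to_text, shapiro_wilk,
                                    ttest_one_tailed)


def test_shapiro_reference_sample():
    """Fixed sample checked against the scipy reference
    implementation of the Shapiro-Wilk coefficients."""
    x = [0.1, 0.2, 0.3, 0.4, 0.5]
    w, p = shapiro_wilk(x)
    w_ref, p_ref = sps.shapiro(x)
    assert w == pytest.approx(float(w_ref), rel=1e-12)
    assert p == pytest.approx(float(p_ref), rel=1e-12)
    assert 0 < w <= 1


def test_shapiro_normal_scores_near_one():
    z = sps.norm.ppf((np.arange(1, 21) - 0.375) / 20.25)
    w, _ = shapiro_wilk(z)
    assert w > 0.99


def test_shapiro_range_and_degenerate():
    with pytest.raises(StatsError):
        shapiro_wilk([1.0, 2.0])
    with pytest.raises(StatsError):
        shapiro_wilk(np.arange(51.0))
    with pytest.raises(StatsError):
        shapiro_wilk([2.0, 2.0, 2.0, 2.0])


def test_ttest_identical_samples():
    t, p = ttest_one_tailed([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], "a>b")
    assert t == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(0.5, abs=1e-12)


def test_ttest_clear_separation():
    t, p = ttest_one_tailed([10.0, 11.0, 12.0], [1.0, 1.5, 2.0], "a>b")
    assert p < 1e-3
    # opposite direction: complementary p
    _, p_rev = ttest_one_tailed([10.0, 11.0, 12.0], [1.0, 1.5, 2.0],
                                "a<b")
    assert p + p_rev == pytest.approx(1.0)


def test_ttest_validation():
    with pytest.raises(StatsError):
        ttest_one_tailed([1.0], [1.0, 2.0], "a>b")
    with pytest.raises(StatsError):
        ttest_one_tailed([1.0, 1.0], [2.0, 2.0], "a>b")
    with pytest.raises(StatsError):
        ttest_one_tailed([1.0, 2.0], [1.0, 3.0], "sideways")


@settings(deadline=None, derandomize=True, max_examples=50)
@given(st.lists(st.floats(-5, 5), min_size=3, max_size=8),
       st.lists(st.floats(-5, 5), min_size=3, max_size=8))
def test_ttest_swap_symmetry(a, b):
    """Swapping the samples and the direction preserves p."""
    if np.ptp(a) < 1e-6 and np.ptp(b) < 1e-6:
        return      # (near-)degenerate: pooled variance underflows
    t1, p1 = ttest_one_tailed(a, b, "a>b")
    t2, p2 = ttest_one_tailed(b, a, "a<b")
    assert t1 == pytest.approx(-t2, abs=1e-9)
    assert p1 == pytest.approx(p2, abs=1e-9)


def _rows(values_by_group, metric="sv", stage="HH25", structure="LV"):
    rows = []
    for g, vals in values_by_group.items():
        for i, v in enumerate(vals):
            rows.append(dict(embryo_id=f"{g}{i}", group=g, stage=stage,
                             structure=structure, metric=metric,
                             value=v))
    return rows


def test_table_validation():
    with pytest.raises(StatsError):
        CohortTable.from_rows([dict(embryo_id="a", group="sham",
                                    stage="HH25", structure="LV",
                                    metric="sv", value=1.0)])
    rows = _rows({"control": [1.0], "LAL": [2.0]})
    with pytest.raises(StatsError):
        CohortTable.from_rows(rows + rows)      # duplicates
    with pytest.raises(StatsError):
        CohortTable(CohortTable.from_rows(rows).frame.drop(
            columns=["value"]))


def test_report_directions_and_stars():
    tbl = CohortTable.from_rows(_rows({
        "control": [10.0, 11.0, 12.0, 10.5],
        "LAL": [1.0, 1.2, 1.4, 1.1]}))
    rep = build_report(tbl, directions={"sv": "control>LAL"})
    row = rep["rows"][0]
    assert row["test"]["direction"] == "control>LAL"
    assert not row["test"]["direction_assumed"]
    assert row["test"]["stars"] == "**"
    assert row["control"]["n"] == 4
    # stated wrong direction: p near 1, no stars
    rep2 = build_report(tbl, directions={"sv": "control<LAL"})
    assert rep2["rows"][0]["test"]["stars"] == ""


def test_report_missing_group_warns():
    tbl = CohortTable.from_rows(_rows({"control": [1.0, 2.0, 3.0]}))
    with pytest.warns(UserWarning):
        rep = build_report(tbl)
    assert "test" not in rep["rows"][0]


def test_report_pure_function():
    tbl = CohortTable.from_rows(_rows({
        "control": [1.0, 2.0, 3.0], "LAL": [2.0, 3.0, 4.0]}))
    j1 = report_to_json(build_report(tbl))
    j2 = report_to_json(build_report(
        CohortTable.from_rows(_rows({
            "control": [1.0, 2.0, 3.0], "LAL": [2.0, 3.0, 4.0]}))))
    assert j1 == j2                      # byte-identical
    txt = report_to_text(build_report(tbl))
    assert "no multiple-testing correction" in txt


def test_av_ratio_cohorts_significant(reports_hh25_control,
                                      reports_hh25_lal):
    """The synthetic cohorts reproduce the study's AV stroke-volume
    ratio finding: one-tailed p < 0.05 for control > LAL."""
    a = [r.av_sv_ratio for r in reports_hh25_control]
    b = [r.av_sv_ratio for r in reports_hh25_lal]
    _, p = ttest_one_tailed(a, b, "a>b")
    assert p < 0.05
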