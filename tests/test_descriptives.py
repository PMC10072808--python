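import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from contactweave import (
    Survey,
    chi2_independence,
    chi2_trend,
    contact_totals,
    distance_mobility_tables,
    duration_midpoint_minutes,
    participant_summaries,
    reporting_method_comparison,
    setting_proportions,
    weighted_median_iqr,
    weighted_quantile,
)
from contactweave.survey import SupplementaryContacts

from conftest import make_contact, make_participant


@pytest.mark.parametrize(
    "cat,minutes",
    [
        ("lt5min", 2.5),
        ("5to14min", 9.5),
        ("15to59min", 37.0),
        ("1to4h", 150.0),
        ("gt4h", 240.0),  # right-truncated at 4 h
    ],
)
def test_duration_midpoints(cat, minutes):
    assert duration_midpoint_minutes(cat) == minutes


def test_unknown_duration_category_rejected():
    with pytest.raises(ValueError):
        duration_midpoint_minutes("2to3h")


def test_participant_summary_arithmetic():
    """2 diary contacts (15-59 min, >4 h) + 3 supplementary -> degree 5,
    hours (37+240)/60."""
    p = make_participant("P1")
    contacts = [
        make_contact("P1", duration_cat="15to59min"),
        make_contact("P1", duration_cat="gt4h"),
    ]
    supp = [SupplementaryContacts("P1", {("16-64", True): 3})]
    summ = participant_summaries(Survey.from_records([p], contacts, supp))
    row = summ.iloc[0]
    assert row["degree_diary"] == 2
    assert row["degree_supplementary"] == 3
    assert row["degree_total"] == 5
    assert row["total_contact_hours"] == pytest.approx((37 + 240) / 60)


def test_zero_contact_participant(tiny_survey):
    summ = participant_summaries(tiny_survey)
    assert (summ["degree_total"] == summ["degree_diary"] + summ["degree_supplementary"]).all()
    p = make_participant("P1")
    lone = participant_summaries(Survey.from_records([p]))
    assert lone.iloc[0]["degree_total"] == 0
    assert lone.iloc[0]["total_contact_hours"] == 0


def test_weighted_median_tie_break_rule():
    """Degrees (1,2,10) with weights (1,1,2): the cumulative share hits
    exactly 0.5 at 2, so the median resolves upward to 10."""
    med, q1, q3 = weighted_median_iqr([1, 2, 10], [1, 1, 2])
    assert med == 10
    assert q1 == 2
    assert q3 == 10


def test_weighted_quantile_equal_weights_matches_brute_force():
    rng = np.random.default_rng(5)
    for _ in range(20):
        v = rng.integers(0, 50, size=int(rng.integers(1, 30))).astype(float)
        w = np.ones_like(v)
        for q in (0.1, 0.25, 0.5, 0.75, 0.9):
            got = weighted_quantile(v, w, q)
            # brute force: smallest value whose ECDF strictly exceeds q
            sv = np.sort(v)
            ecdf = np.arange(1, len(sv) + 1) / len(sv)
            idx = np.argmax(ecdf > q) if (ecdf > q).any() else len(sv) - 1
            assert got == sv[idx]


def test_weighted_median_equal_weights_equals_unweighted_median_odd_n():
    rng = np.random.default_rng(6)
    for _ in range(20):
        v = rng.normal(size=2 * int(rng.integers(1, 15)) + 1)
        med, _, _ = weighted_median_iqr(v)
        assert med == np.median(v)


def test_setting_proportions_sum_to_one_and_multiple_bucket():
    p1 = make_participant("P1", age=30)
    contacts = [
        make_contact("P1", settings=frozenset({"home_household"})),
        make_contact("P1", settings=frozenset({"home_household", "school"})),
        make_contact("P1", settings=frozenset({"transport"})),
        make_contact("P1", settings=frozenset({"work"})),
    ]
    survey = Survey.from_records([p1], contacts)
    tab = setting_proportions(survey, groupby="residence").table
    assert np.allclose(tab.sum(axis=1), 1.0, atol=1e-12)
    row = tab.loc["urban"]
    assert row["multiple"] == pytest.approx(0.25)  # home+school contact
    assert row["other"] == pytest.approx(0.25)  # transport merges into other
    assert row["home_household"] == pytest.approx(0.25)
    assert row["work"] == pytest.approx(0.25)
    assert row["school"] == pytest.approx(0.0)


def test_setting_proportions_respect_weights():
    p1 = make_participant("P1", age=30)
    p2 = make_participant("P2", age=40)
    contacts = [
        make_contact("P1", settings=frozenset({"work"})),
        make_contact("P2", settings=frozenset({"school"})),
    ]
    survey = Survey.from_records([p1, p2], contacts)
    tab = setting_proportions(survey, weights=np.array([3.0, 1.0]),
                              groupby="sex").table
    assert tab.loc["female", "work"] == pytest.approx(0.75)
    assert tab.loc["female", "school"] == pytest.approx(0.25)


def chi2_textbook(table: np.ndarray) -> tuple[float, int]:
    """Independent textbook implementation of Pearson's X^2."""
    table = np.asarray(table, dtype=float)
    n = table.sum()
    stat = 0.0
    for i in range(table.shape[0]):
        for j in range(table.shape[1]):
            e = table[i].sum() * table[:, j].sum() / n
            stat += (table[i, j] - e) ** 2 / e
    return stat, (table.shape[0] - 1) * (table.shape[1] - 1)


def test_chi2_perfect_independence():
    stat, df, p = chi2_independence([[10, 10], [10, 10]])
    assert stat == pytest.approx(0.0, abs=1e-12)
    assert df == 1
    assert p == pytest.approx(1.0)


def test_chi2_hand_computed_2x2():
    """[[20,10],[10,20]]: all expected counts 15, X^2 = 4*(25/15) = 20/3."""
    stat, df, _ = chi2_independence([[20, 10], [10, 20]])
    assert stat == pytest.approx(20 / 3)
    assert df == 1


def test_chi2_df_structure():
    stat, df, _ = chi2_independence([[5, 6], [7, 8], [9, 10], [11, 12]])
    assert df == 3  # 4x2 table


@settings(max_examples=100, deadline=None, derandomize=True)
@given(
    r=st.integers(2, 4),
    c=st.integers(2, 4),
    data=st.data(),
)
def test_chi2_matches_textbook_on_random_tables(r, c, data):
    table = np.array(
        [[data.draw(st.integers(1, 40)) for _ in range(c)] for _ in range(r)]
    )
    stat, df, p = chi2_independence(table)
    exp_stat, exp_df = chi2_textbook(table)
    assert stat == pytest.approx(exp_stat, rel=1e-10)
    assert df == exp_df


def test_chi2_zero_marginal_is_error():
    with pytest.raises(ValueError):
        chi2_independence([[0, 0], [5, 5]])


def test_trend_flat_proportions_give_zero():
    stat, df, p = chi2_trend([[10, 10], [20, 20], [30, 30]])
    assert stat == pytest.approx(0.0, abs=1e-12)
    assert df == 1


def test_trend_hand_computed_monotone_table():
    """r=(1,5,9) of n=10 each, scores 1..3: T=8, Var=5, X^2 = 12.8."""
    stat, df, p = chi2_trend([[1, 9], [5, 5], [9, 1]])
    assert stat == pytest.approx(12.8)
    assert df == 1
    assert p < 0.001


def test_trend_invariant_to_level_reversal():
    table = np.array([[2, 18], [7, 13], [15, 5], [19, 1]])
    s1, _, _ = chi2_trend(table)
    s2, _, _ = chi2_trend(table[::-1])
    assert s1 == pytest.approx(s2)


def test_trend_requires_two_levels():
    with pytest.raises(ValueError):
        chi2_trend([[5, 5]])


def test_reporting_comparison_not_applicable_without_supplementary():
    p = make_participant("P1")
    rep = reporting_method_comparison(Survey.from_records([p], [make_contact("P1")]))
    assert not rep.applicable


def test_reporting_comparison_identical_distributions_give_zero():
    p = make_participant("P1", age=30)
    contacts = [
        make_contact("P1", age=2, physical=True),
        make_contact("P1", age=10, physical=False),
        make_contact("P1", age=30, physical=True),
        make_contact("P1", age=70, physical=False),
    ]
    supp = [
        SupplementaryContacts(
            "P1",
            {
                ("0-4", True): 1,
                ("5-15", False): 1,
                ("16-64", True): 1,
                ("65+", False): 1,
            },
        )
    ]
    rep = reporting_method_comparison(Survey.from_records([p], contacts, supp))
    assert rep.applicable
    stat_age, df_age, _ = rep.age_chi2
    stat_ph, df_ph, _ = rep.physical_chi2
    assert stat_age == pytest.approx(0.0, abs=1e-12)
    assert df_age == 3
    assert stat_ph == pytest.approx(0.0, abs=1e-12)
    assert df_ph == 1
    # diary ages {2, 10, 30, 70} coarsen to one count per band
    assert (rep.age_table["diary"] == 1).all()


def test_physicality_biased_relegation_detected(synthetic_pair):
    """The generator relegates non-physical contacts more readily; the
    physical-proportion comparison must pick this up."""
    survey, _ = synthetic_pair
    rep = reporting_method_comparison(survey)
    stat, df, p = rep.physical_chi2
    assert df == 1
    assert stat > 0
    assert p < 0.05
    # direction: diary contacts more likely physical than supplementary
    phys_share = rep.physical_table.loc["physical"] / rep.physical_table.sum()
    assert phys_share["diary"] > phys_share["supplementary"]


def test_distance_table_shares_and_missing():
    p = make_participant("P1")
    contacts = [
        make_contact("P1", distance_cat="lt1km"),
        make_contact("P1", distance_cat="lt1km"),
        make_contact("P1", distance_cat="gt9km"),
        make_contact("P1", distance_cat=None),
    ]
    dist, mob = distance_mobility_tables(Survey.from_records([p], contacts))
    t = dist.table["share"]
    assert t["lt1km"] == pytest.approx(0.5)
    assert t["gt9km"] == pytest.approx(0.25)
    assert t["missing"] == pytest.approx(0.25)  # reported, never dropped
    assert t.sum() == pytest.approx(1.0)
    assert mob is None  # no mobility questionnaire columns present


def test_mobility_table_hand_tallied():
    p1 = make_participant("P1", age=30)
    p2 = make_participant("P2", age=32)
    survey = Survey.from_records([p1, p2])
    survey.participants["travel_province"] = ["never", "monthly"]
    _, mob = distance_mobility_tables(survey)
    t = mob.table
    assert set(t["admin_level"]) == {"province"}
    shares = t.set_index("frequency")["share"]
    assert shares["never"] == pytest.approx(0.5)
    assert shares["monthly"] == pytest.approx(0.5)


def test_contact_totals_and_diary_share(tiny_survey):
    totals = contact_totals(tiny_survey)
    assert totals["n_diary"] == 5
    assert totals["n_supplementary"] == 3
    assert totals["n_total"] == 8
    assert totals["diary_share_percent"] == pytest.approx(62.5)
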