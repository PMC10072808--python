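import numpy as np
import pytest

from contactweave import (
    AgeBandScheme,
    ContactFilter,
    MATRIX_SCHEME,
    PopulationTable,
    Survey,
    mean_contact_matrix,
    reciprocity_adjust,
    setting_stratified_matrices,
)
from contactweave.survey import resolve_contact_ages

from conftest import make_contact, make_participant

TWO_BANDS = AgeBandScheme("two", (0, 50))


def brute_force_matrix(survey: Survey, weights, scheme) -> np.ndarray:
    """Independent per-contact tally: loop participants and contacts."""
    k = scheme.n_bands
    num = np.zeros((k, k))
    denom = np.zeros(k)
    ages = resolve_contact_ages(survey)
    pdf = survey.participants
    for p_idx, prow in pdf.iterrows():
        i = scheme.band_of(prow["age"])
        w = weights[p_idx]
        denom[i] += w
        for c_idx, crow in survey.diary_contacts.iterrows():
            if crow["participant_id"] != prow["participant_id"]:
                continue
            if np.isnan(ages[c_idx]):
                continue
            j = scheme.band_of(ages[c_idx])
            num[i, j] += w
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / denom[:, None]
    out[denom == 0] = np.nan
    return out


def test_single_participant_row_arithmetic():
    p = make_participant("P1", age=10)
    contacts = [make_contact("P1", age=12) for _ in range(3)]
    survey = Survey.from_records([p], contacts)
    m = mean_contact_matrix(survey)
    assert m.values[2, 2] == 3.0
    row = m.values[2].copy()
    row[2] = 0
    assert np.all(row == 0)
    assert np.all(np.isnan(m.values[[i for i in range(14) if i != 2]]))


def test_weighted_mean_of_two_participants():
    """Weights (1, 3), contact counts into band j of (4, 0):
    c_ij = (1*4 + 3*0) / (1 + 3) = 1.0."""
    p1 = make_participant("P1", age=30)
    p2 = make_participant("P2", age=32)
    contacts = [make_contact("P1", age=10) for _ in range(4)]
    survey = Survey.from_records([p1, p2], contacts)
    m = mean_contact_matrix(survey, weights=np.array([1.0, 3.0]))
    assert m.values[6, 2] == pytest.approx(1.0)


def test_high_intensity_filter_keeps_physical_or_long():
    """A physical <5 min contact passes; a non-physical <5 min contact does
    not; any >= 15 min contact passes."""
    p = make_participant("P1", age=30)
    contacts = [
        make_contact("P1", age=30, physical=True, duration_cat="lt5min"),
        make_contact("P1", age=30, physical=False, duration_cat="lt5min"),
        make_contact("P1", age=30, physical=False, duration_cat="15to59min"),
        make_contact("P1", age=30, physical=False, duration_cat="5to14min"),
    ]
    survey = Survey.from_records([p], contacts)
    m = mean_contact_matrix(survey, contact_filter=ContactFilter(high_intensity=True))
    assert m.values[6, 6] == 2.0


def test_reciprocity_hand_example():
    """2-band case: c = [[0,2],[0,0]], N = (100, 50) ->
    c'_01 = (2*100 + 0*50)/(2*100) = 1, c'_10 = (0 + 2*100)/(2*50) = 2."""
    pop = PopulationTable(TWO_BANDS, "all", np.array([100.0, 50.0]))
    p = make_participant("P1", age=10)
    m = mean_contact_matrix(Survey.from_records([p]), scheme=TWO_BANDS)
    m.values = np.array([[0.0, 2.0], [0.0, 0.0]])
    m.n_participants = np.array([1, 1])
    adj = reciprocity_adjust(m, pop)
    assert np.allclose(adj.values, [[0.0, 1.0], [2.0, 0.0]])
    assert adj.adjusted


def test_reciprocity_fixed_point_identity_conservation_idempotence():
    """On random matrices/populations: the adjusted matrix satisfies
    c'_ij N_i = c'_ji N_j, conserves total contact events, is idempotent,
    and leaves already-balanced matrices untouched."""
    rng = np.random.default_rng(2024)
    for _ in range(300):
        k = int(rng.integers(2, 15))
        scheme = AgeBandScheme("r", tuple(range(0, 5 * k, 5)))
        N = rng.uniform(10, 1e5, size=k)
        pop = PopulationTable(scheme, "all", N)
        c = rng.gamma(1.0, 2.0, size=(k, k))
        m = _raw_matrix(c, scheme)
        adj = reciprocity_adjust(m, pop)
        lhs = adj.values * N[:, None]
        assert np.allclose(lhs, lhs.T, rtol=1e-9)
        assert np.isclose(
            (adj.values * N[:, None]).sum(), (c * N[:, None]).sum(), rtol=1e-9
        )
        twice = reciprocity_adjust(adj, pop)
        assert np.allclose(twice.values, adj.values, rtol=1e-12)
        # a balanced input is a fixed point
        balanced = _raw_matrix(adj.values.copy(), scheme)
        assert np.allclose(
            reciprocity_adjust(balanced, pop).values, adj.values, rtol=1e-12
        )


def _raw_matrix(values, scheme):
    p = make_participant("P1", age=1)
    m = mean_contact_matrix(Survey.from_records([p]), scheme=scheme)
    m.values = values
    m.n_participants = np.ones(scheme.n_bands, dtype=int)
    return m


def test_missing_row_filled_from_transpose_only():
    pop = PopulationTable(TWO_BANDS, "all", np.array([200.0, 100.0]))
    m = _raw_matrix(np.array([[1.0, 3.0], [np.nan, np.nan]]), TWO_BANDS)
    adj = reciprocity_adjust(m, pop)
    # c'_10 from transposed term alone: c_01 N_0 / N_1 = 3*200/100 = 6
    assert adj.values[1, 0] == pytest.approx(6.0)
    assert np.isnan(adj.values[1, 1])
    # the filled cell restores the reciprocity identity
    assert adj.values[0, 1] * 200 == pytest.approx(adj.values[1, 0] * 100)


def test_matches_brute_force_tally_on_small_surveys():
    rng = np.random.default_rng(99)
    for trial in range(5):
        n = int(rng.integers(3, 20))
        participants = [
            make_participant(f"P{i}", age=int(rng.integers(0, 90))) for i in range(n)
        ]
        contacts = []
        for i in range(n):
            for _ in range(int(rng.integers(0, 6))):
                if rng.random() < 0.15:
                    lo = float(rng.integers(0, 80))
                    contacts.append(
                        make_contact(f"P{i}", age=None, contact_age_exact=None,
                                     contact_age_range=(lo, lo + rng.integers(0, 10)))
                    )
                elif rng.random() < 0.1:
                    contacts.append(
                        make_contact(f"P{i}", age=None, contact_age_exact=None)
                    )
                else:
                    contacts.append(make_contact(f"P{i}", age=int(rng.integers(0, 90))))
        survey = Survey.from_records(participants, contacts)
        w = rng.uniform(0.2, 3.0, size=n)
        m = mean_contact_matrix(survey, weights=w)
        expected = brute_force_matrix(survey, w, MATRIX_SCHEME)
        assert np.allclose(
            np.nan_to_num(m.values, nan=-1), np.nan_to_num(expected, nan=-1)
        )


def test_supplementary_contacts_never_enter_matrices(tiny_survey):
    m = mean_contact_matrix(tiny_survey)
    # total tallied contacts = diary contacts with a resolvable age (5 here,
    # one via range); supplementary counts (3) are excluded
    total_contacts = np.nansum(m.values * m.n_participants[:, None])
    assert total_contacts == pytest.approx(5.0)


def test_single_setting_survey_partitions_cleanly():
    pop = PopulationTable(MATRIX_SCHEME, "all", np.full(14, 1000.0))
    p = make_participant("P1", age=30)
    contacts = [make_contact("P1", age=35, settings=frozenset({"work"}))] * 3
    survey = Survey.from_records([p], contacts)
    mats = setting_stratified_matrices(survey, population=pop, adjust=False)
    assert np.nansum(mats["work"].values) == 3.0
    for label in ("home_household", "home_nonhousehold", "school",
                  "other_transport_leisure"):
        assert np.nansum(mats[label].values) == 0.0
    assert np.nansum(mats["all"].values) == 3.0


def test_multi_setting_attribution_each_vs_exclusive():
    pop = PopulationTable(MATRIX_SCHEME, "all", np.full(14, 1000.0))
    p = make_participant("P1", age=30)
    c = make_contact("P1", age=8, settings=frozenset({"home_household", "school"}))
    survey = Survey.from_records([p], [c])
    each = setting_stratified_matrices(survey, population=pop, adjust=False)
    assert np.nansum(each["home_household"].values) == 1.0
    assert np.nansum(each["school"].values) == 1.0
    assert np.nansum(each["all"].values) == 1.0  # counted once overall
    excl = setting_stratified_matrices(
        survey, population=pop, adjust=False, attribution="exclusive"
    )
    assert np.nansum(excl["home_household"].values) == 0.0
    assert np.nansum(excl["school"].values) == 0.0
    assert np.nansum(excl["multiple"].values) == 1.0


def test_school_matrix_support_confined_to_school_ages(recovery_pair):
    """The generator restricts school mixing to bands covering ages ~3-24;
    the estimated school matrix must have no mass outside those bands."""
    survey, truth = recovery_pair
    pop = truth.population["all"]
    mats = setting_stratified_matrices(survey, population=pop, adjust=False)
    school = np.nan_to_num(mats["school"].values)
    # bands 5+ start at age 25: outside the generator's school support
    assert school[5:, :].sum() == 0.0
    assert school[:, 5:].sum() == 0.0
    assert school[:5, :5].sum() > 0.0


def test_adjusted_total_matrix_recovers_ground_truth(recovery_pair):
    """With relegation off and neutral covariates the adjusted matrix is an
    unbiased estimate of the generating matrix (cells within 4 SE at this n;
    the tighter 3-SE bound is asserted at the larger acceptance-test n)."""
    survey, truth = recovery_pair
    pop = truth.population["all"]
    m = mean_contact_matrix(survey, population=pop)
    adj = reciprocity_adjust(m, pop)
    se = _adjusted_cell_se(survey, pop)
    z = (adj.values - truth.true_matrix.values) / np.maximum(se, 1e-12)
    assert np.nanmax(np.abs(z)) < 4.0


def _adjusted_cell_se(survey, pop, scheme=MATRIX_SCHEME):
    """Delta-method Monte-Carlo SE of the adjusted cell estimates."""
    import pandas as pd

    pb = scheme.bands_of(survey.participants["age"].to_numpy())
    ages = resolve_contact_ages(survey)
    ok = ~np.isnan(ages)
    cb = scheme.bands_of(ages[ok])
    pid2idx = pd.Series(
        np.arange(survey.n_participants), index=survey.participants["participant_id"]
    )
    cpi = pid2idx.loc[survey.diary_contacts.loc[ok, "participant_id"]].to_numpy()
    k = scheme.n_bands
    counts = np.zeros((survey.n_participants, k))
    np.add.at(counts, (cpi, cb), 1.0)
    se = np.zeros((k, k))
    for i in range(k):
        sub = counts[pb == i]
        se[i] = sub.std(axis=0, ddof=1) / np.sqrt(len(sub))
    N = pop.N
    return np.sqrt((se * N[:, None]) ** 2 + (se.T * N[None, :]) ** 2) / (2 * N[:, None])
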