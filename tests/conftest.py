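import numpy as np
import pytest

from contactweave import (
    DiaryContact,
    GeneratorConfig,
    Participant,
    SupplementaryContacts,
    Survey,
    generate_survey,
)


def make_participant(pid="P1", age=30, **kw) -> Participant:
    defaults = dict(
        participant_id=pid,
        age=age,
        sex="female",
        residence="urban",
        district_id="U1",
        occupation="agriculture",
        household_size=4,
        n_rooms="2",
        diary_day_type="weekday",
        employment_status="employed",
    )
    defaults.update(kw)
    return Participant(**defaults)


def make_contact(pid="P1", age=25, **kw) -> DiaryContact:
    defaults = dict(
        participant_id=pid,
        settings=frozenset({"home_household"}),
        physical=True,
        duration_cat="15to59min",
        contact_age_exact=age,
    )
    defaults.update(kw)
    return DiaryContact(**defaults)


@pytest.fixture
def tiny_survey() -> Survey:
    """Three participants, five diary contacts, one supplementary record."""
    participants = [
        make_participant("P1", age=10, occupation="student",
                         employment_status="non_working_age"),
        make_participant("P2", age=34, sex="male"),
        make_participant("P3", age=70, residence="rural", occupation="retired",
                         employment_status="non_working_age"),
    ]
    contacts = [
        make_contact("P1", age=12, settings=frozenset({"school"}),
                     duration_cat="1to4h", physical=False,
                     frequency_cat="daily", distance_cat="lt1km"),
        make_contact("P1", age=38, duration_cat="gt4h"),
        make_contact("P2", age=None, contact_age_exact=None,
                     contact_age_range=(30.0, 39.0), physical=False,
                     duration_cat="lt5min", distance_cat="1to9km"),
        make_contact("P2", age=5, settings=frozenset({"home_household", "school"})),
        make_contact("P3", age=68, settings=frozenset({"leisure"}),
                     duration_cat="5to14min", distance_cat="gt9km"),
    ]
    supplementary = [
        SupplementaryContacts("P2", {("0-4", True): 1, ("16-64", False): 2}),
    ]
    return Survey.from_records(participants, contacts, supplementary)


@pytest.fixture(scope="session")
def synthetic_pair():
    """A moderately sized generated survey with its ground truth (shared
    across tests; treat as read-only)."""
    cfg = GeneratorConfig(n_participants=1120, seed=42)
    return generate_survey(cfg)


@pytest.fixture(scope="session")
def recovery_pair():
    """Clean-conditions generated survey for recovery checks: no relegation,
    no covariate degree effects, exact ages only."""
    cfg = GeneratorConfig(
        n_participants=2240,
        seed=7,
        relegation_prob_physical=0.0,
        relegation_prob_nonphysical=0.0,
        degree_coefficients={},
        multi_setting_prob=0.0,
        age_range_prob=0.0,
    )
    return generate_survey(cfg)


def balanced_survey(n_per_stratum=1, seed=0) -> Survey:
    """A survey perfectly balanced over the 7 x 2 x 2 quota design."""
    rng = np.random.default_rng(seed)
    band_ages = [(0, 5), (6, 12), (13, 19), (20, 29), (30, 39), (40, 59), (60, 80)]
    rows = []
    pid = 0
    for lo, hi in band_ages:
        for sex in ("male", "female"):
            for res in ("urban", "rural"):
                for _ in range(n_per_stratum):
                    age = int(rng.integers(lo, hi + 1))
                    rows.append(
                        make_participant(
                            f"B{pid:05d}",
                            age=age,
                            sex=sex,
                            residence=res,
                            occupation="agriculture" if age >= 15 else "child_at_home",
                            employment_status=(
                                "employed" if 15 <= age < 65 else "non_working_age"
                            ),
                        )
                    )
                    pid += 1
    return Survey.from_records(rows)
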