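"""Containers and CSV readers/writers for two-table contact-survey data.

The layout follows the conventional diary-survey convention: one row per
*participant* (demographics plus diary metadata), one row per *diary contact*
(keyed by participant id, with contactee age or age range, settings, duration
band, physicality, frequency and distance band), and one long-form row per
*supplementary* contact-count cell (coarse age band x physical/non-physical).

Supplementary contacts are recalled omissions reported only as counts in four
coarse age bands; they carry no setting or duration and are therefore used in
degree summaries but never in mixing matrices.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .schemes import COARSE_BANDS

__all__ = [
    "SEXES",
    "RESIDENCES",
    "OCCUPATIONS",
    "DAY_TYPES",
    "EMPLOYMENT_STATUSES",
    "SETTINGS",
    "DURATION_CATS",
    "DISTANCE_CATS",
    "N_ROOMS_LEVELS",
    "Participant",
    "DiaryContact",
    "SupplementaryContacts",
    "PopulationTable",
    "Survey",
    "DialectConfig",
    "load_survey",
    "write_survey",
    "resolve_contact_ages",
]

SEXES = ("male", "female")
RESIDENCES = ("urban", "rural")
#: The eleven occupation categories used as a regression covariate.
OCCUPATIONS = (
    "child_at_home",
    "preschooler",
    "student",
    "professional",
    "shop_worker",
    "manual_labour",
    "agriculture",
    "housewife",
    "retired",
    "unemployed",
    "other",
)
DAY_TYPES = ("weekday", "weekend")
EMPLOYMENT_STATUSES = ("non_working_age", "employed", "unemployed")
#: Contact settings; home is split into household vs non-household (visitor)
#: contacts, and a diary line may report several settings at once.
SETTINGS = (
    "home_household",
    "home_nonhousehold",
    "work",
    "school",
    "transport",
    "leisure",
    "other",
)
#: Ordinal duration bands; the top band is right-truncated at 4 h.
DURATION_CATS = ("lt5min", "5to14min", "15to59min", "1to4h", "gt4h")
DISTANCE_CATS = ("lt1km", "1to9km", "gt9km")
N_ROOMS_LEVELS = ("1", "2", "3", "4", "5+")
#: Default frequency-of-contact levels (most to least regular); overridable
#: through the dialect config since surveys word these differently.
FREQUENCY_CATS = ("daily", "weekly", "monthly", "few_times_year", "first_time")

PARTICIPANT_COLUMNS = [
    "participant_id",
    "age",
    "sex",
    "residence",
    "district_id",
    "occupation",
    "household_size",
    "n_rooms",
    "diary_day_type",
    "employment_status",
    "diary_complete_selfreport",
]
CONTACT_COLUMNS = [
    "participant_id",
    "contact_age_exact",
    "contact_age_min",
    "contact_age_max",
    "settings",
    "physical",
    "duration_cat",
    "frequency_cat",
    "distance_cat",
]
SUPPLEMENTARY_COLUMNS = ["participant_id", "band", "physical", "count"]


@dataclass
class Participant:
    participant_id: str
    age: int
    sex: str
    residence: str
    district_id: str
    occupation: str
    household_size: int
    n_rooms: str
    diary_day_type: str
    employment_status: str
    diary_complete_selfreport: bool = True

    def check(self) -> list[str]:
        """Invariant violations as human-readable messages (empty = valid)."""
        out = []
        if not 0 <= self.age <= 120:
            out.append(f"age {self.age} outside [0, 120]")
        if self.sex not in SEXES:
            out.append(f"unknown sex {self.sex!r}")
        if self.residence not in RESIDENCES:
            out.append(f"unknown residence {self.residence!r}")
        if self.occupation not in OCCUPATIONS:
            out.append(f"unknown occupation {self.occupation!r}")
        if self.household_size < 1:
            out.append(f"household_size {self.household_size} < 1")
        if self.n_rooms not in N_ROOMS_LEVELS:
            out.append(f"unknown n_rooms level {self.n_rooms!r}")
        if self.diary_day_type not in DAY_TYPES:
            out.append(f"unknown diary_day_type {self.diary_day_type!r}")
        if self.employment_status not in EMPLOYMENT_STATUSES:
            out.append(f"unknown employment_status {self.employment_status!r}")
        return out


@dataclass
class DiaryContact:
    """One diary line: a two-way conversation in physical presence, or
    skin-to-skin contact, during the 24-h diary window.

    Exactly one of ``contact_age_exact`` and the (min, max) range is given.
    """

    participant_id: str
    settings: frozenset[str]
    physical: bool
    duration_cat: str
    contact_age_exact: float | None = None
    contact_age_range: tuple[float, float] | None = None
    frequency_cat: str | None = None
    distance_cat: str | None = None

    def check(self) -> list[str]:
        out = []
        has_exact = self.contact_age_exact is not None
        has_range = self.contact_age_range is not None
        if has_exact and has_range:
            out.append("both exact age and age range set")
        if has_range:
            lo, hi = self.contact_age_range
            if lo > hi:
                out.append(f"age range min {lo} > max {hi}")
        if not self.settings:
            out.append("empty settings")
        if not self.settings <= set(SETTINGS):
            out.append(f"unknown settings {sorted(set(self.settings) - set(SETTINGS))}")
        if self.duration_cat not in DURATION_CATS:
            out.append(f"unknown duration_cat {self.duration_cat!r}")
        if self.distance_cat is not None and self.distance_cat not in DISTANCE_CATS:
            out.append(f"unknown distance_cat {self.distance_cat!r}")
        return out


@dataclass
class SupplementaryContacts:
    """Recalled extra contacts for one participant, as counts per coarse age
    band (0-4, 5-15, 16-64, 65+) x physical/non-physical."""

    participant_id: str
    counts: dict[tuple[str, bool], int] = field(default_factory=dict)

    def check(self) -> list[str]:
        out = []
        for (band, _phys), n in self.counts.items():
            if band not in COARSE_BANDS:
                out.append(f"unknown coarse band {band!r}")
            if n < 0:
                out.append(f"negative count {n} in band {band}")
        return out

    @property
    def total(self) -> int:
        return int(sum(self.counts.values()))


@dataclass(frozen=True)
class PopulationTable:
    """Population size per age band for one residence stratum.

    ``N[i]`` is the population of band ``i`` of ``scheme`` — the N_i entering
    the reciprocity adjustment of mixing matrices.
    """

    scheme: "object"  # AgeBandScheme; untyped to avoid a circular import
    stratum: str
    N: np.ndarray

    def __post_init__(self) -> None:
        n = np.asarray(self.N, dtype=float)
        if n.shape != (self.scheme.n_bands,):
            raise ValueError("N must have one entry per band")
        if np.any(n <= 0):
            raise ValueError("all band populations must be > 0")
        object.__setattr__(self, "N", n)

    def combined_with(self, other: "PopulationTable") -> "PopulationTable":
        if other.scheme.breaks != self.scheme.breaks:
            raise ValueError("schemes differ")
        return PopulationTable(self.scheme, "all", self.N + other.N)


class Survey:
    """A contact survey: participants, diary contacts and supplementary
    contact counts, held as pandas DataFrames with canonical columns."""

    def __init__(
        self,
        participants: pd.DataFrame,
        diary_contacts: pd.DataFrame,
        supplementary: pd.DataFrame | None = None,
        parse_issues: list[str] | None = None,
    ):
        self.participants = participants.reset_index(drop=True)
        self.diary_contacts = diary_contacts.reset_index(drop=True)
        if supplementary is None:
            supplementary = pd.DataFrame(columns=SUPPLEMENTARY_COLUMNS)
        self.supplementary = supplementary.reset_index(drop=True)
        #: rows that could not be parsed at load time, kept for inspection
        self.parse_issues = parse_issues or []
        self._check_foreign_keys()

    def _check_foreign_keys(self) -> None:
        ids = set(self.participants["participant_id"])
        for name, df in (
            ("diary_contacts", self.diary_contacts),
            ("supplementary", self.supplementary),
        ):
            if len(df) == 0:
                continue
            unknown = sorted(set(df["participant_id"]) - ids)
            if unknown:
                raise ValueError(
                    f"{name} reference unknown participant ids: {unknown}"
                )

    # -- construction -----------------------------------------------------
    @classmethod
    def from_records(
        cls,
        participants: Sequence[Participant],
        diary_contacts: Sequence[DiaryContact] = (),
        supplementary: Sequence[SupplementaryContacts] = (),
    ) -> "Survey":
        pdf = pd.DataFrame(
            [
                {
                    "participant_id": p.participant_id,
                    "age": int(p.age),
                    "sex": p.sex,
                    "residence": p.residence,
                    "district_id": p.district_id,
                    "occupation": p.occupation,
                    "household_size": int(p.household_size),
                    "n_rooms": p.n_rooms,
                    "diary_day_type": p.diary_day_type,
                    "employment_status": p.employment_status,
                    "diary_complete_selfreport": bool(p.diary_complete_selfreport),
                }
                for p in participants
            ],
            columns=PARTICIPANT_COLUMNS,
        )
        crows = []
        for c in diary_contacts:
            lo, hi = (c.contact_age_range or (np.nan, np.nan))
            crows.append(
                {
                    "participant_id": c.participant_id,
                    "contact_age_exact": (
                        np.nan if c.contact_age_exact is None else float(c.contact_age_exact)
                    ),
                    "contact_age_min": lo,
                    "contact_age_max": hi,
                    "settings": frozenset(c.settings),
                    "physical": bool(c.physical),
                    "duration_cat": c.duration_cat,
                    "frequency_cat": c.frequency_cat,
                    "distance_cat": c.distance_cat,
                }
            )
        cdf = pd.DataFrame(crows, columns=CONTACT_COLUMNS)
        srows = []
        for s in supplementary:
            for (band, phys), n in sorted(
                s.counts.items(), key=lambda kv: (COARSE_BANDS.index(kv[0][0]), kv[0][1])
            ):
                srows.append(
                    {
                        "participant_id": s.participant_id,
                        "band": band,
                        "physical": bool(phys),
                        "count": int(n),
                    }
                )
        sdf = pd.DataFrame(srows, columns=SUPPLEMENTARY_COLUMNS)
        return cls(pdf, cdf, sdf)

    # -- accessors --------------------------------------------------------
    @property
    def n_participants(self) -> int:
        return len(self.participants)

    @property
    def n_diary_contacts(self) -> int:
        return len(self.diary_contacts)

    def supplementary_totals(self) -> pd.Series:
        """Total supplementary contact count per participant id (all
        participants, zero-filled)."""
        base = pd.Series(
            0, index=pd.Index(self.participants["participant_id"], name="participant_id")
        )
        if len(self.supplementary):
            tot = self.supplementary.groupby("participant_id")["count"].sum()
            base = base.add(tot, fill_value=0).reindex(base.index)
        return base.astype(int)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"Survey(n_participants={self.n_participants}, "
            f"n_diary_contacts={self.n_diary_contacts}, "
            f"n_supplementary_rows={len(self.supplementary)})"
        )


# ---------------------------------------------------------------------------
# dialect handling


class DialectConfig:
    """Mapping from a file's column names and level labels onto the canonical
    ones.

    ``columns`` maps table name -> {canonical column: actual column};
    ``levels`` maps canonical field -> {actual label: canonical level}.
    An empty config is the canonical dialect itself.
    """

    def __init__(
        self,
        columns: Mapping[str, Mapping[str, str]] | None = None,
        levels: Mapping[str, Mapping[str, str]] | None = None,
        settings_separator: str = "|",
    ):
        self.columns = {k: dict(v) for k, v in (columns or {}).items()}
        self.levels = {k: dict(v) for k, v in (levels or {}).items()}
        self.settings_separator = settings_separator

    @classmethod
    def from_yaml(cls, path: str | Path) -> "DialectConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(
            columns=raw.get("columns"),
            levels=raw.get("levels"),
            settings_separator=raw.get("settings_separator", "|"),
        )

    def rename(self, table: str, df: pd.DataFrame) -> pd.DataFrame:
        mapping = {v: k for k, v in self.columns.get(table, {}).items()}
        return df.rename(columns=mapping)

    def canon_level(self, field_name: str, value):
        if pd.isna(value):
            return value
        table = self.levels.get(field_name)
        if table and value in table:
            return table[value]
        return value


def _require_columns(df: pd.DataFrame, cols: Iterable[str], table: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{table} file missing required column(s): {missing}")


def load_survey(
    participants_path: str | Path,
    contacts_path: str | Path,
    supplementary_path: str | Path | None = None,
    dialect_config: DialectConfig | str | Path | None = None,
) -> Survey:
    """Read the canonical CSV trio (participants, contacts, supplementary).

    Unparseable rows are collected on ``Survey.parse_issues`` rather than
    silently dropped; missing required columns and unresolvable participant
    ids are hard errors.
    """
    if dialect_config is None:
        dialect = DialectConfig()
    elif isinstance(dialect_config, DialectConfig):
        dialect = dialect_config
    else:
        dialect = DialectConfig.from_yaml(dialect_config)

    issues: list[str] = []

    pdf = dialect.rename("participants", pd.read_csv(participants_path, dtype=str))
    _require_columns(
        pdf,
        [c for c in PARTICIPANT_COLUMNS if c != "diary_complete_selfreport"],
        "participants",
    )
    if "diary_complete_selfreport" not in pdf.columns:
        pdf["diary_complete_selfreport"] = "True"
    for fld in ("sex", "residence", "occupation", "diary_day_type", "employment_status", "n_rooms"):
        pdf[fld] = pdf[fld].map(lambda v, f=fld: dialect.canon_level(f, v))
    pdf["age"] = pd.to_numeric(pdf["age"], errors="coerce")
    pdf["household_size"] = pd.to_numeric(pdf["household_size"], errors="coerce")
    bad = pdf["age"].isna() | pdf["household_size"].isna()
    for idx in pdf.index[bad]:
        issues.append(
            f"participants row {idx} (id={pdf.at[idx, 'participant_id']}): "
            "non-numeric age or household_size"
        )
    pdf = pdf[~bad].copy()
    pdf["age"] = pdf["age"].astype(int)
    pdf["household_size"] = pdf["household_size"].astype(int)
    pdf["diary_complete_selfreport"] = pdf["diary_complete_selfreport"].map(
        lambda v: str(v).strip().lower() in ("true", "1", "yes")
    )
    pdf = pdf[PARTICIPANT_COLUMNS]

    cdf = dialect.rename("contacts", pd.read_csv(contacts_path, dtype=str))
    _require_columns(
        cdf, ["participant_id", "settings", "physical", "duration_cat"], "contacts"
    )
    for col in ("contact_age_exact", "contact_age_min", "contact_age_max",
                "frequency_cat", "distance_cat"):
        if col not in cdf.columns:
            cdf[col] = np.nan
    for fld in ("duration_cat", "frequency_cat", "distance_cat"):
        cdf[fld] = cdf[fld].map(lambda v, f=fld: dialect.canon_level(f, v))
    sep = dialect.settings_separator
    cdf["settings"] = cdf["settings"].map(
        lambda s: frozenset(
            dialect.canon_level("setting", tok.strip())
            for tok in str(s).split(sep)
            if tok.strip()
        )
        if not pd.isna(s)
        else frozenset()
    )
    for col in ("contact_age_exact", "contact_age_min", "contact_age_max"):
        cdf[col] = pd.to_numeric(cdf[col], errors="coerce")
    cdf["physical"] = cdf["physical"].map(
        lambda v: str(v).strip().lower() in ("true", "1", "yes")
    )
    bad = cdf["settings"].map(len) == 0
    bad |= ~cdf["duration_cat"].isin(DURATION_CATS)
    for idx in cdf.index[bad]:
        issues.append(
            f"contacts row {idx} (participant={cdf.at[idx, 'participant_id']}): "
            "empty settings or unknown duration category"
        )
    cdf = cdf[~bad][CONTACT_COLUMNS].copy()

    if supplementary_path is not None:
        sdf = dialect.rename("supplementary", pd.read_csv(supplementary_path, dtype=str))
        _require_columns(sdf, SUPPLEMENTARY_COLUMNS, "supplementary")
        sdf["band"] = sdf["band"].map(lambda v: dialect.canon_level("band", v))
        sdf["physical"] = sdf["physical"].map(
            lambda v: str(v).strip().lower() in ("true", "1", "yes")
        )
        sdf["count"] = pd.to_numeric(sdf["count"], errors="coerce")
        bad = sdf["count"].isna() | ~sdf["band"].isin(COARSE_BANDS)
        for idx in sdf.index[bad]:
            issues.append(f"supplementary row {idx}: bad band or count")
        sdf = sdf[~bad][SUPPLEMENTARY_COLUMNS].copy()
        sdf["count"] = sdf["count"].astype(int)
    else:
        sdf = None

    return Survey(pdf, cdf, sdf, parse_issues=issues)


def _fmt_age(v) -> str:
    if pd.isna(v):
        return ""
    f = float(v)
    return str(int(f)) if f == int(f) else repr(f)


def write_survey(survey: Survey, out_dir: str | Path) -> dict[str, Path]:
    """Write the canonical CSV trio; deterministic formatting so that a
    load/write cycle is byte-stable."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "participants": out / "participants.csv",
        "contacts": out / "contacts.csv",
        "supplementary": out / "supplementary.csv",
    }
    survey.participants.to_csv(paths["participants"], index=False)

    cdf = survey.diary_contacts.copy()
    cdf["settings"] = cdf["settings"].map(lambda s: "|".join(sorted(s)))
    for col in ("contact_age_exact", "contact_age_min", "contact_age_max"):
        cdf[col] = cdf[col].map(_fmt_age)
    for col in ("frequency_cat", "distance_cat"):
        cdf[col] = cdf[col].fillna("")
    cdf.to_csv(paths["contacts"], index=False)

    survey.supplementary.to_csv(paths["supplementary"], index=False)
    return paths


def resolve_contact_ages(
    survey: Survey,
    mode: str = "midpoint",
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Point age per diary contact; NaN where no age was reported.

    Ranges resolve to ``floor((min+max)/2)`` by default, or to a uniform
    integer draw from [min, max] under ``mode='uniform'`` (seeded ``rng``
    required).
    """
    cdf = survey.diary_contacts
    ages = cdf["contact_age_exact"].to_numpy(dtype=float).copy()
    lo = cdf["contact_age_min"].to_numpy(dtype=float)
    hi = cdf["contact_age_max"].to_numpy(dtype=float)
    has_range = np.isnan(ages) & ~np.isnan(lo) & ~np.isnan(hi)
    if mode == "midpoint":
        ages[has_range] = np.floor((lo[has_range] + hi[has_range]) / 2.0)
    elif mode == "uniform":
        if rng is None:
            raise ValueError("uniform mode requires a seeded rng")
        draws = rng.integers(
            lo[has_range].astype(int), hi[has_range].astype(int) + 1
        )
        ages[has_range] = draws
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return ages
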