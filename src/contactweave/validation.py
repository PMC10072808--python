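"""Survey validation against domain invariants and the quota sampling design."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .schemes import SAMPLING_SCHEME, AgeBandScheme
from .survey import (
    DiaryContact,
    Participant,
    RESIDENCES,
    SEXES,
    SupplementaryContacts,
    Survey,
)

__all__ = ["SamplingDesign", "ValidationReport", "validate_survey"]


@dataclass(frozen=True)
class SamplingDesign:
    """Quota sampling design: a fixed recruitment target per age band x sex x
    residence stratum."""

    scheme: AgeBandScheme = SAMPLING_SCHEME
    quota_per_stratum: int = 72

    @property
    def n_strata(self) -> int:
        return self.scheme.n_bands * len(SEXES) * len(RESIDENCES)

    @property
    def target_total(self) -> int:
        return self.n_strata * self.quota_per_stratum


@dataclass
class ValidationReport:
    """Findings from validating a survey: hard errors, warnings, and the
    achieved-vs-target quota table.

    A survey with no errors is loadable by every downstream stage.
    """

    errors: list[tuple[str, str, str]] = field(default_factory=list)
    warnings: list[tuple[str, str, str]] = field(default_factory=list)
    quota_table: pd.DataFrame | None = None

    @property
    def ok(self) -> bool:
        return not self.errors

    def summary(self) -> str:
        lines = [
            f"validation: {len(self.errors)} error(s), "
            f"{len(self.warnings)} warning(s)"
        ]
        for loc, rule, msg in self.errors[:20]:
            lines.append(f"  ERROR [{rule}] {loc}: {msg}")
        if self.quota_table is not None:
            met = (self.quota_table["achieved"] == self.quota_table["target"]).all()
            lines.append(f"quota design {'met exactly' if met else 'NOT met'}")
        return "\n".join(lines)


def _participant_record(row) -> Participant:
    return Participant(
        participant_id=row.participant_id,
        age=row.age,
        sex=row.sex,
        residence=row.residence,
        district_id=row.district_id,
        occupation=row.occupation,
        household_size=row.household_size,
        n_rooms=row.n_rooms,
        diary_day_type=row.diary_day_type,
        employment_status=row.employment_status,
        diary_complete_selfreport=row.diary_complete_selfreport,
    )


def validate_survey(
    survey: Survey, sampling_design: SamplingDesign | None = None
) -> ValidationReport:
    """Check every record against its type invariants and tabulate achieved
    recruitment per quota stratum.

    Findings are carried on the report; nothing raises here.
    """
    design = sampling_design or SamplingDesign()
    report = ValidationReport()

    for row in survey.participants.itertuples(index=False):
        msgs = _participant_record(row).check()
        for m in msgs:
            report.errors.append((f"participant {row.participant_id}", "participant", m))

    for i, row in enumerate(survey.diary_contacts.itertuples(index=False)):
        has_exact = not pd.isna(row.contact_age_exact)
        has_range = not (pd.isna(row.contact_age_min) or pd.isna(row.contact_age_max))
        rng = (
            (float(row.contact_age_min), float(row.contact_age_max))
            if has_range
            else None
        )
        rec = DiaryContact(
            participant_id=row.participant_id,
            settings=frozenset(row.settings),
            physical=bool(row.physical),
            duration_cat=row.duration_cat,
            contact_age_exact=float(row.contact_age_exact) if has_exact else None,
            contact_age_range=rng,
            frequency_cat=None if pd.isna(row.frequency_cat) else row.frequency_cat,
            distance_cat=None if pd.isna(row.distance_cat) else row.distance_cat,
        )
        loc = f"contact row {i} (participant {row.participant_id})"
        for m in rec.check():
            report.errors.append((loc, "diary_contact", m))
        if not (has_exact or has_range):
            report.warnings.append((loc, "diary_contact", "no contactee age reported"))

    if len(survey.supplementary):
        dup = survey.supplementary.duplicated(["participant_id", "band", "physical"])
        for idx in survey.supplementary.index[dup]:
            report.errors.append(
                (
                    f"supplementary row {idx}",
                    "supplementary",
                    "duplicate (participant, band, physical) cell",
                )
            )
        for pid, grp in survey.supplementary.groupby("participant_id"):
            rec = SupplementaryContacts(
                pid,
                {
                    (r.band, bool(r.physical)): int(r.count)
                    for r in grp.itertuples(index=False)
                },
            )
            for m in rec.check():
                report.errors.append((f"supplementary {pid}", "supplementary", m))

    # quota table: achieved vs target per age band x sex x residence stratum
    pdf = survey.participants
    valid_age = (pdf["age"] >= 0) & (pdf["age"] <= 120)
    bands = np.full(len(pdf), -1)
    bands[valid_age.to_numpy()] = design.scheme.bands_of(
        pdf.loc[valid_age, "age"].to_numpy()
    )
    tab = []
    for b in range(design.scheme.n_bands):
        for sex in SEXES:
            for res in RESIDENCES:
                mask = (bands == b) & (pdf["sex"] == sex) & (pdf["residence"] == res)
                tab.append(
                    {
                        "age_band": design.scheme.labels[b],
                        "sex": sex,
                        "residence": res,
                        "achieved": int(mask.sum()),
                        "target": design.quota_per_stratum,
                    }
                )
    report.quota_table = pd.DataFrame(tab)
    return report
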