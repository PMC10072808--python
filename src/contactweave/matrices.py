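"""Weighted age-structured contact matrices and the reciprocity adjustment.

The central quantity is the mixing matrix ``c_ij``: the mean number of
contacts a participant in age band *i* reports per diary day with contactees
in band *j*, estimated as a weighted mean over participants of band *i*.
Because every contact is mutual, the population totals must balance:
``c_ij N_i = c_ji N_j`` where ``N_i`` is the population of band *i*. Raw
survey matrices violate this (different bands are sampled and report with
different fidelity), so they are symmetrised by averaging the two directed
total-contact estimates:

    c'_ij = (c_ij N_i + c_ji N_j) / (2 N_i)

which enforces the balance exactly while conserving the overall number of
contact events. Supplementary (recalled, coarse-band) contacts never enter
matrices — their settings and precise ages are unknown.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .raking import WeightVector
from .schemes import MATRIX_SCHEME, AgeBandScheme
from .survey import DURATION_CATS, PopulationTable, Survey, resolve_contact_ages

__all__ = [
    "ContactMatrix",
    "ContactFilter",
    "SETTING_LABELS",
    "merge_setting",
    "mean_contact_matrix",
    "reciprocity_adjust",
    "setting_stratified_matrices",
]

#: The five analysis settings: home split by household membership, work,
#: school/college, and transport+leisure+other merged (each too rare alone).
SETTING_LABELS = (
    "home_household",
    "home_nonhousehold",
    "work",
    "school",
    "other_transport_leisure",
)

_MERGE = {
    "transport": "other_transport_leisure",
    "leisure": "other_transport_leisure",
    "other": "other_transport_leisure",
}

#: duration categories meeting the ">= 15 minutes" cutpoint
_LONG_DURATIONS = frozenset({"15to59min", "1to4h", "gt4h"})


def merge_setting(setting: str) -> str:
    """Map a raw diary setting onto the five analysis labels."""
    return _MERGE.get(setting, setting)


@dataclass(frozen=True)
class ContactFilter:
    """Predicate over diary contacts used to build restricted matrices.

    ``high_intensity`` keeps contacts that are physical OR at least 15
    minutes long. ``settings`` keeps contacts reporting at least one of the
    given raw settings. ``min_duration_cat`` keeps contacts at or above the
    given ordinal duration band.
    """

    settings: frozenset[str] | None = None
    physical_only: bool = False
    min_duration_cat: str | None = None
    high_intensity: bool = False

    def mask(self, contacts: pd.DataFrame) -> np.ndarray:
        keep = np.ones(len(contacts), dtype=bool)
        if self.settings is not None:
            sel = frozenset(self.settings)
            keep &= contacts["settings"].map(lambda s: bool(s & sel)).to_numpy()
        if self.physical_only:
            keep &= contacts["physical"].to_numpy(dtype=bool)
        if self.min_duration_cat is not None:
            lo = DURATION_CATS.index(self.min_duration_cat)
            keep &= contacts["duration_cat"].map(
                lambda d: DURATION_CATS.index(d) >= lo
            ).to_numpy()
        if self.high_intensity:
            phys = contacts["physical"].to_numpy(dtype=bool)
            long = contacts["duration_cat"].isin(_LONG_DURATIONS).to_numpy()
            keep &= phys | long
        return keep


@dataclass
class ContactMatrix:
    """An age-mixing matrix with its band scheme and provenance.

    ``values[i, j]`` is the (possibly reciprocity-adjusted) mean number of
    daily contacts of a band-*i* participant with band-*j* contactees; rows
    with no sampled participants are NaN, not zero.
    """

    scheme: AgeBandScheme
    values: np.ndarray
    n_participants: np.ndarray
    stratum: str = "all"
    setting_label: str = "all"
    adjusted: bool = False
    n_dropped_missing_age: int = 0
    population: PopulationTable | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        k = self.scheme.n_bands
        if v.shape != (k, k):
            raise ValueError(f"values must be {k}x{k}")
        with np.errstate(invalid="ignore"):
            if np.any(v[~np.isnan(v)] < 0):
                raise ValueError("contact rates must be non-negative")
        self.values = v
        self.n_participants = np.asarray(self.n_participants, dtype=int)

    def to_dataframe(self) -> pd.DataFrame:
        """Long form: one row per (band_i, band_j) cell."""
        k = self.scheme.n_bands
        ii, jj = np.meshgrid(range(k), range(k), indexing="ij")
        return pd.DataFrame(
            {
                "stratum": self.stratum,
                "setting": self.setting_label,
                "band_i": [self.scheme.labels[i] for i in ii.ravel()],
                "band_j": [self.scheme.labels[j] for j in jj.ravel()],
                "value": self.values.ravel(),
                "adjusted": self.adjusted,
                "n_i": self.n_participants[ii.ravel()],
            }
        )


def _weights_array(survey: Survey, weights) -> np.ndarray:
    if weights is None:
        return np.ones(survey.n_participants)
    if isinstance(weights, WeightVector):
        w = weights.weights
    else:
        w = np.asarray(weights, dtype=float)
    if len(w) != survey.n_participants:
        raise ValueError("weights not aligned to participants")
    return w


def mean_contact_matrix(
    survey: Survey,
    weights=None,
    scheme: AgeBandScheme = MATRIX_SCHEME,
    population: PopulationTable | None = None,
    contact_filter: ContactFilter | None = None,
    stratum: str = "all",
    age_resolution: str = "midpoint",
) -> ContactMatrix:
    """Weighted mean contact matrix (unadjusted) from diary contacts.

    ``c_ij = sum_{p in band i} w_p n_pj / sum_{p in band i} w_p`` with
    ``n_pj`` the participant's filtered diary contacts whose contactee falls
    in band *j*. Participants with zero contacts stay in the denominator.
    Contacts without any reported contactee age are dropped and counted on
    ``n_dropped_missing_age``. ``stratum`` of 'urban'/'rural' restricts the
    participant set; weights stay aligned to the full survey.
    """
    if survey.n_participants == 0:
        raise ValueError("empty survey")
    if population is not None and population.scheme.breaks != scheme.breaks:
        raise ValueError("population scheme does not match matrix scheme")
    w_all = _weights_array(survey, weights)

    pdf = survey.participants
    keep_p = np.ones(len(pdf), dtype=bool)
    if stratum != "all":
        keep_p = (pdf["residence"] == stratum).to_numpy()
    p_band = scheme.bands_of(pdf["age"].to_numpy())
    k = scheme.n_bands

    denom = np.zeros(k)
    np.add.at(denom, p_band[keep_p], w_all[keep_p])
    n_per_band = np.bincount(p_band[keep_p], minlength=k)

    cdf = survey.diary_contacts
    keep_c = np.ones(len(cdf), dtype=bool)
    if contact_filter is not None:
        keep_c &= contact_filter.mask(cdf)
    # restrict contacts to in-stratum participants
    pid_to_idx = pd.Series(np.arange(len(pdf)), index=pdf["participant_id"])
    c_pidx = pid_to_idx.loc[cdf["participant_id"]].to_numpy()
    keep_c &= keep_p[c_pidx]

    ages = resolve_contact_ages(survey, mode=age_resolution)
    missing = np.isnan(ages)
    n_dropped = int((keep_c & missing).sum())
    keep_c &= ~missing

    num = np.zeros((k, k))
    if keep_c.any():
        ci = p_band[c_pidx[keep_c]]
        cj = scheme.bands_of(ages[keep_c])
        np.add.at(num, (ci, cj), w_all[c_pidx[keep_c]])

    with np.errstate(invalid="ignore", divide="ignore"):
        values = num / denom[:, None]
    values[denom == 0, :] = np.nan

    return ContactMatrix(
        scheme=scheme,
        values=values,
        n_participants=n_per_band,
        stratum=stratum,
        setting_label="all",
        adjusted=False,
        n_dropped_missing_age=n_dropped,
        population=population,
    )


def reciprocity_adjust(
    matrix: ContactMatrix, population: PopulationTable
) -> ContactMatrix:
    """Symmetrise a raw matrix so band-level contact totals balance.

    Every fully observed cell pair becomes
    ``c'_ij = (c_ij N_i + c_ji N_j) / (2 N_i)``, after which
    ``c'_ij N_i = c'_ji N_j`` holds exactly and the total number of contact
    events ``sum_ij c_ij N_i`` is conserved. If ``c_ij`` is missing (no
    sampled participants in band *i*) but ``c_ji`` is observed, the cell is
    filled from the transposed term alone (``c_ji N_j / N_i``); if both
    directions are missing the cell stays missing. Adjusting an already
    balanced matrix is a no-op, and the operation is idempotent.
    """
    if population.scheme.breaks != matrix.scheme.breaks:
        raise ValueError("population scheme does not match matrix scheme")
    N = population.N
    c = matrix.values
    cT = c.T
    NiC = c * N[:, None]  # element (i,j): c_ij N_i
    NjCT = cT * N[None, :]  # element (i,j): c_ji N_j

    both = ~np.isnan(c) & ~np.isnan(cT)
    only_T = np.isnan(c) & ~np.isnan(cT)
    only_C = ~np.isnan(c) & np.isnan(cT)

    Ni = np.broadcast_to(N[:, None], c.shape)
    out = np.full_like(c, np.nan)
    out[both] = (NiC[both] + NjCT[both]) / (2.0 * Ni[both])
    # one-sided cells: keep the observed direction, mirror it into the
    # unobserved one, so the identity holds wherever anything was observed
    out[only_T] = NjCT[only_T] / Ni[only_T]
    out[only_C] = c[only_C]

    return replace(
        matrix, values=out, adjusted=True, population=population
    )


def setting_stratified_matrices(
    survey: Survey,
    weights=None,
    scheme: AgeBandScheme = MATRIX_SCHEME,
    population: PopulationTable | None = None,
    stratum: str = "all",
    contact_filter: ContactFilter | None = None,
    attribution: str = "each",
    adjust: bool = True,
) -> dict[str, ContactMatrix]:
    """One matrix per analysis setting (plus the all-settings matrix).

    Multi-setting contacts contribute once to *each* reported setting's
    matrix under ``attribution='each'`` (default); under ``'exclusive'``
    they instead fall into a separate ``'multiple'`` matrix, mirroring how
    descriptive displays bucket them. The ``'all'`` matrix always counts each
    contact exactly once. Matrices are reciprocity-adjusted against
    ``population`` unless ``adjust=False``.
    """
    if attribution not in ("each", "exclusive"):
        raise ValueError(f"unknown attribution {attribution!r}")
    if population is None and adjust:
        raise ValueError("population required for reciprocity adjustment")

    merged = survey.diary_contacts["settings"].map(
        lambda s: frozenset(merge_setting(x) for x in s)
    )

    out: dict[str, ContactMatrix] = {}

    def _build(mask: np.ndarray, label: str) -> ContactMatrix:
        sub = Survey(
            survey.participants,
            survey.diary_contacts[mask],
            survey.supplementary,
        )
        m = mean_contact_matrix(
            sub, weights, scheme, population, contact_filter, stratum
        )
        m.setting_label = label
        return reciprocity_adjust(m, population) if adjust else m

    for label in SETTING_LABELS:
        has = merged.map(lambda s, L=label: L in s).to_numpy()
        if attribution == "exclusive":
            has &= merged.map(len).to_numpy() == 1
        out[label] = _build(has, label)

    if attribution == "exclusive":
        multi = (merged.map(len) > 1).to_numpy()
        out["multiple"] = _build(multi, "multiple")

    m_all = mean_contact_matrix(
        survey, weights, scheme, population, contact_filter, stratum
    )
    out["all"] = reciprocity_adjust(m_all, population) if adjust else m_all
    return out
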