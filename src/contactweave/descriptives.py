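"""Descriptive summaries: degrees, contact hours, setting proportions,
intensity and distance profiles, and the chi-squared machinery behind the
reporting-method comparison.

A participant's *degree* is their total reported contacts for the diary day —
diary lines plus supplementary (recalled) counts. Contact hours sum the
midpoints of the reported duration bands over diary contacts only, right
truncated at 4 h.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .raking import WeightVector
from .schemes import COARSE_BANDS, REGRESSION_SCHEME, coarse_band_of_age
from .survey import DISTANCE_CATS, Survey, resolve_contact_ages
from .matrices import merge_setting

__all__ = [
    "DURATION_MIDPOINT_MINUTES",
    "duration_midpoint_minutes",
    "participant_summaries",
    "weighted_quantile",
    "weighted_median_iqr",
    "CrossTab",
    "setting_proportions",
    "chi2_independence",
    "chi2_trend",
    "reporting_method_comparison",
    "ReportingComparison",
    "distance_mobility_tables",
    "contact_totals",
]

#: Midpoints of the five duration bands in minutes; the open top band is
#: right-truncated at 4 h (240 min).
DURATION_MIDPOINT_MINUTES = {
    "lt5min": 2.5,
    "5to14min": 9.5,
    "15to59min": 37.0,
    "1to4h": 150.0,
    "gt4h": 240.0,
}


def duration_midpoint_minutes(duration_cat: str) -> float:
    try:
        return DURATION_MIDPOINT_MINUTES[duration_cat]
    except KeyError:
        raise ValueError(f"unknown duration category {duration_cat!r}") from None


def participant_summaries(survey: Survey) -> pd.DataFrame:
    """Per-participant degree decomposition and total diary contact hours.

    Columns: participant_id, degree_diary, degree_supplementary,
    degree_total, total_contact_hours.
    """
    pdf = survey.participants
    idx = pd.Index(pdf["participant_id"], name="participant_id")

    diary = pd.Series(0, index=idx, dtype=int)
    hours = pd.Series(0.0, index=idx)
    cdf = survey.diary_contacts
    if len(cdf):
        diary = (
            diary.add(cdf.groupby("participant_id").size(), fill_value=0)
            .reindex(idx)
            .astype(int)
        )
        mins = cdf["duration_cat"].map(duration_midpoint_minutes)
        hours = hours.add(
            mins.groupby(cdf["participant_id"]).sum() / 60.0, fill_value=0.0
        ).reindex(idx)
    supp = survey.supplementary_totals()

    return pd.DataFrame(
        {
            "participant_id": idx,
            "degree_diary": diary.to_numpy(),
            "degree_supplementary": supp.reindex(idx).fillna(0).astype(int).to_numpy(),
            "total_contact_hours": hours.to_numpy(),
        }
    ).assign(
        degree_total=lambda d: d["degree_diary"] + d["degree_supplementary"]
    )[
        [
            "participant_id",
            "degree_diary",
            "degree_supplementary",
            "degree_total",
            "total_contact_hours",
        ]
    ]


def weighted_quantile(values, weights, q) -> float | np.ndarray:
    """Inverse of the weighted ECDF with an upper tie-break: the smallest
    observed value whose cumulative weight share *exceeds* q (so a boundary
    falling exactly on q resolves to the next observed value)."""
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if v.shape != w.shape:
        raise ValueError("values and weights must align")
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be non-negative with positive total")
    order = np.argsort(v, kind="stable")
    v, w = v[order], w[order]
    cum = np.cumsum(w) / w.sum()
    qs = np.atleast_1d(np.asarray(q, dtype=float))
    out = v[np.searchsorted(cum, qs, side="right").clip(0, len(v) - 1)]
    return out if np.ndim(q) else float(out[0])


def weighted_median_iqr(values, weights=None) -> tuple[float, float, float]:
    """(median, q1, q3) under the weighted type-1 quantile convention."""
    v = np.asarray(values, dtype=float)
    w = np.ones_like(v) if weights is None else np.asarray(weights, dtype=float)
    med, q1, q3 = weighted_quantile(v, w, [0.5, 0.25, 0.75])
    return float(med), float(q1), float(q3)


@dataclass
class CrossTab:
    row_variable: str
    col_variable: str
    table: pd.DataFrame
    weighted: bool = False


#: Display categories for setting proportions; multi-setting contacts fall
#: into an exclusive 'multiple' bucket here (unlike matrix attribution).
_DISPLAY_SETTINGS = (
    "home_household",
    "home_nonhousehold",
    "work",
    "school",
    "other",
    "multiple",
)


def _display_setting(settings: frozenset[str]) -> str:
    merged = {merge_setting(s) for s in settings}
    if len(merged) > 1:
        return "multiple"
    (only,) = merged
    return "other" if only == "other_transport_leisure" else only


def setting_proportions(
    survey: Survey, weights=None, groupby: str = "age_band"
) -> CrossTab:
    """Weighted proportion of diary contacts in each setting, by participant
    group (age band, residence, sex, day type or occupation).

    Rows sum to 1. Supplementary contacts carry no setting and are excluded.
    """
    pdf = survey.participants
    if groupby == "age_band":
        bands = REGRESSION_SCHEME.bands_of(pdf["age"].to_numpy())
        group = pd.Series(
            [REGRESSION_SCHEME.labels[b] for b in bands],
            index=pdf["participant_id"],
        )
    elif groupby in ("residence", "sex", "day_type", "diary_day_type", "occupation"):
        col = "diary_day_type" if groupby == "day_type" else groupby
        group = pd.Series(pdf[col].to_numpy(), index=pdf["participant_id"])
    else:
        raise ValueError(f"unsupported groupby {groupby!r}")

    if isinstance(weights, WeightVector):
        w_p = pd.Series(weights.weights, index=weights.participant_ids)
    elif weights is None:
        w_p = pd.Series(1.0, index=pdf["participant_id"])
    else:
        w_p = pd.Series(np.asarray(weights, float), index=pdf["participant_id"])

    cdf = survey.diary_contacts
    disp = cdf["settings"].map(_display_setting)
    g = group.loc[cdf["participant_id"]].to_numpy()
    w = w_p.loc[cdf["participant_id"]].to_numpy()

    tab = (
        pd.DataFrame({"group": g, "setting": disp.to_numpy(), "w": w})
        .pivot_table(index="group", columns="setting", values="w", aggfunc="sum")
        .reindex(columns=_DISPLAY_SETTINGS)
        .fillna(0.0)
    )
    tab = tab.div(tab.sum(axis=1), axis=0)
    return CrossTab(groupby, "setting", tab, weighted=weights is not None)


def chi2_independence(crosstab) -> tuple[float, int, float]:
    """Pearson chi-squared test of independence on a contingency table of
    counts; returns (statistic, df, p)."""
    table = crosstab.table if isinstance(crosstab, CrossTab) else pd.DataFrame(crosstab)
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("need at least a 2x2 table")
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise ValueError("zero marginal total")
    stat, p, df, _ = stats.chi2_contingency(arr, correction=False)
    return float(stat), int(df), float(p)


def chi2_trend(ordered_binary_table, scores=None) -> tuple[float, int, float]:
    """Cochran–Armitage chi-squared test for trend in proportions.

    ``ordered_binary_table`` is a k x 2 array of counts — one binary outcome
    (e.g. physical yes/no) across k ordered exposure levels (duration or
    frequency bands). Default scores are 1..k. Returns (statistic, 1, p).
    """
    arr = np.asarray(ordered_binary_table, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ValueError("need a k x 2 table with k >= 2 ordered levels")
    k = arr.shape[0]
    s = np.arange(1, k + 1, dtype=float) if scores is None else np.asarray(scores, float)
    n_i = arr.sum(axis=1)
    r_i = arr[:, 0]
    N = n_i.sum()
    R = r_i.sum()
    if R == 0 or R == N:
        return 0.0, 1, 1.0
    pbar = R / N
    T = float(np.sum(s * (r_i - n_i * pbar)))
    var = pbar * (1 - pbar) * (np.sum(n_i * s**2) - np.sum(n_i * s) ** 2 / N)
    if var <= 0:
        return 0.0, 1, 1.0
    stat = T**2 / var
    return float(stat), 1, float(stats.chi2.sf(stat, 1))


@dataclass
class ReportingComparison:
    """Diary vs supplementary reporting: do the two methods see the same
    contacts?"""

    applicable: bool
    age_table: pd.DataFrame | None = None  # coarse band x method counts
    age_chi2: tuple[float, int, float] | None = None
    physical_table: pd.DataFrame | None = None  # physical x method counts
    physical_chi2: tuple[float, int, float] | None = None
    coarse_matrices: dict[str, pd.DataFrame] | None = None


def reporting_method_comparison(survey: Survey) -> ReportingComparison:
    """Compare diary-reported vs supplementary contacts on age distribution
    (four coarse bands, df 3) and physical proportion (df 1), plus coarse
    4x4 participant-band x contact-band matrices per method."""
    if len(survey.supplementary) == 0 or survey.supplementary["count"].sum() == 0:
        return ReportingComparison(applicable=False)

    ages = resolve_contact_ages(survey)
    cdf = survey.diary_contacts
    has_age = ~np.isnan(ages)
    diary_band = pd.Series(
        [coarse_band_of_age(a) for a in ages[has_age]], dtype=object
    )
    diary_age_counts = diary_band.value_counts().reindex(COARSE_BANDS).fillna(0)

    supp = survey.supplementary
    supp_age_counts = (
        supp.groupby("band")["count"].sum().reindex(COARSE_BANDS).fillna(0)
    )
    age_table = pd.DataFrame(
        {"diary": diary_age_counts, "supplementary": supp_age_counts}
    )

    phys_table = pd.DataFrame(
        {
            "diary": [
                int(cdf["physical"].sum()),
                int((~cdf["physical"]).sum()),
            ],
            "supplementary": [
                int(supp.loc[supp["physical"], "count"].sum()),
                int(supp.loc[~supp["physical"], "count"].sum()),
            ],
        },
        index=["physical", "nonphysical"],
    )

    # coarse participant-band x contact-band count matrices per method
    p_ages = survey.participants.set_index("participant_id")["age"]
    p_band_all = p_ages.map(coarse_band_of_age)
    diary_p_band = p_band_all.loc[cdf.loc[has_age, "participant_id"]].to_numpy()
    diary_mat = (
        pd.crosstab(
            pd.Categorical(diary_p_band, categories=COARSE_BANDS),
            pd.Categorical(diary_band.to_numpy(), categories=COARSE_BANDS),
            dropna=False,
        )
    )
    supp_p_band = p_band_all.loc[supp["participant_id"]].to_numpy()
    supp_mat = (
        pd.DataFrame(
            {
                "pb": pd.Categorical(supp_p_band, categories=COARSE_BANDS),
                "cb": pd.Categorical(supp["band"].to_numpy(), categories=COARSE_BANDS),
                "n": supp["count"].to_numpy(),
            }
        )
        .pivot_table(index="pb", columns="cb", values="n", aggfunc="sum", observed=False)
        .fillna(0)
        .astype(int)
    )

    return ReportingComparison(
        applicable=True,
        age_table=age_table,
        age_chi2=chi2_independence(age_table),
        physical_table=phys_table,
        physical_chi2=chi2_independence(phys_table),
        coarse_matrices={"diary": diary_mat, "supplementary": supp_mat},
    )


#: optional participant columns holding usual travel frequency outside each
#: administrative level (ordinal tokens, survey-defined)
MOBILITY_COLUMNS = ("travel_commune", "travel_district", "travel_province", "travel_country")


def distance_mobility_tables(
    survey: Survey, weights=None
) -> tuple[CrossTab, CrossTab | None]:
    """Weighted distribution of diary contacts over distance-from-home bands,
    and (if the questionnaire columns are present) the travel-frequency
    distribution by age band, residence and administrative level.

    Contacts with no reported distance appear under 'missing', never dropped.
    """
    pdf = survey.participants
    if isinstance(weights, WeightVector):
        w_p = pd.Series(weights.weights, index=weights.participant_ids)
    elif weights is None:
        w_p = pd.Series(1.0, index=pdf["participant_id"])
    else:
        w_p = pd.Series(np.asarray(weights, float), index=pdf["participant_id"])

    cdf = survey.diary_contacts
    dist = cdf["distance_cat"].astype(object).where(
        cdf["distance_cat"].isin(DISTANCE_CATS), "missing"
    )
    w = w_p.loc[cdf["participant_id"]].to_numpy()
    totals = (
        pd.Series(w)
        .groupby(dist.to_numpy())
        .sum()
        .reindex(list(DISTANCE_CATS) + ["missing"])
        .fillna(0.0)
    )
    dist_tab = CrossTab(
        "distance_cat",
        "share",
        (totals / totals.sum()).to_frame("share"),
        weighted=weights is not None,
    )

    mob_cols = [c for c in MOBILITY_COLUMNS if c in pdf.columns]
    if not mob_cols:
        return dist_tab, None
    bands = REGRESSION_SCHEME.bands_of(pdf["age"].to_numpy())
    rows = []
    wp = w_p.loc[pdf["participant_id"]].to_numpy()
    for col in mob_cols:
        for (band, res, lvl), grp in pd.DataFrame(
            {
                "band": [REGRESSION_SCHEME.labels[b] for b in bands],
                "res": pdf["residence"].to_numpy(),
                "lvl": pdf[col].fillna("missing").to_numpy(),
                "w": wp,
            }
        ).groupby(["band", "res", "lvl"]):
            rows.append(
                {
                    "admin_level": col.removeprefix("travel_"),
                    "age_band": band,
                    "residence": res,
                    "frequency": lvl,
                    "weight": grp["w"].sum(),
                }
            )
    mob = pd.DataFrame(rows)
    mob["share"] = mob["weight"] / mob.groupby(
        ["admin_level", "age_band", "residence"]
    )["weight"].transform("sum")
    return dist_tab, CrossTab("mobility", "share", mob, weighted=weights is not None)


def contact_totals(survey: Survey) -> dict[str, int]:
    """Total diary, supplementary and combined contact counts, with the diary
    share of the total in percent."""
    n_diary = int(survey.n_diary_contacts)
    n_supp = int(survey.supplementary["count"].sum()) if len(survey.supplementary) else 0
    total = n_diary + n_supp
    return {
        "n_diary": n_diary,
        "n_supplementary": n_supp,
        "n_total": total,
        "diary_share_percent": 100.0 * n_diary / total if total else float("nan"),
    }
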