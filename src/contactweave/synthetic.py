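"""Synthetic contact-survey generator with exactly known ground truth.

The generator emulates the statistical structure of a quota-sampled,
diary-based contact survey: participants recruited to an exact age x sex x
urban/rural quota; a per-participant negative-binomial contact degree; contact
ages drawn from an age-assortative mixing kernel with intergenerational
ridges; per-setting attribution, duration, physicality, frequency and
distance sub-models; and a reporting mechanism that relegates a biased subset
of contacts from the diary to coarse-band "supplementary" counts.

The ground-truth mixing matrix is constructed to satisfy the reciprocity
identity ``c_ij N_i = c_ji N_j`` exactly, so the estimation pipeline has a
recoverable target: with relegation switched off, the reciprocity-adjusted
matrix estimated from a generated survey converges to
``GroundTruth.true_matrix`` as the sample grows.

All randomness flows from a single seed through named per-sub-model streams.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
import pandas as pd
import yaml

from .matrices import SETTING_LABELS, ContactMatrix, reciprocity_adjust
from .schemes import (
    MATRIX_SCHEME,
    SAMPLING_SCHEME,
    AgeBandScheme,
    coarse_band_of_age,
)
from .survey import (
    CONTACT_COLUMNS,
    DURATION_CATS,
    DISTANCE_CATS,
    FREQUENCY_CATS,
    PARTICIPANT_COLUMNS,
    PopulationTable,
    RESIDENCES,
    SEXES,
    SUPPLEMENTARY_COLUMNS,
    Survey,
)

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "generate_population",
    "generate_survey",
    "derive_employment_status",
]

_STREAMS = (
    "ages",
    "occupation",
    "household",
    "day_type",
    "degree",
    "contact_band",
    "contact_age",
    "setting",
    "duration",
    "physical",
    "frequency",
    "distance",
    "age_range",
    "relegation",
    "mobility",
)


def _streams(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(c) for name, c in zip(_STREAMS, children)}


def derive_employment_status(age: int, occupation: str) -> str:
    """Employment status from age and occupation: children and seniors are
    non-working age; working-age adults are employed if their occupation is a
    paid one, else unemployed (housewives/retirees/students included)."""
    if age < 15 or age >= 65:
        return "non_working_age"
    if occupation in ("professional", "shop_worker", "manual_labour", "agriculture", "other"):
        return "employed"
    return "unemployed"


# ---------------------------------------------------------------------------
# population


def generate_population(
    scheme: AgeBandScheme = MATRIX_SCHEME,
    stratum_shares: dict[str, float] | None = None,
    total_size: int = 2_000_000,
    pyramid_shape: float = 0.025,
) -> dict[str, PopulationTable]:
    """Per-stratum population tables with a configurable age pyramid.

    Band weights decay exponentially with the band's midpoint age at rate
    ``pyramid_shape`` per year (0 = uniform; the default gives the young
    pyramid typical of the study setting). Integer counts per band sum
    exactly to each stratum's share of ``total_size`` and are at least 1.
    """
    if total_size <= 0:
        raise ValueError("total_size must be positive")
    shares = stratum_shares or {"urban": 0.5, "rural": 0.5}
    if not np.isclose(sum(shares.values()), 1.0):
        raise ValueError("stratum shares must sum to 1")

    mids = _band_midpoints(scheme)
    w = np.exp(-pyramid_shape * mids)
    w = w / w.sum()

    out = {}
    for stratum, share in shares.items():
        n_str = int(round(total_size * share))
        raw = w * n_str
        N = np.floor(raw).astype(int)
        N = np.maximum(N, 1)
        # largest-remainder top-up to hit the stratum total exactly
        deficit = n_str - N.sum()
        if deficit > 0:
            order = np.argsort(-(raw - np.floor(raw)))
            for k in range(deficit):
                N[order[k % len(N)]] += 1
        elif deficit < 0:
            order = np.argsort(raw - np.floor(raw))
            k = 0
            while deficit < 0:
                i = order[k % len(N)]
                if N[i] > 1:
                    N[i] -= 1
                    deficit += 1
                k += 1
        out[stratum] = PopulationTable(scheme, stratum, N.astype(float))
    return out


def _band_midpoints(scheme: AgeBandScheme, top_width: int = 20) -> np.ndarray:
    br = list(scheme.breaks) + [scheme.breaks[-1] + top_width]
    return np.array([(lo + hi - 1) / 2 for lo, hi in zip(br, br[1:])])


# ---------------------------------------------------------------------------
# configuration


def _default_setting_shares() -> dict[str, float]:
    # approximate contact-share split across the five analysis settings
    return {
        "home_household": 0.29,
        "home_nonhousehold": 0.28,
        "work": 0.05,
        "school": 0.10,
        "other_transport_leisure": 0.28,
    }


def _default_duration_probs() -> dict[str, list[float]]:
    # over (lt5min, 5to14min, 15to59min, 1to4h, gt4h); home and school skew long
    return {
        "home_household": [0.05, 0.10, 0.25, 0.30, 0.30],
        "home_nonhousehold": [0.15, 0.25, 0.30, 0.20, 0.10],
        "work": [0.10, 0.15, 0.30, 0.30, 0.15],
        "school": [0.05, 0.10, 0.25, 0.30, 0.30],
        "other_transport_leisure": [0.30, 0.30, 0.25, 0.10, 0.05],
    }


def _default_physical_probs() -> dict[str, list[float]]:
    # P(physical | setting, duration band): rises with duration in every
    # setting, highest at home with household members and at school
    return {
        "home_household": [0.35, 0.45, 0.55, 0.70, 0.80],
        "home_nonhousehold": [0.20, 0.30, 0.40, 0.50, 0.60],
        "work": [0.10, 0.15, 0.20, 0.30, 0.35],
        "school": [0.30, 0.40, 0.50, 0.65, 0.75],
        "other_transport_leisure": [0.10, 0.15, 0.25, 0.35, 0.45],
    }


@dataclass
class GeneratorConfig:
    """Everything the generator needs; defaults mirror the study design.

    ``degree_coefficients`` are log-linear multipliers on the NB degree mean
    over participant covariates (key format ``"variable[level]"``); they are
    renormalised within each matrix age band so the band-level ground-truth
    matrix stays exact regardless of covariate effects. ``nb_dispersion`` is
    the NB size parameter k (Var = mu + mu^2/k).
    """

    n_participants: int = 2016
    quota_scheme: AgeBandScheme = SAMPLING_SCHEME
    seed: int = 0

    population_total: int = 2_000_000
    pyramid_shape: float = 0.025
    stratum_shares: dict[str, float] = field(
        default_factory=lambda: {"urban": 0.5, "rural": 0.5}
    )

    # ground-truth mixing kernel
    target_mean_degree: float = 31.0
    assortativity_bandwidth: float = 6.0
    intergenerational_offset: float = 28.0
    intergenerational_amplitude: float = 0.5
    intergenerational_bandwidth: float = 8.0
    setting_shares: dict[str, float] = field(default_factory=_default_setting_shares)

    # degree model
    degree_coefficients: dict[str, float] = field(
        default_factory=lambda: {
            "residence[rural]": float(np.log(1.23)),
            "day_type[weekend]": float(np.log(0.81)),
        }
    )
    nb_dispersion: float = 1.2

    # contact attribute sub-models
    duration_probs: dict[str, list[float]] = field(default_factory=_default_duration_probs)
    physical_probs: dict[str, list[float]] = field(default_factory=_default_physical_probs)
    frequency_probs: list[float] = field(
        default_factory=lambda: [0.45, 0.25, 0.12, 0.10, 0.08]
    )
    distance_probs: list[float] = field(default_factory=lambda: [0.88, 0.10, 0.02])
    other_split: list[float] = field(default_factory=lambda: [0.015, 0.010, 0.975])
    age_range_prob: float = 0.15
    missing_age_prob: float = 0.0
    multi_setting_prob: float = 0.05

    # reporting model: probability a contact is relegated from the diary to
    # the supplementary coarse-band counts, by physicality
    relegation_prob_physical: float = 0.40
    relegation_prob_nonphysical: float = 0.62

    weekend_share: float = 0.148

    def __post_init__(self) -> None:
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        for name in ("relegation_prob_physical", "relegation_prob_nonphysical",
                     "age_range_prob", "missing_age_prob", "multi_setting_prob",
                     "weekend_share"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if any(v < 0 for v in self.setting_shares.values()):
            raise ValueError("setting shares must be >= 0")

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def replace(self, **kw) -> "GeneratorConfig":
        return dc_replace(self, **kw)


@dataclass
class GroundTruth:
    """The generating parameters every downstream stage should recover.

    ``true_matrix`` (and the per-setting components) satisfy the reciprocity
    identity against ``population['all']`` by construction.
    """

    true_matrix: ContactMatrix
    setting_matrices: dict[str, ContactMatrix]
    degree_coefficients: dict[str, float]
    weights_target_margins: dict[str, dict[str, float]]
    population: dict[str, PopulationTable]


# ---------------------------------------------------------------------------
# ground-truth kernel


def _setting_support(scheme: AgeBandScheme, label: str) -> np.ndarray:
    """Band-level support mask: school contacts need both sides aged ~3-24,
    work contacts both sides of working age."""
    br = list(scheme.breaks) + [200]
    lo = np.array(br[:-1])
    hi = np.array(br[1:]) - 1
    if label == "school":
        ok = (hi >= 3) & (lo <= 24)
    elif label == "work":
        ok = (hi >= 15) & (lo <= 64)
    else:
        return np.ones((scheme.n_bands, scheme.n_bands), dtype=bool)
    return np.outer(ok, ok)


def build_true_matrices(
    config: GeneratorConfig, population_all: PopulationTable
) -> tuple[ContactMatrix, dict[str, ContactMatrix]]:
    """Construct reciprocal per-setting ground-truth matrices on the 14-band
    matrix scheme, scaled so the population-mean total degree equals
    ``target_mean_degree``."""
    scheme = population_all.scheme
    mids = _band_midpoints(scheme)
    d = mids[:, None] - mids[None, :]

    base = np.exp(-(d**2) / (2 * config.assortativity_bandwidth**2))
    ridge = np.exp(
        -((np.abs(d) - config.intergenerational_offset) ** 2)
        / (2 * config.intergenerational_bandwidth**2)
    )

    N = population_all.N
    pop_share = N / N.sum()

    setting_mats: dict[str, ContactMatrix] = {}
    total = np.zeros_like(base)
    for label in SETTING_LABELS:
        k = base.copy()
        if label == "home_household":
            k = k + config.intergenerational_amplitude * ridge
        elif label == "home_nonhousehold":
            k = k + 0.4 * config.intergenerational_amplitude * ridge + 0.15
        elif label == "other_transport_leisure":
            k = 0.5 * k + 0.25  # flatter: broad community mixing
        k = k * _setting_support(scheme, label)
        # symmetrise in totals against the population (Eq.-style average)
        m = 0.5 * (k * N[:, None] + k.T * N[None, :])
        c = m / N[:, None]
        # normalise so the population-mean row sum is this setting's share
        mean_deg = float(pop_share @ c.sum(axis=1))
        share = config.setting_shares[label]
        c *= share * config.target_mean_degree / (mean_deg * sum(config.setting_shares.values()))
        setting_mats[label] = ContactMatrix(
            scheme=scheme,
            values=c,
            n_participants=np.zeros(scheme.n_bands, dtype=int),
            stratum="all",
            setting_label=label,
            adjusted=True,
            population=population_all,
        )
        total += c

    total_mat = ContactMatrix(
        scheme=scheme,
        values=total,
        n_participants=np.zeros(scheme.n_bands, dtype=int),
        stratum="all",
        setting_label="all",
        adjusted=True,
        population=population_all,
    )
    return total_mat, setting_mats


# ---------------------------------------------------------------------------
# participant attributes

_OCC_BY_AGE = (
    # (min age, max age, occupations, probabilities)
    (0, 2, ("child_at_home",), (1.0,)),
    (3, 4, ("preschooler", "child_at_home"), (0.6, 0.4)),
    (5, 17, ("student", "child_at_home"), (0.9, 0.1)),
    (
        18,
        24,
        ("student", "professional", "shop_worker", "manual_labour",
         "agriculture", "housewife", "unemployed", "other"),
        (0.30, 0.06, 0.12, 0.10, 0.25, 0.07, 0.06, 0.04),
    ),
    (
        25,
        59,
        ("professional", "shop_worker", "manual_labour", "agriculture",
         "housewife", "unemployed", "other"),
        (0.07, 0.14, 0.11, 0.43, 0.12, 0.08, 0.05),
    ),
    (
        60,
        200,
        ("retired", "agriculture", "housewife", "unemployed", "other"),
        (0.40, 0.30, 0.15, 0.05, 0.10),
    ),
)


def _draw_occupations(ages: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    occ = np.empty(len(ages), dtype=object)
    for lo, hi, cats, probs in _OCC_BY_AGE:
        mask = (ages >= lo) & (ages <= hi)
        if mask.any():
            occ[mask] = rng.choice(cats, size=int(mask.sum()), p=probs)
    return occ


def _sampling_band_age_range(scheme: AgeBandScheme, band: int, top_age: int = 84):
    lo = scheme.breaks[band]
    hi = scheme.breaks[band + 1] - 1 if band + 1 < scheme.n_bands else top_age
    return lo, hi


# ---------------------------------------------------------------------------
# main generator


def generate_survey(config: GeneratorConfig) -> tuple[Survey, GroundTruth]:
    """Generate a quota-filled synthetic survey and its ground truth.

    Raises if the quota design is infeasible (a quota cell larger than its
    stratum-band population) or ``n_participants`` does not divide evenly
    over the quota strata.
    """
    rngs = _streams(config.seed)
    scheme = MATRIX_SCHEME
    qscheme = config.quota_scheme

    n_strata = qscheme.n_bands * len(SEXES) * len(RESIDENCES)
    if config.n_participants % n_strata:
        raise ValueError(
            f"n_participants={config.n_participants} not divisible by "
            f"{n_strata} quota strata"
        )
    quota = config.n_participants // n_strata

    pops = generate_population(
        scheme, config.stratum_shares, config.population_total, config.pyramid_shape
    )
    pop_all = pops[RESIDENCES[0]].combined_with(pops[RESIDENCES[1]])

    # quota feasibility: each quota cell must fit inside its stratum population
    for res in RESIDENCES:
        Nr = pops[res].N
        for b in range(qscheme.n_bands):
            lo, hi = _sampling_band_age_range(qscheme, b)
            covered = sum(
                Nr[k]
                for k in range(scheme.n_bands)
                if scheme.breaks[k] <= hi
                and (scheme.breaks[k + 1] - 1 if k + 1 < scheme.n_bands else 200) >= lo
            )
            if quota * len(SEXES) > covered:
                raise ValueError(
                    f"quota {quota} per sex infeasible in {res} band "
                    f"{qscheme.labels[b]} (population {covered:.0f})"
                )

    true_total, true_settings = build_true_matrices(config, pop_all)

    # --- participants ------------------------------------------------------
    rows = []
    pid = 0
    for b in range(qscheme.n_bands):
        lo, hi = _sampling_band_age_range(qscheme, b)
        for sex in SEXES:
            for res in RESIDENCES:
                ages = rngs["ages"].integers(lo, hi + 1, size=quota)
                for a in ages:
                    rows.append((f"P{pid:05d}", int(a), sex, res))
                    pid += 1
    pdf = pd.DataFrame(rows, columns=["participant_id", "age", "sex", "residence"])
    n = len(pdf)

    pdf["district_id"] = [
        ("U" if r == "urban" else "R") + str(i % 3 + 1)
        for i, r in enumerate(pdf["residence"])
    ]
    pdf["occupation"] = _draw_occupations(pdf["age"].to_numpy(), rngs["occupation"])
    pdf["household_size"] = 1 + rngs["household"].poisson(3.2, size=n).clip(max=11)
    pdf["n_rooms"] = np.select(
        [pdf["household_size"] <= 2, pdf["household_size"] <= 4,
         pdf["household_size"] <= 6, pdf["household_size"] <= 8],
        ["1", "2", "3", "4"],
        default="5+",
    )
    pdf["diary_day_type"] = np.where(
        rngs["day_type"].random(n) < config.weekend_share, "weekend", "weekday"
    )
    pdf["employment_status"] = [
        derive_employment_status(a, o)
        for a, o in zip(pdf["age"], pdf["occupation"])
    ]

    # --- degrees -----------------------------------------------------------
    p_band = scheme.bands_of(pdf["age"].to_numpy())
    base_mu = true_total.values.sum(axis=1)[p_band]

    mult = np.ones(n)
    for key, coef in config.degree_coefficients.items():
        var, level = key.rstrip("]").split("[")
        col = "diary_day_type" if var == "day_type" else var
        mult *= np.where(pdf[col].to_numpy() == level, np.exp(coef), 1.0)
    # renormalise within matrix band so band-mean multipliers are 1 and the
    # ground-truth matrix stays exact whatever the covariate effects
    for b in np.unique(p_band):
        mask = p_band == b
        mult[mask] /= mult[mask].mean()

    mu = base_mu * mult
    k_disp = config.nb_dispersion
    degrees = rngs["degree"].negative_binomial(k_disp, k_disp / (k_disp + mu))

    # --- contacts ----------------------------------------------------------
    K = scheme.n_bands
    row_probs = true_total.values / true_total.values.sum(axis=1, keepdims=True)
    c_idx_participant = np.repeat(np.arange(n), degrees)
    ci = p_band[c_idx_participant]
    m = len(ci)

    cj = np.empty(m, dtype=int)
    for b in range(K):
        mask = ci == b
        if mask.any():
            cj[mask] = rngs["contact_band"].choice(K, size=int(mask.sum()), p=row_probs[b])

    # contact ages: uniform within band (65+ -> 65..89)
    lo_b = np.array(scheme.breaks)
    hi_b = np.array(list(scheme.breaks[1:]) + [90])
    c_age = rngs["contact_age"].integers(lo_b[cj], hi_b[cj])

    # setting: P(s | i, j) proportional to the per-setting truth at (i, j)
    P_set = np.stack(
        [true_settings[lab].values for lab in SETTING_LABELS], axis=2
    )
    with np.errstate(invalid="ignore"):
        P_set = P_set / P_set.sum(axis=2, keepdims=True)
    P_set = np.nan_to_num(P_set, nan=1.0 / len(SETTING_LABELS))
    cum = np.cumsum(P_set, axis=2)
    u = rngs["setting"].random(m)
    s_idx = (u[:, None] > cum[ci, cj, :]).sum(axis=1).clip(max=len(SETTING_LABELS) - 1)

    dur_p = np.array([config.duration_probs[lab] for lab in SETTING_LABELS])
    cum_d = np.cumsum(dur_p, axis=1)
    u = rngs["duration"].random(m)
    d_idx = (u[:, None] > cum_d[s_idx, :]).sum(axis=1).clip(max=len(DURATION_CATS) - 1)

    phys_p = np.array([config.physical_probs[lab] for lab in SETTING_LABELS])
    physical = rngs["physical"].random(m) < phys_p[s_idx, d_idx]

    f_idx = rngs["frequency"].choice(len(FREQUENCY_CATS), size=m, p=config.frequency_probs)
    dist_idx = rngs["distance"].choice(len(DISTANCE_CATS), size=m, p=config.distance_probs)

    # raw settings from the analysis label
    labels = np.array(SETTING_LABELS, dtype=object)[s_idx]
    other_raw = rngs["setting"].choice(
        ["transport", "leisure", "other"], size=m, p=config.other_split
    )
    raw_setting = np.where(labels == "other_transport_leisure", other_raw, labels)
    multi = (labels == "home_household") & (
        rngs["setting"].random(m) < config.multi_setting_prob
    )
    settings_col = [
        frozenset((s, "other")) if is_multi else frozenset((s,))
        for s, is_multi in zip(raw_setting, multi)
    ]

    # age reporting: some ages arrive as a range (within-band), some missing
    u = rngs["age_range"].random(m)
    as_range = u < config.age_range_prob
    as_missing = (u >= config.age_range_prob) & (
        u < config.age_range_prob + config.missing_age_prob
    )
    rlo = np.maximum(c_age - 2, lo_b[cj])
    rhi = np.minimum(c_age + 2, hi_b[cj] - 1)

    relegate_p = np.where(
        physical, config.relegation_prob_physical, config.relegation_prob_nonphysical
    )
    relegated = rngs["relegation"].random(m) < relegate_p

    keep = ~relegated
    cdf = pd.DataFrame(
        {
            "participant_id": pdf["participant_id"].to_numpy()[c_idx_participant[keep]],
            "contact_age_exact": np.where(
                as_range[keep] | as_missing[keep], np.nan, c_age[keep].astype(float)
            ),
            "contact_age_min": np.where(as_range[keep], rlo[keep].astype(float), np.nan),
            "contact_age_max": np.where(as_range[keep], rhi[keep].astype(float), np.nan),
            "settings": [settings_col[i] for i in np.flatnonzero(keep)],
            "physical": physical[keep],
            "duration_cat": np.array(DURATION_CATS, dtype=object)[d_idx[keep]],
            "frequency_cat": np.array(FREQUENCY_CATS, dtype=object)[f_idx[keep]],
            "distance_cat": np.array(DISTANCE_CATS, dtype=object)[dist_idx[keep]],
        },
        columns=CONTACT_COLUMNS,
    )

    # supplementary: relegated contacts, coarse-banded, setting/duration erased
    if relegated.any():
        bands = np.array([coarse_band_of_age(a) for a in c_age[relegated]], dtype=object)
        sdf = (
            pd.DataFrame(
                {
                    "participant_id": pdf["participant_id"].to_numpy()[
                        c_idx_participant[relegated]
                    ],
                    "band": bands,
                    "physical": physical[relegated],
                }
            )
            .groupby(["participant_id", "band", "physical"], as_index=False)
            .size()
            .rename(columns={"size": "count"})
        )[SUPPLEMENTARY_COLUMNS]
    else:
        sdf = pd.DataFrame(columns=SUPPLEMENTARY_COLUMNS)

    with_supp = set(sdf["participant_id"]) if len(sdf) else set()
    pdf["diary_complete_selfreport"] = ~pdf["participant_id"].isin(with_supp)
    pdf = pdf[PARTICIPANT_COLUMNS]

    survey = Survey(pdf, cdf, sdf)
    truth = GroundTruth(
        true_matrix=true_total,
        setting_matrices=true_settings,
        degree_coefficients=dict(config.degree_coefficients),
        weights_target_margins=_target_margins(config, pop_all),
        population={**pops, "all": pop_all},
    )
    return survey, truth


def _target_margins(config: GeneratorConfig, pop_all: PopulationTable) -> dict:
    from .schemes import REGRESSION_SCHEME

    # regression-scheme age shares implied by the generated population
    shares = {}
    reg = REGRESSION_SCHEME
    N = pop_all.N
    br = list(pop_all.scheme.breaks)
    for b in range(reg.n_bands):
        lo = reg.breaks[b]
        hi = reg.breaks[b + 1] if b + 1 < reg.n_bands else 10**6
        total = sum(N[k] for k in range(len(br)) if lo <= br[k] < hi)
        shares[reg.labels[b]] = float(total / N.sum())
    return {
        "residence": dict(config.stratum_shares),
        "age_band": shares,
        "diary_day_type": {
            "weekday": 1 - config.weekend_share,
            "weekend": config.weekend_share,
        },
    }
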