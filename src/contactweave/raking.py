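"""Raking (iterative proportional fitting) of per-participant survey weights.

Raking adjusts unit weights multiplicatively, one margin variable at a time,
until the weighted marginal distribution of each variable matches its
population targets. The weighting variables used in this analysis are
urban/rural residence, age group, weekday/weekend diary day, and employment
status (non-working age / employed / unemployed); population margins come
from external census-style sources and are always supplied by the caller.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .schemes import REGRESSION_SCHEME, AgeBandScheme
from .survey import Survey

__all__ = [
    "MarginSpec",
    "WeightVector",
    "rake_weights",
    "margin_deviation",
    "classify_margin",
    "DEFAULT_RAKING_VARIABLES",
]

DEFAULT_RAKING_VARIABLES = (
    "residence",
    "age_band",
    "diary_day_type",
    "employment_status",
)


@dataclass(frozen=True)
class MarginSpec:
    """Population targets for one weighting variable.

    ``targets`` maps level -> population share; shares must be non-negative
    and sum to 1. For ``variable='age_band'`` the levels are the labels of
    ``scheme`` (the 8-band regression scheme by default).
    """

    variable: str
    targets: dict[str, float]
    scheme: AgeBandScheme = REGRESSION_SCHEME

    def __post_init__(self) -> None:
        vals = np.array(list(self.targets.values()), dtype=float)
        if np.any(vals < 0):
            raise ValueError(f"negative target share for {self.variable}")
        if not np.isclose(vals.sum(), 1.0, atol=1e-6):
            raise ValueError(
                f"targets for {self.variable} sum to {vals.sum():.6f}, not 1"
            )


@dataclass
class WeightVector:
    """Raked weights, normalised to mean 1, aligned to participant order."""

    weights: np.ndarray
    iterations_used: int
    converged: bool
    max_margin_error: float
    participant_ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if np.any(w <= 0):
            raise ValueError("weights must be strictly positive")
        self.weights = w

    def as_series(self) -> pd.Series:
        return pd.Series(self.weights, index=self.participant_ids, name="weight")


def classify_margin(survey: Survey, spec: MarginSpec) -> np.ndarray:
    """Level of ``spec.variable`` for each participant, as an object array."""
    pdf = survey.participants
    if spec.variable == "age_band":
        bands = spec.scheme.bands_of(pdf["age"].to_numpy())
        return np.array([spec.scheme.labels[b] for b in bands], dtype=object)
    if spec.variable not in pdf.columns:
        raise ValueError(f"unknown margin variable {spec.variable!r}")
    return pdf[spec.variable].to_numpy(dtype=object)


def _margin_errors(
    w: np.ndarray, level_indicators: list[tuple[np.ndarray, float, str, str]]
) -> float:
    wsum = w.sum()
    worst = 0.0
    for mask, target, _var, _lvl in level_indicators:
        share = w[mask].sum() / wsum
        if target == 0:
            err = np.inf if share > 0 else 0.0
        else:
            err = abs(share - target) / target
        worst = max(worst, err)
    return worst


def _build_indicators(survey: Survey, margin_specs) -> list:
    out = []
    for spec in margin_specs:
        levels = classify_margin(survey, spec)
        observed = set(levels)
        unknown = observed - set(spec.targets)
        if unknown:
            raise ValueError(
                f"sample levels {sorted(unknown)} of {spec.variable} missing "
                "from margin targets"
            )
        for lvl, target in spec.targets.items():
            mask = levels == lvl
            if target > 0 and not mask.any():
                raise ValueError(
                    f"margin level {spec.variable}={lvl!r} has positive target "
                    f"{target} but no sampled participants"
                )
            out.append((mask, float(target), spec.variable, lvl))
    return out


def rake_weights(
    survey: Survey,
    margin_specs: list[MarginSpec],
    tol: float = 1e-8,
    max_iter: int = 1000,
    trim_bounds: tuple[float, float] | None = None,
    initial_weights: np.ndarray | None = None,
    max_trim_cycles: int = 5,
) -> WeightVector:
    """Iterative proportional fitting of participant weights to the margins.

    Each pass rescales weights within every level of every margin variable so
    the weighted share equals the target; passes repeat until the largest
    relative margin error falls below ``tol`` or ``max_iter`` is reached
    (non-convergence is returned, flagged, not raised). Weights are normalised
    to mean 1. Optional trimming clips weights to ``trim_bounds`` (multiples
    of the mean weight) and re-rakes, up to ``max_trim_cycles`` times —
    guarding against extreme weights that inflate design effects.
    """
    n = survey.n_participants
    if n == 0:
        raise ValueError("empty survey")
    indicators = _build_indicators(survey, margin_specs)

    w = (
        np.ones(n)
        if initial_weights is None
        else np.asarray(initial_weights, dtype=float).copy()
    )
    if np.any(w <= 0):
        raise ValueError("initial weights must be positive")

    def _rake(w: np.ndarray) -> tuple[np.ndarray, int, bool]:
        it = 0
        for it in range(1, max_iter + 1):
            for mask, target, _var, _lvl in indicators:
                share = w[mask].sum() / w.sum()
                if share > 0 and target > 0:
                    w[mask] *= target / share
            if _margin_errors(w, indicators) <= tol:
                return w, it, True
        return w, it, False

    w, iters, converged = _rake(w)
    if trim_bounds is not None:
        lo, hi = trim_bounds
        for _ in range(max_trim_cycles):
            mean = w.mean()
            clipped = np.clip(w, lo * mean, hi * mean)
            if np.allclose(clipped, w):
                break
            w, it2, converged = _rake(clipped)
            iters += it2
        # bounds win over margins: end on a clipped, mean-1 state
        for _ in range(100):
            w = w / w.mean()
            clipped = np.clip(w, lo, hi)
            if np.allclose(clipped, w, rtol=0, atol=1e-12):
                break
            w = clipped
        converged = _margin_errors(w, indicators) <= tol

    w = w / w.mean()
    return WeightVector(
        weights=w,
        iterations_used=iters,
        converged=converged,
        max_margin_error=_margin_errors(w, indicators),
        participant_ids=survey.participants["participant_id"].to_numpy(),
    )


def margin_deviation(
    weights: WeightVector | np.ndarray,
    survey: Survey,
    margin_specs: list[MarginSpec],
) -> float:
    """Largest relative deviation of any weighted margin share from its
    target; infinite if a zero-target level carries positive weight."""
    w = weights.weights if isinstance(weights, WeightVector) else np.asarray(weights, float)
    if len(w) != survey.n_participants:
        raise ValueError("weights not aligned to survey")
    indicators = _build_indicators_lenient(survey, margin_specs)
    return _margin_errors(w, indicators)


def _build_indicators_lenient(survey: Survey, margin_specs) -> list:
    # like _build_indicators but without the empty-level hard error, so the
    # deviation of an arbitrary weight vector can always be measured
    out = []
    for spec in margin_specs:
        levels = classify_margin(survey, spec)
        for lvl, target in spec.targets.items():
            out.append((levels == lvl, float(target), spec.variable, lvl))
    return out
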