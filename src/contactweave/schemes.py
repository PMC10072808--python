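"""Age band schemes: named partitions of age into contiguous bands.

Three schemes recur in diary-based contact-survey analysis:

* the *matrix* scheme — 5-year bands from 0 to 64 plus an open 65+ band
  (14 bands), used for mixing matrices;
* the *sampling* scheme — the quota-recruitment bands 0–5, 6–12, 13–19,
  20–29, 30–39, 40–59, 60+ (7 bands);
* the *regression* scheme — 0–4, 5–14, ..., 55–64, 65+ (8 bands), used as a
  categorical covariate in degree/contact-hour models.

Bands are half-open ``[lower, next_lower)`` on integer ages, the last band
open-ended, so a printed label such as "0–5" corresponds to the next lower
bound 6.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AgeBandScheme",
    "assign_age_band",
    "MATRIX_SCHEME",
    "SAMPLING_SCHEME",
    "REGRESSION_SCHEME",
    "COARSE_BANDS",
    "coarse_band_of_age",
]


@dataclass(frozen=True)
class AgeBandScheme:
    """A partition of non-negative integer ages into contiguous bands.

    Parameters
    ----------
    name : str
        Identifier for the scheme.
    breaks : tuple of int
        Strictly ascending lower bounds of each band; the first must be 0.
        Band ``k`` covers ages ``[breaks[k], breaks[k+1])``; the last band is
        open-ended.
    """

    name: str
    breaks: tuple[int, ...]
    labels: tuple[str, ...] = field(default=(), compare=False)

    def __post_init__(self) -> None:
        br = tuple(int(b) for b in self.breaks)
        if len(br) == 0 or br[0] != 0:
            raise ValueError("breaks must start at 0")
        if any(b >= c for b, c in zip(br, br[1:])):
            raise ValueError("breaks must be strictly ascending")
        object.__setattr__(self, "breaks", br)
        if not self.labels:
            labels = [
                f"{lo}-{hi - 1}" for lo, hi in zip(br, br[1:])
            ] + [f"{br[-1]}+"]
            object.__setattr__(self, "labels", tuple(labels))
        elif len(self.labels) != len(br):
            raise ValueError("labels must match number of bands")

    @property
    def n_bands(self) -> int:
        return len(self.breaks)

    def band_of(self, age_years: float) -> int:
        return assign_age_band(age_years, self)

    def bands_of(self, ages) -> np.ndarray:
        """Vectorised band assignment for an array of ages."""
        a = np.asarray(ages, dtype=float)
        if np.any(a < 0):
            raise ValueError("negative age")
        return np.minimum(
            np.searchsorted(self.breaks, a, side="right") - 1,
            self.n_bands - 1,
        ).astype(int)


def assign_age_band(age_years: float, scheme: AgeBandScheme) -> int:
    """Index of the unique band whose half-open interval contains the age.

    The last band is open-ended. Negative ages raise ``ValueError``.
    """
    if age_years < 0:
        raise ValueError(f"negative age: {age_years}")
    idx = int(np.searchsorted(scheme.breaks, age_years, side="right")) - 1
    return min(idx, scheme.n_bands - 1)


#: 5-year bands 0-4 ... 60-64 plus 65+ (14 bands) — mixing-matrix scheme.
MATRIX_SCHEME = AgeBandScheme("matrix", tuple(range(0, 70, 5)))

#: Quota-sampling bands 0-5, 6-12, 13-19, 20-29, 30-39, 40-59, 60+.
SAMPLING_SCHEME = AgeBandScheme(
    "sampling",
    (0, 6, 13, 20, 30, 40, 60),
    ("0-5", "6-12", "13-19", "20-29", "30-39", "40-59", "60+"),
)

#: Regression covariate bands 0-4, 5-14, ..., 55-64, 65+.
REGRESSION_SCHEME = AgeBandScheme(
    "regression", (0, 5, 15, 25, 35, 45, 55, 65)
)

#: Coarse bands used for supplementary (recalled, non-diary) contacts.
COARSE_BANDS = ("0-4", "5-15", "16-64", "65+")

_COARSE_SCHEME = AgeBandScheme("coarse", (0, 5, 16, 65), COARSE_BANDS)


def coarse_band_of_age(age_years: float) -> str:
    """Map an exact age onto the four coarse supplementary-contact bands."""
    return COARSE_BANDS[assign_age_band(age_years, _COARSE_SCHEME)]
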