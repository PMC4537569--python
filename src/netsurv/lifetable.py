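"""Population mortality rate tables ("popmort"-style lifetables).

Expected (other-cause) mortality for cancer patients is taken from national
lifetables stratified by single year of age, calendar year and sex.  The
:class:`RateTable` stores, for every (age, year, sex) cell, the annual
probability ``p*`` of surviving one year, and exposes vectorised lookups of
``p*`` and of the equivalent constant annual hazard ``-ln(p*)``.

Conventions
-----------
* Attained age and attained calendar year advance continuously with
  follow-up time; lookups floor both to integers (annual lifetable cells).
* Lookups outside the declared age/year ranges are clamped to the nearest
  boundary — cancer cohorts routinely contain attained ages beyond the last
  lifetable row.  Clamping is counted and logged, never an error.
* Input tables may give either the annual survival probability (``prob``)
  or the annual mortality rate (``rate``); rates are converted internally
  via ``p* = exp(-rate)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: canonical sex codes: 1 = male, 2 = female
SEX_CODES = {1: 1, 2: 2, "male": 1, "female": 2, "m": 1, "f": 2, "1": 1, "2": 2}

DEFAULT_DIALECT = {"age": "age", "year": "year", "sex": "sex", "prob": "prob", "rate": "rate"}


class RateTableError(ValueError):
    """Raised for malformed or incomplete rate tables."""


def _encode_sex(sex) -> np.ndarray:
    """Map sex codes (1/2, 'male'/'female') to 0-based array indices."""
    arr = np.asarray(sex)
    if arr.dtype.kind in "iu":
        out = arr.astype(np.int64)
        bad = (out != 1) & (out != 2)
        if np.any(bad):
            raise RateTableError(f"unknown sex code {arr[bad].ravel()[0]!r}")
        return out - 1
    flat = np.asarray(
        [SEX_CODES.get(str(s).strip().lower()) for s in np.atleast_1d(arr)], dtype=object
    )
    if any(v is None for v in flat):
        bad = np.atleast_1d(arr)[[v is None for v in flat]][0]
        raise RateTableError(f"unknown sex code {bad!r}")
    return flat.astype(np.int64).reshape(arr.shape) - 1


@dataclass
class RateTable:
    """Annual expected-survival probabilities on a complete (age, year, sex) grid.

    Parameters
    ----------
    p_star : ndarray, shape (2, n_age, n_year)
        Annual survival probability per (sex, age, year), sex axis ordered
        male, female.  All entries must lie in (0, 1].
    age_min, year_min : int
        Age/year of the first grid row/column.
    """

    p_star: np.ndarray
    age_min: int
    year_min: int
    n_clamped: int = field(default=0, compare=False)

    def __post_init__(self) -> None:
        self.p_star = np.asarray(self.p_star, dtype=float)
        if self.p_star.ndim != 3 or self.p_star.shape[0] != 2:
            raise RateTableError("p_star must have shape (2, n_age, n_year)")
        if np.any(~np.isfinite(self.p_star)) or np.any(self.p_star <= 0) or np.any(self.p_star > 1):
            raise RateTableError("all p* must be finite and in (0, 1]")

    @property
    def age_max(self) -> int:
        return self.age_min + self.p_star.shape[1] - 1

    @property
    def year_max(self) -> int:
        return self.year_min + self.p_star.shape[2] - 1

    def _index(self, age, year):
        a = np.floor(np.asarray(age, dtype=float)).astype(np.int64)
        y = np.floor(np.asarray(year, dtype=float)).astype(np.int64)
        ac = np.clip(a, self.age_min, self.age_max)
        yc = np.clip(y, self.year_min, self.year_max)
        clamped = int(np.sum((ac != a) | (yc != y)))
        if clamped:
            self.n_clamped += clamped
            logger.debug("rate-table lookup clamped %d value(s) to table boundary", clamped)
        return ac - self.age_min, yc - self.year_min

    def annual_survival(self, age, year, sex):
        """``p*`` at floor(age), floor(year), clamped to the declared ranges."""
        s = _encode_sex(sex)
        ai, yi = self._index(age, year)
        return self.p_star[s, ai, yi]

    def hazard(self, age, year, sex):
        """Annual expected mortality rate ``-ln(p*)`` (per year), >= 0."""
        return -np.log(self.annual_survival(age, year, sex))

    def to_frame(self) -> pd.DataFrame:
        """Long-format view with columns age, year, sex, prob."""
        ages = np.arange(self.age_min, self.age_max + 1)
        years = np.arange(self.year_min, self.year_max + 1)
        s, a, y = np.meshgrid([1, 2], ages, years, indexing="ij")
        return pd.DataFrame(
            {"age": a.ravel(), "year": y.ravel(), "sex": s.ravel(), "prob": self.p_star.ravel()}
        )

    def save(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_hazard_function(cls, rate_of_age, age_range=(0, 110), year_range=(1970, 2030)):
        """Build a table from an age-only hazard function (constant in year/sex)."""
        ages = np.arange(age_range[0], age_range[1] + 1)
        rates = np.asarray([float(rate_of_age(a)) for a in ages])
        if np.any(rates < 0):
            raise RateTableError("hazard function returned a negative rate")
        n_year = year_range[1] - year_range[0] + 1
        p = np.exp(-rates)[None, :, None] * np.ones((2, 1, n_year))
        return cls(p_star=p, age_min=int(age_range[0]), year_min=int(year_range[0]))


def gompertz_ratetable(intercept: float = -10.2, slope: float = 0.095,
                       max_rate: float = 0.7, age_range=(0, 110),
                       year_range=(1970, 2030)) -> RateTable:
    """Gompertz-type background mortality, rate(a) = min(exp(intercept + slope*a), max_rate).

    The defaults track contemporary high-income national lifetables
    (England & Wales interim tables, males): ~1.8 %/yr at age 65,
    4.6 %/yr at 75, 12 %/yr at 85, 31 %/yr at 95, constant over calendar
    year and sex.  Getting the *level* right matters here: informative
    depletion of older subjects — the phenomenon the net-survival
    estimators differ on — scales directly with the other-cause hazard,
    so an inflated table exaggerates every depletion-driven bias.
    ``max_rate`` closes the table at extreme ages the way published
    lifetables do (an unclamped Gompertz extrapolation exceeds 2/yr past
    age 115, far beyond any observed lifetable).
    """
    return RateTable.from_hazard_function(
        lambda a: min(np.exp(intercept + slope * a), max_rate), age_range, year_range
    )


def load_ratetable(path, dialect: dict | None = None) -> RateTable:
    """Load a long-format popmort CSV into a :class:`RateTable`.

    The file must have columns for age, year and sex, plus either ``prob``
    (annual survival probability) or ``rate`` (annual mortality rate).
    Non-default column names are supplied through ``dialect``, a mapping
    from canonical names (``age``, ``year``, ``sex``, ``prob``, ``rate``)
    to the file's column names.

    Raises
    ------
    RateTableError
        If a grid cell inside the declared age/year range is missing
        (the first missing key is named), or a probability falls
        outside (0, 1].
    """
    cols = dict(DEFAULT_DIALECT)
    if dialect:
        cols.update(dialect)
    df = pd.read_csv(path, float_precision="round_trip")
    for key in ("age", "year", "sex"):
        if cols[key] not in df.columns:
            raise RateTableError(f"missing required column {cols[key]!r}")
    if cols["prob"] in df.columns:
        p = df[cols["prob"]].to_numpy(dtype=float)
    elif cols["rate"] in df.columns:
        r = df[cols["rate"]].to_numpy(dtype=float)
        if np.any(~np.isfinite(r)) or np.any(r < 0):
            raise RateTableError("rates must be finite and >= 0")
        p = np.exp(-r)
    else:
        raise RateTableError("need a 'prob' or 'rate' column")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        bad = p[~np.isfinite(p) | (p <= 0) | (p > 1)][0]
        raise RateTableError(f"survival probability {bad!r} outside (0, 1]")

    age = df[cols["age"]].to_numpy(dtype=np.int64)
    year = df[cols["year"]].to_numpy(dtype=np.int64)
    sex = _encode_sex(df[cols["sex"]].to_numpy())

    age_min, age_max = int(age.min()), int(age.max())
    year_min, year_max = int(year.min()), int(year.max())
    n_age, n_year = age_max - age_min + 1, year_max - year_min + 1
    grid = np.full((2, n_age, n_year), np.nan)
    grid[sex, age - age_min, year - year_min] = p

    missing = np.argwhere(np.isnan(grid))
    if len(missing):
        # sexes present in the file determine which planes must be complete
        present_sexes = np.unique(sex)
        missing = missing[np.isin(missing[:, 0], present_sexes)]
        if len(missing):
            s, a, y = missing[0]
            key = (int(a + age_min), int(y + year_min), "male" if s == 0 else "female")
            raise RateTableError(f"rate table has a hole at (age, year, sex) = {key}")
        # only one sex supplied: duplicate it for the other
        grid[np.setdiff1d([0, 1], present_sexes)[0]] = grid[present_sexes[0]]
    return RateTable(p_star=grid, age_min=age_min, year_min=year_min)


# spec-facing functional aliases ------------------------------------------------

def annual_expected_survival(rt: RateTable, age, year, sex):
    return rt.annual_survival(age, year, sex)


def expected_hazard(rt: RateTable, age, year, sex):
    return rt.hazard(age, year, sex)
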