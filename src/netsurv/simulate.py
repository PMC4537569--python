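"""Cohort generation for the simulation scenarios.

Each subject gets a latent time to death from cancer, drawn from the
scenario's age-specific net-survival distribution, and a latent time to
death from other causes, drawn as a piecewise-exponential across the
one-year attained-age/calendar-year cells of a population rate table.
The observed follow-up is the minimum of the two, administratively
censored at the study horizon (15 years by default).  Both latent times
are retained on the generated cohort so that distributional tests can be
run against the analytic truths.

Cancer times are sampled by inverting U = S(t | age) with a
bracketed-Newton root finder on the cumulative excess hazard (absolute
tolerance 1e-10 on t, horizon capped at 100 years).  Other-cause times
walk cell by cell through the rate table: within a cell with annual rate
r the residual time is exponential with rate r, and attained age and
calendar year advance continuously.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .lifetable import RateTable, _encode_sex
from .scenarios import ScenarioSpec

__all__ = [
    "sample_cancer_time",
    "sample_othercause_time",
    "generate_cohort",
    "COHORT_COLUMNS",
]

#: canonical patient-file column order
COHORT_COLUMNS = ["id", "age_diag", "sex", "year_diag", "time_years", "event"]

_HORIZON = 100.0  # years; latent times are capped here


def sample_cancer_time(spec: ScenarioSpec, age, rng: np.random.Generator,
                       size: int | None = None, tol: float = 1e-10) -> np.ndarray:
    """Draw times to death from cancer with survival function S(t | age).

    ``age`` may be a scalar (with ``size`` draws) or an array (one draw per
    element).  Inversion solves Lambda(t; age) = -ln U by bisection-
    safeguarded Newton iteration to absolute tolerance ``tol`` on t; draws
    beyond the 100-year horizon are capped there.
    """
    age = np.asarray(age, dtype=float)
    if size is not None:
        age = np.broadcast_to(age, (size,)).copy()
    scalar = age.ndim == 0
    age = np.atleast_1d(age)
    u = rng.uniform(size=age.shape)
    target = -np.log(u)  # Exp(1) draws on the cumulative-hazard scale

    lam_max = spec.cum_excess_hazard(age, np.full_like(age, _HORIZON))
    lo = np.zeros_like(age)
    hi = np.full_like(age, _HORIZON)
    capped = target >= lam_max
    t = np.minimum(spec.baseline_cumhaz_inv(target), _HORIZON)  # baseline-shaped guess
    active = np.flatnonzero(~capped)
    for _ in range(100):
        if len(active) == 0:
            break
        ta, aa = t[active], age[active]
        f = spec.cum_excess_hazard(aa, ta) - target[active]
        hi[active] = np.where(f > 0, np.minimum(hi[active], ta), hi[active])
        lo[active] = np.where(f <= 0, np.maximum(lo[active], ta), lo[active])
        lam = spec.excess_hazard(aa, np.maximum(ta, 1e-300))
        with np.errstate(divide="ignore", invalid="ignore"):
            step = np.where(lam > 0, f / lam, 0.0)
        t_new = ta - step
        bad = ~np.isfinite(t_new) | (t_new <= lo[active]) | (t_new >= hi[active])
        t_new = np.where(bad, 0.5 * (lo[active] + hi[active]), t_new)
        t[active] = t_new
        active = active[(hi[active] - lo[active]) >= tol]
    t = np.where(capped, _HORIZON, t)
    t = np.maximum(t, np.finfo(float).tiny)  # U == 1 maps to the minimum positive time
    return float(t[0]) if scalar else t


def sample_othercause_time(rt: RateTable, age, year, sex, rng: np.random.Generator,
                           size: int | None = None) -> np.ndarray:
    """Draw times to death from other causes from a population rate table.

    Piecewise-exponential: the hazard is constant within each one-year
    attained-age/calendar-year cell (value ``-ln p*``), and changes when
    the subject crosses an integer attained age or calendar year.  Draws
    are capped at 100 years (returned as exactly 100.0, effectively
    'never' at cancer-study horizons).
    """
    age = np.asarray(age, dtype=float)
    year = np.asarray(year, dtype=float)
    if size is not None:
        age = np.broadcast_to(age, (size,)).copy()
    scalar = age.ndim == 0
    age, year = np.atleast_1d(age), np.atleast_1d(year)
    age, year = np.broadcast_arrays(age, year)
    sex = np.broadcast_to(np.atleast_1d(np.asarray(sex)), age.shape)

    remaining = -np.log(rng.uniform(size=age.shape))  # Exp(1) budget
    t = np.zeros_like(age)
    out = np.full_like(age, _HORIZON)
    active = np.ones(age.shape, dtype=bool)
    # at most two boundary crossings per year of follow-up
    for _ in range(2 * int(_HORIZON) + 2):
        if not np.any(active):
            break
        a_now = age[active] + t[active]
        y_now = year[active] + t[active]
        r = rt.hazard(a_now, y_now, sex[active])
        # time to the next integer age or calendar-year crossing
        dt = np.minimum(np.floor(a_now + 1.0) - a_now, np.floor(y_now + 1.0) - y_now)
        dt = np.minimum(dt, _HORIZON - t[active])
        dies = remaining[active] <= r * dt
        with np.errstate(divide="ignore"):
            t_death = t[active] + np.where(r > 0, remaining[active] / np.where(r > 0, r, 1.0), np.inf)
        idx = np.flatnonzero(active)
        out[idx[dies]] = np.minimum(t_death[dies], _HORIZON)
        remaining[idx] -= r * dt
        t[idx] += dt
        still = ~dies & (t[idx] < _HORIZON)
        active[idx] = still
    return float(out[0]) if scalar else out


def generate_cohort(spec: ScenarioSpec, rt: RateTable, rng: np.random.Generator,
                    n: int | None = None) -> pd.DataFrame:
    """Generate one simulated patient cohort.

    Returns a DataFrame with the canonical patient columns plus the latent
    ``t_cancer`` and ``t_other`` times.  ``time_years`` is
    ``min(t_cancer, t_other, max_follow)`` and ``event`` is 1 unless the
    administrative cut at ``spec.max_follow`` is the minimum.
    """
    n = spec.n if n is None else int(n)
    if n <= 0:
        raise ValueError("cohort size must be positive")
    age = spec.age_distribution().rvs(size=n, random_state=rng)
    sex = rng.integers(1, 3, size=n)
    y0, y1 = spec.year_range
    year = rng.uniform(y0, y1 + 1, size=n)
    t_cancer = sample_cancer_time(spec, age, rng)
    t_other = sample_othercause_time(rt, age, year, sex, rng)
    t_obs = np.minimum(np.minimum(t_cancer, t_other), spec.max_follow)
    event = (t_obs < spec.max_follow).astype(np.int64)
    return pd.DataFrame(
        {
            "id": np.arange(n),
            "age_diag": age,
            "sex": sex,
            "year_diag": year,
            "time_years": t_obs,
            "event": event,
            "t_cancer": t_cancer,
            "t_other": t_other,
        }
    )


def read_cohort(path) -> pd.DataFrame:
    """Read a patient CSV (id, age_diag, sex, year_diag, time_years, event)."""
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"patient file is missing columns {missing}")
    df = df.copy()
    df["sex"] = _encode_sex(df["sex"].to_numpy()) + 1
    return df


def write_cohort(df: pd.DataFrame, path) -> None:
    cols = [c for c in df.columns if c in COHORT_COLUMNS or c in ("t_cancer", "t_other")]
    df[cols].to_csv(path, index=False, float_format="%.12g")
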