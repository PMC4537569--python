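"""Nonparametric excess-hazard (relative survival) estimators.

Three lifetable estimators share one computation: in each interval j an
excess mortality rate

    lambda_j = (sum_i w_ij d_ij - sum_i w_ij d*_ij) / (sum_i w_ij y_ij)

is formed from observed deaths, expected deaths and person-time, the
cumulative excess hazard is ``Lambda_j = sum_{l<=j} k_l lambda_l`` and
relative survival is ``R_j = exp(-Lambda_j)``.  They differ only in the
weights:

* **Ederer II** — all weights 1;
* **Pohar Perme** — ``w_ij = 1 / S*_ij``, the inverse of the subject's
  expected survival to the interval start, which removes the informative
  depletion of subjects with high other-cause mortality;
* **Brenner** — constant per-subject weights ``w_k/a_k`` re-weighting the
  age distribution at diagnosis to a reference population.

A Poisson-type variance treats expected deaths as fixed:
``var(lambda_j) = sum_i w_ij^2 d_ij / (sum_i w_ij y_ij)^2``, summed as
``var(Lambda_j) = sum_l k_l^2 var(lambda_l)``, with a log-scale 95 % CI
for R, ``R_j exp(-/+ z se(Lambda_j))``.  R is never truncated at 1:
nonparametric estimates can exceed 1 or increase by chance and the curve
records what the data say.

The estimators are exposed both as functions on an
:class:`~netsurv.intervals.IntervalTable` and as sklearn-style classes
(:class:`EdererII`, :class:`PoharPerme`, :class:`Brenner`) fitting a
cohort DataFrame directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.base import BaseEstimator

from .intervals import IntervalTable, split_monthly
from .lifetable import RateTable
from .standardize import StandardWeights

__all__ = [
    "SurvivalCurve",
    "ederer2",
    "pohar_perme",
    "brenner",
    "brenner_weights",
    "curve_variance",
    "EdererII",
    "PoharPerme",
    "Brenner",
]


@dataclass
class SurvivalCurve:
    """A relative-survival curve on an interval grid.

    ``t`` holds interval end points; ``lam`` the per-year excess hazard in
    each interval; ``zero_risk`` flags intervals with no (weighted)
    person-time, which carry ``lam = 0`` so the curve continues.
    """

    t: np.ndarray
    widths: np.ndarray
    lam: np.ndarray
    cumhaz: np.ndarray
    rel_surv: np.ndarray
    var_cumhaz: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    zero_risk: np.ndarray

    def cumhaz_at(self, times):
        """Cumulative excess hazard, piecewise linear within intervals."""
        times = np.asarray(times, dtype=float)
        edges = np.concatenate([[0.0], self.t])
        ch = np.concatenate([[0.0], self.cumhaz])
        j = np.clip(np.searchsorted(edges, times, side="right") - 1, 0, len(self.t) - 1)
        return ch[j] + self.lam[j] * (times - edges[j])

    def rel_surv_at(self, times):
        return np.exp(-self.cumhaz_at(times))

    def var_cumhaz_at(self, times):
        """var(Lambda) at the interval containing each time (step lookup)."""
        times = np.asarray(times, dtype=float)
        j = np.clip(np.searchsorted(self.t, times, side="left"), 0, len(self.t) - 1)
        return self.var_cumhaz[j]

    def ci_at(self, times, alpha: float = 0.05):
        z = norm.ppf(1 - alpha / 2)
        r = self.rel_surv_at(times)
        se = np.sqrt(self.var_cumhaz_at(times))
        return r * np.exp(-z * se), r * np.exp(z * se)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": self.t,
                "lambda": self.lam,
                "cum_excess_hazard": self.cumhaz,
                "rel_surv": self.rel_surv,
                "se": np.sqrt(self.var_cumhaz),
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.12g")


def _lifetable_curve(it: IntervalTable, w: np.ndarray, alpha: float = 0.05) -> SurvivalCurve:
    """Weighted lifetable curve; ``w`` is an (n, J) weight array."""
    num = (w * it.d).sum(axis=0) - (w * it.d_star).sum(axis=0)
    den = (w * it.y).sum(axis=0)
    zero = den <= 0.0
    safe_den = np.where(zero, 1.0, den)
    lam = np.where(zero, 0.0, num / safe_den)
    var_lam = np.where(zero, 0.0, (w**2 * it.d).sum(axis=0) / safe_den**2)
    k = it.widths
    cumhaz = np.cumsum(k * lam)
    var_cumhaz = np.cumsum(k**2 * var_lam)
    rel = np.exp(-cumhaz)
    z = norm.ppf(1 - alpha / 2)
    se = np.sqrt(var_cumhaz)
    return SurvivalCurve(
        t=it.breaks[1:].copy(), widths=k, lam=lam, cumhaz=cumhaz, rel_surv=rel,
        var_cumhaz=var_cumhaz, ci_low=rel * np.exp(-z * se), ci_high=rel * np.exp(z * se),
        zero_risk=zero,
    )


def ederer2(it: IntervalTable) -> SurvivalCurve:
    """Ederer II: unweighted excess-hazard lifetable."""
    if it.n_subjects == 0:
        raise ValueError("empty interval table")
    return _lifetable_curve(it, np.ones_like(it.y))


def pohar_perme(it: IntervalTable) -> SurvivalCurve:
    """Pohar Perme: contributions weighted by inverse expected survival."""
    if it.n_subjects == 0:
        raise ValueError("empty interval table")
    if np.any(it.s_star[it.at_risk] <= 0.0):
        raise ValueError("expected survival S* reached 0; Pohar Perme weight undefined")
    w = np.where(it.at_risk, 1.0 / it.s_star, 0.0)
    return _lifetable_curve(it, w)


def brenner(it: IntervalTable, subject_weights: np.ndarray) -> SurvivalCurve:
    """Brenner: all-age lifetable with constant per-subject weights."""
    if it.n_subjects == 0:
        raise ValueError("empty interval table")
    sw = np.asarray(subject_weights, dtype=float)
    if sw.shape != (it.n_subjects,):
        raise ValueError("one weight per subject required")
    if np.any(sw <= 0):
        raise ValueError("Brenner weights must be positive")
    return _lifetable_curve(it, np.broadcast_to(sw[:, None], it.y.shape))


def brenner_weights(ages, reference: StandardWeights) -> np.ndarray:
    """Per-subject weights w_k/a_k matching the cohort's age mix to ``reference``."""
    return reference.subject_weights(ages)


def curve_variance(it: IntervalTable, weights: np.ndarray | None = None) -> np.ndarray:
    """Poisson-type var(Lambda_j) per interval for the given weighting."""
    if weights is None:
        weights = np.ones_like(it.y)
    elif weights.ndim == 1:
        weights = np.broadcast_to(weights[:, None], it.y.shape)
    return _lifetable_curve(it, weights).var_cumhaz


# ----------------------------------------------------------------------------
# sklearn-style estimator classes


class _LifetableEstimator(BaseEstimator):
    """Shared fit machinery: cohort DataFrame -> fitted SurvivalCurve."""

    def __init__(self, interval_width: float = 1.0 / 12.0, max_years: float = 15.0):
        self.interval_width = interval_width
        self.max_years = max_years

    def _curve(self, it: IntervalTable) -> SurvivalCurve:  # pragma: no cover - abstract
        raise NotImplementedError

    def fit(self, X: pd.DataFrame, y=None, *, rate_table: RateTable):
        """Fit on a patient cohort.

        Parameters
        ----------
        X : DataFrame
            Patient table with ``age_diag``, ``sex``, ``year_diag``,
            ``time_years`` and ``event`` columns.
        rate_table : RateTable
            Population expected-mortality table.
        """
        it = split_monthly(X, rate_table, max_years=self.max_years, width=self.interval_width)
        self.intervals_ = it
        self.curve_ = self._curve(it)
        self.n_subjects_ = it.n_subjects
        return self

    def predict_relative_survival(self, times):
        """Fitted relative survival evaluated at the given times."""
        return self.curve_.rel_surv_at(times)


class EdererII(_LifetableEstimator):
    """All-age Ederer II excess-hazard lifetable estimator."""

    def _curve(self, it):
        return ederer2(it)


class PoharPerme(_LifetableEstimator):
    """Pohar Perme inverse-expected-survival weighted estimator."""

    def _curve(self, it):
        return pohar_perme(it)


class Brenner(_LifetableEstimator):
    """Brenner age-reweighted Ederer II estimator.

    Parameters
    ----------
    reference : StandardWeights or int
        Reference age distribution; an int selects the corresponding
        ICSS weight set.
    """

    def __init__(self, reference=1, interval_width: float = 1.0 / 12.0, max_years: float = 15.0):
        super().__init__(interval_width=interval_width, max_years=max_years)
        self.reference = reference

    def _curve(self, it):
        from .standardize import icss_weights

        ref = icss_weights(self.reference) if isinstance(self.reference, int) else self.reference
        self.subject_weights_ = brenner_weights(it.ages, ref)
        return brenner(it, self.subject_weights_)
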