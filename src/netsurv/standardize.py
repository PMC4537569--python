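"""Internal and external (ICSS) age standardization of relative survival.

A single summary survival figure for a cohort is a weighted average of
age-specific relative survival.  *Internal* standardization weights by the
cohort's own age distribution at diagnosis — the plain mean of individual
curves.  *External* (traditional) standardization forces a reference age
distribution, conventionally one of the three International Cancer
Survival Standard (ICSS) weight sets over the five age groups
15-44, 45-54, 55-64, 65-74 and 75+ years.

Two equivalent computation routes are provided: group-level
(:func:`standardize_grouped`, a weighted average of five age-group curves)
and subject-level (:func:`standardize_individual`, a weighted average of
per-subject predicted curves, the model-based route).  They agree exactly
when every subject within a group shares one curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AGE_GROUP_EDGES",
    "StandardWeights",
    "icss_weights",
    "internal_weights",
    "standardize_grouped",
    "standardize_individual",
    "CombinedCurve",
]

#: lower edges of the five standard age groups (upper edge of the last is +inf)
AGE_GROUP_EDGES = (15.0, 45.0, 55.0, 65.0, 75.0)

_ICSS = {
    1: (0.07, 0.12, 0.23, 0.29, 0.29),
    2: (0.28, 0.17, 0.21, 0.20, 0.14),
    3: (0.60, 0.10, 0.10, 0.10, 0.10),
}


@dataclass(frozen=True)
class StandardWeights:
    """Reference weights over the five standard age groups."""

    weights: np.ndarray
    label: str = "custom"
    edges: tuple = AGE_GROUP_EDGES
    observed: np.ndarray | None = field(default=None, compare=False)

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        if len(w) != len(self.edges):
            raise ValueError("one weight per age group required")
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
        if abs(w.sum() - 1.0) > 1e-12:
            raise ValueError(f"weights must sum to 1 (got {w.sum()!r})")

    def group_index(self, ages) -> np.ndarray:
        """0-based age-group index per age (ages below the first edge map to group 0)."""
        return np.clip(np.searchsorted(self.edges, np.asarray(ages, float), side="right") - 1, 0, None)

    def group_bounds(self):
        """(lower, upper) bounds per group; the last upper bound is +inf."""
        e = list(self.edges) + [np.inf]
        return [(e[k], e[k + 1]) for k in range(len(self.edges))]

    def subject_weights(self, ages) -> np.ndarray:
        """Per-subject standardization factors w_k / a_k.

        a_k is the observed proportion of the cohort in group k.  Raises if
        a group with positive reference weight is empty in the cohort.
        """
        ages = np.asarray(ages, dtype=float)
        g = self.group_index(ages)
        a = np.bincount(g, minlength=len(self.weights)) / len(ages)
        empty = (a == 0) & (self.weights > 0)
        if np.any(empty):
            k = int(np.argmax(empty))
            lo, hi = self.group_bounds()[k]
            raise ValueError(
                f"age group {lo:.0f}-{hi:.0f} is empty but carries weight "
                f"{self.weights[k]} — standardization impossible"
            )
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(a > 0, self.weights / np.where(a > 0, a, 1.0), 0.0)
        return ratio[g]


def icss_weights(which: int) -> StandardWeights:
    """One of the three published ICSS reference weight sets (1, 2 or 3)."""
    if which not in _ICSS:
        raise ValueError(f"ICSS weight set must be 1, 2 or 3, not {which!r}")
    return StandardWeights(weights=np.array(_ICSS[which]), label=f"ICSS{which}")


def internal_weights(ages, edges=AGE_GROUP_EDGES) -> StandardWeights:
    """Observed age-group proportions of a cohort as a weight set."""
    ages = np.asarray(ages, dtype=float)
    if len(ages) == 0:
        raise ValueError("empty cohort")
    g = np.clip(np.searchsorted(edges, ages, side="right") - 1, 0, None)
    a = np.bincount(g, minlength=len(edges)) / len(ages)
    return StandardWeights(weights=a, label="internal", edges=tuple(edges), observed=a)


@dataclass
class CombinedCurve:
    """A standardized relative-survival curve with normal-scale CIs."""

    t: np.ndarray
    rel_surv: np.ndarray
    var_rel_surv: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray

    def rel_surv_at(self, times):
        return np.interp(np.asarray(times, float), self.t, self.rel_surv)

    def ci_at(self, times):
        times = np.asarray(times, float)
        return (np.interp(times, self.t, self.ci_low), np.interp(times, self.t, self.ci_high))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "t": self.t,
                "rel_surv": self.rel_surv,
                "se": np.sqrt(self.var_rel_surv),
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
            }
        )


def standardize_grouped(curves, w: StandardWeights, alpha: float = 0.05) -> CombinedCurve:
    """Weighted average of age-group relative-survival curves.

    ``curves`` is a sequence of five group :class:`~netsurv.estimators.SurvivalCurve`
    objects (ordered by age group) on a common time grid.  The combined
    estimate is ``R_bar = sum_k w_k R_k`` on the survival scale; its
    variance treats the group estimates as independent (they are computed
    on disjoint subjects), ``var(R_bar) = sum_k w_k^2 var(R_k)`` with
    ``var(R_k)`` from the delta method on the cumulative excess hazard.
    The CI is normal on the survival scale.
    """
    from scipy.stats import norm

    curves = list(curves)
    if len(curves) != len(w.weights):
        raise ValueError(f"need {len(w.weights)} group curves, got {len(curves)}")
    if any(c is None for c in curves):
        k = next(i for i, c in enumerate(curves) if c is None)
        raise ValueError(f"missing curve for age group {k} — standardization impossible")
    t = np.asarray(curves[0].t, dtype=float)
    for c in curves[1:]:
        if len(c.t) != len(t) or not np.allclose(c.t, t):
            raise ValueError("group curves must share one time grid")
    R = np.stack([c.rel_surv for c in curves])
    varR = np.stack([c.rel_surv**2 * c.var_cumhaz for c in curves])
    wk = w.weights[:, None]
    rbar = (wk * R).sum(axis=0)
    var = (wk**2 * varR).sum(axis=0)
    z = norm.ppf(1 - alpha / 2)
    se = np.sqrt(var)
    return CombinedCurve(t=t, rel_surv=rbar, var_rel_surv=var,
                         ci_low=rbar - z * se, ci_high=rbar + z * se)


def standardize_individual(curves, mode: str = "internal",
                           w: StandardWeights | None = None, ages=None) -> np.ndarray:
    """Average per-subject relative-survival curves.

    ``curves`` is an (n_subjects, n_times) array of predicted relative
    survival.  ``mode='internal'`` returns the plain mean;
    ``mode='external'`` weights subject i by ``w_k/a_k`` for the subject's
    age group (``ages`` required).
    """
    curves = np.asarray(curves, dtype=float)
    if curves.ndim != 2:
        raise ValueError("curves must be (n_subjects, n_times)")
    if mode == "internal":
        return curves.mean(axis=0)
    if mode != "external":
        raise ValueError("mode must be 'internal' or 'external'")
    if w is None or ages is None:
        raise ValueError("external mode requires weights and subject ages")
    sw = w.subject_weights(ages)
    return (sw[:, None] * curves).sum(axis=0) / len(curves)
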