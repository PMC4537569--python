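"""Flexible parametric excess-mortality model on the log cumulative hazard scale.

The all-cause hazard of subject i is decomposed as
``h_i(t) = h*_i(t) + lambda_i(t)`` with ``h*`` the expected (population)
rate and ``lambda`` the excess rate.  The excess component is modelled
through a restricted-cubic-spline function of log time,

    ln Lambda_i(t) = s0(ln t) + f(age_i) + sum_m f_m(age_i) * s_m(ln t),

so the baseline log cumulative excess hazard is a spline (default 5 df),
age enters either grouped (indicator contrasts over the five standard
age groups) or continuously (restricted cubic spline, default 3 df), and
non-proportional excess hazards are allowed by interacting every age term
with a spline of log time (default 3 df each).

The model is fitted by maximising the exact likelihood

    l = sum_i [ d_i * ln(h*_i(t_i) + lambda_i(t_i)) - Lambda_i(t_i) ]

with ``lambda = dLambda/dt`` obtained analytically from the spline
derivative, using BFGS with an analytic gradient.  During optimisation a
linearly-extended log barrier keeps event contributions defined when a
trial parameter makes ``h* + lambda`` non-positive.

Subject-level predicted relative survival ``R_i(t) = exp(-Lambda_i(t))``
feeds internal or external age standardization; confidence intervals for
standardized curves use a parametric bootstrap over the estimated
coefficient distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from sklearn.base import BaseEstimator

from .lifetable import RateTable
from .standardize import AGE_GROUP_EDGES, StandardWeights, standardize_individual

__all__ = [
    "rcs_basis",
    "FlexibleParametricModel",
    "FittedCurves",
    "fpm_fit",
    "fpm_predict",
    "fpm_standardize",
]


def rcs_basis(x, knots, derivative: bool = False) -> np.ndarray:
    """Restricted cubic spline basis (natural spline, linear beyond boundaries).

    With K knots ``k_1 < ... < k_K`` the basis has K-1 columns: the first
    is x itself; column j (j = 2..K-1) is

        (x - k_j)_+^3 - l_j (x - k_1)_+^3 - (1 - l_j) (x - k_K)_+^3,

    with ``l_j = (k_K - k_j) / (k_K - k_1)``, which forces the second and
    third derivatives to vanish beyond the boundary knots.  With
    ``derivative=True`` the column-wise derivative d/dx is returned.
    """
    x = np.asarray(x, dtype=float)
    knots = np.asarray(knots, dtype=float)
    if len(knots) < 3:
        raise ValueError("restricted cubic splines need at least 3 knots")
    if np.any(np.diff(knots) <= 0):
        raise ValueError("knots must be strictly increasing")
    kmin, kmax = knots[0], knots[-1]
    cols = [np.ones_like(x) if derivative else x]
    for kj in knots[1:-1]:
        lj = (kmax - kj) / (kmax - kmin)
        if derivative:
            col = (
                3.0 * np.maximum(x - kj, 0.0) ** 2
                - lj * 3.0 * np.maximum(x - kmin, 0.0) ** 2
                - (1.0 - lj) * 3.0 * np.maximum(x - kmax, 0.0) ** 2
            )
        else:
            col = (
                np.maximum(x - kj, 0.0) ** 3
                - lj * np.maximum(x - kmin, 0.0) ** 3
                - (1.0 - lj) * np.maximum(x - kmax, 0.0) ** 3
            )
        cols.append(col)
    return np.stack(cols, axis=-1)


def _quantile_knots(values: np.ndarray, df: int) -> np.ndarray:
    """df+1 knots at equally spaced centiles (boundaries at min/max)."""
    q = np.linspace(0.0, 1.0, df + 1)
    knots = np.quantile(values, q)
    # degenerate quantiles (ties) are nudged apart minimally
    for i in range(1, len(knots)):
        if knots[i] <= knots[i - 1]:
            knots[i] = knots[i - 1] + 1e-8
    return knots


@dataclass
class _Design:
    """Frozen design information for building Z(ln t, age) matrices."""

    baseline_knots: np.ndarray
    time_knots: np.ndarray | None
    age_mode: str                 # 'continuous' | 'grouped' | 'none'
    age_knots: np.ndarray | None  # continuous mode
    age_edges: tuple | None       # grouped mode
    kept_age_cols: np.ndarray | None  # mask after dropping degenerate columns
    n_params: int
    # centring/scaling of the non-intercept design columns: raw cubic spline
    # columns span many orders of magnitude and BFGS needs comparable scales
    col_mean: np.ndarray | None = None
    col_scale: np.ndarray | None = None

    def age_terms(self, age: np.ndarray) -> np.ndarray:
        if self.age_mode == "none":
            return np.empty((len(age), 0))
        if self.age_mode == "continuous":
            A = rcs_basis(age, self.age_knots)
        else:
            g = np.clip(np.searchsorted(self.age_edges, age, side="right") - 1, 0, None)
            A = (g[:, None] == np.arange(1, len(self.age_edges))[None, :]).astype(float)
        if self.kept_age_cols is not None:
            A = A[:, self.kept_age_cols]
        return A

    def matrices(self, lnt: np.ndarray, age: np.ndarray):
        """Z and dZ/d(ln t) at (ln t, age) pairs."""
        B = rcs_basis(lnt, self.baseline_knots)
        dB = rcs_basis(lnt, self.baseline_knots, derivative=True)
        A = self.age_terms(age)
        ones = np.ones((len(lnt), 1))
        zeros_a = np.zeros_like(A)
        blocks_z = [ones, B, A]
        blocks_u = [np.zeros_like(ones), dB, zeros_a]
        if self.time_knots is not None and A.shape[1]:
            D = rcs_basis(lnt, self.time_knots)
            dD = rcs_basis(lnt, self.time_knots, derivative=True)
            for m in range(A.shape[1]):
                blocks_z.append(A[:, m : m + 1] * D)
                blocks_u.append(A[:, m : m + 1] * dD)
        Z = np.concatenate(blocks_z, axis=1)
        U = np.concatenate(blocks_u, axis=1)
        if self.col_mean is not None:
            Z = (Z - self.col_mean) / self.col_scale
            U = U / self.col_scale
        return Z, U

    def freeze_scaling(self, Z_raw: np.ndarray) -> None:
        """Fix column centring/scaling from the training design matrix."""
        mean = Z_raw.mean(axis=0)
        scale = Z_raw.std(axis=0)
        mean[0] = 0.0  # leave the intercept column untouched
        scale[0] = 1.0
        scale[scale < 1e-12] = 1.0
        self.col_mean = mean
        self.col_scale = scale


class ConvergenceError(RuntimeError):
    """Raised when the likelihood optimisation fails."""


class FlexibleParametricModel(BaseEstimator):
    """Spline-based excess-hazard model (fit/predict estimator).

    Parameters
    ----------
    df_baseline : int
        Degrees of freedom of the baseline log-cumulative-hazard spline.
    age : {'continuous', 'grouped', 'none'}
        Age coding: restricted cubic spline, standard-age-group
        indicators, or no age effect.
    df_age : int
        Spline df for continuous age.
    df_time : int
        df of the time-dependent effect spline per age term
        (0 = proportional excess hazards).
    """

    def __init__(self, df_baseline: int = 5, age: str = "continuous", df_age: int = 3,
                 df_time: int = 3, age_edges: tuple = AGE_GROUP_EDGES,
                 max_iter: int = 400, tol: float = 1e-9):
        self.df_baseline = df_baseline
        self.age = age
        self.df_age = df_age
        self.df_time = df_time
        self.age_edges = age_edges
        self.max_iter = max_iter
        self.tol = tol

    # -- fitting -------------------------------------------------------------

    def fit(self, X: pd.DataFrame, y=None, *, rate_table: RateTable | None = None,
            max_years: float | None = None):
        """Fit to a patient cohort.

        ``rate_table=None`` fits an ordinary all-cause parametric survival
        model (``h* = 0``), useful for validation against closed-form
        all-cause distributions.
        """
        t = X["time_years"].to_numpy(dtype=float)
        d = X["event"].to_numpy(dtype=float)
        if max_years is not None:
            d = np.where(t > max_years, 0.0, d)
            t = np.minimum(t, max_years)
        if np.any(t <= 0):
            raise ValueError("all follow-up times must be positive")
        if d.sum() == 0:
            raise ValueError("no events in the cohort")
        age = X["age_diag"].to_numpy(dtype=float)
        if rate_table is None:
            hstar = np.zeros_like(t)
        else:
            hstar = rate_table.hazard(
                age + t, X["year_diag"].to_numpy(dtype=float) + t, X["sex"].to_numpy()
            )
        lnt = np.log(t)

        design = self._build_design(lnt, age, d)
        Z_raw, _ = design.matrices(lnt, age)
        design.freeze_scaling(Z_raw)
        Z, U = design.matrices(lnt, age)

        beta0 = self._initial_beta(Z, lnt, t, d)
        nll = self._make_negloglik(Z, U, t, d, hstar)
        res = optimize.minimize(
            nll, beta0, jac=True, method="BFGS",
            options={"maxiter": self.max_iter, "gtol": self.tol * len(t)},
        )
        if not res.success:  # one restart with a fresh Hessian often finishes the job
            res = optimize.minimize(
                nll, res.x, jac=True, method="BFGS",
                options={"maxiter": self.max_iter, "gtol": self.tol * len(t)},
            )
        if not np.all(np.isfinite(res.x)):
            raise ConvergenceError("optimiser returned non-finite coefficients")
        self.design_ = design
        self.coef_ = res.x
        self.loglik_ = -res.fun
        self.n_iter_ = res.nit
        self.converged_ = bool(res.success) or np.linalg.norm(res.jac, np.inf) < 1e-3 * len(t)
        self.gradient_norm_ = float(np.linalg.norm(res.jac, np.inf))
        self.covariance_ = self._covariance(nll, res.x)
        self.n_subjects_ = len(t)
        return self

    def _build_design(self, lnt, age, d) -> _Design:
        ev = d > 0
        baseline_knots = _quantile_knots(lnt[ev], self.df_baseline)
        time_knots = _quantile_knots(lnt[ev], self.df_time) if self.df_time > 0 else None
        age_knots = None
        age_edges = None
        kept = None
        if self.age == "continuous":
            age_knots = _quantile_knots(age, self.df_age)
            A = rcs_basis(age, age_knots)
            kept = A.std(axis=0) > 1e-10  # drop columns constant in this cohort
        elif self.age == "grouped":
            age_edges = tuple(self.age_edges)
            g = np.clip(np.searchsorted(age_edges, age, side="right") - 1, 0, None)
            A = (g[:, None] == np.arange(1, len(age_edges))[None, :]).astype(float)
            kept = A.std(axis=0) > 1e-10
        elif self.age != "none":
            raise ValueError("age must be 'continuous', 'grouped' or 'none'")
        n_age = 0 if kept is None else int(kept.sum())
        n_par = 1 + self.df_baseline + n_age + (self.df_time * n_age if self.df_time else 0)
        return _Design(
            baseline_knots=baseline_knots, time_knots=time_knots, age_mode=self.age,
            age_knots=age_knots, age_edges=age_edges, kept_age_cols=kept, n_params=n_par,
        )

    @staticmethod
    def _initial_beta(Z, lnt, t, d) -> np.ndarray:
        """Regress a crude Nelson-Aalen log cumulative hazard on the design."""
        order = np.argsort(t, kind="stable")
        at_risk = len(t) - np.arange(len(t))
        na = np.cumsum(d[order] / at_risk)
        lnH = np.log(np.maximum(na, 1e-10))
        Zo = Z[order]
        sel = d[order] > 0
        beta, *_ = np.linalg.lstsq(Zo[sel], lnH[sel], rcond=None)
        return beta

    @staticmethod
    def _make_negloglik(Z, U, t, d, hstar, barrier: float = 1e-8, kappa: float = 1e4):
        # eta is clipped at +-30 (Lambda <= ~1e13) so trial steps far from the
        # optimum cannot overflow; event terms below `barrier` switch to a
        # quadratic penalty that pushes h* + lambda back positive.
        def negloglik(beta):
            eta = np.clip(Z @ beta, -30.0, 30.0)
            Lam = np.exp(eta)
            deta = U @ beta
            lam = Lam * deta / t
            arg = hstar + lam
            good = arg > barrier
            log_arg = np.log(np.where(good, arg, barrier))
            short = np.where(good, 0.0, arg - barrier)
            ll = np.sum(d * log_arg) - np.sum(Lam) - kappa * np.sum(d * short**2)
            dll_darg = d * np.where(good, 1.0 / np.where(good, arg, 1.0), -2.0 * kappa * short)
            # dlam/dbeta = (Lam/t) * (Z * deta + U);  dLam/dbeta = Lam * Z
            w1 = dll_darg * Lam / t
            grad = Z.T @ (w1 * deta) + U.T @ w1 - Z.T @ Lam
            return -ll, -grad

        return negloglik

    @staticmethod
    def _covariance(nll, beta) -> np.ndarray:
        """Observed information by central differences of the analytic gradient."""
        p = len(beta)
        H = np.zeros((p, p))
        h = 1e-5 * np.maximum(np.abs(beta), 1.0)
        for j in range(p):
            e = np.zeros(p)
            e[j] = h[j]
            gp = nll(beta + e)[1]
            gm = nll(beta - e)[1]
            H[:, j] = (gp - gm) / (2.0 * h[j])
        H = 0.5 * (H + H.T)
        return np.linalg.pinv(H)

    # -- prediction ----------------------------------------------------------

    def _check_fitted(self):
        if not hasattr(self, "coef_"):
            raise RuntimeError("model is not fitted")

    def cumulative_excess_hazard(self, age, times, coef: np.ndarray | None = None):
        """Lambda(t | age) on a grid; shape (n_ages, n_times)."""
        self._check_fitted()
        beta = self.coef_ if coef is None else coef
        age = np.atleast_1d(np.asarray(age, dtype=float))
        times = np.atleast_1d(np.asarray(times, dtype=float))
        if np.any(times <= 0):
            raise ValueError("prediction times must be positive")
        out = np.empty((len(age), len(times)))
        for k, tt in enumerate(times):
            lnt = np.full(len(age), np.log(tt))
            Z, _ = self.design_.matrices(lnt, age)
            out[:, k] = np.exp(np.clip(Z @ beta, -700.0, 700.0))
        return out

    def predict_relative_survival(self, age, times, coef: np.ndarray | None = None):
        """Subject-level predicted relative survival, shape (n_ages, n_times)."""
        return np.exp(-self.cumulative_excess_hazard(age, times, coef=coef))

    def standardized_survival(self, ages, times, mode: str = "internal",
                              weights: StandardWeights | None = None,
                              n_boot: int = 200, alpha: float = 0.05,
                              rng: np.random.Generator | None = None) -> "FittedCurves":
        """Age-standardized predicted net survival with bootstrap CIs.

        The point estimate averages the per-subject predicted curves over
        ``ages`` (plain mean internally, ``w_k/a_k``-weighted externally).
        The CI is a percentile interval over ``n_boot`` multivariate-normal
        coefficient draws from the fitted covariance.
        """
        self._check_fitted()
        ages = np.asarray(ages, dtype=float)
        times = np.atleast_1d(np.asarray(times, dtype=float))
        point = standardize_individual(
            self.predict_relative_survival(ages, times), mode=mode, w=weights, ages=ages
        )
        if n_boot <= 0:
            return FittedCurves(t=times, rel_surv=point, ci_low=None, ci_high=None, draws=None)
        if rng is None:
            rng = np.random.default_rng(0)
        draws = rng.multivariate_normal(self.coef_, self.covariance_, size=n_boot,
                                        method="svd")
        if mode == "external":
            sw = weights.subject_weights(ages)
        else:
            sw = np.ones(len(ages))
        boot = np.empty((n_boot, len(times)))
        for k, tt in enumerate(times):
            lnt = np.full(len(ages), np.log(tt))
            Z, _ = self.design_.matrices(lnt, ages)
            eta = Z @ draws.T  # (n, n_boot)
            R = np.exp(-np.exp(np.clip(eta, -700.0, 700.0)))
            boot[:, k] = (sw[:, None] * R).sum(axis=0) / len(ages)
        lo = np.quantile(boot, alpha / 2, axis=0)
        hi = np.quantile(boot, 1 - alpha / 2, axis=0)
        return FittedCurves(t=times, rel_surv=point, ci_low=lo, ci_high=hi, draws=boot)

    # -- persistence ---------------------------------------------------------

    def to_dict(self) -> dict:
        self._check_fitted()
        d = self.get_params()
        des = self.design_
        d.update(
            coef=self.coef_.tolist(),
            covariance=self.covariance_.tolist(),
            baseline_knots=des.baseline_knots.tolist(),
            time_knots=None if des.time_knots is None else des.time_knots.tolist(),
            age_knots=None if des.age_knots is None else des.age_knots.tolist(),
            kept_age_cols=None if des.kept_age_cols is None else des.kept_age_cols.tolist(),
            col_mean=None if des.col_mean is None else des.col_mean.tolist(),
            col_scale=None if des.col_scale is None else des.col_scale.tolist(),
            loglik=self.loglik_,
        )
        d["age_edges"] = list(d["age_edges"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "FlexibleParametricModel":
        d = dict(d)
        coef = np.asarray(d.pop("coef"))
        cov = np.asarray(d.pop("covariance"))
        bk = np.asarray(d.pop("baseline_knots"))
        tk = d.pop("time_knots")
        ak = d.pop("age_knots")
        kept = d.pop("kept_age_cols")
        cmean = d.pop("col_mean")
        cscale = d.pop("col_scale")
        loglik = d.pop("loglik")
        d["age_edges"] = tuple(d["age_edges"])
        model = cls(**d)
        model.coef_ = coef
        model.covariance_ = cov
        model.loglik_ = loglik
        model.design_ = _Design(
            baseline_knots=bk,
            time_knots=None if tk is None else np.asarray(tk),
            age_mode=model.age,
            age_knots=None if ak is None else np.asarray(ak),
            age_edges=tuple(model.age_edges) if model.age == "grouped" else None,
            kept_age_cols=None if kept is None else np.asarray(kept, dtype=bool),
            n_params=len(coef),
            col_mean=None if cmean is None else np.asarray(cmean),
            col_scale=None if cscale is None else np.asarray(cscale),
        )
        model.converged_ = True
        return model


@dataclass
class FittedCurves:
    """A standardized model-based curve with percentile bootstrap CIs."""

    t: np.ndarray
    rel_surv: np.ndarray
    ci_low: np.ndarray | None
    ci_high: np.ndarray | None
    draws: np.ndarray | None

    def rel_surv_at(self, times):
        return np.interp(np.asarray(times, float), self.t, self.rel_surv)

    def ci_at(self, times):
        times = np.asarray(times, float)
        return (np.interp(times, self.t, self.ci_low), np.interp(times, self.t, self.ci_high))


# ----------------------------------------------------------------------------
# functional wrappers


def fpm_fit(cohort: pd.DataFrame, rate_table: RateTable | None = None,
            **config) -> FlexibleParametricModel:
    """Fit a flexible parametric excess-hazard model (see the class docs)."""
    return FlexibleParametricModel(**config).fit(cohort, rate_table=rate_table)


def fpm_predict(model: FlexibleParametricModel, age, times):
    """Predicted relative survival for subjects of the given ages."""
    return model.predict_relative_survival(age, times)


def fpm_standardize(model: FlexibleParametricModel, cohort: pd.DataFrame, times,
                    mode: str = "internal", weights: StandardWeights | None = None,
                    n_boot: int = 200, rng=None) -> FittedCurves:
    """Standardize predicted curves over a cohort's age distribution."""
    return model.standardized_survival(
        cohort["age_diag"].to_numpy(dtype=float), times, mode=mode, weights=weights,
        n_boot=n_boot, rng=rng,
    )
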