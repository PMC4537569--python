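"""Simulation harness: replicate cohorts, estimators, bias / MSE / coverage.

For each replicate a cohort is generated from a calibrated scenario, every
requested estimator is applied, and the age-standardized net-survival
estimates at the report times are compared with the known truths:

* the *internal* truth is recomputed per replicate as the mean true net
  survival over that replicate's own subjects (the estimand an internally
  standardized estimator targets is cohort-dependent);
* the *external* truth is fixed, computed once from the age-group truth
  curves under the reference weights.

Aggregation reports, per (scenario, standardization mode, method, time):
bias in percentage points (mean estimate minus truth, x100), MSE on the
percentage scale, coverage (% of replicates whose 95 % CI contains the
truth), the number of replicates used and the Monte-Carlo standard error
of the bias.  Replicates where a method fails (e.g. an empty oldest age
group under external standardization) are excluded for that method and
counted.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .estimators import brenner, brenner_weights, ederer2, pohar_perme
from .fpm import FlexibleParametricModel
from .intervals import split_monthly
from .lifetable import RateTable
from .scenarios import ScenarioSpec, true_standardized
from .simulate import generate_cohort
from .standardize import StandardWeights, icss_weights, internal_weights, standardize_grouped

__all__ = ["SimulationReport", "run_experiment", "summarize", "METHODS"]

#: method name -> standardization modes it supports
METHODS = {
    "pohar_perme": ("internal", "external"),
    "ederer2_all": ("internal",),
    "ederer2_std": ("internal", "external"),
    "brenner": ("external",),
    "fpm_grouped": ("internal", "external"),
    "fpm_continuous": ("internal", "external"),
}

_REPORT_COLS = ["scenario", "mode", "method", "time", "bias", "mse", "coverage",
                "n_reps", "mcse_bias"]


@dataclass
class SimulationReport:
    """Aggregated simulation results (one row per scenario/mode/method/time)."""

    frame: pd.DataFrame
    exclusions: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["mode", "method", "replicate", "reason"]))

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False, float_format="%.12g")

    @classmethod
    def read_csv(cls, path) -> "SimulationReport":
        return cls(frame=pd.read_csv(path))

    def cell(self, mode: str, method: str, time: float) -> pd.Series:
        f = self.frame
        sel = (f["mode"] == mode) & (f["method"] == method) & (f["time"] == time)
        if not sel.any():
            raise KeyError((mode, method, time))
        return f.loc[sel].iloc[0]


def _lifetable_estimates(it, group_idx, n_groups, which, weights, times):
    """Point estimates and CIs at `times` for one lifetable method family."""
    if which == "all_age":
        curve = ederer2(it)
        lo, hi = curve.ci_at(times)
        return curve.rel_surv_at(times), lo, hi
    if which == "pp_all":
        curve = pohar_perme(it)
        lo, hi = curve.ci_at(times)
        return curve.rel_surv_at(times), lo, hi
    if which == "brenner":
        curve = brenner(it, brenner_weights(it.ages, weights))
        lo, hi = curve.ci_at(times)
        return curve.rel_surv_at(times), lo, hi
    estimator = pohar_perme if which == "pp_groups" else ederer2
    curves = []
    for k in range(n_groups):
        sub = it.subset(group_idx == k)
        if sub.n_subjects == 0:
            raise ValueError(f"age group {k} empty — grouped standardization impossible")
        curves.append(estimator(sub))
    comb = standardize_grouped(curves, weights)
    lo, hi = comb.ci_at(times)
    return comb.rel_surv_at(times), lo, hi


def run_experiment(spec: ScenarioSpec, rt: RateTable, methods, n_reps: int,
                   master_seed: int, report_times=(1.0, 5.0, 10.0, 15.0),
                   modes=("internal", "external"),
                   external_weights: StandardWeights | int = 1,
                   n: int | None = None, interval_width: float = 1.0 / 12.0,
                   fpm_boot: int = 200) -> SimulationReport:
    """Run the replicate experiment for one scenario.

    Parameters
    ----------
    methods : sequence of str
        Any of ``pohar_perme``, ``ederer2_all``, ``ederer2_std``,
        ``brenner``, ``fpm_grouped``, ``fpm_continuous``.
    n_reps : int
        Number of replicate cohorts (>= 2).
    master_seed : int
        Master seed; replicate r uses the substream ``(master_seed, r)``.
    """
    if n_reps < 2:
        raise ValueError("need at least 2 replicates")
    methods = list(methods)
    unknown = [m for m in methods if m not in METHODS]
    if unknown:
        raise ValueError(f"unknown methods {unknown}")
    if isinstance(external_weights, int):
        external_weights = icss_weights(external_weights)
    times = np.asarray(report_times, dtype=float)
    tasks = [(m, mode) for m in methods for mode in METHODS[m] if mode in modes]
    if not tasks:
        raise ValueError("no (method, mode) combinations selected")

    ext_truth = None
    if "external" in modes:
        ext_truth = true_standardized(spec, times, "external", weights=external_weights)

    est = {tk: np.full((n_reps, len(times)), np.nan) for tk in tasks}
    ci_lo = {tk: np.full((n_reps, len(times)), np.nan) for tk in tasks}
    ci_hi = {tk: np.full((n_reps, len(times)), np.nan) for tk in tasks}
    int_truth = np.full((n_reps, len(times)), np.nan)
    excl = []

    need_lifetable = any(m != "fpm_grouped" and m != "fpm_continuous" for m, _ in tasks)
    for r in range(n_reps):
        rng = np.random.default_rng(np.random.SeedSequence((master_seed, r)))
        cohort = generate_cohort(spec, rt, rng, n=n)
        ages = cohort["age_diag"].to_numpy(dtype=float)
        int_truth[r] = true_standardized(spec, times, "internal", ages=ages)
        it = group_idx = None
        if need_lifetable:
            it = split_monthly(cohort, rt, max_years=spec.max_follow, width=interval_width)
            group_idx = external_weights.group_index(ages)
        fitted = {}
        for age_mode in ("grouped", "continuous"):
            if any(m == f"fpm_{age_mode}" for m, _ in tasks):
                try:
                    fitted[age_mode] = FlexibleParametricModel(age=age_mode).fit(
                        cohort, rate_table=rt, max_years=spec.max_follow
                    )
                except Exception as e:  # noqa: BLE001 - excluded and reported
                    fitted[age_mode] = e
        for m, mode in tasks:
            w = internal_weights(ages) if mode == "internal" else external_weights
            try:
                if m.startswith("fpm_"):
                    model = fitted[m[4:]]
                    if isinstance(model, Exception):
                        raise model
                    fc = model.standardized_survival(
                        ages, times, mode=mode,
                        weights=w if mode == "external" else None,
                        n_boot=fpm_boot, rng=rng,
                    )
                    e, lo, hi = fc.rel_surv, fc.ci_low, fc.ci_high
                else:
                    which = {
                        "pohar_perme": "pp_all" if mode == "internal" else "pp_groups",
                        "ederer2_all": "all_age",
                        "ederer2_std": "groups",
                        "brenner": "brenner",
                    }[m]
                    e, lo, hi = _lifetable_estimates(
                        it, group_idx, len(external_weights.weights), which, w, times
                    )
                est[(m, mode)][r], ci_lo[(m, mode)][r], ci_hi[(m, mode)][r] = e, lo, hi
            except Exception as exc:  # noqa: BLE001
                excl.append({"mode": mode, "method": m, "replicate": r, "reason": str(exc)})

    rows = []
    for (m, mode) in tasks:
        truth = int_truth if mode == "internal" else np.broadcast_to(ext_truth, int_truth.shape)
        e = est[(m, mode)]
        ok = ~np.isnan(e).any(axis=1)
        if not ok.any():
            raise RuntimeError(f"all replicates failed for method {m!r} ({mode})")
        err = (e[ok] - truth[ok]) * 100.0
        cover = (ci_lo[(m, mode)][ok] <= truth[ok]) & (truth[ok] <= ci_hi[(m, mode)][ok])
        for j, tt in enumerate(times):
            rows.append(
                {
                    "scenario": spec.scenario,
                    "mode": mode,
                    "method": m,
                    "time": tt,
                    "bias": err[:, j].mean(),
                    "mse": (err[:, j] ** 2).mean(),
                    "coverage": 100.0 * cover[:, j].mean(),
                    "n_reps": int(ok.sum()),
                    "mcse_bias": err[:, j].std(ddof=1) / np.sqrt(ok.sum()),
                }
            )
    return SimulationReport(frame=pd.DataFrame(rows, columns=_REPORT_COLS),
                            exclusions=pd.DataFrame(excl, columns=["mode", "method",
                                                                   "replicate", "reason"]))


def ederer2_large_sample_limit(spec: ScenarioSpec, rt: RateTable, age_window,
                               times=(5.0, 10.0, 15.0), width: float = 1.0 / 12.0,
                               n_ages: int = 161, n_sub: int = 4):
    """Deterministic large-n limit of the monthly Ederer II estimator.

    Replaces every Monte-Carlo sum in the estimator by its expectation
    under the scenario: within the age window [lo, hi), subjects follow
    the scenario's net-survival distribution and the rate table's
    other-cause mortality, and the interval sums E[d_j], E[d*_j], E[y_j]
    are evaluated by quadrature over the age distribution and time.  The
    result isolates estimand-level bias (informative depletion within the
    window plus interval discretization) from Monte-Carlo noise.

    Returns ``(limit, truth)``: the estimator's limiting relative survival
    and the true mean net survival over the window, both evaluated at
    ``times``.
    """
    times = np.asarray(times, dtype=float)
    lo = max(age_window[0], spec.age_range[0])
    hi = min(age_window[1], spec.age_range[1])
    if lo >= hi:
        raise ValueError(f"empty age window {age_window}")
    ages = np.linspace(lo, hi, n_ages)
    wa = spec.age_distribution().pdf(ages)
    wa = wa / np.trapezoid(wa, ages)
    year = 0.5 * (spec.year_range[0] + spec.year_range[1])
    sex = 1  # the synthetic tables are sex-constant

    n_int = int(round(spec.max_follow / width))
    fine = np.linspace(0.0, spec.max_follow, n_int * n_sub + 1)
    s_net = spec.net_survival(ages[:, None], fine[None, :])
    rates = rt.hazard(ages[:, None] + fine[None, :], year + fine[None, :], sex)
    h_star = np.concatenate(
        [np.zeros((n_ages, 1)),
         np.cumsum(0.5 * (rates[:, 1:] + rates[:, :-1]) * np.diff(fine)[None, :], axis=1)],
        axis=1,
    )
    s_all = s_net * np.exp(-h_star)
    mid = (np.arange(n_int) + 0.5) * width
    rate_mid = rt.hazard(ages[:, None] + mid[None, :], year + mid[None, :], sex)

    idx = np.arange(0, n_int * n_sub + 1, n_sub)
    cumhaz = 0.0
    curve = np.zeros(n_int)
    for j in range(n_int):
        seg = s_all[:, idx[j]:idx[j + 1] + 1]
        y = np.trapezoid(seg, fine[idx[j]:idx[j + 1] + 1], axis=1)
        e_d = np.trapezoid(wa * (s_all[:, idx[j]] - s_all[:, idx[j + 1]]), ages)
        e_y = np.trapezoid(wa * y, ages)
        e_dstar = np.trapezoid(wa * rate_mid[:, j] * y, ages)
        cumhaz += width * (e_d - e_dstar) / e_y
        curve[j] = np.exp(-cumhaz)
    ends = (np.arange(n_int) + 1) * width
    limit = np.interp(times, ends, curve)
    truth = np.trapezoid(
        wa[:, None] * spec.net_survival(ages[:, None], times[None, :]), ages, axis=0
    )
    return limit, truth


def summarize(report: SimulationReport):
    """Per-mode tables: methods as rows, report times as columns.

    Returns a dict ``(scenario, mode) -> DataFrame`` whose cells stack
    bias / MSE / coverage, plus a ``text`` key with an aligned rendering.
    """
    out = {}
    text = io.StringIO()
    f = report.frame
    for (scen, mode), chunk in f.groupby(["scenario", "mode"], sort=True):
        tbl = chunk.pivot(index="method", columns="time", values=["bias", "mse", "coverage"])
        out[(scen, mode)] = tbl
        print(f"\nScenario {scen} — {mode} age standardization", file=text)
        times = sorted(chunk["time"].unique())
        header = "method".ljust(16) + "".join(f"{t:>12.0f}y" for t in times)
        print(header, file=text)
        for method, rows in chunk.groupby("method", sort=False):
            rows = rows.set_index("time").sort_index()
            print(method.ljust(16) + "".join(f"{rows.loc[t, 'bias']:>13.4f}" for t in times)
                  + "   bias (pp)", file=text)
            print("".ljust(16) + "".join(f"{rows.loc[t, 'mse']:>13.4f}" for t in times)
                  + "   MSE", file=text)
            print("".ljust(16) + "".join(f"{rows.loc[t, 'coverage']:>13.1f}" for t in times)
                  + "   coverage (%)", file=text)
    out["text"] = text.getvalue()
    return out
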