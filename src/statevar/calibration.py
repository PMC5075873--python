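"""Vmax calibration against observed metabolite time courses.

The objective is the sum over fitting-target metabolites and sample times
of squared log10 residuals between simulated and observed amounts, matching
a log-log presentation of fit quality.  Optimization is bounded local least
squares restarted from several seeded random initial guesses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .metabolic_model import MetabolicModel, ModelError
from .ode_engine import OdeError, Perturbation, simulate

logger = logging.getLogger(__name__)

_LOG_FLOOR = 1e-12  # amounts below this are floored before log10


class FitError(RuntimeError):
    """Optimizer failed to converge; carries best-so-far diagnostics."""

    def __init__(self, message: str, best_vmax: dict | None = None, cost: float | None = None):
        super().__init__(message)
        self.best_vmax = best_vmax
        self.cost = cost


@dataclass
class ObservedTimecourse:
    """Long-format observations: metabolite_id, time_days, amount, se."""

    condition: str
    data: pd.DataFrame

    REQUIRED = ("metabolite_id", "time_days", "amount")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValueError(f"observed data missing columns {missing}")
        if "se" not in self.data.columns:
            self.data = self.data.assign(se=np.nan)
        if (self.data["amount"] <= 0).any():
            bad = self.data.loc[self.data["amount"] <= 0, "metabolite_id"].unique()
            raise ValueError(
                f"non-positive observed amounts for {sorted(bad)}; "
                "log-scale fitting requires amounts > 0"
            )

    @property
    def metabolite_ids(self) -> tuple[str, ...]:
        return tuple(self.data["metabolite_id"].unique())

    @property
    def times(self) -> np.ndarray:
        return np.sort(self.data["time_days"].unique())

    @classmethod
    def from_csv(cls, path: str | Path, condition: str | None = None) -> "ObservedTimecourse":
        df = pd.read_csv(path)
        if condition is None:
            if "condition" not in df.columns or df["condition"].nunique() != 1:
                raise ValueError(
                    "pass condition= or provide a CSV with a single-valued "
                    "'condition' column"
                )
            condition = str(df["condition"].iloc[0])
        elif "condition" in df.columns:
            df = df[df["condition"] == condition]
        return cls(condition=condition, data=df.reset_index(drop=True))

    def to_csv(self, path: str | Path) -> None:
        self.data.assign(condition=self.condition)[
            ["condition", "metabolite_id", "time_days", "amount", "se"]
        ].to_csv(path, index=False)


@dataclass
class FitResult:
    model: MetabolicModel
    condition: str
    vmax: dict[str, float]
    cost: float
    n_starts: int
    best_start: int
    trace: list[dict] = field(default_factory=list)


def _simulate_log_amounts(
    model: MetabolicModel,
    condition: str,
    met_ids: Sequence[str],
    times: np.ndarray,
    rtol: float,
    atol: float,
) -> np.ndarray:
    duration = float(times.max())
    interval = float(np.diff(np.concatenate([[0.0], times])).min())
    tc = simulate(
        model,
        Perturbation(),
        duration=duration,
        sample_interval=interval,
        condition=condition,
        rtol=rtol,
        atol=atol,
    )
    cols = []
    t_index = {round(t / interval): k for k, t in enumerate(tc.times)}
    rows = [t_index[round(t / interval)] for t in times]
    for met in met_ids:
        cols.append(tc.amount(met)[rows])
    return np.log10(np.maximum(np.column_stack(cols), _LOG_FLOOR))


def _observed_matrix(observed: ObservedTimecourse, met_ids, times) -> np.ndarray:
    piv = observed.data.pivot_table(
        index="time_days", columns="metabolite_id", values="amount"
    )
    try:
        mat = piv.loc[list(times), list(met_ids)].to_numpy(dtype=float)
    except KeyError as exc:
        raise ValueError(f"observed data missing entries: {exc}") from exc
    if np.isnan(mat).any():
        raise ValueError("observed data has missing metabolite/time combinations")
    return np.log10(mat)


def fit_vmax(
    model: MetabolicModel,
    observed: ObservedTimecourse,
    condition: str,
    vmax_ids: Sequence[str] | None = None,
    n_starts: int = 5,
    seed: int = 0,
    upper_bound: float = 100.0,
    sim_rtol: float = 1e-7,
    sim_atol: float = 1e-9,
    start_spread: float = 2.0,
) -> FitResult:
    """Fit the named condition's Vmax values to the observed time courses.

    ``vmax_ids`` restricts the fit to a subset of reactions (all by
    default).  Start 0 is the model's current Vmax set; the remaining
    starts multiply it by seeded log-uniform factors in
    ``[1/start_spread, start_spread]``.  The best final objective wins,
    ties broken by lowest start index.
    """
    if condition not in model.conditions:
        raise ModelError(f"condition {condition!r} not in {model.conditions}")
    met_ids = [m for m in model.fitting_target_ids if m in observed.metabolite_ids]
    if not met_ids:
        raise ValueError("observed data covers no fitting-target metabolite")
    times = observed.times[observed.times > 0]
    if times.size == 0:
        raise ValueError("observed data has no post-initial sample times")
    log_obs = _observed_matrix(observed, met_ids, times)

    if vmax_ids is None:
        vmax_ids = [r.id for r in model.reactions]
    else:
        vmax_ids = list(vmax_ids)
        for rid in vmax_ids:
            model.reaction(rid)
    x_base = np.array([model.reaction(r).vmax(condition) for r in vmax_ids])
    if (x_base <= 0).any():
        raise ValueError("initial Vmax guesses must be positive for every fitted reaction")

    def residuals(x: np.ndarray) -> np.ndarray:
        trial = model.with_vmax(condition, dict(zip(vmax_ids, x)))
        log_sim = _simulate_log_amounts(
            trial, condition, met_ids, times, sim_rtol, sim_atol
        )
        return (log_sim - log_obs).ravel()

    rng = np.random.default_rng(seed)
    best = None
    trace: list[dict] = []
    for start in range(n_starts):
        if start == 0:
            x0 = x_base.copy()
        else:
            factors = np.exp(
                rng.uniform(-np.log(start_spread), np.log(start_spread), x_base.size)
            )
            x0 = np.clip(x_base * factors, 1e-6, upper_bound)
        try:
            sol = least_squares(
                residuals,
                x0,
                bounds=(0.0, upper_bound),
                x_scale=np.maximum(x_base, 1e-3),
                xtol=1e-10,
                ftol=1e-10,
                gtol=1e-10,
            )
        except OdeError as exc:
            logger.warning("start %d aborted: %s", start, exc)
            trace.append({"start": start, "cost": np.inf, "status": str(exc)})
            continue
        trace.append({"start": start, "cost": float(sol.cost), "status": sol.status})
        logger.info("fit start %d: cost %.6g status %s", start, sol.cost, sol.status)
        if sol.status > 0 and (best is None or sol.cost < best[1] - 1e-15):
            best = (start, float(sol.cost), sol.x.copy())
    if best is None:
        raise FitError("no optimizer start converged", best_vmax=None, cost=None)
    start, cost, x = best
    vmax = {rid: float(v) for rid, v in zip(vmax_ids, x)}
    return FitResult(
        model=model.with_vmax(condition, vmax),
        condition=condition,
        vmax=vmax,
        cost=cost,
        n_starts=n_starts,
        best_start=start,
        trace=trace,
    )


def goodness_of_fit(
    model: MetabolicModel,
    observed: ObservedTimecourse,
    condition: str,
    sim_rtol: float = 1e-8,
    sim_atol: float = 1e-10,
) -> float:
    """Identity-line r^2 of log10 simulated vs log10 observed amounts.

    Pools all fitting targets and post-initial sample times; 1 means exact
    agreement, values <= 0 mean the model explains no more than the mean of
    the observations.
    """
    met_ids = [m for m in model.fitting_target_ids if m in observed.metabolite_ids]
    if not met_ids:
        raise ValueError("observed data covers no fitting-target metabolite")
    times = observed.times[observed.times > 0]
    log_obs = _observed_matrix(observed, met_ids, times).ravel()
    if log_obs.size < 2:
        raise ValueError("need at least two observation points for r^2")
    log_sim = _simulate_log_amounts(
        model, condition, met_ids, times, sim_rtol, sim_atol
    ).ravel()
    ss_res = float(((log_obs - log_sim) ** 2).sum())
    ss_tot = float(((log_obs - log_obs.mean()) ** 2).sum())
    if ss_tot == 0:
        return 1.0 if ss_res == 0 else -np.inf
    return 1.0 - ss_res / ss_tot
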