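"""Numerical integration of a kinetic metabolic model.

Produces daily-sampled metabolite time courses under exhaustive doubling
perturbations of the declared state metabolites.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .metabolic_model import MetabolicModel, ModelError

DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-10
# round-off undershoot below zero tolerated before it is treated as a
# model/integrator failure; kept well above atol so LSODA noise never trips it
DEFAULT_NEG_TOL = 1e-9


class OdeError(RuntimeError):
    """Integration failed or the state left the physical domain."""


@dataclass(frozen=True)
class Perturbation:
    """Initial-condition doubling of a subset of the state metabolites."""

    doubled: tuple[str, ...] = ()

    @property
    def label(self) -> str:
        return "+".join(self.doubled) if self.doubled else "none"


@dataclass
class Timecourse:
    """Sampled amounts from one simulation run."""

    times: np.ndarray                     # (n_times,) days, strictly increasing
    amounts: np.ndarray                   # (n_times, n_metabolites)
    metabolite_ids: tuple[str, ...]
    run_label: str = "none"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.amounts = np.asarray(self.amounts, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("sample times must be strictly increasing")
        if self.amounts.shape != (self.times.size, len(self.metabolite_ids)):
            raise ValueError("amounts shape does not match times/metabolites")

    def amount(self, met_id: str) -> np.ndarray:
        try:
            j = self.metabolite_ids.index(met_id)
        except ValueError:
            raise KeyError(f"metabolite {met_id!r} not in timecourse") from None
        return self.amounts[:, j]

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: run_label, time_days, metabolite_id, amount."""
        n_t, n_m = self.amounts.shape
        return pd.DataFrame(
            {
                "run_label": self.run_label,
                "time_days": np.repeat(self.times, n_m),
                "metabolite_id": list(self.metabolite_ids) * n_t,
                "amount": self.amounts.ravel(),
            }
        )


def _resolve_condition(model: MetabolicModel, condition: str | None) -> str:
    if condition is not None:
        if condition not in model.conditions:
            raise ModelError(
                f"condition {condition!r} not in model conditions {model.conditions}"
            )
        return condition
    if len(model.conditions) == 1:
        return model.conditions[0]
    raise ModelError(
        "model has two conditions; pass condition= explicitly or interpolate() first"
    )


def _compile_rhs(model: MetabolicModel, condition: str):
    """Precompute index arrays for a fast dense RHS closure."""
    idx = {m: j for j, m in enumerate(model.metabolite_ids)}
    n = len(idx)
    rxns = []
    for r in model.reactions:
        sub_idx = np.array([idx[m] for m, _ in r.substrates], dtype=int)
        km = np.array([r.km[m] for m, _ in r.substrates], dtype=float)
        stoich = np.zeros(n)
        for m, c in r.substrates:
            stoich[idx[m]] -= c
        for m, c in r.products:
            stoich[idx[m]] += c
        inh = None
        if r.inhibitor is not None:
            inh = (idx[r.inhibitor[0]], r.inhibitor[1])
        rxns.append((r.vmax(condition), sub_idx, km, stoich, inh))

    def rhs(_t: float, y: np.ndarray) -> np.ndarray:
        s = np.maximum(y, 0.0)  # guard transient round-off negatives
        dy = np.zeros_like(y)
        for vmax, sub_idx, km, stoich, inh in rxns:
            if vmax == 0.0:
                continue
            rate = vmax * np.prod(s[sub_idx] / (km + s[sub_idx]))
            if inh is not None:
                j, ki = inh
                rate *= ki / (ki + s[j])
            dy += rate * stoich
        return dy

    return rhs


def simulate(
    model: MetabolicModel,
    perturbation: Perturbation | None = None,
    duration: float = 4.0,
    sample_interval: float = 1.0,
    condition: str | None = None,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    neg_tol: float = DEFAULT_NEG_TOL,
) -> Timecourse:
    """Integrate ``d[x]/dt = sum stoich * rate`` and sample every interval.

    The perturbation doubles the initial amounts of the named state
    metabolites.  Samples fall at ``t = 0, interval, ..., duration``.
    """
    if duration <= 0:
        raise ValueError(f"duration must be > 0, got {duration}")
    n_steps = duration / sample_interval
    if abs(n_steps - round(n_steps)) > 1e-9:
        raise ValueError(
            f"sample_interval {sample_interval} does not divide duration {duration}"
        )
    cond = _resolve_condition(model, condition)
    perturbation = perturbation or Perturbation()
    state_ids = set(model.state_metabolite_ids)
    for met in perturbation.doubled:
        if met not in state_ids:
            raise ModelError(
                f"perturbation names {met!r}, which is not a declared state metabolite"
            )

    y0 = np.array([m.initial_amount for m in model.metabolites])
    idx = {m: j for j, m in enumerate(model.metabolite_ids)}
    for met in perturbation.doubled:
        y0[idx[met]] *= 2.0

    t_eval = np.linspace(0.0, duration, int(round(n_steps)) + 1)
    sol = solve_ivp(
        _compile_rhs(model, cond),
        (0.0, duration),
        y0,
        method="LSODA",
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise OdeError(
            f"integration failed for perturbation {perturbation.label!r}: "
            f"{sol.message}"
        )
    amounts = sol.y.T
    worst = amounts.min()
    if worst < -neg_tol:
        raise OdeError(
            f"state went negative ({worst:.3e} < -{neg_tol:.0e}) for "
            f"perturbation {perturbation.label!r}; check the model"
        )
    if worst < 0:
        warnings.warn(
            f"clipping round-off negative amounts (min {worst:.3e}) to zero",
            RuntimeWarning,
            stacklevel=2,
        )
        amounts = np.clip(amounts, 0.0, None)
    return Timecourse(
        times=t_eval,
        amounts=amounts,
        metabolite_ids=model.metabolite_ids,
        run_label=perturbation.label,
    )


def enumerate_perturbations(model: MetabolicModel) -> list[Perturbation]:
    """All 2^k doubling subsets of the declared state metabolites.

    Canonical order is binary counting with the first declared state
    metabolite as the least-significant bit; the empty set comes first.
    """
    state = model.state_metabolite_ids
    if not state:
        raise ModelError("model declares no state metabolites")
    out = []
    for code in range(2 ** len(state)):
        out.append(
            Perturbation(
                doubled=tuple(m for j, m in enumerate(state) if code >> j & 1)
            )
        )
    return out


def batch_simulate(
    model: MetabolicModel,
    perturbations: Iterable[Perturbation],
    duration: float = 4.0,
    sample_interval: float = 1.0,
    condition: str | None = None,
    **kwargs,
) -> list[Timecourse]:
    """simulate() over a perturbation list, order preserved, deterministic."""
    out = []
    for p in perturbations:
        try:
            out.append(
                simulate(
                    model,
                    p,
                    duration=duration,
                    sample_interval=sample_interval,
                    condition=condition,
                    **kwargs,
                )
            )
        except OdeError as exc:
            raise OdeError(f"perturbation {p.label!r}: {exc}") from exc
    return out


def write_timecourses_csv(timecourses: Sequence[Timecourse], path: str | Path) -> None:
    pd.concat([tc.to_frame() for tc in timecourses], ignore_index=True).to_csv(
        path, index=False
    )
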