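"""Discrete system states and the two headline statistics.

Variation of state is the Shannon entropy (base 2, reported in bits) of the
empirical distribution of discrete system states pooled over a trajectory
set and a time window.  Robustness is the fraction of module states at the
final observation time that match the unperturbed reference's initial
state, averaged over modules and runs.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .metabolic_model import MetabolicModel
from .ode_engine import Timecourse

State = tuple[int, ...]


@dataclass(frozen=True)
class StateTrajectory:
    """Time-indexed discrete states for one run (index = sample position)."""

    run_label: str
    states: tuple[State, ...]

    def __post_init__(self) -> None:
        if not self.states:
            raise ValueError("trajectory must contain at least one state")
        n = len(self.states[0])
        if any(len(s) != n for s in self.states):
            raise ValueError("inconsistent state tuple length across time")

    @property
    def n_components(self) -> int:
        return len(self.states[0])


@dataclass
class StateDistribution:
    """Empirical counts over discrete states."""

    counts: dict[State, int]
    total: int

    def __post_init__(self) -> None:
        if self.total <= 0:
            raise ValueError("total must be positive")
        if sum(self.counts.values()) != self.total:
            raise ValueError("counts do not sum to total")

    def probabilities(self) -> dict[State, float]:
        return {s: c / self.total for s, c in self.counts.items()}

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: state bit pattern, count, probability."""
        rows = [
            ("".join(map(str, s)), c, c / self.total)
            for s, c in sorted(self.counts.items())
        ]
        return pd.DataFrame(rows, columns=["state", "count", "probability"])


@dataclass(frozen=True)
class MetricsResult:
    variation_of_state: float          # bits
    robustness: float | None           # in [0, 1]; None when not computed
    window: tuple[int, int]
    n_runs: int

    def to_dict(self) -> dict:
        return {
            "variation_of_state_bits": self.variation_of_state,
            "robustness": self.robustness,
            "window": list(self.window),
            "n_runs": self.n_runs,
        }


def discretize(
    timecourse: Timecourse,
    model: MetabolicModel,
    strict: bool = False,
) -> StateTrajectory:
    """Boolean accumulation state per sample time and state metabolite.

    A metabolite counts as accumulated when its amount reaches at least
    double the unperturbed declared initial amount (set ``strict=True`` to
    require strictly more than double, under which a doubled initial
    condition does not register at t = 0).
    """
    state_ids = model.state_metabolite_ids
    if not state_ids:
        raise ValueError("model declares no state metabolites")
    baselines = []
    for met in state_ids:
        b = model.metabolite(met).initial_amount
        if b <= 0:
            raise ValueError(
                f"state metabolite {met!r} has non-positive baseline {b}; "
                "the doubling threshold is undefined"
            )
        baselines.append(b)
    cols = np.column_stack([timecourse.amount(m) for m in state_ids])
    thresh = 2.0 * np.asarray(baselines)
    flags = cols > thresh if strict else cols >= thresh
    states = tuple(tuple(int(v) for v in row) for row in flags)
    return StateTrajectory(run_label=timecourse.run_label, states=states)


def pool_states(
    trajectories: Sequence[StateTrajectory],
    window: tuple[int, int],
) -> StateDistribution:
    """Count state occurrences over all runs and sample indices in [t0, t1]."""
    if not trajectories:
        raise ValueError("empty trajectory list")
    t0, t1 = window
    counts: Counter[State] = Counter()
    for traj in trajectories:
        if t0 < 0 or t1 >= len(traj.states) or t0 > t1:
            raise ValueError(
                f"window {window} outside trajectory range "
                f"[0, {len(traj.states) - 1}] for run {traj.run_label!r}"
            )
        counts.update(traj.states[t0 : t1 + 1])
    return StateDistribution(counts=dict(counts), total=sum(counts.values()))


def variation_of_state(dist: StateDistribution) -> float:
    """H = -sum P(x) log2 P(x) in bits, with 0*log(0) := 0."""
    h = 0.0
    for c in dist.counts.values():
        if c > 0:
            p = c / dist.total
            h -= p * math.log2(p)
    return h


class EntropyAccumulator:
    """Streaming Shannon entropy over a growing state sample.

    Maintains ``S = sum c log2 c`` so that ``H = log2(N) - S / N`` is
    available after every update without revisiting earlier states.
    """

    def __init__(self) -> None:
        self._counts: Counter[State] = Counter()
        self._total = 0
        self._s = 0.0

    def add(self, state: State) -> None:
        c = self._counts[state]
        if c > 0:
            self._s -= c * math.log2(c)
        c += 1
        self._counts[state] = c
        self._s += c * math.log2(c)
        self._total += 1

    @property
    def total(self) -> int:
        return self._total

    def entropy(self) -> float:
        if self._total == 0:
            raise ValueError("no states added")
        return math.log2(self._total) - self._s / self._total

    def distribution(self) -> StateDistribution:
        return StateDistribution(counts=dict(self._counts), total=self._total)


def robustness(
    perturbed: Sequence[StateTrajectory],
    reference: StateTrajectory,
) -> float:
    """Mean over runs and modules of [final state == reference initial state]."""
    if not perturbed:
        raise ValueError("empty trajectory list")
    ref0 = reference.states[0]
    m = len(ref0)
    hits = 0
    for traj in perturbed:
        if traj.n_components != m:
            raise ValueError(
                f"run {traj.run_label!r} has {traj.n_components} components, "
                f"reference has {m}"
            )
        final = traj.states[-1]
        hits += sum(int(a == b) for a, b in zip(final, ref0))
    return hits / (m * len(perturbed))


def percent_of_max(h_before: float, h_after: float, n_states: int) -> int:
    """Entropy change as a rounded percent of the theoretical maximum.

    Positive values are losses, negative values gains; rounding is to the
    nearest integer, halves away from zero.
    """
    if n_states < 2:
        raise ValueError(f"n_states must be >= 2, got {n_states}")
    pct = 100.0 * (h_before - h_after) / math.log2(n_states)
    return int(math.copysign(math.floor(abs(pct) + 0.5), pct))
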