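"""The four computational experiments as reproducible pipeline stages.

Each stage is a pure function of its model/network, configuration, and
seed: a lambda sweep over the blended kinetic models, a four-fold enzyme
over-expression screen with expression-annotation statistics, and the two
Boolean module-network experiments (step-input stimulation and enforced
module expression).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import boolean_dynamics as bd
from .boolean_dynamics import BooleanModuleNetwork
from .metabolic_model import MetabolicModel, interpolate, overexpress
from .ode_engine import Perturbation, batch_simulate, enumerate_perturbations
from .state_metrics import (
    MetricsResult,
    StateTrajectory,
    discretize,
    pool_states,
    robustness,
    variation_of_state,
)
from .stats_tests import (
    ProportionReport,
    RankSumReport,
    binomial_point,
    two_sample_proportion,
    wilcoxon_rank_sum,
)

N_LAMBDA = 33


def lambda_grid(n: int = N_LAMBDA) -> np.ndarray:
    """The interpolation grid {0, 1/(n-1), ..., 1}; 33 points by default."""
    if n < 2:
        raise ValueError("grid needs at least 2 points")
    return np.linspace(0.0, 1.0, n)


@dataclass
class LambdaSweepResult:
    lams: np.ndarray
    metrics: list[MetricsResult]

    def __post_init__(self) -> None:
        if len(self.lams) != len(self.metrics):
            raise ValueError("lambda grid and metrics length mismatch")
        if np.any(np.diff(self.lams) <= 0):
            raise ValueError("lambda grid must be strictly increasing")

    def variation(self) -> np.ndarray:
        return np.array([m.variation_of_state for m in self.metrics])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "lam": self.lams,
                "variation_of_state_bits": self.variation(),
                "robustness": [m.robustness for m in self.metrics],
                "n_runs": [m.n_runs for m in self.metrics],
            }
        )


@dataclass
class ScreenResult:
    baseline: MetricsResult
    table: pd.DataFrame  # reaction_id, variation_of_state_bits, robustness, expressed
    proportion: ProportionReport | None
    proportion_note: str
    binomial_p: float | None
    binomial_n: int
    binomial_k: int


def _metabolic_metrics(
    model: MetabolicModel,
    duration: float,
    interval: float,
    window: tuple[int, int],
) -> tuple[MetricsResult, list[StateTrajectory]]:
    """Run the full 2^k doubling design on a single-condition model."""
    perts = enumerate_perturbations(model)
    tcs = batch_simulate(model, perts, duration=duration, sample_interval=interval)
    trajs = [discretize(tc, model) for tc in tcs]
    dist = pool_states(trajs, window=window)
    # canonical order puts the unperturbed run first; its t=0 state is the
    # unperturbed initial state required by the robustness definition
    r = robustness(trajs, reference=trajs[0])
    return (
        MetricsResult(
            variation_of_state=variation_of_state(dist),
            robustness=r,
            window=window,
            n_runs=len(trajs),
        ),
        trajs,
    )


def lambda_sweep(
    model: MetabolicModel,
    duration: float = 4.0,
    interval: float = 1.0,
    window: tuple[int, int] | None = None,
    n_lambda: int = N_LAMBDA,
) -> LambdaSweepResult:
    """Metrics for every blended model on the 33-point lambda grid."""
    if window is None:
        window = (1, int(round(duration / interval)))
    lams = lambda_grid(n_lambda)
    metrics = [
        _metabolic_metrics(interpolate(model, lam), duration, interval, window)[0]
        for lam in lams
    ]
    return LambdaSweepResult(lams=lams, metrics=metrics)


def region_median_test(
    sweep: LambdaSweepResult, cut: float = 0.375
) -> RankSumReport:
    """Wilcoxon rank-sum on variation of state: lam < cut vs lam >= cut."""
    vos = sweep.variation()
    low = vos[sweep.lams < cut]
    high = vos[sweep.lams >= cut]
    if low.size == 0 or high.size == 0:
        raise ValueError(f"cut {cut} leaves an empty group")
    return wilcoxon_rank_sum(low, high)


def overexpression_screen(
    model: MetabolicModel,
    annotation: pd.DataFrame,
    factor: float = 4.0,
    duration: float = 4.0,
    interval: float = 1.0,
    window: tuple[int, int] | None = None,
    condition: str = "control",
) -> ScreenResult:
    """Four-fold over-expression of each reaction, one at a time.

    Per reaction: multiply its Vmax in the chosen condition, run the full
    doubling-perturbation design, and record variation of state and
    robustness.  Two summary statistics follow: a one-sided two-sample
    proportion test on the fraction of 'expressed' enzymes among cases with
    variation of state below half the control value, and the binomial point
    probability that, among expressed cases whose (robustness, variation)
    pair moved, the observed number landed in the doubly-decreased quadrant
    by chance (quadrant probability 1/4).
    """
    if window is None:
        window = (1, int(round(duration / interval)))
    if not {"reaction_id", "expressed"} <= set(annotation.columns):
        raise ValueError("annotation table needs reaction_id and expressed columns")
    expressed = dict(
        zip(annotation["reaction_id"].astype(str), annotation["expressed"].astype(int))
    )
    lam0 = interpolate(model, 0.0)
    baseline, _ = _metabolic_metrics(lam0, duration, interval, window)
    rows = []
    for rxn in model.reactions:
        edited = interpolate(overexpress(model, rxn.id, factor, condition), 0.0)
        metrics, _ = _metabolic_metrics(edited, duration, interval, window)
        rows.append(
            (
                rxn.id,
                metrics.variation_of_state,
                metrics.robustness,
                expressed.get(rxn.id, 0),
            )
        )
    table = pd.DataFrame(
        rows,
        columns=["reaction_id", "variation_of_state_bits", "robustness", "expressed"],
    )

    half = 0.5 * baseline.variation_of_state
    low = table[table["variation_of_state_bits"] < half]
    high = table[table["variation_of_state_bits"] >= half]
    proportion = None
    note = ""
    if len(low) == 0 or len(high) == 0:
        note = "one of the variation-of-state regions is empty"
    else:
        try:
            proportion = two_sample_proportion(
                int(low["expressed"].sum()),
                len(low),
                int(high["expressed"].sum()),
                len(high),
                sided="one",
            )
        except ValueError as exc:
            note = str(exc)

    moved = table[
        (table["expressed"] == 1)
        & (
            (table["robustness"] != baseline.robustness)
            | (table["variation_of_state_bits"] != baseline.variation_of_state)
        )
    ]
    n_moved = len(moved)
    k_down = int(
        (
            (moved["robustness"] < baseline.robustness)
            & (moved["variation_of_state_bits"] < baseline.variation_of_state)
        ).sum()
    )
    binom_p = binomial_point(n_moved, k_down, 0.25) if n_moved > 0 else None
    return ScreenResult(
        baseline=baseline,
        table=table,
        proportion=proportion,
        proportion_note=note,
        binomial_p=binom_p,
        binomial_n=n_moved,
        binomial_k=k_down,
    )


def _boolean_metrics(
    network: BooleanModuleNetwork,
    n_steps: int,
    window: tuple[int, int],
    reference_state: tuple[int, ...],
) -> MetricsResult:
    """Exhaustive simulation from every initial state, pooled entropy."""
    trajs = [
        StateTrajectory(
            run_label=str(code),
            states=tuple(bd.simulate_boolean(network, init, n_steps)),
        )
        for code, init in enumerate(bd.enumerate_states(network.n_modules))
    ]
    dist = pool_states(trajs, window=window)
    ref = StateTrajectory(run_label="reference", states=(reference_state,))
    return MetricsResult(
        variation_of_state=variation_of_state(dist),
        robustness=robustness(trajs, ref),
        window=window,
        n_runs=len(trajs),
    )


def pma_experiment(
    network: BooleanModuleNetwork,
    n_steps: int = 8,
    window: tuple[int, int] | None = None,
    reference_state: tuple[int, ...] | None = None,
) -> tuple[MetricsResult, MetricsResult]:
    """Metrics before (inputs at pre-onset values) and after (inputs on).

    The robustness reference is the all-inactive module state by
    convention; pass ``reference_state`` to use another.
    """
    if window is None:
        window = (1, n_steps)
    if reference_state is None:
        reference_state = (0,) * network.n_modules
    before = _boolean_metrics(bd.inputs_off(network), n_steps, window, reference_state)
    after = _boolean_metrics(network, n_steps, window, reference_state)
    return before, after


ENFORCED_CASES: Mapping[str, dict] = {
    # differentiation-type enforced expression, step inputs kept on
    "case1": {"clamped": ("A1", "A2", "B2", "C1"), "inputs_on": True},
    # dedifferentiation-type enforced expression, no step inputs
    "case2": {"clamped": ("B2",), "inputs_on": False},
}


def enforced_expression_experiment(
    network: BooleanModuleNetwork,
    case: str,
    n_steps: int = 8,
    window: tuple[int, int] | None = None,
    reference_state: tuple[int, ...] | None = None,
) -> MetricsResult:
    """Clamp the case's modules active for the whole run and measure."""
    if case not in ENFORCED_CASES:
        raise ValueError(
            f"unknown case {case!r}; expected one of {sorted(ENFORCED_CASES)}"
        )
    spec = ENFORCED_CASES[case]
    if window is None:
        window = (1, n_steps)
    if reference_state is None:
        reference_state = (0,) * network.n_modules
    net = bd.with_clamps(network, {m: 1 for m in spec["clamped"]})
    if not spec["inputs_on"]:
        net = bd.inputs_off(net)
    return _boolean_metrics(net, n_steps, window, reference_state)
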