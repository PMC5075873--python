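"""Seeded generators for every pipeline input.

The metabolic fixture is an authored reconstruction of a seedling central
carbon network: glycolysis, fermentation, the TCA cycle, and the GABA shunt
(2-oxoglutarate -> glutamate -> GABA -> succinate), with 33 irreversible
reactions, 11 fitting-target metabolites, and the four GABA-shunt members
flagged as state metabolites.  The stressed Vmax set is tuned so those four
accumulate past double their baseline within a day, emulating a
flooding-type response; kinetic values are plausible orders of magnitude,
not measurements.

The Boolean fixture is a ladder of two four-module channels
(A1-B1-C1-D1 / A2-B2-C2-D2) bridged by inhibitory interactions, with total
interaction multiplicities of 19 promoting and 17 inhibitory, and
step-function inputs on B1 (0 -> 1) and B2 (1 -> 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .boolean_dynamics import BooleanModuleNetwork, Edge, InputSchedule
from .calibration import ObservedTimecourse
from .metabolic_model import (
    CONTROL,
    STRESSED,
    MetaboliteSpec,
    MetabolicModel,
    ReactionSpec,
)
from .ode_engine import Perturbation, simulate


@dataclass(frozen=True)
class GeneratorConfig:
    seed: int = 0
    n_reactions: int = 6
    n_metabolites: int = 5
    noise_cv: float = 0.05
    topology: Literal["fig1", "random"] = "fig1"
    vmax_fold_change_range: tuple[float, float] = (0.25, 4.0)

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")


# id, name, initial amount, fitting target, state metabolite
_METABOLITES = [
    ("Suc", "sucrose", 60.0, False, False),
    ("G6P", "glucose 6-phosphate", 2.0, False, False),
    ("F6P", "fructose 6-phosphate", 1.2, False, False),
    ("FBP", "fructose 1,6-bisphosphate", 0.8, False, False),
    ("GAP", "glyceraldehyde 3-phosphate", 0.5, False, False),
    ("PEP", "phosphoenolpyruvate", 1.0, True, False),
    ("EP", "enolpyruvate", 0.4, False, False),
    ("Pyr", "pyruvate", 2.0, True, False),
    ("Lac", "lactate", 1.0, True, False),
    ("EtOH", "ethanol", 0.5, False, False),
    ("AcCoA", "acetyl-CoA", 0.6, False, False),
    ("Cit", "citrate", 3.0, False, False),
    ("OAA", "oxaloacetate", 0.8, True, False),
    ("2OG", "2-oxoglutarate", 0.4, True, True),
    ("Glu", "glutamate", 0.6, True, True),
    ("GABA", "gamma-aminobutyrate", 0.3, True, True),
    ("SSA", "succinic semialdehyde", 0.15, False, False),
    ("SucCoA", "succinyl-CoA", 0.4, False, False),
    ("Su", "succinate", 0.8, True, True),
    ("Fum", "fumarate", 0.9, False, False),
    ("Mal", "malate", 2.5, False, False),
    ("Ala", "alanine", 2.0, True, False),
    ("Asp", "aspartate", 2.2, True, False),
    ("Gln", "glutamine", 1.8, True, False),
]

# id, substrates, products, Vmax control, Vmax stressed.
# Km defaults to the substrate baseline (half saturation at rest) unless
# overridden in _KM_OVERRIDES below.
_REACTIONS = [
    ("R1", {"Suc": 1}, {"G6P": 1}, 2.0, 8.0),
    ("R2", {"G6P": 1}, {"F6P": 1}, 2.0, 8.0),
    ("R3", {"F6P": 1}, {"FBP": 1}, 2.0, 8.0),
    ("R4", {"FBP": 1}, {"GAP": 2}, 2.0, 8.0),
    ("R5", {"GAP": 1}, {"PEP": 1}, 4.0, 16.0),
    ("R6", {"PEP": 1}, {"EP": 1}, 3.4, 10.0),
    ("R7", {"EP": 1}, {"Pyr": 1}, 3.4, 10.0),
    ("R8", {"PEP": 1}, {"OAA": 1}, 0.6, 4.0),
    ("R9", {"Pyr": 1}, {"Lac": 1}, 1.0, 2.0),
    ("R10", {"Lac": 1}, {"Pyr": 1}, 0.4, 0.2),
    ("R11", {"Pyr": 1}, {"EtOH": 1}, 0.4, 1.2),
    ("R12", {"EtOH": 1}, {}, 0.4, 0.6),
    ("R13", {"Pyr": 1}, {"AcCoA": 1}, 1.6, 3.0),
    ("R14", {"AcCoA": 1, "OAA": 1}, {"Cit": 1}, 3.2, 12.0),
    ("R15", {"Cit": 1}, {"2OG": 1}, 1.6, 8.5),
    ("R16", {"Pyr": 1, "Glu": 1}, {"Ala": 1, "2OG": 1}, 0.8, 0.8),
    ("R17", {"Ala": 1}, {}, 0.4, 0.4),
    ("R18", {"2OG": 1}, {"Glu": 1}, 1.0, 3.2),
    ("R19", {"Glu": 1}, {"GABA": 1}, 1.25, 3.0),
    ("R20", {"GABA": 1}, {"SSA": 1}, 0.3, 0.45),
    ("R21", {"SSA": 1}, {"Su": 1}, 0.5, 1.5),
    ("R22", {"2OG": 1}, {"SucCoA": 1}, 1.2, 0.9),
    ("R23", {"SucCoA": 1}, {"Su": 1}, 1.2, 2.0),
    ("R24", {"Su": 1}, {"Fum": 1}, 1.4, 0.15),
    ("R25", {"Fum": 1}, {"Mal": 1}, 1.4, 0.7),
    ("R26", {"Mal": 1}, {"OAA": 1}, 1.4, 0.7),
    ("R27", {"Glu": 1, "OAA": 1}, {"Asp": 1, "2OG": 1}, 0.8, 0.4),
    ("R28", {"Asp": 1}, {}, 0.4, 0.4),
    ("R29", {"Glu": 1}, {"Gln": 1}, 0.3, 0.15),
    ("R30", {"Gln": 1}, {"Glu": 1}, 0.3, 0.3),
    ("R31", {"Lac": 1}, {}, 0.6, 0.6),
    ("R32", {"Su": 1}, {}, 0.3, 0.1),
    ("R33", {"Glu": 1}, {}, 0.1, 0.05),
]

# Km values that deviate from the substrate-baseline default: the GABA-shunt
# entry reactions are kept far from saturation so doubling upstream pools
# propagates, and GABA degradation saturates at rest.
_KM_OVERRIDES = {
    ("R19", "Glu"): 2.4,
    ("R20", "GABA"): 0.06,
}


def _fig1_model() -> MetabolicModel:
    baselines = {mid: amt for mid, _, amt, _, _ in _METABOLITES}
    mets = tuple(
        MetaboliteSpec(
            id=mid,
            name=name,
            initial_amount=amt,
            is_fitting_target=fit,
            is_state_metabolite=state,
        )
        for mid, name, amt, fit, state in _METABOLITES
    )
    rxns = []
    for rid, subs, prods, v_ctrl, v_str in _REACTIONS:
        km = {
            mid: _KM_OVERRIDES.get((rid, mid), baselines[mid])
            for mid in subs
        }
        rxns.append(
            ReactionSpec(
                id=rid,
                substrates=tuple((m, float(c)) for m, c in subs.items()),
                products=tuple((m, float(c)) for m, c in prods.items()),
                km=km,
                vmax_by_condition={CONTROL: v_ctrl, STRESSED: v_str},
            )
        )
    return MetabolicModel(
        metabolites=mets, reactions=tuple(rxns), conditions=(CONTROL, STRESSED)
    )


def _random_model(config: GeneratorConfig) -> MetabolicModel:
    """Seeded random chain-plus-shortcut network, every metabolite observed."""
    rng = np.random.default_rng(config.seed)
    n_m = max(2, config.n_metabolites)
    n_r = max(1, config.n_reactions)
    amounts = rng.uniform(0.5, 3.0, n_m)
    mets = tuple(
        MetaboliteSpec(
            id=f"M{j + 1}",
            initial_amount=float(amounts[j]),
            is_fitting_target=True,
            is_state_metabolite=(j < min(2, n_m)),
        )
        for j in range(n_m)
    )
    lo, hi = config.vmax_fold_change_range
    rxns = []
    for k in range(n_r):
        if k < n_m - 1:
            src, dst = k, k + 1  # backbone chain keeps the network connected
        else:
            src = int(rng.integers(0, n_m))
            dst = int(rng.integers(0, n_m))
            while dst == src:
                dst = int(rng.integers(0, n_m))
        v = float(rng.uniform(0.5, 2.0))
        rxns.append(
            ReactionSpec(
                id=f"R{k + 1}",
                substrates=((mets[src].id, 1.0),),
                products=((mets[dst].id, 1.0),),
                km={mets[src].id: float(rng.uniform(0.5, 2.0))},
                vmax_by_condition={
                    CONTROL: v,
                    STRESSED: v * float(rng.uniform(lo, hi)),
                },
            )
        )
    return MetabolicModel(
        metabolites=mets, reactions=tuple(rxns), conditions=(CONTROL, STRESSED)
    )


def make_metabolic_fixture(config: GeneratorConfig | None = None) -> MetabolicModel:
    """The packaged kinetic network (topology='fig1') or a seeded random one."""
    config = config or GeneratorConfig()
    if config.topology == "fig1":
        return _fig1_model()
    if config.topology == "random":
        return _random_model(config)
    raise ValueError(f"unknown topology {config.topology!r}")


def make_observed_timecourses(
    model: MetabolicModel,
    config: GeneratorConfig | None = None,
    duration: float = 4.0,
    sample_interval: float = 1.0,
    n_replicates: int = 3,
) -> tuple[ObservedTimecourse, ObservedTimecourse]:
    """Simulate both conditions and emit noisy averaged observations.

    Noise is multiplicative lognormal with coefficient of variation
    ``config.noise_cv`` per replicate; replicates are averaged and the
    standard error reported.  Only fitting-target metabolites are emitted.
    """
    config = config or GeneratorConfig()
    rng = np.random.default_rng(config.seed)
    cv = config.noise_cv
    sigma = float(np.sqrt(np.log1p(cv ** 2)))
    out = []
    for cond in model.conditions:
        tc = simulate(
            model,
            Perturbation(),
            duration=duration,
            sample_interval=sample_interval,
            condition=cond,
        )
        rows = []
        for met in model.fitting_target_ids:
            truth = tc.amount(met)
            for t, x in zip(tc.times, truth):
                if cv > 0:
                    reps = x * np.exp(
                        rng.normal(-0.5 * sigma ** 2, sigma, n_replicates)
                    )
                    mean = float(reps.mean())
                    se = float(reps.std(ddof=1) / np.sqrt(n_replicates))
                else:
                    mean, se = float(x), 0.0
                rows.append((met, float(t), mean, se))
        out.append(
            ObservedTimecourse(
                condition=cond,
                data=pd.DataFrame(
                    rows, columns=["metabolite_id", "time_days", "amount", "se"]
                ),
            )
        )
    return out[0], out[1]


# source, target, sign, multiplicity — totals: 19 promoting, 17 inhibitory
_LADDER_EDGES = [
    # channel 1 (promoting, 10)
    ("A1", "B1", 1, 2),
    ("B1", "C1", 1, 3),
    ("C1", "D1", 1, 2),
    ("B1", "D1", 1, 1),
    ("A1", "C1", 1, 1),
    ("D1", "D1", 1, 1),
    # channel 2 (promoting, 9)
    ("A2", "B2", 1, 2),
    ("B2", "C2", 1, 3),
    ("C2", "D2", 1, 2),
    ("B2", "D2", 1, 1),
    ("A2", "C2", 1, 1),
    # cross-channel bridges (inhibitory, 17)
    ("B1", "B2", -1, 2),
    ("B2", "B1", -1, 2),
    ("C1", "C2", -1, 2),
    ("C2", "C1", -1, 2),
    ("D1", "D2", -1, 2),
    ("D2", "D1", -1, 2),
    ("B1", "C2", -1, 1),
    ("B2", "C1", -1, 1),
    ("C1", "D2", -1, 1),
    ("C2", "D1", -1, 1),
    ("A1", "A2", -1, 1),
]


def make_ladder_network(
    config: GeneratorConfig | None = None, n_modules: int = 8
) -> BooleanModuleNetwork:
    """Two bridged promoting channels with step inputs on B1 and B2.

    The default 8-module network is a fixed authored reconstruction; smaller
    even sizes produce a minimal two-channel toy with the same conventions.
    """
    if n_modules == 8:
        return BooleanModuleNetwork(
            modules=("A1", "B1", "C1", "D1", "A2", "B2", "C2", "D2"),
            edges=tuple(Edge(*e) for e in _LADDER_EDGES),
            inputs={
                "B1": InputSchedule(before_value=0, after_value=1, onset_time=0),
                "B2": InputSchedule(before_value=1, after_value=0, onset_time=0),
            },
        )
    if n_modules < 2 or n_modules % 2:
        raise ValueError("n_modules must be 8 or a smaller positive even number")
    half = n_modules // 2
    mods = tuple(f"M{j + 1}c{ch + 1}" for ch in range(2) for j in range(half))
    edges = []
    for ch in range(2):
        for j in range(half - 1):
            edges.append(Edge(f"M{j + 1}c{ch + 1}", f"M{j + 2}c{ch + 1}", 1, 1))
    for j in range(half):
        edges.append(Edge(f"M{j + 1}c1", f"M{j + 1}c2", -1, 1))
    inputs = {
        mods[0]: InputSchedule(before_value=0, after_value=1, onset_time=0),
        mods[half]: InputSchedule(before_value=1, after_value=0, onset_time=0),
    }
    return BooleanModuleNetwork(modules=mods, edges=tuple(edges), inputs=inputs)


#: reactions whose enzymes count as detected in the packaged annotation table
_EXPRESSED = ("R1", "R5", "R9", "R13", "R16", "R19", "R22", "R24", "R26", "R29")


def make_expression_annotation(model: MetabolicModel) -> pd.DataFrame:
    """Packaged protein-expression flags: reaction_id, expressed (0/1)."""
    return pd.DataFrame(
        {
            "reaction_id": [r.id for r in model.reactions],
            "expressed": [int(r.id in _EXPRESSED) for r in model.reactions],
        }
    )
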