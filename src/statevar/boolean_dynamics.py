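"""Synchronous Boolean simulator for module-level transcriptional networks.

Modules are Boolean units connected by signed, weighted interactions.  The
update rule is a signed threshold with memory: each module sums
``sign * multiplicity`` over incoming active modules plus any external input,
switches on for a positive sum, off for a negative sum, and holds its current
value on a tie.  Clamped modules ignore the rule entirely.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

SCHEMA_VERSION = 1

BooleanState = tuple[int, ...]
TieRule = Literal["hold", "inactive"]


class NetworkError(ValueError):
    """A network file failed to parse or violated a structural invariant."""


@dataclass(frozen=True)
class InputSchedule:
    """Step-function external input: before_value until onset, after_value from onset."""

    before_value: int
    after_value: int
    onset_time: int = 0

    def __post_init__(self) -> None:
        for v in (self.before_value, self.after_value):
            if v not in (0, 1):
                raise NetworkError(f"input values must be 0/1, got {v}")

    def value(self, t: int) -> int:
        return self.before_value if t < self.onset_time else self.after_value


@dataclass(frozen=True)
class Edge:
    source: str
    target: str
    sign: int
    multiplicity: int = 1

    def __post_init__(self) -> None:
        if self.sign not in (1, -1):
            raise NetworkError(
                f"edge {self.source}->{self.target}: sign must be +1/-1, got {self.sign}"
            )
        if self.multiplicity < 1:
            raise NetworkError(
                f"edge {self.source}->{self.target}: multiplicity must be >= 1"
            )


@dataclass(frozen=True)
class BooleanModuleNetwork:
    modules: tuple[str, ...]
    edges: tuple[Edge, ...]
    inputs: Mapping[str, InputSchedule] = field(default_factory=dict)
    clamps: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.modules)) != len(self.modules):
            raise NetworkError("duplicate module labels")
        known = set(self.modules)
        for e in self.edges:
            if e.source not in known or e.target not in known:
                raise NetworkError(
                    f"edge {e.source}->{e.target} references unknown module"
                )
        for m in self.inputs:
            if m not in known:
                raise NetworkError(f"input schedule for unknown module {m!r}")
        for m, v in self.clamps.items():
            if m not in known:
                raise NetworkError(f"clamp on unknown module {m!r}")
            if v not in (0, 1):
                raise NetworkError(f"clamp value for {m!r} must be 0/1, got {v}")

    @property
    def n_modules(self) -> int:
        return len(self.modules)

    def index(self, module: str) -> int:
        try:
            return self.modules.index(module)
        except ValueError:
            raise NetworkError(f"unknown module {module!r}") from None

    def weight_matrix(self) -> np.ndarray:
        """W[j, i] = net signed weight of module j onto module i."""
        w = np.zeros((self.n_modules, self.n_modules), dtype=int)
        for e in self.edges:
            w[self.index(e.source), self.index(e.target)] += e.sign * e.multiplicity
        return w


def net_weight(network: BooleanModuleNetwork, source: str, target: str) -> int:
    """Sum of sign * multiplicity over all parallel edges source -> target."""
    i, j = network.index(source), network.index(target)
    return int(network.weight_matrix()[i, j])


def step(
    network: BooleanModuleNetwork,
    state: BooleanState,
    t: int = 0,
    rule: TieRule = "hold",
) -> BooleanState:
    """One synchronous update of every module."""
    if len(state) != network.n_modules:
        raise NetworkError(
            f"state length {len(state)} != number of modules {network.n_modules}"
        )
    w = network.weight_matrix()
    s = np.asarray(state, dtype=int)
    drive = s @ w
    nxt = list(state)
    for i, m in enumerate(network.modules):
        if m in network.clamps:
            nxt[i] = network.clamps[m]
            continue
        total = drive[i]
        if m in network.inputs:
            total += network.inputs[m].value(t)
        if total > 0:
            nxt[i] = 1
        elif total < 0:
            nxt[i] = 0
        else:
            nxt[i] = state[i] if rule == "hold" else 0
    return tuple(nxt)


def simulate_boolean(
    network: BooleanModuleNetwork,
    initial: BooleanState,
    n_steps: int,
    rule: TieRule = "hold",
) -> list[BooleanState]:
    """Deterministic trajectory of length n_steps + 1 including t = 0."""
    if n_steps < 0:
        raise ValueError("n_steps must be >= 0")
    traj = [tuple(int(v) for v in initial)]
    for t in range(n_steps):
        traj.append(step(network, traj[-1], t=t, rule=rule))
    return traj


def enumerate_states(n_modules: int) -> list[BooleanState]:
    """All 2^n Boolean tuples in binary counting order (first module = LSB)."""
    if n_modules < 1:
        raise ValueError(f"n_modules must be >= 1, got {n_modules}")
    return [
        tuple(code >> j & 1 for j in range(n_modules))
        for code in range(2 ** n_modules)
    ]


def inputs_off(network: BooleanModuleNetwork) -> BooleanModuleNetwork:
    """Freeze every input at its pre-onset value (the unstimulated condition)."""
    frozen = {
        m: InputSchedule(s.before_value, s.before_value, 0)
        for m, s in network.inputs.items()
    }
    return replace(network, inputs=frozen)


def with_clamps(
    network: BooleanModuleNetwork, clamps: Mapping[str, int]
) -> BooleanModuleNetwork:
    merged = dict(network.clamps)
    merged.update(clamps)
    return replace(network, clamps=merged)


# -- file I/O ---------------------------------------------------------------


def network_to_dict(network: BooleanModuleNetwork) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "modules": list(network.modules),
        "edges": [
            {
                "source": e.source,
                "target": e.target,
                "sign": e.sign,
                "multiplicity": e.multiplicity,
            }
            for e in network.edges
        ],
        "inputs": {
            m: {
                "before_value": s.before_value,
                "after_value": s.after_value,
                "onset_time": s.onset_time,
            }
            for m, s in network.inputs.items()
        },
        "clamps": dict(network.clamps),
    }


def network_from_dict(data: Mapping) -> BooleanModuleNetwork:
    version = data.get("schema_version")
    if version != SCHEMA_VERSION:
        raise NetworkError(
            f"unsupported schema_version {version!r}; this package reads "
            f"version {SCHEMA_VERSION}"
        )
    for key in ("modules", "edges"):
        if key not in data:
            raise NetworkError(f"network file missing top-level key {key!r}")
    try:
        edges = tuple(
            Edge(
                source=str(e["source"]),
                target=str(e["target"]),
                sign=int(e["sign"]),
                multiplicity=int(e.get("multiplicity", 1)),
            )
            for e in data["edges"]
        )
    except KeyError as exc:
        raise NetworkError(f"edge entry missing field {exc}") from exc
    inputs = {
        str(m): InputSchedule(
            before_value=int(s["before_value"]),
            after_value=int(s["after_value"]),
            onset_time=int(s.get("onset_time", 0)),
        )
        for m, s in (data.get("inputs") or {}).items()
    }
    return BooleanModuleNetwork(
        modules=tuple(str(m) for m in data["modules"]),
        edges=edges,
        inputs=inputs,
        clamps={str(m): int(v) for m, v in (data.get("clamps") or {}).items()},
    )


def load_network(path: str | Path) -> BooleanModuleNetwork:
    path = Path(path)
    text = path.read_text()
    try:
        if path.suffix == ".json":
            data = json.loads(text)
        else:
            data = yaml.safe_load(text)
    except (yaml.YAMLError, json.JSONDecodeError) as exc:
        raise NetworkError(f"could not parse {path}: {exc}") from exc
    if not isinstance(data, Mapping):
        raise NetworkError(f"{path}: expected a mapping at top level")
    return network_from_dict(data)


def save_network(network: BooleanModuleNetwork, path: str | Path) -> None:
    path = Path(path)
    data = network_to_dict(network)
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))


def trajectories_to_frame(
    trajectories: Sequence[Sequence[BooleanState]],
    modules: Sequence[str],
    run_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Tidy table: run_id, t, module, value."""
    rows = []
    for r, traj in enumerate(trajectories):
        rid = run_ids[r] if run_ids is not None else str(r)
        for t, state in enumerate(traj):
            for m, v in zip(modules, state):
                rows.append((rid, t, m, v))
    return pd.DataFrame(rows, columns=["run_id", "t", "module", "value"])
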