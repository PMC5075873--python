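"""Data model and file I/O for kinetic metabolic networks.

A :class:`MetabolicModel` bundles metabolite pools with irreversible
Michaelis--Menten reactions whose maximum velocities are stored per
condition (``control`` / ``stressed``).  The module also provides the two
model edits used throughout the pipeline: linear interpolation between the
two condition-specific Vmax sets, and single-reaction over-expression.

Units: amounts in umol/g dry weight, velocities in amount/day.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import yaml

SCHEMA_VERSION = 1
CONTROL = "control"
STRESSED = "stressed"
#: condition label attached to models produced by :func:`interpolate`
BLEND = "blend"


class ModelError(ValueError):
    """A model file failed to parse or violated a structural invariant."""


@dataclass(frozen=True)
class MetaboliteSpec:
    """One metabolite pool.

    ``is_state_metabolite`` marks membership in the Boolean tuple that
    defines the discrete system state; ``is_fitting_target`` marks the
    metabolites matched against observed time courses during calibration.
    """

    id: str
    initial_amount: float
    name: str = ""
    is_fitting_target: bool = False
    is_state_metabolite: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise ModelError("metabolite id must be non-empty")
        if self.initial_amount < 0:
            raise ModelError(
                f"metabolite {self.id!r}: initial_amount must be >= 0, "
                f"got {self.initial_amount}"
            )


@dataclass(frozen=True)
class ReactionSpec:
    """One irreversible reaction with multiplicative saturation kinetics.

    ``km`` maps each substrate id to its Michaelis constant.  An optional
    ``inhibitor`` is a ``(metabolite_id, Ki)`` pair applying a
    non-competitive factor ``Ki / (Ki + I)`` to the rate.
    """

    id: str
    substrates: tuple[tuple[str, float], ...]
    products: tuple[tuple[str, float], ...]
    km: Mapping[str, float]
    vmax_by_condition: Mapping[str, float]
    inhibitor: tuple[str, float] | None = None

    def __post_init__(self) -> None:
        for met, coeff in tuple(self.substrates) + tuple(self.products):
            if coeff <= 0:
                raise ModelError(
                    f"reaction {self.id!r}: stoichiometric coefficient for "
                    f"{met!r} must be > 0, got {coeff}"
                )
        for met, _ in self.substrates:
            if met not in self.km:
                raise ModelError(
                    f"reaction {self.id!r}: missing Km for substrate {met!r}"
                )
            if self.km[met] <= 0:
                raise ModelError(
                    f"reaction {self.id!r}: Km for {met!r} must be > 0, "
                    f"got {self.km[met]}"
                )
        for cond, v in self.vmax_by_condition.items():
            if v < 0:
                raise ModelError(
                    f"reaction {self.id!r}: Vmax[{cond!r}] must be >= 0, got {v}"
                )
        if self.inhibitor is not None and self.inhibitor[1] <= 0:
            raise ModelError(f"reaction {self.id!r}: Ki must be > 0")

    def vmax(self, condition: str) -> float:
        try:
            return float(self.vmax_by_condition[condition])
        except KeyError:
            raise ModelError(
                f"reaction {self.id!r}: no Vmax for condition {condition!r}"
            ) from None


@dataclass(frozen=True)
class MetabolicModel:
    metabolites: tuple[MetaboliteSpec, ...]
    reactions: tuple[ReactionSpec, ...]
    conditions: tuple[str, ...] = (CONTROL, STRESSED)

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        met_ids = [m.id for m in self.metabolites]
        if len(set(met_ids)) != len(met_ids):
            dup = sorted({i for i in met_ids if met_ids.count(i) > 1})
            raise ModelError(f"duplicate metabolite ids: {dup}")
        rxn_ids = [r.id for r in self.reactions]
        if len(set(rxn_ids)) != len(rxn_ids):
            dup = sorted({i for i in rxn_ids if rxn_ids.count(i) > 1})
            raise ModelError(f"duplicate reaction ids: {dup}")
        if not 1 <= len(self.conditions) <= 2:
            raise ModelError(
                f"model must declare one or two conditions, got {self.conditions}"
            )
        known = set(met_ids)
        for r in self.reactions:
            for met, _ in tuple(r.substrates) + tuple(r.products):
                if met not in known:
                    raise ModelError(
                        f"reaction {r.id!r} references undeclared metabolite {met!r}"
                    )
            if r.inhibitor is not None and r.inhibitor[0] not in known:
                raise ModelError(
                    f"reaction {r.id!r} inhibitor references undeclared "
                    f"metabolite {r.inhibitor[0]!r}"
                )
            for cond in self.conditions:
                r.vmax(cond)  # raises if missing

    # -- lookups ------------------------------------------------------------

    def metabolite(self, met_id: str) -> MetaboliteSpec:
        for m in self.metabolites:
            if m.id == met_id:
                return m
        raise ModelError(f"unknown metabolite id {met_id!r}")

    def reaction(self, rxn_id: str) -> ReactionSpec:
        for r in self.reactions:
            if r.id == rxn_id:
                return r
        raise ModelError(f"unknown reaction id {rxn_id!r}")

    @property
    def metabolite_ids(self) -> tuple[str, ...]:
        return tuple(m.id for m in self.metabolites)

    @property
    def state_metabolite_ids(self) -> tuple[str, ...]:
        return tuple(m.id for m in self.metabolites if m.is_state_metabolite)

    @property
    def fitting_target_ids(self) -> tuple[str, ...]:
        return tuple(m.id for m in self.metabolites if m.is_fitting_target)

    def initial_amounts(self) -> dict[str, float]:
        return {m.id: m.initial_amount for m in self.metabolites}

    # -- derived models -----------------------------------------------------

    def with_vmax(self, condition: str, values: Mapping[str, float]) -> "MetabolicModel":
        """Return a copy with the given reactions' Vmax replaced in one condition."""
        unknown = set(values) - {r.id for r in self.reactions}
        if unknown:
            raise ModelError(f"unknown reaction ids {sorted(unknown)}")
        new = []
        for r in self.reactions:
            if r.id in values:
                vbc = dict(r.vmax_by_condition)
                vbc[condition] = float(values[r.id])
                r = replace(r, vmax_by_condition=vbc)
            new.append(r)
        return replace(self, reactions=tuple(new))


def reaction_rate(
    reaction: ReactionSpec,
    amounts: Mapping[str, float],
    condition_vmax: float,
) -> float:
    """Rate = Vmax * prod_i S_i / (Km_i + S_i), optionally times Ki/(Ki+I).

    The rate is bounded in ``[0, condition_vmax]`` and vanishes whenever a
    substrate is absent.
    """
    rate = float(condition_vmax)
    for met, _ in reaction.substrates:
        s = amounts[met]
        if s < 0:
            raise ValueError(
                f"reaction {reaction.id!r}: negative amount for {met!r}: {s}"
            )
        rate *= s / (reaction.km[met] + s)
    if reaction.inhibitor is not None:
        met, ki = reaction.inhibitor
        i = amounts[met]
        if i < 0:
            raise ValueError(
                f"reaction {reaction.id!r}: negative amount for inhibitor {met!r}"
            )
        rate *= ki / (ki + i)
    return rate


def interpolate(model: MetabolicModel, lam: float) -> MetabolicModel:
    """Blend the two condition Vmax sets: V(lam) = V(0) + lam * (V(1) - V(0)).

    ``lam = 0`` reproduces the control condition, ``lam = 1`` the stressed
    condition.  The result is a single-condition model labelled ``blend``.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lam must lie in [0, 1], got {lam}")
    if len(model.conditions) != 2:
        raise ModelError("interpolate requires a two-condition model")
    c0, c1 = model.conditions
    new = []
    for r in model.reactions:
        v0, v1 = r.vmax(c0), r.vmax(c1)
        # endpoints must reproduce the stored condition values bit-exactly
        blended = v1 if lam == 1.0 else v0 + lam * (v1 - v0)
        new.append(replace(r, vmax_by_condition={BLEND: blended}))
    return replace(model, reactions=tuple(new), conditions=(BLEND,))


def overexpress(
    model: MetabolicModel,
    reaction_id: str,
    factor: float,
    condition: str | None = None,
) -> MetabolicModel:
    """Multiply one reaction's Vmax by ``factor`` in one condition.

    Defaults to the model's first condition (the control set for two-condition
    models), matching an enzyme over-expression screen run on the control
    parameterization.
    """
    if factor <= 0:
        raise ValueError(f"factor must be > 0, got {factor}")
    cond = model.conditions[0] if condition is None else condition
    rxn = model.reaction(reaction_id)  # raises on unknown id
    return model.with_vmax(cond, {reaction_id: rxn.vmax(cond) * factor})


# -- file I/O ---------------------------------------------------------------


def model_to_dict(model: MetabolicModel) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "conditions": list(model.conditions),
        "metabolites": [
            {
                "id": m.id,
                "name": m.name,
                "initial_amount": m.initial_amount,
                "fitting_target": m.is_fitting_target,
                "state_metabolite": m.is_state_metabolite,
            }
            for m in model.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "substrates": [{"id": i, "coeff": c} for i, c in r.substrates],
                "products": [{"id": i, "coeff": c} for i, c in r.products],
                "km": dict(r.km),
                "vmax": dict(r.vmax_by_condition),
                **(
                    {"inhibitor": {"id": r.inhibitor[0], "ki": r.inhibitor[1]}}
                    if r.inhibitor is not None
                    else {}
                ),
            }
            for r in model.reactions
        ],
    }


def model_from_dict(data: Mapping) -> MetabolicModel:
    version = data.get("schema_version")
    if version != SCHEMA_VERSION:
        raise ModelError(
            f"unsupported schema_version {version!r}; this package reads "
            f"version {SCHEMA_VERSION} — re-export the model file"
        )
    for key in ("metabolites", "reactions", "conditions"):
        if key not in data:
            raise ModelError(f"model file missing top-level key {key!r}")
    try:
        mets = tuple(
            MetaboliteSpec(
                id=str(m["id"]),
                name=str(m.get("name", "")),
                initial_amount=float(m["initial_amount"]),
                is_fitting_target=bool(m.get("fitting_target", False)),
                is_state_metabolite=bool(m.get("state_metabolite", False)),
            )
            for m in data["metabolites"]
        )
    except KeyError as exc:
        raise ModelError(f"metabolite entry missing field {exc}") from exc
    rxns = []
    for r in data["reactions"]:
        try:
            inhibitor = None
            if "inhibitor" in r:
                inhibitor = (str(r["inhibitor"]["id"]), float(r["inhibitor"]["ki"]))
            rxns.append(
                ReactionSpec(
                    id=str(r["id"]),
                    substrates=tuple(
                        (str(s["id"]), float(s["coeff"])) for s in r["substrates"]
                    ),
                    products=tuple(
                        (str(p["id"]), float(p["coeff"])) for p in r["products"]
                    ),
                    km={str(k): float(v) for k, v in r["km"].items()},
                    vmax_by_condition={
                        str(k): float(v) for k, v in r["vmax"].items()
                    },
                    inhibitor=inhibitor,
                )
            )
        except KeyError as exc:
            raise ModelError(
                f"reaction entry {r.get('id', '?')!r} missing field {exc}"
            ) from exc
    return MetabolicModel(
        metabolites=mets,
        reactions=tuple(rxns),
        conditions=tuple(str(c) for c in data["conditions"]),
    )


def load_model(path: str | Path) -> MetabolicModel:
    """Load and validate a model file (YAML or JSON by extension)."""
    path = Path(path)
    text = path.read_text()
    try:
        if path.suffix == ".json":
            data = json.loads(text)
        else:
            data = yaml.safe_load(text)
    except (yaml.YAMLError, json.JSONDecodeError) as exc:
        raise ModelError(f"could not parse {path}: {exc}") from exc
    if not isinstance(data, Mapping):
        raise ModelError(f"{path}: expected a mapping at top level")
    return model_from_dict(data)


def save_model(model: MetabolicModel, path: str | Path) -> None:
    path = Path(path)
    data = model_to_dict(model)
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))


def load_sbml(path: str | Path) -> MetabolicModel:
    """Optional SBML Level 3 import.

    Expects kinetic-law local parameters named ``Vmax_control``,
    ``Vmax_stressed`` and ``Km_<substrate>``.  Requires ``python-libsbml``,
    which is not a hard dependency.
    """
    try:
        import libsbml  # type: ignore
    except ImportError as exc:  # pragma: no cover - optional path
        raise ModelError(
            "SBML import requires the optional dependency python-libsbml"
        ) from exc
    doc = libsbml.readSBML(str(path))  # pragma: no cover - optional path
    if doc.getNumErrors() > 0:  # pragma: no cover
        raise ModelError(f"SBML parse errors in {path}")
    sm = doc.getModel()  # pragma: no cover
    mets = tuple(  # pragma: no cover
        MetaboliteSpec(
            id=s.getId(),
            name=s.getName() or "",
            initial_amount=s.getInitialAmount() or 0.0,
        )
        for s in sm.getListOfSpecies()
    )
    rxns = []  # pragma: no cover
    for r in sm.getListOfReactions():  # pragma: no cover
        kl = r.getKineticLaw()
        params = {
            p.getId(): p.getValue() for p in kl.getListOfLocalParameters()
        } if kl else {}
        subs = tuple(
            (sr.getSpecies(), sr.getStoichiometry() or 1.0)
            for sr in r.getListOfReactants()
        )
        rxns.append(
            ReactionSpec(
                id=r.getId(),
                substrates=subs,
                products=tuple(
                    (sr.getSpecies(), sr.getStoichiometry() or 1.0)
                    for sr in r.getListOfProducts()
                ),
                km={s: params.get(f"Km_{s}", 1.0) for s, _ in subs},
                vmax_by_condition={
                    CONTROL: params.get("Vmax_control", 0.0),
                    STRESSED: params.get("Vmax_stressed", 0.0),
                },
            )
        )
    return MetabolicModel(metabolites=mets, reactions=tuple(rxns))  # pragma: no cover
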