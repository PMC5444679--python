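"""Domain types for small stoichiometric metabolic models.

A model is a list of metabolites, a list of reactions with signed rational
stoichiometries (negative = substrate), and a set of metabolite ids that may
carry an exchange flux across the system boundary.  The steady-state flux
constraint is ``S v - E e = 0`` where ``S`` is the metabolite x reaction
stoichiometric matrix and ``E`` an identity-like selector with one unit
column per exchangeable metabolite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

__all__ = [
    "Metabolite",
    "Reaction",
    "StoichiometricModel",
    "BiomassSpec",
    "Finding",
    "ModelValidationError",
    "stoichiometric_matrix",
    "validate_model",
]


class ModelValidationError(ValueError):
    """Raised when a model or biomass specification violates its contract."""


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str = ""
    is_cofactor: bool = False
    default_exchangeable: bool = False


@dataclass(frozen=True)
class Reaction:
    """One reaction column of the model.

    ``stoich`` maps metabolite id to a signed coefficient; substrates are
    negative.  Irreversible reactions must have a lower bound of exactly 0.
    Bounds are in the model's relative flux units (the scale set by the
    carbon-source uptake bound).
    """

    id: str
    stoich: Mapping[str, float]
    metacyc_id: str = ""
    display_index: int = 0
    reversible: bool = False
    lower_bound: float = 0.0
    upper_bound: float = math.inf

    def __post_init__(self) -> None:
        if not self.stoich:
            raise ModelValidationError(f"reaction {self.id!r}: empty stoichiometry")
        if self.lower_bound > self.upper_bound:
            raise ModelValidationError(
                f"reaction {self.id!r}: lower bound {self.lower_bound} above upper "
                f"bound {self.upper_bound}"
            )
        if not self.reversible and self.lower_bound != 0.0:
            raise ModelValidationError(
                f"reaction {self.id!r}: irreversible reactions must have a lower "
                f"bound of exactly 0 (got {self.lower_bound})"
            )
        # freeze the mapping so reactions are safely shareable
        object.__setattr__(self, "stoich", dict(self.stoich))

    def with_stoich(self, stoich: Mapping[str, float]) -> "Reaction":
        return replace(self, stoich=dict(stoich))


@dataclass(frozen=True)
class BiomassSpec:
    """Drains of the growth pseudo-reaction, per unit of growth flux.

    ``precursors`` are carbon-skeleton demands (all >= 0).  ``atp`` and
    ``nadph`` are cofactor demands (> 0); ``nadh`` is the net NADH *produced*
    per unit growth (amino-acid synthesis is a net NADH source).  The growth
    flux is reported in comparative units: the stand-in set is scaled so that
    a flux of 1 corresponds to roughly 10 g of biomass, which puts simulated
    growth fluxes near 0.1 at the reference sugar uptake of 10.
    """

    precursors: Mapping[str, float]
    atp: float
    nadph: float
    nadh: float = 0.0
    provenance: str = "standin"

    def __post_init__(self) -> None:
        for met, coeff in self.precursors.items():
            if coeff < 0:
                raise ModelValidationError(
                    f"biomass spec: precursor drain {met!r} is negative ({coeff})"
                )
        if self.atp <= 0:
            raise ModelValidationError("biomass spec: ATP drain must be > 0")
        if self.nadph <= 0:
            raise ModelValidationError("biomass spec: NADPH drain must be > 0")
        if self.nadh < 0:
            raise ModelValidationError(
                "biomass spec: net NADH production must be >= 0"
            )
        object.__setattr__(self, "precursors", dict(self.precursors))

    def growth_stoich(self) -> dict[str, float]:
        """Stoichiometry of the growth reaction embedding this spec."""
        st: dict[str, float] = {m: -c for m, c in self.precursors.items() if c != 0}
        # acetyl-CoA drain returns free CoA
        if "accoa" in self.precursors:
            st["coa"] = self.precursors["accoa"]
        st["atp"] = st.get("atp", 0.0) - self.atp
        st["adp"] = self.atp
        st["pi"] = st.get("pi", 0.0) + self.atp
        st["nadph"] = -self.nadph
        st["nadp"] = self.nadph
        if self.nadh:
            st["nadh"] = self.nadh
            st["nad"] = -self.nadh
        st["biomass"] = 1.0
        return st


@dataclass(frozen=True)
class StoichiometricModel:
    metabolites: tuple[Metabolite, ...]
    reactions: tuple[Reaction, ...]
    exchangeable: frozenset[str]
    constants: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "metabolites", tuple(self.metabolites))
        object.__setattr__(self, "reactions", tuple(self.reactions))
        object.__setattr__(self, "exchangeable", frozenset(self.exchangeable))
        object.__setattr__(self, "constants", dict(self.constants))
        met_ids = [m.id for m in self.metabolites]
        if len(set(met_ids)) != len(met_ids):
            dup = sorted({m for m in met_ids if met_ids.count(m) > 1})
            raise ModelValidationError(f"duplicate metabolite ids: {dup}")
        rxn_ids = [r.id for r in self.reactions]
        if len(set(rxn_ids)) != len(rxn_ids):
            dup = sorted({r for r in rxn_ids if rxn_ids.count(r) > 1})
            raise ModelValidationError(f"duplicate reaction ids: {dup}")
        known = set(met_ids)
        for rxn in self.reactions:
            missing = set(rxn.stoich) - known
            if missing:
                raise ModelValidationError(
                    f"reaction {rxn.id!r} references unknown metabolites: "
                    f"{sorted(missing)}"
                )
        stray = self.exchangeable - known
        if stray:
            raise ModelValidationError(
                f"exchangeable set references unknown metabolites: {sorted(stray)}"
            )

    # -- lookups -----------------------------------------------------------
    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def metabolite(self, met_id: str) -> Metabolite:
        for m in self.metabolites:
            if m.id == met_id:
                return m
        raise KeyError(met_id)

    def reaction(self, rxn_id: str) -> Reaction:
        for r in self.reactions:
            if r.id == rxn_id:
                return r
        raise KeyError(rxn_id)

    def metabolite_index(self) -> dict[str, int]:
        return {m.id: i for i, m in enumerate(self.metabolites)}

    def reaction_index(self) -> dict[str, int]:
        return {r.id: j for j, r in enumerate(self.reactions)}

    def by_metacyc(self, metacyc_id: str) -> Reaction:
        for r in self.reactions:
            if r.metacyc_id == metacyc_id:
                return r
        raise KeyError(metacyc_id)

    def replace_reaction(self, rxn: Reaction) -> "StoichiometricModel":
        reactions = tuple(rxn if r.id == rxn.id else r for r in self.reactions)
        if rxn.id not in {r.id for r in self.reactions}:
            raise KeyError(rxn.id)
        return replace(self, reactions=reactions)

    def drop_reaction(self, rxn_id: str) -> "StoichiometricModel":
        self.reaction(rxn_id)  # raise KeyError on unknown
        return replace(
            self, reactions=tuple(r for r in self.reactions if r.id != rxn_id)
        )


def stoichiometric_matrix(
    model: StoichiometricModel,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Return ``(S, E, exchange_order)`` for ``S v - E e = 0``.

    ``S`` is metabolites x reactions; ``E`` is metabolites x exchangeables
    with exactly one unit entry per column; ``exchange_order`` gives the
    metabolite id of each E column.
    """
    midx = model.metabolite_index()
    S = np.zeros((len(model.metabolites), len(model.reactions)))
    for j, rxn in enumerate(model.reactions):
        for met, coeff in rxn.stoich.items():
            S[midx[met], j] = coeff
    exchange_order = [m.id for m in model.metabolites if m.id in model.exchangeable]
    E = np.zeros((len(model.metabolites), len(exchange_order)))
    for k, met in enumerate(exchange_order):
        E[midx[met], k] = 1.0
    return S, E, exchange_order


@dataclass(frozen=True)
class Finding:
    """One validator observation.  Findings are returned, never raised."""

    kind: str  # "orphan-metabolite" | "dead-end" | "bound-violation"
    subject: str
    message: str


def validate_model(model: StoichiometricModel) -> list[Finding]:
    """Structural audit: orphan metabolites, dead ends, bound violations.

    A dead end is a non-exchangeable metabolite that is only ever produced or
    only ever consumed (taking reversible reactions as bidirectional), so it
    can never carry steady-state flux.
    """
    findings: list[Finding] = []
    produced: dict[str, bool] = {m.id: False for m in model.metabolites}
    consumed: dict[str, bool] = {m.id: False for m in model.metabolites}
    seen: dict[str, int] = {m.id: 0 for m in model.metabolites}
    for rxn in model.reactions:
        for met, coeff in rxn.stoich.items():
            seen[met] += 1
            if coeff > 0 or rxn.reversible:
                produced[met] = True
            if coeff < 0 or rxn.reversible:
                consumed[met] = True
    for met in model.metabolites:
        if seen[met.id] == 0:
            findings.append(
                Finding("orphan-metabolite", met.id, f"{met.id} appears in no reaction")
            )
        elif met.id not in model.exchangeable and produced[met.id] != consumed[met.id]:
            side = "produced" if produced[met.id] else "consumed"
            findings.append(
                Finding(
                    "dead-end",
                    met.id,
                    f"{met.id} is only {side} and cannot be exchanged",
                )
            )
    for rxn in model.reactions:
        if rxn.lower_bound > rxn.upper_bound:
            findings.append(
                Finding("bound-violation", rxn.id, "lower bound above upper bound")
            )
        if not rxn.reversible and rxn.lower_bound < 0:
            findings.append(
                Finding("bound-violation", rxn.id, "irreversible with negative lower bound")
            )
    return findings
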