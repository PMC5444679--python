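"""Detection of internal substrate cycles.

A substrate cycle is a non-zero internal flux vector that balances every
carbon-skeleton metabolite with all exchanges closed, while turning over
cofactors (ATP hydrolysis, NADH->NADPH transfer, ...).  Such cycles can
carry arbitrarily high flux without affecting any mass balance except the
cofactor rows, so reported flux maps must not carry gratuitous cycle flux.

Detection solves, for every reaction and orientation, a small LP on the
null space of the stoichiometric matrix restricted to non-cofactor rows
(water is also exempt, since it is not balanced in this model), then
minimises total flux to obtain a minimal support set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
from scipy.optimize import linprog

from .core import StoichiometricModel, stoichiometric_matrix

__all__ = ["CycleRecord", "detect_internal_cycles"]

_TOL = 1e-6


@dataclass(frozen=True)
class CycleRecord:
    """One minimal internal cycle.

    ``direction`` is a normalised flux vector spanning the cycle (largest
    entry 1); ``net_conversion`` is its turnover of the exempt (cofactor)
    metabolites per unit of cycle flux.
    """

    reactions: frozenset[str]
    direction: Mapping[str, float]
    net_conversion: Mapping[str, float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "direction", dict(self.direction))
        object.__setattr__(
            self,
            "net_conversion",
            {m: c for m, c in dict(self.net_conversion).items() if abs(c) > _TOL},
        )


def detect_internal_cycles(
    model: StoichiometricModel,
    inactive: Iterable[str] = (),
) -> list[CycleRecord]:
    """Minimal support sets of internal loops capable of unbounded flux.

    ``inactive`` reactions are excluded (deactivating one member of a pair
    such as FBP/PFK removes the cycle).  Exchange fluxes are all closed;
    cofactor rows and water are exempt from the balance, so the returned
    cycles are exactly the flux modes whose only net effect is cofactor
    turnover.
    """
    S, _, _ = stoichiometric_matrix(model)
    inactive = set(inactive)
    exempt = {m.id for m in model.metabolites if m.is_cofactor} | {"h2o"}
    keep_rows = [i for i, m in enumerate(model.metabolites) if m.id not in exempt]
    active = [j for j, r in enumerate(model.reactions) if r.id not in inactive]
    A = S[np.ix_(keep_rows, active)]
    rxns = [model.reactions[j] for j in active]
    bounds = [(-1.0, 1.0) if r.reversible else (0.0, 1.0) for r in rxns]
    n = len(rxns)

    found: dict[frozenset[str], CycleRecord] = {}
    for j, rxn in enumerate(rxns):
        orientations = (1.0, -1.0) if rxn.reversible else (1.0,)
        for sign in orientations:
            # can reaction j carry flux in this orientation inside a loop?
            c = np.zeros(n)
            c[j] = -sign
            probe = linprog(c, A_eq=A, b_eq=np.zeros(A.shape[0]), bounds=bounds,
                            method="highs-ds")
            if probe.status != 0 or sign * probe.x[j] < 0.5:
                continue
            # minimal support: min sum |v| with v_j pinned to +/-1
            c_min = np.concatenate([np.zeros(n), np.ones(n)])
            A_eq = np.hstack([A, np.zeros((A.shape[0], n))])
            pin = np.zeros(2 * n)
            pin[j] = 1.0
            A_eq = np.vstack([A_eq, pin])
            b_eq = np.concatenate([np.zeros(A.shape[0]), [sign]])
            rows = []
            for k in range(n):
                r1 = np.zeros(2 * n); r1[k], r1[n + k] = 1.0, -1.0
                r2 = np.zeros(2 * n); r2[k], r2[n + k] = -1.0, -1.0
                rows += [r1, r2]
            res = linprog(c_min, A_eq=A_eq, b_eq=b_eq,
                          A_ub=np.vstack(rows), b_ub=np.zeros(2 * n),
                          bounds=[(lo, hi) for lo, hi in bounds] + [(0, None)] * n,
                          method="highs-ds")
            if res.status != 0:
                continue
            v = res.x[:n]
            support = frozenset(
                rxns[k].id for k in range(n) if abs(v[k]) > _TOL
            )
            if not support or support in found:
                continue
            scale = np.max(np.abs(v))
            direction = {
                rxns[k].id: float(v[k] / scale) for k in range(n) if abs(v[k]) > _TOL
            }
            full = np.zeros(len(model.reactions))
            ridx = model.reaction_index()
            for rid, val in direction.items():
                full[ridx[rid]] = val
            net = S @ full
            net_conversion = {
                m.id: float(net[i])
                for i, m in enumerate(model.metabolites)
                if abs(net[i]) > _TOL
            }
            found[support] = CycleRecord(
                reactions=support,
                direction=direction,
                net_conversion=net_conversion,
            )
    # keep only minimal supports (drop any cycle that strictly contains another)
    records = list(found.values())
    minimal = [
        rec
        for rec in records
        if not any(
            other.reactions < rec.reactions for other in records
        )
    ]
    return sorted(minimal, key=lambda r: sorted(r.reactions))
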