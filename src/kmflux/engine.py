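"""LP formulation and solution of the steady-state flux problem.

The constraint system is ``S v - E e = 0`` with one equality row per
metabolite.  Internal fluxes ``v`` are bounded by their reactions (the
solver boxes nominally unbounded fluxes at +/-1e6 and flags solutions that
touch the box); exchange fluxes ``e`` are bounded by an :class:`ExchangePolicy`.
Sign convention: ``e > 0`` is net export/accumulation, ``e < 0`` uptake.

Optimisation is linear programming (HiGHS dual simplex through scipy, with
deterministic settings and a fixed variable ordering, so repeated runs are
bit-identical).  Reported flux maps are refined by parsimonious tie-breaking
(minimal total internal flux at the fixed optimum), which suppresses
substrate cycles that do not contribute to the objective.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
from scipy.optimize import linprog

from .core import StoichiometricModel, stoichiometric_matrix

__all__ = [
    "BIG_BOUND",
    "FEAS_TOL",
    "OBJ_TOL",
    "ExchangePolicy",
    "Objective",
    "LPProblem",
    "FluxSolution",
    "FluxRange",
    "ConfigurationError",
    "assemble_lp",
    "solve_fba",
    "parsimonious_refine",
    "flux_variability",
    "metabolite_balance",
]

#: Box bound standing in for an unbounded flux.
BIG_BOUND = 1e6
#: Feasibility / constraint-residual tolerance.
FEAS_TOL = 1e-9
#: Tolerance for objective-value comparisons.
OBJ_TOL = 1e-7

_SOLVER_OPTIONS = {
    "presolve": True,
    "primal_feasibility_tolerance": 1e-10,
    "dual_feasibility_tolerance": 1e-10,
}


class ConfigurationError(ValueError):
    """Unknown reaction/metabolite id in a policy, objective or edit."""


_MODES = ("closed", "export", "uptake", "fixed", "free")


@dataclass(frozen=True)
class ExchangePolicy:
    """Per-metabolite exchange modes.

    ``modes`` maps exchangeable metabolite ids to one of

    * ``closed``  -- no exchange column (e = 0),
    * ``export``  -- accumulate only (0 <= e),
    * ``uptake``  -- uptake only (lb <= e <= 0, finite lb),
    * ``fixed``   -- e pinned to a value (the carbon-source convention:
      Methods-style "uptake constrained to a value of 10" means e = -10),
    * ``free``    -- unbounded in both directions.

    ``bounds`` carries the finite value for ``uptake`` (the lb, negative)
    and ``fixed`` modes.  Metabolites not mentioned are closed.
    """

    modes: Mapping[str, str] = field(default_factory=dict)
    bounds: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "modes", dict(self.modes))
        object.__setattr__(self, "bounds", dict(self.bounds))
        for met, mode in self.modes.items():
            if mode not in _MODES:
                raise ConfigurationError(f"unknown exchange mode {mode!r} for {met!r}")
            if mode in ("uptake", "fixed") and met not in self.bounds:
                raise ConfigurationError(f"mode {mode!r} for {met!r} needs a bound")

    def mode(self, met: str) -> str:
        return self.modes.get(met, "closed")

    def with_mode(self, met: str, mode: str, bound: float | None = None) -> "ExchangePolicy":
        modes = {**self.modes, met: mode}
        bounds = dict(self.bounds)
        if bound is not None:
            bounds[met] = bound
        return ExchangePolicy(modes=modes, bounds=bounds)

    def variable_bounds(self, met: str) -> tuple[float, float] | None:
        """(lb, ub) of the exchange variable, or None if closed."""
        mode = self.mode(met)
        if mode == "closed":
            return None
        if mode == "export":
            return (0.0, BIG_BOUND)
        if mode == "uptake":
            return (self.bounds[met], 0.0)
        if mode == "fixed":
            value = self.bounds[met]
            return (value, value)
        return (-BIG_BOUND, BIG_BOUND)


@dataclass(frozen=True)
class Objective:
    """Maximisation objective over reaction and exchange fluxes."""

    reaction_weights: Mapping[str, float] = field(default_factory=dict)
    exchange_weights: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "reaction_weights", dict(self.reaction_weights))
        object.__setattr__(self, "exchange_weights", dict(self.exchange_weights))
        if not any(self.reaction_weights.values()) and not any(
            self.exchange_weights.values()
        ):
            raise ConfigurationError("objective has no non-zero weight")


@dataclass(frozen=True)
class LPProblem:
    """Assembled LP: max c.x  s.t.  A_eq x = 0,  lb <= x <= ub.

    Variables are ordered: all internal fluxes in model reaction order,
    then one exchange flux per non-closed exchangeable metabolite in model
    metabolite order.
    """

    model: StoichiometricModel
    policy: ExchangePolicy
    objective: Objective
    A_eq: np.ndarray
    c: np.ndarray          # maximisation weights
    lb: np.ndarray
    ub: np.ndarray
    reaction_order: tuple[str, ...]
    exchange_order: tuple[str, ...]

    @property
    def n_reactions(self) -> int:
        return len(self.reaction_order)

    def column(self, name: str) -> int:
        """Column index of reaction id or exchange id ``ex:<met>``."""
        if name.startswith("ex:"):
            return self.n_reactions + self.exchange_order.index(name[3:])
        return self.reaction_order.index(name)

    def with_bounds(self, name: str, lo: float, hi: float) -> "LPProblem":
        lb, ub = self.lb.copy(), self.ub.copy()
        j = self.column(name)
        lb[j], ub[j] = lo, hi
        return replace(self, lb=lb, ub=ub)


@dataclass(frozen=True)
class FluxSolution:
    status: str                      # optimal | infeasible | unbounded
    objective_value: float
    v: Mapping[str, float]           # reaction id -> flux
    e: Mapping[str, float]           # exchangeable metabolite id -> flux
    residual: float = 0.0            # max |S v - E e|
    at_box: tuple[str, ...] = ()     # variables touching the +/-1e6 box

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


@dataclass(frozen=True)
class FluxRange:
    """Per-variable [min, max] attainable with the objective at its optimum."""

    ranges: Mapping[str, tuple[float, float]]
    failures: Mapping[str, str] = field(default_factory=dict)

    def __getitem__(self, name: str) -> tuple[float, float]:
        return self.ranges[name]

    def width(self, name: str) -> float:
        lo, hi = self.ranges[name]
        return hi - lo


def assemble_lp(
    model: StoichiometricModel,
    policy: ExchangePolicy,
    objective: Objective,
    edits: Mapping[str, tuple[float, float]] | None = None,
) -> LPProblem:
    """Build the equality system and bounds for one scenario.

    ``edits`` are reaction bound overrides applied last, e.g. ``{"pfk":
    (0.0, 0.0)}`` to deactivate a reaction.
    """
    S, _, _ = stoichiometric_matrix(model)
    rxn_ids = model.reaction_ids
    known_rxns = set(rxn_ids)
    for rid in objective.reaction_weights:
        if rid not in known_rxns:
            raise ConfigurationError(f"objective references unknown reaction {rid!r}")
    for rid in (edits or {}):
        if rid not in known_rxns:
            raise ConfigurationError(f"bound edit references unknown reaction {rid!r}")
    for met in list(policy.modes) + list(objective.exchange_weights):
        if met not in model.exchangeable:
            raise ConfigurationError(
                f"{met!r} is not an exchangeable metabolite of this model"
            )

    exchange_order = [
        m.id
        for m in model.metabolites
        if m.id in model.exchangeable and policy.mode(m.id) != "closed"
    ]
    midx = model.metabolite_index()
    n_r, n_e = len(rxn_ids), len(exchange_order)
    A = np.zeros((len(model.metabolites), n_r + n_e))
    A[:, :n_r] = S
    for k, met in enumerate(exchange_order):
        A[midx[met], n_r + k] = -1.0  # S v - E e = 0

    lb = np.empty(n_r + n_e)
    ub = np.empty(n_r + n_e)
    for j, rxn in enumerate(model.reactions):
        lb[j] = max(rxn.lower_bound, -BIG_BOUND)
        ub[j] = min(rxn.upper_bound, BIG_BOUND)
    for rid, (lo, hi) in (edits or {}).items():
        j = rxn_ids.index(rid)
        lb[j], ub[j] = lo, hi
    for k, met in enumerate(exchange_order):
        lo, hi = policy.variable_bounds(met)
        lb[n_r + k] = max(lo, -BIG_BOUND)
        ub[n_r + k] = min(hi, BIG_BOUND)

    c = np.zeros(n_r + n_e)
    for rid, w in objective.reaction_weights.items():
        c[rxn_ids.index(rid)] = w
    for met, w in objective.exchange_weights.items():
        if met not in exchange_order:
            raise ConfigurationError(
                f"objective weights exchange of {met!r} but its exchange is closed"
            )
        c[n_r + exchange_order.index(met)] = w

    return LPProblem(
        model=model,
        policy=policy,
        objective=objective,
        A_eq=A,
        c=c,
        lb=lb,
        ub=ub,
        reaction_order=tuple(rxn_ids),
        exchange_order=tuple(exchange_order),
    )


def _run(lp: LPProblem, c_min: np.ndarray, extra_ub=None, extra_b=None):
    """linprog wrapper: minimise c_min.x over lp's feasible set."""
    bounds = list(zip(lp.lb, lp.ub))
    n_extra = len(c_min) - len(lp.lb)
    if n_extra:
        bounds += [(0.0, None)] * n_extra
    A_eq = lp.A_eq
    if n_extra:
        A_eq = np.hstack([A_eq, np.zeros((A_eq.shape[0], n_extra))])
    return linprog(
        c=c_min,
        A_eq=A_eq,
        b_eq=np.zeros(A_eq.shape[0]),
        A_ub=extra_ub,
        b_ub=extra_b,
        bounds=bounds,
        method="highs-ds",
        options=_SOLVER_OPTIONS,
    )


def _to_solution(lp: LPProblem, x: np.ndarray) -> FluxSolution:
    n_r = lp.n_reactions
    v = {rid: float(x[j]) for j, rid in enumerate(lp.reaction_order)}
    e = {met: float(x[n_r + k]) for k, met in enumerate(lp.exchange_order)}
    residual = float(np.max(np.abs(lp.A_eq @ x[: n_r + len(lp.exchange_order)])))
    at_box = tuple(
        name
        for j, name in enumerate(
            list(lp.reaction_order) + [f"ex:{m}" for m in lp.exchange_order]
        )
        if abs(abs(x[j]) - BIG_BOUND) < 1e-3
    )
    return FluxSolution(
        status="optimal",
        objective_value=float(lp.c @ x[: len(lp.c)]),
        v=v,
        e=e,
        residual=residual,
        at_box=at_box,
    )


_STATUS = {2: "infeasible", 3: "unbounded"}


def solve_fba(lp: LPProblem) -> FluxSolution:
    """Maximise the objective.  Infeasible/unbounded are reported as
    statuses, never as silent zeros."""
    res = _run(lp, -lp.c)
    if res.status != 0:
        return FluxSolution(
            status=_STATUS.get(res.status, f"solver-status-{res.status}"),
            objective_value=math.nan,
            v={},
            e={},
        )
    return _to_solution(lp, res.x)


def _optimum_rows(lp: LPProblem, optimum: float, n_vars: int):
    """Inequality row pinning the objective to its optimum.

    Equality within FEAS_TOL (scaled): slack beyond solver precision would
    let refinement trade objective for parsimony (e.g. a spurious trickle
    of glycerol in place of growth)."""
    slack = FEAS_TOL
    row = np.zeros(n_vars)
    row[: len(lp.c)] = -lp.c
    return row.reshape(1, -1), np.array([-(optimum - slack)])


def parsimonious_refine(lp: LPProblem, optimum: float) -> FluxSolution:
    """Minimise total internal flux |v| at the fixed optimum.

    Reported figure-scenario solutions always pass through this refinement;
    it zeroes substrate-cycle flux that does not serve the objective.
    """
    n_r, n_e = lp.n_reactions, len(lp.exchange_order)
    n = n_r + n_e
    # variables: [x, t] with t_j >= |v_j|
    c_min = np.concatenate([np.zeros(n), np.ones(n_r)])
    rows = []
    for j in range(n_r):
        r1 = np.zeros(n + n_r)
        r1[j], r1[n + j] = 1.0, -1.0     # v_j - t_j <= 0
        r2 = np.zeros(n + n_r)
        r2[j], r2[n + j] = -1.0, -1.0    # -v_j - t_j <= 0
        rows += [r1, r2]
    obj_row, obj_b = _optimum_rows(lp, optimum, n + n_r)
    A_ub = np.vstack(rows + [obj_row])
    b_ub = np.concatenate([np.zeros(2 * n_r), obj_b])
    res = _run(lp, c_min, extra_ub=A_ub, extra_b=b_ub)
    if res.status != 0:
        return FluxSolution(
            status=_STATUS.get(res.status, f"solver-status-{res.status}"),
            objective_value=math.nan,
            v={},
            e={},
        )
    return _to_solution(lp, res.x[:n])


def flux_variability(
    lp: LPProblem,
    optimum: float,
    variables: Iterable[str] | None = None,
) -> FluxRange:
    """Per-variable min/max with the objective fixed at its optimum.

    Covers internal reactions and open exchanges (``ex:<met>``).  A solver
    failure on one variable is recorded in ``failures``, not raised.
    """
    names = (
        list(variables)
        if variables is not None
        else list(lp.reaction_order) + [f"ex:{m}" for m in lp.exchange_order]
    )
    n = lp.n_reactions + len(lp.exchange_order)
    obj_row, obj_b = _optimum_rows(lp, optimum, n)
    ranges: dict[str, tuple[float, float]] = {}
    failures: dict[str, str] = {}
    for name in names:
        j = lp.column(name)
        lohi = []
        for sense in (1.0, -1.0):
            c_min = np.zeros(n)
            c_min[j] = sense
            res = _run(lp, c_min, extra_ub=obj_row, extra_b=obj_b)
            if res.status != 0:
                failures[name] = _STATUS.get(res.status, f"solver-status-{res.status}")
                break
            lohi.append(sense * res.fun)
        else:
            ranges[name] = (float(lohi[0]), float(lohi[1]))
    return FluxRange(ranges=ranges, failures=failures)


def metabolite_balance(
    lp_or_model, sol: FluxSolution, met: str
) -> float:
    """Net production of ``met`` in an optimal solution.

    Equals the exchange flux when the metabolite's exchange is open in the
    scenario, and 0 (steady state) otherwise.
    """
    model = lp_or_model.model if isinstance(lp_or_model, LPProblem) else lp_or_model
    if met not in {m.id for m in model.metabolites}:
        raise KeyError(f"unknown metabolite {met!r}")
    if not sol.optimal:
        raise ValueError("metabolite balance requires an optimal solution")
    return sol.e.get(met, 0.0)
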