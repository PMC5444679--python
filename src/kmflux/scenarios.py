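"""Figure scenarios: model edits, exchange policies and derived quantities.

Each simulation of the study is an immutable :class:`ScenarioConfig`: a
carbon source (glucose or xylose, uptake fixed at 10 relative flux units),
aerobiosis, reaction activity edits, optional cofactor-specificity swaps,
a set of metabolites allowed to accumulate, and a maximisation objective.

Futile-cycle handling: no substrate cycle may carry gratuitous flux in a
reported solution.  Objective-neutral cycles are removed by parsimonious
refinement; cycles that would *improve* an objective by laundering
cofactors (the malic-enzyme triangle, and the PEP/pyruvate interconversion
pairs) are deactivated in the aerobic scenarios, where the organism shows
no evidence of them.  The anaerobic scenario keeps malic enzyme active --
there its cycle is the point.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import StoichiometricModel
from .cycles import CycleRecord, detect_internal_cycles
from .engine import (
    BIG_BOUND,
    ConfigurationError,
    ExchangePolicy,
    FluxRange,
    FluxSolution,
    Objective,
    assemble_lp,
    flux_variability,
    metabolite_balance,
    parsimonious_refine,
    solve_fba,
)
from .reference import BIOMASS_PRECURSORS, COFACTOR_PARTNERS, build_reference_model

__all__ = [
    "ScenarioConfig",
    "ScenarioReport",
    "ExpressionRecord",
    "ComparisonResult",
    "FIGURE_IDS",
    "AEROBIC_CYCLE_OFF",
    "TABLE1",
    "scenario_registry",
    "limited_malic_config",
    "configure_scenario",
    "resolve_reaction_id",
    "expression_fold_change",
    "fold_change_table",
    "set_reaction_activity",
    "swap_cofactor",
    "run_scenario",
    "compare_conditions",
]

FIGURE_IDS = tuple(f"fig{i}" for i in range(1, 12))

#: Futile-cycle enablers held inactive in the aerobic scenarios: malic
#: enzyme, PEP synthase and PEP carboxykinase.
AEROBIC_CYCLE_OFF: tuple[str, ...] = ("mae", "pps", "pck")

_BALANCE_METS = ("atp", "nadh", "nadph", "glyc", "etoh", "xlt", "ac", "co2", "o2")
_CARBON_EXCHANGE = {"glucose": "glc", "xylose": "xyl"}
_TOL = 1e-6


@dataclass(frozen=True)
class ScenarioConfig:
    name: str
    carbon_source: str                       # "glucose" | "xylose"
    aerobic: bool
    objective: Objective
    inactive_reactions: frozenset[str] = frozenset()
    cofactor_swaps: tuple[tuple[str, tuple[str, str], tuple[str, str]], ...] = ()
    accumulate: tuple[str, ...] = ()         # metabolites with export-only e
    uptake: float = 10.0
    edits: Mapping[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.carbon_source not in _CARBON_EXCHANGE:
            raise ConfigurationError(
                f"unknown carbon source {self.carbon_source!r}"
            )
        object.__setattr__(self, "inactive_reactions", frozenset(self.inactive_reactions))
        object.__setattr__(self, "edits", dict(self.edits))

    def exchange_policy(self) -> ExchangePolicy:
        """Assemble the scenario's exchange policy.

        Carbon-source uptake is a fixed exchange (e = -uptake); CO2, water
        and orthophosphate are free; fermentation/overflow products are
        export-only; O2 is uptake-only when aerobic and closed otherwise.
        Each accumulating metabolite gets an export-only exchange, with its
        conjugate cofactor partner (if any) opened freely so conserved
        moieties stay balanced.
        """
        modes: dict[str, str] = {}
        bounds: dict[str, float] = {}
        carbon = _CARBON_EXCHANGE[self.carbon_source]
        modes[carbon] = "fixed"
        bounds[carbon] = -self.uptake
        for met in ("co2", "h2o", "pi"):
            modes[met] = "free"
        for met in ("etoh", "glyc", "ac", "xlt", "etac", "biomass"):
            modes[met] = "export"
        if self.aerobic:
            modes["o2"] = "uptake"
            bounds["o2"] = -BIG_BOUND
        for met in self.accumulate:
            modes[met] = "export"
            partner = COFACTOR_PARTNERS.get(met)
            if partner and modes.get(partner) != "export":
                modes[partner] = "free"
        return ExchangePolicy(modes=modes, bounds=bounds)


@dataclass(frozen=True)
class ExpressionRecord:
    """FPKM of one gene under the glucose and xylose conditions."""

    gene: str
    fpkm_glucose: float
    fpkm_xylose: float

    def __post_init__(self) -> None:
        if self.fpkm_glucose < 0 or self.fpkm_xylose < 0:
            raise ValueError(f"{self.gene}: FPKM must be >= 0")


@dataclass(frozen=True)
class ScenarioReport:
    config: ScenarioConfig
    model: StoichiometricModel
    status: str
    solution: FluxSolution | None            # parsimony-refined
    raw_objective: float | None
    fva: FluxRange | None
    balances: Mapping[str, float]
    growth: float | None
    active_cycles: tuple[tuple[CycleRecord, float], ...]  # pinned, flux-carrying
    audit: tuple[CycleRecord, ...]           # gratuitous cycles: must be empty

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"

    def flux(self, rxn_id: str) -> float:
        return self.solution.v[rxn_id]


def _growth_objective() -> Objective:
    return Objective(reaction_weights={"vgrowth": 1.0})


def scenario_registry(fig_id: str) -> ScenarioConfig:
    """Configuration of one figure simulation (``fig1`` ... ``fig11``)."""
    precursors = BIOMASS_PRECURSORS
    aero = AEROBIC_CYCLE_OFF
    g6pdh_swap = (("zwf", ("nadp", "nadph"), ("nad", "nadh")),)
    registry: dict[str, ScenarioConfig] = {
        # Reference simulations: aerobic growth, ATP may accumulate.
        "fig1": ScenarioConfig(
            name="fig1", carbon_source="glucose", aerobic=True,
            objective=_growth_objective(),
            inactive_reactions=frozenset(aero), accumulate=("atp",),
        ),
        "fig2": ScenarioConfig(
            name="fig2", carbon_source="xylose", aerobic=True,
            objective=_growth_objective(),
            inactive_reactions=frozenset(aero), accumulate=("atp",),
        ),
        # NADPH maximisation: cofactors open, complete cycling (FBP active).
        "fig3": ScenarioConfig(
            name="fig3", carbon_source="xylose", aerobic=True,
            objective=Objective(exchange_weights={"nadph": 1.0}),
            inactive_reactions=frozenset(aero),
            accumulate=("atp", "nadh", "nadph"),
        ),
        # Incomplete cycling: FBP inactive, NADPH + GAP co-optimised 1:1.
        "fig4": ScenarioConfig(
            name="fig4", carbon_source="xylose", aerobic=True,
            objective=Objective(exchange_weights={"nadph": 1.0, "gap": 1.0}),
            inactive_reactions=frozenset(aero) | {"fbp"},
            accumulate=("atp", "nadh", "nadph", "gap"),
        ),
        # Growth with PFK inactive / FBP active; precursors + ATP + NADPH open.
        "fig5": ScenarioConfig(
            name="fig5", carbon_source="xylose", aerobic=True,
            objective=_growth_objective(),
            inactive_reactions=frozenset(aero) | {"pfk"},
            accumulate=precursors + ("atp", "nadph"),
        ),
        # As fig5 with the NADPH balance closed.
        "fig6": ScenarioConfig(
            name="fig6", carbon_source="xylose", aerobic=True,
            objective=_growth_objective(),
            inactive_reactions=frozenset(aero) | {"pfk"},
            accumulate=precursors + ("atp",),
        ),
        # ATP balance closed, FBP inactive: glycerol + PDB expected.
        "fig7": ScenarioConfig(
            name="fig7", carbon_source="xylose", aerobic=True,
            objective=_growth_objective(),
            inactive_reactions=frozenset(aero) | {"fbp"},
            accumulate=precursors + ("nadph",),
        ),
        # ATP balance closed, FBP and PFK both active: substrate cycle as sink.
        "fig8": ScenarioConfig(
            name="fig8", carbon_source="xylose", aerobic=True,
            objective=_growth_objective(),
            inactive_reactions=frozenset(aero),
            accumulate=precursors + ("nadph",),
        ),
        # Oxidative PPP swapped to NAD+ at G6P dehydrogenase; FBP active.
        "fig9": ScenarioConfig(
            name="fig9", carbon_source="xylose", aerobic=True,
            objective=_growth_objective(),
            inactive_reactions=frozenset(aero) | {"pfk"},
            cofactor_swaps=g6pdh_swap,
            accumulate=precursors + ("nadph", "atp"),
        ),
        "fig10": ScenarioConfig(
            name="fig10", carbon_source="xylose", aerobic=True,
            objective=_growth_objective(),
            inactive_reactions=frozenset(aero) | {"fbp"},
            cofactor_swaps=g6pdh_swap,
            accumulate=precursors + ("nadph", "atp"),
        ),
        # Anaerobic xylose: malic enzyme active (its cycle carries the redox
        # transfer), PEP/pyruvate cycle enablers still off.
        "fig11": ScenarioConfig(
            name="fig11", carbon_source="xylose", aerobic=False,
            objective=_growth_objective(),
            inactive_reactions=frozenset({"pps", "pck"}),
            accumulate=precursors + ("nadph", "atp"),
        ),
    }
    try:
        return registry[fig_id]
    except KeyError:
        raise ConfigurationError(
            f"unknown scenario {fig_id!r}; known: {', '.join(FIGURE_IDS)}"
        ) from None


def resolve_reaction_id(model: StoichiometricModel, rxn_id: str) -> str:
    """Accept either a short reaction id or a MetaCyc id."""
    ids = {r.id for r in model.reactions}
    if rxn_id in ids:
        return rxn_id
    for r in model.reactions:
        if r.metacyc_id == rxn_id:
            return r.id
    raise ConfigurationError(f"unknown reaction {rxn_id!r}")


def set_reaction_activity(
    config: ScenarioConfig, rxn_id: str, active: bool,
    model: StoichiometricModel | None = None,
) -> ScenarioConfig:
    """Return a new config with one reaction (de)activated.

    Inactive reactions have both bounds pinned to 0; re-activating restores
    the model's own bounds.  Accepts short or MetaCyc reaction ids.
    """
    rid = resolve_reaction_id(model if model is not None else build_reference_model(), rxn_id)
    inactive = set(config.inactive_reactions)
    if active:
        inactive.discard(rid)
    else:
        inactive.add(rid)
    return replace(config, inactive_reactions=frozenset(inactive))


def swap_cofactor(
    model: StoichiometricModel,
    rxn_id: str,
    old_pair: tuple[str, str],
    new_pair: tuple[str, str],
) -> StoichiometricModel:
    """Move a reaction's redox-cofactor pair to a different pair.

    ``old_pair``/``new_pair`` are (oxidised, reduced) metabolite ids; the
    coefficients are transferred unchanged, all other coefficients are
    untouched.  Swapping twice restores the original model.
    """
    rid = resolve_reaction_id(model, rxn_id)
    rxn = model.reaction(rid)
    missing = [m for m in old_pair if m not in rxn.stoich]
    if missing:
        raise ConfigurationError(
            f"reaction {rid!r} does not use cofactor(s) {missing}"
        )
    stoich = dict(rxn.stoich)
    for old, new in zip(old_pair, new_pair):
        coeff = stoich.pop(old)
        stoich[new] = stoich.get(new, 0.0) + coeff
        if stoich[new] == 0.0:
            del stoich[new]
    return model.replace_reaction(rxn.with_stoich(stoich))


def configure_scenario(model, config):
    """Apply swaps, open the scenario's exchange columns, assemble the LP."""
    for rxn_id, old_pair, new_pair in config.cofactor_swaps:
        model = swap_cofactor(model, rxn_id, old_pair, new_pair)
    opened = set(config.accumulate)
    opened |= {COFACTOR_PARTNERS[m] for m in config.accumulate if m in COFACTOR_PARTNERS}
    model = replace(model, exchangeable=frozenset(model.exchangeable | opened))
    edits = {rid: (0.0, 0.0) for rid in config.inactive_reactions}
    edits.update(config.edits)
    lp = assemble_lp(model, config.exchange_policy(), config.objective, edits=edits)
    return model, lp


def _cycle_activity(sol: FluxSolution, cycle: CycleRecord) -> tuple[float, int]:
    """Largest multiple of the cycle direction contained in the solution."""
    for sign in (1, -1):
        ratios = []
        for rid, d in cycle.direction.items():
            r = sol.v[rid] / (sign * d)
            if r <= _TOL:
                break
            ratios.append(r)
        else:
            return min(ratios), sign
    return 0.0, 1


def _removal_feasible(lp, sol, cycle, lam, sign) -> bool:
    """Can ``lam`` units of the cycle be removed without breaking the
    scenario constraints or changing the objective?  If so the cycle flux
    was gratuitous."""
    model = lp.model
    midx = model.metabolite_index()
    d_full = np.zeros(len(model.reactions))
    ridx = model.reaction_index()
    for rid, d in cycle.direction.items():
        d_full[ridx[rid]] = sign * d
    from .core import stoichiometric_matrix

    S, _, _ = stoichiometric_matrix(model)
    net = S @ d_full
    delta_obj = -lam * sum(
        lp.objective.reaction_weights.get(rid, 0.0) * sign * d
        for rid, d in cycle.direction.items()
    )
    for i, met in enumerate(model.metabolites):
        change = lam * net[i]
        if abs(change) < _TOL:
            continue
        if met.id not in lp.exchange_order:
            return False  # balance row would break: cycle is pinned
        new_e = sol.e[met.id] - change
        lo, hi = lp.policy.variable_bounds(met.id)
        if not (lo - _TOL <= new_e <= hi + _TOL):
            return False
        delta_obj -= lp.objective.exchange_weights.get(met.id, 0.0) * change
    return abs(delta_obj) <= _TOL


def run_scenario(
    model: StoichiometricModel,
    config: ScenarioConfig,
    fva: bool = True,
) -> ScenarioReport:
    """Assemble, solve, refine, audit cycles and compute balances.

    Deterministic across runs.  Infeasible scenarios are reported with
    their status and empty balances.
    """
    model, lp = configure_scenario(model, config)
    raw = solve_fba(lp)
    if not raw.optimal:
        return ScenarioReport(
            config=config, model=model, status=raw.status, solution=None,
            raw_objective=None, fva=None, balances={}, growth=None,
            active_cycles=(), audit=(),
        )
    sol = parsimonious_refine(lp, raw.objective_value)
    ranges = flux_variability(lp, raw.objective_value) if fva else None
    balances = {m: metabolite_balance(lp, sol, m) for m in _BALANCE_METS}
    cycles = detect_internal_cycles(model, inactive=config.inactive_reactions)
    active: list[tuple[CycleRecord, float]] = []
    gratuitous: list[CycleRecord] = []
    for cyc in cycles:
        lam, sign = _cycle_activity(sol, cyc)
        if lam <= _TOL:
            continue
        active.append((cyc, sign * lam))
        if _removal_feasible(lp, sol, cyc, lam, sign):
            gratuitous.append(cyc)
    return ScenarioReport(
        config=config, model=model, status="optimal", solution=sol,
        raw_objective=raw.objective_value, fva=ranges, balances=balances,
        growth=sol.v["vgrowth"], active_cycles=tuple(active),
        audit=tuple(gratuitous),
    )


def limited_malic_config(
    model: StoichiometricModel, fraction: float = 0.5
) -> ScenarioConfig:
    """Anaerobic xylose scenario with malic enzyme capped.

    The cap is ``fraction`` of the malic-enzyme flux in the unconstrained
    anaerobic optimum.  Any cap forces xylitol export (the NADH produced by
    xylitol dehydrogenase loses its sink); below roughly 15 % of the
    unconstrained flux no anaerobic steady state exists at the forced
    uptake, so the default probe sits at 50 %.
    """
    base = scenario_registry("fig11")
    rep = run_scenario(model, base, fva=False)
    if not rep.optimal:
        raise ValueError(f"anaerobic reference scenario is {rep.status}")
    cap = fraction * rep.flux("mae")
    return replace(base, name="fig11-limited-malic", edits={"mae": (0.0, cap)})


@dataclass(frozen=True)
class ComparisonResult:
    """Cross-condition table with pairwise ratios and sign-flip flags."""

    table: pd.DataFrame                       # metrics x scenario names
    ratios: Mapping[tuple[str, str], pd.Series]
    direction_flips: Mapping[tuple[str, str], tuple[str, ...]]


def compare_conditions(reports: Sequence[ScenarioReport]) -> ComparisonResult:
    """Tabulate growth and balances across >= 2 reports.

    Ratios are pairwise (b relative to a, NaN where a's value is ~0);
    ``direction_flips`` lists reactions whose flux changes sign between two
    conditions (e.g. glucose-6-phosphate isomerase between the glucose and
    xylose reference simulations).
    """
    if len(reports) < 2:
        raise ValueError("need at least two reports to compare")
    cols = {}
    for rep in reports:
        if not rep.optimal:
            raise ValueError(f"report {rep.config.name!r} is not optimal")
        cols[rep.config.name] = pd.Series(
            {"growth": rep.growth, **{f"balance:{m}": v for m, v in rep.balances.items()}}
        )
    table = pd.DataFrame(cols)
    ratios: dict[tuple[str, str], pd.Series] = {}
    flips: dict[tuple[str, str], tuple[str, ...]] = {}
    for i, a in enumerate(reports):
        for b in reports[i + 1:]:
            key = (a.config.name, b.config.name)
            base = table[a.config.name]
            ratios[key] = table[b.config.name].where(base.abs() > _TOL).div(
                base.where(base.abs() > _TOL)
            )
            flipped = tuple(
                rid
                for rid in a.solution.v
                if a.solution.v[rid] * b.solution.v.get(rid, 0.0) < -_TOL**2
                and abs(a.solution.v[rid]) > _TOL
                and abs(b.solution.v[rid]) > _TOL
            )
            flips[key] = flipped
    return ComparisonResult(table=table, ratios=ratios, direction_flips=flips)


def expression_fold_change(rec: ExpressionRecord) -> float | None:
    """Xylose/glucose FPKM ratio; ``None`` (undefined) on a zero denominator."""
    if rec.fpkm_glucose == 0:
        return None
    return rec.fpkm_xylose / rec.fpkm_glucose


#: RNA-seq transcript abundances (FPKM) of the phosphofructokinase subunits
#: and fructose-1,6-bisphosphatase in glucose vs xylose medium.
TABLE1: tuple[ExpressionRecord, ...] = (
    ExpressionRecord("PFK1", 1640.1, 341.0),
    ExpressionRecord("PFK2", 1856.4, 395.4),
    ExpressionRecord("FBP1", 13.7, 374.6),
)


def fold_change_table(
    records: Sequence[ExpressionRecord] = TABLE1,
) -> pd.DataFrame:
    """Fold changes alongside the raw FPKM values, one row per gene."""
    rows = []
    for rec in records:
        fc = expression_fold_change(rec)
        rows.append(
            {
                "gene": rec.gene,
                "fpkm_glucose": rec.fpkm_glucose,
                "fpkm_xylose": rec.fpkm_xylose,
                "fold_change": fc,
                "defined": fc is not None,
            }
        )
    return pd.DataFrame(rows).set_index("gene")
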