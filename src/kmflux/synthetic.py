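"""Random small models, a brute-force LP oracle and biomass perturbation.

These make every engine property testable without external data: the
vertex-enumeration oracle shares no code path with the LP engine (it reads
the model directly and enumerates basic feasible solutions), random models
are generated deterministically from a counter-based (Philox) seed with a
planted uptake->export pathway so a non-trivial feasible flux always
exists, and biomass perturbation provides the sensitivity surface for the
stand-in growth-drain coefficients.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .core import BiomassSpec, Metabolite, Reaction, StoichiometricModel
from .engine import ExchangePolicy, Objective

__all__ = [
    "GeneratorSpec",
    "OracleSizeError",
    "random_small_model",
    "uptake_export_policy",
    "export_objective",
    "brute_force_optimum",
    "perturb_biomass",
]

_ORACLE_TOL = 1e-7
_MAX_ENUMERATIONS = 2_000_000


class OracleSizeError(ValueError):
    """The instance is too large for exact vertex enumeration."""


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of the random-model generator.

    The planted pathway is a 1:1 linear chain from the uptake metabolite to
    the export metabolite, so with no side reactions the export optimum at
    uptake bound ``b`` is exactly ``b``.
    """

    n_metabolites: int = 6
    n_reactions: int = 9
    reversible_fraction: float = 0.3
    bound_magnitude: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (2 <= self.n_metabolites <= 8):
            raise ValueError("n_metabolites must be in [2, 8] (oracle tractability)")
        if not (self.n_metabolites - 1 <= self.n_reactions <= 12):
            raise ValueError(
                "n_reactions must be in [n_metabolites-1, 12] (oracle tractability)"
            )
        if not (0.0 <= self.reversible_fraction <= 1.0):
            raise ValueError("reversible_fraction must be in [0, 1]")
        if self.bound_magnitude <= 0:
            raise ValueError("bound_magnitude must be positive")


def _rng(seed: int) -> np.random.Generator:
    return np.random.Generator(np.random.Philox(key=abs(int(seed))))


def random_small_model(spec: GeneratorSpec) -> StoichiometricModel:
    """Deterministic random model with a planted uptake->export pathway.

    Metabolite ``m0`` is the uptake species, the last metabolite the export
    species; chain reactions convert each metabolite to the next with unit
    coefficients, then random side reactions with coefficients in
    {-2,-1,1,2} are added.  All fluxes are box-bounded by
    ``bound_magnitude``.
    """
    rng = _rng(spec.seed)
    k, b = spec.n_metabolites, spec.bound_magnitude
    metabolites = [
        Metabolite(f"m{i}", f"metabolite {i}", default_exchangeable=i in (0, k - 1))
        for i in range(k)
    ]
    reactions: list[Reaction] = []
    for i in range(k - 1):
        reactions.append(
            Reaction(
                id=f"chain{i}",
                stoich={f"m{i}": -1.0, f"m{i+1}": 1.0},
                display_index=i + 1,
                reversible=False,
                lower_bound=0.0,
                upper_bound=b,
            )
        )
    n_side = spec.n_reactions - (k - 1)
    for s in range(n_side):
        size = int(rng.integers(2, min(4, k) + 1))
        mets = rng.choice(k, size=size, replace=False)
        coeffs = rng.choice([-2.0, -1.0, 1.0, 2.0], size=size)
        if all(c > 0 for c in coeffs):
            coeffs[0] = -coeffs[0]
        if all(c < 0 for c in coeffs):
            coeffs[-1] = -coeffs[-1]
        reversible = bool(rng.random() < spec.reversible_fraction)
        reactions.append(
            Reaction(
                id=f"side{s}",
                stoich={f"m{int(m)}": float(c) for m, c in zip(mets, coeffs)},
                display_index=k + s,
                reversible=reversible,
                lower_bound=-b if reversible else 0.0,
                upper_bound=b,
            )
        )
    return StoichiometricModel(
        metabolites=tuple(metabolites),
        reactions=tuple(reactions),
        exchangeable=frozenset({"m0", f"m{k-1}"}),
        constants={"default_uptake": b / 2},
    )


def uptake_export_policy(
    model: StoichiometricModel, uptake_bound: float
) -> ExchangePolicy:
    """Uptake on the first exchangeable, export on all the others."""
    order = [m.id for m in model.metabolites if m.id in model.exchangeable]
    modes = {order[0]: "uptake"}
    modes.update({m: "export" for m in order[1:]})
    return ExchangePolicy(modes=modes, bounds={order[0]: -abs(uptake_bound)})


def export_objective(model: StoichiometricModel) -> Objective:
    """Maximise export of the last exchangeable metabolite."""
    order = [m.id for m in model.metabolites if m.id in model.exchangeable]
    return Objective(exchange_weights={order[-1]: 1.0})


def _dense_problem(model, policy, objective):
    """Independent dense assembly (no shared code with the engine)."""
    met_ids = [m.id for m in model.metabolites]
    open_ex = [
        m for m in met_ids if m in model.exchangeable and policy.mode(m) != "closed"
    ]
    n_r, n_e = len(model.reactions), len(open_ex)
    A = np.zeros((len(met_ids), n_r + n_e))
    for j, rxn in enumerate(model.reactions):
        for met, coeff in rxn.stoich.items():
            A[met_ids.index(met), j] = coeff
    for kk, met in enumerate(open_ex):
        A[met_ids.index(met), n_r + kk] = -1.0
    lb = np.empty(n_r + n_e)
    ub = np.empty(n_r + n_e)
    for j, rxn in enumerate(model.reactions):
        lb[j], ub[j] = rxn.lower_bound, rxn.upper_bound
    for kk, met in enumerate(open_ex):
        lo, hi = policy.variable_bounds(met)
        lb[n_r + kk], ub[n_r + kk] = lo, hi
    c = np.zeros(n_r + n_e)
    for rid, w in objective.reaction_weights.items():
        c[[r.id for r in model.reactions].index(rid)] = w
    for met, w in objective.exchange_weights.items():
        c[n_r + open_ex.index(met)] = w
    return A, lb, ub, c


def brute_force_optimum(
    model: StoichiometricModel,
    policy: ExchangePolicy,
    objective: Objective,
) -> float | None:
    """Exact LP maximum by enumeration of basic feasible solutions.

    Every vertex of {x : A x = 0, lb <= x <= ub} has n - rank(A) variables
    at a bound; the oracle enumerates all such bases and returns the best
    feasible objective, or ``None`` when no vertex is feasible
    (infeasible).  Refuses instances beyond its enumeration budget rather
    than approximating.
    """
    A, lb, ub, c = _dense_problem(model, policy, objective)
    if not (np.all(np.isfinite(lb)) and np.all(np.isfinite(ub))):
        raise OracleSizeError("oracle requires a fully box-bounded problem")
    n = A.shape[1]
    # orthonormal row basis: same solution set, full row rank
    u, s, vt = np.linalg.svd(A)
    r = int(np.sum(s > 1e-10 * s[0])) if s.size else 0
    if r == 0:
        # no coupling: optimum at the bounds
        return float(np.sum(np.where(c > 0, c * ub, c * lb)))
    A_red = u[:, :r].T @ A
    free = n - r
    n_cases = math.comb(n, r) * (2 ** free)
    if n_cases > _MAX_ENUMERATIONS:
        raise OracleSizeError(f"{n_cases} bases exceed the enumeration budget")
    cols = np.arange(n)
    # all lb/ub assignments for the non-basic variables
    patterns = np.array(
        [[(case >> i) & 1 for i in range(free)] for case in range(2 ** free)],
        dtype=float,
    )
    best: float | None = None
    feasible = False
    scale = max(1.0, float(np.max(np.abs(ub))), float(np.max(np.abs(lb))))
    for basic in combinations(range(n), r):
        basic = np.array(basic)
        nonbasic = np.setdiff1d(cols, basic)
        A_B = A_red[:, basic]
        if abs(np.linalg.det(A_B)) < 1e-12:
            continue
        xn = lb[nonbasic] + patterns * (ub[nonbasic] - lb[nonbasic])  # cases x free
        rhs = -A_red[:, nonbasic] @ xn.T                              # r x cases
        xb = np.linalg.solve(A_B, rhs)                                # r x cases
        ok = np.all(
            (xb >= lb[basic, None] - 1e-7 * scale)
            & (xb <= ub[basic, None] + 1e-7 * scale),
            axis=0,
        )
        if not np.any(ok):
            continue
        feasible = True
        vals = c[basic] @ xb[:, ok] + xn[ok] @ c[nonbasic]
        cand = float(np.max(vals))
        if best is None or cand > best:
            best = cand
    return best if feasible else None


def perturb_biomass(
    spec: BiomassSpec, relative_noise: float, seed: int
) -> BiomassSpec:
    """Multiply every drain by an independent factor in [1-noise, 1+noise].

    Deterministic per seed; provenance is set to ``standin:<seed>``.  Used
    to show that the study's sign/ordering conclusions do not hinge on the
    exact growth-drain coefficients.
    """
    if not (0.0 <= relative_noise <= 0.5):
        raise ValueError("relative_noise must be in [0, 0.5]")
    rng = _rng(seed)

    def jitter(value: float) -> float:
        return value * (1.0 + relative_noise * float(rng.uniform(-1.0, 1.0)))

    precursors = {m: jitter(cf) for m, cf in sorted(spec.precursors.items())}
    return BiomassSpec(
        precursors=precursors,
        atp=jitter(spec.atp),
        nadph=jitter(spec.nadph),
        nadh=jitter(spec.nadh),
        provenance=f"standin:{seed}",
    )
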