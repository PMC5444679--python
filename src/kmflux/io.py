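"""Plain-text model and result formats.

Model dialect (documented, round-trip stable):

* **Tabular** -- a directory holding ``metabolites.tsv`` (id, name,
  is_cofactor, default_exchangeable), ``reactions.tsv`` (id, metacyc_id,
  index, equation, reversible, lb, ub) and ``constants.tsv`` (key, value).
  Equations are written ``2 a + b -> c + 1.5 d`` with substrates on the
  left; reversibility is carried by the ``reversible`` column, bounds by
  ``lb``/``ub`` (``inf``/``-inf`` allowed).  UTF-8, tab-separated.
* **JSON** -- a single ``.json`` file mirroring the same field names.

Flux solutions and FVA ranges serialize to TSV (one row per reaction, then
one per exchange flux) with a ``#``-prefixed header block, and to JSON.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

from .core import Metabolite, ModelValidationError, Reaction, StoichiometricModel
from .engine import FluxRange, FluxSolution

__all__ = [
    "ModelFormatError",
    "read_model_table",
    "write_model_table",
    "solution_to_json",
    "write_solution_tsv",
    "write_fva_tsv",
]


class ModelFormatError(ValueError):
    """Parse/validation failure, with file and line context where known."""


def _fmt(x: float) -> str:
    if x == math.inf:
        return "inf"
    if x == -math.inf:
        return "-inf"
    return repr(float(x))


def _fmt_coeff(c: float) -> str:
    return "" if c == 1.0 else _fmt(c) + " "


def format_equation(rxn: Reaction) -> str:
    subs = sorted((m, -c) for m, c in rxn.stoich.items() if c < 0)
    prods = sorted((m, c) for m, c in rxn.stoich.items() if c > 0)
    left = " + ".join(f"{_fmt_coeff(c)}{m}" for m, c in subs)
    right = " + ".join(f"{_fmt_coeff(c)}{m}" for m, c in prods)
    return f"{left} -> {right}"


def parse_equation(text: str, known: set[str], where: str) -> dict[str, float]:
    stoich: dict[str, float] = {}
    try:
        left, right = text.split("->")
    except ValueError:
        raise ModelFormatError(f"{where}: equation needs one '->': {text!r}") from None
    for side, sign in ((left, -1.0), (right, 1.0)):
        side = side.strip()
        if not side:
            continue
        for term in side.split("+"):
            parts = term.split()
            if len(parts) == 1:
                coeff, met = 1.0, parts[0]
            elif len(parts) == 2:
                try:
                    coeff = float(parts[0])
                except ValueError:
                    raise ModelFormatError(
                        f"{where}: bad coefficient {parts[0]!r}"
                    ) from None
                met = parts[1]
            else:
                raise ModelFormatError(f"{where}: malformed term {term.strip()!r}")
            if met not in known:
                raise ModelFormatError(f"{where}: unknown metabolite {met!r}")
            stoich[met] = stoich.get(met, 0.0) + sign * coeff
    return {m: c for m, c in stoich.items() if c != 0.0}


_BOOL = {"true": True, "false": False}


def _read_rows(path: Path, expected: list[str]):
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines:
        raise ModelFormatError(f"{path.name}: empty file")
    header = lines[0].split("\t")
    if header != expected:
        raise ModelFormatError(
            f"{path.name}:1: header must be {expected}, got {header}"
        )
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        cells = line.split("\t")
        if len(cells) != len(expected):
            raise ModelFormatError(
                f"{path.name}:{lineno}: expected {len(expected)} columns"
            )
        yield lineno, cells


def _model_from_parts(metabolites, reactions, constants, source: str):
    try:
        return StoichiometricModel(
            metabolites=tuple(metabolites),
            reactions=tuple(reactions),
            exchangeable=frozenset(
                m.id for m in metabolites if m.default_exchangeable
            ),
            constants=constants,
        )
    except ModelValidationError as exc:
        raise ModelFormatError(f"{source}: {exc}") from exc


def read_model_table(path: str | Path) -> StoichiometricModel:
    """Read a model from the tabular directory dialect or a ``.json`` file."""
    path = Path(path)
    if path.suffix == ".json":
        return _read_json(path)
    metabolites = []
    for lineno, (mid, name, cof, exch) in _read_rows(
        path / "metabolites.tsv", ["id", "name", "is_cofactor", "default_exchangeable"]
    ):
        for flag in (cof, exch):
            if flag not in _BOOL:
                raise ModelFormatError(
                    f"metabolites.tsv:{lineno}: boolean must be true/false, got {flag!r}"
                )
        metabolites.append(Metabolite(mid, name, _BOOL[cof], _BOOL[exch]))
    known = {m.id for m in metabolites}
    if len(known) != len(metabolites):
        raise ModelFormatError("metabolites.tsv: duplicate metabolite id")

    reactions = []
    seen: dict[str, int] = {}
    for lineno, (rid, metacyc, index, equation, rev, lb, ub) in _read_rows(
        path / "reactions.tsv",
        ["id", "metacyc_id", "index", "equation", "reversible", "lb", "ub"],
    ):
        where = f"reactions.tsv:{lineno}"
        if rid in seen:
            raise ModelFormatError(
                f"{where}: duplicate reaction id {rid!r} (first at line {seen[rid]})"
            )
        seen[rid] = lineno
        if rev not in _BOOL:
            raise ModelFormatError(f"{where}: reversible must be true/false")
        try:
            reactions.append(
                Reaction(
                    id=rid,
                    metacyc_id=metacyc,
                    display_index=int(index),
                    stoich=parse_equation(equation, known, where),
                    reversible=_BOOL[rev],
                    lower_bound=float(lb),
                    upper_bound=float(ub),
                )
            )
        except ModelValidationError as exc:
            raise ModelFormatError(f"{where}: {exc}") from exc

    constants: dict[str, float] = {}
    const_path = path / "constants.tsv"
    if const_path.exists():
        for _, (key, value) in _read_rows(const_path, ["key", "value"]):
            constants[key] = float(value)
    return _model_from_parts(metabolites, reactions, constants, str(path))


def write_model_table(model: StoichiometricModel, path: str | Path) -> Path:
    """Write a model; a ``.json`` target selects the JSON dialect."""
    path = Path(path)
    if path.suffix == ".json":
        return _write_json(model, path)
    path.mkdir(parents=True, exist_ok=True)
    met_lines = ["id\tname\tis_cofactor\tdefault_exchangeable"]
    for m in model.metabolites:
        met_lines.append(
            f"{m.id}\t{m.name}\t{str(m.is_cofactor).lower()}"
            f"\t{str(m.default_exchangeable).lower()}"
        )
    (path / "metabolites.tsv").write_text("\n".join(met_lines) + "\n", encoding="utf-8")
    rxn_lines = ["id\tmetacyc_id\tindex\tequation\treversible\tlb\tub"]
    for r in model.reactions:
        rxn_lines.append(
            f"{r.id}\t{r.metacyc_id}\t{r.display_index}\t{format_equation(r)}"
            f"\t{str(r.reversible).lower()}\t{_fmt(r.lower_bound)}\t{_fmt(r.upper_bound)}"
        )
    (path / "reactions.tsv").write_text("\n".join(rxn_lines) + "\n", encoding="utf-8")
    const_lines = ["key\tvalue"] + [
        f"{k}\t{_fmt(v)}" for k, v in model.constants.items()
    ]
    (path / "constants.tsv").write_text("\n".join(const_lines) + "\n", encoding="utf-8")
    return path


def _read_json(path: Path) -> StoichiometricModel:
    data = json.loads(path.read_text(encoding="utf-8"))
    metabolites = [
        Metabolite(
            d["id"], d.get("name", ""), d.get("is_cofactor", False),
            d.get("default_exchangeable", False),
        )
        for d in data["metabolites"]
    ]
    known = {m.id for m in metabolites}
    reactions = []
    for d in data["reactions"]:
        unknown = set(d["stoich"]) - known
        if unknown:
            raise ModelFormatError(
                f"{path.name}: reaction {d['id']!r} references unknown "
                f"metabolites {sorted(unknown)}"
            )
        try:
            reactions.append(
                Reaction(
                    id=d["id"],
                    metacyc_id=d.get("metacyc_id", ""),
                    display_index=d.get("index", 0),
                    stoich={m: float(c) for m, c in d["stoich"].items()},
                    reversible=d["reversible"],
                    lower_bound=float(d["lb"]),
                    upper_bound=float(d["ub"]),
                )
            )
        except ModelValidationError as exc:
            raise ModelFormatError(f"{path.name}: reaction {d['id']!r}: {exc}") from exc
    return _model_from_parts(
        metabolites, reactions, data.get("constants", {}), path.name
    )


def _write_json(model: StoichiometricModel, path: Path) -> Path:
    data = {
        "metabolites": [
            {
                "id": m.id,
                "name": m.name,
                "is_cofactor": m.is_cofactor,
                "default_exchangeable": m.default_exchangeable,
            }
            for m in model.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "metacyc_id": r.metacyc_id,
                "index": r.display_index,
                "stoich": dict(r.stoich),
                "reversible": r.reversible,
                "lb": None if r.lower_bound == -math.inf else r.lower_bound,
                "ub": None if r.upper_bound == math.inf else r.upper_bound,
            }
            for r in model.reactions
        ],
        "constants": dict(model.constants),
    }
    for rxn in data["reactions"]:  # JSON has no inf literal
        if rxn["lb"] is None:
            rxn["lb"] = "-inf"
        if rxn["ub"] is None:
            rxn["ub"] = "inf"
    path.write_text(json.dumps(data, indent=1), encoding="utf-8")
    return path


def solution_to_json(sol: FluxSolution) -> dict:
    return {
        "status": sol.status,
        "objective_value": sol.objective_value,
        "v": dict(sol.v),
        "e": dict(sol.e),
        "residual": sol.residual,
    }


def _header(lines: list[str], sol_status: str, objective: float) -> None:
    lines.append(f"# status\t{sol_status}")
    lines.append(f"# objective\t{_fmt(objective)}")


def write_solution_tsv(
    sol: FluxSolution, model: StoichiometricModel, path: str | Path
) -> Path:
    path = Path(path)
    lines: list[str] = []
    _header(lines, sol.status, sol.objective_value)
    lines.append("id\tmetacyc_id\tflux")
    for rxn in model.reactions:
        lines.append(f"{rxn.id}\t{rxn.metacyc_id}\t{_fmt(sol.v[rxn.id])}")
    for met, flux in sol.e.items():
        lines.append(f"ex:{met}\t\t{_fmt(flux)}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def write_fva_tsv(
    fva: FluxRange, model: StoichiometricModel, objective: float, path: str | Path
) -> Path:
    path = Path(path)
    lines: list[str] = []
    _header(lines, "optimal", objective)
    lines.append("id\tmetacyc_id\tmin\tmax")
    metacyc = {r.id: r.metacyc_id for r in model.reactions}
    for name, (lo, hi) in fva.ranges.items():
        lines.append(f"{name}\t{metacyc.get(name, '')}\t{_fmt(lo)}\t{_fmt(hi)}")
    for name, why in fva.failures.items():
        lines.append(f"{name}\t{metacyc.get(name, '')}\t{why}\t{why}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path
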