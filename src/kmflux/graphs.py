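"""Flux-map export as standard graph files (GraphML / DOT).

Mirrors the figure colour semantics of the flux maps: metabolite nodes are
annotated as consumed (net uptake), produced/accumulated (net export),
allowed (exchange open but balance ~0) or balanced; reaction nodes carry
their flux, and every edge weight is |flux| so renderers can reproduce the
fraction-of-highest-flux greyscale.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx

from .scenarios import ScenarioReport

__all__ = ["flux_graph", "export_flux_graph"]

_TOL = 1e-6


def flux_graph(report: ScenarioReport) -> nx.DiGraph:
    if not report.optimal:
        raise ValueError("flux graph requires an optimal report")
    sol = report.solution
    g = nx.DiGraph(
        scenario=report.config.name,
        objective_value=float(sol.objective_value),
    )
    max_flux = max((abs(f) for f in sol.v.values()), default=1.0) or 1.0
    for met in report.model.metabolites:
        e = sol.e.get(met.id)
        if e is None:
            status = "balanced"
        elif e > _TOL:
            status = "accumulated"
        elif e < -_TOL:
            status = "consumed"
        else:
            status = "allowed"
        g.add_node(
            met.id, kind="metabolite", name=met.name, status=status,
            exchange=float(e) if e is not None else 0.0,
        )
    for rxn in report.model.reactions:
        flux = sol.v[rxn.id]
        g.add_node(
            rxn.id, kind="reaction", metacyc_id=rxn.metacyc_id,
            flux=float(flux), relative_flux=float(abs(flux) / max_flux),
        )
        for met, coeff in rxn.stoich.items():
            src, dst = (met, rxn.id) if coeff < 0 else (rxn.id, met)
            if flux < -_TOL:  # reversible running backwards: flip arrows
                src, dst = dst, src
            g.add_edge(src, dst, weight=float(abs(flux)), coefficient=float(coeff))
    return g


def _write_dot(g: nx.DiGraph, path: Path) -> None:
    lines = ["digraph fluxmap {"]
    for node, data in g.nodes(data=True):
        shape = "box" if data.get("kind") == "reaction" else "ellipse"
        label = node.replace('"', "")
        lines.append(f'  "{label}" [shape={shape}, status="{data.get("status", "")}"];')
    for u, v, data in g.edges(data=True):
        lines.append(f'  "{u}" -> "{v}" [weight={data["weight"]:.6g}];')
    lines.append("}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def export_flux_graph(report: ScenarioReport, path: str | Path) -> Path:
    """Write the report's flux map; ``.graphml`` or ``.dot`` by extension."""
    path = Path(path)
    g = flux_graph(report)
    try:
        if path.suffix == ".dot":
            _write_dot(g, path)
        else:
            nx.write_graphml(g, path)
    except OSError as exc:
        raise OSError(f"cannot write flux graph to {path}: {exc}") from exc
    return path
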