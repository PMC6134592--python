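"""Two-dimensional slices and the bipartite interaction web.

Any two dimensions of the datacube can be laid out as a table by
constraining the third: One Environment (metabolites x organisms),
One Organism (metabolites x environments) and One Metabolite
(environments x organisms).  All views share one cell encoding:

====================  ==========  =======================================
action                color code  meaning
====================  ==========  =======================================
detected              tan         present in the control pool
not detected          gray        absent from the control pool
increase              red         more abundant after transformation
decrease              blue        less abundant after transformation
no change             white       no significant net turnover
not investigated      checkered   no assertion for this combination
====================  ==========  =======================================

Shade is confidence / 5 in [0, 1] and encodes certainty of the call, not
abundance; color encodes direction only.  A (metabolite, organism,
environment) combination without an observation renders as a checkered
``not investigated`` cell in every view, so the three slices always agree
cell-for-cell.

The web view is a bipartite graph over one environment: metabolite nodes
sized by the number of interacting organisms (increase/decrease edges
only), filled when the metabolite was detected in the control pool and
hollow when it appeared only after microbial transformation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import networkx as nx
import pandas as pd

from .core import (
    CONFIDENCE_CAP,
    CONTROL_NAME,
    ActionCode,
    Datacube,
    Observation,
    search_metabolites,
)
from .errors import AmbiguousMetaboliteError, ExocubeError, UnknownEntityError

#: Fixed color scheme of the table and web views.
COLOR_CODES: dict[ActionCode, str] = {
    ActionCode.DETECTED: "tan",
    ActionCode.NOT_DETECTED: "gray",
    ActionCode.INCREASED: "red",
    ActionCode.DECREASED: "blue",
    ActionCode.NO_CHANGE: "white",
    ActionCode.NOT_INVESTIGATED: "checkered",
}


@dataclass(frozen=True)
class Cell:
    """One table cell: qualitative action plus its visual encoding."""

    action: ActionCode
    confidence: float
    shade: float
    color_code: str


def _cell(obs: Optional[Observation]) -> Cell:
    if obs is None:
        return Cell(ActionCode.NOT_INVESTIGATED, 0.0, 0.0, "checkered")
    return Cell(
        action=obs.action,
        confidence=obs.confidence,
        shade=obs.confidence / CONFIDENCE_CAP,
        color_code=COLOR_CODES[obs.action],
    )


@dataclass
class SliceTable:
    """A two-dimensional slice of the datacube."""

    constrained_dimension: str  # "environment" | "organism" | "metabolite"
    constrained_value: str
    row_labels: list[str]
    column_labels: list[str]
    cells: dict[tuple[str, str], Cell]

    def cell(self, row: str, column: str) -> Cell:
        return self.cells[(row, column)]


def _sorted_organism_columns(names: set[str]) -> list[str]:
    """Control column first, then organisms lexicographically."""
    rest = sorted(n for n in names if n != CONTROL_NAME)
    return ([CONTROL_NAME] if CONTROL_NAME in names else []) + rest


def one_environment(cube: Datacube, environment: str) -> SliceTable:
    """Metabolites x organisms within a single environment.

    Rows are all metabolites observed in the environment; the control
    column comes first.
    """
    observed = list(cube.iter_environment(environment))
    rows = sorted({o.metabolite for o in observed})
    cols = _sorted_organism_columns({o.organism for o in observed})
    cells = {
        (m, org): _cell(cube.get(m, org, environment)) for m in rows for org in cols
    }
    return SliceTable("environment", environment, rows, cols, cells)


def one_organism(cube: Datacube, organism: str) -> SliceTable:
    """Metabolites x environments for a single organism.

    Selecting the control pseudo-organism compares the compositions of the
    untransformed control pools across environments.  Rows are the union
    of metabolites the organism was assayed on in any of its environments;
    combinations never assayed render as checkered cells.
    """
    if organism not in cube.organisms:
        raise UnknownEntityError(f"unknown organism: {organism!r}")
    observed = [o for o in cube.observations.values() if o.organism == organism]
    rows = sorted({o.metabolite for o in observed})
    cols = sorted({o.environment for o in observed})
    cells = {
        (m, env): _cell(cube.get(m, organism, env)) for m in rows for env in cols
    }
    return SliceTable("organism", organism, rows, cols, cells)


def one_metabolite(
    cube: Datacube, query: str, pick: Optional[str] = None
) -> SliceTable:
    """Environments x organisms for a single compound.

    ``query`` is a case-insensitive substring search; when it matches more
    than one metabolite an :class:`AmbiguousMetaboliteError` listing the
    candidates is raised unless ``pick`` names the intended one.  No match
    raises :class:`UnknownEntityError`.
    """
    matches = [m.name for m in search_metabolites(cube, query)]
    if not matches:
        raise UnknownEntityError(f"no metabolite matches {query!r}")
    if pick is not None:
        if pick not in matches:
            raise UnknownEntityError(f"{pick!r} is not among matches for {query!r}")
        name = pick
    elif len(matches) > 1:
        raise AmbiguousMetaboliteError(query, matches)
    else:
        name = matches[0]
    observed = [o for o in cube.observations.values() if o.metabolite == name]
    rows = sorted({o.environment for o in observed})
    cols = _sorted_organism_columns(
        {
            o.organism
            for o in cube.observations.values()
            if o.environment in set(rows)
        }
    )
    cells = {(env, org): _cell(cube.get(name, org, env)) for env in rows for org in cols}
    return SliceTable("metabolite", name, rows, cols, cells)


def export_table(table: SliceTable, path: Union[str, Path], sep: str = "\t") -> None:
    """Write a slice as long-format delimited text.

    Columns: row | column | action | confidence | shade | color; one line
    per cell, deterministic (row, column) order.
    """
    records = [
        {
            "row": r,
            "column": c,
            "action": table.cells[(r, c)].action.value,
            "confidence": table.cells[(r, c)].confidence,
            "shade": table.cells[(r, c)].shade,
            "color": table.cells[(r, c)].color_code,
        }
        for r in table.row_labels
        for c in table.column_labels
    ]
    pd.DataFrame(
        records, columns=["row", "column", "action", "confidence", "shade", "color"]
    ).to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# the web
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WebEdge:
    organism: str
    metabolite: str
    action: ActionCode  # INCREASED or DECREASED only
    shade: float


@dataclass(frozen=True)
class MetaboliteNode:
    name: str
    degree: int  # number of organisms interacting (incident edges)
    in_control: bool  # filled circle when True, hollow when False


@dataclass
class WebGraph:
    """Bipartite organism-metabolite interaction web for one environment."""

    environment: str
    organisms: list[str]
    metabolites: dict[str, MetaboliteNode]
    edges: list[WebEdge] = field(default_factory=list)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph(environment=self.environment)
        for org in self.organisms:
            g.add_node(org, kind="organism")
        for node in self.metabolites.values():
            g.add_node(
                node.name, kind="metabolite", degree=node.degree, in_control=node.in_control
            )
        for e in self.edges:
            g.add_edge(e.organism, e.metabolite, action=e.action.value, shade=e.shade)
        return g


def build_web(cube: Datacube, environment: str) -> WebGraph:
    """Build the interaction web of one environment.

    Edges exist only for increase/decrease assertions; a metabolite node
    appears when it has at least one edge or was detected in the control
    pool (control-only nodes keep degree 0 and are drawn filled but
    unconnected).
    """
    observed = list(cube.iter_environment(environment))
    organisms = sorted({o.organism for o in observed if o.organism != CONTROL_NAME})
    in_control = {
        o.metabolite for o in observed
        if o.organism == CONTROL_NAME and o.action is ActionCode.DETECTED
    }
    edges = sorted(
        (
            WebEdge(
                organism=o.organism,
                metabolite=o.metabolite,
                action=o.action,
                shade=o.confidence / CONFIDENCE_CAP,
            )
            for o in observed
            if o.organism != CONTROL_NAME
            and o.action in (ActionCode.INCREASED, ActionCode.DECREASED)
        ),
        key=lambda e: (e.organism, e.metabolite),
    )
    degree: dict[str, int] = {}
    for e in edges:
        degree[e.metabolite] = degree.get(e.metabolite, 0) + 1
    node_names = sorted(set(degree) | in_control)
    metabolites = {
        name: MetaboliteNode(name, degree.get(name, 0), name in in_control)
        for name in node_names
    }
    return WebGraph(environment, organisms, metabolites, edges)


def export_graph(
    graph: WebGraph, path: Union[str, Path], format: str = "json"
) -> None:
    """Write the web as node-link JSON or GraphML.

    The JSON schema: ``{"environment", "nodes": [{"id", "type", "degree",
    "in_control"}...], "links": [{"organism", "metabolite", "action",
    "shade"}...]}`` with deterministic ordering.
    """
    path = Path(path)
    if format == "json":
        data = {
            "environment": graph.environment,
            "nodes": (
                [{"id": o, "type": "organism"} for o in graph.organisms]
                + [
                    {
                        "id": n.name,
                        "type": "metabolite",
                        "degree": n.degree,
                        "in_control": n.in_control,
                    }
                    for _, n in sorted(graph.metabolites.items())
                ]
            ),
            "links": [
                {
                    "organism": e.organism,
                    "metabolite": e.metabolite,
                    "action": e.action.value,
                    "shade": e.shade,
                }
                for e in graph.edges
            ],
        }
        path.write_text(json.dumps(data, indent=1, sort_keys=True) + "\n")
    elif format == "graphml":
        nx.write_graphml(graph.to_networkx(), path)
    else:
        raise ExocubeError(f"unknown graph format {format!r} (json|graphml)")


def import_graph(path: Union[str, Path]) -> WebGraph:
    """Read node-link JSON written by :func:`export_graph` back into a WebGraph."""
    data = json.loads(Path(path).read_text())
    organisms = sorted(n["id"] for n in data["nodes"] if n["type"] == "organism")
    metabolites = {
        n["id"]: MetaboliteNode(n["id"], n["degree"], n["in_control"])
        for n in data["nodes"]
        if n["type"] == "metabolite"
    }
    edges = sorted(
        (
            WebEdge(
                organism=link["organism"],
                metabolite=link["metabolite"],
                action=ActionCode(link["action"]),
                shade=link["shade"],
            )
            for link in data["links"]
        ),
        key=lambda e: (e.organism, e.metabolite),
    )
    return WebGraph(data["environment"], organisms, metabolites, edges)
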