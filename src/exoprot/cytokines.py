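"""Network-based cytokine inference from a scored interaction network.

Given the significantly case- or control-associated proteins and a
STRING-style scored edge list, the analysis asks which cytokines are
preferentially wired to one class:

1. edges are filtered to combined score strictly greater than 0.4;
2. cytokines must have at least five filtered connections to significant
   proteins to be eligible;
3. for each eligible cytokine ``c`` and class ``d`` (case / control), the
   enrichment score is the double ratio

       e_d(c) = (k_d(c) / T_d) / (k_total(c) / T_total)

   where ``k_d(c)`` counts c's filtered edges to class-d proteins, ``T_d``
   is a class total (by default the number of class-d significant proteins;
   alternatively the number of filtered protein-protein edges incident to
   the class) and ``T_total = T_case + T_control``;
4. the fold-connection ratio ``e_case / e_control`` summarizes each
   cytokine's leaning — a ratio of +inf (no control connections) is reported
   as such, never capped.

The default cytokine panel is TGFb, TNF, IFN, IL1-40, CXCL1-16 and CCL1-27
(86 identifiers after range expansion); identity matching against the panel
is case-insensitive with an optional alias table.  A small editable
classification table marks IL6 and TNF pro-inflammatory and IL10
anti-inflammatory for network coloring; everything else is unclassified.
"""

from __future__ import annotations

import re
import warnings
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_PANEL_SPEC",
    "DEFAULT_CYTOKINE_CLASSES",
    "expand_cytokine_panel",
    "build_network",
    "filter_edges",
    "eligible_cytokines",
    "enrichment_scores",
    "decorate_network",
    "write_graphml",
    "write_sif",
]

DEFAULT_PANEL_SPEC = ["TGFb", "TNF", "IFN", "IL1-40", "CXCL1-16", "CCL1-27"]

#: default pro/anti-inflammatory classification, overridable via file
DEFAULT_CYTOKINE_CLASSES: dict[str, str] = {
    "IL6": "pro_inflammatory",
    "TNF": "pro_inflammatory",
    "IL10": "anti_inflammatory",
}

_RANGE_RE = re.compile(r"^([A-Za-z][A-Za-z0-9_]*?)(\d+)-(\d+)$")


def expand_cytokine_panel(spec: Iterable[str]) -> list[str]:
    """Expand range strings like ``CXCL1-16`` into explicit identifier lists.

    Plain names pass through; ``PREFIXa-b`` expands to PREFIXa..PREFIXb.
    The result is de-duplicated preserving first-seen order.
    """
    out: list[str] = []
    seen: set[str] = set()
    for item in spec:
        item = str(item).strip()
        if not item:
            raise ValueError("empty panel entry")
        m = _RANGE_RE.match(item)
        if m:
            prefix, a, b = m.group(1), int(m.group(2)), int(m.group(3))
            if a > b:
                raise ValueError(f"malformed range {item!r}: {a} > {b}")
            names = [f"{prefix}{k}" for k in range(a, b + 1)]
        elif "-" in item:
            raise ValueError(f"malformed range {item!r}")
        else:
            names = [item]
        for name in names:
            if name not in seen:
                seen.add(name)
                out.append(name)
    return out


def _canonical(name: str, panel: Iterable[str], aliases: Mapping[str, str] | None = None) -> str | None:
    """Case-insensitive match of a node name against the panel (with aliases)."""
    lut = {p.upper(): p for p in panel}
    key = str(name).upper()
    if aliases:
        key = {a.upper(): b.upper() for a, b in aliases.items()}.get(key, key)
    return lut.get(key)


def build_network(
    edges: pd.DataFrame,
    cytokine_panel: Iterable[str],
    aliases: Mapping[str, str] | None = None,
) -> nx.Graph:
    """Assemble an undirected scored graph from a three-column edge list.

    Nodes matching the cytokine panel (case-insensitively, honoring aliases)
    get ``kind='cytokine'`` and are renamed to the panel's canonical
    spelling; all other nodes are proteins.  Self-edges are rejected; a
    duplicate edge keeps the higher score.
    """
    panel = list(cytokine_panel)
    G = nx.Graph()
    for u, v, score in edges[["node1", "node2", "combined_score"]].itertuples(index=False):
        if not 0.0 <= score <= 1.0:
            raise ValueError(f"combined_score {score} outside [0, 1] on edge ({u}, {v})")
        cu, cv = _canonical(u, panel, aliases), _canonical(v, panel, aliases)
        u = cu if cu is not None else str(u)
        v = cv if cv is not None else str(v)
        if u == v:
            raise ValueError(f"self-edge on node {u!r}")
        G.add_node(u, kind="cytokine" if cu is not None else "protein")
        G.add_node(v, kind="cytokine" if cv is not None else "protein")
        if G.has_edge(u, v):
            G[u][v]["combined_score"] = max(G[u][v]["combined_score"], float(score))
        else:
            G.add_edge(u, v, combined_score=float(score))
    return G


def filter_edges(network: nx.Graph, min_score: float = 0.4) -> nx.Graph:
    """Keep edges with combined score strictly greater than ``min_score``."""
    G = nx.Graph()
    G.add_nodes_from(network.nodes(data=True))
    G.add_edges_from(
        (u, v, d) for u, v, d in network.edges(data=True) if d["combined_score"] > min_score
    )
    return G


def _cytokine_nodes(network: nx.Graph) -> list[str]:
    return [n for n, d in network.nodes(data=True) if d.get("kind") == "cytokine"]


def eligible_cytokines(
    network: nx.Graph,
    significant_proteins: Mapping[str, str],
    min_connections: int = 5,
) -> list[str]:
    """Cytokines with at least ``min_connections`` edges to significant proteins.

    ``significant_proteins`` maps protein id to its class label
    (``case_associated`` / ``control_associated``); connections to either
    class count toward eligibility.
    """
    out = []
    for cyt in _cytokine_nodes(network):
        k = sum(1 for nb in network.neighbors(cyt) if nb in significant_proteins)
        if k >= min_connections:
            out.append(cyt)
    return out


def enrichment_scores(
    network: nx.Graph,
    significant_proteins: Mapping[str, str],
    class_weighting: str = "protein_count",
    min_connections: int = 5,
) -> pd.DataFrame:
    """Per-cytokine class enrichment and fold-connection ratios.

    Class totals ``T_d`` depend on ``class_weighting``:

    * ``protein_count`` — number of significant proteins in class d;
    * ``edge_count`` — filtered protein-protein edges incident to class-d
      proteins (cytokine edges excluded).

    Rows are sorted by decreasing fold_connection (+inf first), then by
    decreasing k_case, then identifier.  A class with ``T_d = 0`` yields NaN
    enrichment for that class.
    """
    if class_weighting not in ("protein_count", "edge_count"):
        raise ValueError("class_weighting must be 'protein_count' or 'edge_count'")
    case_set = {p for p, c in significant_proteins.items() if c.startswith("case")}
    ctrl_set = {p for p, c in significant_proteins.items() if c.startswith("control")}

    if class_weighting == "protein_count":
        t_case, t_ctrl = len(case_set), len(ctrl_set)
    else:
        kinds = nx.get_node_attributes(network, "kind")
        t_case = t_ctrl = 0
        for u, v in network.edges():
            if kinds.get(u) == "cytokine" or kinds.get(v) == "cytokine":
                continue
            if u in case_set or v in case_set:
                t_case += 1
            if u in ctrl_set or v in ctrl_set:
                t_ctrl += 1
    t_total = t_case + t_ctrl

    rows = []
    for cyt in eligible_cytokines(network, significant_proteins, min_connections):
        nbrs = set(network.neighbors(cyt))
        k_case = len(nbrs & case_set)
        k_ctrl = len(nbrs & ctrl_set)
        k_total = k_case + k_ctrl
        e_case = (k_case / t_case) / (k_total / t_total) if t_case > 0 else np.nan
        e_ctrl = (k_ctrl / t_ctrl) / (k_total / t_total) if t_ctrl > 0 else np.nan
        if np.isnan(e_case) or np.isnan(e_ctrl):
            fold = np.nan
        elif e_ctrl == 0.0:
            fold = np.inf if e_case > 0 else np.nan
        else:
            fold = e_case / e_ctrl
        rows.append([cyt, k_case, k_ctrl, k_total, e_case, e_ctrl, fold])

    table = pd.DataFrame(
        rows,
        columns=["cytokine", "k_case", "k_control", "k_total", "e_case", "e_control", "fold_connection"],
    ).set_index("cytokine")
    if len(table):
        table = table.sort_values(
            ["fold_connection", "k_case", "cytokine"], ascending=[False, False, True],
            na_position="last",
        )
    return table


def decorate_network(
    network: nx.Graph,
    differential: pd.DataFrame,
    enrichment: pd.DataFrame,
    classes: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Node and edge attribute tables for Cytoscape-style rendering.

    Significant proteins are sized by |pi|; each protein is colored ``pro``
    if it touches any pro-inflammatory enriched cytokine, ``anti`` if it
    touches only anti-inflammatory ones, and ``none`` otherwise (``pro``
    takes precedence on mixed connections).  Proteins absent from the
    differential table get missing attributes with a warning.
    """
    if classes is None:
        classes = DEFAULT_CYTOKINE_CLASSES
    class_lut = {k.upper(): v for k, v in classes.items()}
    enriched = set(enrichment.index)
    pro = {c for c in enriched if class_lut.get(c.upper()) == "pro_inflammatory"}
    anti = {c for c in enriched if class_lut.get(c.upper()) == "anti_inflammatory"}

    node_rows = []
    missing = []
    for node, data in network.nodes(data=True):
        kind = data.get("kind", "protein")
        pi = np.nan
        size = np.nan
        if kind == "protein":
            if node in differential.index:
                pi = float(differential.at[node, "pi_score"])
                if differential.at[node, "class_label"] != "not_significant":
                    size = abs(pi)
            else:
                missing.append(node)
        nbrs = set(network.neighbors(node))
        if nbrs & pro:
            color = "pro"
        elif nbrs & anti:
            color = "anti"
        else:
            color = "none"
        node_rows.append([node, kind, pi, size, color])
    if missing:
        warnings.warn(f"proteins absent from the differential table: {sorted(missing)}")

    nodes = pd.DataFrame(
        node_rows, columns=["node", "kind", "pi_score", "size", "inflammation_color"]
    ).set_index("node")
    edges = pd.DataFrame(
        [(u, v, d["combined_score"]) for u, v, d in network.edges(data=True)],
        columns=["node1", "node2", "combined_score"],
    )
    return nodes, edges


def write_graphml(network: nx.Graph, node_attrs: pd.DataFrame, path) -> None:
    """GraphML export with decoration attributes attached to nodes."""
    G = network.copy()
    for node, row in node_attrs.iterrows():
        if node not in G:
            continue
        G.nodes[node]["kind"] = str(row["kind"])
        G.nodes[node]["inflammation_color"] = str(row["inflammation_color"])
        if np.isfinite(row["pi_score"]):
            G.nodes[node]["pi_score"] = float(row["pi_score"])
        if np.isfinite(row["size"]):
            G.nodes[node]["size"] = float(row["size"])
    nx.write_graphml(G, path)


def write_sif(network: nx.Graph, path, relation: str = "interacts") -> None:
    """Cytoscape SIF export (node1 relation node2 per line)."""
    with open(path, "w") as fh:
        for u, v in network.edges():
            fh.write(f"{u}\t{relation}\t{v}\n")
        for node in nx.isolates(network):
            fh.write(f"{node}\n")
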