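"""Molecule similarity network: threshold graph, components, centrality.

Molecules are nodes; an undirected edge joins molecules k and l whenever
|TPSM(k, l)| strictly exceeds the threshold (default 0.6, the conventional
cut for a moderately high Pearson correlation). Edges carry the signed TPSM
value as metadata only — shortest paths are unweighted.

Betweenness centrality uses Brandes' algorithm and is normalized by
2 / ((n - 1)(n - 2)) with n the number of nodes that have at least one edge
(the network as drawn); per-component normalization is available by flag.
deg_Normalized divides a molecule's degree by the size of its own metabolic
group within the analysed panel, so densely intra-connected small groups
score high.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

TPSM_THRESHOLD = 0.6


@dataclass
class MoleculeGraph:
    """Thresholded |TPSM| graph plus derived per-node statistics."""

    graph: nx.Graph                       # all molecules as nodes
    threshold: float
    components: dict[str, int] = field(default_factory=dict)
    isolated: list[str] = field(default_factory=list)
    betweenness: dict[str, float] = field(default_factory=dict)
    deg_normalized: dict[str, float] = field(default_factory=dict)

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def edges(self) -> pd.DataFrame:
        rows = [
            dict(
                source=u,
                target=v,
                tpsm=d["tpsm"],
                abs_tpsm=d["abs_tpsm"],
                sign="positive" if d["tpsm"] >= 0 else "negative",
            )
            for u, v, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["source", "target", "tpsm", "abs_tpsm", "sign"])

    def node_table(self) -> pd.DataFrame:
        g = self.graph
        return pd.DataFrame(
            {
                "molecule": list(g.nodes),
                "group": [g.nodes[n].get("group", "other") for n in g.nodes],
                "degree": [g.degree(n) for n in g.nodes],
                "component": [self.components.get(n, -1) for n in g.nodes],
                "betweenness": [self.betweenness.get(n, 0.0) for n in g.nodes],
                "deg_normalized": [self.deg_normalized.get(n, 0.0) for n in g.nodes],
            }
        )


def build_graph(
    tpsm: pd.DataFrame,
    threshold: float = TPSM_THRESHOLD,
    groups: dict[str, str] | None = None,
) -> MoleculeGraph:
    """Edge (k, l) iff |TPSM(k, l)| > threshold (strict), k != l."""
    mat = np.asarray(tpsm, dtype=float)
    if mat.shape[0] != mat.shape[1]:
        raise ValueError("TPSM matrix must be square")
    asym = np.nan_to_num(mat) - np.nan_to_num(mat).T
    if np.abs(asym).max() > 1e-9:
        raise ValueError("TPSM matrix is not symmetric")

    mols = list(tpsm.index)
    g = nx.Graph()
    for m in mols:
        g.add_node(m, group=(groups or {}).get(m, "other"))
    n = len(mols)
    for a in range(n):
        for b in range(a + 1, n):
            val = mat[a, b]
            if not np.isnan(val) and abs(val) > threshold:
                g.add_edge(mols[a], mols[b], tpsm=float(val), abs_tpsm=float(abs(val)))
    return MoleculeGraph(graph=g, threshold=threshold)


def connected_components(mg: MoleculeGraph) -> MoleculeGraph:
    """Components over nodes with >= 1 edge; isolated nodes listed apart.

    Component ids are 1-based, ordered by decreasing size then by the first
    member's name for determinism.
    """
    g = mg.graph
    connected_nodes = [n for n in g.nodes if g.degree(n) > 0]
    mg.isolated = [n for n in g.nodes if g.degree(n) == 0]
    comps = [sorted(c) for c in nx.connected_components(g.subgraph(connected_nodes))]
    comps.sort(key=lambda c: (-len(c), c[0]))
    mg.components = {n: i + 1 for i, c in enumerate(comps) for n in c}
    return mg


def betweenness(mg: MoleculeGraph, per_component: bool = False) -> MoleculeGraph:
    """Brandes betweenness over unweighted shortest paths.

    Normalization divides by (n - 1)(n - 2) / 2 where n is the number of
    connected nodes in the whole graph (default) or of each node's own
    component (``per_component=True``). Fewer than 3 connected nodes give
    all zeros.
    """
    g = mg.graph
    connected = [n for n in g.nodes if g.degree(n) > 0]
    sub = g.subgraph(connected)
    if per_component:
        values: dict[str, float] = {}
        for comp in nx.connected_components(sub):
            comp_g = sub.subgraph(comp)
            values.update(nx.betweenness_centrality(comp_g, normalized=len(comp) > 2))
    else:
        raw = nx.betweenness_centrality(sub, normalized=False)
        n = len(connected)
        scale = 2.0 / ((n - 1) * (n - 2)) if n > 2 else 0.0
        values = {node: v * scale for node, v in raw.items()}
    mg.betweenness = {n: values.get(n, 0.0) for n in g.nodes}
    return mg


def degree_normalized(
    mg: MoleculeGraph, groups: dict[str, str] | None = None
) -> MoleculeGraph:
    """deg_Normalized(k) = degree(k) / size of k's metabolic group."""
    g = mg.graph
    if groups is None:
        groups = {n: g.nodes[n].get("group") for n in g.nodes}
    missing = [n for n in g.nodes if groups.get(n) in (None, "")]
    if missing:
        raise ValueError(f"nodes without a metabolic group: {missing}")
    sizes: dict[str, int] = {}
    for n in g.nodes:
        sizes[groups[n]] = sizes.get(groups[n], 0) + 1
    mg.deg_normalized = {n: g.degree(n) / sizes[groups[n]] for n in g.nodes}
    return mg


def write_graphml(mg: MoleculeGraph, path) -> None:
    """Export the graph with per-node statistics as GraphML."""
    g = mg.graph.copy()
    for n in g.nodes:
        g.nodes[n]["component"] = int(mg.components.get(n, -1))
        g.nodes[n]["betweenness"] = float(mg.betweenness.get(n, 0.0))
        g.nodes[n]["deg_normalized"] = float(mg.deg_normalized.get(n, 0.0))
    nx.write_graphml(g, path)


def analyse_network(
    tpsm: pd.DataFrame,
    groups: dict[str, str],
    threshold: float = TPSM_THRESHOLD,
    per_component_betweenness: bool = False,
) -> MoleculeGraph:
    """Build the graph and compute components, betweenness, deg_Normalized."""
    mg = build_graph(tpsm, threshold=threshold, groups=groups)
    connected_components(mg)
    betweenness(mg, per_component=per_component_betweenness)
    degree_normalized(mg, groups)
    return mg
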