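"""Network construction and topology statistics.

Builds the undirected weighted co-expression graph from a thresholded edge
list and computes the statistics reported for such networks: per-node
degree and its histogram, connected components (sub-networks), adjacency
queries, and radiality.

Radiality is a closeness-like centrality normalised per connected
component: for a node v in component C with unweighted diameter D >= 1,

    Rad(v) = (D + 1 - mean_{w in C, w != v} d(v, w)) / D

which lies in [0, 1] and equals 1 exactly when v is adjacent to every other
node of its component.  Distances are hop counts; edge weights are carried
as attributes but never enter the shortest paths.  Singleton components
have no defined radiality (reported as NaN).  Cross-component distances are
treated as undefined, not infinite: every quantity is per-component.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

import networkx as nx
import pandas as pd

__all__ = [
    "TopologyReport",
    "build_network",
    "degree",
    "degree_histogram",
    "connected_components",
    "neighbors",
    "radiality",
    "topology_report",
]

#: node attributes attached from a gene catalog, with defaults for genes
#: absent from the catalog
_CATALOG_DEFAULTS = {
    "block_id": "unknown",
    "is_anchor": False,
    "is_tf": False,
    "is_organelle_encoded": False,
    "localization": "unknown",
}


@dataclass(frozen=True)
class TopologyReport:
    """Per-node table (degree, component, radiality) plus summaries."""

    nodes: pd.DataFrame
    degree_histogram: dict[int, int]
    component_sizes: tuple[int, ...]

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_components(self) -> int:
        return len(self.component_sizes)


def build_network(edges: pd.DataFrame, catalog: pd.DataFrame | None = None) -> nx.Graph:
    """Undirected weighted graph from an edge list.

    The node set is exactly the set of edge endpoints: anchor genes that
    retained no edge do not become nodes.  Catalog attributes are attached
    where available, defaulting to unknown/False otherwise.

    Raises
    ------
    ValueError
        On self-edges or duplicate gene pairs (conflicting or not).
    """
    net = nx.Graph()
    seen: set[tuple[str, str]] = set()
    for gene_a, gene_b, weight in edges[["gene_a", "gene_b", "weight"]].itertuples(index=False):
        a, b = str(gene_a), str(gene_b)
        if a == b:
            raise ValueError(f"self-edge on gene {a}")
        key = (a, b) if a < b else (b, a)
        if key in seen:
            raise ValueError(f"duplicate edge {key[0]}-{key[1]}")
        seen.add(key)
        net.add_edge(a, b, weight=float(weight))
    for node in net.nodes:
        if catalog is not None and node in catalog.index:
            row = catalog.loc[node]
            for attr in _CATALOG_DEFAULTS:
                if attr in row.index:
                    net.nodes[node][attr] = row[attr]
                else:
                    net.nodes[node][attr] = _CATALOG_DEFAULTS[attr]
        else:
            net.nodes[node].update(_CATALOG_DEFAULTS)
    return net


def degree(net: nx.Graph) -> dict[str, int]:
    """Per-node degree."""
    return {node: d for node, d in net.degree()}


def degree_histogram(net: nx.Graph) -> dict[int, int]:
    """Degree -> node count, keyed ascending."""
    counts = Counter(d for _, d in net.degree())
    return dict(sorted(counts.items()))


def connected_components(net: nx.Graph) -> list[list[str]]:
    """Maximal connected components, largest first.

    Each component is a sorted node list; ties in size break on the first
    node id, giving a stable ordering.
    """
    comps = [sorted(c) for c in nx.connected_components(net)]
    comps.sort(key=lambda c: (-len(c), c[0]))
    return comps


def neighbors(net: nx.Graph, gene: str) -> list[str]:
    """Sorted adjacency set of `gene`."""
    if gene not in net:
        raise KeyError(f"gene {gene!r} is not a node of the network")
    return sorted(net.neighbors(gene))


def radiality(net: nx.Graph) -> dict[str, float]:
    """Per-node radiality (NaN for singleton components)."""
    result: dict[str, float] = {}
    for comp in nx.connected_components(net):
        comp = list(comp)
        m = len(comp)
        if m == 1:
            result[comp[0]] = math.nan
            continue
        dist_sum: dict[str, int] = {}
        diameter = 0
        for v in comp:
            lengths = nx.single_source_shortest_path_length(net, v)
            dist_sum[v] = sum(lengths.values())
            ecc = max(lengths.values())
            if ecc > diameter:
                diameter = ecc
        for v in comp:
            mean_dist = dist_sum[v] / (m - 1)
            result[v] = (diameter + 1.0 - mean_dist) / diameter
    return result


def topology_report(net: nx.Graph) -> TopologyReport:
    """Degree, component id and radiality per node plus graph summaries.

    Component ids are assigned in the order of :func:`connected_components`
    (0 = largest).  The handshake invariant sum(degree) == 2 |E| holds by
    construction.
    """
    comps = connected_components(net)
    comp_of = {node: i for i, comp in enumerate(comps) for node in comp}
    deg = degree(net)
    rad = radiality(net)
    nodes = pd.DataFrame(
        {
            "degree": [deg[n] for n in sorted(net.nodes)],
            "component": [comp_of[n] for n in sorted(net.nodes)],
            "radiality": [rad[n] for n in sorted(net.nodes)],
        },
        index=pd.Index(sorted(net.nodes), name="gene_id"),
    )
    return TopologyReport(
        nodes=nodes,
        degree_histogram=degree_histogram(net),
        component_sizes=tuple(len(c) for c in comps),
    )
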