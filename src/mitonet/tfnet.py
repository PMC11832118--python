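"""Transcription-factor-augmented network.

The anchor gene set is extended with a TF list, run through the same
PCIT + threshold pipeline, and then pruned with the TF-retention rule:
a TF-only node is excluded when it has strictly more connections to other
TF-only nodes than to anchor genes.  Genes that are both TF and anchor
count as anchors on the neighbour side and are exempt from removal.
Filtering is a single simultaneous pass: all neighbour counts are evaluated
on the unfiltered graph, so the result is order-independent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import pandas as pd

from .topology import radiality as _radiality

__all__ = [
    "ANCHOR_ONLY",
    "TF_ONLY",
    "BOTH",
    "TfNetworkReport",
    "build_tf_gene_set",
    "filter_tf_nodes",
    "rank_tf",
]

ANCHOR_ONLY = "anchor-only"
TF_ONLY = "tf-only"
BOTH = "both"

_ANCHOR_SIDE = frozenset({ANCHOR_ONLY, BOTH})


@dataclass(frozen=True)
class TfNetworkReport:
    """Per-TF connection counts and retention decisions.

    One row per TF node present in the unfiltered network (tf-only and
    both-labelled), with columns n_tf (neighbours labelled tf-only),
    n_mito (neighbours labelled anchor-only or both), and retained.
    """

    table: pd.DataFrame

    @property
    def retained(self) -> list[str]:
        return sorted(self.table.index[self.table["retained"]])

    @property
    def excluded(self) -> list[str]:
        return sorted(self.table.index[~self.table["retained"]])


def build_tf_gene_set(
    anchor: Sequence[str], tfs: Sequence[str]
) -> tuple[list[str], dict[str, str]]:
    """Union of anchor and TF lists with per-gene labels.

    Labels are anchor-only, tf-only, or both; the combined list is sorted.
    """
    if not anchor or not tfs:
        raise ValueError("anchor and TF lists must both be non-empty")
    anchor_set = {str(g) for g in anchor}
    tf_set = {str(g) for g in tfs}
    labels = {}
    for gene in sorted(anchor_set | tf_set):
        if gene in anchor_set and gene in tf_set:
            labels[gene] = BOTH
        elif gene in anchor_set:
            labels[gene] = ANCHOR_ONLY
        else:
            labels[gene] = TF_ONLY
    return sorted(labels), labels


def filter_tf_nodes(
    net: nx.Graph, labels: Mapping[str, str]
) -> tuple[nx.Graph, TfNetworkReport]:
    """Drop TF-only nodes with more TF-only than anchor neighbours.

    Neighbour counts are taken on the unfiltered graph (single pass);
    removal requires a strict majority of TF-only neighbours (ties retain).
    Removed nodes take their incident edges with them.  Anchor-only and
    both-labelled nodes are never removed.

    Raises
    ------
    ValueError
        If any network node is missing from `labels`.
    """
    missing = [n for n in net.nodes if n not in labels]
    if missing:
        raise ValueError(f"labels missing for node(s): {', '.join(sorted(missing)[:5])}")
    rows = []
    to_remove = []
    for node in sorted(net.nodes):
        if labels[node] not in (TF_ONLY, BOTH):
            continue
        n_tf = sum(1 for nb in net.neighbors(node) if labels[nb] == TF_ONLY)
        n_mito = sum(1 for nb in net.neighbors(node) if labels[nb] in _ANCHOR_SIDE)
        removed = labels[node] == TF_ONLY and n_tf > n_mito
        if removed:
            to_remove.append(node)
        rows.append((node, labels[node], n_tf, n_mito, not removed))
    filtered = net.copy()
    filtered.remove_nodes_from(to_remove)
    table = pd.DataFrame(
        rows, columns=["tf_id", "label", "n_tf", "n_mito", "retained"]
    ).set_index("tf_id")
    return filtered, TfNetworkReport(table=table)


def rank_tf(net: nx.Graph, labels: Mapping[str, str], top_k: int | None = None) -> pd.DataFrame:
    """Degree and radiality rankings of the TF nodes of `net`.

    Returns one row per TF node (tf-only or both) with degree, radiality,
    degree_rank and radiality_rank (1 = best; ties break on gene id).
    With `top_k`, only TFs in the top k of either ranking are kept.
    """
    rad = _radiality(net)
    tf_nodes = sorted(n for n in net.nodes if labels.get(n) in (TF_ONLY, BOTH))
    frame = pd.DataFrame(
        {
            "degree": [net.degree(n) for n in tf_nodes],
            "radiality": [rad[n] for n in tf_nodes],
            "label": [labels[n] for n in tf_nodes],
        },
        index=pd.Index(tf_nodes, name="tf_id"),
    )
    by_degree = sorted(tf_nodes, key=lambda n: (-frame.at[n, "degree"], n))
    by_rad = sorted(
        tf_nodes,
        key=lambda n: (
            -(frame.at[n, "radiality"] if frame.at[n, "radiality"] == frame.at[n, "radiality"] else -1.0),
            n,
        ),
    )
    frame["degree_rank"] = pd.Series({n: i + 1 for i, n in enumerate(by_degree)})
    frame["radiality_rank"] = pd.Series({n: i + 1 for i, n in enumerate(by_rad)})
    frame = frame.sort_values(["degree_rank"])
    if top_k is not None:
        keep = (frame["degree_rank"] <= top_k) | (frame["radiality_rank"] <= top_k)
        frame = frame[keep]
    return frame
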