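"""Differential-expression overlay on the co-expression network.

Consumes a long-format (gene, contrast, log2fc[, is_de]) table produced by
an upstream differential-expression fit, applies the expression filter used
to gate such fits (>= 1 CPM in at least half the samples), attaches fold
changes and up/down/unaffected classes to network nodes, and answers
cross-contrast consistency queries (genes moving the same direction in
every contrast).

Sign convention: positive log2fc means upregulated in the
high-feed-efficiency (Low-RFI) group; the table is data, so callers can
flip signs upstream if their contrast is oriented the other way.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

__all__ = [
    "cpm_filter",
    "classify_node",
    "attach_overlay",
    "consistent_genes",
    "DIRECTIONS",
]

DIRECTIONS = ("up", "down")


def cpm_filter(
    counts: pd.DataFrame,
    min_cpm: float = 1.0,
    min_fraction: float = 0.5,
    *,
    library_sizes: pd.Series | None = None,
) -> list[str]:
    """Genes with CPM >= `min_cpm` in at least `min_fraction` of samples.

    CPM = count / library_size * 1e6.  Library sizes default to column sums.
    "At least half" uses the ceiling rule for odd sample counts: a gene is
    kept iff the number of qualifying samples is >= ceil(min_fraction * n).

    Raises
    ------
    ValueError
        If any library size is zero (the offending sample is named).
    """
    if library_sizes is None:
        library_sizes = counts.sum(axis=0)
    zero = library_sizes[library_sizes <= 0]
    if len(zero):
        raise ValueError(f"zero library size in sample(s): {', '.join(map(str, zero.index[:5]))}")
    cpm = counts.div(library_sizes, axis=1) * 1e6
    needed = math.ceil(min_fraction * counts.shape[1])
    qualifying = (cpm >= min_cpm).sum(axis=1)
    return [str(g) for g in counts.index[qualifying >= needed]]


def classify_node(log2fc: float, is_de: bool | None = None, *, floor: float = 0.0) -> str:
    """Classify one (gene, contrast) observation as up, down or unaffected.

    With a DE flag: unaffected unless flagged, then by the sign of log2fc
    (zero ties resolve to unaffected).  Without a flag: by sign, with
    |log2fc| strictly below `floor` treated as unaffected.  Missing values
    (NaN) are always unaffected.
    """
    if log2fc is None or (isinstance(log2fc, float) and math.isnan(log2fc)):
        return "unaffected"
    if is_de is not None and not is_de:
        return "unaffected"
    if is_de is None and abs(log2fc) < floor:
        return "unaffected"
    if log2fc > 0:
        return "up"
    if log2fc < 0:
        return "down"
    return "unaffected"


def _contrasts(table: pd.DataFrame) -> list[str]:
    contrasts = sorted(table["contrast_id"].unique())
    if not contrasts:
        raise ValueError("overlay table has an empty contrast set")
    return contrasts


def _classify_table(table: pd.DataFrame, floor: float) -> pd.DataFrame:
    has_de = "is_de" in table.columns
    out = table.copy()
    out["node_class"] = [
        classify_node(fc, bool(de) if has_de else None, floor=floor)
        for fc, de in zip(out["log2fc"], out["is_de"] if has_de else [None] * len(out))
    ]
    return out


def attach_overlay(net: nx.Graph, table: pd.DataFrame, *, floor: float = 0.0) -> nx.Graph:
    """Copy of `net` with per-contrast log2fc and class node attributes.

    Each node gains ``log2fc_<contrast>`` and ``class_<contrast>`` for every
    contrast in the table; genes absent from the table get NaN fold change
    and class "unaffected".  Structure (node and edge sets) is unchanged,
    and re-attaching the same table is idempotent.
    """
    contrasts = _contrasts(table)
    classified = _classify_table(table, floor)
    lookup = {
        (g, c): (fc, cls)
        for g, c, fc, cls in classified[["gene_id", "contrast_id", "log2fc", "node_class"]].itertuples(index=False)
    }
    out = net.copy()
    for node in out.nodes:
        for contrast in contrasts:
            fc, cls = lookup.get((node, contrast), (math.nan, "unaffected"))
            out.nodes[node][f"log2fc_{contrast}"] = float(fc)
            out.nodes[node][f"class_{contrast}"] = cls
    return out


def consistent_genes(
    table: pd.DataFrame,
    direction: str,
    scope: Iterable[str] | None = None,
    *,
    floor: float = 0.0,
) -> list[str]:
    """Genes classified `direction` in every contrast, sorted.

    A gene missing any contrast is never consistent.  `scope` optionally
    restricts the query to a node set (e.g. one sub-network).
    """
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {DIRECTIONS}, got {direction!r}")
    contrasts = _contrasts(table)
    classified = _classify_table(table, floor)
    if scope is not None:
        scope_set = {str(g) for g in scope}
        classified = classified[classified["gene_id"].isin(scope_set)]
    hits = []
    for gene, group in classified.groupby("gene_id", sort=True):
        if set(group["contrast_id"]) != set(contrasts):
            continue
        if (group["node_class"] == direction).all():
            hits.append(str(gene))
    return hits
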