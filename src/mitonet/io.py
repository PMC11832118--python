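"""File formats, configuration and pipeline orchestration.

Canonical tabular dialect: tab-separated, UTF-8, Unix newlines, header row.
Gene identifiers are opaque strings.  All writers emit deterministically
ordered output so a fixed (inputs, config, seed) reproduces every file
bit-for-bit.  Logging goes to stderr; results go to files only.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import anchors, overlay as overlay_mod, pcit, tfnet, topology as topo_mod

__all__ = [
    "read_expression",
    "write_expression",
    "read_counts",
    "read_gene_list",
    "write_gene_list",
    "read_orthologs",
    "write_orthologs",
    "read_overlay_table",
    "write_overlay_table",
    "read_edges",
    "write_edges",
    "write_sif",
    "write_graphml",
    "write_node_attributes",
    "PipelineConfig",
    "run_pipeline",
]

logger = logging.getLogger("mitonet")

NETWORK_FORMATS = ("edge-tsv", "sif", "graphml")


# ---------------------------------------------------------------------------
# tabular readers / writers
# ---------------------------------------------------------------------------

def _read_matrix(path: str | Path, *, dtype: str) -> pd.DataFrame:
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise ValueError(f"{path}: empty file")
        columns = header.split("\t")[1:]
        if not columns:
            raise ValueError(f"{path}: header has no sample columns")
        ids: list[str] = []
        rows: list[list] = []
        seen: set[str] = set()
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(columns) + 1:
                raise ValueError(
                    f"{path}: line {lineno}: expected {len(columns) + 1} fields, got {len(fields)}"
                )
            gene = fields[0]
            if gene in seen:
                raise ValueError(f"{path}: line {lineno}: duplicate gene id {gene!r}")
            seen.add(gene)
            try:
                if dtype == "int":
                    values = [int(v) for v in fields[1:]]
                else:
                    values = [float(v) for v in fields[1:]]
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from None
            if any(v < 0 for v in values):
                raise ValueError(f"{path}: line {lineno}: negative value for gene {gene!r}")
            ids.append(gene)
            rows.append(values)
    frame = pd.DataFrame(rows, index=pd.Index(ids, name="gene_id"), columns=columns)
    return frame.astype(np.int64 if dtype == "int" else np.float64)


def read_expression(path: str | Path) -> pd.DataFrame:
    """Genes x samples expression TSV (first column gene id, header row)."""
    return _read_matrix(path, dtype="float")


def read_counts(path: str | Path) -> pd.DataFrame:
    """Genes x samples integer count TSV."""
    return _read_matrix(path, dtype="int")


def _write_matrix(frame: pd.DataFrame, path: str | Path, fmt) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("gene_id\t" + "\t".join(str(c) for c in frame.columns) + "\n")
        for gene, row in zip(frame.index, frame.to_numpy()):
            fh.write(str(gene) + "\t" + "\t".join(fmt(v) for v in row) + "\n")


def write_expression(expr: pd.DataFrame, path: str | Path) -> None:
    # repr() round-trips doubles exactly through read_expression
    _write_matrix(expr, path, lambda v: repr(float(v)))


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    _write_matrix(counts, path, lambda v: str(int(v)))


def read_gene_list(path: str | Path) -> list[str]:
    """One gene id per line; blank lines ignored."""
    with open(path, encoding="utf-8") as fh:
        return [line.strip() for line in fh if line.strip()]


def write_gene_list(genes: Sequence[str], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for gene in genes:
            fh.write(f"{gene}\n")


def read_orthologs(path: str | Path) -> pd.DataFrame:
    """Two-column ortholog TSV (header row); duplicate rows are dropped."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if frame.shape[1] < 2:
        raise ValueError(f"{path}: ortholog table needs two columns, got {frame.shape[1]}")
    frame = frame.iloc[:, :2]
    frame.columns = ["source_gene_id", "target_gene_id"]
    return frame.drop_duplicates(ignore_index=True)


def write_orthologs(orthologs: pd.DataFrame, path: str | Path) -> None:
    orthologs.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_overlay_table(path: str | Path) -> pd.DataFrame:
    """Long-format overlay TSV: gene_id, contrast_id, log2fc[, is_de]."""
    frame = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "contrast_id": str})
    required = {"gene_id", "contrast_id", "log2fc"}
    if not required.issubset(frame.columns):
        raise ValueError(f"{path}: overlay table must have columns {sorted(required)}")
    if "is_de" in frame.columns:
        frame["is_de"] = frame["is_de"].astype(bool)
    dupes = frame.duplicated(subset=["gene_id", "contrast_id"])
    if dupes.any():
        raise ValueError(f"{path}: duplicate (gene, contrast) rows")
    return frame


def write_overlay_table(table: pd.DataFrame, path: str | Path) -> None:
    out = table.copy()
    if "is_de" in out.columns:
        out["is_de"] = out["is_de"].astype(int)
    out.to_csv(path, sep="\t", index=False, float_format="%.6f", lineterminator="\n")


def read_catalog(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", dtype={"gene_id": str}).set_index("gene_id")
    for flag in ("is_anchor", "is_tf", "is_organelle_encoded"):
        if flag in frame.columns:
            frame[flag] = frame[flag].astype(bool)
    return frame


def write_catalog(catalog: pd.DataFrame, path: str | Path) -> None:
    out = catalog.copy()
    for flag in ("is_anchor", "is_tf", "is_organelle_encoded"):
        if flag in out.columns:
            out[flag] = out[flag].astype(int)
    out.to_csv(path, sep="\t", index=True, lineterminator="\n")


# ---------------------------------------------------------------------------
# network writers
# ---------------------------------------------------------------------------

def read_edges(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", dtype={"gene_a": str, "gene_b": str})
    if list(frame.columns[:3]) != list(pcit.EDGE_COLUMNS):
        raise ValueError(f"{path}: expected columns {pcit.EDGE_COLUMNS}")
    return frame


def write_edges(edges: pd.DataFrame, path: str | Path) -> None:
    """Edge TSV with signed correlations to 6 decimals."""
    edges.to_csv(path, sep="\t", index=False, float_format="%.6f", lineterminator="\n")


def _canonical_graph(net: nx.Graph) -> nx.Graph:
    """Copy with sorted node/edge insertion order for byte-stable writers."""
    out = nx.Graph()
    for node in sorted(net.nodes):
        out.add_node(node, **dict(sorted(net.nodes[node].items())))
    for a, b in sorted(tuple(sorted(e)) for e in net.edges):
        out.add_edge(a, b, **dict(sorted(net.edges[a, b].items())))
    return out


def write_sif(net: nx.Graph, path: str | Path) -> None:
    """Simple interaction format: one `gene_a pp gene_b` line per edge."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in net.edges):
            fh.write(f"{a}\tpp\t{b}\n")


def write_graphml(net: nx.Graph, path: str | Path) -> None:
    """GraphML with all node attributes (NaN serialised, not dropped)."""
    canon = _canonical_graph(net)
    for node in canon.nodes:
        for key, value in list(canon.nodes[node].items()):
            if isinstance(value, float) and math.isnan(value):
                canon.nodes[node][key] = "NA"
            elif isinstance(value, (bool, np.bool_)):
                canon.nodes[node][key] = bool(value)
    nx.write_graphml(canon, str(path), named_key_ids=True)


def write_node_attributes(net: nx.Graph, path: str | Path) -> None:
    """Node attribute TSV for import into graph-visualization tools."""
    keys = sorted({k for n in net.nodes for k in net.nodes[n]})
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("gene_id\t" + "\t".join(keys) + "\n")
        for node in sorted(net.nodes):
            row = []
            for key in keys:
                value = net.nodes[node].get(key, "")
                if isinstance(value, float):
                    row.append("NA" if math.isnan(value) else f"{value:.6f}")
                elif isinstance(value, (bool, np.bool_)):
                    row.append(str(int(value)))
                else:
                    row.append(str(value))
            fh.write(str(node) + "\t" + "\t".join(row) + "\n")


def write_network(net: nx.Graph, path: str | Path, fmt: str = "edge-tsv") -> None:
    """Write the network as edge-tsv, sif, or graphml."""
    if fmt == "edge-tsv":
        rows = [
            (a, b, net.edges[a, b].get("weight", math.nan))
            for a, b in sorted(tuple(sorted(e)) for e in net.edges)
        ]
        write_edges(pd.DataFrame(rows, columns=list(pcit.EDGE_COLUMNS)), path)
    elif fmt == "sif":
        write_sif(net, path)
    elif fmt == "graphml":
        write_graphml(net, path)
    else:
        raise ValueError(f"unknown network format {fmt!r}; expected one of {NETWORK_FORMATS}")


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Full pipeline configuration; defaults follow the published protocol
    (PCIT significance, |r| >= 0.7, CPM >= 1 in at least half the samples)."""

    expression_path: str
    orthologs_path: str
    organelle_path: str
    output_dir: str
    catalog_path: str | None = None
    tf_path: str | None = None
    overlay_path: str | None = None
    counts_path: str | None = None
    cutoff: float = 0.7
    inclusive_threshold: bool = True
    keep_negative: bool = True
    min_cpm: float = 1.0
    min_cpm_fraction: float = 0.5
    classification_floor: float = 0.0
    seed: int = 1
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)


def _edge_recall(edges: pd.DataFrame, catalog: pd.DataFrame) -> dict | None:
    """Planted-module recall when block ids are available in the catalog."""
    if "block_id" not in catalog.columns:
        return None
    blocks = catalog["block_id"]
    module_blocks = sorted(b for b in blocks.unique() if str(b).startswith("module_"))
    if not module_blocks:
        return None
    edge_set = {tuple(sorted((a, b))) for a, b in zip(edges["gene_a"], edges["gene_b"])}
    within_total = within_found = 0
    for block in module_blocks:
        members = sorted(blocks.index[blocks == block])
        for i, a in enumerate(members):
            for b in members[i + 1 :]:
                within_total += 1
                if (a, b) in edge_set:
                    within_found += 1
    return {
        "within_module_pairs": within_total,
        "within_module_edges": within_found,
        "within_module_recall": round(within_found / within_total, 6) if within_total else None,
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute select-genes -> pcit -> network -> topology [-> overlay, tf].

    Writes all stage outputs plus a JSON run report into `output_dir` and
    returns the report dict.  The report echoes the configuration and the
    stage counts (genes in, anchor set, significant pairs, edges, nodes,
    components); a fixed (inputs, config, seed) reproduces every output
    byte-for-byte.
    """
    logging.basicConfig(level=config.log_level, format="%(name)s %(levelname)s %(message)s")
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": config.to_dict(), "stages": {}}

    expr = read_expression(config.expression_path)
    report["stages"]["expression"] = {"genes": int(expr.shape[0]), "samples": int(expr.shape[1])}
    logger.info("expression: %d genes x %d samples", *expr.shape)

    orthologs = read_orthologs(config.orthologs_path)
    organelle = read_gene_list(config.organelle_path)
    anchor_set, sel = anchors.build_anchor_set(orthologs, organelle, list(expr.index))
    write_gene_list(anchor_set, out / "anchor_genes.txt")
    report["stages"]["anchor_selection"] = {
        "mapped": sel.n_mapped,
        "union": sel.n_union,
        "present": sel.n_present,
    }
    logger.info("anchor selection: mapped=%d union=%d present=%d", sel.n_mapped, sel.n_union, sel.n_present)

    catalog = read_catalog(config.catalog_path) if config.catalog_path else None

    anchor_expr = expr.loc[anchor_set]
    constant = anchor_expr.index[anchor_expr.var(axis=1) == 0.0]
    if len(constant):
        logger.warning("dropping %d zero-variance gene(s)", len(constant))
        anchor_expr = anchor_expr.drop(index=constant)
    corr = pcit.correlation_matrix(anchor_expr)
    result = pcit.pcit_significance(corr)
    edges = pcit.threshold_edges(
        result,
        config.cutoff,
        inclusive=config.inclusive_threshold,
        keep_negative=config.keep_negative,
    )
    write_edges(edges, out / "edges.tsv")
    n_pairs = corr.n_genes * (corr.n_genes - 1) // 2
    report["stages"]["pcit"] = {
        "genes": corr.n_genes,
        "pairs_tested": n_pairs,
        "significant_pairs": result.n_significant_pairs,
        "edges_after_threshold": int(len(edges)),
        "cutoff": config.cutoff,
    }
    logger.info(
        "pcit: %d genes, %d/%d significant pairs, %d edges at |r|>=%.2f",
        corr.n_genes, result.n_significant_pairs, n_pairs, len(edges), config.cutoff,
    )

    net = topo_mod.build_network(edges, catalog)
    topo = topo_mod.topology_report(net)
    topo.nodes.to_csv(out / "topology.tsv", sep="\t", float_format="%.6f", lineterminator="\n")
    write_sif(net, out / "network.sif")
    write_graphml(net, out / "network.graphml")
    report["stages"]["topology"] = {
        "nodes": topo.n_nodes,
        "edges": int(len(edges)),
        "components": topo.n_components,
        "component_sizes": list(topo.component_sizes),
        "max_degree": int(topo.nodes["degree"].max()) if topo.n_nodes else 0,
    }
    if catalog is not None:
        recall = _edge_recall(edges, catalog)
        if recall is not None:
            report["stages"]["planted_recovery"] = recall
    logger.info("topology: %d nodes, %d components", topo.n_nodes, topo.n_components)

    if config.overlay_path:
        table = read_overlay_table(config.overlay_path)
        if config.counts_path:
            counts = read_counts(config.counts_path)
            kept = overlay_mod.cpm_filter(counts, config.min_cpm, config.min_cpm_fraction)
            report["stages"]["cpm_filter"] = {
                "genes_in": int(counts.shape[0]),
                "genes_kept": len(kept),
            }
            table = table[table["gene_id"].isin(set(kept))]
        overlaid = overlay_mod.attach_overlay(net, table, floor=config.classification_floor)
        write_graphml(overlaid, out / "network_overlay.graphml")
        write_node_attributes(overlaid, out / "node_attributes.tsv")
        cons_up = overlay_mod.consistent_genes(table, "up", floor=config.classification_floor)
        cons_down = overlay_mod.consistent_genes(table, "down", floor=config.classification_floor)
        write_gene_list(cons_up, out / "consistent_up.txt")
        write_gene_list(cons_down, out / "consistent_down.txt")
        report["stages"]["overlay"] = {
            "contrasts": int(table["contrast_id"].nunique()),
            "genes_in_table": int(table["gene_id"].nunique()),
            "consistent_up": len(cons_up),
            "consistent_down": len(cons_down),
        }
        logger.info("overlay: %d consistent up, %d down", len(cons_up), len(cons_down))

    if config.tf_path:
        tf_list = read_gene_list(config.tf_path)
        combined, labels = tfnet.build_tf_gene_set(anchor_set, tf_list)
        tf_expr = expr.loc[[g for g in combined if g in expr.index]]
        tf_expr = tf_expr[tf_expr.var(axis=1) > 0.0]
        tf_corr = pcit.correlation_matrix(tf_expr)
        tf_result = pcit.pcit_significance(tf_corr)
        tf_edges = pcit.threshold_edges(
            tf_result,
            config.cutoff,
            inclusive=config.inclusive_threshold,
            keep_negative=config.keep_negative,
        )
        tf_net = topo_mod.build_network(tf_edges, catalog)
        filtered, tf_report = tfnet.filter_tf_nodes(tf_net, labels)
        rankings = tfnet.rank_tf(filtered, labels)
        write_network(filtered, out / "tf_edges.tsv", "edge-tsv")
        tf_report.table.to_csv(out / "tf_filter_report.tsv", sep="\t", lineterminator="\n")
        rankings.to_csv(out / "tf_rankings.tsv", sep="\t", float_format="%.6f", lineterminator="\n")
        report["stages"]["tf_network"] = {
            "combined_genes": len(combined),
            "genes_in_expression": int(tf_expr.shape[0]),
            "edges": int(len(tf_edges)),
            "tf_nodes": int(len(tf_report.table)),
            "tf_retained": len(tf_report.retained),
            "tf_excluded": len(tf_report.excluded),
        }
        logger.info("tf network: %d retained, %d excluded", len(tf_report.retained), len(tf_report.excluded))

    with open(out / "report.json", "w", encoding="utf-8", newline="\n") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report
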