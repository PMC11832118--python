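"""Seeded synthetic data with planted, recoverable structure.

The generator emulates the regime of a large multi-tissue RNA-seq expression
atlas: an FPKM-like non-negative genes x samples matrix with

* block-correlated gene modules (compound-symmetric correlation ``rho``
  planted in log space, zero across blocks),
* one tight quasi-isolated cluster standing in for the mtDNA-encoded genes,
  correlated only among themselves (its own connected component downstream),
* independent background genes,
* standalone transcription-factor genes plus one TF planted inside each
  module (a gene that is both a TF and an anchor),
* a raw count matrix with heterogeneous library sizes and a designated set
  of low-expression genes that fail the CPM filter,
* multi-contrast log2 fold-change tables with a planted subset of
  consistently signed genes.

Expression values are drawn as a multivariate normal in log space and
exponentiated, giving skewed non-negative marginals.  All outputs are
bit-reproducible for a fixed :class:`SyntheticSpec` (the seed drives three
independent streams: expression, counts, overlay).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SyntheticSpec",
    "CountData",
    "OverlayData",
    "gene_ids",
    "generate_expression",
    "generate_counts",
    "generate_overlay",
    "LOCALIZATIONS",
    "CATALOG_COLUMNS",
]

LOCALIZATIONS = ("matrix", "inner membrane", "intermembrane space", "outer membrane", "membrane")
CATALOG_COLUMNS = ("block_id", "is_anchor", "is_tf", "is_organelle_encoded", "localization")

#: mean of log-expression; exp(3) ~ 20 FPKM-like units
_LOG_MEAN = 3.0
#: sd of log-expression; at 0.5 the exponentiation attenuates a planted
#: correlation by < 2%, so module rho stays interpretable on the FPKM scale
_LOG_SIGMA = 0.5


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the planted-structure generator.

    Defaults describe the study conditions used throughout the test suite:
    five 20-gene modules at rho 0.85, 40 independent background genes, a
    28-gene isolated cluster (13 mRNA- plus 15 tRNA-like members, mirroring
    the size of an mtDNA sub-network), 20 standalone TFs, six treatment
    contrasts, and 200 samples.
    """

    n_samples: int = 200
    modules: tuple[tuple[int, float], ...] = tuple(((20, 0.85),) * 5)
    n_background_genes: int = 40
    isolated_cluster_size: int = 28
    isolated_rho: float = 0.9
    tf_count: int = 20
    n_contrasts: int = 6
    consistent_gene_fraction: float = 0.05
    n_low_expression: int = 5
    seed: int = 1

    def __post_init__(self) -> None:
        if self.n_samples < 3:
            raise ValueError("n_samples must be >= 3 (correlation is degenerate below that)")
        for size, rho in self.modules:
            if size < 1:
                raise ValueError("module sizes must be positive")
            if not 0.0 <= rho < 1.0:
                raise ValueError(f"module rho must lie in [0, 1), got {rho}")
        if not 0.0 <= self.isolated_rho < 1.0:
            raise ValueError("isolated_rho must lie in [0, 1)")
        if min(self.n_background_genes, self.isolated_cluster_size, self.tf_count) < 0:
            raise ValueError("gene-group sizes must be non-negative")
        if self.n_contrasts < 1:
            raise ValueError("n_contrasts must be >= 1")
        if not 0.0 <= self.consistent_gene_fraction <= 1.0:
            raise ValueError("consistent_gene_fraction must lie in [0, 1]")
        if not 0 <= self.n_low_expression <= self.n_background_genes:
            raise ValueError("n_low_expression must not exceed n_background_genes")

    @property
    def n_genes(self) -> int:
        return (
            sum(size for size, _ in self.modules)
            + self.n_background_genes
            + self.isolated_cluster_size
            + self.tf_count
        )


@dataclass(frozen=True)
class CountData:
    """Integer count matrix with its planted low-expression gene set."""

    counts: pd.DataFrame
    library_sizes: pd.Series
    low_expression_genes: tuple[str, ...]


@dataclass(frozen=True)
class OverlayData:
    """Long-format log2 fold-change table with planted consistent genes."""

    table: pd.DataFrame
    consistent_up: tuple[str, ...]
    consistent_down: tuple[str, ...]


def gene_ids(spec: SyntheticSpec) -> tuple[str, ...]:
    """Deterministic gene identifiers, in generator row order."""
    ids: list[str] = []
    for m, (size, _) in enumerate(spec.modules):
        ids.extend(f"MOD{m + 1:02d}_G{j + 1:03d}" for j in range(size))
    ids.extend(f"MT_G{j + 1:03d}" for j in range(spec.isolated_cluster_size))
    ids.extend(f"BG_G{j + 1:03d}" for j in range(spec.n_background_genes))
    ids.extend(f"TF_G{j + 1:03d}" for j in range(spec.tf_count))
    return tuple(ids)


def _draw_block(rng: np.random.Generator, size: int, rho: float, n_samples: int) -> np.ndarray:
    """Compound-symmetric correlated block in log space (unit variance)."""
    shared = rng.standard_normal(n_samples)
    noise = rng.standard_normal((size, n_samples))
    return math.sqrt(rho) * shared + math.sqrt(1.0 - rho) * noise


def generate_expression(spec: SyntheticSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Expression matrix (genes x samples, non-negative) and gene catalog.

    Within-module pairwise correlation in log space equals the module's rho;
    blocks are mutually independent; the isolated cluster correlates only
    among itself.  The catalog marks block membership, anchor/TF flags, the
    organelle-encoded flag (isolated cluster), and a localization class per
    module.  The first gene of each module is additionally flagged as a TF,
    emulating TFs that are themselves anchor genes.
    """
    rng = np.random.default_rng(spec.seed)
    blocks: list[np.ndarray] = []
    for size, rho in spec.modules:
        blocks.append(_draw_block(rng, size, rho, spec.n_samples))
    if spec.isolated_cluster_size:
        blocks.append(_draw_block(rng, spec.isolated_cluster_size, spec.isolated_rho, spec.n_samples))
    if spec.n_background_genes:
        blocks.append(rng.standard_normal((spec.n_background_genes, spec.n_samples)))
    if spec.tf_count:
        blocks.append(rng.standard_normal((spec.tf_count, spec.n_samples)))
    if blocks:
        log_expr = _LOG_MEAN + _LOG_SIGMA * np.vstack(blocks)
    else:
        log_expr = np.empty((0, spec.n_samples))
    ids = gene_ids(spec)
    expr = pd.DataFrame(
        np.exp(log_expr),
        index=pd.Index(ids, name="gene_id"),
        columns=[f"S{j + 1:03d}" for j in range(spec.n_samples)],
    )

    records = []
    for m, (size, _) in enumerate(spec.modules):
        loc = LOCALIZATIONS[m % len(LOCALIZATIONS)]
        for j in range(size):
            records.append((f"module_{m + 1}", True, j == 0, False, loc))
    for _ in range(spec.isolated_cluster_size):
        records.append(("isolated", True, False, True, "inner membrane"))
    for _ in range(spec.n_background_genes):
        records.append(("background", False, False, False, "unknown"))
    for _ in range(spec.tf_count):
        records.append(("tf", False, True, False, "unknown"))
    catalog = pd.DataFrame(records, columns=list(CATALOG_COLUMNS), index=expr.index)
    return expr, catalog


def generate_counts(spec: SyntheticSpec) -> CountData:
    """Raw count matrix with heterogeneous library scales.

    The first ``n_low_expression`` background genes are planted at an
    expected depth far below 1 CPM in every sample, so they (and only they)
    fail the default CPM filter; all other genes sit comfortably above it.
    """
    rng = np.random.default_rng([1, spec.seed])
    ids = gene_ids(spec)
    n = len(ids)
    base = rng.lognormal(mean=3.0, sigma=0.8, size=n)  # nominal per-million depth
    low = tuple(f"BG_G{j + 1:03d}" for j in range(spec.n_low_expression))
    low_index = [ids.index(g) for g in low]
    base[low_index] = 0.05
    scale = rng.uniform(0.5, 2.0, size=spec.n_samples)  # relative library depth
    lam = np.outer(base, scale)
    counts = rng.poisson(lam).astype(np.int64)
    frame = pd.DataFrame(
        counts,
        index=pd.Index(ids, name="gene_id"),
        columns=[f"S{j + 1:03d}" for j in range(spec.n_samples)],
    )
    return CountData(
        counts=frame,
        library_sizes=frame.sum(axis=0),
        low_expression_genes=low,
    )


def contrast_ids(spec: SyntheticSpec) -> tuple[str, ...]:
    return tuple(f"contrast_{i + 1}" for i in range(spec.n_contrasts))


def generate_overlay(
    spec: SyntheticSpec,
    genes: Sequence[str] | None = None,
    *,
    include_de: bool = True,
) -> OverlayData:
    """Per-gene, per-contrast log2 fold changes with planted consistency.

    A seeded fraction of genes receives the same sign in every contrast
    (magnitudes 0.25-2, i.e. mostly sub-2-fold); the rest draw independent
    N(0, 1) values per contrast.  With ``include_de`` (default) a boolean
    ``is_de`` column flags every planted-gene entry and, for background
    genes, entries with |log2fc| > 1.5; without it the table is sign-only.
    """
    if genes is None:
        genes = gene_ids(spec)
    genes = list(genes)
    if not genes:
        raise ValueError("generate_overlay requires a non-empty gene list")
    rng = np.random.default_rng([2, spec.seed])
    k = spec.n_contrasts
    n = len(genes)
    n_consistent = int(round(spec.consistent_gene_fraction * n))
    chosen = rng.choice(n, size=n_consistent, replace=False)
    chosen_set = set(chosen.tolist())

    contrasts = contrast_ids(spec)
    rows: list[tuple[str, str, float, bool]] = []
    up: list[str] = []
    down: list[str] = []
    for i, gene in enumerate(genes):
        if i in chosen_set:
            sign = 1.0 if rng.random() < 0.5 else -1.0
            values = sign * rng.uniform(0.25, 2.0, size=k)
            de_flags = [True] * k
            (up if sign > 0 else down).append(gene)
        else:
            values = rng.normal(0.0, 1.0, size=k)
            de_flags = [abs(v) > 1.5 for v in values]
        for c, v, d in zip(contrasts, values, de_flags):
            rows.append((gene, c, float(v), bool(d)))
    table = pd.DataFrame(rows, columns=["gene_id", "contrast_id", "log2fc", "is_de"])
    if not include_de:
        table = table.drop(columns=["is_de"])
    return OverlayData(table=table, consistent_up=tuple(up), consistent_down=tuple(down))
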