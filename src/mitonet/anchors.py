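"""Anchor gene-set assembly.

The network is anchored on a predefined gene set: orthologs of a curated
mitoproteome catalog mapped into the target species, plus the genes encoded
on the organelle genome itself, intersected with the genes actually present
in the expression data.  Only set algebra happens here — identifier matching
is exact and case-sensitive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

__all__ = ["SelectionReport", "AnchorSelectionError", "build_anchor_set"]


@dataclass(frozen=True)
class SelectionReport:
    """Stage counts of the anchor selection.

    n_mapped: distinct ortholog target ids (many-to-one mappings collapse).
    n_union: mapped targets united with the organelle-encoded list.
    n_present: union members present in the expression data (the anchor set).
    """

    n_mapped: int
    n_union: int
    n_present: int


class AnchorSelectionError(ValueError):
    """Empty anchor set — usually an id-namespace mismatch between inputs."""

    def __init__(self, report: SelectionReport):
        self.report = report
        super().__init__(
            "anchor set is empty after intersecting with expressed genes "
            f"(mapped={report.n_mapped}, union={report.n_union}, present=0); "
            "check that ortholog targets and expression gene ids share a namespace"
        )


def _ortholog_targets(orthologs) -> set[str]:
    if isinstance(orthologs, pd.DataFrame):
        if orthologs.shape[1] < 2:
            raise ValueError("ortholog table needs at least two columns (source, target)")
        return set(orthologs.iloc[:, 1].astype(str))
    return {str(target) for _, target in orthologs}


def build_anchor_set(
    orthologs: pd.DataFrame | Iterable[tuple[str, str]],
    organelle_genes: Sequence[str],
    expressed_genes: Sequence[str],
) -> tuple[list[str], SelectionReport]:
    """Assemble the anchor gene set.

    anchor_set = (distinct ortholog targets ∪ organelle_genes) ∩ expressed_genes,
    returned sorted.  Duplicate ortholog rows never inflate the counts.

    Raises
    ------
    ValueError
        If any input is empty.
    AnchorSelectionError
        If the intersection with the expressed genes is empty; the report
        with the stage counts is attached.
    """
    targets = _ortholog_targets(orthologs)
    organelle = {str(g) for g in organelle_genes}
    expressed = {str(g) for g in expressed_genes}
    if not targets:
        raise ValueError("ortholog table is empty")
    if not organelle:
        raise ValueError("organelle-encoded gene list is empty")
    if not expressed:
        raise ValueError("expressed gene list is empty")
    union = targets | organelle
    anchor = sorted(union & expressed)
    report = SelectionReport(n_mapped=len(targets), n_union=len(union), n_present=len(anchor))
    if not anchor:
        raise AnchorSelectionError(report)
    return anchor, report
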