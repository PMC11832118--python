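"""Partial correlation and information theory (PCIT) edge inference.

PCIT decides which pairwise co-expression correlations survive as network
edges.  For every unordered trio of genes (x, y, z) it computes the three
first-order partial correlations, e.g.

    r_xy.z = (r_xy - r_xz * r_yz) / sqrt((1 - r_xz^2) * (1 - r_yz^2))

and a data-driven tolerance

    eps = (|r_xy.z / r_xy| + |r_xz.y / r_xz| + |r_yz.x / r_yz|) / 3 .

Within the trio, the pair (x, y) is flagged *eliminated* when its direct
correlation is explainable through z:

    |r_xy| <= eps * |r_xz|   and   |r_xy| <= eps * |r_yz| .

A pair is significant overall iff no trio eliminates it.  Significant pairs
are then thresholded on |r| (default 0.7) to yield the edge list.

Two implementations are provided with identical floating-point semantics:
a numba-compiled trio loop (`pcit_significance`) and a pure-Python
brute-force oracle (`pcit_brute_force`).  Their boolean masks agree
bit-for-bit; the test suite asserts this on random instances.

Numerical conventions shared by both implementations:

* a ratio whose direct correlation has magnitude < 1e-12 contributes 0 to
  eps (orthogonal pairs carry no tolerance information);
* a trio with eps == 0 eliminates nothing (a zero tolerance is vacuous);
* the three ratio terms are sorted numerically before the (a+b)+c summation
  so eps is bit-identical from every pair's perspective and under any gene
  permutation;
* gene order is canonicalised (sorted ids) before trio enumeration, making
  the result independent of input order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from numba import njit

__all__ = [
    "CorrelationMatrix",
    "PCITResult",
    "correlation_matrix",
    "partial_correlation",
    "trio_epsilon",
    "pcit_significance",
    "pcit_brute_force",
    "threshold_edges",
    "EDGE_COLUMNS",
]

#: magnitude below which a direct correlation is treated as zero when
#: forming the tolerance ratios
ZERO_GUARD = 1e-12

EDGE_COLUMNS = ("gene_a", "gene_b", "weight")


@dataclass(frozen=True)
class CorrelationMatrix:
    """Symmetric product-moment correlation matrix over an ordered gene list."""

    genes: tuple[str, ...]
    r: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.r, dtype=np.float64)
        object.__setattr__(self, "r", r)
        n = len(self.genes)
        if r.shape != (n, n):
            raise ValueError(f"correlation matrix shape {r.shape} does not match {n} genes")
        if len(set(self.genes)) != n:
            raise ValueError("duplicate gene ids in correlation matrix")
        if not np.array_equal(r, r.T):
            raise ValueError("correlation matrix is not symmetric")
        if np.any(np.abs(r) > 1.0):
            raise ValueError("correlation coefficients must lie in [-1, 1]")
        if not np.all(np.diag(r) == 1.0):
            raise ValueError("correlation matrix diagonal must be exactly 1")

    @property
    def n_genes(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class PCITResult:
    """Correlation matrix plus the symmetric PCIT significance mask."""

    correlation: CorrelationMatrix
    significant: np.ndarray

    def __post_init__(self) -> None:
        mask = np.asarray(self.significant, dtype=bool)
        object.__setattr__(self, "significant", mask)
        n = self.correlation.n_genes
        if mask.shape != (n, n):
            raise ValueError("significance mask shape does not match correlation matrix")
        if not np.array_equal(mask, mask.T):
            raise ValueError("significance mask is not symmetric")
        if np.any(np.diag(mask)):
            raise ValueError("significance mask diagonal must be False")

    @property
    def n_significant_pairs(self) -> int:
        return int(self.significant.sum()) // 2


def correlation_matrix(expr: pd.DataFrame) -> CorrelationMatrix:
    """Pairwise product-moment correlation across samples for every gene pair.

    Parameters
    ----------
    expr
        Genes x samples expression matrix (gene ids in the index).

    Raises
    ------
    ValueError
        If fewer than 3 samples are present, or any gene has zero variance
        across samples (a constant transcript; the caller should drop it).
    """
    if expr.shape[1] < 3:
        raise ValueError(f"correlation requires at least 3 samples, got {expr.shape[1]}")
    values = expr.to_numpy(dtype=np.float64)
    variances = values.var(axis=1)
    flat = np.flatnonzero(variances == 0.0)
    if flat.size:
        names = ", ".join(str(expr.index[i]) for i in flat[:5])
        raise ValueError(f"zero-variance gene(s) cannot be correlated: {names}")
    r = np.corrcoef(values)
    r = (r + r.T) / 2.0  # BLAS matrix products are not exactly symmetric
    np.clip(r, -1.0, 1.0, out=r)
    np.fill_diagonal(r, 1.0)
    return CorrelationMatrix(tuple(str(g) for g in expr.index), r)


def partial_correlation(r_xy: float, r_xz: float, r_yz: float) -> float:
    """First-order partial correlation of (x, y) given z."""
    denom = math.sqrt((1.0 - r_xz * r_xz) * (1.0 - r_yz * r_yz))
    if denom == 0.0:
        raise ValueError("partial correlation undefined: a conditioning correlation is +/-1")
    return (r_xy - r_xz * r_yz) / denom


def trio_epsilon(r_xy: float, r_xz: float, r_yz: float) -> float:
    """PCIT tolerance for the trio with the three given direct correlations.

    Mean of the three |partial/direct| ratios; a ratio whose direct
    correlation has magnitude below ``ZERO_GUARD`` contributes 0.
    """
    p_xy = partial_correlation(r_xy, r_xz, r_yz)
    p_xz = partial_correlation(r_xz, r_xy, r_yz)
    p_yz = partial_correlation(r_yz, r_xy, r_xz)
    t1 = abs(p_xy) / abs(r_xy) if abs(r_xy) >= ZERO_GUARD else 0.0
    t2 = abs(p_xz) / abs(r_xz) if abs(r_xz) >= ZERO_GUARD else 0.0
    t3 = abs(p_yz) / abs(r_yz) if abs(r_yz) >= ZERO_GUARD else 0.0
    lo, mid, hi = sorted((t1, t2, t3))
    return ((lo + mid) + hi) / 3.0


@njit(cache=True)
def _eliminate_kernel(R: np.ndarray) -> np.ndarray:  # pragma: no cover - compiled
    n = R.shape[0]
    elim = np.zeros((n, n), np.bool_)
    for x in range(n - 2):
        for y in range(x + 1, n - 1):
            rxy = R[x, y]
            dxy = 1.0 - rxy * rxy
            for z in range(y + 1, n):
                rxz = R[x, z]
                ryz = R[y, z]
                dxz = 1.0 - rxz * rxz
                dyz = 1.0 - ryz * ryz
                pxy = (rxy - rxz * ryz) / math.sqrt(dxz * dyz)
                pxz = (rxz - rxy * ryz) / math.sqrt(dxy * dyz)
                pyz = (ryz - rxy * rxz) / math.sqrt(dxy * dxz)
                axy = abs(rxy)
                axz = abs(rxz)
                ayz = abs(ryz)
                t1 = abs(pxy) / axy if axy >= 1e-12 else 0.0
                t2 = abs(pxz) / axz if axz >= 1e-12 else 0.0
                t3 = abs(pyz) / ayz if ayz >= 1e-12 else 0.0
                if t1 > t2:
                    t1, t2 = t2, t1
                if t2 > t3:
                    t2, t3 = t3, t2
                if t1 > t2:
                    t1, t2 = t2, t1
                eps = ((t1 + t2) + t3) / 3.0
                if eps > 0.0:
                    if axy <= eps * axz and axy <= eps * ayz:
                        elim[x, y] = True
                        elim[y, x] = True
                    if axz <= eps * axy and axz <= eps * ayz:
                        elim[x, z] = True
                        elim[z, x] = True
                    if ayz <= eps * axy and ayz <= eps * axz:
                        elim[y, z] = True
                        elim[z, y] = True
    return elim


def _eliminate_bruteforce(R: np.ndarray) -> np.ndarray:
    """Reference oracle: explicit Python trio loops, no algebraic shortcuts."""
    n = R.shape[0]
    elim = np.zeros((n, n), dtype=bool)
    rows = R.tolist()
    for x in range(n - 2):
        for y in range(x + 1, n - 1):
            rxy = rows[x][y]
            dxy = 1.0 - rxy * rxy
            for z in range(y + 1, n):
                rxz = rows[x][z]
                ryz = rows[y][z]
                dxz = 1.0 - rxz * rxz
                dyz = 1.0 - ryz * ryz
                pxy = (rxy - rxz * ryz) / math.sqrt(dxz * dyz)
                pxz = (rxz - rxy * ryz) / math.sqrt(dxy * dyz)
                pyz = (ryz - rxy * rxz) / math.sqrt(dxy * dxz)
                axy = abs(rxy)
                axz = abs(rxz)
                ayz = abs(ryz)
                t1 = abs(pxy) / axy if axy >= ZERO_GUARD else 0.0
                t2 = abs(pxz) / axz if axz >= ZERO_GUARD else 0.0
                t3 = abs(pyz) / ayz if ayz >= ZERO_GUARD else 0.0
                if t1 > t2:
                    t1, t2 = t2, t1
                if t2 > t3:
                    t2, t3 = t3, t2
                if t1 > t2:
                    t1, t2 = t2, t1
                eps = ((t1 + t2) + t3) / 3.0
                if eps > 0.0:
                    if axy <= eps * axz and axy <= eps * ayz:
                        elim[x, y] = elim[y, x] = True
                    if axz <= eps * axy and axz <= eps * ayz:
                        elim[x, z] = elim[z, x] = True
                    if ayz <= eps * axy and ayz <= eps * axz:
                        elim[y, z] = elim[z, y] = True
    return elim


def _prepare(corr: CorrelationMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Canonicalise gene order and validate the off-diagonal magnitudes."""
    n = corr.n_genes
    if n < 2:
        raise ValueError("PCIT requires at least 2 genes")
    off = np.abs(corr.r[~np.eye(n, dtype=bool)])
    if off.size and np.any(off == 1.0):
        raise ValueError(
            "off-diagonal correlation of magnitude 1: perfectly collinear genes "
            "must be deduplicated before PCIT"
        )
    order = np.argsort(np.asarray(corr.genes))
    return order, corr.r[np.ix_(order, order)]


def _finish(corr: CorrelationMatrix, order: np.ndarray, elim_sorted: np.ndarray) -> PCITResult:
    n = corr.n_genes
    inverse = np.empty(n, dtype=np.intp)
    inverse[order] = np.arange(n)
    elim = elim_sorted[np.ix_(inverse, inverse)]
    significant = ~elim & ~np.eye(n, dtype=bool)
    return PCITResult(correlation=corr, significant=significant)


def pcit_significance(corr: CorrelationMatrix) -> PCITResult:
    """PCIT trio-elimination significance mask (compiled implementation).

    A pair is significant iff no trio eliminates it.  With 2 genes no trio
    exists, so the single pair is vacuously significant.
    """
    order, R = _prepare(corr)
    return _finish(corr, order, _eliminate_kernel(np.ascontiguousarray(R)))


def pcit_brute_force(corr: CorrelationMatrix) -> PCITResult:
    """Brute-force PCIT oracle; identical contract to :func:`pcit_significance`."""
    order, R = _prepare(corr)
    return _finish(corr, order, _eliminate_bruteforce(R))


def threshold_edges(
    result: PCITResult,
    cutoff: float = 0.7,
    *,
    inclusive: bool = True,
    keep_negative: bool = True,
) -> pd.DataFrame:
    """Edge list of significant pairs with correlation magnitude past `cutoff`.

    Returns a DataFrame with columns (gene_a, gene_b, weight), gene_a < gene_b
    lexicographically, sorted by (gene_a, gene_b).  `inclusive` selects
    |r| >= cutoff (default) versus strict |r| > cutoff; `keep_negative=False`
    additionally drops negative correlations.
    """
    if not 0.0 < cutoff < 1.0:
        raise ValueError(f"cutoff must lie strictly between 0 and 1, got {cutoff}")
    r = result.correlation.r
    genes = result.correlation.genes
    strong = np.abs(r) >= cutoff if inclusive else np.abs(r) > cutoff
    mask = result.significant & strong
    if not keep_negative:
        mask &= r > 0
    ii, jj = np.nonzero(np.triu(mask, k=1))
    records = []
    for i, j in zip(ii.tolist(), jj.tolist()):
        a, b = genes[i], genes[j]
        if b < a:
            a, b = b, a
        records.append((a, b, r[i, j]))
    records.sort(key=lambda rec: (rec[0], rec[1]))
    return pd.DataFrame(records, columns=list(EDGE_COLUMNS))
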