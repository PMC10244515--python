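"""Functional connectivity network construction.

A subject's ROI x ROI Pearson correlation matrix is turned into a stack of
unweighted, undirected, *connected* graphs across a grid of edge densities.
Connectivity is guaranteed by seeding every network with the maximum spanning
tree (MST) of the correlation matrix; the remaining edges are added in
decreasing order of signed correlation until the target edge count for the
density is reached, and weights are then discarded (binarization).

Because the edge ordering is fixed per subject, the networks in a stack are
nested: every edge present at density d is present at every density > d.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterable, Sequence

import numpy as np
import networkx as nx
from scipy.cluster.hierarchy import DisjointSet

logger = logging.getLogger(__name__)

#: absolute tolerance under which an asymmetric input is silently symmetrized
SYMMETRY_TOL = 1e-8
#: absolute tolerance under which an off-unit diagonal is normalized to 1
DIAGONAL_TOL = 1e-3


@dataclass(frozen=True)
class FCMatrix:
    """One subject's symmetric ROI x ROI Pearson correlation matrix.

    Parameters
    ----------
    subject_id : str
        Cohort-unique subject identifier.
    group : str
        Group label, conventionally ``"young"`` or ``"old"``.
    values : ndarray of shape (n, n)
        Symmetric correlation matrix with unit diagonal, entries in [-1, 1].
    roi_ids : tuple of str
        Ordered ROI identifiers matching the matrix rows.
    """

    subject_id: str
    group: str
    values: np.ndarray
    roi_ids: tuple

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("FC matrix must be square")
        n = v.shape[0]
        if n < 3:
            raise ValueError("FC matrix needs at least 3 ROIs")
        if len(self.roi_ids) != n:
            raise ValueError("roi_ids length does not match matrix size")
        if not np.all(np.isfinite(v)):
            raise ValueError("FC matrix contains non-finite entries")
        asym = np.abs(v - v.T).max()
        if asym > SYMMETRY_TOL:
            raise ValueError(
                f"FC matrix asymmetry {asym:.3g} exceeds tolerance {SYMMETRY_TOL:g}"
            )
        v = (v + v.T) / 2.0
        dmax = np.abs(np.diag(v) - 1.0).max()
        if dmax > DIAGONAL_TOL:
            raise ValueError(
                f"FC matrix diagonal deviates from 1 by {dmax:.3g}"
            )
        if dmax > 0:
            logger.info(
                "subject %s: diagonal off unity by %.3g, normalized to 1",
                self.subject_id, dmax,
            )
        np.fill_diagonal(v, 1.0)
        if np.abs(v).max() > 1 + 1e-9:
            raise ValueError("correlation entries outside [-1, 1]")
        v.flags.writeable = False
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "roi_ids", tuple(self.roi_ids))

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class DensityGrid:
    """Strictly increasing edge-density fractions in (0, 1]."""

    densities: tuple

    def __post_init__(self):
        d = tuple(float(x) for x in self.densities)
        if len(d) == 0:
            raise ValueError("density grid is empty")
        if any(not (0 < x <= 1) for x in d):
            raise ValueError("densities must lie in (0, 1]")
        if any(b <= a for a, b in zip(d, d[1:])):
            raise ValueError("densities must be strictly increasing")
        object.__setattr__(self, "densities", d)

    @classmethod
    def default(cls) -> "DensityGrid":
        """The standard 2%-50% grid in 1% steps (49 densities)."""
        return cls(tuple(round(0.02 + 0.01 * k, 2) for k in range(49)))

    @classmethod
    def from_spec(cls, lo: float, hi: float, step: float) -> "DensityGrid":
        k = int(round((hi - lo) / step)) + 1
        return cls(tuple(round(lo + step * i, 10) for i in range(k)))

    def __len__(self) -> int:
        return len(self.densities)

    def __iter__(self):
        return iter(self.densities)

    @property
    def span(self) -> float:
        return self.densities[-1] - self.densities[0]


@dataclass(frozen=True)
class FCN:
    """An unweighted, undirected, connected network at a stated edge density.

    Edges are stored as 0-based index pairs ``(i, j)`` with ``i < j`` into
    ``roi_ids``.
    """

    roi_ids: tuple
    edges: tuple
    density: float
    subject_id: str = ""

    @property
    def n(self) -> int:
        return len(self.roi_ids)

    @cached_property
    def adjacency(self) -> np.ndarray:
        a = np.zeros((self.n, self.n), dtype=bool)
        for i, j in self.edges:
            a[i, j] = a[j, i] = True
        a.flags.writeable = False
        return a

    @cached_property
    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=0).astype(int)

    @cached_property
    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n))
        g.add_edges_from(self.edges)
        return g

    def triangle_counts(self) -> np.ndarray:
        """tri(e) for every edge, as common-neighbor counts (same edge order)."""
        a = self.adjacency.astype(np.int32)
        paths2 = a @ a
        return np.array([paths2[i, j] for i, j in self.edges], dtype=int)

    def is_connected(self) -> bool:
        return nx.is_connected(self.graph)


def _ordered_pairs(values: np.ndarray):
    """All i<j pairs sorted by (-weight, i, j): the deterministic edge order."""
    n = values.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    w = values[iu, ju]
    order = np.lexsort((ju, iu, -w))
    return list(zip(iu[order].tolist(), ju[order].tolist())), w[order]


def maximum_spanning_tree(fc: FCMatrix) -> list:
    """Kruskal maximum spanning tree of the correlation matrix.

    Ties between equal correlations are broken deterministically by
    (smaller index, larger index), so the result is bit-reproducible.

    Returns the n-1 tree edges as sorted (i, j) index pairs.
    """
    pairs, _ = _ordered_pairs(fc.values)
    ds = DisjointSet(range(fc.n))
    tree = []
    for i, j in pairs:
        if ds.merge(i, j):
            tree.append((i, j))
            if len(tree) == fc.n - 1:
                break
    return tree


def target_edge_count(n: int, density: float) -> int:
    """Edge count realizing a density: round(density * E_max) half away from
    zero, floored at the MST size n-1 and capped at E_max = n(n-1)/2."""
    if not 0 < density <= 1:
        raise ValueError("density must lie in (0, 1]")
    e_max = n * (n - 1) // 2
    k = math.floor(density * e_max + 0.5)
    return min(e_max, max(n - 1, k))


def construct_fcn(fc: FCMatrix, density: float) -> FCN:
    """Build one binarized network: MST plus the highest-correlation non-tree
    pairs (signed ordering) until the target edge count is reached."""
    return construct_fcn_stack(fc, DensityGrid((density,)))[0]


def construct_fcn_stack(fc: FCMatrix, grid: DensityGrid) -> list:
    """One FCN per grid density, with nested edge sets across densities."""
    mst = maximum_spanning_tree(fc)
    mst_set = set(mst)
    pairs, weights = _ordered_pairs(fc.values)
    extra = [(p, w) for p, w in zip(pairs, weights) if p not in mst_set]

    stack = []
    for density in grid:
        k = target_edge_count(fc.n, density)
        n_extra = k - (fc.n - 1)
        chosen = extra[:n_extra]
        neg = sum(1 for _, w in chosen if w <= 0)
        if neg:
            logger.warning(
                "subject %s density %.2f: %d added edge(s) with correlation <= 0",
                fc.subject_id, density, neg,
            )
        edges = tuple(sorted(mst + [p for p, _ in chosen]))
        fcn = FCN(roi_ids=fc.roi_ids, edges=edges, density=density,
                  subject_id=fc.subject_id)
        assert fcn.is_connected(), "constructed FCN must be connected"
        stack.append(fcn)
    return stack
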