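"""Discrete Ricci curvatures on unweighted graphs.

Two non-equivalent discretizations of Ricci curvature are computed per edge:

* **Forman-Ricci curvature (FRC)**, in its augmented form that counts
  triangles (3-cycles) as 2-cells of a CW complex. On an unweighted graph it
  reduces to the combinatorial expression

      F(e) = 4 - deg(i) - deg(j) + 3 * tri(e)

  where tri(e) is the number of triangles containing edge e = (i, j). The
  general weighted form (vertex, edge and triangle weights) is implemented as
  well; at unit weights it coincides with the combinatorial formula.

* **Ollivier-Ricci curvature (ORC)**,

      O(e) = 1 - W1(m_i, m_j) / d(i, j)

  where m_i is the uniform probability measure on the neighbors of i (zero
  mass on i itself by default), d is the hop distance on the full graph, and
  W1 is the Wasserstein-1 (earth mover's) distance, solved as an exact
  transportation linear program.

Node (scalar) curvature is the sum of the curvatures of the incident edges.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import networkx as nx
from scipy.optimize import linprog
from scipy.sparse import csr_matrix

from .construct import FCN

#: decimal places to which transport optima are rounded (cross-platform floats)
_ROUND = 12


# ---------------------------------------------------------------------------
# Forman-Ricci curvature
# ---------------------------------------------------------------------------

def edge_frc_combinatorial(fcn: FCN, edge) -> int:
    """Augmented FRC of one edge of an unweighted graph:
    4 - deg(i) - deg(j) + 3*tri(e)."""
    i, j = edge
    a = fcn.adjacency
    if not a[i, j]:
        raise ValueError(f"edge {edge} not in graph")
    tri = int(np.count_nonzero(a[i] & a[j]))
    return 4 - int(fcn.degrees[i]) - int(fcn.degrees[j]) + 3 * tri


@dataclass(frozen=True)
class ComplexWeights:
    """Positive weights on the cells (vertices, edges, triangles) of a graph
    viewed as a 2-dimensional CW complex.

    ``w_f`` is keyed by sorted vertex triples; every key must be a 3-clique.
    """

    w_v: Mapping
    w_e: Mapping
    w_f: Mapping

    @classmethod
    def unit(cls, fcn: FCN) -> "ComplexWeights":
        """All cells weighted 1 (the unweighted case)."""
        return cls(
            w_v={v: 1.0 for v in range(fcn.n)},
            w_e={e: 1.0 for e in fcn.edges},
            w_f={t: 1.0 for t in enumerate_triangles(fcn)},
        )


def enumerate_triangles(fcn: FCN) -> list:
    """All 3-cliques as sorted vertex triples (each 2-cell keyed once)."""
    a = fcn.adjacency
    out = []
    for i, j in fcn.edges:
        for k in np.nonzero(a[i] & a[j])[0]:
            if k > j:
                out.append((i, j, int(k)))
    return out


def edge_frc_weighted(fcn: FCN, weights: ComplexWeights, edge) -> float:
    """General augmented FRC with vertex/edge/triangle weights.

    Two edges are *parallel* iff they share a vertex or a triangle but not
    both; each parallel edge contributes an absolute-value penalty term.
    """
    i, j = edge = tuple(sorted(edge))
    a = fcn.adjacency
    if not a[i, j]:
        raise ValueError(f"edge {edge} not in graph")
    try:
        we = weights.w_e[edge]
        wvi, wvj = weights.w_v[i], weights.w_v[j]
    except KeyError as err:
        raise KeyError(f"missing weight for cell {err}") from None

    common = np.nonzero(a[i] & a[j])[0]
    tris_e = [tuple(sorted((i, j, int(k)))) for k in common]
    for t in tris_e:
        if t not in weights.w_f:
            raise KeyError(f"missing weight for triangle {t}")

    direct = sum(we / weights.w_f[t] for t in tris_e) + (wvi + wvj) / we

    # candidate parallel edges: those sharing >=1 vertex with e (in a simple
    # graph no two edges share a triangle without sharing a vertex)
    penalty = 0.0
    for v, other in ((i, j), (j, i)):
        for u in np.nonzero(a[v])[0]:
            u = int(u)
            if u == other:
                continue
            eh = tuple(sorted((v, u)))
            shared_tris = [t for t in tris_e if v in t and u in t]
            # shares vertex v; parallel iff no shared triangle
            if shared_tris:
                continue
            weh = weights.w_e[eh]
            penalty += abs(0.0 - weights.w_v[v] / math.sqrt(we * weh))
    # edges sharing a triangle with e: each triangle's two other sides share a
    # vertex with e as well, hence are NOT parallel; nothing to add.
    return we * (direct - penalty)


# ---------------------------------------------------------------------------
# Ollivier-Ricci curvature
# ---------------------------------------------------------------------------

def hop_distances(fcn: FCN, sources, targets) -> np.ndarray:
    """Hop-count distances on the full graph from each source to each target
    (breadth-first search per source)."""
    g = fcn.graph
    targets = list(targets)
    out = np.empty((len(list(sources)), len(targets)))
    for r, s in enumerate(sources):
        lengths = nx.single_source_shortest_path_length(g, s)
        for c, t in enumerate(targets):
            if t not in lengths:
                raise ValueError("graph is disconnected")
            out[r, c] = lengths[t]
    return out


@dataclass(frozen=True)
class TransportProblem:
    """A discrete optimal-transport instance: two probability measures and the
    pairwise ground distances between their supports."""

    m_i: np.ndarray
    m_j: np.ndarray
    dists: np.ndarray

    def __post_init__(self):
        mi = np.asarray(self.m_i, float)
        mj = np.asarray(self.m_j, float)
        d = np.asarray(self.dists, float)
        if abs(mi.sum() - 1) > 1e-9 or abs(mj.sum() - 1) > 1e-9:
            raise ValueError("measures must each sum to 1")
        if np.any(mi < 0) or np.any(mj < 0):
            raise ValueError("measures must be nonnegative")
        if d.shape != (mi.size, mj.size):
            raise ValueError("distance matrix shape mismatch")
        if not np.all(np.isfinite(d)):
            raise ValueError("non-finite transport distances")
        object.__setattr__(self, "m_i", mi)
        object.__setattr__(self, "m_j", mj)
        object.__setattr__(self, "dists", d)


def wasserstein1(problem: TransportProblem, return_plan: bool = False):
    """Exact Wasserstein-1 distance: the optimum of the transportation LP

        min sum d(i', j') mu(i', j')
        s.t. row sums of mu = m_i, column sums = m_j, mu >= 0.

    Solved with the HiGHS simplex backend; the optimum is rounded to 12
    decimals for cross-platform stability.
    """
    mi, mj, d = problem.m_i, problem.m_j, problem.dists
    a, b = mi.size, mj.size
    if a == 1:
        val = round(float(d[0] @ mj), _ROUND)
        return (val, mj.reshape(1, -1).copy()) if return_plan else val
    if b == 1:
        val = round(float(mi @ d[:, 0]), _ROUND)
        return (val, mi.reshape(-1, 1).copy()) if return_plan else val

    # equality constraints: a row-sum rows + b column-sum rows (one redundant)
    rows, cols, vals = [], [], []
    for i in range(a):
        rows.extend([i] * b)
        cols.extend(range(i * b, (i + 1) * b))
        vals.extend([1.0] * b)
    for j in range(b - 1):  # drop last redundant column constraint
        rows.extend([a + j] * a)
        cols.extend(range(j, a * b, b))
        vals.extend([1.0] * a)
    a_eq = csr_matrix((vals, (rows, cols)), shape=(a + b - 1, a * b))
    b_eq = np.concatenate([mi, mj[:-1]])
    res = linprog(d.ravel(), A_eq=a_eq, b_eq=b_eq, bounds=(0, None),
                  method="highs")
    if res.status != 0:
        raise RuntimeError(f"transport LP failed: {res.message}")
    val = round(float(res.fun), _ROUND)
    if return_plan:
        return val, res.x.reshape(a, b)
    return val


def edge_orc(fcn: FCN, edge, idleness: float = 0.0) -> float:
    """Ollivier-Ricci curvature O(e) = 1 - W1(m_i, m_j)/d(i, j) of one edge.

    m_i is uniform over the neighbors of i; with ``idleness`` alpha > 0, mass
    alpha stays on i and (1-alpha) spreads uniformly over the neighbors
    (default 0: pure neighbor measure). For an edge d(i, j) = 1.
    """
    i, j = edge
    a = fcn.adjacency
    if not a[i, j]:
        raise ValueError(f"edge {edge} not in graph")
    if not 0 <= idleness < 1:
        raise ValueError("idleness must lie in [0, 1)")
    supp_i = [int(v) for v in np.nonzero(a[i])[0]]
    supp_j = [int(v) for v in np.nonzero(a[j])[0]]
    m_i = np.full(len(supp_i), (1 - idleness) / len(supp_i))
    m_j = np.full(len(supp_j), (1 - idleness) / len(supp_j))
    if idleness > 0:
        supp_i.append(i)
        supp_j.append(j)
        m_i = np.append(m_i, idleness)
        m_j = np.append(m_j, idleness)
    d = hop_distances(fcn, supp_i, supp_j)
    w1 = wasserstein1(TransportProblem(m_i, m_j, d))
    return round(1.0 - w1, _ROUND)


# ---------------------------------------------------------------------------
# Per-network aggregation
# ---------------------------------------------------------------------------

METHODS = ("frc", "orc")


@dataclass(frozen=True)
class EdgeCurvatures:
    """Curvature of every edge of one FCN for one method."""

    method: str
    values: Mapping
    density: float
    subject_id: str = ""


@dataclass(frozen=True)
class NodeCurvatures:
    """Scalar (node) curvature of every node of one FCN for one method."""

    method: str
    values: Mapping
    density: float
    subject_id: str = ""


def all_edge_curvatures(fcn: FCN, method: str, idleness: float = 0.0
                        ) -> EdgeCurvatures:
    """Curvature of every edge. FRC is evaluated vectorized over the adjacency
    matrix; ORC solves one transport LP per edge."""
    method = method.lower()
    if method == "frc":
        deg = fcn.degrees
        tri = fcn.triangle_counts()
        vals = {
            e: int(4 - deg[e[0]] - deg[e[1]] + 3 * t)
            for e, t in zip(fcn.edges, tri)
        }
    elif method == "orc":
        vals = {e: edge_orc(fcn, e, idleness=idleness) for e in fcn.edges}
    else:
        raise ValueError(f"unknown curvature method {method!r}")
    return EdgeCurvatures(method=method, values=vals, density=fcn.density,
                          subject_id=fcn.subject_id)


def node_curvatures(ec: EdgeCurvatures, fcn: FCN) -> NodeCurvatures:
    """Node curvature: sum of curvatures of the edges incident on each node."""
    if set(ec.values) != set(fcn.edges):
        raise ValueError("edge curvatures do not cover the FCN edge set")
    acc = dict.fromkeys(range(fcn.n), 0.0)
    for (i, j), c in ec.values.items():
        acc[i] += c
        acc[j] += c
    return NodeCurvatures(method=ec.method, values=acc, density=ec.density,
                          subject_id=ec.subject_id)


def average_edge_curvature(ec: EdgeCurvatures) -> float:
    """Arithmetic mean of the per-edge curvatures (whole-brain summary)."""
    if not ec.values:
        raise ValueError("no edge curvatures to average")
    return float(np.mean(list(ec.values.values())))
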