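"""Standard global network measures used alongside the curvature summaries.

Eight measures per network: clique number (exact), average clustering
coefficient, global efficiency, average (normalized) node betweenness,
average local efficiency, average shortest path length, Louvain modularity,
and degree assortativity. Definitions follow the standard forms implemented
in networkx; the clique number uses an in-package Tomita-style
branch-and-bound with greedy-coloring bound and a wall-clock budget
(exceeding the budget raises instead of returning an approximation).
"""

from __future__ import annotations

import time
from dataclasses import dataclass
from typing import Optional

import numpy as np
import networkx as nx

from .construct import FCN


class CliqueBudgetExceeded(RuntimeError):
    """Raised when the exact maximum-clique search exceeds its time budget."""


def clique_number(fcn: FCN, time_budget: float = 60.0) -> int:
    """Exact maximum clique size by branch and bound with a greedy-coloring
    upper bound. Deterministic (vertices expanded in degeneracy-ish order)."""
    adj = {v: set(np.nonzero(fcn.adjacency[v])[0].tolist())
           for v in range(fcn.n)}
    deadline = time.monotonic() + time_budget
    best = [1]

    def color_sort(cand):
        # greedy coloring: returns candidates with color-number upper bounds
        order, bounds = [], []
        color_classes = []
        for v in sorted(cand, key=lambda u: -len(adj[u] & cand)):
            for ci, cl in enumerate(color_classes):
                if not (adj[v] & cl):
                    cl.add(v)
                    break
            else:
                color_classes.append({v})
        for ci, cl in enumerate(color_classes):
            for v in sorted(cl):
                order.append(v)
                bounds.append(ci + 1)
        return order, bounds

    def expand(clique_size, cand):
        if time.monotonic() > deadline:
            raise CliqueBudgetExceeded(
                f"maximum-clique search exceeded {time_budget:g}s budget")
        order, bounds = color_sort(cand)
        for idx in range(len(order) - 1, -1, -1):
            if clique_size + bounds[idx] <= best[0]:
                return
            v = order[idx]
            new_cand = cand & adj[v]
            if not new_cand:
                best[0] = max(best[0], clique_size + 1)
            else:
                expand(clique_size + 1, new_cand)
            cand = cand - {v}

    expand(0, set(range(fcn.n)))
    return best[0]


@dataclass(frozen=True)
class GlobalMeasureRecord:
    """The eight non-curvature global measures of one FCN."""

    subject_id: str
    density: float
    clique_number: int
    avg_clustering: float
    global_efficiency: float
    avg_betweenness: float
    avg_local_efficiency: float
    avg_shortest_path: float
    modularity: float
    assortativity: Optional[float]   # None when degree variance is zero

    MEASURES = (
        "clique_number", "avg_clustering", "global_efficiency",
        "avg_betweenness", "avg_local_efficiency", "avg_shortest_path",
        "modularity", "assortativity",
    )


def global_measures(fcn: FCN, seed: int = 0,
                    clique_budget: float = 60.0) -> GlobalMeasureRecord:
    """All eight global measures of a connected FCN.

    Louvain community detection is the only seeded step; its partition and
    the reported Newman-Girvan Q are mutually consistent by construction.
    Assortativity is flagged None (undefined) on regular graphs.
    """
    g = fcn.graph
    if not nx.is_connected(g):
        raise ValueError("global measures require a connected network")
    deg = fcn.degrees
    bc = nx.betweenness_centrality(g, normalized=True)
    communities = nx.community.louvain_communities(g, seed=seed, resolution=1)
    q = nx.community.modularity(g, communities)
    assort = None
    if deg.std() > 0:
        assort = float(nx.degree_assortativity_coefficient(g))
    return GlobalMeasureRecord(
        subject_id=fcn.subject_id,
        density=fcn.density,
        clique_number=clique_number(fcn, time_budget=clique_budget),
        avg_clustering=float(nx.average_clustering(g)),
        global_efficiency=float(nx.global_efficiency(g)),
        avg_betweenness=float(np.mean(list(bc.values()))),
        avg_local_efficiency=float(nx.local_efficiency(g)),
        avg_shortest_path=float(nx.average_shortest_path_length(g)),
        modularity=float(q),
        assortativity=assort,
    )
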