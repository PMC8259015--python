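"""Candidate partitions of a weighted integration graph.

Two complementary graph clustering algorithms produce the candidate consensus
partitions at each support threshold: Louvain community detection (LCD), which
optimizes weighted modularity and tends toward larger communities, and Markov
clustering (MCL), which simulates stochastic flow and tends toward smaller,
tighter clusters.  Both are unsupervised and need no preset cluster count.

Isolated nodes carry no co-clustering evidence at the current threshold and
are excluded from candidate partitions; they join the filtered-out pool and
may be reassigned after consensus selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import networkx as nx
import numpy as np
from networkx.algorithms.community import louvain_communities

from .graph import IntegrationGraph

__all__ = ["CandidatePartition", "lcd_cluster", "mcl_cluster", "MCLConvergenceError"]

Algorithm = Literal["LCD", "MCL"]


class MCLConvergenceError(RuntimeError):
    """Raised when the Markov flow matrix fails to converge."""


@dataclass
class CandidatePartition:
    """A hard partition of the non-isolated nodes of one filtered graph."""

    assignment: dict[str, str]
    algorithm: Algorithm
    threshold: int = 0
    params: dict = field(default_factory=dict)

    @property
    def n_clusters(self) -> int:
        return len(set(self.assignment.values()))

    @property
    def n_nodes(self) -> int:
        return len(self.assignment)

    def clusters(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for s, lab in self.assignment.items():
            out.setdefault(lab, []).append(s)
        for v in out.values():
            v.sort()
        return out


def _clustered_subgraph(ig: IntegrationGraph) -> nx.Graph:
    g = ig.graph
    non_isolated = [n for n in g.nodes if g.degree(n) > 0]
    if not non_isolated:
        raise ValueError("no structure to cluster: the graph has no edge")
    return g.subgraph(non_isolated)


def _label_communities(communities: list[set[str]]) -> dict[str, str]:
    # deterministic labels: clusters ordered by their smallest member
    ordered = sorted(communities, key=min)
    return {s: str(i + 1) for i, comm in enumerate(ordered) for s in comm}


def lcd_cluster(
    ig: IntegrationGraph, seed: int, resolution: float = 1.0
) -> CandidatePartition:
    """Louvain community detection on the support-weighted graph.

    Deterministic for a fixed seed.  Only nodes with at least one incident
    edge are partitioned.
    """
    sub = _clustered_subgraph(ig)
    comms = louvain_communities(
        sub, weight="supports", resolution=resolution, seed=int(seed)
    )
    return CandidatePartition(
        assignment=_label_communities([set(c) for c in comms]),
        algorithm="LCD",
        params={"seed": int(seed), "resolution": resolution},
    )


def mcl_cluster(
    ig: IntegrationGraph,
    inflation: float = 2.0,
    expansion: int = 2,
    prune_threshold: float = 1e-5,
    max_iter: int = 100,
    convergence_tol: float = 1e-8,
    self_loop: float = 1.0,
) -> CandidatePartition:
    """Markov clustering: alternate flow expansion and inflation to convergence.

    The support counts act as flow capacities.  Self-loops of weight
    ``self_loop`` are added to guarantee aperiodicity.  After convergence,
    attractors (nodes retaining flow on their own column) define the clusters;
    each node joins the attractor system receiving the largest share of its
    flow, ties resolved toward the lexicographically smallest attractor system.
    Flow cannot cross connected components, so components are never merged.
    """
    if inflation <= 1:
        raise ValueError("inflation must be > 1")
    sub = _clustered_subgraph(ig)
    order = sorted(sub.nodes)
    idx = {n: i for i, n in enumerate(order)}
    n = len(order)

    a = np.zeros((n, n))
    for u, v, w in sub.edges(data="supports"):
        a[idx[u], idx[v]] = w
        a[idx[v], idx[u]] = w
    np.fill_diagonal(a, self_loop)

    m = a / a.sum(axis=0, keepdims=True)
    residual = np.inf
    for _ in range(max_iter):
        prev = m
        m = np.linalg.matrix_power(m, expansion)  # expansion
        m = m**inflation  # inflation
        m[m < prune_threshold] = 0.0
        colsum = m.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        m = m / colsum
        residual = float(np.abs(m - prev).max())
        if residual < convergence_tol:
            break
    else:
        raise MCLConvergenceError(
            f"MCL did not converge in {max_iter} iterations "
            f"(residual {residual:.3e} > {convergence_tol:.1e})"
        )

    # attractors keep flow on their own column after convergence
    attractors = np.flatnonzero(np.diag(m) > prune_threshold)
    if attractors.size == 0:  # degenerate; fall back to all nodes
        attractors = np.arange(n)
    # attractor systems: connected attractors form one cluster nucleus
    att_graph = nx.Graph()
    att_graph.add_nodes_from(attractors.tolist())
    sym = m + m.T
    for i in attractors:
        for j in attractors:
            if j > i and sym[i, j] > 0:
                att_graph.add_edge(int(i), int(j))
    systems = [sorted(c) for c in nx.connected_components(att_graph)]
    systems.sort(key=lambda s: order[s[0]])

    assignment: dict[str, str] = {}
    flow_to_system = np.stack([m[s, :].sum(axis=0) for s in systems])  # (S, n)
    for j in range(n):
        flows = flow_to_system[:, j]
        best = int(np.flatnonzero(flows == flows.max())[0])  # ties -> smallest system
        assignment[order[j]] = f"sys{best}"

    communities = [
        {s for s, lab in assignment.items() if lab == f"sys{k}"}
        for k in range(len(systems))
    ]
    communities = [c for c in communities if c]
    return CandidatePartition(
        assignment=_label_communities(communities),
        algorithm="MCL",
        params={
            "inflation": inflation,
            "expansion": expansion,
            "prune_threshold": prune_threshold,
        },
    )
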