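"""Consensus selection: threshold sweep, size filtering, wMQ scoring, reassignment.

The integration graph is filtered at every possible support threshold
``t = 1 .. max_supports``; at each threshold both Louvain (LCD) and Markov
(MCL) candidate partitions are computed on the surviving structure, clusters
below ``min_size_cluster`` are discarded, candidates retaining fewer than
``min_size_consensus`` samples are rejected, and each surviving candidate is
scored with the weighted modularization quality (wMQ).  The candidate with the
maximal wMQ becomes the consensus.  Samples filtered out along the way can be
reassigned to the consensus cluster with which they share the highest mean
number of supports in the unfiltered integration graph.

The wMQ of a partition ``C = (C_1, ..., C_k)`` on a weighted graph with
maximum possible edge weight ``max_w`` is

    wMQ = 1/(k * max_w) * sum_i [ 2*W_ii / (|C_i|*(|C_i|-1))
                                  - 1/(k-1) * sum_{j != i} W_ij / (|C_i|*|C_j|) ]

where ``W_ii`` sums the weights of edges internal to ``C_i`` and ``W_ij`` the
weights of edges between ``C_i`` and ``C_j``.  It ranges from -1 (no
intra-cluster edge, every inter-cluster pair connected at max weight) to +1
(every intra-cluster pair connected at max weight, no inter-cluster edge).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal

import networkx as nx

from .cluster import CandidatePartition, MCLConvergenceError, lcd_cluster, mcl_cluster
from .graph import IntegrationGraph

__all__ = [
    "ConsensusParams",
    "ConsensusResult",
    "NoCandidateError",
    "filter_graph",
    "wmq",
    "sweep_and_select",
    "reassign",
    "run_consensus",
]

log = logging.getLogger(__name__)


class NoCandidateError(RuntimeError):
    """No (threshold, algorithm) candidate survived the filtering steps."""

    def __init__(self, reasons: list[dict]):
        self.reasons = reasons
        lines = "; ".join(
            f"t={r['threshold']}/{r['algorithm']}: {r['reason']}" for r in reasons
        )
        super().__init__(f"no candidate consensus passed the filters ({lines})")


@dataclass
class ConsensusParams:
    """Tuning knobs of the consensus sweep.

    ``min_size_cluster`` and ``min_size_consensus`` are absolute counts when
    given as ints (>= 1) and fractions of the reference population when given
    as floats in (0, 1].  The reference population defaults to the integration
    graph's node set; pass ``reference_population`` to resolve fractions
    against another cohort (e.g. the fully-measured multi-omics samples when
    partial data is present).
    """

    min_size_cluster: int | float = 1
    min_size_consensus: int | float = 1
    reference_population: list[str] | None = None
    wmq_graph: Literal["unfiltered", "filtered"] = "unfiltered"
    reassign: bool = True
    lcd_resolution: float = 1.0
    mcl_inflation: float = 2.0

    def _resolve(self, value: int | float, n_ref: int, name: str) -> int:
        if isinstance(value, bool):
            raise ValueError(f"{name} must be a positive int or a fraction")
        if isinstance(value, int):
            if value < 1:
                raise ValueError(f"{name} must be >= 1, got {value}")
            return value
        if not 0 < value <= 1:
            raise ValueError(f"fractional {name} must lie in (0, 1], got {value}")
        return max(1, round(value * n_ref))

    def resolved_sizes(self, ig: IntegrationGraph) -> tuple[int, int]:
        n_ref = len(self.reference_population) if self.reference_population else len(
            ig.nodes
        )
        return (
            self._resolve(self.min_size_cluster, n_ref, "min_size_cluster"),
            self._resolve(self.min_size_consensus, n_ref, "min_size_consensus"),
        )


@dataclass
class ConsensusResult:
    """Selected consensus partition plus full sweep provenance."""

    assignment: dict[str, str]
    threshold: int
    algorithm: str
    wmq: float
    clustered: set[str]
    reassigned: set[str]
    unassigned: set[str]
    sweep_table: list[dict]
    params: dict = field(default_factory=dict)

    def cluster_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for lab in self.assignment.values():
            sizes[lab] = sizes.get(lab, 0) + 1
        return sizes


def filter_graph(ig: IntegrationGraph, t: int) -> IntegrationGraph:
    """Keep exactly the edges with at least ``t`` supports; nodes are kept.

    Nodes left without any edge become isolated, which downstream clustering
    treats as filtered-out individuals.
    """
    if not 1 <= t <= ig.max_supports:
        raise ValueError(f"threshold {t} outside [1, {ig.max_supports}]")
    g = nx.Graph()
    g.add_nodes_from(ig.graph.nodes)
    g.add_edges_from(
        (u, v, {"supports": w}) for u, v, w in ig.edges() if w >= t
    )
    return IntegrationGraph(graph=g, max_supports=ig.max_supports)


def wmq(ig: IntegrationGraph, partition: dict[str, str], max_w: int | None = None) -> float:
    """Weighted modularization quality of ``partition`` on the integration graph.

    Edges touching samples outside the partition are ignored.  Conventions for
    degenerate shapes: with a single cluster the external term is 0; a
    singleton cluster contributes an internal ratio of 0 (both logged).
    """
    if not partition:
        raise ValueError("partition is empty")
    if max_w is None:
        max_w = ig.max_supports
    if max_w < 1:
        raise ValueError("max_w must be >= 1")
    missing = [s for s in partition if s not in ig.graph]
    if missing:
        raise KeyError(f"partition samples absent from the graph: {missing[:5]}")

    labels = sorted(set(partition.values()))
    k = len(labels)
    index = {lab: i for i, lab in enumerate(labels)}
    sizes = [0] * k
    for lab in partition.values():
        sizes[index[lab]] += 1

    w_in = [0.0] * k
    w_between = [[0.0] * k for _ in range(k)]
    for u, v, w in ig.edges():
        lu, lv = partition.get(u), partition.get(v)
        if lu is None or lv is None:
            continue
        i, j = index[lu], index[lv]
        if i == j:
            w_in[i] += w
        else:
            w_between[i][j] += w
            w_between[j][i] += w

    total = 0.0
    for i in range(k):
        if sizes[i] > 1:
            internal = 2.0 * w_in[i] / (sizes[i] * (sizes[i] - 1))
        else:
            log.warning("singleton cluster %r: internal connectivity ratio set to 0",
                        labels[i])
            internal = 0.0
        if k > 1:
            external = sum(
                w_between[i][j] / (sizes[i] * sizes[j]) for j in range(k) if j != i
            ) / (k - 1)
        else:
            external = 0.0
        total += internal - external
    if k == 1:
        log.warning("single-cluster partition: external connectivity term is 0")
    return total / (k * max_w)


def _apply_size_filters(
    part: CandidatePartition, min_size_cluster: int
) -> tuple[dict[str, str], set[str]]:
    """Drop clusters below the size floor; return (retained assignment, dropped samples)."""
    retained: dict[str, str] = {}
    dropped: set[str] = set()
    for lab, members in part.clusters().items():
        if len(members) >= min_size_cluster:
            for s in members:
                retained[s] = lab
        else:
            dropped.update(members)
    return retained, dropped


def sweep_and_select(
    ig: IntegrationGraph, params: ConsensusParams, seed: int
) -> ConsensusResult:
    """Test every (support threshold, algorithm) configuration; keep the best wMQ.

    Each candidate is recorded in the sweep table with its cluster count, node
    count, wMQ and acceptance status.  Ties on wMQ prefer the higher threshold
    (stronger consensus evidence), then LCD over MCL, then fewer clusters.
    """
    min_cluster, min_consensus = params.resolved_sizes(ig)
    sweep: list[dict] = []
    candidates: list[tuple[tuple, dict[str, str], dict]] = []

    for t in range(1, ig.max_supports + 1):
        fg = filter_graph(ig, t)
        for algo in ("LCD", "MCL"):
            row = {"threshold": t, "algorithm": algo, "n_clusters": None,
                   "n_nodes": None, "wmq": None, "accepted": False, "reason": ""}
            try:
                if algo == "LCD":
                    part = lcd_cluster(fg, seed=seed, resolution=params.lcd_resolution)
                else:
                    part = mcl_cluster(fg, inflation=params.mcl_inflation)
            except (ValueError, MCLConvergenceError) as exc:
                row["reason"] = str(exc)
                sweep.append(row)
                continue
            retained, _ = _apply_size_filters(part, min_cluster)
            row["n_clusters"] = len(set(retained.values()))
            row["n_nodes"] = len(retained)
            if len(retained) < min_consensus:
                row["reason"] = (
                    f"retained {len(retained)} nodes < min_size_consensus {min_consensus}"
                )
                sweep.append(row)
                continue
            score_graph = ig if params.wmq_graph == "unfiltered" else fg
            score = wmq(score_graph, retained, max_w=ig.max_supports)
            row["wmq"] = score
            row["accepted"] = True
            sweep.append(row)
            rank = (score, t, 1 if algo == "LCD" else 0, -row["n_clusters"])
            candidates.append((rank, retained, row))

    if not candidates:
        raise NoCandidateError([r for r in sweep if not r["accepted"]])

    rank, retained, row = max(candidates, key=lambda c: c[0])
    clustered = set(retained)
    unassigned = ig.nodes - clustered
    return ConsensusResult(
        assignment=dict(retained),
        threshold=row["threshold"],
        algorithm=row["algorithm"],
        wmq=row["wmq"],
        clustered=clustered,
        reassigned=set(),
        unassigned=unassigned,
        sweep_table=sweep,
        params={
            "min_size_cluster": min_cluster,
            "min_size_consensus": min_consensus,
            "wmq_graph": params.wmq_graph,
            "seed": seed,
            "lcd_resolution": params.lcd_resolution,
            "mcl_inflation": params.mcl_inflation,
        },
    )


def reassign(ig_unfiltered: IntegrationGraph, result: ConsensusResult) -> ConsensusResult:
    """Place filtered-out samples by mean number of supports to each consensus cluster.

    For a filtered-out sample ``u`` and cluster ``C``, the score is
    ``sum_{v in C} weight(u, v) / |C|`` on the *unfiltered* integration graph
    (such placements need not meet the selected support threshold).  ``u``
    joins the best-scoring cluster if its score is positive, otherwise it stays
    unassigned.  Core consensus labels never change.
    """
    clusters: dict[str, list[str]] = {}
    for s, lab in result.assignment.items():
        clusters.setdefault(lab, []).append(s)

    newly_assigned: dict[str, str] = {}
    still_unassigned: set[str] = set()
    for u in sorted(result.unassigned):
        best_lab, best_score = None, 0.0
        for lab in sorted(clusters):
            members = clusters[lab]
            score = sum(ig_unfiltered.weight(u, v) for v in members) / len(members)
            if score > best_score:
                best_lab, best_score = lab, score
        if best_lab is None:
            still_unassigned.add(u)
        else:
            newly_assigned[u] = best_lab

    assignment = dict(result.assignment)
    assignment.update(newly_assigned)
    return ConsensusResult(
        assignment=assignment,
        threshold=result.threshold,
        algorithm=result.algorithm,
        wmq=result.wmq,
        clustered=result.clustered,
        reassigned=set(newly_assigned),
        unassigned=still_unassigned,
        sweep_table=result.sweep_table,
        params=result.params,
    )


def run_consensus(
    ig: IntegrationGraph, params: ConsensusParams, seed: int
) -> ConsensusResult:
    """Sweep, select, and (optionally) reassign in one call."""
    result = sweep_and_select(ig, params, seed)
    if params.reassign:
        result = reassign(ig, result)
    return result
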