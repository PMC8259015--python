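"""Shared fixtures and independent brute-force oracles."""

from __future__ import annotations

from itertools import combinations

import networkx as nx
import numpy as np
import pytest

from clustfuse import IntegrationGraph, InputClustering


def make_ig(nodes, edges, max_w: int) -> IntegrationGraph:
    """Integration graph from explicit (u, v, weight) triples."""
    g = nx.Graph()
    g.add_nodes_from(nodes)
    g.add_edges_from((u, v, {"supports": w}) for u, v, w in edges)
    return IntegrationGraph(graph=g, max_supports=max_w)


def wmq_brute(ig: IntegrationGraph, partition: dict[str, str], max_w: int) -> float:
    """O(n^2) evaluation of the weighted modularization quality, straight from
    its definition: loop over every node pair, accumulate intra/inter weight
    sums per cluster (pair), then combine the connectivity ratios."""
    labels = sorted(set(partition.values()))
    k = len(labels)
    members = {lab: sorted(s for s, l in partition.items() if l == lab)
               for lab in labels}
    total = 0.0
    for lab in labels:
        ci = members[lab]
        w_in = sum(ig.weight(u, v) for u, v in combinations(ci, 2))
        internal = 2.0 * w_in / (len(ci) * (len(ci) - 1)) if len(ci) > 1 else 0.0
        external = 0.0
        if k > 1:
            for other in labels:
                if other == lab:
                    continue
                cj = members[other]
                w_ij = sum(ig.weight(u, v) for u in ci for v in cj)
                external += w_ij / (len(ci) * len(cj))
            external /= k - 1
        total += internal - external
    return total / (k * max_w)


def ari_brute(p1: dict[str, str], p2: dict[str, str]) -> float:
    """Hubert-Arabie ARI by explicit pair counting over the sample intersection."""
    common = sorted(set(p1) & set(p2))
    a = b = c = d = 0  # same/same, same/diff, diff/same, diff/diff
    for u, v in combinations(common, 2):
        s1 = p1[u] == p1[v]
        s2 = p2[u] == p2[v]
        if s1 and s2:
            a += 1
        elif s1:
            b += 1
        elif s2:
            c += 1
        else:
            d += 1
    num = 2.0 * (a * d - b * c)
    den = (a + b) * (b + d) + (a + c) * (c + d)
    return num / den if den else 1.0


def random_partition(rng: np.random.Generator, samples: list[str], k: int) -> dict[str, str]:
    codes = rng.integers(0, k, len(samples))
    codes[: min(k, len(samples))] = np.arange(min(k, len(samples)))
    return {s: f"c{c}" for s, c in zip(samples, codes)}


def random_weighted_ig(rng: np.random.Generator, n: int, max_w: int,
                       p_edge: float = 0.5) -> IntegrationGraph:
    nodes = [f"n{i:02d}" for i in range(n)]
    edges = [(u, v, int(rng.integers(1, max_w + 1)))
             for u, v in combinations(nodes, 2) if rng.random() < p_edge]
    return make_ig(nodes, edges, max_w)


@pytest.fixture
def two_cliques() -> tuple[IntegrationGraph, dict[str, str]]:
    """Two 4-cliques at maximum weight joined by a single weight-1 edge."""
    a = [f"a{i}" for i in range(4)]
    b = [f"b{i}" for i in range(4)]
    edges = [(u, v, 5) for grp in (a, b) for u, v in combinations(grp, 2)]
    edges.append(("a0", "b0", 1))
    truth = {**{s: "A" for s in a}, **{s: "B" for s in b}}
    return make_ig(a + b, edges, 5), truth


@pytest.fixture
def small_ensemble() -> tuple[dict[str, str], list[InputClustering]]:
    """Three hand-written clusterings over 6 samples, agreeing on {s1..s3} vs {s4..s6}."""
    truth = {f"s{i}": ("x" if i <= 3 else "y") for i in range(1, 7)}
    mk = lambda name, method, omics, assign: InputClustering(  # noqa: E731
        name=name, method=method, omics=frozenset(omics), assignment=assign)
    c1 = mk("m1.o1", "m1", {"o1"}, dict(truth))
    c2 = mk("m2.o1", "m2", {"o1"}, dict(truth))
    flipped = dict(truth)
    flipped["s3"] = "y"  # one disagreement
    c3 = mk("m1.o2", "m1", {"o2"}, flipped)
    return truth, [c1, c2, c3]
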