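"""Support and integration graphs for evidence-accumulation consensus clustering.

Every input clustering casts one vote ("support") for each pair of samples it
places in the same cluster.  The *support graph* records, per sample pair, the
set of input clusterings that co-clustered the pair.  Given an *integration
scenario* (the subset of clusterings being fused), the *integration graph* is
an undirected weighted simple graph whose edge weights count the scenario
clusterings supporting each pair.  Samples covered by only part of the inputs
(partial data) simply accumulate fewer possible supports.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx

__all__ = [
    "InputClustering",
    "IntegrationScenario",
    "SupportGraph",
    "IntegrationGraph",
    "build_support_graph",
    "build_integration_graph",
    "total_weight_conservation_check",
]


@dataclass(frozen=True)
class InputClustering:
    """One input partition, tagged with the method and data source(s) that produced it.

    Parameters
    ----------
    name
        Unique identifier of this clustering within a run.
    method
        Name of the clustering tool that produced it.
    omics
        Data source tags (at least one), e.g. ``{"expression"}``.
    assignment
        Mapping from sample identifier to cluster label.  Samples absent from
        the mapping were not covered by this clustering (partial data).
    """

    name: str
    method: str
    omics: frozenset[str]
    assignment: dict[str, str]

    def __post_init__(self) -> None:
        if not self.assignment:
            raise ValueError(f"clustering {self.name!r}: assignment is empty")
        if not self.omics:
            raise ValueError(f"clustering {self.name!r}: omics set is empty")

    @property
    def samples(self) -> set[str]:
        return set(self.assignment)

    def clusters(self) -> dict[str, list[str]]:
        """Cluster label -> sorted member list."""
        out: dict[str, list[str]] = {}
        for s, lab in self.assignment.items():
            out.setdefault(lab, []).append(s)
        for members in out.values():
            members.sort()
        return out


@dataclass(frozen=True)
class IntegrationScenario:
    """The set of input clusterings being fused.

    Its cardinality is the maximum possible number of supports on an
    integration edge (every scenario clustering agreeing on a pair).
    """

    clusterings: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.clusterings)) != len(self.clusterings):
            dupes = sorted({c for c in self.clusterings if self.clusterings.count(c) > 1})
            raise ValueError(f"scenario lists duplicate clusterings: {dupes}")
        if len(self.clusterings) < 2:
            raise ValueError("a scenario needs at least 2 input clusterings")

    @property
    def max_supports(self) -> int:
        return len(self.clusterings)

    @classmethod
    def select(
        cls,
        clusterings: list[InputClustering],
        methods: set[str] | None = None,
        omics: set[str] | None = None,
    ) -> "IntegrationScenario":
        """Build a scenario from (methods x omics) selectors; None selects all."""
        names = [
            c.name
            for c in clusterings
            if (methods is None or c.method in methods)
            and (omics is None or c.omics & omics)
        ]
        return cls(tuple(names))


@dataclass
class SupportGraph:
    """Per-pair record of which input clusterings co-clustered the pair."""

    nodes: set[str]
    supports: dict[tuple[str, str], set[str]]
    provenance: dict[str, InputClustering] = field(repr=False, default_factory=dict)

    @staticmethod
    def pair(u: str, v: str) -> tuple[str, str]:
        return (u, v) if u < v else (v, u)


@dataclass
class IntegrationGraph:
    """Weighted simple graph over samples; edge attribute ``supports`` counts votes.

    ``nodes`` includes samples that end up with no edge (isolated), so that
    reporting can account for every scenario sample.  ``max_supports`` is the
    scenario cardinality, the maximum possible edge weight.
    """

    graph: nx.Graph
    max_supports: int

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    def weight(self, u: str, v: str) -> int:
        """Number of supports for pair (u, v); 0 if no edge."""
        data = self.graph.get_edge_data(u, v)
        return 0 if data is None else data["supports"]

    def edges(self):
        for u, v, w in self.graph.edges(data="supports"):
            yield u, v, w

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def total_weight(self) -> int:
        return sum(w for _, _, w in self.edges())


def build_support_graph(clusterings: list[InputClustering]) -> SupportGraph:
    """Accumulate co-clustering evidence from a set of input clusterings.

    For every clustering and every cluster of size ``s`` within it, all
    ``C(s, 2)`` sample pairs gain that clustering's name in their support set.
    Samples absent from a clustering receive no vote from it.
    """
    if not clusterings:
        raise ValueError("at least one input clustering is required")
    names = [c.name for c in clusterings]
    if len(set(names)) != len(names):
        raise ValueError("input clustering names must be unique")

    nodes: set[str] = set()
    supports: dict[tuple[str, str], set[str]] = {}
    for clu in clusterings:
        nodes.update(clu.assignment)
        for members in clu.clusters().values():
            for u, v in combinations(members, 2):  # members sorted, so u < v
                supports.setdefault((u, v), set()).add(clu.name)
    return SupportGraph(nodes=nodes, supports=supports,
                        provenance={c.name: c for c in clusterings})


def build_integration_graph(
    sg: SupportGraph, scenario: IntegrationScenario
) -> IntegrationGraph:
    """Count, per sample pair, the scenario clusterings supporting the association.

    The node set is the union of samples covered by the scenario clusterings;
    pairs with zero supports share no edge.
    """
    missing = [n for n in scenario.clusterings if n not in sg.provenance]
    if missing:
        raise KeyError(f"scenario references unknown clusterings: {missing}")
    chosen = set(scenario.clusterings)

    g = nx.Graph()
    for name in scenario.clusterings:
        g.add_nodes_from(sg.provenance[name].assignment)
    for (u, v), votes in sg.supports.items():
        w = len(votes & chosen)
        if w > 0:
            g.add_edge(u, v, supports=w)
    return IntegrationGraph(graph=g, max_supports=scenario.max_supports)


def total_weight_conservation_check(
    ig: IntegrationGraph,
    clusterings: list[InputClustering],
    scenario: IntegrationScenario | None = None,
) -> bool:
    """Total edge weight must equal the number of co-clustered pairs over all inputs.

    Sum over scenario clusterings of sum over clusters of C(size, 2) equals the
    sum of integration-edge weights; a cheap global sanity check on the build.
    """
    if scenario is not None:
        chosen = set(scenario.clusterings)
        clusterings = [c for c in clusterings if c.name in chosen]
    expected = sum(
        len(members) * (len(members) - 1) // 2
        for c in clusterings
        for members in c.clusters().values()
    )
    return ig.total_weight() == expected
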