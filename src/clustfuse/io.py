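"""On-disk artifacts: clustering tables, survival/clinical tables, graph exports, reports.

Input clustering tables are 2-column delimited files (sample_id, cluster_label),
tab-separated by default, with an optional header line.  Survival tables carry
(sample_id, time, event); clinical tables are wide, with column kinds declared
separately in the run configuration.  Integration graphs export to GraphML or a
plain edge list, with the integer ``supports`` weight preserved; consensus
results export to a TSV plus a JSON report.

Sample IDs and cluster labels are opaque, case-sensitive strings.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import pandas as pd

from .consensus import ConsensusResult
from .graph import InputClustering, IntegrationGraph

__all__ = [
    "ClusteringFileSpec",
    "read_clustering",
    "write_clustering",
    "read_survival",
    "read_clinical",
    "write_consensus",
    "read_consensus",
    "write_report",
    "export_graph",
    "read_graph",
]

HEADER_TOKENS = {"label", "cluster", "cluster_label"}


@dataclass(frozen=True)
class ClusteringFileSpec:
    """Where one input clustering lives and how it is tagged.

    ``name`` defaults to ``method.omics1+omics2``; it must be unique in a run.
    """

    path: str | Path
    method: str
    omics: frozenset[str]
    name: str | None = None

    def __post_init__(self) -> None:
        if not self.omics:
            raise ValueError("omics set must be non-empty")

    @property
    def resolved_name(self) -> str:
        if self.name:
            return self.name
        return f"{self.method}.{'+'.join(sorted(self.omics))}"


def _read_two_columns(path: str | Path, sep: str, header: str | bool) -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep, header=None, dtype=str, comment=None,
                     skip_blank_lines=True)
    if df.empty:
        raise ValueError(f"{path}: empty clustering file")
    if df.shape[1] != 2:
        raise ValueError(f"{path}: expected 2 columns, found {df.shape[1]}")
    df.columns = ["sample_id", "cluster_label"]
    df = df.apply(lambda c: c.str.strip())
    if header == "auto":
        first_label = df.iloc[0, 1]
        drop = (not first_label.replace(".", "", 1).lstrip("-").isdigit()
                and first_label.lower() in HEADER_TOKENS)
    else:
        drop = bool(header)
    if drop:
        df = df.iloc[1:]
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    return df.reset_index(drop=True)


def read_clustering(
    spec: ClusteringFileSpec, sep: str = "\t", header: str | bool = "auto"
) -> InputClustering:
    """Read one input clustering table.

    ``header`` may be True, False, or "auto" (drop the first row when its
    second field is a non-numeric header token such as "label" or "cluster").
    Duplicate sample IDs are an error; partial coverage (samples missing from
    the file) is allowed.
    """
    df = _read_two_columns(spec.path, sep, header)
    dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].unique()
    if dupes.size:
        raise ValueError(
            f"{spec.path}: duplicate sample_id(s): {', '.join(dupes[:5])}"
        )
    return InputClustering(
        name=spec.resolved_name,
        method=spec.method,
        omics=frozenset(spec.omics),
        assignment=dict(zip(df["sample_id"], df["cluster_label"])),
    )


def write_clustering(
    assignment: dict[str, str], path: str | Path, sep: str = "\t",
    header: bool = True,
) -> None:
    """Write a partition as a 2-column table (sorted by sample ID)."""
    df = pd.DataFrame(sorted(assignment.items()),
                      columns=["sample_id", "cluster_label"])
    df.to_csv(path, sep=sep, index=False, header=header)


def read_survival(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    """Read a survival table: sample_id, time (days, >= 0), event (1/0)."""
    df = pd.read_csv(path, sep=sep, dtype={"sample_id": str})
    required = {"sample_id", "time", "event"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: survival table needs columns {sorted(required)}")
    if df["sample_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate sample_id in survival table")
    if (df["time"] < 0).any():
        raise ValueError(f"{path}: negative survival times")
    if not df["event"].isin([0, 1]).all():
        raise ValueError(f"{path}: event must be 0 (censored) or 1 (event)")
    return df


def read_clinical(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    """Read a wide clinical table keyed by sample_id; column kinds come from config."""
    df = pd.read_csv(path, sep=sep, dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise ValueError(f"{path}: clinical table needs a sample_id column")
    if df["sample_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate sample_id in clinical table")
    return df


def write_consensus(result: ConsensusResult, path: str | Path, sep: str = "\t") -> None:
    """Write the consensus partition with per-sample status.

    Status is ``clustered`` for consensus-core samples, ``reassigned`` for
    samples placed post hoc by mean supports, and ``unassigned`` for samples
    the consensus could not place (those have an empty label field).
    """
    rows = []
    for s in sorted(result.clustered | result.reassigned | result.unassigned):
        if s in result.reassigned:
            status = "reassigned"
        elif s in result.clustered:
            status = "clustered"
        else:
            status = "unassigned"
        rows.append((s, result.assignment.get(s, ""), status))
    pd.DataFrame(rows, columns=["sample_id", "cluster_label", "status"]).to_csv(
        path, sep=sep, index=False
    )


def read_consensus(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    """Read back a consensus table written by :func:`write_consensus`."""
    df = pd.read_csv(path, sep=sep, dtype=str).fillna("")
    required = {"sample_id", "cluster_label", "status"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: consensus table needs columns {sorted(required)}")
    return df


def write_report(result: ConsensusResult, path: str | Path,
                 extra: dict | None = None) -> None:
    """Write the structured run report (JSON): selection, parameters, sweep table."""
    report = {
        "threshold": result.threshold,
        "algorithm": result.algorithm,
        "wmq": result.wmq,
        "n_clusters": len(set(result.assignment.values())),
        "n_clustered": len(result.clustered),
        "n_reassigned": len(result.reassigned),
        "n_unassigned": len(result.unassigned),
        "cluster_sizes": dict(sorted(result.cluster_sizes().items())),
        "params": result.params,
        "sweep_table": result.sweep_table,
    }
    if extra:
        report.update(extra)
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=False) + "\n")


def export_graph(ig: IntegrationGraph, path: str | Path, format: str = "graphml") -> None:
    """Export the integration graph; nodes carry sample IDs, edges the supports count."""
    if format == "graphml":
        g = nx.Graph(max_supports=ig.max_supports)
        g.add_nodes_from(ig.graph.nodes)
        g.add_edges_from((u, v, {"supports": int(w)}) for u, v, w in ig.edges())
        nx.write_graphml(g, path)
    elif format == "edge-list":
        with open(path, "w") as fh:
            fh.write(f"# max_supports={ig.max_supports}\n")
            for u, v, w in sorted(ig.edges()):
                fh.write(f"{u}\t{v}\t{int(w)}\n")
    else:
        raise ValueError(f"unknown graph export format: {format!r}")


def read_graph(path: str | Path, format: str = "graphml") -> IntegrationGraph:
    """Read an exported integration graph back (round-trip of :func:`export_graph`)."""
    if format == "graphml":
        g = nx.read_graphml(path)
        max_supports = int(g.graph.get("max_supports", 0)) or max(
            (int(w) for _, _, w in g.edges(data="supports")), default=1
        )
        clean = nx.Graph()
        clean.add_nodes_from(str(n) for n in g.nodes)
        clean.add_edges_from(
            (str(u), str(v), {"supports": int(w)})
            for u, v, w in g.edges(data="supports")
        )
        return IntegrationGraph(graph=clean, max_supports=max_supports)
    if format == "edge-list":
        g = nx.Graph()
        max_supports = 1
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith("#"):
                    if "max_supports=" in line:
                        max_supports = int(line.split("max_supports=")[1])
                    continue
                u, v, w = line.split("\t")
                g.add_edge(u, v, supports=int(w))
        return IntegrationGraph(graph=g, max_supports=max_supports)
    raise ValueError(f"unknown graph format: {format!r}")
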