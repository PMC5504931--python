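"""Co-prescription network: construction, clustering, cores, export.

The network is built from the top-ranked two-CHM combinations: nodes are
the CHMs involved (sized by single-item prevalence), edges carry the
combination's support (how often the pair is co-prescribed), confidence
and lift (how strongly the two are associated beyond chance).  Clusters
are detected automatically by greedy agglomerative modularity
maximization (Clauset-Newman-Moore); each cluster's core is its most
prevalent, best-connected member, and the global core is the same
maximizer over the whole network.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx

from .mining import CombinationRow

__all__ = [
    "NetworkNode",
    "NetworkEdge",
    "CoPrescriptionNetwork",
    "build_network",
    "detect_clusters",
    "identify_cores",
    "export_graph",
    "read_graphml_network",
]

EDGE_WEIGHTS = ("support", "lift", "unweighted")


@dataclass
class NetworkNode:
    code: str
    name: str = ""
    kind: str = ""
    prevalence: float = 0.0
    cluster_id: int | None = None
    is_cluster_core: bool = False


@dataclass(frozen=True)
class NetworkEdge:
    endpoints: frozenset[str]
    support: float
    confidence: float
    lift: float

    def __post_init__(self) -> None:
        if len(self.endpoints) != 2:
            raise ValueError("an edge needs two distinct endpoints")


@dataclass
class CoPrescriptionNetwork:
    """Simple undirected graph over CHMs with a modularity partition."""

    nodes: dict[str, NetworkNode] = field(default_factory=dict)
    edges: list[NetworkEdge] = field(default_factory=list)
    modularity: float | None = None
    global_core: str | None = None

    def to_networkx(self, weight: str = "support") -> nx.Graph:
        """Deterministic graph view: nodes and edges inserted in sorted order."""
        if weight not in EDGE_WEIGHTS:
            raise ValueError(f"weight must be one of {EDGE_WEIGHTS}")
        g = nx.Graph()
        for code in sorted(self.nodes):
            n = self.nodes[code]
            attrs = {
                "name": n.name,
                "kind": n.kind,
                "prevalence": n.prevalence,
                "is_cluster_core": n.is_cluster_core,
            }
            if n.cluster_id is not None:
                attrs["cluster_id"] = n.cluster_id
            g.add_node(code, **attrs)
        for e in sorted(self.edges, key=lambda e: tuple(sorted(e.endpoints))):
            a, b = sorted(e.endpoints)
            attrs = {"support": e.support, "confidence": e.confidence, "lift": e.lift}
            if weight != "unweighted":
                attrs["weight"] = attrs[weight]
            g.add_edge(a, b, **attrs)
        return g

    def cluster_sizes(self) -> dict[int, int]:
        sizes: dict[int, int] = {}
        for n in self.nodes.values():
            if n.cluster_id is not None:
                sizes[n.cluster_id] = sizes.get(n.cluster_id, 0) + 1
        return dict(sorted(sizes.items()))

    def n_clusters(self) -> int:
        return len({n.cluster_id for n in self.nodes.values() if n.cluster_id is not None})

    def cluster_cores(self) -> dict[int, str]:
        return {
            n.cluster_id: n.code
            for n in self.nodes.values()
            if n.is_cluster_core and n.cluster_id is not None
        }


def build_network(
    top_pairs: Sequence[CombinationRow],
    item_prevalence: Mapping[str, float],
    item_names: Mapping[str, str] | None = None,
    item_kinds: Mapping[str, str] | None = None,
) -> CoPrescriptionNetwork:
    """Simple undirected graph from ranked two-CHM combinations.

    Every endpoint must have a prevalence entry; duplicate pair rows
    violate the simple-graph contract and are rejected.
    """
    if not top_pairs:
        raise ValueError("top_pairs is empty")
    names = item_names or {}
    kinds = item_kinds or {}
    net = CoPrescriptionNetwork()
    seen: set[frozenset[str]] = set()
    for row in top_pairs:
        if len(row.items) != 2:
            raise ValueError(f"not a pair: {row.items}")
        pair = frozenset(row.items)
        if pair in seen:
            raise ValueError(f"duplicate combination row: {sorted(pair)}")
        seen.add(pair)
        for code in row.items:
            if code not in net.nodes:
                if code not in item_prevalence:
                    raise ValueError(f"no prevalence entry for item {code!r}")
                net.nodes[code] = NetworkNode(
                    code=code,
                    name=names.get(code, code),
                    kind=kinds.get(code, ""),
                    prevalence=item_prevalence[code],
                )
        net.edges.append(
            NetworkEdge(
                endpoints=pair,
                support=row.support,
                confidence=row.confidence,
                lift=row.lift,
            )
        )
    return net


def detect_clusters(
    network: CoPrescriptionNetwork, weight_attribute: str = "support"
) -> CoPrescriptionNetwork:
    """Label every node with a CNM greedy-modularity community (in place).

    Cluster ids are assigned 1..C in order of decreasing community size
    (ties: smallest member code), so the largest cluster is cluster 1.
    Disconnected dyads end up as their own clusters.  The overall
    modularity of the partition (on the same weights) is stored.
    """
    if not network.nodes:
        raise ValueError("network is empty")
    g = network.to_networkx(weight=weight_attribute)
    wkey = None if weight_attribute == "unweighted" else "weight"
    if g.number_of_edges() == 0:
        communities = [frozenset({n}) for n in sorted(g.nodes)]
    else:
        communities = list(
            nx.community.greedy_modularity_communities(g, weight=wkey)
        )
    communities.sort(key=lambda c: (-len(c), min(c)))
    for cid, members in enumerate(communities, start=1):
        for code in members:
            network.nodes[code].cluster_id = cid
    network.modularity = float(
        nx.community.modularity(g, communities, weight=wkey)
    )
    return network


def _core_key(network: CoPrescriptionNetwork):
    wdeg: dict[str, float] = {c: 0.0 for c in network.nodes}
    for e in network.edges:
        for c in e.endpoints:
            wdeg[c] += e.support

    def key(code: str):
        n = network.nodes[code]
        return (-n.prevalence, -wdeg[code], code)

    return key


def identify_cores(
    network: CoPrescriptionNetwork,
) -> tuple[dict[int, str], str]:
    """Per-cluster core CHMs and the global core.

    The core maximizes (prevalence, support-weighted degree) with
    lexicographically smallest code as the final tie-break.  Flags are set
    on the nodes; returns (cluster_id -> core code, global core code).
    """
    if any(n.cluster_id is None for n in network.nodes.values()):
        raise ValueError("run detect_clusters before identify_cores")
    key = _core_key(network)
    by_cluster: dict[int, list[str]] = {}
    for code, n in network.nodes.items():
        n.is_cluster_core = False
        by_cluster.setdefault(n.cluster_id, []).append(code)
    cores = {cid: min(members, key=key) for cid, members in by_cluster.items()}
    for code in cores.values():
        network.nodes[code].is_cluster_core = True
    global_core = min(network.nodes, key=key)
    network.global_core = global_core
    return dict(sorted(cores.items())), global_core


def export_graph(
    network: CoPrescriptionNetwork, path: str | Path, format: str = "graphml"
) -> Path:
    """Write the network as GraphML, whitespace edge list, or JSON.

    GraphML carries all node and edge attributes and round-trips exactly
    through :func:`read_graphml_network`.
    """
    path = Path(path)
    g = network.to_networkx(weight="support")
    if format == "graphml":
        nx.write_graphml(g, path, infer_numeric_types=False)
    elif format == "edgelist":
        with path.open("w") as fh:
            for e in sorted(network.edges, key=lambda e: tuple(sorted(e.endpoints))):
                a, b = sorted(e.endpoints)
                fh.write(f"{a} {b} {e.support!r} {e.confidence!r} {e.lift!r}\n")
    elif format == "json":
        data = nx.node_link_data(g, edges="links")
        if network.modularity is not None:
            data["modularity"] = network.modularity
        if network.global_core is not None:
            data["global_core"] = network.global_core
        path.write_text(json.dumps(data, indent=2) + "\n")
    else:
        raise ValueError(f"unknown export format {format!r}")
    return path


def read_graphml_network(path: str | Path) -> CoPrescriptionNetwork:
    """Re-read an exported GraphML network (inverse of graphml export)."""
    g = nx.read_graphml(Path(path))
    net = CoPrescriptionNetwork()
    for code, attrs in g.nodes(data=True):
        net.nodes[code] = NetworkNode(
            code=code,
            name=attrs.get("name", ""),
            kind=attrs.get("kind", ""),
            prevalence=float(attrs.get("prevalence", 0.0)),
            cluster_id=int(attrs["cluster_id"]) if "cluster_id" in attrs else None,
            is_cluster_core=bool(attrs.get("is_cluster_core", False)),
        )
    for a, b, attrs in g.edges(data=True):
        net.edges.append(
            NetworkEdge(
                endpoints=frozenset((a, b)),
                support=float(attrs["support"]),
                confidence=float(attrs["confidence"]),
                lift=float(attrs["lift"]),
            )
        )
    net.edges.sort(key=lambda e: tuple(sorted(e.endpoints)))
    return net
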