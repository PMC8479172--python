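"""Residue correlation networks, communities, centralities, and suboptimal
paths.

Nodes are residues (plus ligand residues and ions when included); an edge
joins two nodes when |C_ij| meets the correlation threshold (0.7 by
default, i.e. motion vectors within 45°), weighted w = −ln|C_ij| so that
strong correlation means a short path.  Communities come from greedy
modularity maximization; suboptimal paths are the k lowest-weight simple
paths between source and sink residue sets.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import islice
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

from .dynamics import CrossCorrelationMatrix

__all__ = [
    "ResidueNetwork",
    "CommunityPartition",
    "CommunityGraph",
    "PathSet",
    "NodeCentrality",
    "build_network",
    "detect_communities",
    "community_graph",
    "centrality",
    "suboptimal_paths",
    "fraction_through",
    "partition_similarity",
]


@dataclass
class ResidueNetwork:
    graph: nx.Graph                      # edge attrs: weight (−ln|C|), corr
    node_ids: tuple[int, ...]
    threshold: float

    def edge_weight(self, a: int, b: int) -> float:
        return self.graph.edges[a, b]["weight"]


@dataclass
class CommunityPartition:
    membership: dict[int, int]   # node -> community id
    modularity: float
    sizes: dict[int, int] = field(default_factory=dict)

    def communities(self) -> dict[int, set[int]]:
        out: dict[int, set[int]] = {}
        for node, cid in self.membership.items():
            out.setdefault(cid, set()).add(node)
        return out


@dataclass
class CommunityGraph:
    variant: str                         # "overlay" | "simplified"
    radii: dict[int, float]              # community id -> R_i = N_i / 3
    edges: dict[tuple[int, int], float]  # (cid, cid) -> E_ij
    centers: dict[int, np.ndarray] = field(default_factory=dict)
    pruned: tuple[int, ...] = ()         # communities with no external edge


@dataclass
class PathSet:
    paths: tuple[tuple[int, ...], ...]   # node sequences, ascending weight
    weights: tuple[float, ...]
    sources: tuple[int, ...]
    sinks: tuple[int, ...]

    def __len__(self) -> int:
        return len(self.paths)


@dataclass
class NodeCentrality:
    degree: dict[int, int]
    betweenness: dict[int, float]


def build_network(corr: CrossCorrelationMatrix,
                  threshold: float = 0.7) -> ResidueNetwork:
    """Edges wherever |C_ij| >= threshold (i != j), weight −ln|C_ij|.

    Absolute correlation is used throughout, so strongly anticorrelated
    pairs also connect.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    c = corr.matrix
    nodes = corr.node_ids
    g = nx.Graph()
    g.add_nodes_from(nodes)
    n = len(nodes)
    absc = np.abs(c)
    for i in range(n):
        for j in range(i + 1, n):
            if absc[i, j] >= threshold:
                cij = float(absc[i, j])
                w = 0.0 if cij >= 1.0 else -math.log(cij)
                g.add_edge(nodes[i], nodes[j], weight=w, corr=float(c[i, j]),
                           strength=cij)
    return ResidueNetwork(graph=g, node_ids=nodes, threshold=threshold)


def detect_communities(net: ResidueNetwork) -> CommunityPartition:
    """Greedy (agglomerative) modularity communities.

    Edgeless networks return every node as its own community with a
    warning.  Community ids are assigned in order of each community's
    lowest node id, which makes the labelling deterministic.
    """
    g = net.graph
    if g.number_of_edges() == 0:
        warnings.warn("network has no edges; every node is its own community",
                      stacklevel=2)
        comms = [{n} for n in sorted(g.nodes)]
        mod = 0.0
    else:
        comms = [set(c) for c in
                 nx.community.greedy_modularity_communities(g, weight="strength")]
        mod = nx.community.modularity(g, comms, weight="strength")
    comms.sort(key=lambda s: min(s))
    membership = {}
    sizes = {}
    for cid, members in enumerate(comms):
        sizes[cid] = len(members)
        for node in members:
            membership[node] = cid
    return CommunityPartition(membership=membership, modularity=float(mod),
                              sizes=sizes)


def community_graph(
    partition: CommunityPartition,
    net: ResidueNetwork,
    variant: str = "simplified",
    coords: Mapping[int, np.ndarray] | None = None,
) -> CommunityGraph:
    """Community-level summary graph.

    Radii are R_i = N_i/3 in both variants.  Edge weights are
    E_ij = −ln|max C_ij| / 4 for the structure-overlay variant and
    E_ij = −ln|max C_ij| for the simplified diagram, where max C_ij is the
    largest |correlation| among network edges spanning the two communities.
    Communities without any inter-community edge are pruned.
    """
    if variant not in ("overlay", "simplified"):
        raise ValueError("variant must be 'overlay' or 'simplified'")
    scale = 4.0 if variant == "overlay" else 1.0
    membership = partition.membership
    best: dict[tuple[int, int], float] = {}
    for a, b, data in net.graph.edges(data=True):
        ca, cb = membership[a], membership[b]
        if ca == cb:
            continue
        key = (min(ca, cb), max(ca, cb))
        best[key] = max(best.get(key, 0.0), abs(data["corr"]))
    edges = {
        key: (-math.log(c) / scale if c < 1.0 else 0.0)
        for key, c in best.items()
    }
    connected = {cid for key in edges for cid in key}
    pruned = tuple(sorted(set(partition.sizes) - connected))
    radii = {cid: partition.sizes[cid] / 3.0 for cid in connected}
    centers: dict[int, np.ndarray] = {}
    if coords is not None and variant == "overlay":
        for cid in connected:
            members = [n for n, c in membership.items() if c == cid]
            centers[cid] = np.mean([coords[n] for n in members], axis=0)
    return CommunityGraph(variant=variant, radii=radii, edges=edges,
                          centers=centers, pruned=pruned)


def centrality(net: ResidueNetwork, weighted: bool = True) -> NodeCentrality:
    """Degree (incident edges) and betweenness (shortest paths through the
    node, endpoints excluded, unnormalized)."""
    g = net.graph
    degree = {n: int(d) for n, d in g.degree()}
    btw = nx.betweenness_centrality(
        g, weight="weight" if weighted else None, normalized=False
    )
    return NodeCentrality(degree=degree, betweenness={n: float(v) for n, v in btw.items()})


def suboptimal_paths(
    net: ResidueNetwork,
    sources: Sequence[int],
    sinks: Sequence[int],
    k: int = 500,
) -> PathSet:
    """The k lowest-weight simple paths over all source–sink pairs.

    Each pair contributes its own k-shortest simple paths (Yen's
    deviation search); the union is sorted globally by (total weight,
    lexicographic node sequence) and truncated to k.  Disconnected pairs
    contribute nothing; if no pair connects, the result is empty with a
    warning.
    """
    g = net.graph
    collected: list[tuple[float, tuple[int, ...]]] = []
    any_connected = False
    for s in sources:
        for t in sinks:
            if s == t or s not in g or t not in g:
                continue
            if not nx.has_path(g, s, t):
                continue
            any_connected = True
            gen = nx.shortest_simple_paths(g, s, t, weight="weight")
            for path in islice(gen, k):
                w = sum(g.edges[a, b]["weight"]
                        for a, b in zip(path[:-1], path[1:]))
                collected.append((w, tuple(path)))
    if not any_connected:
        warnings.warn("no source-sink pair is connected; empty path set",
                      stacklevel=2)
    collected.sort(key=lambda t: (t[0], t[1]))
    collected = collected[:k]
    return PathSet(
        paths=tuple(p for _, p in collected),
        weights=tuple(w for w, _ in collected),
        sources=tuple(sources),
        sinks=tuple(sinks),
    )


def fraction_through(paths: PathSet, nodes: int | Sequence[int]) -> float:
    """Fraction of paths whose interior passes through any of the nodes."""
    if len(paths) == 0:
        raise ValueError("path set is empty")
    targets = {nodes} if isinstance(nodes, int) else set(nodes)
    hits = sum(
        1 for p in paths.paths if targets & set(p[1:-1])
    )
    return hits / len(paths)


def partition_similarity(
    pa: CommunityPartition,
    pb: CommunityPartition,
    analogy_threshold: float = 60.0,
) -> dict:
    """Best-match Jaccard overlap (%) of each community of A against B.

    Returns per-community overlap percentages, the matched community ids,
    and which pairs clear the analogy threshold.
    """
    if set(pa.membership) != set(pb.membership):
        raise ValueError("partitions cover different node universes")
    ca = pa.communities()
    cb = pb.communities()
    per_community = {}
    for cid, members in sorted(ca.items()):
        best_pct = 0.0
        best_match = None
        for cid_b, members_b in sorted(cb.items()):
            inter = len(members & members_b)
            union = len(members | members_b)
            pct = 100.0 * inter / union if union else 0.0
            if pct > best_pct:
                best_pct = pct
                best_match = cid_b
        per_community[cid] = {
            "overlap_pct": best_pct,
            "match": best_match,
            "analogous": best_pct >= analogy_threshold,
        }
    n_analogous = sum(1 for v in per_community.values() if v["analogous"])
    return {
        "per_community": per_community,
        "n_analogous": n_analogous,
        "mean_overlap_pct": float(
            np.mean([v["overlap_pct"] for v in per_community.values()])
        ),
    }
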