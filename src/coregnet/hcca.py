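"""Heuristic Cluster Chiseling Algorithm (HCCA) for network partitioning.

HCCA grows a candidate cluster around every node as its depth-bounded
vicinity subgraph, then "chisels" the candidate — repeatedly removing, all
at once, every member with more connections outside the set than inside —
until the set is stable. Stable candidates within the accepted size range
are scored by their internal-edge fraction and greedily accepted without
overlap; accepted nodes are cut from the working graph and the process
repeats until no candidate survives. Nodes never captured remain
unassigned.

All tie-breaks are deterministic (score desc, size desc, smallest seed ID;
simultaneous removal during chiseling), so identical inputs give identical
partitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from coregnet.coexpression import CoexpressionNetwork
from coregnet.preprocessing import InputError


@dataclass
class HccaConfig:
    """HCCA parameters.

    vicinity_depth
        Shortest-path radius of the seed vicinity. The default (3) suits
        sparse HRR-filtered networks whose degree is bounded by the HRR
        cutoff; on dense graphs choose a depth at which vicinities remain
        local, otherwise every vicinity spans the whole graph and the
        chiseling rule has nothing to cut against.
    min_size, max_size
        Accepted cluster size range (defaults 3–100).
    max_rounds
        Cap on accept-and-remove rounds.
    """

    vicinity_depth: int = 3
    min_size: int = 3
    max_size: int = 100
    max_rounds: int = 100

    def __post_init__(self) -> None:
        if self.vicinity_depth < 1:
            raise InputError(f"vicinity_depth must be ≥ 1, got {self.vicinity_depth}")
        if not 1 <= self.min_size <= self.max_size:
            raise InputError(
                f"need 1 ≤ min_size ≤ max_size, got [{self.min_size}, {self.max_size}]"
            )
        if self.max_rounds < 1:
            raise InputError(f"max_rounds must be ≥ 1, got {self.max_rounds}")


@dataclass
class ClusterAssignment:
    """Disjoint gene clusters plus the set of unassigned nodes.

    ``scores[k]`` is the internal-edge fraction of ``clusters[k]`` measured
    in the working graph at acceptance time.
    """

    clusters: list[set[str]]
    scores: list[float]
    unassigned: set[str]

    @property
    def n_clustered(self) -> int:
        return sum(len(c) for c in self.clusters)

    def labels(self) -> dict[str, int]:
        """Gene → cluster index; unassigned genes map to −1."""
        lab = {g: -1 for g in self.unassigned}
        for k, members in enumerate(self.clusters):
            for g in members:
                lab[g] = k
        return lab

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for k, members in enumerate(self.clusters):
            for g in sorted(members):
                rows.append((g, str(k), self.scores[k]))
        for g in sorted(self.unassigned):
            rows.append((g, "unassigned", float("nan")))
        return pd.DataFrame(rows, columns=["gene_id", "cluster_id", "cluster_score"])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _graph(net) -> nx.Graph:
    return net.graph if isinstance(net, CoexpressionNetwork) else net


def node_vicinity(net, seed: str, depth: int) -> set[str]:
    """All nodes within shortest-path distance ``depth`` of ``seed`` (inclusive)."""
    g = _graph(net)
    if seed not in g:
        raise InputError(f"seed node {seed!r} not in network")
    return set(nx.single_source_shortest_path_length(g, seed, cutoff=depth))


def chisel(net, candidate: set[str]) -> set[str]:
    """Shrink a candidate set to its chisel-stable core.

    Each round simultaneously removes every member whose edge count to
    nodes outside the current set strictly exceeds its edge count inside;
    rounds repeat until nothing changes. May return the empty set.
    """
    g = _graph(net)
    current = {n for n in candidate if n in g}
    while current:
        drop = set()
        for n in current:
            inside = sum(1 for nb in g.neighbors(n) if nb in current)
            outside = g.degree(n) - inside
            if outside > inside:
                drop.add(n)
        if not drop:
            break
        current -= drop
    return current


def _score(g: nx.Graph, nodes: set[str]) -> float:
    """Internal-edge fraction: edges inside / (inside + boundary)."""
    internal = g.subgraph(nodes).number_of_edges()
    boundary = sum(1 for n in nodes for nb in g.neighbors(n) if nb not in nodes)
    total = internal + boundary
    return internal / total if total else 1.0


def hcca_cluster(net, cfg: HccaConfig | None = None) -> ClusterAssignment:
    """Partition a network into HCCA clusters plus an unassigned remainder."""
    cfg = cfg or HccaConfig()
    g = _graph(net).copy()
    if g.number_of_nodes() == 0:
        raise InputError("cannot cluster an empty network")
    clusters: list[set[str]] = []
    scores: list[float] = []
    for _ in range(cfg.max_rounds):
        if g.number_of_nodes() == 0:
            break
        # one candidate per distinct stable set, tagged with its smallest seed
        candidates: dict[frozenset, str] = {}
        for seed in g.nodes:
            stable = chisel(g, node_vicinity(g, seed, cfg.vicinity_depth))
            if seed not in stable:
                continue
            if not cfg.min_size <= len(stable) <= cfg.max_size:
                continue
            key = frozenset(stable)
            if key not in candidates or str(seed) < str(candidates[key]):
                candidates[key] = seed
        if not candidates:
            break
        ranked = sorted(
            (
                (-_score(g, set(nodes)), -len(nodes), str(seed), nodes)
                for nodes, seed in candidates.items()
            )
        )
        taken: set[str] = set()
        accepted_this_round = 0
        for neg_score, _neg_size, _seed, nodes in ranked:
            members = set(nodes)
            if members & taken:
                continue
            clusters.append(members)
            scores.append(-neg_score)
            taken |= members
            accepted_this_round += 1
        if accepted_this_round == 0:
            break
        g.remove_nodes_from(taken)
    return ClusterAssignment(clusters=clusters, scores=scores, unassigned=set(g.nodes))
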