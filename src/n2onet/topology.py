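"""Network topology summaries, module detection, and keystone (Zi) calls.

"Vertices" counts non-isolated nodes only: co-occurrence tooling reports
connected nodes, and isolated taxa carry no interaction information
(``count_isolated=True`` switches to all nodes). Modules are found by seeded
Louvain maximization of Newman-Girvan modularity on the unsigned, unweighted
edge skeleton; high within-module degree z-scores (Zi) mark module hubs,
the keystone taxa.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .datatypes import ConsistencyError


@dataclass
class TopologySummary:
    n_edges: int
    n_pos_edges: int
    n_neg_edges: int
    n_vertices: int
    avg_degree: float
    mean_clustering: float
    centralization_betweenness: float
    pos_neg_ratio: float  # inf when no negative edges

    def as_dict(self) -> dict[str, float]:
        return {
            "n_edges": self.n_edges,
            "n_pos_edges": self.n_pos_edges,
            "n_neg_edges": self.n_neg_edges,
            "n_vertices": self.n_vertices,
            "avg_degree": self.avg_degree,
            "mean_clustering": self.mean_clustering,
            "centralization_betweenness": self.centralization_betweenness,
            "pos_neg_ratio": self.pos_neg_ratio,
        }


@dataclass
class ModulePartition:
    assignment: dict[str, int]
    modularity_q: float
    algorithm: str = "louvain"
    seed: int | None = None

    def members(self, module: int) -> list[str]:
        return sorted(n for n, m in self.assignment.items() if m == module)

    @property
    def modules(self) -> list[int]:
        return sorted(set(self.assignment.values()))


@dataclass
class KeystoneReport:
    zi: dict[str, float]
    keystone_flags: dict[str, bool]
    zi_threshold: float = 2.5
    keystones: list[str] = field(init=False)

    def __post_init__(self) -> None:
        self.keystones = sorted(n for n, f in self.keystone_flags.items() if f)


def topology_summary(net: nx.Graph, count_isolated: bool = False) -> TopologySummary:
    """The per-network topological metric vector.

    Local clustering 2T_i / (k_i (k_i - 1)) is averaged over nodes of degree
    >= 2 only; betweenness centralization is Freeman's, on unweighted
    shortest paths over the non-isolated node set:
    sum_i (B_max - B_i) / [(V-1) * (V-1)(V-2)/2].
    """
    signs = nx.get_edge_attributes(net, "sign")
    n_edges = net.number_of_edges()
    n_neg = sum(1 for s in signs.values() if s == "-")
    n_pos = n_edges - n_neg

    active = [n for n in net.nodes if net.degree(n) > 0]
    n_vertices = net.number_of_nodes() if count_isolated else len(active)
    avg_degree = 2.0 * n_edges / n_vertices if n_vertices > 0 else 0.0

    clus = nx.clustering(net)
    eligible = [c for n, c in clus.items() if net.degree(n) >= 2]
    mean_clustering = float(np.mean(eligible)) if eligible else 0.0

    cb = _betweenness_centralization(net.subgraph(active))

    if n_neg == 0:
        ratio = math.inf if n_pos > 0 else math.nan
    else:
        ratio = n_pos / n_neg
    return TopologySummary(
        n_edges=n_edges,
        n_pos_edges=n_pos,
        n_neg_edges=n_neg,
        n_vertices=n_vertices,
        avg_degree=avg_degree,
        mean_clustering=mean_clustering,
        centralization_betweenness=cb,
        pos_neg_ratio=ratio,
    )


def _betweenness_centralization(g: nx.Graph) -> float:
    v = g.number_of_nodes()
    if v < 3:
        return 0.0
    # raw betweenness, each unordered pair counted once
    b = nx.betweenness_centrality(g, normalized=False)
    bmax = max(b.values())
    denom = (v - 1) * ((v - 1) * (v - 2) / 2.0)
    return float(sum(bmax - bi for bi in b.values()) / denom)


def detect_modules(net: nx.Graph, seed: int = 0) -> ModulePartition:
    """Seeded Louvain partition of the unsigned, unweighted skeleton.

    Modules are relabeled 1, 2, ... by descending size (ties by smallest
    member name); singleton components are their own modules. Raises on an
    edgeless network — there is nothing to partition.
    """
    if net.number_of_edges() == 0:
        raise ValueError("cannot partition an edgeless network")
    communities = nx.community.louvain_communities(net, weight=None, seed=seed)
    q = nx.community.modularity(net, communities, weight=None)
    ordered = sorted(communities, key=lambda c: (-len(c), min(c)))
    assignment = {n: m for m, comm in enumerate(ordered, start=1) for n in comm}
    return ModulePartition(assignment=assignment, modularity_q=float(q), seed=seed)


def within_module_degree_z(
    net: nx.Graph, part: ModulePartition, zi_threshold: float = 2.5
) -> KeystoneReport:
    """Within-module degree z-score (Zi) with keystone flags.

    For node i in module s, kappa_i is the number of edges from i to other
    members of s; Zi standardizes kappa within the module using the
    population sd. Modules with sd 0 give Zi = 0 for all members. Nodes at
    or above ``zi_threshold`` are flagged as keystones (module hubs).
    """
    missing = [n for n in net.nodes if n not in part.assignment]
    if missing:
        raise ConsistencyError(f"nodes missing from partition: {sorted(missing)}")
    zi: dict[str, float] = {}
    for m in part.modules:
        members = [n for n in net.nodes if part.assignment.get(n) == m]
        member_set = set(members)
        kappa = np.array(
            [sum(1 for nb in net.neighbors(n) if nb in member_set) for n in members],
            dtype=float,
        )
        sd = kappa.std()  # population sd
        if sd == 0:
            for n in members:
                zi[n] = 0.0
        else:
            mean = kappa.mean()
            for n, k in zip(members, kappa):
                zi[n] = float((k - mean) / sd)
    flags = {n: z >= zi_threshold - 1e-12 for n, z in zi.items()}
    return KeystoneReport(zi=zi, keystone_flags=flags, zi_threshold=zi_threshold)
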