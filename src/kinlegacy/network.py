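"""IBD networks: pruning, modularity clustering, projection, familial groups.

Cohort members who share very large amounts of IBD (>= 700 cM, i.e. close
kin or duplicates) would dominate network structure, so one endpoint of
every such pair is removed before building the weighted graph.  Community
structure is found by greedy modularity maximization over the remaining
total-cM-weighted edges, historical individuals are projected onto
clusters by their mean sharing with cluster members, and familial groups
are communities of the close relatives (>= 30 cM to a historical
individual) expanded by their own >= 100 cM relatives.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .relatedness import PairSummary


@dataclass
class ClusterSet:
    clusters: list[list[str]]
    modularity: float
    node_cluster: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.node_cluster:
            self.node_cluster = {n: i for i, c in enumerate(self.clusters)
                                 for n in c}


def build_graph(summaries: list[PairSummary], prune_cM: float = 700.0,
                node_ids: list[str] | None = None) -> nx.Graph:
    """Total-cM weighted graph over cohort members sharing < prune_cM.

    For every pair sharing >= ``prune_cM`` the endpoint with the larger
    total degree weight (ties: lexicographically larger id) is removed,
    iteratively, until no such pair remains.  The pruning log is stored in
    ``graph.graph["pruned"]``.
    """
    g = nx.Graph()
    if node_ids:
        g.add_nodes_from(node_ids)
    for s in summaries:
        g.add_edge(s.id1, s.id2, weight=s.total_cM)
    pruned: list[str] = []
    while True:
        heavy = [(u, v) for u, v, w in g.edges(data="weight") if w >= prune_cM]
        if not heavy:
            break
        strength = {n: 0.0 for e in heavy for n in e}
        for n in strength:
            strength[n] = sum(w for _, _, w in g.edges(n, data="weight"))
        # remove the single worst offender, then re-evaluate
        victim = max(strength, key=lambda n: (strength[n], n))
        g.remove_node(victim)
        pruned.append(victim)
    g.graph["pruned"] = pruned
    return g


def cluster_graph(g: nx.Graph, resolution: float = 1.0,
                  seed: int = 0) -> ClusterSet:
    """Greedy modularity communities over canonical node order.

    Deterministic: nodes are relabelled into sorted order before
    clustering so the result is invariant to insertion order; ``seed`` is
    accepted for interface stability (the greedy algorithm ignores it).
    """
    if g.number_of_nodes() == 0:
        return ClusterSet([], 0.0)
    h = nx.Graph()
    h.add_nodes_from(sorted(g.nodes))
    h.add_weighted_edges_from((min(u, v), max(u, v), w)
                              for u, v, w in g.edges(data="weight"))
    if h.number_of_edges() == 0:
        clusters = [[n] for n in sorted(h.nodes)]
        return ClusterSet(clusters, 0.0)
    comms = nx.community.greedy_modularity_communities(
        h, weight="weight", resolution=resolution)
    clusters = sorted((sorted(c) for c in comms), key=lambda c: c[0])
    mod = nx.community.modularity(h, [set(c) for c in clusters],
                                  weight="weight", resolution=resolution)
    return ClusterSet(clusters, float(mod))


def cluster_summary(clusters: ClusterSet, metadata: pd.DataFrame,
                    ancestry_cols: list[str]) -> pd.DataFrame:
    """Per-cluster mean ancestry and majority region label."""
    meta = metadata.set_index("participant_id")
    rows = []
    for i, members in enumerate(clusters.clusters):
        present = [m for m in members if m in meta.index]
        sub = meta.loc[present]
        row = {"cluster": i, "n_members": len(members)}
        for c in ancestry_cols:
            row[f"mean_{c}"] = float(sub[c].mean()) if len(sub) else float("nan")
        if "region" in sub.columns and len(sub):
            row["majority_region"] = sub["region"].mode().iloc[0]
        rows.append(row)
    return pd.DataFrame(rows)


def project_historical(summaries: list[PairSummary], clusters: ClusterSet,
                       historical_ids: set) -> pd.DataFrame:
    """Mean IBD between each historical individual and each cluster.

    The weight is the mean total_cM over cluster members with nonzero
    sharing; clusters with no sharing are omitted.
    """
    rows = []
    for hist in sorted(historical_ids):
        shared: dict[int, list[float]] = {}
        for s in summaries:
            other = None
            if s.id1 == hist and s.id2 not in historical_ids:
                other = s.id2
            elif s.id2 == hist and s.id1 not in historical_ids:
                other = s.id1
            if other is None or other not in clusters.node_cluster:
                continue
            shared.setdefault(clusters.node_cluster[other], []).append(s.total_cM)
        for c, vals in sorted(shared.items()):
            rows.append({"historical_id": hist, "cluster": c,
                         "mean_cM": float(pd.Series(vals).mean()),
                         "n_members_sharing": len(vals)})
    return pd.DataFrame(rows, columns=["historical_id", "cluster",
                                       "mean_cM", "n_members_sharing"])


def familial_groups(connections: pd.DataFrame, summaries: list[PairSummary],
                    close_cM: float = 30.0, expand_cM: float = 100.0,
                    resolution: float = 1.0, seed: int = 0) -> ClusterSet:
    """Close relatives plus their own >= expand_cM relatives, clustered.

    Node set = cohort members with >= close_cM to a historical individual,
    union cohort members sharing >= expand_cM with such a close relative;
    edges are all pairwise totals within the node set.
    """
    close = set(connections.loc[connections["total_cM"] >= close_cM,
                                "participant_id"])
    if not close:
        return ClusterSet([], 0.0)
    nodes = set(close)
    for s in summaries:
        if s.total_cM >= expand_cM:
            if s.id1 in close:
                nodes.add(s.id2)
            if s.id2 in close:
                nodes.add(s.id1)
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for s in summaries:
        if s.id1 in nodes and s.id2 in nodes:
            g.add_edge(s.id1, s.id2, weight=s.total_cM)
    return cluster_graph(g, resolution=resolution, seed=seed)


def to_graphml(g: nx.Graph, path, metadata: pd.DataFrame | None = None,
               attr_cols: list[str] | None = None) -> None:
    """GraphML export with optional node attributes from metadata."""
    h = g.copy()
    # GraphML has no list type; flatten the pruning log
    if isinstance(h.graph.get("pruned"), list):
        h.graph["pruned"] = ",".join(h.graph["pruned"])
    if metadata is not None and attr_cols:
        meta = metadata.set_index("participant_id")
        for n in h.nodes:
            if n in meta.index:
                for c in attr_cols:
                    h.nodes[n][c] = meta.loc[n, c]
    nx.write_graphml(h, str(path))
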