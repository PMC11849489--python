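"""CDR3 similarity network with random-walk communities.

The workflow mirrors how repertoire similarity networks are commonly built:

1. cluster similar CDR3s (length-stratified single-linkage under Hamming
   distance; an import hook accepts externally produced cluster tables);
2. compute pairwise Hamming distances within clusters (length strata make
   an explicit multiple alignment the identity, so no aligner is invoked;
   an import hook accepts an external alignment for variable-length use);
3. link two sequences when their Hamming distance is below a threshold
   (default 3, i.e. at most two substitutions);
4. weight nodes by combining betweenness centrality and degree, min-max
   scaled within each connected component;
5. partition the graph with walktrap random-walk community detection;
6. summarize each community as a frequency-weighted position weight matrix
   (members share one length by construction).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import igraph as ig
import networkx as nx
import numpy as np
import pandas as pd

from .errors import EmptyInputError
from .features import PositionWeightMatrix, pwm_from_sequences
from .model import Repertoire


def hamming_distance(a: str, b: str) -> int:
    """Number of mismatching positions between equal-length strings."""
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a, b))


def _encode(seqs: list[str]) -> np.ndarray:
    """Stack equal-length sequences into a byte matrix for vector Hamming."""
    return np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8).reshape(
        len(seqs), -1
    )


def _pairwise_hamming(seqs: list[str]) -> np.ndarray:
    mat = _encode(seqs)
    return (mat[:, None, :] != mat[None, :, :]).sum(axis=2)


@dataclass
class ClusterSet:
    """A partition of unique CDR3s into similarity clusters.

    Clusters are stored as lists of sequences; every cluster is
    single-length by construction of :func:`cluster_cdr3` (imported cluster
    tables may relax this, in which case only equal-length pairs can ever be
    linked downstream).
    """

    clusters: list[list[str]]
    assignment: dict[str, int]
    max_intra_distance: int = 2
    length_stratified: bool = True


def cluster_cdr3(rep: Repertoire, max_intra_distance: int = 2) -> ClusterSet:
    """Length-stratified single-linkage clustering under Hamming distance.

    Sequences of different lengths never co-cluster.  Within a length
    stratum, connected components of the ``distance <= max_intra_distance``
    graph form the clusters; singletons are kept.
    """
    seqs = sorted(set(rep.sequences))
    clusters: list[list[str]] = []
    by_length: dict[int, list[str]] = {}
    for s in seqs:
        by_length.setdefault(len(s), []).append(s)
    for length in sorted(by_length):
        stratum = by_length[length]
        if len(stratum) == 1:
            clusters.append(stratum)
            continue
        dist = _pairwise_hamming(stratum)
        adj = dist <= max_intra_distance
        g = ig.Graph.Adjacency(adj.tolist(), mode="undirected")
        for comp in g.connected_components():
            clusters.append([stratum[i] for i in comp])
    assignment = {s: i for i, members in enumerate(clusters) for s in members}
    return ClusterSet(
        clusters=clusters, assignment=assignment, max_intra_distance=max_intra_distance
    )


def read_cluster_table(path: str | Path) -> ClusterSet:
    """Import an externally produced cluster table (sequence TAB cluster-id).

    A header line is tolerated.  This is the hook for substituting clusters
    from a dedicated large-scale clustering tool.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, header=None, comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two tab-separated columns")
    first = str(df.iloc[0, 0])
    if any(ch not in "ACDEFGHIKLMNPQRSTVWY" for ch in first):
        df = df.iloc[1:]
    groups: dict[str, list[str]] = {}
    for seq, cid in zip(df.iloc[:, 0], df.iloc[:, 1]):
        groups.setdefault(str(cid), []).append(str(seq).upper())
    clusters = [groups[cid] for cid in sorted(groups)]
    assignment = {s: i for i, members in enumerate(clusters) for s in members}
    return ClusterSet(
        clusters=clusters,
        assignment=assignment,
        max_intra_distance=-1,
        length_stratified=False,
    )


@dataclass
class TCRNetwork:
    """A Hamming-proximity graph over unique CDR3s.

    ``graph`` is an undirected :class:`networkx.Graph` whose nodes are CDR3
    strings with attributes ``frequency``, ``count``, and after
    :func:`node_weights` also ``degree``, ``betweenness``, ``weight``.
    Edges carry ``hamming_distance``.
    """

    graph: nx.Graph
    link_threshold: int = 3
    communities: dict[str, int] = field(default_factory=dict)
    community_logos: dict[int, PositionWeightMatrix] = field(default_factory=dict)

    @property
    def nodes(self):
        return self.graph.nodes

    @property
    def edges(self):
        return self.graph.edges


def build_network(
    rep: Repertoire, clusters: ClusterSet | None = None, link_threshold: int = 3
) -> TCRNetwork:
    """Link within-cluster sequence pairs whose Hamming distance is below
    ``link_threshold``; cross-cluster edges are never created."""
    if len(rep) == 0:
        raise EmptyInputError(f"repertoire {rep.sample_id} has no clonotypes")
    if clusters is None:
        clusters = cluster_cdr3(rep)
    freq = {}
    count = {}
    for c in rep.clonotypes:
        freq[c.cdr3_aa] = freq.get(c.cdr3_aa, 0.0) + c.frequency
        count[c.cdr3_aa] = count.get(c.cdr3_aa, 0) + c.count
    g = nx.Graph()
    for members in clusters.clusters:
        for s in members:
            g.add_node(s, frequency=freq.get(s, 0.0), count=count.get(s, 0))
        by_length: dict[int, list[str]] = {}
        for s in members:
            by_length.setdefault(len(s), []).append(s)
        for stratum in by_length.values():
            if len(stratum) < 2:
                continue
            dist = _pairwise_hamming(stratum)
            ii, jj = np.nonzero((dist > 0) & (dist < link_threshold))
            for i, j in zip(ii, jj):
                if i < j:
                    g.add_edge(
                        stratum[i], stratum[j], hamming_distance=int(dist[i, j])
                    )
    return TCRNetwork(graph=g, link_threshold=link_threshold)


def _minmax(values: np.ndarray) -> np.ndarray:
    lo, hi = values.min(), values.max()
    if hi - lo < 1e-15:
        return np.full_like(values, 0.5, dtype=float)
    return (values - lo) / (hi - lo)


def node_weights(
    net: TCRNetwork, betweenness_coef: float = 0.5, degree_coef: float = 0.5
) -> TCRNetwork:
    """Attach degree, betweenness and a combined node weight.

    Betweenness is shortest-path betweenness centrality on unweighted
    edges.  Both measures are min-max scaled within each connected
    component (a constant component maps to 0.5) and combined as a convex
    sum, so isolated nodes get weight 0.5.
    """
    g = net.graph
    betweenness = nx.betweenness_centrality(g, normalized=True)
    for comp in nx.connected_components(g):
        nodes = sorted(comp)
        b = _minmax(np.array([betweenness[n] for n in nodes]))
        d = _minmax(np.array([g.degree(n) for n in nodes], dtype=float))
        for n, bb, dd in zip(nodes, b, d):
            g.nodes[n]["degree"] = g.degree(n)
            g.nodes[n]["betweenness"] = float(betweenness[n])
            g.nodes[n]["weight"] = float(betweenness_coef * bb + degree_coef * dd)
    return net


def detect_communities(net: TCRNetwork, steps: int = 4, seed: int = 0) -> TCRNetwork:
    """Walktrap random-walk community detection (walk length ``steps``).

    The walktrap agglomeration is deterministic; ``seed`` is accepted for
    interface stability with stochastic alternatives.  Isolated nodes form
    singleton communities and every node receives exactly one community id.
    """
    g = net.graph
    nodes = sorted(g.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    edges = [(index[u], index[v]) for u, v in g.edges]
    if not edges:
        net.communities = {n: i for i, n in enumerate(nodes)}
    else:
        graph = ig.Graph(n=len(nodes), edges=edges)
        membership = graph.community_walktrap(steps=steps).as_clustering().membership
        net.communities = {n: int(membership[index[n]]) for n in nodes}
    for n, cid in net.communities.items():
        g.nodes[n]["community"] = cid
    return net


def community_logos(
    net: TCRNetwork, rep: Repertoire | None = None
) -> dict[int, PositionWeightMatrix]:
    """Frequency-weighted PWM per community.

    Members of a community share one length because communities live inside
    length-stratified clusters.
    """
    if not net.communities:
        raise EmptyInputError("communities not assigned; run detect_communities first")
    groups: dict[int, list[str]] = {}
    for n, cid in net.communities.items():
        groups.setdefault(cid, []).append(n)
    logos = {}
    for cid, members in sorted(groups.items()):
        members = sorted(members)
        weights = [net.graph.nodes[m].get("frequency", 1.0) or 1.0 for m in members]
        logos[cid] = pwm_from_sequences(members, weights)
    net.community_logos = logos
    return logos


def to_node_table(net: TCRNetwork) -> pd.DataFrame:
    rows = []
    for n, attrs in sorted(net.graph.nodes(data=True)):
        rows.append(
            {
                "cdr3_aa": n,
                "frequency": attrs.get("frequency", 0.0),
                "count": attrs.get("count", 0),
                "degree": attrs.get("degree", net.graph.degree(n)),
                "betweenness": attrs.get("betweenness", float("nan")),
                "weight": attrs.get("weight", float("nan")),
                "community": attrs.get("community", -1),
            }
        )
    return pd.DataFrame(rows)


def to_edge_table(net: TCRNetwork) -> pd.DataFrame:
    rows = [
        {"source": min(u, v), "target": max(u, v), "hamming_distance": d}
        for u, v, d in net.graph.edges(data="hamming_distance")
    ]
    df = pd.DataFrame(rows, columns=["source", "target", "hamming_distance"])
    return df.sort_values(["source", "target"]).reset_index(drop=True)


def write_graphml(net: TCRNetwork, path: str | Path) -> None:
    nx.write_graphml(net.graph, str(path))
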