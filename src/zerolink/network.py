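"""Signed association networks: construction, topology metrics, hubs, consensus.

Co-occurrence networks keep only strong positive associations, co-exclusive
networks only strong negative ones (strict cutoffs |r| > 0.6, p < 0.001 by
default). Topology metrics follow the Cytoscape NetworkAnalyzer conventions;
consensus networks intersect edge sets across runs to expose what survives a
change of zero policy or correlation method.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .correlation import PairCorrelation
from .profile import ProfileError

log = logging.getLogger(__name__)

__all__ = [
    "AssociationNetwork",
    "NetworkMetrics",
    "build_network",
    "compute_metrics",
    "hub_subnetwork",
    "consensus_network",
    "overlap_counts",
    "export_network",
    "import_edge_tsv",
]

KINDS = ("co_occurrence", "co_exclusive", "mixed")


@dataclass
class AssociationNetwork:
    """Undirected signed graph of microbial associations.

    Edges carry ``sign`` ('+' or '-') and ``weight`` (the correlation
    coefficient). A co_occurrence network holds only '+' edges, a
    co_exclusive network only '-'.
    """

    graph: nx.Graph
    kind: str
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ProfileError(f"unknown network kind {self.kind!r}")
        for u, v, data in self.graph.edges(data=True):
            if u == v:
                raise ProfileError("self-loops are not allowed")
            sign = data.get("sign")
            if sign not in ("+", "-"):
                raise ProfileError(f"edge ({u}, {v}) missing sign")
            if self.kind == "co_occurrence" and sign != "+":
                raise ProfileError("co_occurrence network contains a negative edge")
            if self.kind == "co_exclusive" and sign != "-":
                raise ProfileError("co_exclusive network contains a positive edge")

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_set(self) -> set[tuple[str, str, str]]:
        """Canonical (min_id, max_id, sign) triples."""
        return {
            (min(u, v), max(u, v), d["sign"])
            for u, v, d in self.graph.edges(data=True)
        }


def build_network(
    results: Sequence[PairCorrelation],
    r_cutoff: float = 0.6,
    p_cutoff: float = 0.001,
    kind: str = "co_occurrence",
) -> AssociationNetwork:
    """Threshold pair correlations into a signed network.

    Strict cutoffs: an edge is kept iff ``p < p_cutoff`` and ``r > r_cutoff``
    (co_occurrence), ``r < -r_cutoff`` (co_exclusive), or ``|r| > r_cutoff``
    (mixed). Nodes are the endpoints of kept edges. All input records must
    come from a single method/policy combination.
    """
    if kind not in KINDS:
        raise ProfileError(f"unknown network kind {kind!r}")
    combos = {(c.method, c.policy) for c in results}
    if len(combos) > 1:
        raise ProfileError(f"mixed method/policy combinations in input: {sorted(combos)}")
    g = nx.Graph()
    for c in results:
        if not (c.p < p_cutoff) or math.isnan(c.p):
            continue
        if kind == "co_occurrence" and not c.r > r_cutoff:
            continue
        if kind == "co_exclusive" and not c.r < -r_cutoff:
            continue
        if kind == "mixed" and not abs(c.r) > r_cutoff:
            continue
        u, v = sorted((c.taxon_i, c.taxon_j))
        g.add_edge(u, v, sign="+" if c.r > 0 else "-", weight=float(c.r))
    prov = {"r_cutoff": r_cutoff, "p_cutoff": p_cutoff}
    if combos:
        (method, policy), = combos
        prov.update(method=method, policy=policy)
    return AssociationNetwork(g, kind, prov)


@dataclass(frozen=True)
class NetworkMetrics:
    """Topology summary; NaN marks metrics undefined for the graph at hand."""

    n_nodes: int
    n_edges: int
    avg_neighbors: float
    diameter: float
    radius: float
    characteristic_path_length: float
    clustering_coefficient: float
    density: float
    heterogeneity: float
    centralization: float
    n_components: int


def compute_metrics(network: AssociationNetwork) -> NetworkMetrics:
    """Topology metrics under Cytoscape NetworkAnalyzer definitions.

    density = 2E / (N(N-1)); avg_neighbors = 2E / N; heterogeneity =
    sqrt(var(degree)) / mean(degree); centralization = N/(N-2) *
    (max_degree/(N-1) - density). The characteristic path length averages
    shortest paths over all connected node pairs; diameter and radius are
    taken on the largest connected component (per-component values are
    logged). Metrics undefined for very small graphs come back as NaN.
    """
    g = network.graph
    N, E = g.number_of_nodes(), g.number_of_edges()
    nan = float("nan")
    if N == 0:
        return NetworkMetrics(0, 0, nan, nan, nan, nan, nan, nan, nan, nan, 0)
    degrees = np.array([d for _, d in g.degree()], dtype=float)
    avg_neighbors = 2.0 * E / N
    density = 2.0 * E / (N * (N - 1)) if N > 1 else nan
    mean_deg = degrees.mean()
    heterogeneity = float(np.sqrt(degrees.var()) / mean_deg) if mean_deg > 0 else nan
    if N > 2 and not math.isnan(density):
        centralization = (N / (N - 2.0)) * (degrees.max() / (N - 1.0) - density)
    else:
        centralization = nan
    clustering = float(nx.average_clustering(g)) if N > 0 else nan

    components = sorted(nx.connected_components(g), key=lambda c: (-len(c), min(c)))
    n_components = len(components)
    total_len, total_pairs = 0.0, 0
    diameters = []
    radii = []
    for comp in components:
        sub = g.subgraph(comp)
        if len(comp) > 1:
            ecc = nx.eccentricity(sub)
            diameters.append(max(ecc.values()))
            radii.append(min(ecc.values()))
            for _, dists in nx.all_pairs_shortest_path_length(sub):
                total_len += sum(dists.values())
            total_pairs += len(comp) * (len(comp) - 1)
        else:
            diameters.append(0)
            radii.append(0)
    cpl = total_len / total_pairs if total_pairs else nan
    diameter = float(diameters[0]) if components and len(components[0]) > 1 else nan
    radius = float(radii[0]) if components and len(components[0]) > 1 else nan
    log.info("compute_metrics: per-component diameters %s, radii %s", diameters, radii)
    return NetworkMetrics(
        n_nodes=N, n_edges=E, avg_neighbors=avg_neighbors,
        diameter=diameter, radius=radius, characteristic_path_length=cpl,
        clustering_coefficient=clustering, density=density,
        heterogeneity=heterogeneity, centralization=centralization,
        n_components=n_components,
    )


def hub_subnetwork(network: AssociationNetwork, top_k: int = 10) -> AssociationNetwork:
    """Induced subgraph on the ``top_k`` most connected nodes and their first neighbors.

    Degree ties at the boundary are broken by lexicographic taxon ID
    (deterministic) and recorded in provenance.
    """
    g = network.graph
    if g.number_of_nodes() == 0:
        raise ProfileError("hub_subnetwork of an empty network")
    ranked = sorted(g.nodes, key=lambda n: (-g.degree(n), n))
    hubs = ranked[:top_k]
    tie_note = None
    if len(ranked) > top_k and g.degree(ranked[top_k - 1]) == g.degree(ranked[top_k]):
        tied = [n for n in ranked if g.degree(n) == g.degree(ranked[top_k - 1])]
        tie_note = {"tied_degree": g.degree(ranked[top_k - 1]), "tied_nodes": tied}
        log.info("hub_subnetwork: degree tie at rank %d among %s", top_k, tied)
    keep = set(hubs)
    for h in hubs:
        keep.update(g.neighbors(h))
    sub = g.subgraph(keep).copy()
    prov = {**network.provenance, "hubs": hubs, "top_k": top_k}
    if tie_note:
        prov["degree_tie"] = tie_note
    return AssociationNetwork(sub, network.kind, prov)


def consensus_network(networks: Sequence[AssociationNetwork]) -> AssociationNetwork:
    """Intersect edge sets (unordered pair + sign) across networks.

    Nodes of the consensus are the endpoints of surviving edges; each edge's
    weight is the mean of the member weights. All members must share a kind.
    """
    if not networks:
        raise ProfileError("consensus of zero networks")
    kinds = {n.kind for n in networks}
    if len(kinds) > 1:
        raise ProfileError(f"cannot take consensus across kinds {sorted(kinds)}")
    shared = set.intersection(*(n.edge_set() for n in networks))
    g = nx.Graph()
    for u, v, sign in sorted(shared):
        weights = [n.graph[u][v]["weight"] for n in networks]
        g.add_edge(u, v, sign=sign, weight=float(np.mean(weights)))
    return AssociationNetwork(
        g, kinds.pop(),
        {"consensus_of": [n.provenance for n in networks], "n_members": len(networks)},
    )


def overlap_counts(
    net_a: AssociationNetwork, net_b: AssociationNetwork
) -> tuple[int, int]:
    """(shared edges, shared nodes) between two networks of the same kind.

    Shared edges match on unordered pair and sign; shared nodes are the bare
    node-set intersection (endpoints of shared edges are available through
    :func:`consensus_network` for the alternative reading).
    """
    if net_a.kind != net_b.kind:
        raise ProfileError("overlap_counts requires networks of the same kind")
    shared_edges = net_a.edge_set() & net_b.edge_set()
    shared_nodes = net_a.nodes & net_b.nodes
    return len(shared_edges), len(shared_nodes)


# -- export / import -------------------------------------------------------


def export_network(network: AssociationNetwork, path: str | Path, format: str = "edge_tsv") -> None:
    """Write a network as GraphML (for Cytoscape) or an edge TSV."""
    path = Path(path)
    if format == "graphml":
        g = nx.Graph()
        g.add_nodes_from(network.graph.nodes)
        for u, v, d in network.graph.edges(data=True):
            g.add_edge(u, v, sign=d["sign"], weight=float(d["weight"]))
        nx.write_graphml(g, path)
    elif format == "edge_tsv":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("source\ttarget\tsign\tweight\n")
            for u, v, sign in sorted(network.edge_set()):
                fh.write(f"{u}\t{v}\t{sign}\t{network.graph[u][v]['weight']!r}\n")
    else:
        raise ProfileError(f"unknown export format {format!r}")


def import_edge_tsv(path: str | Path, kind: str = "mixed") -> AssociationNetwork:
    """Read an edge TSV written by :func:`export_network`."""
    g = nx.Graph()
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["source", "target", "sign", "weight"]:
            raise ProfileError(f"unexpected edge TSV header: {header}")
        for line in fh:
            u, v, sign, weight = line.rstrip("\n").split("\t")
            g.add_edge(u, v, sign=sign, weight=float(weight))
    return AssociationNetwork(g, kind, {"source": str(path)})
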