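"""Median-joining haplotype networks.

Works on the complete-deletion-reduced haplotype strings of a catalog.
The algorithm iterates: build the epsilon-relaxed minimum spanning network
(MSN) over the current node set, generate consensus (median) vectors from
linked triplets at minimal connection cost, and repeat until no new medians
appear. Median vectors that end up with degree <= 2 are pruned (degree-2
medians lying on a geodesic are contracted). The result is the MSN over the
final node set: every observed-haplotype MSN edge is represented either
directly or by a geodesic path through median vectors.
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np

from .errors import InputError
from .haplotypes import HaplotypeCatalog

log = logging.getLogger("phylopop.network")


def _hamming(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def minimum_spanning_network(
    nodes: dict[str, str], epsilon: int = 0
) -> set[tuple[str, str]]:
    """Edges of the epsilon-relaxed minimum spanning network.

    ``nodes`` maps label -> sequence. An edge of weight w is feasible when
    its endpoints are in different connected components of the graph built
    from all edges of weight < w - epsilon.
    """
    labels = sorted(nodes)
    dist = {
        (a, b): _hamming(nodes[a], nodes[b])
        for a, b in itertools.combinations(labels, 2)
    }
    weights = sorted(set(dist.values()))
    edges: set[tuple[str, str]] = set()
    for w in weights:
        uf = nx.utils.UnionFind(labels)
        for (a, b), d in dist.items():
            if d < w - epsilon:
                uf.union(a, b)
        for (a, b), d in sorted(dist.items()):
            if d == w and uf[a] != uf[b]:
                edges.add((a, b))
    return edges


def _median_sequence(x: str, y: str, z: str) -> str:
    """Per-column majority consensus; all-distinct columns take z's state.

    z is the shared node of the triplet (the one linked to both x and y), so
    the tie-break keeps the median on a path through the link structure.
    """
    out = []
    for cx, cy, cz in zip(x, y, z):
        if cx == cy or cx == cz:
            out.append(cx)
        elif cy == cz:
            out.append(cy)
        else:
            out.append(cz)
    return "".join(out)


@dataclass(frozen=True)
class MJNetwork:
    """Median-joining network with observed and inferred (median) nodes."""

    graph: nx.Graph
    epsilon: int

    @property
    def observed_nodes(self) -> tuple[str, ...]:
        return tuple(
            n for n, d in self.graph.nodes(data=True) if not d["median"]
        )

    @property
    def median_nodes(self) -> tuple[str, ...]:
        return tuple(n for n, d in self.graph.nodes(data=True) if d["median"])

    @property
    def star_likeness(self) -> float:
        """Max node degree / number of observed haplotypes (diagnostic)."""
        n_obs = len(self.observed_nodes)
        if n_obs == 0:
            return 0.0
        return max(dict(self.graph.degree).values(), default=0) / n_obs

    def geodesic_weight(self, a: str, b: str) -> int:
        return nx.shortest_path_length(self.graph, a, b, weight="weight")

    def write_edges_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("node_a\tnode_b\tsteps\n")
            for a, b, d in sorted(self.graph.edges(data=True)):
                fh.write(f"{a}\t{b}\t{d['weight']}\n")

    def to_dict(self) -> dict:
        return {
            "epsilon": self.epsilon,
            "nodes": [
                {
                    "id": n,
                    "median": d["median"],
                    "frequency": d.get("frequency", 0),
                    "populations": d.get("populations", {}),
                }
                for n, d in sorted(self.graph.nodes(data=True))
            ],
            "edges": [
                {"a": a, "b": b, "steps": d["weight"]}
                for a, b, d in sorted(self.graph.edges(data=True))
            ],
            "star_likeness": self.star_likeness,
        }


def median_joining(
    cat: HaplotypeCatalog, epsilon: int = 0, seed: int | None = None
) -> MJNetwork:
    """Build a median-joining network from a haplotype catalog.

    Deterministic for a fixed input: ties are broken by (weight,
    lexicographic label); ``seed`` is accepted for interface symmetry but
    unused. Requires a catalog with sequences.
    """
    if not cat.keys and not cat.sequences:
        raise InputError("catalog has no sequences to build a network from")
    seqs = cat.keys if cat.keys else cat.sequences
    nodes: dict[str, str] = dict(zip(cat.labels, seqs))
    if len(set(nodes.values())) != len(nodes):
        raise InputError("catalog contains duplicate haplotype sequences")
    if len(nodes) == 1:
        g = nx.Graph()
        g.add_node(next(iter(nodes)))
        _decorate(g, cat, nodes)
        return MJNetwork(graph=g, epsilon=epsilon)

    n_median = 0
    for _ in range(64):  # convergence cap; tiny networks converge in 1-2
        edges = minimum_spanning_network(nodes, epsilon=epsilon)
        adjacency: dict[str, set[str]] = {lab: set() for lab in nodes}
        for a, b in edges:
            adjacency[a].add(b)
            adjacency[b].add(a)
        candidates: dict[str, tuple[int, str]] = {}
        best_cost = None
        for z in sorted(nodes):
            for x, y in itertools.combinations(sorted(adjacency[z]), 2):
                m = _median_sequence(nodes[x], nodes[y], nodes[z])
                if m in nodes.values() or m in candidates:
                    continue
                cost = (
                    _hamming(m, nodes[x])
                    + _hamming(m, nodes[y])
                    + _hamming(m, nodes[z])
                )
                candidates[m] = (cost, z)
                if best_cost is None or cost < best_cost:
                    best_cost = cost
        if not candidates:
            break
        added = False
        for m, (cost, _z) in sorted(candidates.items(), key=lambda kv: (kv[1][0], kv[0])):
            if cost <= best_cost + epsilon:
                n_median += 1
                nodes[f"mv{n_median}"] = m
                added = True
        if not added:
            break
    # final MSN over the augmented node set
    edges = minimum_spanning_network(nodes, epsilon=epsilon)
    g = nx.Graph()
    for lab in nodes:
        g.add_node(lab)
    for a, b in edges:
        g.add_edge(a, b, weight=_hamming(nodes[a], nodes[b]))
    _prune_medians(g, nodes, set(cat.labels))
    # keep every observed-MSN connection: an MSN edge may be dropped only
    # when an equal-weight geodesic through median vectors replaces it
    observed_only = {lab: nodes[lab] for lab in cat.labels}
    for a, b in minimum_spanning_network(observed_only, epsilon=epsilon):
        w = _hamming(nodes[a], nodes[b])
        try:
            via = nx.shortest_path_length(g, a, b, weight="weight")
        except nx.NetworkXNoPath:
            via = None
        if via is None or via > w:
            g.add_edge(a, b, weight=w)
    _prune_medians(g, nodes, set(cat.labels))
    _decorate(g, cat, nodes)
    log.info(
        "MJ network: %d observed, %d medians, %d edges",
        len(cat.labels), len(g) - len(cat.labels), g.number_of_edges(),
    )
    return MJNetwork(graph=g, epsilon=epsilon)


def _prune_medians(g: nx.Graph, nodes: dict[str, str], observed: set[str]) -> None:
    """Drop median vectors of degree <= 2 (contracting geodesic pass-throughs)."""
    changed = True
    while changed:
        changed = False
        for lab in sorted(g.nodes):
            if lab in observed:
                continue
            deg = g.degree(lab)
            if deg <= 1:
                g.remove_node(lab)
                changed = True
            elif deg == 2:
                u, v = list(g.neighbors(lab))
                d_direct = _hamming(nodes[u], nodes[v])
                via = g[lab][u]["weight"] + g[lab][v]["weight"]
                if via >= d_direct:
                    g.remove_node(lab)
                    if not g.has_edge(u, v):
                        g.add_edge(u, v, weight=d_direct)
                    changed = True


def _decorate(g: nx.Graph, cat: HaplotypeCatalog, nodes: dict[str, str]) -> None:
    pooled = dict(zip(cat.labels, cat.pooled_counts))
    for lab in g.nodes:
        is_median = lab not in pooled
        g.nodes[lab]["median"] = is_median
        g.nodes[lab]["frequency"] = 0 if is_median else int(pooled[lab])
        if not is_median:
            h = cat.labels.index(lab)
            comp = {
                pop: int(cat.counts[p, h])
                for p, pop in enumerate(cat.populations)
                if cat.counts[p, h] > 0
            }
            g.nodes[lab]["populations"] = comp
        else:
            g.nodes[lab]["populations"] = {}
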