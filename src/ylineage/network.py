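"""Weighted median-joining networks of Y-STR haplotypes.

Distances are weighted L1 on repeat counts (each unit difference is one
mutational step under the single-step model). Locus weights follow the
inverse-variance convention used by the Network software: rapidly mutating
loci carry little phylogenetic signal and get low weight. The median-joining
construction alternates between the epsilon-relaxed minimum spanning network
and the insertion of quasi-median (coordinate-wise median) Steiner vectors,
then prunes median vectors that no longer shorten the network.
"""

from __future__ import annotations

import itertools
import json
import logging
from collections.abc import Sequence
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.sparse.csgraph import minimum_spanning_tree as _scipy_mst

from .profiles import STRProfile, active_loci, allele_matrix

logger = logging.getLogger(__name__)

MAX_WEIGHT = 99
MIN_WEIGHT = 1


def compute_str_weights(
    profiles: Sequence[STRProfile], scheme: str = "muzzio"
) -> dict[str, int]:
    """Integer locus weights in [1, 99].

    scheme="muzzio": weight inversely proportional to the locus's allele
    variance across the profiles, scaled so the most variable locus gets
    weight 1, rounded and clamped to [1, 99]; zero-variance loci get the
    maximum weight. scheme="uniform": every locus weighs 1.
    """
    if not profiles:
        raise ValueError("empty profile collection")
    loci = active_loci(profiles)
    if scheme == "uniform":
        return {l: 1 for l in loci}
    if scheme != "muzzio":
        raise ValueError(f"unknown weight scheme {scheme!r}")
    mat, loci = allele_matrix(profiles, loci)
    var = mat.var(axis=0)
    vmax = var.max()
    weights = {}
    for l, v in zip(loci, var):
        if v == 0 or vmax == 0:
            weights[l] = MAX_WEIGHT
        else:
            raw = vmax / v  # most variable locus -> 1
            weights[l] = int(min(MAX_WEIGHT, max(MIN_WEIGHT, round(raw))))
    return weights


def _weight_vector(loci: Sequence[str], weights: dict[str, int] | None) -> np.ndarray:
    if weights is None:
        return np.ones(len(loci), dtype=np.int64)
    return np.array([int(weights[l]) for l in loci], dtype=np.int64)


def weighted_steps(x, y, wvec) -> int:
    return int(np.abs(np.asarray(x) - np.asarray(y)).dot(wvec))


def _distance_matrix(haps: Sequence[tuple], wvec: np.ndarray) -> np.ndarray:
    arr = np.asarray(haps, dtype=np.int64)
    diff = np.abs(arr[:, None, :] - arr[None, :, :])
    return diff.dot(wvec)


def _bottleneck_matrix(dist: np.ndarray) -> np.ndarray:
    """Minimax path distances: max edge weight on the (any) MST path.

    Identical across all MSTs, hence independent of tie-breaking.
    """
    n = dist.shape[0]
    mst = _scipy_mst(dist).toarray()
    adj: list[list[tuple[int, float]]] = [[] for _ in range(n)]
    for i in range(n):
        for j in range(n):
            if mst[i, j] > 0:
                adj[i].append((j, mst[i, j]))
                adj[j].append((i, mst[i, j]))
    bottleneck = np.zeros((n, n))
    for src in range(n):
        seen = {src}
        stack = [(src, 0.0)]
        while stack:
            node, best = stack.pop()
            for nxt, w in adj[node]:
                if nxt not in seen:
                    seen.add(nxt)
                    b = max(best, w)
                    bottleneck[src, nxt] = b
                    stack.append((nxt, b))
    return bottleneck


def minimum_spanning_network(
    haps: Sequence[tuple], wvec: np.ndarray, epsilon: float = 0.0
) -> list[tuple[int, int]]:
    """Edges (i, j) of the epsilon-relaxed minimum spanning network.

    An edge is kept iff d(u, v) <= bottleneck(u, v) + epsilon; at epsilon=0
    this is exactly the union of all minimum spanning trees, so the result
    is canonical and connected.
    """
    n = len(haps)
    if n == 1:
        return []
    dist = _distance_matrix(haps, wvec)
    bottleneck = _bottleneck_matrix(dist.astype(float))
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            if dist[i, j] <= bottleneck[i, j] + epsilon:
                edges.append((i, j))
    return edges


@dataclass
class MJNetwork:
    """A median-joining network over observed and inferred haplotypes."""

    graph: nx.Graph
    loci: tuple[str, ...]
    weights: dict[str, int]
    epsilon: float = 0.0

    @property
    def observed_nodes(self) -> list[int]:
        return [n for n, d in self.graph.nodes(data=True) if d["kind"] == "observed"]

    @property
    def median_nodes(self) -> list[int]:
        return [n for n, d in self.graph.nodes(data=True) if d["kind"] == "median"]

    def total_length(self) -> float:
        return sum(d["weight"] for _, _, d in self.graph.edges(data=True))

    def frequency_sum(self) -> int:
        return sum(d["frequency"] for _, d in self.graph.nodes(data=True))

    def haplotype_of(self, node: int) -> tuple[int, ...]:
        return tuple(self.graph.nodes[node]["haplotype"])


def build_mj_network(
    profiles: Sequence[STRProfile],
    weights: dict[str, int] | None = None,
    epsilon: float = 0.0,
    max_medians: int | None = None,
) -> MJNetwork:
    """Median-joining network of the given STR profiles.

    1. Collapse identical haplotypes into frequency-weighted nodes
       (excluded loci, DYS385a/b by default, never enter distances).
    2. Compute the epsilon-relaxed minimum spanning network under the
       weighted single-step distance.
    3. For every triplet with at least two network links, propose the
       coordinate-wise median as a quasi-median vector; insert all
       candidates whose connection cost is within epsilon of the cheapest.
    4. Repeat until no candidate is inserted.
    5. Prune obsolete median vectors (degree <= 2 never shortens an L1
       Steiner topology) and recompute the network.
    """
    if not profiles:
        raise ValueError("empty profile collection")
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    loci = active_loci(profiles)
    excluded = set(profiles[0].alleles) - set(loci)
    if excluded:
        logger.info("loci excluded from network distances: %s", sorted(excluded))
    wvec = _weight_vector(loci, weights)
    wmap = weights or {l: 1 for l in loci}

    members: dict[tuple, list[STRProfile]] = {}
    for p in profiles:
        members.setdefault(p.vector(loci), []).append(p)
    observed = sorted(members)  # lexicographic: deterministic node order
    if max_medians is None:
        max_medians = max(50, 10 * len(observed))

    nodes: list[tuple] = list(observed)
    node_set = set(nodes)
    for _ in range(200):  # safety bound; lattice growth terminates long before
        edges = minimum_spanning_network(nodes, wvec, epsilon)
        adj: dict[int, set[int]] = {i: set() for i in range(len(nodes))}
        for i, j in edges:
            adj[i].add(j)
            adj[j].add(i)
        candidates: dict[tuple, float] = {}
        for u in range(len(nodes)):
            for v, w in itertools.combinations(sorted(adj[u]), 2):
                trip = np.array([nodes[u], nodes[v], nodes[w]], dtype=np.int64)
                med = tuple(int(x) for x in np.median(trip, axis=0))
                if med in node_set:
                    continue
                cost = sum(weighted_steps(med, nodes[k], wvec) for k in (u, v, w))
                if med not in candidates or cost < candidates[med]:
                    candidates[med] = cost
        if not candidates:
            break
        lam = min(candidates.values())
        new = sorted(m for m, c in candidates.items() if c <= lam + epsilon)
        room = max_medians - (len(nodes) - len(observed))
        if room <= 0:
            logger.warning("median insertion stopped: max_medians=%d reached", max_medians)
            break
        for m in new[:room]:
            nodes.append(m)
            node_set.add(m)

    # prune obsolete medians, iterating because degrees change on removal
    while True:
        edges = minimum_spanning_network(nodes, wvec, epsilon)
        degree = {i: 0 for i in range(len(nodes))}
        for i, j in edges:
            degree[i] += 1
            degree[j] += 1
        obsolete = [
            i for i, h in enumerate(nodes) if h not in members and degree[i] <= 2
        ]
        if not obsolete:
            break
        nodes = [h for i, h in enumerate(nodes) if i not in set(obsolete)]

    edges = minimum_spanning_network(nodes, wvec, epsilon)
    graph = nx.Graph()
    for i, hap in enumerate(nodes):
        profs = members.get(hap, [])
        pops: dict[str, int] = {}
        for p in profs:
            pops[p.population] = pops.get(p.population, 0) + 1
        graph.add_node(
            i,
            haplotype=hap,
            kind="observed" if profs else "median",
            frequency=len(profs),
            samples=tuple(p.sample_id for p in profs),
            populations=pops,
        )
    for i, j in edges:
        diff = {
            l: int(abs(a - b))
            for l, a, b in zip(loci, nodes[i], nodes[j])
            if a != b
        }
        graph.add_edge(i, j, weight=weighted_steps(nodes[i], nodes[j], wvec), steps=diff)
    return MJNetwork(graph=graph, loci=loci, weights=dict(wmap), epsilon=epsilon)


def export_network(net: MJNetwork, path, fmt: str = "graphml") -> None:
    """Write the network as GraphML, DOT or a TSV edge list."""
    if fmt == "graphml":
        g = nx.Graph()
        for n, d in net.graph.nodes(data=True):
            g.add_node(
                n,
                haplotype=json.dumps(list(d["haplotype"])),
                kind=d["kind"],
                frequency=int(d["frequency"]),
                samples=json.dumps(list(d["samples"])),
                populations=json.dumps(d["populations"]),
            )
        for u, v, d in net.graph.edges(data=True):
            g.add_edge(u, v, weight=float(d["weight"]), steps=json.dumps(d["steps"]))
        nx.write_graphml(g, path)
    elif fmt == "dot":
        # hand-rolled writer: the networkx DOT backends need pydot/pygraphviz
        lines = ["graph mjnetwork {"]
        for n, d in net.graph.nodes(data=True):
            label = f"{d['kind']}:{d['frequency']}"
            lines.append(f'  n{n} [label="{label}"];')
        for u, v, d in net.graph.edges(data=True):
            lines.append(f'  n{u} -- n{v} [label="{d["weight"]}"];')
        lines.append("}")
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")
    elif fmt == "tsv":
        with open(path, "w") as fh:
            fh.write("source\ttarget\tweight\tsteps\n")
            for u, v, d in net.graph.edges(data=True):
                fh.write(f"{u}\t{v}\t{d['weight']}\t{json.dumps(d['steps'])}\n")
    else:
        raise ValueError(f"unknown export format {fmt!r}")


def read_graphml_network(path) -> nx.Graph:
    """Round-trip reader for GraphML exports (JSON-decoded attributes)."""
    g = nx.read_graphml(path)
    out = nx.Graph()
    for n, d in g.nodes(data=True):
        out.add_node(
            int(n),
            haplotype=tuple(json.loads(d["haplotype"])),
            kind=d["kind"],
            frequency=int(d["frequency"]),
            samples=tuple(json.loads(d["samples"])),
            populations=json.loads(d["populations"]),
        )
    for u, v, d in g.edges(data=True):
        out.add_edge(int(u), int(v), weight=float(d["weight"]), steps=json.loads(d["steps"]))
    return out
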