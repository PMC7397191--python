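"""Median-joining networks of Y-STR haplotypes with rate-derived weights.

Haplotypes are vectors of allele sizes in tenths of a repeat unit
(micro-variant steps such as 37 -> 37.2 are exact 2-tenth steps), and the
distance between two haplotypes is the weighted Manhattan distance

    d(u, v) = sum_i w_i |u_i - v_i|

with integer locus weights in [1, 99] anti-monotone with mutation rate
(fast loci carry little phylogenetic signal, so they get low weight).

The network is built iteratively: compute the (epsilon-relaxed) minimum
spanning network over the current node set; for linked triples whose
coordinatewise median would strictly reduce the cost of connecting the
triple, add the median as an inferred node; repeat until no median is
added; finally prune inferred nodes of degree < 3.  With epsilon = 0 and
no cost-reducing medians the result is exactly the minimum spanning
network (the union of all minimum spanning trees).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import numpy as np

from .dataset import PopulationDataset
from .loci import DEFAULT_MUTATION_RATES


def derive_weights(rates: dict[str, float]) -> dict[str, int]:
    """Integer locus weights in [1, 99], inverse to mutation rate.

    weight_i = round(99 * min_rate / rate_i), clamped to at least 1; the
    slowest locus gets weight 99.  Scale-invariant: multiplying every
    rate by a constant leaves the weights unchanged.
    """
    if not rates:
        raise ValueError("empty rate table")
    if any(r <= 0 for r in rates.values()):
        raise ValueError("rates must be positive")
    m_min = min(rates.values())
    out = {}
    for name, r in rates.items():
        w = int(np.floor(99.0 * m_min / r + 0.5))  # round half-up
        out[name] = max(1, min(99, w))
    return out


HapVec = tuple[int, ...]  # allele sizes in tenths per locus


@dataclass(frozen=True)
class MJNode:
    vector: HapVec
    kind: str  # "observed" | "median"
    multiplicity: int = 0
    sample_ids: tuple[str, ...] = ()


def _distance(u: HapVec, v: HapVec, w: tuple[int, ...]) -> int:
    return sum(wi * abs(a - b) for wi, a, b in zip(w, u, v))


def _components_below(
    nodes: list[HapVec], edges: list[tuple[int, int, int]], threshold: float
) -> dict[int, int]:
    """Union-find components using edges strictly lighter than threshold."""
    parent = list(range(len(nodes)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j, d in edges:
        if d < threshold:
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[ri] = rj
    return {i: find(i) for i in range(len(nodes))}


def minimum_spanning_network(
    nodes: list[HapVec], weights: tuple[int, ...], epsilon: int = 0
) -> set[tuple[int, int]]:
    """Edges of the epsilon-relaxed minimum spanning network.

    An edge (u, v) of length d belongs to the network iff u and v fall in
    different components of the graph restricted to edges strictly
    shorter than d - epsilon; for epsilon = 0 this is exactly the union
    of all minimum spanning trees.
    """
    if epsilon < 0:
        raise ValueError("epsilon must be non-negative")
    edges = [
        (i, j, _distance(nodes[i], nodes[j], weights))
        for i, j in combinations(range(len(nodes)), 2)
    ]
    out: set[tuple[int, int]] = set()
    for d in sorted({e[2] for e in edges}):
        comp = _components_below(nodes, edges, d - epsilon)
        for i, j, dij in edges:
            if dij == d and comp[i] != comp[j]:
                out.add((i, j))
    return out


def _median_vector(u: HapVec, v: HapVec, w: HapVec) -> HapVec:
    return tuple(sorted(t)[1] for t in zip(u, v, w))


@dataclass
class MJGraph:
    """Median-joining network: observed and inferred haplotype nodes."""

    graph: nx.Graph  # nodes keyed by HapVec, attrs kind/multiplicity/sample_ids
    loci: tuple[str, ...]
    weights: tuple[int, ...]

    @property
    def observed(self) -> list[HapVec]:
        return [n for n, a in self.graph.nodes(data=True) if a["kind"] == "observed"]

    @property
    def medians(self) -> list[HapVec]:
        return [n for n, a in self.graph.nodes(data=True) if a["kind"] == "median"]

    def spanning_length(self) -> int:
        """Total weighted length of an MST within the final network."""
        t = nx.minimum_spanning_tree(self.graph, weight="length")
        return sum(d["length"] for _, _, d in t.edges(data=True))

    def _indexed(self) -> nx.Graph:
        """Copy with integer node ids and string attributes, for export."""
        order = {n: i for i, n in enumerate(sorted(self.graph.nodes))}
        g = nx.Graph()
        for n, a in self.graph.nodes(data=True):
            g.add_node(
                order[n],
                kind=a["kind"],
                multiplicity=int(a["multiplicity"]),
                haplotype=",".join(f"{x / 10:g}" for x in n),
            )
        for u, v, d in self.graph.edges(data=True):
            g.add_edge(
                order[u],
                order[v],
                length=int(d["length"]),
                loci_changed=",".join(d["loci_changed"]),
            )
        return g

    def write_gml(self, path) -> None:
        nx.write_gml(self._indexed(), path)

    def write_dot(self, path) -> None:
        g = self._indexed()
        with open(path, "w") as fh:
            fh.write("graph mj {\n")
            for n, a in g.nodes(data=True):
                shape = "circle" if a["kind"] == "observed" else "diamond"
                fh.write(
                    f'  {n} [label="{a["haplotype"]}" shape={shape} '
                    f'multiplicity={a["multiplicity"]}];\n'
                )
            for u, v, d in g.edges(data=True):
                fh.write(f'  {u} -- {v} [label="{d["length"]}"];\n')
            fh.write("}\n")

    def write_tables(self, node_path, edge_path) -> None:
        with open(node_path, "w") as fh:
            fh.write("id\tkind\tmultiplicity\thaplotype\tsamples\n")
            for idx, (n, a) in enumerate(sorted(self.graph.nodes(data=True))):
                hap = ",".join(f"{x / 10:g}" for x in n)
                fh.write(
                    f"{idx}\t{a['kind']}\t{a['multiplicity']}\t{hap}\t"
                    + ";".join(a["sample_ids"])
                    + "\n"
                )
        index = {n: i for i, (n, _) in enumerate(sorted(self.graph.nodes(data=True)))}
        with open(edge_path, "w") as fh:
            fh.write("u\tv\tlength\tloci_changed\n")
            for u, v, d in sorted(
                self.graph.edges(data=True), key=lambda e: (index[e[0]], index[e[1]])
            ):
                fh.write(
                    f"{index[u]}\t{index[v]}\t{d['length']}\t{','.join(d['loci_changed'])}\n"
                )


def build_network(
    haplotypes: dict[HapVec, tuple[int, tuple[str, ...]]],
    loci: tuple[str, ...],
    weights: dict[str, int],
    epsilon: int = 0,
    max_rounds: int = 25,
) -> MJGraph:
    """Median-joining network over observed haplotype vectors.

    ``haplotypes`` maps each distinct haplotype vector (tenths of repeat
    units, one slot per locus) to its (multiplicity, sample id) record.
    """
    if len(haplotypes) < 2:
        raise ValueError("need at least 2 distinct haplotypes")
    w = tuple(weights[l] for l in loci)
    observed = sorted(haplotypes)
    nodes: list[HapVec] = list(observed)
    node_set = set(nodes)

    for _ in range(max_rounds):
        links = minimum_spanning_network(nodes, w, epsilon)
        adj: dict[int, set[int]] = {i: set() for i in range(len(nodes))}
        for i, j in links:
            adj[i].add(j)
            adj[j].add(i)
        link_set = {frozenset(e) for e in links}
        new_medians: set[HapVec] = set()
        for i in range(len(nodes)):
            for j, k in combinations(sorted(adj[i]), 2):
                # triple with at least two feasible links (i-j and i-k)
                u, v, x = nodes[i], nodes[j], nodes[k]
                m = _median_vector(u, v, x)
                if m in node_set or m in new_medians:
                    continue
                duv = _distance(u, v, w)
                duw = _distance(u, x, w)
                dvw = _distance(v, x, w)
                star = _distance(u, m, w) + _distance(v, m, w) + _distance(x, m, w)
                direct = duv + duw + dvw - max(duv, duw, dvw)
                if star < direct:
                    new_medians.add(m)
        if not new_medians:
            break
        nodes.extend(sorted(new_medians))
        node_set.update(new_medians)
        nodes.sort()

    # prune inferred nodes of degree < 3, repeating until stable
    while True:
        links = minimum_spanning_network(nodes, w, epsilon)
        degree = {i: 0 for i in range(len(nodes))}
        for i, j in links:
            degree[i] += 1
            degree[j] += 1
        drop = {
            i
            for i in range(len(nodes))
            if nodes[i] not in haplotypes and degree[i] < 3
        }
        if not drop:
            break
        nodes = [n for i, n in enumerate(nodes) if i not in drop]

    g = nx.Graph()
    for n in nodes:
        if n in haplotypes:
            mult, sids = haplotypes[n]
            g.add_node(n, kind="observed", multiplicity=mult, sample_ids=sids)
        else:
            g.add_node(n, kind="median", multiplicity=0, sample_ids=())
    for i, j in minimum_spanning_network(nodes, w, epsilon):
        u, v = nodes[i], nodes[j]
        changed = tuple(l for l, a, b in zip(loci, u, v) if a != b)
        g.add_edge(u, v, length=_distance(u, v, w), loci_changed=changed)
    return MJGraph(g, loci, w)


def network_from_dataset(
    dataset: PopulationDataset,
    rates: dict[str, float] | None = None,
    include_multicopy: bool = False,
    epsilon: int = 0,
) -> MJGraph:
    """Build an MJ network from a dataset slice (single-copy loci by default).

    Haplotypes must be free of null and copy-number variants at the used
    loci; micro-variant (".2") alleles are allowed and handled exactly as
    2-tenth steps.
    """
    rates = rates if rates is not None else DEFAULT_MUTATION_RATES
    used = [
        l for l in dataset.panel if include_multicopy or l.copy_number == 1
    ]
    # sorted-slot coding: one vector slot per allele copy
    slots = tuple(name for l in used for name in [l.name] * l.copy_number)
    weights = derive_weights({l.name: rates[l.name] for l in used})
    haps: dict[HapVec, tuple[int, list[str]]] = {}
    for s in dataset:
        vec: list[int] = []
        for l in used:
            call = s.haplotype.calls[l.name]
            if call.is_null or call.is_copy_anomaly:
                raise ValueError(
                    f"{s.sample_id}: {l.name} carries a null/CNV call; filter first"
                )
            vec.extend(a.tenths for a in call.alleles)
        key = tuple(vec)
        mult, sids = haps.get(key, (0, []))
        haps[key] = (mult + 1, sids + [s.sample_id])
    packed = {v: (m, tuple(sids)) for v, (m, sids) in haps.items()}
    return build_network(packed, slots, weights, epsilon)


@dataclass(frozen=True)
class ClusterReport:
    carrier_nodes: tuple[HapVec, ...]
    n_components: int
    components: tuple[tuple[HapVec, ...], ...]
    boundary_edges: tuple[tuple[HapVec, HapVec], ...]


def annotate_clusters(
    mj: MJGraph, locus: str, predicate=lambda tenths: tenths % 10 == 2
) -> ClusterReport:
    """Carrier structure of a focal variant (default: ".2" micro-variant).

    Labels every node by whether its allele at ``locus`` satisfies the
    predicate, then reports the connected components of the carrier
    subgraph and the edges crossing from carriers to non-carriers.
    """
    if locus not in mj.loci:
        raise KeyError(f"locus {locus} not in network loci")
    idx = mj.loci.index(locus)
    carriers = [n for n in mj.graph.nodes if predicate(n[idx])]
    sub = mj.graph.subgraph(carriers)
    comps = tuple(
        tuple(sorted(c)) for c in sorted(nx.connected_components(sub), key=sorted)
    )
    boundary = tuple(
        (u, v)
        for u, v in mj.graph.edges
        if (predicate(u[idx])) != (predicate(v[idx]))
    )
    return ClusterReport(tuple(sorted(carriers)), len(comps), comps, boundary)
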