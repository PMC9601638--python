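"""Weighted median-joining networks for Y-STR haplotypes.

The network is built on condensed haplotypes (identical 23-locus repeat
vectors merged, with multiplicities and label compositions).  Distances are
weighted single-step distances Σ_l w_l |a_l − b_l| with integer locus
weights inversely proportional to the mutation rate — fast loci contribute
less to the topology, as recurrent mutation makes their differences less
informative about descent.

Construction follows the median-joining idea for multistate data:

1. build the minimum-spanning network (all edges that occur in some
   minimum spanning tree, relaxed by ``epsilon``);
2. for triplets of nodes adjacent in the MSN, form the consensus median
   vector: per locus the median of the three repeat counts, i.e. the
   majority state when two agree and the middle value otherwise (repeat
   counts are ordered, so a median always exists — it is the L1 Steiner
   point of the triplet);
3. add the candidate that most reduces the minimum-spanning-tree cost;
   repeat to a fixed point, then prune median nodes whose removal does
   not increase the tree cost.

Ties are broken by lexicographic vector order so results are reproducible
across platforms.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import networkx as nx

from .haplotypes import HaplotypeTable
from .popdiff import repeat_vectors

__all__ = [
    "LocusWeights",
    "CondensedNode",
    "HaploNetwork",
    "weights_from_rates",
    "condense",
    "weighted_distance",
    "minimum_spanning_network",
    "median_joining",
    "annotate_clusters",
]

_TOL = 1e-9


def weights_from_rates(rates: dict[str, float]) -> dict[str, int]:
    """Integer locus weights inversely proportional to mutation rate.

    ``w_l = round(c / μ_l)`` with the constant chosen so that the median
    weight is 10 (the conventional scale), clamped to [1, 99].
    """
    if not rates:
        raise ValueError("empty rate table")
    for locus, mu in rates.items():
        if mu <= 0:
            raise ValueError(f"nonpositive mutation rate for {locus}")
    c = 10.0 * float(np.median(list(rates.values())))
    return {
        locus: int(min(99, max(1, round(c / mu)))) for locus, mu in rates.items()
    }


@dataclass
class CondensedNode:
    """A distinct repeat vector with its sample multiplicity and labels."""

    vector: tuple[float, ...]
    multiplicity: int
    labels: Counter = field(default_factory=Counter)
    kind: str = "sampled"
    sample_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.kind == "sampled" and self.multiplicity < 1:
            raise ValueError("sampled node needs multiplicity >= 1")
        if self.kind == "median" and self.multiplicity != 0:
            raise ValueError("median node must have multiplicity 0")


def condense(t: HaplotypeTable, label: str = "tribe") -> list[CondensedNode]:
    """Merge identical network repeat vectors into condensed nodes.

    The table must be network-filtered and DYS389-adjusted.  Nodes are
    returned in lexicographic vector order (the documented tie-break).
    """
    if not t.records:
        raise ValueError("cannot condense an empty table")
    x = repeat_vectors(t)
    labels = t.group_labels(label)
    by_vec: dict[tuple[float, ...], CondensedNode] = {}
    for row, h, lab in zip(x, t.records, labels):
        vec = tuple(float(v) for v in row)
        node = by_vec.get(vec)
        if node is None:
            node = CondensedNode(vec, 1, Counter(), "sampled", ())
            node.multiplicity = 0  # incremented below for every carrier
            by_vec[vec] = node
        node.multiplicity += 1
        node.labels[lab] += 1
        node.sample_ids = node.sample_ids + (h.sample_id,)
    return [by_vec[v] for v in sorted(by_vec)]


def weighted_distance(
    a: tuple[float, ...] | np.ndarray,
    b: tuple[float, ...] | np.ndarray,
    weights: np.ndarray,
) -> float:
    """Σ_l w_l |a_l − b_l| — the weighted single-step network distance."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.shape != np.asarray(weights).shape:
        raise ValueError("panel mismatch between vectors and weights")
    return float(np.sum(np.asarray(weights) * np.abs(a - b)))


def _distance_matrix(vectors: np.ndarray, weights: np.ndarray) -> np.ndarray:
    diff = np.abs(vectors[:, None, :] - vectors[None, :, :])
    return np.tensordot(diff, weights, axes=([2], [0]))


def _mst_edges(d: np.ndarray) -> tuple[list[tuple[int, int]], float]:
    """Deterministic Prim MST with lexicographic (weight, i, j) tie-break."""
    n = d.shape[0]
    if n == 1:
        return [], 0.0
    in_tree = [0]
    out = set(range(1, n))
    edges: list[tuple[int, int]] = []
    cost = 0.0
    best = {j: (d[0, j], 0) for j in out}
    while out:
        j = min(out, key=lambda v: (best[v][0], best[v][1], v))
        w, i = best[j]
        edges.append((min(i, j), max(i, j)))
        cost += w
        out.remove(j)
        in_tree.append(j)
        for v in out:
            if d[j, v] < best[v][0] - _TOL or (
                abs(d[j, v] - best[v][0]) <= _TOL and j < best[v][1]
            ):
                best[v] = (d[j, v], j)
    return edges, cost


def _bottleneck_matrix(d: np.ndarray, mst: list[tuple[int, int]]) -> np.ndarray:
    """Minimax (bottleneck) path weight between all pairs, via the MST."""
    n = d.shape[0]
    adj: dict[int, list[int]] = {i: [] for i in range(n)}
    for i, j in mst:
        adj[i].append(j)
        adj[j].append(i)
    bn = np.zeros((n, n))
    for src in range(n):
        stack = [src]
        seen = {src}
        while stack:
            u = stack.pop()
            for v in adj[u]:
                if v not in seen:
                    seen.add(v)
                    bn[src, v] = max(bn[src, u], d[u, v])
                    stack.append(v)
    return bn


def minimum_spanning_network(
    d: np.ndarray, epsilon: float = 0.0
) -> list[tuple[int, int]]:
    """Edges of the ε-relaxed minimum spanning network.

    An edge (i, j) is included iff d_ij ≤ bottleneck(i, j) + ε, where the
    bottleneck is the minimax path weight.  With ε = 0 this is exactly the
    union of all minimum spanning trees.
    """
    n = d.shape[0]
    if n <= 1:
        return []
    mst, _ = _mst_edges(d)
    bn = _bottleneck_matrix(d, mst)
    return [
        (i, j)
        for i in range(n)
        for j in range(i + 1, n)
        if d[i, j] <= bn[i, j] + epsilon + _TOL
    ]


def _added_mst_cost(
    d: np.ndarray, mst: list[tuple[int, int]], cand_dists: np.ndarray
) -> float:
    """MST cost of the graph extended by one node.

    The MST of G + v is contained in (MST of G) ∪ star(v), so only
    n − 1 + n edges need be considered.
    """
    n = d.shape[0]
    edges = [(d[i, j], i, j) for i, j in mst]
    edges += [(cand_dists[i], i, n) for i in range(n)]
    edges.sort(key=lambda e: (e[0], e[1], e[2]))
    parent = list(range(n + 1))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    cost, used = 0.0, 0
    for w, i, j in edges:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
            cost += w
            used += 1
            if used == n:
                break
    return cost


def _triplet_median(
    u: tuple[float, ...], v: tuple[float, ...], w: tuple[float, ...]
) -> tuple[float, ...]:
    """Coordinate-wise median of three repeat vectors (majority state when
    two agree, middle value otherwise)."""
    return tuple(sorted((a, b, c))[1] for a, b, c in zip(u, v, w))


@dataclass
class HaploNetwork:
    """Median-joining network: condensed nodes plus inferred medians."""

    nodes: list[CondensedNode]
    edges: list[tuple[int, int, float]]
    epsilon: float
    weights: np.ndarray
    mst_cost: float

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for idx, node in enumerate(self.nodes):
            g.add_node(
                idx,
                kind=node.kind,
                multiplicity=node.multiplicity,
                vector=",".join(f"{v:g}" for v in node.vector),
                labels=";".join(f"{k}:{c}" for k, c in sorted(node.labels.items())),
            )
        for i, j, w in self.edges:
            g.add_edge(i, j, weight=w)
        return g

    def write_graphml(self, path: str) -> None:
        nx.write_graphml(self.to_networkx(), path)

    def write_dot(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("graph haplonet {\n")
            for idx, node in enumerate(self.nodes):
                shape = "circle" if node.kind == "sampled" else "point"
                size = max(0.2, 0.25 * (node.multiplicity or 1) ** 0.5)
                label = str(node.multiplicity) if node.kind == "sampled" else ""
                fh.write(
                    f'  n{idx} [shape={shape}, width={size:.2f}, label="{label}"];\n'
                )
            for i, j, w in self.edges:
                fh.write(f'  n{i} -- n{j} [label="{w:g}"];\n')
            fh.write("}\n")


def median_joining(
    nodes: list[CondensedNode],
    weights: np.ndarray,
    epsilon: float = 0.0,
    max_medians: int = 500,
) -> HaploNetwork:
    """Build the median-joining network over condensed haplotypes.

    Candidate medians are coordinate-wise medians of MSN-adjacent
    triplets; at each round the candidate giving the largest reduction in
    minimum-spanning-tree cost is added.  After the fixed point, median
    nodes whose removal leaves the tree cost unchanged are pruned.
    """
    if not nodes:
        raise ValueError("no nodes to network")
    weights = np.asarray(weights, dtype=float)
    sampled = list(nodes)
    vectors = [n.vector for n in sampled]
    median_vecs: list[tuple[float, ...]] = []

    def matrix(vecs: list[tuple[float, ...]]) -> np.ndarray:
        return _distance_matrix(np.asarray(vecs, dtype=float), weights)

    while len(median_vecs) < max_medians:
        allv = vectors + median_vecs
        d = matrix(allv)
        mst, cost = _mst_edges(d)
        msn = minimum_spanning_network(d, epsilon)
        adj: dict[int, set[int]] = {i: set() for i in range(len(allv))}
        for i, j in msn:
            adj[i].add(j)
            adj[j].add(i)
        existing = set(allv)
        candidates: set[tuple[float, ...]] = set()
        for u in range(len(allv)):
            for v, w in itertools.combinations(sorted(adj[u]), 2):
                med = _triplet_median(allv[u], allv[v], allv[w])
                if med not in existing:
                    candidates.add(med)
        if not candidates:
            break
        best_vec, best_cost = None, cost - _TOL
        for med in sorted(candidates):
            cd = np.array([weighted_distance(med, x, weights) for x in allv])
            new_cost = _added_mst_cost(d, mst, cd)
            if new_cost < best_cost - _TOL:
                best_vec, best_cost = med, new_cost
        if best_vec is None:
            break
        median_vecs.append(best_vec)

    # prune medians whose removal leaves the spanning cost unchanged
    changed = True
    while changed and median_vecs:
        changed = False
        allv = vectors + median_vecs
        _, full_cost = _mst_edges(matrix(allv))
        for m in list(median_vecs):
            rest = vectors + [x for x in median_vecs if x != m]
            _, cost_wo = _mst_edges(matrix(rest))
            if cost_wo <= full_cost + _TOL:
                median_vecs.remove(m)
                changed = True
                break

    allv = vectors + median_vecs
    d = matrix(allv)
    msn = minimum_spanning_network(d, epsilon)
    _, cost = _mst_edges(d)
    out_nodes = list(sampled) + [
        CondensedNode(m, 0, Counter(), "median", ()) for m in median_vecs
    ]
    edges = [(i, j, float(d[i, j])) for i, j in msn]
    return HaploNetwork(out_nodes, edges, epsilon, weights, cost)


def annotate_clusters(
    net: HaploNetwork,
    n_clusters: int | None = None,
    quantile: float = 0.9,
    min_size: int | None = None,
) -> list[dict]:
    """Partition the network by cutting long edges and summarize labels.

    With ``n_clusters`` given, the longest edges of the network's minimum
    spanning tree are cut until that many clusters exist (single-linkage
    with a known cluster count); a cut is only accepted when both sides
    keep at least ``min_size`` samples (default 5% of the sample, at
    least 2), which stops single outlier lineages from absorbing a cut.
    Otherwise every edge strictly longer than the given quantile of MST
    edge lengths is cut.  Each cluster is reported with its sample count,
    label composition, purity, and modal allele per locus (the profile
    that separates clusters).
    """
    allvecs = [n.vector for n in net.nodes]
    d = _distance_matrix(np.asarray(allvecs, dtype=float), net.weights)
    mst, _ = _mst_edges(d)
    total_samples = sum(n.multiplicity for n in net.nodes)
    if min_size is None:
        min_size = max(2, int(np.ceil(0.05 * total_samples)))

    g = nx.Graph()
    g.add_nodes_from(range(len(net.nodes)))
    g.add_edges_from(mst)

    def _component_samples(comp: set[int]) -> int:
        return sum(net.nodes[i].multiplicity for i in comp)

    if mst and n_clusters is not None:
        if n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        made = 1
        for e in sorted(mst, key=lambda e: (-d[e], e)):
            if made >= n_clusters:
                break
            g.remove_edge(*e)
            a = nx.node_connected_component(g, e[0])
            b = nx.node_connected_component(g, e[1])
            if _component_samples(a) >= min_size and _component_samples(b) >= min_size:
                made += 1
            else:
                g.add_edge(*e)
    elif mst:
        lengths = np.array([d[e] for e in mst])
        thr = float(np.quantile(lengths, quantile))
        for e in mst:
            if d[e] > thr + _TOL:
                g.remove_edge(*e)
    clusters = []
    for comp in nx.connected_components(g):
        members = sorted(comp)
        sampled = [net.nodes[i] for i in members if net.nodes[i].kind == "sampled"]
        if not sampled:
            continue
        size = sum(nd.multiplicity for nd in sampled)
        labels: Counter = Counter()
        for nd in sampled:
            labels.update(nd.labels)
        modal = []
        for locus_idx in range(len(allvecs[0])):
            cnt: Counter = Counter()
            for nd in sampled:
                cnt[nd.vector[locus_idx]] += nd.multiplicity
            modal.append(cnt.most_common(1)[0][0])
        purity = {k: v / size for k, v in sorted(labels.items())}
        clusters.append(
            {
                "members": members,
                "size": size,
                "labels": dict(labels),
                "purity": purity,
                "modal_profile": tuple(modal),
            }
        )
    clusters.sort(key=lambda c: -c["size"])
    return clusters
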