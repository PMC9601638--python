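"""Median-joining network construction: weights, MSN, median insertion,
exhaustive oracles and cluster annotation."""

import itertools

import numpy as np
import pytest

from ystrkit.haplotypes import HaplotypeTable, adjust_dys389_table
from ystrkit.loci import NETWORK_LOCI, default_mutation_rates
from ystrkit.network import (
    CondensedNode,
    _distance_matrix,
    _mst_edges,
    annotate_clusters,
    condense,
    median_joining,
    minimum_spanning_network,
    weighted_distance,
    weights_from_rates,
)
from ystrkit.simulate import (
    BASE_HAPLOTYPE,
    SimulationConfig,
    TribeSpec,
    simulate_population,
)

from conftest import make_haplotype


# ---------------------------------------------------------------------------
# locus weights


def test_equal_rates_give_the_median_weight_everywhere():
    w = weights_from_rates({f"L{i}": 0.004 for i in range(8)})
    assert set(w.values()) == {10}


def test_inverse_proportionality():
    w = weights_from_rates({"slow": 0.002, "mid": 0.004, "fast": 0.008})
    assert w["fast"] < w["mid"] < w["slow"]
    assert w["fast"] == pytest.approx(w["mid"] / 2, abs=1)
    assert w["slow"] == pytest.approx(w["mid"] * 2, abs=1)


def test_bundled_rates_order_fast_loci_below_slow():
    w = weights_from_rates(default_mutation_rates())
    for fast in ("DYS627", "DYS576", "DYS518"):
        for slow in ("DYS392", "DYS438"):
            assert w[fast] < w[slow]
    assert all(1 <= v <= 99 for v in w.values())


def test_nonpositive_rate_rejected():
    with pytest.raises(ValueError):
        weights_from_rates({"L": 0.0})


# ---------------------------------------------------------------------------
# condensation


def _filtered_table(records):
    t = HaplotypeTable(records)
    t, _ = adjust_dys389_table(t)
    return t


def test_condense_merges_identical_vectors():
    records = [make_haplotype(f"A{i}", tribe="T1") for i in range(5)]
    records += [make_haplotype(f"B{i}", offsets={"DYS19": 1}, tribe="T2") for i in range(2)]
    nodes = condense(_filtered_table(records))
    assert len(nodes) == 2
    assert sorted(n.multiplicity for n in nodes) == [2, 5]
    assert sum(n.multiplicity for n in nodes) == 7
    assert sum(sum(n.labels.values()) for n in nodes) == 7


def test_condense_all_distinct():
    records = [make_haplotype(f"C{i}", offsets={"DYS19": i}) for i in range(4)]
    nodes = condense(_filtered_table(records))
    assert len(nodes) == 4
    # lexicographic vector ordering
    assert [n.vector for n in nodes] == sorted(n.vector for n in nodes)


# ---------------------------------------------------------------------------
# weighted distance


def test_weighted_distance_definition_and_metric():
    w = np.array([10.0, 5.0, 1.0])
    a, b = (14.0, 12.0, 10.0), (14.0, 12.0, 10.0)
    assert weighted_distance(a, b, w) == 0.0
    c = (16.0, 12.0, 10.0)
    assert weighted_distance(a, c, w) == 20.0
    rng = np.random.default_rng(0)
    for _ in range(20):
        x, y, z = (tuple(rng.integers(8, 15, 3).astype(float)) for _ in range(3))
        brute = sum(wi * abs(xi - yi) for wi, xi, yi in zip(w, x, y))
        assert weighted_distance(x, y, w) == pytest.approx(brute, abs=1e-12)
        assert weighted_distance(x, z, w) <= (
            weighted_distance(x, y, w) + weighted_distance(y, z, w) + 1e-12
        )
    with pytest.raises(ValueError):
        weighted_distance(a, (1.0, 2.0), w)


# ---------------------------------------------------------------------------
# minimum spanning network


def brute_force_msn(d: np.ndarray) -> set[tuple[int, int]]:
    """Union of all minimum spanning trees by exhaustive enumeration."""
    n = d.shape[0]
    all_edges = list(itertools.combinations(range(n), 2))
    best_cost, best_union = None, set()
    for tree in itertools.combinations(all_edges, n - 1):
        parent = list(range(n))

        def find(x):
            while parent[x] != x:
                x = parent[x]
            return x

        ok = True
        for i, j in tree:
            ri, rj = find(i), find(j)
            if ri == rj:
                ok = False
                break
            parent[ri] = rj
        if not ok:
            continue
        cost = sum(d[i, j] for i, j in tree)
        if best_cost is None or cost < best_cost - 1e-9:
            best_cost, best_union = cost, set(tree)
        elif abs(cost - best_cost) <= 1e-9:
            best_union |= set(tree)
    return best_union


def test_msn_trivial_shapes():
    d2 = np.array([[0.0, 3.0], [3.0, 0.0]])
    assert minimum_spanning_network(d2) == [(0, 1)]
    # three equidistant nodes: tie -> all three edges
    d3 = np.full((3, 3), 2.0)
    np.fill_diagonal(d3, 0.0)
    assert set(minimum_spanning_network(d3)) == {(0, 1), (0, 2), (1, 2)}


@pytest.mark.parametrize("seed", range(8))
def test_msn_equals_union_of_all_msts(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(3, 7))
    x = rng.integers(0, 4, size=(n, 2)).astype(float)
    d = np.abs(x[:, None, :] - x[None, :, :]).sum(-1)
    got = set(minimum_spanning_network(d, epsilon=0.0))
    assert got == brute_force_msn(d)


def test_epsilon_relaxation_only_adds_edges():
    rng = np.random.default_rng(3)
    x = rng.integers(0, 5, size=(6, 3)).astype(float)
    d = np.abs(x[:, None, :] - x[None, :, :]).sum(-1)
    e0 = set(minimum_spanning_network(d, 0.0))
    e2 = set(minimum_spanning_network(d, 2.0))
    assert e0 <= e2


# ---------------------------------------------------------------------------
# median joining


def _nodes(vectors):
    return [CondensedNode(tuple(map(float, v)), 1) for v in vectors]


def test_two_nodes_single_edge_no_medians():
    hn = median_joining(_nodes([(14, 12), (15, 12)]), np.ones(2))
    assert len(hn.nodes) == 2
    assert len(hn.edges) == 1
    assert all(n.kind == "sampled" for n in hn.nodes)


def test_triplet_gains_steiner_median():
    hn = median_joining(_nodes([(14, 12, 10), (15, 13, 10), (15, 12, 11)]), np.ones(3))
    medians = [n.vector for n in hn.nodes if n.kind == "median"]
    assert medians == [(15.0, 12.0, 10.0)]
    assert hn.mst_cost == pytest.approx(3.0)  # down from the 4.0 MST


def test_star_data_stays_a_star():
    """Founder + k one-step derivatives: the founder-effect shape."""
    founder = (14.0,) * 6
    neighbors = []
    for i in range(6):
        v = list(founder)
        v[i] += 1
        neighbors.append(tuple(v))
    hn = median_joining(_nodes([founder] + neighbors), np.ones(6))
    assert sum(1 for n in hn.nodes if n.kind == "median") == 0
    assert len(hn.edges) == 6
    deg = {i: 0 for i in range(len(hn.nodes))}
    for i, j, _ in hn.edges:
        deg[i] += 1
        deg[j] += 1
    assert max(deg.values()) == 6  # founder is the hub


def steiner_optimum(vecs, w, max_extra=2):
    """Exhaustive Steiner search over the integer bounding box."""
    arr = np.array(vecs, float)
    lo, hi = arr.min(0), arr.max(0)
    grid = [
        tuple(map(float, p))
        for p in itertools.product(*[range(int(l), int(h) + 1) for l, h in zip(lo, hi)])
    ]
    grid = [p for p in grid if p not in set(map(tuple, vecs))]
    best = _mst_edges(_distance_matrix(arr, w))[1]
    for k in range(1, max_extra + 1):
        for extra in itertools.combinations(grid, k):
            allv = np.array(list(vecs) + list(extra), float)
            cost = _mst_edges(_distance_matrix(allv, w))[1]
            best = min(best, cost)
    return best


@pytest.mark.parametrize("seed", range(12))
def test_mj_cost_matches_exhaustive_steiner_search(seed):
    rng = np.random.default_rng(seed)
    nloci = int(rng.integers(2, 4))
    nnodes = int(rng.integers(3, 6))
    vecs = set()
    while len(vecs) < nnodes:
        vecs.add(tuple(float(v) for v in rng.integers(10, 13, nloci)))
    vecs = sorted(vecs)
    w = np.ones(nloci)
    hn = median_joining(_nodes(vecs), w)
    mst_cost = _mst_edges(_distance_matrix(np.array(vecs, float), w))[1]
    assert hn.mst_cost <= mst_cost + 1e-9
    assert hn.mst_cost == pytest.approx(steiner_optimum(vecs, w), abs=1e-9)


def test_weight_scaling_leaves_topology_unchanged():
    rng = np.random.default_rng(2)
    vecs = sorted({tuple(float(v) for v in rng.integers(10, 14, 4)) for _ in range(6)})
    w = np.array([3.0, 1.0, 2.0, 1.0])
    h1 = median_joining(_nodes(vecs), w)
    h2 = median_joining(_nodes(vecs), w * 7.0)
    assert [n.vector for n in h1.nodes] == [n.vector for n in h2.nodes]
    assert [(i, j) for i, j, _ in h1.edges] == [(i, j) for i, j, _ in h2.edges]


def test_median_nodes_never_duplicate_sampled_vectors():
    rng = np.random.default_rng(6)
    vecs = sorted({tuple(float(v) for v in rng.integers(10, 13, 3)) for _ in range(7)})
    hn = median_joining(_nodes(vecs), np.ones(3))
    sampled = {n.vector for n in hn.nodes if n.kind == "sampled"}
    medians = {n.vector for n in hn.nodes if n.kind == "median"}
    assert not (sampled & medians)


def test_network_is_connected():
    import networkx as nx

    rng = np.random.default_rng(8)
    vecs = sorted({tuple(float(v) for v in rng.integers(8, 14, 5)) for _ in range(10)})
    hn = median_joining(_nodes(vecs), np.ones(5))
    g = hn.to_networkx()
    assert nx.is_connected(g)


# ---------------------------------------------------------------------------
# cluster annotation


def _founder_population(n_tribes: int, seed: int, n: int = 60):
    tribes = tuple(
        TribeSpec(chr(65 + i), 1 / n_tribes, 15, 1.0) for i in range(n_tribes)
    )
    cfg = SimulationConfig(
        tribes=tribes,
        n=n,
        seed=seed,
        split_generations=150,
        dys448_null_rate=0.0,
        dys19_dup_rate=0.0,
        microvariant_rate=0.0,
    )
    samp = simulate_population(cfg)
    t, _ = adjust_dys389_table(samp.table)
    return t


def _network_for(t):
    nodes = condense(t, "tribe")
    rates = {d.name: d.mutation_rate for d in t.panel if d.in_network_panel}
    w = weights_from_rates(rates)
    wvec = np.array([w[l] for l in NETWORK_LOCI], float)
    return median_joining(nodes, wvec)


def test_two_founder_deep_split_recovers_assignment():
    t = _founder_population(2, seed=21, n=40)
    clusters = annotate_clusters(_network_for(t), n_clusters=2)
    assert len(clusters) == 2
    correct = sum(max(c["labels"].values()) for c in clusters)
    assert correct / 40 >= 0.95


def test_single_founder_single_cluster_and_purity_sums():
    t = _founder_population(1, seed=5, n=25)
    clusters = annotate_clusters(_network_for(t), n_clusters=1)
    assert len(clusters) == 1
    for c in clusters:
        assert sum(c["purity"].values()) == pytest.approx(1.0)
        assert c["size"] == sum(c["labels"].values())


def test_three_founder_recovery_and_modal_profiles_differ():
    t = _founder_population(3, seed=11, n=90)
    clusters = annotate_clusters(_network_for(t), n_clusters=3)
    assert len(clusters) == 3
    correct = sum(max(c["labels"].values()) for c in clusters)
    assert correct / 90 >= 0.95
    profiles = {c["modal_profile"] for c in clusters}
    assert len(profiles) == 3
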