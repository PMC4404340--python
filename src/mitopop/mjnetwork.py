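"""Median-joining haplotype networks (Bandelt-Forster-Roehl style).

Observed haplotypes are connected through an epsilon-relaxed minimum
spanning network; median vectors (site-wise majority consensus sequences
of connected triplets) are inserted while they reduce the total network
cost; maximum-parsimony post-processing removes median vectors and links
that lie on no minimal-cost path between observed haplotypes.

Site weights let transversions count more than transitions (the usual
weighting is 3x), and a per-site weight vector can downweight
hypervariable positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations, product

import networkx as nx
import numpy as np

from mitopop.haplotypes import HaplotypeSet, is_transition
from mitopop.seqio import SampleTable


def weighted_hamming(
    a: str,
    b: str,
    tv_weight: float = 3.0,
    site_weights: np.ndarray | None = None,
) -> float:
    """Sum over differing sites of w_s, with w_s multiplied by
    ``tv_weight`` when the state pair at that site is a transversion."""
    if len(a) != len(b):
        raise ValueError("sequences differ in length")
    total = 0.0
    for s, (x, y) in enumerate(zip(a, b)):
        if x == y:
            continue
        w = 1.0 if site_weights is None else float(site_weights[s])
        if not is_transition(x, y):
            w *= tv_weight
        total += w
    return total


def _mst_cost(nodes: list[str], dist) -> float:
    """Total weight of a minimum spanning tree over ``nodes``."""
    g = nx.Graph()
    g.add_nodes_from(range(len(nodes)))
    for i, j in combinations(range(len(nodes)), 2):
        g.add_edge(i, j, weight=dist(nodes[i], nodes[j]))
    return sum(d["weight"] for _, _, d in
               nx.minimum_spanning_edges(g, data=True))


def _epsilon_network(nodes: list[str], dist, epsilon: float) -> nx.Graph:
    """Epsilon-relaxed minimum spanning network.

    An edge (u, v) is kept iff its length is within epsilon of the cost of
    the Kruskal step at which u and v first become connectable (their
    minimax-path bottleneck in the complete graph).
    """
    n = len(nodes)
    pairs = sorted(
        ((dist(nodes[i], nodes[j]), i, j)
         for i, j in combinations(range(n), 2)),
        key=lambda t: (t[0], t[1], t[2]),
    )
    # union-find recording the merge cost of each component pair
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    connect_cost = np.zeros((n, n))
    # process by distinct distance levels so ties merge simultaneously
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    k = 0
    while k < len(pairs):
        lvl = pairs[k][0]
        batch = []
        while k < len(pairs) and pairs[k][0] == lvl:
            batch.append(pairs[k])
            k += 1
        for d, i, j in batch:
            ri, rj = find(i), find(j)
            if ri == rj:
                continue
            for u in members[ri]:
                for v in members[rj]:
                    connect_cost[u, v] = connect_cost[v, u] = lvl
            parent[rj] = ri
            members[ri].extend(members[rj])
            del members[rj]
    g = nx.Graph()
    for i in range(n):
        g.add_node(nodes[i])
    for d, i, j in pairs:
        if d <= connect_cost[i, j] + epsilon:
            g.add_edge(nodes[i], nodes[j], weight=d)
    return g


def _medians_of(u: str, v: str, w: str) -> list[str]:
    """Site-wise majority consensus candidates of a triplet.

    Sites where all three states differ generate one candidate per state;
    candidates are returned in lexicographic order (deterministic).
    """
    options: list[tuple[str, ...]] = []
    for a, b, c in zip(u, v, w):
        if a == b or a == c:
            options.append((a,))
        elif b == c:
            options.append((b,))
        else:
            options.append(tuple(sorted({a, b, c})))
    n_cand = 1
    for o in options:
        n_cand *= len(o)
        if n_cand > 64:  # cap blow-up at hypervariable triplets
            options = [o[:1] for o in options]
            break
    return sorted("".join(p) for p in product(*options))


@dataclass
class HaploNetwork:
    """Observed haplotypes plus inferred median vectors with weighted edges."""

    graph: nx.Graph = field(repr=False)
    observed: dict[str, str]  # haplotype_id -> sequence
    medians: dict[str, str]  # median node id -> sequence
    epsilon: float
    total_cost: float

    @property
    def n_medians(self) -> int:
        return len(self.medians)


def build_mjn(
    hset: HaplotypeSet,
    epsilon: float = 0.0,
    tv_weight: float = 3.0,
    site_weights: np.ndarray | None = None,
    max_median_rounds: int = 50,
) -> HaploNetwork:
    """Median-joining network of a haplotype set.

    The total network cost (weight of a minimum spanning tree over the
    final node set) never increases across median-insertion iterations;
    post-processing never disconnects observed haplotypes.
    """
    if hset.K < 2:
        raise ValueError("median-joining needs at least 2 haplotypes")
    seq_of = dict(zip(hset.haplotype_ids, hset.sequences))
    cache: dict[tuple[str, str], float] = {}

    def dist(x: str, y: str) -> float:
        key = (x, y) if x <= y else (y, x)
        if key not in cache:
            cache[key] = weighted_hamming(
                key[0], key[1], tv_weight=tv_weight, site_weights=site_weights
            )
        return cache[key]

    # iterate: relax network, scan connected triplets, insert best median
    node_seqs = list(dict.fromkeys(hset.sequences))
    median_seqs: list[str] = []
    cost = _mst_cost(node_seqs, dist)
    for _ in range(max_median_rounds):
        g = _epsilon_network(node_seqs, dist, epsilon)
        candidates: set[str] = set()
        for u in g.nodes:
            nbrs = sorted(g.neighbors(u))
            for v, w in combinations(nbrs, 2):
                for m in _medians_of(u, v, w):
                    if m not in node_seqs:
                        candidates.add(m)
        best_seq, best_cost = None, cost
        for m in sorted(candidates):
            c = _mst_cost(node_seqs + [m], dist)
            if c < best_cost - 1e-9 or (
                best_seq is not None and abs(c - best_cost) <= 1e-9 and m < best_seq
            ):
                best_seq, best_cost = m, c
        if best_seq is None:
            break
        node_seqs.append(best_seq)
        median_seqs.append(best_seq)
        cost = best_cost

    # name nodes: observed keep their haplotype ids, medians get mv1..mvM
    name_of = {seq: hid for hid, seq in seq_of.items()}
    for i, m in enumerate(median_seqs):
        name_of[m] = f"mv{i + 1}"
    g = _epsilon_network(node_seqs, dist, epsilon)
    net = nx.relabel_nodes(g, name_of)

    # MP post-processing: keep only nodes/edges on minimal-cost paths
    # between observed haplotypes; then smooth out degree-<=2 medians.
    obs_nodes = list(seq_of)
    keep_nodes: set[str] = set(obs_nodes)
    keep_edges: set[frozenset[str]] = set()
    for a, b in combinations(obs_nodes, 2):
        for path in nx.all_shortest_paths(net, a, b, weight="weight"):
            keep_nodes.update(path)
            keep_edges.update(
                frozenset(e) for e in zip(path[:-1], path[1:])
            )
    pruned = net.edge_subgraph(
        [tuple(e) for e in keep_edges]
    ).copy()
    pruned.add_nodes_from(obs_nodes)

    seq_lookup = {v: k for k, v in name_of.items()}
    changed = True
    while changed:
        changed = False
        for node in [n for n in pruned.nodes if n.startswith("mv")]:
            deg = pruned.degree(node)
            if deg <= 1:
                pruned.remove_node(node)
                changed = True
            elif deg == 2:
                # a degree-2 median adds no branching: replace the chain
                # through it by the direct edge (same or shorter length)
                a, b = list(pruned.neighbors(node))
                if not pruned.has_edge(a, b):
                    pruned.add_edge(
                        a, b, weight=dist(seq_lookup[a], seq_lookup[b])
                    )
                pruned.remove_node(node)
                changed = True

    medians = {
        name_of[m]: m for m in median_seqs if name_of[m] in pruned.nodes
    }
    # annotate edges with the differing site positions
    for a, b, data in pruned.edges(data=True):
        sa, sb = seq_lookup[a], seq_lookup[b]
        data["sites"] = tuple(
            i for i, (x, y) in enumerate(zip(sa, sb)) if x != y
        )
    final_cost = _mst_cost([seq_lookup[v] for v in pruned.nodes], dist)
    # frequencies on observed nodes
    freq = dict(zip(hset.haplotype_ids, hset.frequencies))
    for v in pruned.nodes:
        pruned.nodes[v]["frequency"] = freq.get(v, 0)
        pruned.nodes[v]["median"] = v.startswith("mv")
        pruned.nodes[v]["sequence"] = seq_lookup[v]
    return HaploNetwork(
        graph=pruned,
        observed=seq_of,
        medians=medians,
        epsilon=epsilon,
        total_cost=final_cost,
    )


def annotate_network(
    net: HaploNetwork, hset: HaplotypeSet, samples: SampleTable,
    by: str = "population",
):
    """Per-node frequency and composition table, plus founder candidates.

    Returns (rows, founders): rows are dicts of node id, frequency, degree
    and per-level composition; founders are the nodes maximising
    (frequency, degree).
    """
    import pandas as pd

    member_of = {
        hid: mem for hid, mem in zip(hset.haplotype_ids, hset.members)
    }
    rows = []
    for v in net.graph.nodes:
        freq = net.graph.nodes[v]["frequency"]
        comp: dict[str, int] = {}
        for sid in member_of.get(v, ()):
            lab = samples.labels_for([sid], column=by)[0]
            comp[lab] = comp.get(lab, 0) + 1
        if member_of.get(v) and sum(comp.values()) != freq:
            raise ValueError(f"unknown sample ids on node {v}")
        rows.append(
            {"node": v, "frequency": freq,
             "degree": net.graph.degree(v),
             "median": net.graph.nodes[v]["median"],
             **{f"n_{k}": c for k, c in sorted(comp.items())}}
        )
    df = pd.DataFrame(rows).fillna(0)
    observed = df[~df["median"]]
    best = observed.sort_values(
        ["frequency", "degree", "node"], ascending=[False, False, True]
    )
    founders = list(best.head(1)["node"])
    return df, founders
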