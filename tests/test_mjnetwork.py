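from itertools import combinations, product

import networkx as nx
import numpy as np
import pytest

from mitopop.haplotypes import HaplotypeSet
from mitopop.mjnetwork import (
    annotate_network,
    build_mjn,
    weighted_hamming,
    _epsilon_network,
    _medians_of,
)


def _hset(seq_freq_pairs):
    seqs, freqs = zip(*seq_freq_pairs)
    return HaplotypeSet.from_frequencies(freqs, sequences=seqs)


class TestWeightedHamming:
    def test_identical_zero(self):
        assert weighted_hamming("ACGT", "ACGT") == 0.0

    def test_transition_counts_one(self):
        assert weighted_hamming("A", "G") == 1.0
        assert weighted_hamming("C", "T") == 1.0

    def test_transversion_counts_tv_weight(self):
        assert weighted_hamming("A", "T") == 3.0
        assert weighted_hamming("A", "T", tv_weight=1.0) == 1.0

    def test_site_weights_apply(self):
        w = np.array([2.0, 0.5])
        # site0: A->G transition (2.0); site1: C->A transversion (0.5 * 3)
        assert weighted_hamming("AC", "GA", site_weights=w) == pytest.approx(3.5)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            weighted_hamming("AC", "ACG")


class TestMedians:
    def test_majority_per_site(self):
        # classic triangle: the Steiner point of AAT, ATA, TAA is AAA
        assert _medians_of("AAT", "ATA", "TAA") == ["AAA"]

    def test_agreeing_sites_kept(self):
        assert _medians_of("ACGT", "ACGA", "ACGT") == ["ACGT"]

    def test_three_way_tie_yields_all_states(self):
        cands = _medians_of("A", "C", "G")
        assert cands == ["A", "C", "G"]


class TestEpsilonNetwork:
    def _dist(self, tv_weight=1.0):
        return lambda a, b: weighted_hamming(a, b, tv_weight=tv_weight)

    def test_epsilon_zero_is_msn(self):
        # square of 4 haplotypes: all nearest-neighbour edges length 1,
        # diagonals length 2 are excluded at epsilon=0
        nodes = ["AA", "AT", "TA", "TT"]
        g = _epsilon_network(nodes, self._dist(), epsilon=0.0)
        assert g.number_of_edges() == 4
        assert not g.has_edge("AA", "TT")

    def test_edges_monotone_in_epsilon(self):
        rng = np.random.default_rng(5)
        nodes = list({"".join(rng.choice(list("AT"), 6)) for _ in range(8)})
        counts = []
        for eps in (0.0, 1.0, 2.0, 10.0):
            g = _epsilon_network(nodes, self._dist(), epsilon=eps)
            counts.append(g.number_of_edges())
            assert nx.is_connected(g)
        assert all(a <= b for a, b in zip(counts, counts[1:]))

    def test_large_epsilon_complete_graph(self):
        nodes = ["AA", "AT", "TA", "TT"]
        g = _epsilon_network(nodes, self._dist(), epsilon=100.0)
        assert g.number_of_edges() == 6


def steiner_lower_bound(seqs, alphabet=("A", "T")):
    """Brute-force minimum Steiner-tree cost over the full hypercube.

    Only feasible for short binary-state sequences; unit weights. An
    optimal Steiner tree on k terminals needs at most k-2 extra points,
    so exhaustive search over subsets of that size is exact.
    """
    from itertools import combinations as comb

    from scipy.sparse.csgraph import minimum_spanning_tree

    L = len(seqs[0])
    universe = ["".join(p) for p in product(alphabet, repeat=L)]
    idx = {u: i for i, u in enumerate(universe)}
    arr = np.array([list(u) for u in universe])
    dmat = (arr[:, None, :] != arr[None, :, :]).sum(axis=2).astype(float)

    term_idx = sorted({idx[s] for s in seqs})
    extra_idx = [i for i in range(len(universe)) if i not in term_idx]

    def mst_cost(ids):
        sub = dmat[np.ix_(ids, ids)]
        return float(minimum_spanning_tree(sub).sum())

    best = mst_cost(term_idx)
    for k in range(1, max(1, len(term_idx) - 1)):
        for extra in comb(extra_idx, k):
            c = mst_cost(term_idx + list(extra))
            if c < best:
                best = c
    return best


class TestBuildMJN:
    def test_two_haplotypes_single_edge(self):
        net = build_mjn(_hset([("AAAA", 3), ("AAAT", 2)]))
        assert net.graph.number_of_edges() == 1
        assert net.n_medians == 0
        assert net.total_cost == pytest.approx(3.0)  # one transversion

    def test_single_haplotype_rejected(self):
        with pytest.raises(ValueError):
            build_mjn(_hset([("AAAA", 5)]))

    def test_star_triplet_gains_central_median(self):
        # AAT/ATA/TAA: inserting AAA drops MST cost from 4 to 3
        net = build_mjn(
            _hset([("AAT", 1), ("ATA", 1), ("TAA", 1)]), tv_weight=1.0
        )
        assert net.n_medians == 1
        assert list(net.medians.values()) == ["AAA"]
        assert net.total_cost == pytest.approx(3.0)

    def test_observed_never_disconnected(self):
        for seed in range(5):
            r = np.random.default_rng(seed)
            seqs = list({"".join(r.choice(list("ACGT"), 8)) for _ in range(6)})
            hs = _hset([(s, 1) for s in seqs])
            net = build_mjn(hs)
            assert nx.is_connected(net.graph)
            assert set(hs.haplotype_ids) <= set(net.graph.nodes)

    def test_cost_never_above_plain_mst(self, rng):
        from mitopop.mjnetwork import _mst_cost

        for seed in range(5):
            r = np.random.default_rng(100 + seed)
            seqs = list({"".join(r.choice(list("ACGT"), 10)) for _ in range(7)})
            hs = _hset([(s, 1) for s in seqs])
            net = build_mjn(hs, tv_weight=1.0)
            dist = lambda a, b: weighted_hamming(a, b, tv_weight=1.0)
            assert net.total_cost <= _mst_cost(seqs, dist) + 1e-9

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_steiner_optimum_small_binary(self, seed):
        """On <=5 binary-site haplotypes with unit weights the final
        network cost equals the brute-force Steiner minimum."""
        r = np.random.default_rng(seed)
        seqs: set[str] = set()
        while len(seqs) < 4:
            seqs.add("".join(r.choice(list("AT"), 5)))
        seqs = sorted(seqs)
        hs = _hset([(s, 1) for s in seqs])
        net = build_mjn(hs, tv_weight=1.0, epsilon=10.0)
        assert net.total_cost == pytest.approx(
            steiner_lower_bound(seqs), abs=1e-9
        )

    def test_edges_annotated_with_sites(self):
        net = build_mjn(_hset([("AAAA", 1), ("AATA", 1)]))
        (_, _, data), = net.graph.edges(data=True)
        assert data["sites"] == (2,)

    def test_deterministic_across_runs(self):
        hs = _hset([("AATC", 2), ("ATAC", 1), ("TAAC", 1), ("AATT", 3)])
        n1 = build_mjn(hs)
        n2 = build_mjn(hs)
        assert sorted(n1.graph.nodes) == sorted(n2.graph.nodes)
        assert sorted(map(sorted, n1.graph.edges)) == sorted(
            map(sorted, n2.graph.edges)
        )


class TestAnnotate:
    def test_composition_and_founder(self):
        import pandas as pd

        from mitopop.seqio import SampleTable

        hs = HaplotypeSet(
            haplotype_ids=("H1", "H2"),
            sequences=("AAAA", "AAAT"),
            frequencies=(3, 1),
            members=(("s1", "s2", "s3"), ("s4",)),
            L_used=4,
        )
        net = build_mjn(hs)
        rows = [
            {"sample_id": f"s{i}", "population": "P1" if i < 3 else "P2",
             "country": "P1" if i < 3 else "P2", "group": "G",
             "host_plant": "h", "lat": 0.0, "lon": float(i)}
            for i in range(1, 5)
        ]
        table = SampleTable(pd.DataFrame(rows))
        df, founders = annotate_network(net, hs, table)
        assert founders == ["H1"]  # most frequent
        row = df[df["node"] == "H1"].iloc[0]
        assert row["n_P1"] == 2 and row["n_P2"] == 1
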