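"""Similarity indices, weighted distance, cutoff networks and GCFs."""

import itertools

import numpy as np
import pytest

from bgcmine.core_detection import BGCInventory
from bgcmine.gcf_network import (
    DEFAULT_ANCHORS,
    GCF,
    PairDistance,
    adjacency_index,
    build_network,
    conserved_gcfs,
    dsi,
    jaccard_index,
    pair_distance,
    prune_reference_only,
)
from bgcmine.alignment import local_align
from bgcmine.synthetic_data import make_protein, mutate_to_identity


def inv(bgc_id, copies):
    """BGCInventory from an ordered list of (domain, seq)."""
    out = BGCInventory(bgc_id=bgc_id)
    for d, s in copies:
        out.types[d] += 1
        out.copies.append((d, s))
        out.linear.append(d)
    return out


def seqs(*domains, length=120, seed=0):
    rng = np.random.default_rng(seed)
    return [(d, make_protein(length, rng)) for d in domains]


class TestJaccard:
    def test_identical_and_disjoint(self):
        a = inv("a", seqs("KS", "AT", "ACP"))
        b = inv("b", seqs("C", "A", "T"))
        assert jaccard_index(a, a) == 1.0
        assert jaccard_index(a, b) == 0.0

    def test_three_quarters(self):
        a = inv("a", seqs("KS", "AT", "ACP"))
        b = inv("b", seqs("KS", "AT", "KR", "ACP"))
        assert jaccard_index(a, b) == pytest.approx(3 / 4)

    def test_both_empty_is_zero(self):
        assert jaccard_index(inv("a", []), inv("b", [])) == 0.0


class TestDSI:
    def test_identical_loci_score_one(self):
        a = inv("a", seqs("KS", "AT", seed=3))
        assert dsi(a, a) == pytest.approx(1.0)

    def test_no_shared_types_is_zero(self):
        a = inv("a", seqs("KS", seed=1))
        b = inv("b", seqs("TC", seed=2))
        assert dsi(a, b) == 0.0

    def test_two_copy_weighted_average(self):
        """Two KS copies paired greedily; each pair counts both its copies."""
        base1 = make_protein(150, 11)
        base2 = make_protein(150, 12)
        a = inv("a", [("KS", base1), ("KS", base2)])
        c1 = mutate_to_identity(base1, 0.8, 13)
        c2 = mutate_to_identity(base2, 0.6, 14)
        b = inv("b", [("KS", c1), ("KS", c2)])
        # hand formula: the greedy pairing must match base1-c1 and base2-c2
        # (cross identities are far lower); per-copy weighted average.
        # arguments sorted: DSI canonicalises pair order for symmetry
        i11 = local_align(*sorted((base1, c1))).identity_pct / 100
        i22 = local_align(*sorted((base2, c2))).identity_pct / 100
        expected = (2 * i11 + 2 * i22) / 4
        assert dsi(a, b) == pytest.approx(expected)

    def test_unpaired_copies_drag_the_average_down(self):
        base = make_protein(150, 15)
        a = inv("a", [("KS", base), ("KS", base)])
        b = inv("b", [("KS", base)])
        assert dsi(a, b) == pytest.approx(2 / 3)

    def test_anchor_weighting(self):
        ks = make_protein(150, 16)
        cs = make_protein(150, 17)
        a = inv("a", [("KS", ks), ("CS", cs)])
        b = inv("b", [("KS", ks), ("CS", mutate_to_identity(cs, 0.5, 18))])
        ics = local_align(*sorted((cs, b.copies[1][1]))).identity_pct / 100
        w = 2.0  # CS is an anchor
        expected = (2 * 1.0 + 2 * w * ics) / (2 + 2 * w)
        assert dsi(a, b) == pytest.approx(expected)
        assert "CS" in DEFAULT_ANCHORS

    def test_missing_subsequence_is_an_error(self):
        a = inv("a", [("KS", "")])
        with pytest.raises(ValueError):
            dsi(a, a)


class TestAdjacency:
    def test_identical_sequences(self):
        a = inv("a", seqs("KS", "AT", "ACP"))
        assert adjacency_index(a, a) == 1.0

    def test_shuffled_with_no_shared_adjacency(self):
        a = inv("a", seqs("KS", "AT", "ACP", "KR"))
        b = inv("b", list(reversed(seqs("KS", "AT", "ACP", "KR"))))
        # pairs of a: KS-AT, AT-ACP, ACP-KR; of b: KR-ACP, ACP-AT, AT-KS
        assert adjacency_index(a, b) == 0.0

    def test_single_domain_loci_score_zero(self):
        a = inv("a", seqs("KS"))
        assert adjacency_index(a, a) == 0.0


class TestPairDistance:
    def test_self_distance_zero_with_two_domains(self):
        a = inv("a", seqs("KS", "AT", seed=21))
        assert pair_distance(a, a).distance == pytest.approx(0.0)

    def test_disjoint_distance_one(self):
        a = inv("a", seqs("KS", "AT", seed=22))
        b = inv("b", seqs("C", "T", seed=23))
        assert pair_distance(a, b).distance == pytest.approx(1.0)

    def test_weights_matter(self):
        a = inv("a", seqs("KS", "AT", "ACP", seed=24))
        b = inv("b", seqs("KS", "AT", seed=25))
        d1 = pair_distance(a, b).distance
        d2 = pair_distance(a, b, weights=(0.75, 0.2, 0.05)).distance
        assert d1 != d2

    def test_symmetry(self):
        a = inv("a", seqs("KS", "AT", "KR", seed=26))
        b = inv("b", seqs("KS", "KR", seed=27))
        assert pair_distance(a, b).distance == pytest.approx(
            pair_distance(b, a).distance
        )


def _fake_nodes(n):
    return [inv(f"n{i:02d}", seqs("KS", "AT", seed=100 + i)) for i in range(n)]


def _fake_distances(nodes, rng):
    out = []
    for a, b in itertools.combinations([x.bgc_id for x in nodes], 2):
        out.append(PairDistance(a, b, 0, 0, 0, float(rng.uniform(0, 1))))
    return out


class TestNetwork:
    def test_single_bgc_is_a_singleton(self):
        nodes = _fake_nodes(1)
        _, gcfs = build_network(nodes, 0.4, distances=[])
        assert len(gcfs) == 1 and gcfs[0].is_singleton

    def test_transitivity_through_middle_node(self):
        nodes = _fake_nodes(3)
        d = [
            PairDistance("n00", "n01", 0, 0, 0, 0.2),
            PairDistance("n01", "n02", 0, 0, 0, 0.35),
            PairDistance("n00", "n02", 0, 0, 0, 0.9),
        ]
        _, gcfs = build_network(nodes, 0.4, distances=d)
        assert [set(g.members) for g in gcfs] == [{"n00", "n01", "n02"}]
        _, gcfs03 = build_network(nodes, 0.3, distances=d)
        assert sorted(map(sorted, (g.members for g in gcfs03))) == [
            ["n00", "n01"],
            ["n02"],
        ]

    def test_strict_inequality_at_cutoff(self):
        nodes = _fake_nodes(2)
        d = [PairDistance("n00", "n01", 0, 0, 0, 0.4)]
        edges, gcfs = build_network(nodes, 0.4, distances=d)
        assert edges == [] and len(gcfs) == 2

    def test_components_match_brute_force_closure(self):
        rng = np.random.default_rng(7)
        nodes = _fake_nodes(50)
        dist = _fake_distances(nodes, rng)
        cutoff = 0.08
        _, gcfs = build_network(nodes, cutoff, distances=dist)
        # brute-force transitive closure by repeated expansion
        ids = [n.bgc_id for n in nodes]
        adj = {i: {i} for i in ids}
        for d in dist:
            if d.distance < cutoff:
                adj[d.bgc1].add(d.bgc2)
                adj[d.bgc2].add(d.bgc1)
        changed = True
        while changed:
            changed = False
            for i in ids:
                new = set().union(*(adj[j] for j in adj[i]))
                if new != adj[i]:
                    adj[i] = new
                    changed = True
        expected = {frozenset(adj[i]) for i in ids}
        assert {frozenset(g.members) for g in gcfs} == expected

    def test_partitions_nest_across_cutoffs(self):
        rng = np.random.default_rng(8)
        nodes = _fake_nodes(30)
        dist = _fake_distances(nodes, rng)
        parts = {}
        for cutoff in (0.3, 0.4, 0.5, 0.6):
            _, gcfs = build_network(nodes, cutoff, distances=dist)
            parts[cutoff] = [set(g.members) for g in gcfs]
        for lo, hi in zip((0.3, 0.4, 0.5), (0.4, 0.5, 0.6)):
            for small in parts[lo]:
                assert any(small <= big for big in parts[hi])

    def test_every_bgc_in_exactly_one_gcf(self):
        rng = np.random.default_rng(9)
        nodes = _fake_nodes(20)
        _, gcfs = build_network(nodes, 0.5, distances=_fake_distances(nodes, rng))
        members = [m for g in gcfs for m in g.members]
        assert sorted(members) == sorted(n.bgc_id for n in nodes)


class TestPruneAndConserved:
    def test_reference_only_component_removed_mixed_kept_intact(self):
        gcfs = [
            GCF("GCF0001", ["ref1", "ref2"], 0.4),
            GCF("GCF0002", ["ref3", "bgcA", "bgcB"], 0.4),
            GCF("GCF0003", ["bgcC"], 0.4),
        ]
        flags = {"ref1": True, "ref2": True, "ref3": True}
        kept = prune_reference_only(gcfs, flags)
        assert [g.gcf_id for g in kept] == ["GCF0002", "GCF0003"]
        assert kept[0].members == ["ref3", "bgcA", "bgcB"]  # intact

    def test_no_references_is_identity(self):
        gcfs = [GCF("GCF0001", ["a"], 0.4), GCF("GCF0002", ["b", "c"], 0.4)]
        assert prune_reference_only(gcfs, {}) == gcfs

    def test_conserved_counting(self):
        universe = {"s1", "s2", "s3"}
        gcfs = [
            GCF("g1", ["a", "b", "c"], 0.4, species={"s1", "s2", "s3"}),
            GCF("g2", ["d", "e"], 0.4, species={"s1", "s2"}),
        ]
        assert conserved_gcfs(gcfs, universe) == 1
        assert conserved_gcfs([], universe) == 0


def test_divergence_ladder_monotonicity():
    """DSI non-increasing / distance non-decreasing as one locus's domain
    sequences drift from 95% down to 50% identity (nested mutation sets)."""
    rng = np.random.default_rng(33)
    base = [(d, make_protein(200, rng)) for d in ("KS", "AT", "ACP")]
    a = inv("a", base)
    order = {d + str(i): rng.permutation(200) for i, (d, _) in enumerate(base)}
    dsis, dists = [], []
    for t in (0.95, 0.85, 0.75, 0.65, 0.55, 0.50):
        copies = []
        for i, (d, s) in enumerate(base):
            n_mut = round((1 - t) * len(s))
            chars = list(s)
            for pos in order[d + str(i)][:n_mut]:
                chars[pos] = "W" if chars[pos] != "W" else "Y"
            copies.append((d, "".join(chars)))
        b = inv(f"b{t}", copies)
        pd_ = pair_distance(a, b)
        dsis.append(pd_.dsi)
        dists.append(pd_.distance)
    assert all(x >= y - 1e-12 for x, y in zip(dsis, dsis[1:]))
    assert all(x <= y + 1e-12 for x, y in zip(dists, dists[1:]))
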