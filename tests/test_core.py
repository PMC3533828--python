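"""Window enumeration, neighbor graph, and the qualification filters."""

import random

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import polysirna as ps
from polysirna.core import WindowOcc, pack_windows, packed_hd
from polysirna.fixtures import oracle_graph
from polysirna.seqio import GeneRecord

P = ps.DesignParams(length=21, d_t=4, d_n=6)

dna21 = st.text(alphabet="ACGT", min_size=21, max_size=21)


def rand_seq(rng, n):
    return "".join(rng.choice("ACGT") for _ in range(n))


class TestEnumerateWindows:
    def test_window_counts(self):
        params = ps.DesignParams()
        one = ps.enumerate_windows([GeneRecord("g", rand_seq(random.Random(0), 21))], params)
        assert len(one) == 1 and one[0].offset == 0
        five = ps.enumerate_windows([GeneRecord("g", rand_seq(random.Random(1), 25))], params)
        assert [o.offset for o in five] == [0, 1, 2, 3, 4]

    def test_short_gene_yields_nothing(self):
        assert ps.enumerate_windows([GeneRecord("g", "ACGT")], ps.DesignParams()) == []

    def test_n_windows_discarded(self):
        seq = "A" * 10 + "N" + "A" * 20
        occs = ps.enumerate_windows([GeneRecord("g", seq)], ps.DesignParams())
        # brute-force: windows not straddling position 10
        expected = [
            off
            for off in range(len(seq) - 21 + 1)
            if "N" not in seq[off : off + 21]
        ]
        assert [o.offset for o in occs] == expected
        assert all("N" not in o.seq for o in occs)

    def test_all_initially_marked(self):
        occs = ps.enumerate_windows([GeneRecord("g", rand_seq(random.Random(2), 40))], ps.DesignParams())
        assert all(o.marked for o in occs)


class TestHamming:
    def test_contract(self):
        assert ps.hamming("AAAA", "AAAA") == 0
        assert ps.hamming("AAAA", "TTTT") == 4
        with pytest.raises(ValueError):
            ps.hamming("AAA", "AAAA")

    @settings(max_examples=100, derandomize=True)
    @given(dna21, dna21)
    def test_matches_positionwise_count(self, a, b):
        assert ps.hamming(a, b) == sum(x != y for x, y in zip(a, b))

    @settings(max_examples=100, derandomize=True)
    @given(dna21, dna21)
    def test_packed_distance_equals_plain(self, a, b):
        packed = pack_windows([a, b])
        assert int(packed_hd(packed[0], packed[1])) == ps.hamming(a, b)


class TestRevcomp:
    def test_fixed_points(self):
        assert ps.guide_of("A" * 21) == "T" * 21
        palindrome = "ACGT" * 3  # revcomp(ACGT)=ACGT
        assert ps.revcomp(palindrome) == palindrome

    @settings(max_examples=100, derandomize=True)
    @given(dna21)
    def test_involution(self, s):
        assert ps.revcomp(ps.revcomp(s)) == s


def make_occs(rng, n_genes, n_per_gene, mutate_prob=0.5):
    """Random windows with planted similarity so relations are non-trivial."""
    base = rand_seq(rng, 21)
    occs = []
    for g in range(n_genes):
        for i in range(n_per_gene):
            if rng.random() < mutate_prob:
                s = list(base)
                for p in rng.sample(range(21), rng.randint(0, 7)):
                    s[p] = rng.choice("ACGT")
                seq = "".join(s)
            else:
                seq = rand_seq(rng, 21)
            occs.append(WindowOcc(f"g{g}", i * 30, seq))
    return occs


class TestBuildGraph:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_equals_all_pairs_oracle(self, seed):
        rng = random.Random(seed)
        occs = make_occs(rng, 6, 8)
        graph = ps.build_graph(occs, P)
        nbrs, fars = oracle_graph(occs, P)
        for i in range(len(occs)):
            assert set(graph.neighbors[i].tolist()) == nbrs[i]
            assert set(graph.far_neighbors[i].tolist()) == fars[i]

    def test_boundary_semantics(self):
        base = "A" * 21
        at_dt = "C" * P.d_t + "A" * (21 - P.d_t)  # HD exactly d_T
        at_dn = "C" * P.d_n + "A" * (21 - P.d_n)  # HD exactly d_N
        occs = [
            WindowOcc("g1", 0, base),
            WindowOcc("g2", 0, at_dt),
            WindowOcc("g3", 0, at_dn),
        ]
        graph = ps.build_graph(occs, P)
        assert list(graph.neighbors[0]) == [1]  # <= d_T: neighbor
        assert list(graph.far_neighbors[0]) == []  # == d_N: no relation
        assert graph.neighbor_dists[0].tolist() == [P.d_t]

    def test_identical_windows_distinct_occs(self):
        seq = rand_seq(random.Random(3), 21)
        occs = [WindowOcc("g1", 0, seq), WindowOcc("g2", 5, seq)]
        graph = ps.build_graph(occs, P)
        assert list(graph.neighbors[0]) == [1]
        assert graph.neighbor_dists[0].tolist() == [0]

    def test_relations_symmetric_irreflexive_disjoint(self):
        rng = random.Random(9)
        occs = make_occs(rng, 5, 6)
        graph = ps.build_graph(occs, P)
        for i in range(len(occs)):
            assert i not in graph.neighbors[i]
            assert i not in graph.far_neighbors[i]
            assert not (set(graph.neighbors[i]) & set(graph.far_neighbors[i]))
            for j in graph.neighbors[i]:
                assert i in graph.neighbors[j]
            for j in graph.far_neighbors[i]:
                assert i in graph.far_neighbors[j]


class TestFiltersAgainstDirectRules:
    """Filters on random graphs equal a direct restatement of each rule."""

    @pytest.mark.parametrize("seed", [4, 5, 6])
    def test_far_neighbor_rule(self, seed):
        rng = random.Random(seed)
        occs = make_occs(rng, 6, 6)
        graph = ps.build_graph(occs, P)
        ps.far_neighbor_filter(graph)
        for i, occ in enumerate(graph.occs):
            T = {occ.gene_id} | {graph.occs[j].gene_id for j in graph.neighbors[i]}
            ok = all(graph.occs[j].gene_id in T for j in graph.far_neighbors[i])
            assert occ.marked == ok

    @pytest.mark.parametrize("seed", [4, 5, 6])
    def test_powerful_flags_match_definition(self, seed):
        rng = random.Random(seed)
        occs = make_occs(rng, 6, 6)
        graph = ps.build_graph(occs, P)
        ps.far_neighbor_filter(graph)
        ps.powerful_filter(graph)
        for i, occ in enumerate(graph.occs):
            union = set()
            for v in graph.neighbors[i]:
                union |= set(graph.neighbors[v].tolist())
            assert occ.powerful == (union <= set(graph.neighbors[i].tolist()) | {i})

    @pytest.mark.parametrize("seed", [4, 5, 6])
    def test_dominated_target_sets_covered_by_dominator(self, seed):
        rng = random.Random(seed)
        occs = make_occs(rng, 6, 6)
        graph = ps.build_graph(occs, P)
        ps.far_neighbor_filter(graph)
        before = [o.marked for o in graph.occs]
        ps.powerful_filter(graph)
        for i, occ in enumerate(graph.occs):
            if before[i] and not occ.marked:
                dominators = [
                    v
                    for v in graph.neighbors[i]
                    if graph.occs[v].powerful and before[v]
                ]
                assert dominators
                assert any(
                    ps.target_set(i, graph) <= ps.target_set(v, graph)
                    for v in dominators
                )


class TestExcludedHitFilter:
    def test_empty_excluded_no_change(self):
        occs = make_occs(random.Random(1), 3, 3)
        graph = ps.build_graph(occs, P)
        marks = [o.marked for o in graph.occs]
        ps.excluded_hit_filter(graph, [])
        assert [o.marked for o in graph.occs] == marks

    def test_exact_copy_in_excluded_unmarks(self):
        seq = rand_seq(random.Random(2), 21)
        graph = ps.build_graph([WindowOcc("g1", 0, seq)], P)
        ps.excluded_hit_filter(graph, [GeneRecord("e1", seq, "excluded")])
        assert not graph.occs[0].marked

    def test_n_in_excluded_matches_any_base(self):
        # excluded window: five N positions (wildcard, distance 0) plus one
        # real mismatch -> effective distance 1 < d_N, a hit
        seq = "A" * 21
        ex = "N" * (P.d_n - 1) + "C" + "A" * (21 - P.d_n)
        graph = ps.build_graph([WindowOcc("g1", 0, seq)], P)
        ps.excluded_hit_filter(graph, [GeneRecord("e1", ex, "excluded")])
        assert not graph.occs[0].marked

    def test_distance_at_dn_is_not_a_hit(self):
        seq = "A" * 21
        ex = "C" * P.d_n + "A" * (21 - P.d_n)
        graph = ps.build_graph([WindowOcc("g1", 0, seq)], P)
        ps.excluded_hit_filter(graph, [GeneRecord("e1", ex, "excluded")])
        assert graph.occs[0].marked


def _mut(seq, positions):
    nxt = {"A": "C", "C": "G", "G": "T", "T": "A"}
    s = list(seq)
    for p in positions:
        s[p] = nxt[s[p]]
    return "".join(s)


@pytest.fixture(scope="module")
def topology_graph():
    """Windows realising the canonical filter-cascade topology.

    A hub S2 with three neighbors (S1, S4, S6) in distinct genes and one
    far_neighbor S5 sharing its gene with neighbor S4; a far pair S9/S10
    across genes; isolated windows S3, S7, S8, S11; an excluded gene
    carrying a near-copy of S11.
    """
    rng = random.Random(20)
    base = rand_seq(rng, 21)
    s2 = base
    s1 = _mut(base, [0, 1, 2])
    s4 = _mut(base, [3, 4, 5])
    s6 = _mut(base, [6, 7, 8])
    s5 = _mut(base, [9, 10, 11, 12, 13])
    s3, s7, s8, s9, s11 = (rand_seq(rng, 21) for _ in range(5))
    s10 = _mut(s9, [1, 3, 5, 7, 9])
    occs = [
        WindowOcc("C2", 0, s1),    # 0: S1
        WindowOcc("C1", 0, s2),    # 1: S2 (hub, powerful)
        WindowOcc("C1", 100, s3),  # 2: S3 isolated
        WindowOcc("C4", 0, s4),    # 3: S4
        WindowOcc("C4", 100, s5),  # 4: S5 far_neighbor of S2
        WindowOcc("C3", 0, s6),    # 5: S6
        WindowOcc("C5", 0, s7),    # 6: S7 isolated
        WindowOcc("C5", 100, s8),  # 7: S8 isolated
        WindowOcc("C6", 0, s9),    # 8: S9 far pair
        WindowOcc("C7", 0, s10),   # 9: S10 far pair
        WindowOcc("C8", 0, s11),   # 10: S11 excluded-gene hit
    ]
    excluded = [GeneRecord("E1", _mut(s11, [2, 8, 14]), "excluded")]
    graph = ps.build_graph(occs, P)
    return graph, excluded


class TestFilterCascadeTopology:
    """The three filters unmark exactly the windows the model predicts."""

    def test_intended_adjacency_realised(self, topology_graph):
        graph, _ = topology_graph
        assert set(graph.neighbors[1].tolist()) == {0, 3, 5}
        assert set(graph.far_neighbors[1].tolist()) == {4}
        assert set(graph.far_neighbors[8].tolist()) == {9}
        for iso in (2, 6, 7, 10):
            assert len(graph.neighbors[iso]) == 0
            assert len(graph.far_neighbors[iso]) == 0

    def test_far_neighbor_stage(self, topology_graph):
        graph, _ = topology_graph
        for o in graph.occs:
            o.marked = True
        ps.far_neighbor_filter(graph)
        unmarked = {i for i, o in enumerate(graph.occs) if not o.marked}
        # S5, S9, S10 carry far_neighbors outside their target sets; the
        # hub survives because its far_neighbor's gene is already a target
        assert unmarked == {4, 8, 9}

    def test_powerful_stage(self, topology_graph):
        graph, _ = topology_graph
        for o in graph.occs:
            o.marked = True
        ps.far_neighbor_filter(graph)
        ps.powerful_filter(graph)
        assert graph.occs[1].powerful and graph.occs[1].marked
        unmarked = {i for i, o in enumerate(graph.occs) if not o.marked}
        # hub dominates S1, S4, S6
        assert unmarked == {4, 8, 9} | {0, 3, 5}

    def test_excluded_stage_and_survivors(self, topology_graph):
        graph, excluded = topology_graph
        for o in graph.occs:
            o.marked = True
        ps.far_neighbor_filter(graph)
        ps.powerful_filter(graph)
        ps.excluded_hit_filter(graph, excluded)
        assert not graph.occs[10].marked  # S11: excluded-gene hit
        survivors = {i for i, o in enumerate(graph.occs) if o.marked}
        assert survivors == {1, 2, 6, 7}  # S2, S3, S7, S8


class TestMonotonicity:
    def test_raising_dt_never_shrinks_neighbor_sets(self):
        rng = random.Random(12)
        occs = make_occs(rng, 5, 6)
        g1 = ps.build_graph(occs, ps.DesignParams(21, 3, 6))
        g2 = ps.build_graph(occs, ps.DesignParams(21, 4, 6))
        for i in range(len(occs)):
            assert set(g1.neighbors[i].tolist()) <= set(g2.neighbors[i].tolist())
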