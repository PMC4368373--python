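import numpy as np
import pytest

from penmir.clustering import (
    Cluster,
    build_clusters,
    dominance_test,
    screen_contaminants,
    select_candidates,
)
from penmir.io_preprocess import CollapsedRead


def _cluster(members):
    """members: {seq: {lib: count}}"""
    return Cluster("c1", members)


def closure_clusters_bruteforce(counted):
    """Independent oracle: pairwise substring tests + transitive closure.

    ``counted``: {seq: total_count}.  Returns the set of frozensets of
    member sequences after discarding components with < 2 total copies.
    """
    seqs = sorted(counted)
    adj = {s: set() for s in seqs}
    for a in seqs:
        for b in seqs:
            if a != b and (a in b or b in a):
                adj[a].add(b)
                adj[b].add(a)
    seen, components = set(), []
    for s in seqs:
        if s in seen:
            continue
        stack, comp = [s], set()
        while stack:
            x = stack.pop()
            if x in comp:
                continue
            comp.add(x)
            stack.extend(adj[x] - comp)
        seen |= comp
        if sum(counted[x] for x in comp) >= 2:
            components.append(frozenset(comp))
    return set(components)


def random_read_pool(rng, n_reads):
    """Reads with realistic containment: fragments of a few source strings."""
    sources = ["".join(rng.choice(list("ACGT"), size=60)) for _ in range(4)]
    reads = []
    for _ in range(n_reads):
        src = sources[int(rng.integers(len(sources)))]
        ln = int(rng.integers(18, 27))
        st = int(rng.integers(0, len(src) - ln + 1))
        reads.append(src[st : st + ln])
    return reads


class TestBuildClusters:
    def test_two_identical_reads_form_one_cluster(self):
        libs = {"L1": [CollapsedRead("A" * 21, 1)], "L2": [CollapsedRead("A" * 21, 1)]}
        clusters = build_clusters(libs)
        assert len(clusters) == 1 and clusters[0].abundance == 2

    def test_prefix_containment_and_unrelated(self):
        long = "ACGTACGTACGTACGTACGTA"  # 21
        libs = {
            "L1": [
                CollapsedRead(long, 5),
                CollapsedRead(long[:20], 3),
                CollapsedRead("TTGGCCAATTGGCCAATTGGC", 4),
            ]
        }
        clusters = build_clusters(libs)
        assert sorted(c.abundance for c in clusters) == [4, 8]
        big = max(clusters, key=lambda c: c.abundance)
        assert big.representative == long

    def test_singleton_low_copy_discarded(self):
        libs = {"L1": [CollapsedRead("ACGTACGTACGTACGTACGTA", 1)]}
        assert build_clusters(libs) == []

    def test_matches_bruteforce_closure(self, rng):
        reads = random_read_pool(rng, 150)
        counted = {}
        for s in reads:
            counted[s] = counted.get(s, 0) + 1
        clusters = build_clusters({"L1": [CollapsedRead(s, c) for s, c in counted.items()]})
        got = {frozenset(c.members) for c in clusters}
        assert got == closure_clusters_bruteforce(counted)

    def test_partition_and_order_invariance(self, rng):
        reads = random_read_pool(rng, 120)
        counted = {}
        for s in reads:
            counted[s] = counted.get(s, 0) + 1
        items = [CollapsedRead(s, c) for s, c in counted.items()]
        a = build_clusters({"L1": items})
        shuffled = [items[i] for i in rng.permutation(len(items))]
        b = build_clusters({"L1": shuffled})
        parts_a = {frozenset(c.members) for c in a}
        parts_b = {frozenset(c.members) for c in b}
        assert parts_a == parts_b
        all_members = [s for c in a for s in c.members]
        assert len(all_members) == len(set(all_members))  # no read in 2 clusters


class TestSizeProfile:
    def test_profile_sums(self):
        cl = _cluster({"A" * 21: {"L1": 100}, "A" * 20: {"L1": 6}})
        assert cl.size_profile() == {21: 100, 20: 6}
        assert sum(cl.size_profile().values()) == cl.abundance

    def test_single_length(self):
        cl = _cluster({"C" * 22: {"L1": 9}})
        assert cl.size_profile() == {22: 9}

    def test_per_library_view(self):
        cl = _cluster({"A" * 21: {"L1": 4, "L2": 2}})
        assert cl.size_profile("L2") == {21: 2}


class TestDominance:
    def test_clear_21nt_dominance(self):
        cl = _cluster(
            {"A" * 21: {"L1": 100}, "A" * 20: {"L1": 6}, "A" * 22: {"L1": 4}}
        )
        dec = dominance_test(cl)
        assert dec.passed and dec.dominant_length == 21
        assert dec.dominance_fraction == pytest.approx(100 / 110)

    def test_flat_profile_fails(self):
        cl = _cluster(
            {
                "A" * 19: {"L1": 10},
                "A" * 20: {"L1": 11},
                "A" * 21: {"L1": 12},
                "A" * 22: {"L1": 10},
            }
        )
        dec = dominance_test(cl)
        assert not dec.passed
        assert dec.dominance_fraction == pytest.approx(12 / 43)

    def test_single_species(self):
        dec = dominance_test(_cluster({"T" * 21: {"L1": 50}}))
        assert dec.passed and dec.dominance_fraction == 1.0

    def test_empty_cluster_errors(self):
        with pytest.raises(ValueError):
            dominance_test(_cluster({}))

    def test_tie_goes_to_shorter_length(self):
        cl = _cluster({"A" * 20: {"L1": 10}, "A" * 21: {"L1": 10}})
        assert dominance_test(cl).dominant_length == 20


class TestContaminantScreen:
    def test_exact_hit_annotated(self):
        cl = _cluster({"ACGTACGTACGTACGTACGTA": {"L1": 5}})
        ann = screen_contaminants([cl], {"rrna": ["TTT" + cl.representative + "GGG"]})
        assert ann == {"c1": ["rrna"]}

    def test_empty_sets(self):
        cl = _cluster({"ACGTACGTACGTACGTACGTA": {"L1": 5}})
        assert screen_contaminants([cl], {}) == {}

    def test_one_mismatch_budget(self):
        rep = "ACGTACGTACGTACGTACGTA"
        mutated = rep[:10] + "T" + rep[11:]
        cl = _cluster({rep: {"L1": 5}})
        assert screen_contaminants([cl], {"db": [mutated]}, max_mismatches=0) == {}
        assert screen_contaminants([cl], {"db": [mutated]}, max_mismatches=1) == {
            "c1": ["db"]
        }


class TestSelectCandidates:
    def _setup(self):
        a = Cluster("a", {"T" + "A" * 20: {"vitro": 100}})
        b = Cluster("b", {"T" + "C" * 20: {"vitro": 50, "field": 5}})
        c = Cluster("c", {"T" + "G" * 20: {"field": 80}})
        clusters = [a, b, c]
        decisions = {cl.id: dominance_test(cl) for cl in clusters}
        origins = {"vitro": "in_vitro", "field": "field"}
        return clusters, decisions, origins

    def test_field_only_cluster_excluded(self):
        clusters, decisions, origins = self._setup()
        out = select_candidates(clusters, decisions, origins)
        assert [cl.id for cl in out] == ["a", "b"]

    def test_n_top_truncation(self):
        clusters, decisions, origins = self._setup()
        assert [c.id for c in select_candidates(clusters, decisions, origins, n_top=1)] == ["a"]

    def test_n_top_larger_than_pool(self):
        clusters, decisions, origins = self._setup()
        assert len(select_candidates(clusters, decisions, origins, n_top=99)) == 2
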