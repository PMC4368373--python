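import pytest
from hypothesis import given, settings, strategies as st

from penmir import catalog
from penmir.conserved import (
    ReferenceMiRNA,
    assign_families,
    best_overlap_alignment,
    cross_species_scan,
    family_mean_count,
    family_number,
)

dna = st.text(alphabet="ACGT", min_size=18, max_size=26)


def exhaustive_best(query, ref, min_overlap=17):
    """Independent enumeration of every ungapped offset."""
    lq, lr = len(query), len(ref)
    best = None
    for offset in range(-lr + 1, lq):
        start, end = max(0, offset), min(lq, offset + lr)
        overlap = end - start
        if overlap < min_overlap:
            continue
        mism = sum(1 for i in range(start, end) if query[i] != ref[i - offset])
        key = (mism, -overlap, abs(offset), offset)
        if best is None or key < best:
            best = key
    return best


class TestBestOverlapAlignment:
    def test_identical_sequences(self):
        aln = best_overlap_alignment("ACGT" * 6, "ACGT" * 6)
        assert (aln.offset, aln.overlap_len, aln.mismatches) == (0, 24, 0)

    def test_algal_homolog_pairs(self):
        expected = {"pen-miR8183.2": 2, "pen-miR8185": 1, "pen-miR1144": 2}
        for pair in catalog.load_algal_homologs():
            aln = best_overlap_alignment(pair.pen_seq, pair.algal_seq)
            assert aln.mismatches == expected[pair.name]
            assert aln.overlap_len == 18

    def test_no_valid_overlap_raises(self):
        with pytest.raises(ValueError, match="no valid overlap"):
            best_overlap_alignment("ACGTACGTACGTACGTAC", "TTTTTTTTTTTTTTTTTT", min_overlap=19)

    def test_matches_exhaustive_enumeration(self, rng):
        for _ in range(200):
            q = "".join(rng.choice(list("ACGT"), size=int(rng.integers(18, 27))))
            r = list(q)
            for p in rng.choice(len(r), size=int(rng.integers(0, 4)), replace=False):
                r[p] = "ACGT"[int(rng.integers(4))]
            r = "".join(r)[int(rng.integers(0, 3)) :]
            if len(r) < 17:
                continue
            aln = best_overlap_alignment(q, r)
            assert (aln.mismatches, -aln.overlap_len, abs(aln.offset), aln.offset) == exhaustive_best(q, r)

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(dna, dna)
    def test_symmetry(self, q, r):
        try:
            a = best_overlap_alignment(q, r)
        except ValueError:
            return
        b = best_overlap_alignment(r, q)
        assert (a.overlap_len, a.mismatches) == (b.overlap_len, b.mismatches)

    def test_mismatch_positions_reported(self):
        pair = next(p for p in catalog.load_algal_homologs() if p.name == "pen-miR8185")
        aln = best_overlap_alignment(pair.pen_seq, pair.algal_seq)
        assert len(aln.mismatch_positions) == 1
        (pos,) = aln.mismatch_positions
        assert pair.pen_seq[pos - 1] != pair.algal_seq[pos - 1 - aln.offset]


class TestAssignFamilies:
    REFS = [
        ReferenceMiRNA("miR999", "a", "xxx", "TGACAGAAGAGAGTGAGCACA"),
        ReferenceMiRNA("miR999", "b", "xxx", "TGACAGAAGAGAGTGAGCACT"),
        ReferenceMiRNA("miR777", "", "xxx", "TTTGGATTGAAGGGAGCTCTA"),
    ]

    def test_exact_containment_mn_zero(self):
        hits = assign_families({"q": "TGACAGAAGAGAGTGAGCAC"}, self.REFS)
        assert hits and hits[0].alignment.mismatches == 0

    def test_over_budget_unassigned(self):
        # three central edits: every overlap of >= 17 nt contains all three,
        # so no offset can stay within the 2-mismatch budget
        q = list("TGACAGAAGAGAGTGAGCAC")
        for p in (7, 9, 11):
            q[p] = {"A": "C", "C": "A", "G": "T", "T": "G"}[q[p]]
        assert assign_families({"q": "".join(q)}, self.REFS[:2], max_mismatches=2) == []

    def test_two_members_one_family(self):
        hits = assign_families({"q": "TGACAGAAGAGAGTGAGCAC"}, self.REFS)
        mine = [h for h in hits if h.family == "miR999"]
        assert len(mine) == 2 and {h.member for h in mine} == {"a", "b"}
        assert len({h.family for h in mine}) == 1

    def test_monotone_in_budget(self, rng):
        queries = {
            f"q{i}": "".join(rng.choice(list("ACGT"), size=21)) for i in range(30)
        }
        sizes = [
            len(assign_families(queries, self.REFS, max_mismatches=k))
            for k in range(0, 5)
        ]
        assert sizes == sorted(sizes)

    def test_empty_reference_is_config_error(self):
        with pytest.raises(ValueError):
            assign_families({"q": "A" * 21}, [])


class TestFamilyMeanCount:
    def test_single_member_mean(self):
        assignments = assign_families(
            {"q": "TGACAGAAGAGAGTGAGCAC"}, TestAssignFamilies.REFS
        )
        counts = {"q": {"L1": 10, "L2": 20, "L3": 30, "L4": 0, "L5": 0}}
        means = family_mean_count(assignments, counts, ["L1", "L2", "L3", "L4", "L5"])
        assert means["miR999"] == pytest.approx(12.0)

    def test_no_assigned_reads(self):
        assert family_mean_count([], {}, ["L1"]) == {}

    def test_two_members_summed(self):
        refs = TestAssignFamilies.REFS
        assignments = assign_families(
            {"q1": refs[0].seq, "q2": refs[1].seq}, refs
        )
        counts = {"q1": {"L1": 5, "L2": 5}, "q2": {"L1": 5, "L2": 5}}
        means = family_mean_count(assignments, counts, ["L1", "L2"])
        assert means["miR999"] == pytest.approx(10.0)


class TestCrossSpeciesScan:
    def test_identical_zero_mismatch_hit(self):
        hits = cross_species_scan({"c": "ACGT" * 6}, {"f": "ACGT" * 6})
        assert hits[0][2].mismatches == 0

    def test_catalogue_pair_reports_mismatch_position(self):
        pair = next(p for p in catalog.load_algal_homologs() if p.name == "pen-miR8185")
        hits = cross_species_scan({"pen": pair.pen_seq}, {"cre": pair.algal_seq})
        assert len(hits) == 1 and hits[0][2].mismatches == 1
        assert len(hits[0][2].mismatch_positions) == 1

    def test_dissimilar_set_empty(self, rng):
        # shuffled-alphabet foreign set: expected mismatches far above budget
        cand = {"c": "ACGTACGTACGTACGTACGTA"}
        foreign = {
            f"f{i}": "".join(rng.choice(list("ACGT"), size=21)) for i in range(20)
        }
        hits = cross_species_scan(cand, foreign, max_mismatches=0)
        brute = [
            f
            for f, seq in foreign.items()
            if exhaustive_best(cand["c"], seq) and exhaustive_best(cand["c"], seq)[0] == 0
        ]
        assert sorted(h[1] for h in hits) == sorted(brute)


def test_family_number_parsing():
    assert family_number("ath-miR156") == "156"
    assert family_number("osa-miR535") == "535"
    assert family_number("not-a-mir") is None
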