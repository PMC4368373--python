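import pytest

from penmir.hairpin import (
    FoldResult,
    build_precursor_candidate,
    detect_arm_pairs,
    find_precursor_windows,
    fold,
    infer_star,
    validate_hairpin,
    vienna_available,
)
from penmir.simulate import revcomp

PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}


def max_pairs_bruteforce(seq, i=0, j=None):
    """Exhaustive enumeration over all nested structures (min loop 3)."""
    if j is None:
        j = len(seq) - 1
    if j - i < 4:
        return 0
    best = max_pairs_bruteforce(seq, i + 1, j)
    for k in range(i + 4, j + 1):
        if (seq[i], seq[k]) in PAIRS:
            best = max(
                best,
                1
                + max_pairs_bruteforce(seq, i + 1, k - 1)
                + max_pairs_bruteforce(seq, k + 1, j),
            )
    return best


def perfect_hairpin(mir, loop="AAAA"):
    return mir + loop + revcomp(mir)


class TestFold:
    def test_perfect_inverted_repeat_fully_paired(self):
        s = "ATGCATGCATGCATG"  # 15 nt
        fr = fold(s + "AAAA" + revcomp(s))
        assert fr.score == 15 and fr.n_pairs() == 15
        assert all(fr.pair_table[i] for i in range(1, 16))

    def test_homopolymer_unpaired(self):
        fr = fold("AAAAAA")
        assert fr.structure == "......" and fr.score == 0

    def test_matches_exhaustive_enumeration(self, rng):
        for n in (8, 10, 12, 14, 16, 18):
            for _ in range(6):
                s = "".join(rng.choice(list("ACGT"), size=n))
                assert fold(s).score == max_pairs_bruteforce(s), s

    def test_pair_table_involutive_and_nested(self, rng):
        for _ in range(10):
            s = "".join(rng.choice(list("ACGT"), size=60))
            fr = fold(s)
            pt = fr.pair_table
            opened = []
            for i in range(1, len(s) + 1):
                if pt[i]:
                    assert pt[pt[i]] == i  # involution
                    assert (s[i - 1], s[pt[i] - 1]) in PAIRS  # legal pairs
                    assert abs(pt[i] - i) > 3  # min loop
            # crossing-free: dot-bracket parses with a simple stack
            stack = []
            for i, c in enumerate(fr.structure, start=1):
                if c == "(":
                    stack.append(i)
                elif c == ")":
                    assert pt[i] == stack.pop()

    def test_invalid_characters_error(self):
        with pytest.raises(ValueError):
            fold("ACGTNNN")

    def test_vienna_engine_tagged(self):
        if not vienna_available():
            pytest.xfail("RNAfold executable not on PATH")
        mir = "TTGCATGCTAGCATGCATGCT"
        fr = fold(perfect_hairpin(mir, "GAAAG"), engine="vienna")
        assert fr.engine == "vienna" and fr.score < 0
        assert len(fr.structure) == len(fr.seq)
        assert fr.pair_table[fr.pair_table.index(max(fr.pair_table))] > 0


class TestValidateHairpin:
    MIR = "ATGCATGCATGCATGCATGC"  # 20 nt

    def test_perfect_five_prime_arm_accepted(self):
        fr = fold(perfect_hairpin(self.MIR))
        arm, mism = validate_hairpin(fr, 1, 20)
        assert arm == "five_prime" and mism == 0

    def test_mir_spanning_loop_rejected(self):
        fr = fold(perfect_hairpin(self.MIR))
        # a "mature" spanning the loop has partners on both sides
        arm, _ = validate_hairpin(fr, 11, 34)
        assert arm is None

    def test_forty_percent_unpaired_rejected(self):
        # constructed pair table: 12 of 20 mir positions paired (60% paired
        # passes); 8 unpaired exceeds neither, so drop to 40% paired
        n = 60
        pt = [0] * (n + 1)
        for i in range(1, 9):  # only 8 of 20 positions paired
            pt[i] = n - i + 1
            pt[n - i + 1] = i
        fr = FoldResult("A" * n, "." * n, pt, 8.0, "maxpair")
        arm, _ = validate_hairpin(fr, 1, 20)
        assert arm is None


class TestInferStar:
    def test_perfect_stem_spec_geometry(self):
        # 44-nt hairpin, pairs i <-> 45 - i, miRNA at [1, 20], loop 21-24
        mir = "ATGCATGCATGCATGCATGC"
        fr = fold(perfect_hairpin(mir))
        assert len(fr.seq) == 44
        star = infer_star(fr, 1, 20, "five_prime")
        assert star == (27, 44)

    def test_three_prime_arm_mirrored(self):
        mir = "ATGCATGCATGCATGCATGC"
        fr = fold(perfect_hairpin(mir))
        star = infer_star(fr, 25, 44, "three_prime")
        assert star == (1, 18)

    def test_star_revcomp_matches_mir_over_pairs(self):
        mir = "TTGACCGTAGCATGCATGCA"
        hp = perfect_hairpin(mir)
        fr = fold(hp)
        s, e = infer_star(fr, 1, 20, "five_prime")
        star = hp[s - 1 : e]
        # with a perfect duplex and 2-nt overhang, the star's reverse
        # complement reproduces the miRNA over the paired region
        assert revcomp(star) == mir[:18]


class TestPrecursorWindows:
    def test_absent_mirna(self):
        assert find_precursor_windows("A" * 21, {"t": "C" * 100}) == []

    def test_window_arithmetic(self):
        mir = "ATGCATGCATGCATGCATGCA"  # 21 nt
        t = "C" * 249 + mir + "G" * 730  # occurrence at 250-270 of 1000 nt
        (win,) = find_precursor_windows(mir, {"t": t}, flank=200)
        assert win == ("t", 50, 470, 250, 270)

    def test_two_occurrences(self):
        mir = "ATGCATGCATGCATGCATGCA"
        t = "C" * 50 + mir + "G" * 100 + mir + "C" * 50
        assert len(find_precursor_windows(mir, {"t": t})) == 2


class TestArmPairs:
    def _two_arm_candidates(self):
        mir = "TATCGTAGCATGCATGCATGA"
        hp = perfect_hairpin(mir, "GAGAGAGA")
        t = "C" * 150 + hp + "G" * 150
        w5 = find_precursor_windows(mir, {"t": t})[0]
        c5 = build_precursor_candidate("t", t, mir, w5[1:], mirna_id="m5")
        star = t[c5.star[0] - 1 : c5.star[1]]
        w3 = find_precursor_windows(star, {"t": t})[0]
        c3 = build_precursor_candidate("t", t, star, w3[1:], mirna_id="m3")
        assert c5 and c3 and {c5.arm, c3.arm} == {"five_prime", "three_prime"}
        return [c5, c3]

    def test_both_arms_abundant(self):
        pairs = detect_arm_pairs(self._two_arm_candidates(), {"m5": 1000, "m3": 800})
        assert len(pairs) == 1
        assert pairs[0]["both_abundant"] and pairs[0]["ratio"] == pytest.approx(0.8)

    def test_single_arm_no_pair(self):
        cands = self._two_arm_candidates()[:1]
        assert detect_arm_pairs(cands, {"m5": 1000}) == []

    def test_skewed_ratio_not_flagged(self):
        pairs = detect_arm_pairs(self._two_arm_candidates(), {"m5": 1000, "m3": 50})
        assert len(pairs) == 1 and not pairs[0]["both_abundant"]


class TestPlantedAndShuffled:
    def test_planted_precursors_accepted_and_shuffled_rejected(
        self, small_experiment, rng
    ):
        exp = small_experiment
        accepted = 0
        for m in exp.truth.mirnas:
            t = exp.transcripts[m.transcript_id]
            wins = find_precursor_windows(m.seq, {m.transcript_id: t})
            assert any(
                build_precursor_candidate(m.transcript_id, t, m.seq, w[1:])
                for w in wins
            )
            accepted += 1
        assert accepted == len(exp.truth.mirnas)
        # shuffled windows: same composition, no planted structure
        rejected = 0
        trials = 60
        mir = exp.truth.mirnas[0]
        for _ in range(trials):
            window = "".join(
                rng.permutation(list(exp.transcripts[mir.transcript_id][:440]))
            )
            seq = window[:200] + mir.seq + window[200:]
            win = (1, len(seq), 201, 200 + len(mir.seq))
            if build_precursor_candidate("x", seq, mir.seq, win) is None:
                rejected += 1
        assert rejected / trials >= 0.95
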