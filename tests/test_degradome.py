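import numpy as np
import pytest

from penmir.degradome import (
    TPlot,
    build_tplots,
    call_cleavage,
    map_tags,
    mapped_library_size,
    normalize_tp1m,
    summarize_targets,
)
from penmir.orf import CodingAnnotation
from penmir.simulate import revcomp
from penmir.targets import DuplexAlignment, TargetCandidate


def _target(tid="t", site=(100, 120)):
    dup = DuplexAlignment("m", "A" * 21, tid, site, "W" * 21)
    end = site[1]
    return TargetCandidate(
        dup,
        retained=True,
        predicted_cleavage_window=(end - 10, end - 9, end - 8),
        canonical_cleavage=end - 9,
    )


class TestMapTags:
    TX = {"t1": "A" * 50 + "CGTACGTACGTACGTACG" + "A" * 50, "t2": "CGTACGTACGTACGTACG" + "T" * 80}

    def test_single_occurrence(self):
        (tag,) = map_tags({"CGTACGTACGTACG" + "AAAA": 3}, {"t1": self.TX["t1"]})
        assert tag.mapped_positions == [("t1", 55)] and tag.multiplicity == 1

    def test_two_transcripts(self):
        (tag,) = map_tags({"CGTACGTACGTACGTACG": 1}, self.TX)
        assert tag.multiplicity == 2

    def test_unmapped_excluded_from_library_size(self):
        tags = map_tags({"CGTACGTACGTACGTACG": 4, "GGGGGGGGGGGGGG": 9}, self.TX)
        assert mapped_library_size(tags) == 4


class TestNormalize:
    def test_printed_formula(self):
        assert normalize_tp1m(10, 2_000_000, 1) == pytest.approx(5.0)

    def test_multiplicity_division(self):
        assert normalize_tp1m(10, 2_000_000, 2) == pytest.approx(2.5)

    def test_zero_raw(self):
        assert normalize_tp1m(0, 100, 1) == 0.0

    def test_errors(self):
        with pytest.raises(ValueError):
            normalize_tp1m(1, 0, 1)
        with pytest.raises(ValueError):
            normalize_tp1m(1, 100, 0)


class TestTPlotAndCalls:
    def _tplot(self):
        # signals straight from the threshold worked example
        return TPlot("t", {100: 50.0, 7: 1.0, 300: 1.0}, {100: 50, 7: 1, 300: 1}, 52)

    def test_threshold_is_mean_over_tag_positions(self):
        assert self._tplot().threshold == pytest.approx(52 / 3)

    def test_single_position_threshold_equals_signal(self):
        tp = TPlot("t", {10: 5.0}, {10: 5}, 5)
        assert tp.threshold == 5.0
        # strict inequality: a single-position T-plot can never yield
        # category 1/2 — its only signal equals the mean
        call = call_cleavage(tp, _target(site=(1, 21)))
        assert call is None or call.category == 3

    def test_empty_plot(self):
        tp = TPlot("t", {}, {}, 10)
        assert tp.threshold is None
        assert call_cleavage(tp, _target()) is None

    def test_category_one_at_unique_maximum(self):
        call = call_cleavage(self._tplot(), _target(site=(89, 109)))
        # window {98, 99, 100... wait: end=109 -> window {99, 100, 101}
        assert call is not None
        assert call.observed_position == 100 and call.category == 1
        assert call.matched_window_offset == 0

    def test_category_three_below_threshold(self):
        tp = TPlot("t", {100: 50.0, 7: 1.0, 300: 5.0}, {}, 56)
        call = call_cleavage(tp, _target(site=(289, 309)))
        assert call is not None and call.category == 3

    def test_no_signal_in_window_no_call(self):
        call = call_cleavage(self._tplot(), _target(site=(180, 200)))
        assert call is None

    def test_never_calls_outside_window(self, rng):
        tp = self._tplot()
        for end in range(20, 320, 7):
            call = call_cleavage(tp, _target(site=(end - 20, end)))
            if call is not None:
                assert call.observed_position in {end - 10, end - 9, end - 8}


class TestBuildTPlots:
    def test_count_conservation(self, rng):
        transcripts = {
            f"t{i}": "".join(rng.choice(list("ACGT"), size=400)) for i in range(4)
        }
        tags = {}
        for tid, seq in transcripts.items():
            for _ in range(30):
                p = int(rng.integers(0, 380))
                tags[seq[p : p + 20]] = tags.get(seq[p : p + 20], 0) + int(
                    rng.integers(1, 5)
                )
        mapped = map_tags(tags, transcripts)
        tplots = build_tplots(mapped)
        # per transcript, summed raw per-position counts equal the summed
        # raw counts of tags mapping there
        for tid, tp in tplots.items():
            expect = sum(
                t.count
                for t in mapped
                for (mtid, _pos) in t.mapped_positions
                if mtid == tid
            )
            assert sum(tp.raw.values()) == expect

    def test_scaling_invariance(self, rng):
        transcripts = {"t": "".join(rng.choice(list("ACGT"), size=500))}
        tags = {}
        for _ in range(40):
            p = int(rng.integers(0, 470))
            tags[transcripts["t"][p : p + 20]] = int(rng.integers(1, 6))
        mapped1 = map_tags(tags, transcripts)
        tp1 = build_tplots(mapped1)["t"]
        scaled = {s: c * 7 for s, c in tags.items()}
        tp7 = build_tplots(map_tags(scaled, transcripts))["t"]
        assert tp1.signal == pytest.approx(tp7.signal)
        assert tp1.threshold == pytest.approx(tp7.threshold)
        target = _target(tid="t", site=(200, 220))
        c1, c7 = call_cleavage(tp1, target), call_cleavage(tp7, target)
        assert (c1 is None) == (c7 is None)
        if c1:
            assert (c1.observed_position, c1.category) == (
                c7.observed_position,
                c7.category,
            )


class TestSummarize:
    def _call(self, mid, pos=111, cat=1):
        dup = DuplexAlignment(mid, "A" * 21, "t", (100, 120), "W" * 21)
        tc = TargetCandidate(dup, True, None, (110, 111, 112), 111)
        from penmir.degradome import CleavageCall

        return CleavageCall(tc, pos, 50.0, cat, 0)

    def test_shared_site_collapsed_to_one_row(self):
        ann = {"t": CodingAnnotation("t", (50, 400), 0, "+", 1.0, True, 600)}
        table = summarize_targets(
            [self._call("miR472"), self._call("miR482"), self._call("miR2118")], ann
        )
        assert len(table) == 1
        assert table.iloc[0]["mirnas"] == "miR2118;miR472;miR482"
        assert table.iloc[0]["cleavage_region"] == "CDS"

    def test_utr_region_label(self):
        ann = {"t": CodingAnnotation("t", (5, 50), 0, "+", 1.0, True, 600)}
        table = summarize_targets([self._call("m")], ann)
        assert table.iloc[0]["cleavage_region"] == "3' UTR"


class TestSpikeRecovery:
    def test_planted_spikes_called_category_one(self, rng):
        """>= 95% of planted canonical-position spikes (5% of transcript
        tags over uniform background) come back as category-1 calls."""
        n_tx, L, n_tags, spike_frac = 200, 1500, 200, 0.05
        transcripts = {}
        targets = {}
        tags = {}
        for i in range(n_tx):
            tid = f"t{i:03d}"
            seq = "".join(rng.choice(list("ACGT"), size=L))
            transcripts[tid] = seq
            canonical = int(rng.integers(200, L - 200))
            targets[tid] = _target(tid=tid, site=(canonical - 11, canonical + 9))
            n_spike = int(round(spike_frac * n_tags))
            counts = {}
            counts[canonical] = counts.get(canonical, 0) + n_spike
            for _ in range(n_tags - n_spike):
                p = int(rng.integers(1, L - 19))
                counts[p] = counts.get(p, 0) + 1
            for p, c in counts.items():
                tag = seq[p - 1 : p + 19]
                tags[tag] = tags.get(tag, 0) + c
        mapped = map_tags(tags, transcripts)
        tplots = build_tplots(mapped)
        hits = 0
        for tid, target in targets.items():
            call = call_cleavage(tplots[tid], target)
            if (
                call is not None
                and call.category == 1
                and call.observed_position == target.canonical_cleavage
            ):
                hits += 1
        assert hits / n_tx >= 0.95
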