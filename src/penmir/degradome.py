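"""Degradome (PARE) mapping, T-plots, and cleavage-site calling.

Degradome tags are the 5' ends of uncapped mRNA fragments; a miRNA-guided
slicing event leaves a sharp pile-up of tag 5' ends at the cleavage
position.  Tags are mapped to transcripts by exact match, per-position
signals are normalized to TP1M — tags per million divided by the tag's
transcript multiplicity:

    TP1M = (raw / library_size) * 1e6 / m

and per-transcript *T-plots* are compared against the cleavage window
predicted from the miRNA:target duplex (positions facing miRNA 9-11).
Each T-plot's threshold is the mean TP1M over tag-bearing positions, and
calls fall into three categories:

1. the window position is above threshold and is the unique
   transcript-wide signal maximum;
2. above threshold but not the unique maximum;
3. non-zero window signal at or below threshold (low confidence).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .orf import CodingAnnotation, REGION_LABELS, classify_region
from .targets import TargetCandidate


@dataclass
class DegradomeTag:
    seq: str
    count: int
    mapped_positions: List[Tuple[str, int]] = field(default_factory=list)

    @property
    def multiplicity(self) -> int:
        return len({tid for tid, _ in self.mapped_positions})


@dataclass
class TPlot:
    transcript_id: str
    signal: Dict[int, float]  # position -> TP1M
    raw: Dict[int, int]  # position -> raw tag count
    library_size: int

    @property
    def threshold(self) -> Optional[float]:
        """Mean TP1M over tag-bearing positions (None for empty plots)."""
        if not self.signal:
            return None
        return sum(self.signal.values()) / len(self.signal)


@dataclass
class CleavageCall:
    target: TargetCandidate
    observed_position: int
    signal_value: float
    category: int
    matched_window_offset: int  # -1/0/+1 relative to the canonical position


def map_tags(
    tags: Mapping[str, int], transcripts: Mapping[str, str]
) -> List[DegradomeTag]:
    """Exact forward-strand mapping of tag sequences.

    Every occurrence is recorded as ``(transcript_id, 5'-position)``
    (1-based).  Multiplicity counts distinct transcripts hit, not
    occurrences.
    """
    by_tag: Dict[str, DegradomeTag] = {
        seq: DegradomeTag(seq, tags[seq]) for seq in tags
    }
    # scan each transcript once per tag length with a rolling window
    lengths = sorted({len(s) for s in tags if s})
    for tid in sorted(transcripts):
        tseq = transcripts[tid]
        for L in lengths:
            for start in range(len(tseq) - L + 1):
                hit = by_tag.get(tseq[start : start + L])
                if hit is not None:
                    hit.mapped_positions.append((tid, start + 1))
    return [by_tag[seq] for seq in sorted(by_tag)]


def mapped_library_size(tags: Iterable[DegradomeTag]) -> int:
    """Total raw count of tags with at least one mapping.

    Unmapped tags are excluded from the normalization denominator; this
    choice is recorded in output metadata.
    """
    return sum(t.count for t in tags if t.mapped_positions)


def normalize_tp1m(raw: int, library_size: int, m: int) -> float:
    """TP1M = (raw / library_size) * 1e6 / multiplicity."""
    if library_size <= 0:
        raise ValueError("library_size must be > 0")
    if m < 1:
        raise ValueError("multiplicity must be >= 1")
    return raw / library_size * 1e6 / m


def build_tplots(
    tags: Sequence[DegradomeTag],
    library_size: Optional[int] = None,
) -> Dict[str, TPlot]:
    """Per-transcript T-plots from mapped tags.

    The signal at a position is the summed TP1M of tags whose 5' end maps
    there.  ``library_size`` defaults to the mapped-tag total.
    """
    if library_size is None:
        library_size = mapped_library_size(tags)
    signal: Dict[str, Dict[int, float]] = {}
    raw: Dict[str, Dict[int, int]] = {}
    for tag in tags:
        if not tag.mapped_positions:
            continue
        m = tag.multiplicity
        tp1m = normalize_tp1m(tag.count, library_size, m)
        for tid, pos in tag.mapped_positions:
            signal.setdefault(tid, {})
            raw.setdefault(tid, {})
            signal[tid][pos] = signal[tid].get(pos, 0.0) + tp1m
            raw[tid][pos] = raw[tid].get(pos, 0) + tag.count
    return {
        tid: TPlot(tid, signal[tid], raw[tid], library_size) for tid in signal
    }


def call_cleavage(
    tplot: TPlot, target: TargetCandidate
) -> Optional[CleavageCall]:
    """Evaluate one predicted target against a T-plot.

    The candidate position is the signal argmax inside the predicted 9-11
    window (ties resolved towards the canonical position, then 5').
    No call is ever made outside that window.
    """
    window = target.predicted_cleavage_window
    canonical = target.canonical_cleavage
    in_window = [
        (p, tplot.signal.get(p, 0.0)) for p in window if tplot.signal.get(p, 0.0) > 0
    ]
    if not in_window:
        return None
    pos, value = max(
        in_window,
        key=lambda pv: (pv[1], -abs(pv[0] - (canonical or pv[0])), -pv[0]),
    )
    threshold = tplot.threshold or 0.0
    max_signal = max(tplot.signal.values())
    if value > threshold:
        unique_max = value == max_signal and sum(
            1 for v in tplot.signal.values() if v == max_signal
        ) == 1
        category = 1 if unique_max else 2
    else:
        category = 3
    return CleavageCall(
        target=target,
        observed_position=pos,
        signal_value=value,
        category=category,
        matched_window_offset=(pos - canonical) if canonical is not None else 0,
    )


def summarize_targets(
    calls: Sequence[CleavageCall],
    annotations: Mapping[str, CodingAnnotation],
) -> pd.DataFrame:
    """Final target table: one row per (cleavage site, transcript).

    miRNAs sharing one site on one transcript are collapsed into a single
    row listing all miRNA species.  The cleavage region is classified
    against the coding annotation when one exists.
    """
    grouped: Dict[Tuple[str, int], List[CleavageCall]] = {}
    for call in calls:
        key = (call.target.duplex.transcript_id, call.observed_position)
        grouped.setdefault(key, []).append(call)
    rows = []
    for (tid, pos), group in sorted(grouped.items()):
        ann = annotations.get(tid)
        region = REGION_LABELS[classify_region(ann, pos)] if ann else "NA"
        group = sorted(group, key=lambda c: c.target.duplex.mirna_id)
        rows.append(
            {
                "transcript_id": tid,
                "cleavage_site": pos,
                "cleavage_region": region,
                "mirnas": ";".join(
                    dict.fromkeys(c.target.duplex.mirna_id for c in group)
                ),
                "category": min(c.category for c in group),
                "signal_tp1m": group[0].signal_value,
                "total_score": min(c.target.duplex.total_score for c in group),
                "seed_score": min(c.target.duplex.seed_score for c in group),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "transcript_id",
            "cleavage_site",
            "cleavage_region",
            "mirnas",
            "category",
            "signal_tp1m",
            "total_score",
            "seed_score",
        ],
    )


def write_tplot_tsv(tplot: TPlot, path) -> None:
    with open(path, "w") as fh:
        fh.write("position\traw\ttp1m\n")
        for pos in sorted(tplot.signal):
            fh.write(f"{pos}\t{tplot.raw[pos]}\t{tplot.signal[pos]:.6f}\n")
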