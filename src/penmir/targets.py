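"""miRNA target-site scanning with mismatch / G:U wobble scoring.

Plant miRNAs guide cleavage of near-perfectly complementary sites.  The
scanner slides a mature miRNA along a transcript without gaps; at every
offset each miRNA position is classified against the antiparallel
transcript base as Watson-Crick (WC), G:U wobble (GU) or mismatch (MM).
The penalty is 1 point per mismatch and 0.5 per G:U pair, summed over all
positions (*total score*) and over miRNA positions 1-12 (*seed score*,
counted from the miRNA 5' end).  Default retention discards duplexes with
total score >= 4 or seed score > 2.5.

RISC slices the target opposite miRNA position 10; the transcript
position facing it is the *canonical cleavage site*, and positions facing
miRNA 9-11 form the window against which degradome evidence is compared.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .io_preprocess import encode_seq, normalize_seq

WC, GU, MM = "W", "G", "M"

#: display notation for pairing states in report files
STATE_DISPLAY = {WC: "|", GU: "o", MM: "x"}
_DISPLAY_STATE = {v: k for k, v in STATE_DISPLAY.items()}

# pair class for (miRNA base, transcript base), codes A=0 C=1 G=2 T=3:
# 0 = WC, 1 = GU wobble, 2 = mismatch
_PAIR_CLASS = np.full((4, 4), 2, dtype=np.uint8)
for _m, _t in [(0, 3), (3, 0), (2, 1), (1, 2)]:
    _PAIR_CLASS[_m, _t] = 0
for _m, _t in [(2, 3), (3, 2)]:
    _PAIR_CLASS[_m, _t] = 1


@dataclass
class DuplexAlignment:
    """An ungapped miRNA:target duplex.

    ``site`` is 1-based inclusive on the transcript, 5'->3'.  ``states``
    holds one state per miRNA position 1..n (5'->3'), so position ``k``
    faces transcript position ``site[1] - k + 1`` (antiparallel pairing).
    """

    mirna_id: str
    mirna_seq: str
    transcript_id: str
    site: Tuple[int, int]
    states: str

    @property
    def total_score(self) -> float:
        return self.states.count(MM) + 0.5 * self.states.count(GU)

    @property
    def seed_score(self) -> float:
        seed = self.states[:12]
        return seed.count(MM) + 0.5 * seed.count(GU)

    def display_states(self) -> str:
        return "".join(STATE_DISPLAY[s] for s in self.states)


@dataclass
class TargetCandidate:
    duplex: DuplexAlignment
    retained: bool
    rejection_reason: Optional[str] = None
    predicted_cleavage_window: Tuple[int, ...] = ()
    canonical_cleavage: Optional[int] = None


def score_duplex(duplex: DuplexAlignment) -> Tuple[float, float]:
    """(total, seed) scores: 1 per mismatch, 0.5 per G:U wobble."""
    return duplex.total_score, duplex.seed_score


def scan_targets(
    mirna_seq: str,
    transcript_seq: str,
    mirna_id: str = "mirna",
    transcript_id: str = "transcript",
    score_ceiling: float = 7.0,
) -> List[DuplexAlignment]:
    """All ungapped sites with total score below ``score_ceiling``.

    Vectorized over offsets; each returned alignment carries its full
    per-position pairing-state string.
    """
    m = normalize_seq(mirna_seq)
    t = normalize_seq(transcript_seq)
    n = len(m)
    if not 18 <= n <= 26:
        raise ValueError("miRNA length must be 18-26 nt")
    if len(t) < n:
        return []
    mc = encode_seq(m)
    tc = encode_seq(t)
    windows = sliding_window_view(tc, n)
    # classify every (offset, miRNA position); miRNA position k (1-based)
    # faces window column n - k
    cls = _PAIR_CLASS[mc[None, :], windows[:, ::-1]]
    mm = (cls == 2).sum(axis=1)
    gu = (cls == 1).sum(axis=1)
    totals = mm + 0.5 * gu
    out = []
    for off in np.nonzero(totals < score_ceiling)[0]:
        states = "".join("WGM"[c] for c in cls[off])
        out.append(
            DuplexAlignment(
                mirna_id, m, transcript_id, (int(off) + 1, int(off) + n), states
            )
        )
    return out


def predicted_cleavage_window(
    duplex: DuplexAlignment, transcript_length: Optional[int] = None
) -> Tuple[Tuple[int, ...], Optional[int]]:
    """Transcript positions facing miRNA positions 9-11 (and 10 alone).

    Returns ``(window, canonical)``; the canonical position faces miRNA
    position 10.  Both are clipped to the transcript when a length is
    given (the canonical position becomes ``None`` if it falls outside).
    """
    end = duplex.site[1]
    canonical = end - 9
    window = (end - 10, end - 9, end - 8)
    lo, hi = 1, transcript_length if transcript_length else max(window)
    clipped = tuple(p for p in window if lo <= p <= hi)
    return clipped, canonical if lo <= canonical <= hi else None


def filter_duplexes(
    duplexes: Sequence[DuplexAlignment],
    total_max: float = 4.0,
    seed_max: float = 2.5,
    combine: str = "either",
    transcript_lengths: Optional[Mapping[str, int]] = None,
) -> List[TargetCandidate]:
    """Apply the retention thresholds and attach cleavage windows.

    With ``combine="either"`` (default) a duplex is discarded when the
    total score reaches ``total_max`` *or* the seed score exceeds
    ``seed_max``; ``combine="both"`` requires both conditions to discard.
    Every discard carries its reason.
    """
    if combine not in ("either", "both"):
        raise ValueError("combine must be 'either' or 'both'")
    out = []
    for d in duplexes:
        total, seed = score_duplex(d)
        over_total = total >= total_max
        over_seed = seed > seed_max
        discard = (over_total or over_seed) if combine == "either" else (
            over_total and over_seed
        )
        reasons = []
        if over_total:
            reasons.append("total")
        if over_seed:
            reasons.append("seed")
        tl = (
            transcript_lengths.get(d.transcript_id)
            if transcript_lengths
            else None
        )
        window, canonical = predicted_cleavage_window(d, tl)
        out.append(
            TargetCandidate(
                duplex=d,
                retained=not discard,
                rejection_reason="+".join(reasons) if discard else None,
                predicted_cleavage_window=window,
                canonical_cleavage=canonical,
            )
        )
    return out


def import_external_sites(
    path,
) -> Tuple[List[DuplexAlignment], List[Tuple[int, str]]]:
    """Parse externally predicted sites from TSV.

    Columns: miRNA id, miRNA sequence, transcript id, site start, site
    end, pairing-state string in ``|``/``o``/``x`` (or W/G/M) notation.
    Malformed rows are reported as ``(line_number, message)`` and skipped.
    """
    duplexes: List[DuplexAlignment] = []
    errors: List[Tuple[int, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 6:
                errors.append((lineno, "expected 6 tab-separated columns"))
                continue
            mid, mseq, tid, start_s, end_s, states_in = parts
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                errors.append((lineno, "non-integer site coordinates"))
                continue
            states = "".join(_DISPLAY_STATE.get(c, c) for c in states_in)
            if any(s not in (WC, GU, MM) for s in states):
                errors.append((lineno, "bad pairing-state character"))
                continue
            if end - start + 1 != len(states):
                errors.append((lineno, "state string length != site length"))
                continue
            mseq = normalize_seq(mseq)
            if len(mseq) != len(states):
                errors.append((lineno, "state string length != miRNA length"))
                continue
            duplexes.append(DuplexAlignment(mid, mseq, tid, (start, end), states))
    return duplexes, errors
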