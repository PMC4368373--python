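"""Pre-miRNA stem-loop prediction and miR/miR* duplex validation.

A genuine plant pre-miRNA folds into a stem-loop in which the mature miRNA
pairs against a single opposing arm (the star arm), and the miR/miR*
duplex is excised with 2-nt 3' overhangs.  Candidate mature sequences are
located in assembled transcripts, a window around each occurrence is
folded, and the fold is checked for these structural hallmarks.

Two folding engines sit behind one interface:

* ``maxpair`` (built in, default) — deterministic base-pair maximization by
  dynamic programming over canonical (A-U, G-C) plus G-U wobble pairs with
  a minimum hairpin loop of 3 nt; the score is the pair count.
* ``vienna`` (optional) — thermodynamic minimum-free-energy folding via the
  ``RNAfold`` executable; the score is the free energy in kcal/mol.

Scores are engine-tagged and never compared across engines.
"""

from __future__ import annotations

import shutil
import subprocess
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
from numba import njit

from .io_preprocess import encode_seq, normalize_seq

MIN_LOOP = 3

# pairable[a, b] for codes A=0 C=1 G=2 T=3: A-T, G-C, G-T wobble
_PAIRABLE = np.zeros((4, 4), dtype=np.uint8)
for _a, _b in [(0, 3), (3, 0), (2, 1), (1, 2), (2, 3), (3, 2)]:
    _PAIRABLE[_a, _b] = 1


@dataclass
class FoldResult:
    """A secondary structure: dot-bracket string plus 1-based pair table.

    ``pair_table[i]`` is the partner of position ``i`` (1-based) or 0 when
    unpaired; index 0 is unused.
    """

    seq: str
    structure: str
    pair_table: List[int]
    score: float
    engine: str

    def partner(self, i: int) -> int:
        return self.pair_table[i]

    def n_pairs(self) -> int:
        return sum(1 for p in self.pair_table[1:] if p) // 2


@dataclass
class PrecursorCandidate:
    """An accepted hairpin placement of a mature miRNA in a transcript.

    Coordinates are 1-based inclusive on the transcript; ``mir`` and
    ``star`` lie inside ``window``.
    """

    transcript_id: str
    window: Tuple[int, int]
    mir: Tuple[int, int]
    fold: FoldResult
    arm: str  # "five_prime" | "three_prime"
    duplex_mismatches: int
    star: Optional[Tuple[int, int]] = None
    star_seq: Optional[str] = None
    star_supported: bool = False
    mirna_id: Optional[str] = None


@njit(cache=True)
def _nussinov_fill(codes, pairable):  # pragma: no cover - numba kernel
    n = codes.shape[0]
    M = np.zeros((n, n), dtype=np.int32)
    for span in range(MIN_LOOP + 1, n):
        for i in range(n - span):
            j = i + span
            best = M[i + 1, j]
            if M[i, j - 1] > best:
                best = M[i, j - 1]
            if pairable[codes[i], codes[j]]:
                v = M[i + 1, j - 1] + 1
                if v > best:
                    best = v
            for k in range(i + 1, j):
                v = M[i, k] + M[k + 1, j]
                if v > best:
                    best = v
            M[i, j] = best
    return M


def _traceback(M: np.ndarray, codes: np.ndarray) -> List[int]:
    """Deterministic traceback: prefer pairing (i, j), then leaving i or j
    unpaired, then the smallest bifurcation point."""
    n = len(codes)
    pair = [0] * (n + 1)
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if j - i <= MIN_LOOP:
            continue
        m = M[i, j]
        if _PAIRABLE[codes[i], codes[j]] and m == M[i + 1, j - 1] + 1:
            pair[i + 1] = j + 1
            pair[j + 1] = i + 1
            stack.append((i + 1, j - 1))
        elif m == M[i + 1, j]:
            stack.append((i + 1, j))
        elif m == M[i, j - 1]:
            stack.append((i, j - 1))
        else:
            for k in range(i + 1, j):
                if M[i, k] + M[k + 1, j] == m:
                    stack.append((i, k))
                    stack.append((k + 1, j))
                    break
    return pair


def _pair_table_to_dotbracket(pair: Sequence[int]) -> str:
    out = []
    for i in range(1, len(pair)):
        if pair[i] == 0:
            out.append(".")
        elif pair[i] > i:
            out.append("(")
        else:
            out.append(")")
    return "".join(out)


def fold(seq: str, engine: str = "maxpair") -> FoldResult:
    """Fold a sequence with the selected engine."""
    s = normalize_seq(seq)
    if not s or any(c not in "ACGT" for c in s):
        raise ValueError("sequence must be non-empty over A/C/G/T/U")
    if engine == "maxpair":
        codes = encode_seq(s)
        M = _nussinov_fill(codes, _PAIRABLE)
        pair = _traceback(M, codes)
        return FoldResult(
            s, _pair_table_to_dotbracket(pair), pair, float(M[0, len(s) - 1]), "maxpair"
        )
    if engine == "vienna":
        return _fold_vienna(s)
    raise ValueError(f"unknown engine {engine!r}")


def vienna_available() -> bool:
    return shutil.which("RNAfold") is not None


def _fold_vienna(seq: str) -> FoldResult:
    proc = subprocess.run(
        ["RNAfold", "--noPS"],
        input=seq + "\n",
        capture_output=True,
        text=True,
        check=True,
    )
    line = proc.stdout.strip().splitlines()[-1]
    structure = line.split()[0]
    energy = float(line[line.rindex("(") + 1 : line.rindex(")")])
    pair = [0] * (len(seq) + 1)
    stack = []
    for i, c in enumerate(structure, start=1):
        if c == "(":
            stack.append(i)
        elif c == ")":
            j = stack.pop()
            pair[i], pair[j] = j, i
    return FoldResult(seq, structure, pair, energy, "vienna")


def find_precursor_windows(
    mirna: str,
    transcripts: Mapping[str, str],
    flank: int = 200,
) -> List[Tuple[str, int, int, int, int]]:
    """Exact forward-strand occurrences of a mature sequence, with flanks.

    Returns ``(transcript_id, win_start, win_end, mir_start, mir_end)``
    tuples, all 1-based inclusive, windows clipped to transcript bounds.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    m = normalize_seq(mirna)
    out = []
    for tid in sorted(transcripts):
        seq = transcripts[tid]
        start = seq.find(m)
        while start != -1:
            mir_start, mir_end = start + 1, start + len(m)
            out.append(
                (
                    tid,
                    max(1, mir_start - flank),
                    min(len(seq), mir_end + flank),
                    mir_start,
                    mir_end,
                )
            )
            start = seq.find(m, start + 1)
    return out


def validate_hairpin(
    fold_result: FoldResult,
    mir_start: int,
    mir_end: int,
    paired_fraction: float = 0.6,
    max_unpaired: int = 5,
) -> Tuple[Optional[str], int]:
    """Check that the mature miRNA sits in the stem of the folded window.

    Positions are 1-based within the folded sequence.  Acceptance requires
    (a) at least ``paired_fraction`` of miRNA positions paired, (b) all
    partners on a single side of the miRNA (no self-pairing, no pairing
    across the terminal loop), (c) at most ``max_unpaired`` unpaired miRNA
    positions.  Returns ``(arm, duplex_mismatches)`` on acceptance and
    ``(None, mismatches)`` otherwise.
    """
    pt = fold_result.pair_table
    n_mir = mir_end - mir_start + 1
    partners = [pt[i] for i in range(mir_start, mir_end + 1) if pt[i] != 0]
    unpaired = n_mir - len(partners)
    if any(mir_start <= p <= mir_end for p in partners):
        return None, unpaired
    upstream = [p for p in partners if p < mir_start]
    downstream = [p for p in partners if p > mir_end]
    if upstream and downstream:
        return None, unpaired
    if not partners:
        return None, unpaired
    if len(partners) / n_mir < paired_fraction:
        return None, unpaired
    if unpaired > max_unpaired:
        return None, unpaired
    arm = "five_prime" if downstream else "three_prime"
    return arm, unpaired


def infer_star(
    fold_result: FoldResult,
    mir_start: int,
    mir_end: int,
    arm: str,
) -> Tuple[int, int]:
    """Star span under the 2-nt 3'-overhang convention (window coordinates).

    The star covers the opposing-arm partners of the miRNA, shifted by 2 nt
    towards the miRNA 3' side (+2 for a 5'-arm miRNA, -2 for a 3'-arm
    miRNA) and clipped to the window.  The opposing arm is taken as the
    dominant contiguous run of partner positions (gaps of up to 6 nt are
    tolerated as interior loops), so isolated long-range pairs of the
    outermost miRNA bases cannot inflate the star.  Unpaired miRNA ends
    thereby fall back to the innermost paired positions automatically.
    """
    pt = fold_result.pair_table
    n = len(fold_result.seq)
    partners = sorted(
        pt[i]
        for i in range(mir_start, mir_end + 1)
        if pt[i] and not mir_start <= pt[i] <= mir_end
    )
    if len(partners) < 2:
        raise ValueError("fewer than 2 paired miRNA positions")
    runs: List[List[int]] = [[partners[0]]]
    for p in partners[1:]:
        if p - runs[-1][-1] <= 6:
            runs[-1].append(p)
        else:
            runs.append([p])
    run = max(runs, key=len)
    if len(run) < 2:
        raise ValueError("fewer than 2 paired miRNA positions")
    o = 2 if arm == "five_prime" else -2
    a, b = run[0] + o, run[-1] + o
    return max(1, a), min(n, b)


def star_read_support(
    star_seq: str,
    read_seqs: Set[str],
    window_seq: str,
    star_start: int,
    star_end: int,
) -> bool:
    """Is the star sequence (allowing 1-nt end wobble) present in the reads?

    End variants are taken from the window context so that extensions use
    the true neighbouring nucleotides.
    """
    n = len(window_seq)
    for ds in (-1, 0, 1):
        for de in (-1, 0, 1):
            s, e = star_start + ds, star_end + de
            if 1 <= s <= e <= n:
                if window_seq[s - 1 : e] in read_seqs:
                    return True
    return star_seq in read_seqs


def build_precursor_candidate(
    transcript_id: str,
    transcript_seq: str,
    mirna: str,
    window: Tuple[int, int, int, int],
    read_seqs: Optional[Set[str]] = None,
    engine: str = "maxpair",
    paired_fraction: float = 0.6,
    max_unpaired: int = 5,
    mirna_id: Optional[str] = None,
) -> Optional[PrecursorCandidate]:
    """Fold one candidate window and validate it end to end."""
    win_start, win_end, mir_start, mir_end = window
    wseq = transcript_seq[win_start - 1 : win_end]
    fr = fold(wseq, engine=engine)
    rel_start = mir_start - win_start + 1
    rel_end = mir_end - win_start + 1
    arm, mism = validate_hairpin(
        fr, rel_start, rel_end, paired_fraction, max_unpaired
    )
    if arm is None:
        return None
    try:
        s_rel_start, s_rel_end = infer_star(fr, rel_start, rel_end, arm)
    except ValueError:
        return None
    star_seq = wseq[s_rel_start - 1 : s_rel_end]
    supported = (
        star_read_support(star_seq, read_seqs, wseq, s_rel_start, s_rel_end)
        if read_seqs is not None
        else False
    )
    return PrecursorCandidate(
        transcript_id=transcript_id,
        window=(win_start, win_end),
        mir=(mir_start, mir_end),
        fold=fr,
        arm=arm,
        duplex_mismatches=mism,
        star=(s_rel_start + win_start - 1, s_rel_end + win_start - 1),
        star_seq=star_seq,
        star_supported=supported,
        mirna_id=mirna_id,
    )


def detect_arm_pairs(
    candidates: Sequence[PrecursorCandidate],
    abundances: Mapping[str, int],
    min_ratio: float = 0.2,
) -> List[Dict]:
    """Find 5p/3p candidate pairs sharing one hairpin.

    Two accepted candidates pair when they sit on the same transcript, on
    opposite arms, with overlapping windows.  ``abundances`` maps candidate
    ``mirna_id`` to pooled read counts; a pair is flagged ``both_abundant``
    when the min/max abundance ratio reaches ``min_ratio``.
    """
    pairs = []
    for i, a in enumerate(candidates):
        for b in candidates[i + 1 :]:
            if a.transcript_id != b.transcript_id or a.arm == b.arm:
                continue
            if a.window[0] > b.window[1] or b.window[0] > a.window[1]:
                continue
            ab_a = abundances.get(a.mirna_id or "", 0)
            ab_b = abundances.get(b.mirna_id or "", 0)
            ratio = min(ab_a, ab_b) / max(ab_a, ab_b) if max(ab_a, ab_b) else 0.0
            five, three = (a, b) if a.arm == "five_prime" else (b, a)
            pairs.append(
                {
                    "transcript_id": a.transcript_id,
                    "five_prime": five.mirna_id,
                    "three_prime": three.mirna_id,
                    "abundance_5p": abundances.get(five.mirna_id or "", 0),
                    "abundance_3p": abundances.get(three.mirna_id or "", 0),
                    "ratio": ratio,
                    "both_abundant": ratio >= min_ratio,
                }
            )
    return pairs


# ---------------------------------------------------------------------------
# structure output
# ---------------------------------------------------------------------------


def write_connect_table(fr: FoldResult, path) -> None:
    """Connect-table TSV: position, base (as RNA), partner."""
    with open(path, "w") as fh:
        fh.write("position\tbase\tpartner\n")
        for i, base in enumerate(fr.seq, start=1):
            fh.write(f"{i}\t{'U' if base == 'T' else base}\t{fr.pair_table[i]}\n")


def write_dotbracket(fr: FoldResult, name: str, path) -> None:
    with open(path, "a") as fh:
        rna = fr.seq.replace("T", "U")
        fh.write(f">{name}\n{rna}\n{fr.structure} ({fr.score:g}; {fr.engine})\n")
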