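"""Coding-region annotation of assembled transcripts.

Target-site positions are reported relative to the protein-coding
structure of the transcript (5' UTR / CDS / 3' UTR).  The coding region is
found with a codon-usage log-odds scorer: a model trained on a set of
coding sequences assigns each codon ``log(freq / (1/64))`` (add-one
smoothed), and the best-scoring ATG...stop open reading frame across the
three forward frames is taken as the CDS.  Assembled transcripts are
assumed sense-oriented; a 6-frame scan is available via ``both_strands``.

This is a deliberate simplification of indel-tolerant HMM coding scanners:
it assumes frame-intact transcripts, which holds for assembled transcripts
and for the synthetic data used in testing.
"""

from __future__ import annotations

import bisect
import math
from dataclasses import dataclass
from itertools import product
from typing import Dict, Iterable, List, Mapping, Optional, Tuple

from .io_preprocess import normalize_seq

STOP_CODONS = ("TAA", "TAG", "TGA")
ALL_CODONS = ["".join(p) for p in product("ACGT", repeat=3)]

FIVE_PRIME_UTR = "five_prime_UTR"
CDS = "CDS"
THREE_PRIME_UTR = "three_prime_UTR"

REGION_LABELS = {FIVE_PRIME_UTR: "5' UTR", CDS: "CDS", THREE_PRIME_UTR: "3' UTR"}


@dataclass
class CodonUsageModel:
    """Per-codon log-odds against a uniform 1/64 background."""

    log_odds: Dict[str, float]

    def score(self, codons: Iterable[str]) -> float:
        return sum(self.log_odds[c] for c in codons)


@dataclass
class CodingAnnotation:
    transcript_id: str
    cds: Tuple[int, int]  # 1-based inclusive; includes the stop codon
    frame: int
    strand: str
    score: float
    complete: bool  # False when the ORF runs off the transcript end
    transcript_length: int


def train_codon_model(training_seqs: Iterable[str]) -> CodonUsageModel:
    """Codon frequencies of in-frame training CDS vs uniform background.

    ``log_odds[c] = log((count_c + 1) / (total + 64)) - log(1/64)`` — the
    add-one smoothing keeps unseen codons finite.
    """
    counts = {c: 0 for c in ALL_CODONS}
    total = 0
    n_seqs = 0
    for seq in training_seqs:
        s = normalize_seq(seq)
        if len(s) < 33 or len(s) % 3:
            raise ValueError(
                "training sequences must have length >= 33 and divisible by 3"
            )
        n_seqs += 1
        for i in range(0, len(s), 3):
            codon = s[i : i + 3]
            if codon in counts:
                counts[codon] += 1
                total += 1
    if n_seqs == 0:
        raise ValueError("empty training set")
    return CodonUsageModel(
        {
            c: math.log((counts[c] + 1) / (total + 64)) - math.log(1 / 64)
            for c in ALL_CODONS
        }
    )


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def _scan_strand(
    seq: str, model: CodonUsageModel, min_codons: int
) -> List[Tuple[float, int, int, int, bool]]:
    """Candidate ORFs on one strand: (score, start0, end0, frame, complete).

    Stops partition each frame into segments; the candidate ORF of a
    segment runs from the first ATG of the segment to the segment's stop
    (the longest-ORF-per-stop convention of standard coding scanners), so
    nested same-stop ATGs do not compete with their full-length ORF.
    """
    orfs = []
    n = len(seq)
    for frame in range(3):
        codons = [seq[i : i + 3] for i in range(frame, n - 2, 3)]
        prefix = [0.0]
        for c in codons:
            prefix.append(prefix[-1] + model.log_odds[c])
        seg_start = 0
        segments = []  # (first codon, last coding codon, stop codon index)
        for ci, c in enumerate(codons):
            if c in STOP_CODONS:
                segments.append((seg_start, ci - 1, ci))
                seg_start = ci + 1
        if seg_start <= len(codons) - 1:
            segments.append((seg_start, len(codons) - 1, None))
        for lo, last_ci, stop_ci in segments:
            if last_ci < lo:
                continue
            atg = next(
                (ci for ci in range(lo, last_ci + 1) if codons[ci] == "ATG"), None
            )
            if atg is None or last_ci - atg + 1 < min_codons:
                continue
            score = prefix[last_ci + 1] - prefix[atg]
            start0 = frame + 3 * atg
            end0 = (
                frame + 3 * (stop_ci + 1) - 1
                if stop_ci is not None
                else frame + 3 * (last_ci + 1) - 1
            )
            orfs.append((score, start0, end0, frame, stop_ci is not None))
    return orfs


def find_coding_region(
    transcript_id: str,
    seq: str,
    model: CodonUsageModel,
    min_codons: int = 20,
    both_strands: bool = False,
) -> Optional[CodingAnnotation]:
    """Best-scoring ORF, or ``None`` for transcripts marked non-coding.

    Ties on score go to the longer ORF, then the leftmost.  Transcripts
    with no ORF of at least ``min_codons`` codons are non-coding and are
    excluded from target-region classification.
    """
    s = normalize_seq(seq)
    candidates: List[Tuple[float, int, int, int, bool, str]] = [
        (*o, "+") for o in _scan_strand(s, model, min_codons)
    ]
    if both_strands:
        rc = _revcomp(s)
        candidates += [(*o, "-") for o in _scan_strand(rc, model, min_codons)]
    if not candidates:
        return None
    best = max(candidates, key=lambda o: (o[0], o[2] - o[1], -o[1]))
    score, start0, end0, frame, complete, strand = best
    return CodingAnnotation(
        transcript_id=transcript_id,
        cds=(start0 + 1, end0 + 1),
        frame=frame,
        strand=strand,
        score=score,
        complete=complete,
        transcript_length=len(s),
    )


def classify_region(annotation: CodingAnnotation, position: int) -> str:
    """Classify a 1-based transcript position as 5' UTR, CDS or 3' UTR."""
    if not 1 <= position <= annotation.transcript_length:
        raise ValueError("position outside transcript")
    if position < annotation.cds[0]:
        return FIVE_PRIME_UTR
    if position <= annotation.cds[1]:
        return CDS
    return THREE_PRIME_UTR


def write_gff3(annotations: Iterable[CodingAnnotation], path) -> None:
    """CDS/UTR features per transcript as GFF3."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for a in annotations:
            rows = []
            if a.cds[0] > 1:
                rows.append(("five_prime_UTR", 1, a.cds[0] - 1))
            rows.append(("CDS", a.cds[0], a.cds[1]))
            if a.cds[1] < a.transcript_length:
                rows.append(("three_prime_UTR", a.cds[1] + 1, a.transcript_length))
            for ftype, start, end in rows:
                fh.write(
                    f"{a.transcript_id}\tpenmir\t{ftype}\t{start}\t{end}\t"
                    f"{a.score:.2f}\t{a.strand}\t.\tID={a.transcript_id}.{ftype}\n"
                )


def write_model_tsv(model: CodonUsageModel, path) -> None:
    with open(path, "w") as fh:
        fh.write("codon\tlog_odds\n")
        for c in ALL_CODONS:
            fh.write(f"{c}\t{model.log_odds[c]:.6f}\n")


def read_model_tsv(path) -> CodonUsageModel:
    log_odds = {}
    with open(path) as fh:
        next(fh)
        for line in fh:
            codon, v = line.split()
            log_odds[codon] = float(v)
    return CodonUsageModel(log_odds)
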