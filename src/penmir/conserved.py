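"""Conserved miRNA family assignment by ungapped overlap alignment.

Mature miRNAs are short enough (18-26 nt) that family membership can be
decided by sliding one sequence along the other without gaps and counting
mismatches in the overlapping region (the *Mn* statistic).  A query is
assigned to every reference family for which some member aligns with at
most ``max_mismatches`` (default 2) over at least ``min_overlap`` (default
17) positions.  The same machinery drives the cross-species scan that looks
for homologs of novel miRNAs in foreign small-RNA data sets.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from numba import njit

from .io_preprocess import encode_seq, normalize_seq, read_fasta


@dataclass(frozen=True)
class ReferenceMiRNA:
    family: str
    member: str
    species: str
    seq: str


@dataclass(frozen=True)
class OverlapAlignment:
    """Best ungapped offset alignment of two short sequences.

    ``offset`` is the 0-based position of the reference start relative to
    the query start (negative when the reference overhangs the query 5'
    end).  ``mismatch_positions`` are 1-based query coordinates.
    """

    query_seq: str
    ref_seq: str
    offset: int
    overlap_len: int
    mismatches: int
    mismatch_positions: Tuple[int, ...] = ()


@dataclass
class FamilyAssignment:
    query_id: str
    family: str
    member: str
    species: str
    alignment: OverlapAlignment


def best_overlap_alignment(
    query: str, ref: str, min_overlap: int = 17
) -> OverlapAlignment:
    """Minimize mismatches over all ungapped offsets with sufficient overlap.

    Ties are broken by larger overlap, then by smaller absolute offset
    (preferring containment-style alignments), then by sign for full
    determinism.  Raises ``ValueError`` when no offset reaches
    ``min_overlap``.
    """
    q, r = normalize_seq(query), normalize_seq(ref)
    lq, lr = len(q), len(r)
    if lq < min_overlap or lr < min_overlap:
        raise ValueError("no valid overlap")
    best: Optional[Tuple[Tuple[int, int, int, int], OverlapAlignment]] = None
    for offset in range(-(lr - min_overlap), lq - min_overlap + 1):
        start = max(0, offset)
        end = min(lq, offset + lr)
        overlap = end - start
        if overlap < min_overlap:
            continue
        mpos = tuple(
            i + 1 for i in range(start, end) if q[i] != r[i - offset]
        )
        key = (len(mpos), -overlap, abs(offset), offset)
        aln = OverlapAlignment(q, r, offset, overlap, len(mpos), mpos)
        if best is None or key < best[0]:
            best = (key, aln)
    if best is None:
        raise ValueError("no valid overlap")
    return best[1]


@njit(cache=True)
def _min_overlap_mismatches(q, r, min_overlap):  # pragma: no cover - numba kernel
    """Minimum mismatch count over all ungapped offsets with enough overlap."""
    lq, lr = q.shape[0], r.shape[0]
    best = 1 << 30
    for offset in range(-(lr - min_overlap), lq - min_overlap + 1):
        start = offset if offset > 0 else 0
        end = lq if lq < offset + lr else offset + lr
        if end - start < min_overlap:
            continue
        mism = 0
        for i in range(start, end):
            if q[i] != r[i - offset]:
                mism += 1
        if mism < best:
            best = mism
    return best


def assign_families(
    queries: Mapping[str, str],
    refs: Sequence[ReferenceMiRNA],
    max_mismatches: int = 2,
    min_overlap: int = 17,
) -> List[FamilyAssignment]:
    """All (query, reference) hits within the mismatch budget.

    A query hitting several members or families is reported under each; the
    primary hit for a query is its lowest-Mn assignment (first in the
    returned order).
    """
    if not refs:
        raise ValueError("empty reference catalogue")
    ref_codes = [encode_seq(normalize_seq(r.seq)) for r in refs]
    out: List[FamilyAssignment] = []
    for qid, qseq in queries.items():
        q_code = encode_seq(normalize_seq(qseq))
        hits = []
        for ref, r_code in zip(refs, ref_codes):
            if len(qseq) < min_overlap or len(ref.seq) < min_overlap:
                continue
            # cheap minimum-mismatch screen; the full alignment (with
            # offsets and mismatch positions) is only built for real hits
            if _min_overlap_mismatches(q_code, r_code, min_overlap) > max_mismatches:
                continue
            aln = best_overlap_alignment(qseq, ref.seq, min_overlap)
            if aln.mismatches <= max_mismatches:
                hits.append(FamilyAssignment(qid, ref.family, ref.member, ref.species, aln))
        hits.sort(key=lambda h: (h.alignment.mismatches, h.family, h.member))
        out.extend(hits)
    return out


def family_mean_count(
    assignments: Iterable[FamilyAssignment],
    query_library_counts: Mapping[str, Mapping[str, int]],
    libraries: Sequence[str],
    per_million: bool = False,
    library_totals: Optional[Mapping[str, int]] = None,
) -> Dict[str, float]:
    """Mean over libraries of summed counts of all reads assigned per family."""
    seen: Dict[str, set] = {}
    for a in assignments:
        seen.setdefault(a.family, set()).add(a.query_id)
    out: Dict[str, float] = {}
    for family, qids in seen.items():
        per_lib = []
        for lib in libraries:
            total = sum(
                query_library_counts.get(q, {}).get(lib, 0) for q in qids
            )
            if per_million:
                if not library_totals or not library_totals.get(lib):
                    raise ValueError("library_totals required for per-million")
                total = total / library_totals[lib] * 1e6
            per_lib.append(total)
        out[family] = sum(per_lib) / len(libraries) if libraries else 0.0
    return out


def cross_species_scan(
    candidates: Mapping[str, str],
    foreign_seqs: Mapping[str, str],
    max_mismatches: int = 2,
    min_overlap: int = 17,
) -> List[Tuple[str, str, OverlapAlignment]]:
    """Report homologous (candidate, foreign) pairs within the budget."""
    hits = []
    for cid, cseq in candidates.items():
        for fid, fseq in foreign_seqs.items():
            try:
                aln = best_overlap_alignment(cseq, fseq, min_overlap)
            except ValueError:
                continue
            if aln.mismatches <= max_mismatches:
                hits.append((cid, fid, aln))
    hits.sort(key=lambda h: (h[2].mismatches, h[0], h[1]))
    return hits


# ---------------------------------------------------------------------------
# reference catalogue I/O
# ---------------------------------------------------------------------------

_FAMILY_NUM = re.compile(r"miR[A-Za-z]*?(\d+)", re.IGNORECASE)


def family_number(family_or_name: str) -> Optional[str]:
    """Extract the numeric family identifier from a miRNA name.

    ``ath-miR156a`` -> ``156``; species prefixes and member suffixes are
    ignored.
    """
    m = _FAMILY_NUM.search(family_or_name)
    return m.group(1) if m else None


def base_family(name: str) -> str:
    """Strip member suffixes: trailing arm tags (-5p/-3p), ``.N``, letters."""
    name = re.sub(r"-[35]p\*?$", "", name)
    name = re.sub(r"\.\d+$", "", name)
    name = re.sub(r"(?<=\d)[a-z]+$", "", name)
    return name


def load_reference_tsv(path) -> List[ReferenceMiRNA]:
    """4-column TSV: family, member, species, sequence (header optional)."""
    out = []
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        for row in reader:
            if not row or row[0].lower() == "family":
                continue
            family, member, species, seq = row[:4]
            out.append(ReferenceMiRNA(family, member, species, normalize_seq(seq)))
    return out


def load_reference_fasta(path) -> List[ReferenceMiRNA]:
    """FASTA with ``family|member|species`` headers."""
    out = []
    for read in read_fasta(path):
        parts = (read.id.split("|") + ["", ""])[:3]
        out.append(ReferenceMiRNA(parts[0], parts[1], parts[2], read.seq))
    return out
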