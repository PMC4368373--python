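"""Reference-free clustering of small-RNA reads and candidate selection.

Without a genome, reads cannot be grouped by locus.  Instead, reads are
grouped into *clusters*: connected components under the relation "one
sequence is an exact ungapped substring of the other".  A genuine miRNA
produces a cluster dominated by its canonical-length species plus a tail of
5'/3' trimmed or extended variants, whereas degradation products scatter
across lengths.  Candidate novel miRNAs are clusters with a clearly
dominant read length in the 20-21 nt band, no contaminant annotation,
and presence in at least one axenically grown (in vitro) library.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

from .io_preprocess import CollapsedRead


@dataclass
class Cluster:
    """A group of co-aligned reads with per-library counts.

    ``members`` maps each member sequence to its per-library counts.  The
    representative is the longest member (ties broken lexicographically),
    and the *mature* sequence — used downstream as the miRNA species of the
    cluster — is the most abundant member.
    """

    id: str
    members: Dict[str, Dict[str, int]]

    @property
    def representative(self) -> str:
        return max(self.members, key=lambda s: (len(s), [-ord(c) for c in s]))

    @property
    def mature_seq(self) -> str:
        return max(
            self.members, key=lambda s: (sum(self.members[s].values()), s)
        )

    @property
    def abundance(self) -> int:
        return sum(c for per_lib in self.members.values() for c in per_lib.values())

    def library_counts(self) -> Dict[str, int]:
        out: Dict[str, int] = {}
        for per_lib in self.members.values():
            for lib, c in per_lib.items():
                out[lib] = out.get(lib, 0) + c
        return out

    @property
    def library_presence(self) -> Set[str]:
        return {lib for per_lib in self.members.values() for lib in per_lib}

    def size_profile(self, library: Optional[str] = None) -> Dict[int, int]:
        """Summed count per read length (pooled, or for one library)."""
        profile: Dict[int, int] = {}
        for seq, per_lib in self.members.items():
            c = per_lib.get(library, 0) if library else sum(per_lib.values())
            if c:
                profile[len(seq)] = profile.get(len(seq), 0) + c
        return profile

    @property
    def gc_content(self) -> float:
        rep = self.representative
        return sum(1 for c in rep if c in "GC") / len(rep)

    def first_nt_profile(self) -> Dict[str, float]:
        """Count-weighted fraction of member 5' nucleotides."""
        counts = {b: 0 for b in "ACGT"}
        for seq, per_lib in self.members.items():
            counts[seq[0]] += sum(per_lib.values())
        total = sum(counts.values())
        return {b: c / total for b, c in counts.items()}


@dataclass
class CandidateDecision:
    cluster_id: str
    dominant_length: int
    dominance_fraction: float
    passed: bool
    reasons: List[str] = field(default_factory=list)


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def build_clusters(
    library_reads: Mapping[str, Iterable[CollapsedRead]],
    min_total: int = 2,
) -> List[Cluster]:
    """Group reads from all libraries into substring-containment clusters.

    Two sequences belong to the same cluster iff they are connected under
    the transitive closure of exact substring containment.  Clusters whose
    total copy number (counting multiplicity over all libraries) falls
    below ``min_total`` are discarded.  The result is invariant to input
    order: clusters are sorted by decreasing pooled abundance, then by
    representative.
    """
    counts: Dict[str, Dict[str, int]] = {}
    for lib, reads in library_reads.items():
        for r in reads:
            per_lib = counts.setdefault(r.seq, {})
            per_lib[lib] = per_lib.get(lib, 0) + r.count
    seqs = sorted(counts, key=lambda s: (len(s), s))
    index = {s: i for i, s in enumerate(seqs)}
    lengths = sorted({len(s) for s in seqs})
    uf = _UnionFind(len(seqs))
    for s in seqs:
        si = index[s]
        for L in lengths:
            if L >= len(s):
                break
            for off in range(len(s) - L + 1):
                j = index.get(s[off : off + L])
                if j is not None:
                    uf.union(si, j)
    groups: Dict[int, List[str]] = {}
    for s in seqs:
        groups.setdefault(uf.find(index[s]), []).append(s)
    clusters = []
    for members in groups.values():
        cl = Cluster("", {s: dict(counts[s]) for s in members})
        if cl.abundance >= min_total:
            clusters.append(cl)
    clusters.sort(key=lambda c: (-c.abundance, c.representative))
    for i, cl in enumerate(clusters, start=1):
        cl.id = f"cluster_{i:05d}"
    return clusters


def dominance_test(
    cluster: Cluster,
    preferred_band: Sequence[int] = (20, 21),
    min_fraction: float = 0.5,
) -> CandidateDecision:
    """Decide whether one read length clearly dominates the cluster.

    The dominant length is the argmax of the pooled size profile (ties go
    to the shorter length).  The cluster passes when the dominant fraction
    reaches ``min_fraction`` and the dominant length lies in the preferred
    band.
    """
    profile = cluster.size_profile()
    if not profile:
        raise ValueError("empty cluster")
    dominant = max(profile, key=lambda L: (profile[L], -L))
    fraction = profile[dominant] / sum(profile.values())
    reasons = []
    if fraction < min_fraction:
        reasons.append("no_dominant_length")
    if dominant not in preferred_band:
        reasons.append("dominant_length_outside_band")
    return CandidateDecision(
        cluster.id, dominant, fraction, passed=not reasons, reasons=reasons
    )


def _matches_with_mismatches(needle: str, haystack: str, max_mm: int) -> bool:
    n, h = len(needle), len(haystack)
    if n > h:
        return False
    for off in range(h - n + 1):
        mm = 0
        for i in range(n):
            if haystack[off + i] != needle[i]:
                mm += 1
                if mm > max_mm:
                    break
        else:
            return True
    return False


def screen_contaminants(
    clusters: Iterable[Cluster],
    contaminant_sets: Mapping[str, Iterable[str]],
    max_mismatches: int = 0,
) -> Dict[str, List[str]]:
    """Annotate clusters whose representative occurs in a contaminant set.

    A cluster is annotated with every named set in which its representative
    matches some sequence as an ungapped substring with at most
    ``max_mismatches``.  Annotated clusters are excluded from candidacy but
    kept in reports.
    """
    sets = {name: list(seqs) for name, seqs in contaminant_sets.items()}
    annotations: Dict[str, List[str]] = {}
    for cl in clusters:
        rep = cl.representative
        hits = [
            name
            for name, seqs in sets.items()
            if any(_matches_with_mismatches(rep, s, max_mismatches) for s in seqs)
        ]
        if hits:
            annotations[cl.id] = hits
    return annotations


def select_candidates(
    clusters: Sequence[Cluster],
    decisions: Mapping[str, CandidateDecision],
    library_origins: Mapping[str, str],
    n_top: Optional[int] = None,
    annotations: Optional[Mapping[str, List[str]]] = None,
    gc_range: Optional[Tuple[float, float]] = None,
    require_5prime_U: bool = False,
) -> List[Cluster]:
    """Rank candidate clusters for novel-miRNA follow-up.

    Candidates must pass the dominance test, carry no contaminant
    annotation, and be present in at least one in vitro library.  GC
    content and 5'-nucleotide filters are off by default (both features are
    reported, not thresholded).  Ranking is by pooled abundance descending,
    ties by representative, truncated to ``n_top``.
    """
    annotations = annotations or {}
    in_vitro = {lib for lib, o in library_origins.items() if o == "in_vitro"}
    out = []
    for cl in clusters:
        dec = decisions.get(cl.id)
        if dec is None or not dec.passed:
            continue
        if cl.id in annotations:
            continue
        if not (cl.library_presence & in_vitro):
            continue
        if gc_range is not None and not (
            gc_range[0] <= cl.gc_content <= gc_range[1]
        ):
            continue
        if require_5prime_U and not cl.mature_seq.startswith("T"):
            continue
        out.append(cl)
    out.sort(key=lambda c: (-c.abundance, c.representative))
    return out[:n_top] if n_top is not None else out
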