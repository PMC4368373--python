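"""Seeded synthetic experiments with known ground truth.

The generator emulates the data layout of a genome-less plant small-RNA
study: an assembled transcriptome with one coding region per transcript,
MIR hairpins planted in 3' UTRs, five small-RNA libraries (three from
axenic in vitro culture, two from field material carrying contaminant
reads), and a degradome library with tag-5'-end spikes at the canonical
cleavage position of each planted target site.

Every planted feature is recorded in a :class:`GroundTruth` object so that
each pipeline stage can be scored for recovery.  All randomness flows from
a single seeded generator; identical configurations produce byte-identical
outputs.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import yaml

from . import catalog
from .hairpin import build_precursor_candidate
from .io_preprocess import normalize_seq

#: TruSeq small-RNA 3' adapter, used for both sRNA and degradome reads
DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# Codon usage for planted coding regions: 20 preferred codons at 4x the
# weight of the remaining sense codons (balanced GC so that coding regions
# do not skew the transcriptome-wide GC content); stops never occur inside
# an ORF.
PREFERRED_CODONS = (
    "GCT", "GGA", "CTG", "CCA", "GTC", "TCG", "GAG", "CAG", "GAC", "AGC",
    "ATC", "ACT", "TGT", "AAG", "GAA", "TTC", "CAT", "TAC", "AGT", "CTA",
)
STOPS = ("TAA", "TAG", "TGA")
_SENSE_CODONS = [
    "".join((a, b, c))
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if "".join((a, b, c)) not in STOPS
]
_CODON_WEIGHTS = np.array(
    [4.0 if c in PREFERRED_CODONS else 1.0 for c in _SENSE_CODONS]
)
_CODON_WEIGHTS /= _CODON_WEIGHTS.sum()


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition parameters of a synthetic experiment."""

    seed: int
    n_transcripts: int = 50
    transcript_length: Tuple[int, int] = (1200, 2000)
    gc: float = 0.5
    n_conserved: int = 10
    n_novel: int = 10
    libraries: Tuple[Tuple[str, str, int], ...] = (
        ("vitro_f1", "in_vitro", 100_000),
        ("vitro_f2", "in_vitro", 100_000),
        ("vitro_m1", "in_vitro", 100_000),
        ("field_f1", "field", 100_000),
        ("field_m1", "field", 100_000),
    )
    expression_mu: float = 4.0
    expression_sigma: float = 1.5
    canonical_fraction: float = 0.85
    star_ratio: float = 0.1
    background_fraction: float = 0.4
    contaminant_fraction: float = 0.05
    n_contaminants: int = 10
    n_targets: int = 15
    spike_fraction: float = 0.3
    degradome_background_rate: float = 0.05
    tag_length: int = 20
    adapter: str = DEFAULT_ADAPTER

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in (
            "gc",
            "canonical_fraction",
            "star_ratio",
            "background_fraction",
            "contaminant_fraction",
            "spike_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for _, origin, depth in self.libraries:
            if origin not in ("in_vitro", "field"):
                raise ValueError(f"bad origin {origin!r}")
            if depth < 1000:
                raise ValueError("library depth must be >= 1000")


@dataclass
class PlantedMiRNA:
    name: str
    seq: str
    kind: str  # "conserved" | "novel"
    family: str  # reference family for conserved miRNAs, else ""
    transcript_id: str
    hairpin: Tuple[int, int]
    mir: Tuple[int, int]
    star: Tuple[int, int]
    star_seq: str
    arm: str


@dataclass
class PlantedTarget:
    mirna_name: str
    mirna_seq: str
    transcript_id: str
    site: Tuple[int, int]
    canonical_cleavage: int


@dataclass
class GroundTruth:
    mirnas: List[PlantedMiRNA] = field(default_factory=list)
    targets: List[PlantedTarget] = field(default_factory=list)
    coding: Dict[str, Tuple[int, int]] = field(default_factory=dict)
    contaminants: Dict[str, str] = field(default_factory=dict)
    library_mirna_counts: Dict[str, Dict[str, int]] = field(default_factory=dict)
    degradome_spike_counts: Dict[str, int] = field(default_factory=dict)

    def mirna_by_name(self, name: str) -> PlantedMiRNA:
        for m in self.mirnas:
            if m.name == name:
                return m
        raise KeyError(name)

    @property
    def planted_seqs(self) -> Set[str]:
        """Planted mature and star sequences (both are real planted species)."""
        out = set()
        for m in self.mirnas:
            out.add(m.seq)
            out.add(m.star_seq)
        return out


@dataclass
class SyntheticExperiment:
    config: SimulationConfig
    transcripts: Dict[str, str]
    truth: GroundTruth
    libraries: Dict[str, Tuple[str, List[Tuple[str, int]]]]
    degradome_tags: Dict[str, int]
    training_cds: List[str]


def _random_dna(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(list("ACGT"), size=n, p=p))


def _random_codons(rng: np.random.Generator, n: int) -> str:
    idx = rng.choice(len(_SENSE_CODONS), size=n, p=_CODON_WEIGHTS)
    return "".join(_SENSE_CODONS[i] for i in idx)


def generate_transcriptome(
    config: SimulationConfig, rng: np.random.Generator
) -> Tuple[Dict[str, str], Dict[str, Tuple[int, int]]]:
    """Random transcripts, each with one planted ORF flanked by UTRs.

    The codon immediately 5' of (and in frame with) the start codon is set
    to a stop so that the planted reading frame has an unambiguous start,
    as real 5' UTRs commonly do.
    """
    transcripts: Dict[str, str] = {}
    coding: Dict[str, Tuple[int, int]] = {}
    lo, hi = config.transcript_length
    for i in range(config.n_transcripts):
        tid = f"tx{i + 1:04d}"
        L = int(rng.integers(lo, hi + 1))
        utr5 = int(rng.integers(100, 301))
        max_codons = (L - utr5 - 3 - 200) // 3
        n_codons = int(rng.integers(120, max(121, min(221, max_codons + 1))))
        cds = "ATG" + _random_codons(rng, n_codons - 1) + STOPS[int(rng.integers(3))]
        utr3_len = L - utr5 - len(cds)
        seq = _random_dna(rng, utr5, config.gc) + cds + _random_dna(
            rng, utr3_len, config.gc
        )
        # in-frame stop just upstream of the planted ATG
        seq = seq[: utr5 - 3] + "TAA" + seq[utr5:]
        transcripts[tid] = seq
        coding[tid] = (utr5 + 1, utr5 + len(cds))
    return transcripts, coding


def _edit_seq(rng: np.random.Generator, seq: str, n_edits: int) -> str:
    s = list(seq)
    if n_edits == 0:
        return seq
    positions = rng.choice(len(s), size=min(n_edits, len(s)), replace=False)
    for p in positions:
        choices = [b for b in "ACGT" if b != s[p]]
        s[p] = choices[int(rng.integers(3))]
    return "".join(s)


def _free_span(
    rng: np.random.Generator,
    occupied: List[Tuple[int, int]],
    lo: int,
    hi: int,
    length: int,
    tries: int = 50,
) -> Optional[int]:
    """A 0-based start in [lo, hi - length] clear of occupied spans."""
    if hi - length < lo:
        return None
    for _ in range(tries):
        start = int(rng.integers(lo, hi - length + 1))
        span = (start, start + length)
        if all(span[1] <= a or span[0] >= b for a, b in occupied):
            occupied.append(span)
            return start
    return None


def plant_mir_hairpins(
    transcripts: Dict[str, str],
    coding: Mapping[str, Tuple[int, int]],
    config: SimulationConfig,
    rng: np.random.Generator,
    occupied: Optional[Dict[str, List[Tuple[int, int]]]] = None,
) -> GroundTruth:
    """Insert MIR hairpins into transcript 3' UTRs.

    Each hairpin is mature + loop (8-15 nt) + a reverse complement carrying
    up to 2 point edits (arm side chosen at random).  Conserved matures are
    copies (<= 2 edits) of bundled reference sequences; novel matures are
    random 21-mers starting with U at probability 0.8.  Construction is
    validated in place: the planted window must fold into an accepted
    hairpin, otherwise loop/edits/placement are redrawn.
    """
    if occupied is None:
        occupied = {}
    truth = GroundTruth(coding=dict(coding))
    refs = catalog.load_known_mirnas()
    ref_idx = rng.choice(len(refs), size=min(config.n_conserved, len(refs)), replace=False)
    planned: List[Tuple[str, str, str]] = []
    for k, ri in enumerate(ref_idx):
        ref = refs[int(ri)]
        mature = _edit_seq(rng, ref.seq, int(rng.integers(0, 3)))
        planned.append((f"sim-cons{k + 1:02d}", mature, ref.family))
    for k in range(config.n_novel):
        first = "T" if rng.random() < 0.8 else "ACG"[int(rng.integers(3))]
        mature = first + _random_dna(rng, 20, 0.5)
        planned.append((f"sim-nov{k + 1:02d}", mature, ""))

    # one hairpin per transcript, and the whole fold window (mir +- 200 nt)
    # is reserved so later planting cannot change a hairpin's fold
    tids = sorted(transcripts)
    free_hosts = [tids[i] for i in rng.permutation(len(tids))]
    for name, mature, family in planned:
        placed = False
        for attempt in range(min(40, len(free_hosts))):
            tid = free_hosts[attempt]
            seq = transcripts[tid]
            cds_end = coding[tid][1]
            loop = _random_dna(rng, int(rng.integers(8, 16)), 0.5)
            arm_seq = _edit_seq(rng, revcomp(mature), int(rng.integers(0, 3)))
            on_five = bool(rng.random() < 0.5)
            hp = mature + loop + arm_seq if on_five else arm_seq + loop + mature
            occ = occupied.setdefault(tid, [])
            start0 = _free_span(
                rng, occ, cds_end + 10, len(seq) - 10, len(hp), tries=10
            )
            if start0 is None:
                continue
            new_seq = seq[:start0] + hp + seq[start0 + len(hp) :]
            if on_five:
                mir_start = start0 + 1
            else:
                mir_start = start0 + len(arm_seq) + len(loop) + 1
            mir_end = mir_start + len(mature) - 1
            win = (
                max(1, mir_start - 200),
                min(len(new_seq), mir_end + 200),
                mir_start,
                mir_end,
            )
            cand = build_precursor_candidate(
                tid, new_seq, mature, win, read_seqs=None, mirna_id=name
            )
            star_ok = (
                cand is not None
                and cand.star_seq is not None
                and 18 <= len(cand.star_seq) <= 26
            )
            if not star_ok or new_seq.count(mature) != 1:
                occ.remove((start0, start0 + len(hp)))
                continue
            # widen the reservation to the full fold window
            occ.remove((start0, start0 + len(hp)))
            occ.append((max(0, start0 - 205), min(len(new_seq), start0 + len(hp) + 205)))
            free_hosts.remove(tid)
            transcripts[tid] = new_seq
            truth.mirnas.append(
                PlantedMiRNA(
                    name=name,
                    seq=mature,
                    kind="conserved" if family else "novel",
                    family=family,
                    transcript_id=tid,
                    hairpin=(start0 + 1, start0 + len(hp)),
                    mir=(mir_start, mir_end),
                    star=cand.star or (0, 0),
                    star_seq=cand.star_seq or "",
                    arm=cand.arm,
                )
            )
            placed = True
            break
        if not placed:
            raise RuntimeError(f"could not place hairpin for {name}")
    return truth


def plant_target_sites(
    transcripts: Dict[str, str],
    truth: GroundTruth,
    config: SimulationConfig,
    rng: np.random.Generator,
    occupied: Dict[str, List[Tuple[int, int]]],
) -> None:
    """Insert perfect-complement target sites for a subset of planted miRNAs.

    Sites go into transcripts other than the miRNA's own hairpin host,
    in the CDS or 3' UTR, avoiding previously planted features.  The
    canonical cleavage position (facing miRNA position 10) is recorded.
    """
    n = min(config.n_targets, len(truth.mirnas))
    chosen = rng.choice(len(truth.mirnas), size=n, replace=False)
    tids = sorted(transcripts)
    for mi in chosen:
        m = truth.mirnas[int(mi)]
        site_seq = revcomp(m.seq)
        placed = False
        for _ in range(60):
            tid = tids[int(rng.integers(len(tids)))]
            if tid == m.transcript_id:
                continue
            seq = transcripts[tid]
            cds_start, cds_end = truth.coding[tid]
            if rng.random() < 0.6:
                lo, hi = cds_start + 30, cds_end - 30
            else:
                lo, hi = cds_end + 10, len(seq) - 30
            occ = occupied.setdefault(tid, [])
            start0 = _free_span(rng, occ, lo, hi, len(site_seq), tries=10)
            if start0 is None:
                continue
            new_seq = seq[:start0] + site_seq + seq[start0 + len(site_seq) :]
            if new_seq.count(site_seq) != 1:
                occ.remove((start0, start0 + len(site_seq)))
                continue
            transcripts[tid] = new_seq
            site = (start0 + 1, start0 + len(site_seq))
            truth.targets.append(
                PlantedTarget(
                    mirna_name=m.name,
                    mirna_seq=m.seq,
                    transcript_id=tid,
                    site=site,
                    canonical_cleavage=site[1] - 9,
                )
            )
            placed = True
            break
        if not placed:
            raise RuntimeError(f"could not place target for {m.name}")


def _sample_fragments(
    rng: np.random.Generator,
    seqs: Sequence[str],
    n: int,
    min_len: int = 18,
    max_len: int = 26,
) -> Counter:
    """Uniform-position fragments of the given sequences (degradation-like)."""
    out: Counter = Counter()
    if n <= 0 or not seqs:
        return out
    lengths = np.array([len(s) for s in seqs], dtype=float)
    which = rng.choice(len(seqs), size=n, p=lengths / lengths.sum())
    frag_lens = rng.integers(min_len, max_len + 1, size=n)
    starts = rng.random(size=n)
    for i in range(n):
        s = seqs[which[i]]
        fl = int(frag_lens[i])
        if len(s) <= fl:
            continue
        st = int(starts[i] * (len(s) - fl + 1))
        out[s[st : st + fl]] += 1
    return out


def simulate_srna_libraries(
    truth: GroundTruth,
    transcripts: Mapping[str, str],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> Dict[str, Tuple[str, List[Tuple[str, int]]]]:
    """Per-library collapsed adapter-ligated reads.

    miRNA abundances are log-normal (one weight per planted miRNA, shared
    across libraries); each miRNA's reads are the canonical mature at
    ``canonical_fraction`` plus 1-nt 5'/3' variants taken from the hairpin
    context; star reads are generated at ``star_ratio``; the remaining
    depth is degradation background (uniform transcript fragments), with a
    contaminant spike-in replacing part of the background in field
    libraries.
    """
    weights = rng.lognormal(config.expression_mu, config.expression_sigma, len(truth.mirnas))
    if len(weights):
        weights /= weights.sum()
    mirna_variants: List[List[str]] = []
    for m in truth.mirnas:
        t = transcripts[m.transcript_id]
        s, e = m.mir
        canonical = t[s - 1 : e]
        variants = [
            t[max(0, s - 2) : e],  # 5' extension
            t[s:e],  # 5' trim
            t[s - 1 : min(len(t), e + 1)],  # 3' extension
            t[s - 1 : e - 1],  # 3' trim
        ]
        mirna_variants.append([canonical] + variants)

    tx_seqs = [transcripts[tid] for tid in sorted(transcripts)]
    libraries: Dict[str, Tuple[str, List[Tuple[str, int]]]] = {}
    for lib_name, origin, depth in config.libraries:
        n_cont = round(depth * config.contaminant_fraction) if origin == "field" else 0
        n_bg = round(depth * config.background_fraction) - n_cont
        n_mir = depth - n_bg - n_cont
        if not truth.mirnas:
            n_bg += n_mir
            n_mir = 0
        n_mature = round(n_mir / (1 + config.star_ratio))
        n_star = n_mir - n_mature
        reads: Counter = Counter()
        per_mirna = (
            rng.multinomial(n_mature, weights) if len(weights) else []
        )
        truth.library_mirna_counts.setdefault(lib_name, {})
        cf = config.canonical_fraction
        var_p = np.array([cf] + [(1 - cf) / 4] * 4)
        for m, count, variants in zip(truth.mirnas, per_mirna, mirna_variants):
            truth.library_mirna_counts[lib_name][m.name] = int(count)
            if count == 0:
                continue
            per_variant = rng.multinomial(int(count), var_p)
            for vseq, vc in zip(variants, per_variant):
                if vc:
                    reads[vseq] += int(vc)
        per_star = rng.multinomial(n_star, weights) if len(weights) else []
        for m, count in zip(truth.mirnas, per_star):
            if count and m.star_seq:
                reads[m.star_seq] += int(count)
        reads.update(_sample_fragments(rng, tx_seqs, n_bg))
        if n_cont:
            cont_seqs = [truth.contaminants[k] for k in sorted(truth.contaminants)]
            reads.update(_sample_fragments(rng, cont_seqs, n_cont))
        adapter = config.adapter
        libraries[lib_name] = (
            origin,
            sorted((s + adapter, c) for s, c in reads.items()),
        )
    return libraries


def simulate_degradome(
    truth: GroundTruth,
    transcripts: Mapping[str, str],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> Dict[str, int]:
    """Adapter-ligated degradome tags with spikes at planted cleavage sites.

    Background tag 5' ends fall uniformly along every transcript at
    ``degradome_background_rate`` per nucleotide; for each planted target,
    ``spike_fraction`` of that transcript's tags start exactly at the
    canonical cleavage position.
    """
    tags: Counter = Counter()
    spikes = {(t.transcript_id, t.canonical_cleavage) for t in truth.targets}
    tl = config.tag_length
    for tid in sorted(transcripts):
        seq = transcripts[tid]
        n_bg = int(rng.poisson(config.degradome_background_rate * len(seq)))
        positions = rng.integers(1, len(seq) - 13 + 1, size=n_bg)
        for pos in positions:
            tags[seq[pos - 1 : pos - 1 + tl]] += 1
        tx_spikes = [s for s in spikes if s[0] == tid]
        for _, pos in tx_spikes:
            sf = config.spike_fraction
            n_spike = max(1, round(sf / (1 - sf) * n_bg)) if sf < 1 else n_bg
            tag = seq[pos - 1 : pos - 1 + tl]
            if len(tag) >= 14:
                tags[tag] += n_spike
                truth.degradome_spike_counts[f"{tid}:{pos}"] = n_spike
    return {s + config.adapter: c for s, c in sorted(tags.items())}


def generate_contaminants(
    config: SimulationConfig, rng: np.random.Generator
) -> Dict[str, str]:
    return {
        f"contam{i + 1:02d}": _random_dna(rng, 120, 0.5)
        for i in range(config.n_contaminants)
    }


def generate_training_cds(
    rng: np.random.Generator, n_seqs: int = 30, n_codons: int = 200
) -> List[str]:
    """In-frame coding sequences drawn from the planted codon usage."""
    return ["ATG" + _random_codons(rng, n_codons - 1) for _ in range(n_seqs)]


def simulate_experiment(config: SimulationConfig) -> SyntheticExperiment:
    """Run the full generator: transcriptome, hairpins, targets, libraries,
    degradome, contaminants and training CDS, all from one seed."""
    rng = np.random.default_rng(config.seed)
    transcripts, coding = generate_transcriptome(config, rng)
    occupied: Dict[str, List[Tuple[int, int]]] = {}
    truth = plant_mir_hairpins(transcripts, coding, config, rng, occupied)
    truth.contaminants = generate_contaminants(config, rng)
    plant_target_sites(transcripts, truth, config, rng, occupied)
    libraries = simulate_srna_libraries(truth, transcripts, config, rng)
    degradome_tags = simulate_degradome(truth, transcripts, config, rng)
    training_cds = generate_training_cds(rng)
    return SyntheticExperiment(
        config=config,
        transcripts=transcripts,
        truth=truth,
        libraries=libraries,
        degradome_tags=degradome_tags,
        training_cds=training_cds,
    )


# ---------------------------------------------------------------------------
# run-directory output
# ---------------------------------------------------------------------------


def write_experiment(exp: SyntheticExperiment, outdir) -> Dict[str, str]:
    """Write an experiment as plain-text files under one run directory."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, str] = {}

    def _fasta(name: str, records) -> None:
        p = out / name
        with open(p, "w") as fh:
            for rid, seq in records:
                fh.write(f">{rid}\n{seq}\n")
        paths[name] = str(p)

    _fasta("transcripts.fasta", sorted(exp.transcripts.items()))
    _fasta("contaminants.fasta", sorted(exp.truth.contaminants.items()))
    _fasta(
        "training_cds.fasta",
        [(f"cds{i + 1:03d}", s) for i, s in enumerate(exp.training_cds)],
    )
    manifest = []
    for lib_name in sorted(exp.libraries):
        origin, reads = exp.libraries[lib_name]
        p = out / f"{lib_name}.fastq"
        with open(p, "w") as fh:
            i = 0
            for seq, count in reads:
                for _ in range(count):
                    i += 1
                    fh.write(f"@{lib_name}_{i}\n{seq}\n+\n{'I' * len(seq)}\n")
        paths[f"{lib_name}.fastq"] = str(p)
        manifest.append({"name": lib_name, "path": p.name, "origin": origin})
    with open(out / "libraries.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    paths["libraries.yaml"] = str(out / "libraries.yaml")
    p = out / "degradome.fastq"
    with open(p, "w") as fh:
        i = 0
        for seq in sorted(exp.degradome_tags):
            for _ in range(exp.degradome_tags[seq]):
                i += 1
                fh.write(f"@deg_{i}\n{seq}\n+\n{'I' * len(seq)}\n")
    paths["degradome.fastq"] = str(p)

    with open(out / "truth_mirnas.tsv", "w") as fh:
        fh.write(
            "name\tseq\tkind\tfamily\ttranscript\thairpin_start\thairpin_end"
            "\tmir_start\tmir_end\tstar_start\tstar_end\tstar_seq\tarm\n"
        )
        for m in exp.truth.mirnas:
            fh.write(
                f"{m.name}\t{m.seq}\t{m.kind}\t{m.family}\t{m.transcript_id}\t"
                f"{m.hairpin[0]}\t{m.hairpin[1]}\t{m.mir[0]}\t{m.mir[1]}\t"
                f"{m.star[0]}\t{m.star[1]}\t{m.star_seq}\t{m.arm}\n"
            )
    paths["truth_mirnas.tsv"] = str(out / "truth_mirnas.tsv")
    with open(out / "truth_targets.tsv", "w") as fh:
        fh.write("mirna\tmirna_seq\ttranscript\tsite_start\tsite_end\tcanonical_cleavage\n")
        for t in exp.truth.targets:
            fh.write(
                f"{t.mirna_name}\t{t.mirna_seq}\t{t.transcript_id}\t"
                f"{t.site[0]}\t{t.site[1]}\t{t.canonical_cleavage}\n"
            )
    paths["truth_targets.tsv"] = str(out / "truth_targets.tsv")
    with open(out / "truth_coding.tsv", "w") as fh:
        fh.write("transcript\tcds_start\tcds_end\n")
        for tid in sorted(exp.truth.coding):
            s, e = exp.truth.coding[tid]
            fh.write(f"{tid}\t{s}\t{e}\n")
    paths["truth_coding.tsv"] = str(out / "truth_coding.tsv")
    cfg = asdict(exp.config)
    cfg["libraries"] = [list(t) for t in cfg["libraries"]]
    cfg["transcript_length"] = list(cfg["transcript_length"])
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    paths["config.yaml"] = str(out / "config.yaml")
    return paths
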