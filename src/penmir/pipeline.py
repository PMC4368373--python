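"""End-to-end orchestration of the discovery pipeline.

The in-memory entry points are :func:`run_discovery` (reads -> clusters ->
conserved families + validated novel miRNAs -> predicted targets) and
:func:`run_degradome` (degradome tags -> T-plots -> cleavage calls).  The
file-based stage runner (:func:`run_stage`) wraps the same code over a run
directory with per-stage manifests, so that reruns with identical inputs
and parameters are byte-identical and stale upstream outputs are refused.

A cluster becomes an annotated novel miRNA only if, beyond the read-profile
heuristics, it sits in a transcript window that folds into an accepted
hairpin and its inferred star sequence is observed among the small-RNA
reads (the standard structural + star-evidence criteria for plant miRNA
annotation).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import pandas as pd
import yaml

from . import catalog, clustering, conserved, degradome, hairpin, io_preprocess, orf, simulate, targets
from .clustering import CandidateDecision, Cluster
from .conserved import FamilyAssignment, ReferenceMiRNA
from .degradome import CleavageCall
from .hairpin import PrecursorCandidate
from .io_preprocess import CollapsedRead, Library
from .orf import CodingAnnotation
from .targets import TargetCandidate

STAGES = (
    "trim",
    "cluster",
    "conserved",
    "novel",
    "fold",
    "orf",
    "targets",
    "degradome",
    "simulate",
    "all",
)


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineParams:
    """Every tunable constant of the pipeline, with its default."""

    adapter: str = simulate.DEFAULT_ADAPTER
    max_error_rate: float = 0.1
    srna_min_overlap: int = 7
    srna_require_adapter: bool = False
    min_len: int = 18
    max_len: int = 26
    min_count: int = 2
    cluster_min_total: int = 2
    dominance_band: Tuple[int, ...] = (20, 21)
    dominance_min_fraction: float = 0.5
    contaminant_max_mismatches: int = 0
    family_max_mismatches: int = 2
    family_min_overlap: int = 17
    n_top: int = 50
    flank: int = 200
    fold_engine: str = "maxpair"
    paired_fraction: float = 0.6
    max_unpaired: int = 5
    require_star: bool = True
    score_ceiling: float = 7.0
    total_max: float = 4.0
    seed_max: float = 2.5
    combine: str = "either"
    deg_min_overlap: int = 19
    deg_require_adapter: bool = True
    deg_min_len: int = 14
    min_codons: int = 20


@dataclass
class NovelMiRNACall:
    cluster_id: str
    mature_seq: str
    representative: str
    abundance: int
    precursors: List[PrecursorCandidate]

    @property
    def star_supported(self) -> bool:
        return any(p.star_supported for p in self.precursors)


@dataclass
class DiscoveryResult:
    libraries: Dict[str, Library]
    clusters: List[Cluster]
    decisions: Dict[str, CandidateDecision]
    contaminant_annotations: Dict[str, List[str]]
    assignments: List[FamilyAssignment]
    candidates: List[Cluster]
    novel: List[NovelMiRNACall]
    arm_pairs: List[dict]
    coding: Dict[str, CodingAnnotation]
    target_candidates: List[TargetCandidate]
    read_seqs: Set[str] = field(default_factory=set)

    @property
    def assigned_cluster_ids(self) -> Set[str]:
        return {a.query_id for a in self.assignments}

    def mature_by_cluster(self) -> Dict[str, str]:
        return {c.id: c.mature_seq for c in self.clusters}


def preprocess_library(
    name: str,
    origin: str,
    counted_reads: Iterable[Tuple[str, int]],
    params: PipelineParams,
) -> Tuple[Library, List[CollapsedRead]]:
    """Trim, collapse and filter one library of (raw seq, count) pairs.

    ``total_count`` of the returned library is the number of
    adapter-identified reads before length selection (the per-million
    denominator).
    """
    raw = io_preprocess.collapse_counted(counted_reads)
    seqs = sorted(raw)
    trimmed = io_preprocess.trim_adapter_batch(
        seqs,
        params.adapter,
        min_overlap=params.srna_min_overlap,
        max_error_rate=params.max_error_rate,
        require_adapter=params.srna_require_adapter,
    )
    inserts: Dict[str, int] = {}
    total = 0
    for s, (insert, found) in zip(seqs, trimmed):
        if found:
            total += raw[s]
        if insert:
            inserts[insert] = inserts.get(insert, 0) + raw[s]
    collapsed = [CollapsedRead(s, c) for s, c in sorted(inserts.items())]
    collapsed = io_preprocess.filter_by_length(
        collapsed, params.min_len, params.max_len
    )
    collapsed = io_preprocess.filter_low_count(collapsed, params.min_count)
    lib = Library(
        name=name,
        origin=origin,
        reads={r.seq: r.count for r in collapsed},
        total_count=total,
    )
    return lib, collapsed


def run_discovery(
    raw_libraries: Mapping[str, Tuple[str, Sequence[Tuple[str, int]]]],
    transcripts: Mapping[str, str],
    reference: Sequence[ReferenceMiRNA],
    contaminant_sets: Optional[Mapping[str, Iterable[str]]] = None,
    training_cds: Optional[Sequence[str]] = None,
    params: Optional[PipelineParams] = None,
) -> DiscoveryResult:
    """The full small-RNA side of the pipeline, in memory."""
    params = params or PipelineParams()
    libraries: Dict[str, Library] = {}
    per_lib_reads: Dict[str, List[CollapsedRead]] = {}
    for name, (origin, counted) in raw_libraries.items():
        lib, collapsed = preprocess_library(name, origin, counted, params)
        libraries[name] = lib
        per_lib_reads[name] = collapsed
    read_seqs: Set[str] = set()
    for reads in per_lib_reads.values():
        read_seqs.update(r.seq for r in reads)

    clusters = clustering.build_clusters(per_lib_reads, params.cluster_min_total)
    decisions = {
        c.id: clustering.dominance_test(
            c, params.dominance_band, params.dominance_min_fraction
        )
        for c in clusters
    }
    annotations = clustering.screen_contaminants(
        clusters, contaminant_sets or {}, params.contaminant_max_mismatches
    )
    assignments = conserved.assign_families(
        {c.id: c.mature_seq for c in clusters},
        list(reference),
        params.family_max_mismatches,
        params.family_min_overlap,
    )
    assigned = {a.query_id for a in assignments}
    origins = {name: lib.origin for name, lib in libraries.items()}
    candidates = clustering.select_candidates(
        [c for c in clusters if c.id not in assigned],
        decisions,
        origins,
        n_top=params.n_top,
        annotations=annotations,
    )

    novel: List[NovelMiRNACall] = []
    all_precursors: List[PrecursorCandidate] = []
    for cl in candidates:
        mature = cl.mature_seq
        accepted = []
        for win in hairpin.find_precursor_windows(
            mature, transcripts, params.flank
        ):
            tid = win[0]
            cand = hairpin.build_precursor_candidate(
                tid,
                transcripts[tid],
                mature,
                win[1:],
                read_seqs=read_seqs,
                engine=params.fold_engine,
                paired_fraction=params.paired_fraction,
                max_unpaired=params.max_unpaired,
                mirna_id=cl.id,
            )
            if cand is not None:
                accepted.append(cand)
        if not accepted:
            continue
        call = NovelMiRNACall(cl.id, mature, cl.representative, cl.abundance, accepted)
        if params.require_star and not call.star_supported:
            continue
        novel.append(call)
        all_precursors.extend(accepted)
    abundances = {c.id: c.abundance for c in clusters}
    arm_pairs = hairpin.detect_arm_pairs(all_precursors, abundances)

    coding: Dict[str, CodingAnnotation] = {}
    if training_cds:
        model = orf.train_codon_model(training_cds)
        for tid in sorted(transcripts):
            ann = orf.find_coding_region(tid, transcripts[tid], model, params.min_codons)
            if ann is not None:
                coding[tid] = ann

    mature_by_cluster = {c.id: c.mature_seq for c in clusters}
    scan_ids = sorted(
        {n.cluster_id for n in novel} | {a.query_id for a in assignments}
    )
    tlen = {tid: len(seq) for tid, seq in transcripts.items()}
    target_candidates: List[TargetCandidate] = []
    for cid in scan_ids:
        mseq = mature_by_cluster[cid]
        if not params.min_len <= len(mseq) <= params.max_len:
            continue
        duplexes = []
        for tid in sorted(transcripts):
            duplexes.extend(
                targets.scan_targets(
                    mseq, transcripts[tid], cid, tid, params.score_ceiling
                )
            )
        target_candidates.extend(
            targets.filter_duplexes(
                duplexes, params.total_max, params.seed_max, params.combine, tlen
            )
        )

    return DiscoveryResult(
        libraries=libraries,
        clusters=clusters,
        decisions=decisions,
        contaminant_annotations=annotations,
        assignments=assignments,
        candidates=candidates,
        novel=novel,
        arm_pairs=arm_pairs,
        coding=coding,
        target_candidates=target_candidates,
        read_seqs=read_seqs,
    )


def run_degradome(
    counted_tags: Iterable[Tuple[str, int]],
    transcripts: Mapping[str, str],
    target_candidates: Sequence[TargetCandidate],
    coding: Mapping[str, CodingAnnotation],
    params: Optional[PipelineParams] = None,
) -> Tuple[List[CleavageCall], pd.DataFrame, int]:
    """Degradome side: trim, map, build T-plots, call cleavage sites."""
    params = params or PipelineParams()
    raw = io_preprocess.collapse_counted(counted_tags)
    seqs = sorted(raw)
    trimmed = io_preprocess.trim_adapter_batch(
        seqs,
        params.adapter,
        min_overlap=params.deg_min_overlap,
        max_error_rate=params.max_error_rate,
        require_adapter=params.deg_require_adapter,
    )
    tag_counts: Dict[str, int] = {}
    for s, (insert, _found) in zip(seqs, trimmed):
        if insert and len(insert) >= params.deg_min_len:
            tag_counts[insert] = tag_counts.get(insert, 0) + raw[s]
    mapped = degradome.map_tags(tag_counts, transcripts)
    library_size = degradome.mapped_library_size(mapped)
    tplots = degradome.build_tplots(mapped, library_size)
    calls: List[CleavageCall] = []
    for tc in target_candidates:
        if not tc.retained:
            continue
        tplot = tplots.get(tc.duplex.transcript_id)
        if tplot is None:
            continue
        call = degradome.call_cleavage(tplot, tc)
        if call is not None:
            calls.append(call)
    table = degradome.summarize_targets(calls, coding)
    return calls, table, library_size


# ---------------------------------------------------------------------------
# recovery scoring against synthetic ground truth
# ---------------------------------------------------------------------------


@dataclass
class RecoveryReport:
    mirna_recovery: float
    target_recovery: float
    spurious_novel_fraction: float
    n_planted_mirnas: int
    n_recovered_mirnas: int
    n_planted_targets: int
    n_recovered_targets: int
    n_novel_emitted: int
    n_novel_spurious: int


def score_recovery(
    result: DiscoveryResult,
    calls: Sequence[CleavageCall],
    truth: "simulate.GroundTruth",
) -> RecoveryReport:
    """Score a pipeline run against the generator's ground truth.

    A planted miRNA counts as recovered when some cluster carrying its
    mature sequence was either assigned to a reference family or emitted
    as a validated novel miRNA.  An emitted novel miRNA is spurious when
    its mature sequence is neither a planted mature nor a planted star
    (star-arm clusters are planted species, annotated as the other arm of
    the same hairpin).  A planted target is recovered by a category-1/2
    cleavage call of its miRNA at the planted site.
    """
    mature_by_cluster = result.mature_by_cluster()
    cluster_of_seq: Dict[str, str] = {}
    for cl in result.clusters:
        for s in cl.members:
            cluster_of_seq[s] = cl.id
    hit_cluster_ids = {a.query_id for a in result.assignments} | {
        n.cluster_id for n in result.novel
    }
    # membership-level: co-clustered family members (e.g. two planted
    # matures differing by 1 nt) are recovered by one assigned cluster
    recovered = [
        m for m in truth.mirnas if cluster_of_seq.get(m.seq) in hit_cluster_ids
    ]
    planted_seqs = truth.planted_seqs
    spurious = [n for n in result.novel if n.mature_seq not in planted_seqs]

    call_index = set()
    for c in calls:
        if c.category <= 2:
            call_index.add(
                (
                    c.target.duplex.mirna_id,
                    c.target.duplex.transcript_id,
                    c.observed_position,
                )
            )
    hit_targets = [
        t
        for t in truth.targets
        if (
            cluster_of_seq.get(t.mirna_seq),
            t.transcript_id,
            t.canonical_cleavage,
        )
        in call_index
    ]
    n_novel = len(result.novel)
    return RecoveryReport(
        mirna_recovery=len(recovered) / len(truth.mirnas) if truth.mirnas else 1.0,
        target_recovery=len(hit_targets) / len(truth.targets) if truth.targets else 1.0,
        spurious_novel_fraction=len(spurious) / n_novel if n_novel else 0.0,
        n_planted_mirnas=len(truth.mirnas),
        n_recovered_mirnas=len(recovered),
        n_planted_targets=len(truth.targets),
        n_recovered_targets=len(hit_targets),
        n_novel_emitted=n_novel,
        n_novel_spurious=len(spurious),
    )


# ---------------------------------------------------------------------------
# bundled-catalogue self-checks
# ---------------------------------------------------------------------------


def verify_fixtures() -> List[Tuple[str, object, object, bool]]:
    """Recompute the bundled-catalogue statistics and compare with the
    published values.  Returns (check, expected, observed, ok) tuples."""
    checks: List[Tuple[str, object, object, bool]] = []
    pairs = {p.name: p for p in catalog.load_algal_homologs()}
    expected_mn = {"pen-miR8183.2": 2, "pen-miR8185": 1, "pen-miR1144": 2}
    for name, exp_mn in expected_mn.items():
        aln = conserved.best_overlap_alignment(
            pairs[name].pen_seq, pairs[name].algal_seq, min_overlap=17
        )
        checks.append((f"algal_homolog_mn[{name}]", exp_mn, aln.mismatches, aln.mismatches == exp_mn))
    novel = catalog.load_novel_mirnas()
    checks.append(("novel_catalogue_rows", 42, len(novel), len(novel) == 42))
    fams = {m.family for m in novel if m.is_novel}
    checks.append(("novel_families", 34, len(fams), len(fams) == 34))
    known = catalog.load_known_mirnas()
    kfams = {conserved.family_number(r.family) for r in known}
    checks.append(("conserved_families", 11, len(kfams), len(kfams) == 11))
    for name, exp_len in (("pen-miR8163", 23), ("pen-miR8187", 24)):
        m = catalog.get_novel(name)
        got = len(m.seq) if m else None
        checks.append((f"mature_length[{name}]", exp_len, got, got == exp_len))
    return checks


# ---------------------------------------------------------------------------
# file-based stage runner
# ---------------------------------------------------------------------------


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunConfig:
    """File-level configuration of a pipeline run directory."""

    run_dir: str
    libraries_manifest: str = "libraries.yaml"
    transcripts: str = "transcripts.fasta"
    degradome_reads: str = "degradome.fastq"
    reference_catalogue: Optional[str] = None  # None -> bundled catalogue
    contaminants: Optional[str] = "contaminants.fasta"
    training_cds: Optional[str] = "training_cds.fasta"
    seed: Optional[int] = None
    sim: Dict[str, object] = field(default_factory=dict)
    params: PipelineParams = field(default_factory=PipelineParams)

    def path(self, name: str) -> Path:
        p = Path(name)
        return p if p.is_absolute() else Path(self.run_dir) / p

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        params = PipelineParams(**data.pop("params", {}))
        if isinstance(params.dominance_band, list):
            params.dominance_band = tuple(params.dominance_band)
        return cls(params=params, **data)


def _load_counted_fastx(path: Path) -> List[Tuple[str, int]]:
    counts: Dict[str, int] = {}
    for read in io_preprocess.read_reads(path):
        counts[read.seq] = counts.get(read.seq, 0) + 1
    return sorted(counts.items())


def _write_manifest(outdir: Path, stage: str, inputs: Dict[str, Path], params: dict, outputs: List[Path]) -> None:
    manifest = {
        "stage": stage,
        "params": params,
        "inputs": {str(p): _sha256(p) for p in inputs.values()},
        "outputs": {str(p): _sha256(p) for p in outputs},
    }
    with open(outdir / f"manifest_{stage}.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)


def _check_upstream(outdir: Path, stage: str, needed: Sequence[str]) -> None:
    for up in needed:
        mpath = outdir / f"manifest_{up}.json"
        if not mpath.exists():
            raise PipelineError(f"stage {stage!r} needs outputs of stage {up!r}; run it first")
        with open(mpath) as fh:
            manifest = json.load(fh)
        for out_path, digest in manifest["outputs"].items():
            p = Path(out_path)
            if not p.exists() or _sha256(p) != digest:
                raise PipelineError(
                    f"outputs of stage {up!r} are stale or missing; rerun {up!r}"
                )


def run_stage(name: str, config: RunConfig):
    """Run one named pipeline stage over a run directory.

    The file-based runner executes the in-memory pipeline up to the
    requested stage and writes that stage's outputs plus a manifest with
    input hashes and parameters; downstream stages refuse to run against
    stale upstream outputs.  ``all`` chains trim -> cluster -> conserved ->
    novel -> fold -> orf -> targets -> degradome.
    """
    if name not in STAGES:
        raise PipelineError(f"unknown stage {name!r}")
    outdir = Path(config.run_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    if name == "simulate":
        if config.seed is None:
            raise PipelineError("simulate requires a seed")
        sim_kwargs = dict(config.sim)
        if "libraries" in sim_kwargs:
            sim_kwargs["libraries"] = tuple(tuple(t) for t in sim_kwargs["libraries"])
        if "transcript_length" in sim_kwargs:
            sim_kwargs["transcript_length"] = tuple(sim_kwargs["transcript_length"])
        exp = simulate.simulate_experiment(
            simulate.SimulationConfig(seed=config.seed, **sim_kwargs)
        )
        paths = simulate.write_experiment(exp, outdir)
        _write_manifest(outdir, "simulate", {}, {"seed": config.seed}, [Path(p) for p in paths.values()])
        return paths
    if name == "all":
        out = None
        for stage in ("trim", "cluster", "conserved", "novel", "fold", "orf", "targets", "degradome"):
            out = run_stage(stage, config)
        return out
    return _STAGE_FUNCS[name](config)


def _load_libraries(config: RunConfig):
    entries = io_preprocess.load_library_manifest(config.path(config.libraries_manifest))
    return {
        e["name"]: (e["origin"], _load_counted_fastx(config.path(e["path"])))
        for e in entries
    }


def _discovery_inputs(config: RunConfig):
    transcripts = io_preprocess.load_fasta_dict(config.path(config.transcripts))
    if config.reference_catalogue:
        ref_path = config.path(config.reference_catalogue)
        if str(ref_path).endswith((".tsv", ".txt")):
            reference = conserved.load_reference_tsv(ref_path)
        else:
            reference = conserved.load_reference_fasta(ref_path)
    else:
        reference = catalog.load_known_mirnas()
    contaminants = {}
    if config.contaminants and config.path(config.contaminants).exists():
        contaminants = {"contaminants": list(io_preprocess.load_fasta_dict(config.path(config.contaminants)).values())}
    training = None
    if config.training_cds and config.path(config.training_cds).exists():
        training = list(io_preprocess.load_fasta_dict(config.path(config.training_cds)).values())
    return transcripts, reference, contaminants, training


_RESULT_CACHE: Dict[str, Tuple[str, DiscoveryResult]] = {}


def _full_discovery(config: RunConfig) -> DiscoveryResult:
    """The stage runner recomputes the in-memory result once per config."""
    key = str(Path(config.run_dir).resolve())
    fingerprint = json.dumps(asdict(config.params), sort_keys=True, default=str)
    cached = _RESULT_CACHE.get(key)
    if cached and cached[0] == fingerprint:
        return cached[1]
    raw = _load_libraries(config)
    transcripts, reference, contaminants, training = _discovery_inputs(config)
    result = run_discovery(raw, transcripts, reference, contaminants, training, config.params)
    _RESULT_CACHE[key] = (fingerprint, result)
    return result


def _stage_trim(config: RunConfig):
    outdir = Path(config.run_dir)
    result = _full_discovery(config)
    outputs = []
    for lib_name, lib in sorted(result.libraries.items()):
        p = outdir / f"collapsed_{lib_name}.tsv"
        reads = [CollapsedRead(s, c) for s, c in sorted(lib.reads.items())]
        io_preprocess.write_collapsed_tsv(reads, p)
        outputs.append(p)
    p = outdir / "library_totals.tsv"
    with open(p, "w") as fh:
        fh.write("library\torigin\ttotal_count\tretained_reads\n")
        for lib_name, lib in sorted(result.libraries.items()):
            fh.write(
                f"{lib_name}\t{lib.origin}\t{lib.total_count}\t{sum(lib.reads.values())}\n"
            )
    outputs.append(p)
    inputs = {
        e["name"]: config.path(e["path"])
        for e in io_preprocess.load_library_manifest(config.path(config.libraries_manifest))
    }
    _write_manifest(outdir, "trim", inputs, asdict(config.params), outputs)
    return outputs


def _stage_cluster(config: RunConfig):
    outdir = Path(config.run_dir)
    _check_upstream(outdir, "cluster", ["trim"])
    result = _full_discovery(config)
    p = outdir / "clusters.tsv"
    rows = []
    for cl in result.clusters:
        dec = result.decisions[cl.id]
        first_nt = cl.first_nt_profile()
        rows.append(
            {
                "cluster_id": cl.id,
                "representative": cl.representative,
                "mature_seq": cl.mature_seq,
                "length": len(cl.representative),
                "abundance": cl.abundance,
                **{f"count_{lib}": c for lib, c in sorted(cl.library_counts().items())},
                "dominant_length": dec.dominant_length,
                "dominance_fraction": round(dec.dominance_fraction, 4),
                "gc_content": round(cl.gc_content, 4),
                **{f"first_{b}": round(first_nt[b], 4) for b in "ACGT"},
                "annotations": ";".join(result.contaminant_annotations.get(cl.id, [])),
                "passed_dominance": dec.passed,
            }
        )
    pd.DataFrame(rows).to_csv(p, sep="\t", index=False)
    p2 = outdir / "cluster_profiles.tsv"
    with open(p2, "w") as fh:
        fh.write("cluster_id\tlibrary\tlength\tcount\n")
        for cl in result.clusters:
            for lib in sorted(cl.library_presence):
                for L, c in sorted(cl.size_profile(lib).items()):
                    fh.write(f"{cl.id}\t{lib}\t{L}\t{c}\n")
    _write_manifest(outdir, "cluster", {}, asdict(config.params), [p, p2])
    return [p, p2]


def _stage_conserved(config: RunConfig):
    outdir = Path(config.run_dir)
    _check_upstream(outdir, "conserved", ["cluster"])
    result = _full_discovery(config)
    lib_counts = {
        cl.id: cl.library_counts() for cl in result.clusters
    }
    means = conserved.family_mean_count(
        result.assignments, lib_counts, sorted(result.libraries)
    )
    p = outdir / "assignments.tsv"
    with open(p, "w") as fh:
        fh.write("cluster_id\tfamily\tmember\tspecies\toffset\toverlap\tmn\tfamily_mean_count\n")
        for a in result.assignments:
            fh.write(
                f"{a.query_id}\t{a.family}\t{a.member}\t{a.species}\t"
                f"{a.alignment.offset}\t{a.alignment.overlap_len}\t"
                f"{a.alignment.mismatches}\t{means[a.family]:.2f}\n"
            )
    _write_manifest(outdir, "conserved", {}, asdict(config.params), [p])
    return [p]


def _stage_novel(config: RunConfig):
    outdir = Path(config.run_dir)
    _check_upstream(outdir, "novel", ["cluster", "conserved"])
    result = _full_discovery(config)
    p = outdir / "candidates.tsv"
    with open(p, "w") as fh:
        fh.write("cluster_id\tmature_seq\trepresentative\tabundance\tdominant_length\tdominance_fraction\n")
        for cl in result.candidates:
            dec = result.decisions[cl.id]
            fh.write(
                f"{cl.id}\t{cl.mature_seq}\t{cl.representative}\t{cl.abundance}\t"
                f"{dec.dominant_length}\t{dec.dominance_fraction:.4f}\n"
            )
    _write_manifest(outdir, "novel", {}, asdict(config.params), [p])
    return [p]


def _stage_fold(config: RunConfig):
    outdir = Path(config.run_dir)
    _check_upstream(outdir, "fold", ["novel"])
    result = _full_discovery(config)
    p = outdir / "precursors.tsv"
    with open(p, "w") as fh:
        fh.write(
            "cluster_id\tmature_seq\ttranscript\twin_start\twin_end\tmir_start\tmir_end"
            "\tarm\tduplex_mismatches\tstar_start\tstar_end\tstar_seq\tstar_supported"
            "\tengine\tscore\n"
        )
        for call in result.novel:
            for pc in call.precursors:
                fh.write(
                    f"{call.cluster_id}\t{call.mature_seq}\t{pc.transcript_id}\t"
                    f"{pc.window[0]}\t{pc.window[1]}\t{pc.mir[0]}\t{pc.mir[1]}\t"
                    f"{pc.arm}\t{pc.duplex_mismatches}\t"
                    f"{pc.star[0] if pc.star else ''}\t{pc.star[1] if pc.star else ''}\t"
                    f"{pc.star_seq or ''}\t{pc.star_supported}\t"
                    f"{pc.fold.engine}\t{pc.fold.score:g}\n"
                )
    p2 = outdir / "hairpins.fasta"
    with open(p2, "w") as fh:
        for call in result.novel:
            for pc in call.precursors:
                fh.write(
                    f">{call.cluster_id}|{pc.transcript_id}:{pc.window[0]}-{pc.window[1]}\n"
                    f"{pc.fold.seq}\n"
                )
    p3 = outdir / "arm_pairs.tsv"
    pd.DataFrame(result.arm_pairs).to_csv(p3, sep="\t", index=False)
    _write_manifest(outdir, "fold", {}, asdict(config.params), [p, p2, p3])
    return [p, p2, p3]


def _stage_orf(config: RunConfig):
    outdir = Path(config.run_dir)
    result = _full_discovery(config)
    p = outdir / "coding.gff3"
    orf.write_gff3(
        [result.coding[tid] for tid in sorted(result.coding)], p
    )
    _write_manifest(outdir, "orf", {}, asdict(config.params), [p])
    return [p]


def _stage_targets(config: RunConfig):
    outdir = Path(config.run_dir)
    _check_upstream(outdir, "targets", ["fold", "orf"])
    result = _full_discovery(config)
    p = outdir / "targets.tsv"
    with open(p, "w") as fh:
        fh.write(
            "cluster_id\tmirna_seq\ttranscript\tsite_start\tsite_end\tpairing"
            "\ttotal_score\tseed_score\tretained\treason\twindow\tcanonical\tregion\n"
        )
        for tc in result.target_candidates:
            d = tc.duplex
            region = ""
            ann = result.coding.get(d.transcript_id)
            if ann and tc.canonical_cleavage:
                region = orf.REGION_LABELS[orf.classify_region(ann, tc.canonical_cleavage)]
            fh.write(
                f"{d.mirna_id}\t{d.mirna_seq}\t{d.transcript_id}\t{d.site[0]}\t{d.site[1]}\t"
                f"{d.display_states()}\t{d.total_score:g}\t{d.seed_score:g}\t{tc.retained}\t"
                f"{tc.rejection_reason or ''}\t"
                f"{','.join(map(str, tc.predicted_cleavage_window))}\t"
                f"{tc.canonical_cleavage or ''}\t{region}\n"
            )
    _write_manifest(outdir, "targets", {}, asdict(config.params), [p])
    return [p]


def _stage_degradome(config: RunConfig):
    outdir = Path(config.run_dir)
    _check_upstream(outdir, "degradome", ["targets"])
    result = _full_discovery(config)
    transcripts = io_preprocess.load_fasta_dict(config.path(config.transcripts))
    counted = _load_counted_fastx(config.path(config.degradome_reads))
    calls, table, library_size = run_degradome(
        counted, transcripts, result.target_candidates, result.coding, config.params
    )
    p = outdir / "cleavage_calls.tsv"
    with open(p, "w") as fh:
        fh.write("cluster_id\ttranscript\tposition\tsignal_tp1m\tcategory\twindow_offset\n")
        for c in calls:
            fh.write(
                f"{c.target.duplex.mirna_id}\t{c.target.duplex.transcript_id}\t"
                f"{c.observed_position}\t{c.signal_value:.6f}\t{c.category}\t"
                f"{c.matched_window_offset}\n"
            )
    p2 = outdir / "target_table.tsv"
    table.to_csv(p2, sep="\t", index=False)
    p3 = outdir / "degradome_meta.tsv"
    with open(p3, "w") as fh:
        fh.write("key\tvalue\n")
        fh.write(f"library_size_mapped\t{library_size}\n")
        fh.write("normalization\tTP1M (mapped-tag denominator)\n")
    _write_manifest(outdir, "degradome", {}, asdict(config.params), [p, p2, p3])
    return [p, p2, p3]


_STAGE_FUNCS = {
    "trim": _stage_trim,
    "cluster": _stage_cluster,
    "conserved": _stage_conserved,
    "novel": _stage_novel,
    "fold": _stage_fold,
    "orf": _stage_orf,
    "targets": _stage_targets,
    "degradome": _stage_degradome,
}
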