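# penmir

Reference-free discovery and validation of plant microRNAs from small-RNA
sequencing, with degradome-based confirmation of their cleavage targets.

Most plant miRNA annotation pipelines start from a genome: reads are mapped,
loci are folded, and precursors are called.  For organisms without a
sequenced genome — the motivating case is the liverwort *Pellia
endiviifolia*, a basal land plant — none of that machinery applies.
`penmir` implements the genome-free alternative: small-RNA reads are grouped
into **clusters** of perfectly co-aligned sequences, clusters are screened by
the read-length profile that distinguishes miRNAs from degradation products,
conserved families are recognised by mismatch-budgeted overlap alignment
against known mature miRNAs, and novel candidates are validated structurally
(a stem-loop precursor in an assembled transcript, with the star strand
observed among the reads) and functionally (a degradome tag spike at the
predicted slicing position of each target).

## The statistics at the core

**Overlap alignment (Mn).**  Two mature sequences are compared over every
ungapped offset with overlap ≥ 17 nt; the reported alignment minimises the
number of mismatches *Mn* in the overlapping region.  A query is assigned to
a reference family when *Mn* ≤ 2.

**Duplex score.**  A miRNA:target duplex is scored per miRNA position
(numbered 5′→3′): Watson–Crick = 0, G:U wobble = 0.5, mismatch = 1.
Duplexes with a total score ≥ 4, or a score > 2.5 over miRNA positions
1–12, are discarded.

**T-plots and TP1M.**  Degradome tags are mapped exactly to transcripts and
each 5′-end position is normalised as

    TP1M = (raw count / library size) × 10⁶ / m

where *m* is the number of distinct transcripts the tag maps to.  A
per-transcript threshold is the mean TP1M over tag-bearing positions.  The
transcript position facing miRNA position 10 (canonical slicing site) and
its 9–11 window are compared against the T-plot: category 1 = above
threshold and the unique transcript-wide maximum, category 2 = above
threshold but not the unique maximum, category 3 = non-zero but below
threshold.

**Hairpin validation.**  Candidate matures are located in transcripts, a
±200-nt window is folded (deterministic base-pair maximisation over
canonical + G:U pairs, minimum loop 3 nt; a thermodynamic `RNAfold` backend
is available behind the same interface), and the fold is accepted when ≥ 60%
of miRNA positions pair into a single opposing arm.  The star sequence is
inferred under the 2-nt 3′-overhang convention and must be present among the
sequenced reads.

## Worked example

Everything is driven by a seeded synthetic experiment with known ground
truth (five libraries of 100 000 reads, 20 planted miRNAs, 15 planted
target sites):

```python
from penmir import catalog
from penmir.simulate import SimulationConfig, simulate_experiment
from penmir.pipeline import run_discovery, run_degradome, score_recovery

exp = simulate_experiment(SimulationConfig(seed=1))
res = run_discovery(exp.libraries, exp.transcripts, catalog.load_known_mirnas(),
                    {"contaminants": list(exp.truth.contaminants.values())},
                    exp.training_cds)
calls, table, libsize = run_degradome(exp.degradome_tags.items(), exp.transcripts,
                                      res.target_candidates, res.coding)
print(score_recovery(res, calls, exp.truth))
```

prints (seed 1):

```
clusters: 4436
family-assigned clusters: 13
novel candidates examined: 50
validated novel miRNAs (hairpin + star): 12
cleavage calls: 24 (category 1: 10)
recovery: 20/20 miRNAs, 15/15 targets
```

i.e. every planted miRNA comes back either as a conserved-family assignment
or as a hairpin-validated novel miRNA, and every planted target receives a
category-1/2 cleavage call at its planted slicing position.  The final
target table mirrors the usual degradome report:

```
transcript_id  cleavage_site cleavage_region                      mirnas  category  signal_tp1m
       tx0001           1291          3' UTR               cluster_00019         1      8102.63
       tx0013           1111          3' UTR cluster_00009;cluster_00010         2       225.07
```

The overlap alignment is equally usable on its own — for example on the
bundled liverwort/green-alga homolog pair:

```python
from penmir import catalog, best_overlap_alignment
pair = next(p for p in catalog.load_algal_homologs() if p.name == "pen-miR8185")
aln = best_overlap_alignment(pair.pen_seq, pair.algal_seq)
print(aln.overlap_len, aln.mismatches)   # -> 18 1
```

A command-line interface wraps the same stages over a run directory:

```
penmir simulate --seed 1 --out run1
penmir run all --run-dir run1
penmir verify
```

## Layout

| module | role |
| --- | --- |
| `penmir.io_preprocess` | FASTQ/FASTA input, adapter trimming, collapsing, length/copy filters |
| `penmir.clustering` | substring-containment clusters, size profiles, candidate selection |
| `penmir.conserved` | overlap alignment, family assignment, cross-species scan |
| `penmir.hairpin` | folding engines, hairpin validation, star inference, 5p/3p pairs |
| `penmir.orf` | codon-usage coding-region annotation (5′ UTR / CDS / 3′ UTR) |
| `penmir.targets` | duplex scanning, mismatch/G:U scoring, retention thresholds |
| `penmir.degradome` | tag mapping, TP1M T-plots, cleavage calling, final table |
| `penmir.simulate` | seeded synthetic experiments with full ground truth |
| `penmir.pipeline` / `penmir.cli` | orchestration, manifests, command line |

See `docs/methods.md` for the model assumptions, parameter defaults and
known limitations.
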