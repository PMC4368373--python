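# Methods

This note documents the models and procedures implemented in `penmir`, the
defaults chosen where the underlying methodology leaves the choice open,
and what the synthetic experiments do and do not demonstrate.

## Read preprocessing

Adapter removal is a suffix-anchored search: the adapter may occur anywhere
in the read, but a partial match is only accepted at the read's 3′ end.  At
each position the overlap is `min(len(adapter), len(read) − p)`; a position
is a hit when the overlap is at least `min_overlap` with at most
`floor(overlap × max_error_rate)` mismatches, and the leftmost hit wins.
Two presets reflect the two library types: small-RNA mode (`min_overlap=7`,
reads without a recognisable adapter are kept) and degradome mode
(`min_overlap=19`, adapter required, trimmed tags must exceed 13 nt).
`max_error_rate` defaults to 0.1, the convention of standard trimmers.
Reads containing N are dropped at collapse time so that all downstream
sequence arithmetic is over a 4-letter alphabet.  The per-million
denominator of a library is the number of adapter-identified reads before
length selection; this choice is recorded in the output metadata.  After
collapsing, the 18–26-nt window is applied and sequences seen fewer than
`min_count = 2` times in a library are treated as noise (the copy-number
analogue of a quality filter; base-quality information is deliberately not
modelled).

A vectorised batch trimmer (`trim_adapter_batch`) implements the identical
rule over numpy arrays; the test suite asserts scalar/batch agreement on
random inputs.

## Clustering

"Perfectly co-aligned" is operationalised as exact substring containment:
two reads share a cluster iff they are connected under the transitive
closure of "one sequence is an exact ungapped substring of the other".
This reproduces the observed picture of a miRNA cluster — a dominant
canonical species plus shorter/contained and slightly extended variants —
while being order-independent and cheap to compute (each sequence indexes
all of its substrings at lengths present in the data; components come from
union–find).  Clusters with fewer than two read copies are discarded.
Clusters are built on the pooled multi-library read set with per-library
counts retained; building per library and merging by representative yields
the same partition whenever representatives coincide, and pooling avoids
the merge step entirely.

Each cluster reports a length→count *size profile* (pooled and per
library), GC content and the count-weighted 5′-nucleotide profile.  The
dominance test passes when the argmax length (ties to the shorter length)
carries at least `min_fraction = 0.5` of the cluster's reads — the
methodology only requires a "clearly dominant" length, so 0.5 is a
config-exposed default — and lies in the preferred 20–21-nt band
(configurable to 19–24).  GC content and 5′-nucleotide composition are
reported, not thresholded: they were used qualitatively in the original
selection.  Candidate ranking is by pooled raw abundance; the top
`n_top = 50` unannotated, dominance-passing clusters present in at least
one in vitro library proceed to structural validation.  The in vitro
requirement exists because field-collected material carries fungal/algal
contamination; contaminant screening additionally annotates (and excludes)
clusters whose representative occurs, with at most `max_mismatches = 0`
substitutions, in any user-supplied contaminant set.

## Conserved-family assignment

`best_overlap_alignment` enumerates every ungapped offset with overlap
≥ `min_overlap = 17` and minimises the mismatch count (Mn); ties prefer the
larger overlap, then the smaller absolute offset (containment-favouring),
then the offset sign, making the result fully deterministic.  17 gives one
position of slack below the 18-nt overlaps observed in practice.  A query
is assigned to every family with a member at Mn ≤ 2; its primary hit is
the lowest-Mn assignment.  Family mean counts are the per-library sums of
all assigned reads, averaged over libraries (raw by default, per-million by
flag).  The same alignment drives the cross-species homology scan, which
additionally reports the mismatch positions within the overlap.  A numba
kernel pre-screens the minimum mismatch count per pair; the full Python
alignment is only constructed for actual hits (performance only — results
are identical, and the pure-Python path is the one checked against the
exhaustive oracle).

## Hairpin validation and star inference

The built-in folding engine maximises the base-pair count by dynamic
programming over A-U, G-C and G-U pairs with a minimum hairpin loop of
3 nt, with a deterministic traceback (pair the interval ends when optimal,
otherwise leave an end unpaired, otherwise bifurcate at the smallest
split).  Maximisation rather than thermodynamics keeps every test exact and
reproducible; an `RNAfold` backend is available behind the same interface,
with scores engine-tagged (pair counts and kcal/mol are never compared).
Windows are the exact mature occurrence ±200 nt — plant pre-miRNA
fold-backs span roughly 55–830 nt, so a 440-nt window covers the common
range; a wider flank is a flag away.

A window is accepted when (a) ≥ 60% of miRNA positions are paired, (b) all
partners lie on a single side of the miRNA (no self-pairing, no pairing
across the terminal loop), and (c) at most 5 miRNA positions are unpaired.
These thresholds follow common plant-miRNA annotation practice and are
config-exposed; the underlying methodology does not state numeric values.

The star span applies the 2-nt 3′-overhang convention to the partners of
the miRNA ends.  Because a maximum-pairing fold occasionally pairs an
outermost miRNA base with a distant same-side position, the star is derived
from the *dominant contiguous run* of partner positions (gaps ≤ 6 nt
tolerated as interior loops) rather than from the raw endpoint partners;
on a clean stem the two rules coincide (asserted in the tests).  Star
support requires the star sequence — allowing 1-nt wobble at either end,
taken from the window context — to occur among the length- and
count-filtered reads of any library.

A cluster is annotated as a novel miRNA only when at least one window
passes hairpin validation *and* the star is read-supported.  This is the
standard structural + star-evidence criterion for plant miRNA annotation,
and it is what keeps the false-annotation rate low: degradation fragments
frequently sit in foldable sequence, but their implied stars are almost
never sequenced.  Accepted precursors on opposite arms of one hairpin are
reported as 5p/3p pairs, flagged `both_abundant` when the minor/major
abundance ratio reaches 0.2.

## Coding-region annotation

A codon-usage model assigns each codon `log(freq / (1/64))` with add-one
smoothing, trained on an in-frame coding set.  Candidate ORFs follow the
longest-ORF-per-stop convention of standard coding scanners: stops
partition each forward frame into segments, and each segment's ORF runs
from its first ATG to its stop (so nested same-stop ATGs do not compete
with the full-length reading frame).  The best-scoring ORF wins, ties to
the longer then the leftmost; transcripts without a 20-codon ORF are
non-coding.  This deliberately simplifies indel-tolerant HMM scanners
(single codon model, no frameshift repair): assembled transcripts are
assumed frame-intact and sense-oriented, with a 6-frame scan behind a
flag.  Cleavage positions are classified as 5′ UTR / CDS / 3′ UTR against
the resulting annotation (CDS bounds inclusive of the stop codon).

## Target prediction

The native scanner is ungapped: at every transcript offset each miRNA
position (5′→3′) is classified against the antiparallel transcript base as
WC, G:U or mismatch, scored 0 / 0.5 / 1.  Bulged duplexes are not scored —
the scoring rule defines no bulge penalty — but externally predicted
(possibly gapped) site lists can be imported and pushed through the
identical scoring and filtering.  Retention discards duplexes with total
score ≥ 4 **or** positions-1–12 score > 2.5; reading the published
criterion's "and" as either-condition-discards matches the cited
Schwab-style rules, and the literal conjunction is available as
`combine="both"`.  G:U contributes 0.5 to the positions-1–12 sum as well —
whether the original "substitution score" excluded wobbles is ambiguous,
and the choice is isolated behind `score_duplex` for sensitivity testing.
The canonical cleavage position faces miRNA position 10 (`site_end − 9`);
the comparison window faces positions 9–11.

## Degradome analysis

Tags map by exact forward-strand substring match; the normalisation
denominator is the total count of mapped tags (unmapped tags are excluded;
recorded in output metadata).  TP1M divides each tag's per-million
abundance by its transcript multiplicity.  The per-T-plot threshold is the
mean TP1M over tag-bearing positions — of the three readings of "mean
counts of the total tags aligned to the transcript" (per tag, per
tag-bearing position, per nucleotide) this is the strictest that is
independent of transcript length; the alternatives are selectable.
Within the predicted 9–11 window the argmax position (ties towards the
canonical position) is called: category 1 when strictly above threshold
and the unique transcript-wide maximum, category 2 when above threshold
only, category 3 when non-zero but at or below threshold.  No call is ever
emitted outside the window.  Strict inequality means a single-position
T-plot can never exceed its own mean — a deliberately conservative edge
case.  The final table collapses miRNAs sharing one site on one transcript
into a single row.

## Synthetic experiments

The generator emulates the study design that motivated the pipeline:

* **Transcriptome** — 50 transcripts of 1200–2000 nt at GC 0.5, each with
  one planted ORF (120–220 codons from a 20-preferred-codon usage table
  balanced to GC 0.5) flanked by UTRs; an in-frame stop is placed directly
  upstream of the start codon, as real 5′ UTRs commonly provide.
* **MIR hairpins** — 10 conserved-like matures (bundled reference
  sequences with ≤ 2 edits) and 10 novel matures (random 21-mers, 5′ U
  with probability 0.8), each embedded in a 3′ UTR as
  mature + loop (8–15 nt) + reverse complement with ≤ 2 edits, arm side
  random.  Construction is validated in place with the pipeline's own
  acceptance rule, and the entire fold window is reserved (one hairpin per
  transcript, no later feature within the window) so that pipeline-time
  folding sees exactly the validated context.  The inferred star must fall
  in the 18–26-nt sequencing window.
* **Libraries** — three in vitro and two field libraries of 100 000 reads.
  Per-miRNA abundance is log-normal (μ = 4, σ = 1.5 on the natural-log
  scale, spanning the 10⁰–10⁵ count range typical of real catalogues);
  within a miRNA, 85% of reads are the canonical sequence and the rest are
  1-nt 5′/3′ variants taken from the hairpin context; star reads are
  generated at 10% of mature; 40% of each library is degradation
  background (uniform transcript fragments of 18–26 nt, so clustering and
  contaminant screening face realistic near-duplicates); field libraries
  replace 5% of depth with fragments of 10 synthetic contaminant
  sequences.  All reads carry the TruSeq small-RNA 3′ adapter.
* **Degradome** — background tag 5′ ends at 0.05 per nucleotide on every
  transcript; for each of the 15 planted perfect-complement target sites,
  spiked tags at the canonical position amounting to a 0.3 fraction of
  that transcript's tags.

All randomness flows from one seeded generator; identical configurations
are byte-identical.  End-to-end recovery (seeds 1–5 at the defaults) is
scored as: a planted miRNA is recovered when its sequence lies in a
family-assigned or novel-annotated cluster; an emitted novel miRNA is
spurious when its mature is neither a planted mature nor a planted star
(star-arm clusters are planted sequences — a real pipeline reports them as
the other arm of the same locus); a planted target is recovered by a
category-1/2 call of its miRNA's cluster at the planted position.

What the simulations do **not** model: sequencing errors beyond adapter
presence, quality-score variation, 24-nt heterochromatic siRNA classes,
multi-locus miRNA families sharing one mature, bulged target sites, and
RNA secondary-structure thermodynamics (the planted hairpins are
near-perfect inverted repeats).  Passing tests therefore demonstrate the
correctness and calibration of the algorithms under clean expression
structure, not performance on raw field data.

## Numerical and problem-size choices

Unit tests run a scaled-down experiment (12 transcripts, three libraries of
3000 reads, 6 miRNAs); the acceptance suite runs the full default
experiment for seeds 1–5, which completes in a few seconds per seed.
Oracle checks pin each core algorithm to an independent brute force at
small sizes: clustering vs pairwise-closure on ≤ 200 reads, overlap
alignment vs exhaustive offsets on ≤ 26-nt pairs, folding vs exhaustive
nested-structure enumeration on ≤ 18-nt sequences, and target scanning vs
an all-offsets scorer on ≤ 300-nt transcripts.  Ties everywhere are broken
deterministically (documented per function); reruns of any stage with
identical inputs and parameters are byte-identical, which the stage
manifests (input/output SHA-256) both record and enforce.

## Known limitations

* The folding engine maximises pair count, not free energy; its scores are
  structural counts and must not be read as stabilities.  MFE-based
  filtering requires the `RNAfold` backend.
* Exact-match tag mapping and exact-substring clustering mean sequencing
  errors fragment clusters and drop degradome tags rather than being
  absorbed; real data benefit from an upstream error-correction step.
* The ORF scanner assumes frame-intact transcripts; frameshifted
  assemblies will be annotated as truncated or non-coding.
* Cross-species homology reports sequence similarity only; it cannot by
  itself distinguish conserved miRNAs from conserved siRNA loci.
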