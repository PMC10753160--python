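# Methods

This note documents the models and procedures implemented in `t2tkit`,
the parameters that matter, what the synthetic-data generator does and
does not emulate, and the numerical choices behind the detectors.

## Scope and coordinate conventions

`t2tkit` covers the finishing and mining steps that surround a gap-free
(telomere-to-telomere) plant genome assembly: telomere identification
and terminal patching, centromere prediction, k-mer consensus quality
(QV), and gene-family mining with SRS6-based classification of
flavonoid B-ring hydroxylases. Assembly itself, scaffolding, polishing,
annotation and tree inference are out of scope; their outputs (FASTA,
GFF3, PAF, BED, domain tables, FPKM matrices) are inputs here.

All in-memory coordinates are 0-based half-open. GFF3 (1-based
inclusive) is converted at the I/O boundary; PAF and BED pass through
natively. "ORF" in the cluster rule means an annotated gene model in
the GFF, not a six-frame scan: the rule is applied to a genome's
annotated gene set, and distances are measured in per-chromosome gene
ranks (dense index of genes sorted by start).

## Telomere scan and terminal patching

Chromosome ends are scanned for the plant telomere motifs, by default
`CCCATTT` at the 5′ end and `TTTAGGG` at the 3′ end. Both are config
fields: note the 5′ default is *not* the reverse complement of the 3′
motif (that would be `CCCTAAA`); the defaults deliberately follow the
convention described for this assembly workflow, and users working with
canonical plant telomeres can override them. Counting is exact,
non-overlapping and strand-specific (`str.count` semantics; a 7-mer
cannot overlap itself).

Parameters:

- `terminal_window` (bp, default 150 000): span scanned at each end,
  clipped to the sequence. Large enough to hold the deepest observed
  arrays (2673 copies × 7 bp ≈ 19 kb) with margin.
- `min_repeats` (default 100): an end is telomeric iff its count
  reaches this. No published threshold exists for the workflow we
  re-implement; the observed accept/reject cases (111 accepted, 2
  rejected) only bracket it, and 100 sits in that bracket.

Patching follows the terminal-read procedure: reads whose alignment
endpoint lies within a screening window (default 50 bp) of a
chromosome terminus are collected per end; the read with the most
motif repeats becomes the reference (ties: longest read, then smallest
id), the rest are queries. Counting for selection happens in *target
orientation* — minus-strand reads are reverse-complemented first,
since the motifs are strand-specific. The reference read's aligned
span replaces the terminal span of the chromosome and its unaligned
overhang (extra telomere the assembly lacks) extends it. Consensus
polishing of reference+queries is an external-tool step in the
original workflow and is not re-implemented; the reference read itself
is the donor. If the donor would not increase the repeat count the
sequence is left untouched (`already_complete`), so patching is
monotone: post-count ≥ pre-count always.

## Centromere prediction

Centromeres are called in fixed tiling windows (default 60 kb) from
four lines of evidence: tandem-repeat coverage, gene count, Gypsy-LTR
coverage, and optionally a Hi-C blank-region mask. A window passes if
`tandem_fraction ≥ 0.3`, `gene_count ≤ 1`, `gypsy_fraction ≥ 0.1`, and
(only when a blank mask is supplied) its midpoint falls in a blank.
Passing windows at gaps ≤ 2 windows merge into candidates scored by
summed tandem coverage; the top candidate per chromosome is selected
unless the runner-up scores within 20% (relative), in which case the
chromosome is flagged ambiguous and no call is made — twin-array
chromosomes are reported as two candidates rather than an arbitrary
pick. Only the 60 kb window granularity follows the original workflow;
every threshold above is this package's default and all are exposed in
config. When the caller passes the detected arrays alongside the
window features, candidate boundaries are refined from window
granularity to the extent of the supporting arrays.

### Tandem-array detector

The detector is a deterministic self-match profile method, not a port
of alignment-based tandem repeat finders (whose wraparound DP scoring
is out of scope). For a candidate period `p`, the profile is the
boolean vector `m[i] = (s[i] == s[i+p])`; inside an array of period
`p` with per-copy divergence `d` the match rate is ≈ `1 − 2d(3/4)`,
against ≈ 0.25 in random sequence.

- **Candidate periods** are seeded from the distance spectrum of
  repeated 12-mers: positions sharing a 12-mer are collected, and
  inter-occurrence distances in `[min_period, max_period]` with
  support ≥ `max(10, min_array_len/20)` become candidates. In a tandem
  array most 12-mers recur exactly one period downstream, so the true
  period always appears; a fixed geometric ladder of periods would not
  be guaranteed to contain a multiple of it. Inputs ≤ 10 kb (or with
  `max_period ≤ 64`) fall back to an exhaustive period scan.
- **Region finding**: the profile is smoothed with a sliding window on
  the scale of `min_array_len`; window positions above `min_purity`
  seed regions. A global purity criterion alone is *not* used for
  extension — a long pure array can drag several hundred kilobases of
  background along before cumulative purity drops below threshold — so
  region edges are sharpened with a small local window
  (`max(16, 2p)` bp) and snapped to matching positions.
- **Reporting**: purity is the fraction of positions `i` in
  `[start, end−p)` with `s[i]==s[i+p]`; `copies = length/p`. Where
  detections at several periods overlap (an array of period `p` also
  matches at `2p`, `3p`, …), the smallest period reaching the purity
  threshold wins; accepted arrays are maximal and non-overlapping.

Defaults: `min_period 20`, `max_period 2000`, `min_array_len 10 000`,
`min_purity 0.7` — sized for centromere-scale arrays of 100–200 bp
monomers at a few percent divergence.

## Consensus QV

QV uses the standard k-mer spectrum estimator: with `Y` assembly k-mer
positions (canonical k-mers, k = 21 by default, windows containing N
excluded) and `X` of them unsupported by the read k-mer set, the
per-base error rate is

    E = 1 − (1 − X/Y)^(1/k),   QV = −10·log10(E)

with `X = 0` reported as a cap (99.0). Read k-mers below
`read_kmer_min_count` (default 2) are treated as absent, which filters
k-mers that only exist because of sequencing errors in the reads; with
error-free reads at low coverage the caller should set it to 1.
Each substitution in unique sequence creates up to k unsupported
k-mers, so the estimator inverts a planted substitution rate to within
a few hundredths of a phred unit on megabase genomes; nearby errors
and repeats (where a corrupted k-mer may still exist elsewhere) bias
QV slightly upward, which is why the parameter-recovery tests allow
±1 phred.

## Gene-family mining

The profile-HMM search is consumed, not implemented: hits arrive as a
domain-table TSV (configurable column indices). The module owns:

- **Length filter**: keep candidates with 400 ≤ length ≤ 600 aa,
  boundaries inclusive (the filter removes `<400` and `>600`, so the
  boundary lengths survive). Dropped ids are reported with reasons.
- **Cluster rule**: two family genes are linked iff they are on the
  same chromosome within 8 gene ranks; clusters are connected
  components (chains link transitively), singletons are not reported,
  and adjacent-rank pairs are flagged as tandem duplicates. On sorted
  ranks the components reduce to splitting at gaps > 8, which is what
  the implementation does; the test suite checks it against an
  explicit all-pairs + connected-components oracle. Whether "within a
  distance of eight ORFs" means rank difference ≤ 8 (implemented) or
  ≤ 8 intervening genes is ambiguous in the source; the gap is
  configurable (`max_gap`).
- **Identity**: global alignment with affine gaps (BLOSUM62, open −10,
  extend −0.5, via Biopython's pairwise aligner); percent identity is
  identical columns over *all* alignment columns, gaps included in the
  denominator, to 2 decimals. The alignment method behind published
  identity values for such families is rarely stated, so comparisons
  carry method tolerance.
- **SRS6 classification**: the substrate recognition site 6 window is
  defined on a user-supplied anchor protein (coordinates in config;
  published alignments give the window but not absolute coordinates,
  so the anchor travels with the analysis). Each candidate is globally
  aligned to the anchor and the anchor's SRS6 columns are projected
  onto it; the residue in the column of SRS6 position 8 decides:
  Thr/Ser → F3′H-like (CYP75B pattern), Ala → F3′5′H-like (CYP75A
  pattern), anything else (including a gap) → unclassified.
- **Expression**: heatmap values are log10(FPKM + 1); fold ratios
  between genes are computed on raw per-tissue means (not logged),
  to 2 decimals.

## Synthetic data and what passing tests mean

The generator plants every feature the detectors look for and writes a
truth manifest that fully determines expected outputs on error-free
input. Telomere arrays are placed exactly at sequence termini at
configured copy numbers (the canned nine-chromosome configuration
spans 111–2673 copies across 17 ends with one 2-copy end); centromeric
arrays are tiled from a random monomer (default 171 bp) with per-base
divergence (default 2%); genes avoid centromeres (mean spacing 20 kb,
mean length 4004 bp); Gypsy intervals cover ~30% of centromeres vs
~5% of background; terminal reads span a terminus and overhang it
with extra telomere repeats (per-read overhangs spread over
[0, extension] so the deepest read is always present); family members
derive from a shared anchor with an exact number of substitutions, so
pairwise identities are exact by construction; assembly corruption is
per-base Bernoulli substitution with the exact count returned.

Two deliberate departures from pure i.i.d. background: chance
occurrences of the two telomere motifs outside planted arrays are
removed (one base re-drawn per occurrence) — an unscrubbed 150 kb
window would contain ~9 random 7-mer hits, making exact
manifest-vs-scan comparisons impossible — and centromere monomers are
drawn so that their tandem junctions cannot form the motifs. The
corresponding limitation: real terminal windows do contain chance
motif hits and degenerate interstitial repeats, so on real data the
counts are upper-bounded estimates near the threshold; passing the
synthetic tests demonstrates correctness of the procedures, not
robustness to telomere-like noise. Similarly the generator has no
read-error profile beyond uniform substitutions, no heterozygosity,
and no retroelement sequence structure (Gypsy intervals are
annotations only) — detector performance on real repeat landscapes
(nested arrays, higher-order repeats, segmental duplications) is not
established by these tests.

## Problem sizes and determinism

All randomness flows from single seeded NumPy generators; identical
(config, seed) pairs give byte-identical artifacts, and the end-to-end
report is deterministic under a fixed seed. The packaged study-scale
runs use nine 1 Mb chromosomes for telomere recovery, four 5 Mb
chromosomes with 0.4–0.8 Mb arrays for centromere recovery (one
chromosome carries twin equal arrays to exercise the ambiguity rule),
a 2 Mb genome for QV recovery, and a 260-gene layout with 49 planted
clusters (156 clustered genes) for the cluster rule — chosen as the
smallest sizes at which each detector's behaviour is
indistinguishable from larger runs.

## Known limitations

- The patch donor is a single read; without a consensus step, read
  errors propagate into the patched terminus (the monotonicity guard
  only protects the repeat count, not base accuracy).
- The tandem detector reports one period per region; nested or
  higher-order repeat structure collapses to the smallest qualifying
  period.
- Window-level centromere evidence assumes annotation quality; a
  gene-dense mis-annotation inside a true centromere suppresses the
  call.
- The QV estimator shares the known biases of k-mer QV: repeats mask
  errors (QV biased up), and read k-mer filtering at low coverage can
  create false missing k-mers (QV biased down).
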