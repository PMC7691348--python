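# Methods

This note documents the models, algorithms and numerical choices behind
`umilink`, the assumptions they rest on, and what the simulation-based
validation does and does not show.

## The measurement model

A directed-evolution library is a pool of gene variants differing from a
parental reference in a few point mutations (error-prone PCR introduces a
Poisson-distributed number of substitutions per gene).  Each template
molecule is tagged with a unique molecular identifier (UMI) — a fully
random oligonucleotide — and a round-specific barcode, and sequenced as a
long read covering the whole construct.  Long reads carry 5–15% per-base
errors; the UMI provides the only reliable link between a read and its
molecule of origin.  All inference in this package is base-space: the raw
signal is never used, and consensus accuracy comes entirely from majority
agreement across the reads of one UMI cluster.

## Simulator

`umilink.simulate` generates the full data-generating process with ground
truth attached to every object:

* **Library** — per template, mutation count ~ Poisson(`mean_mutations`,
  default 3.5 per gene), positions uniform without replacement,
  substitutions uniform over the three alternatives (an optional weight
  table can encode transition/transversion bias; it is off by default
  because only the aggregate rate is specified for the mutagenesis
  protocol this emulates).  UMIs are uniform random of length
  `umi_length` (default 50) and regenerated on collision, so they are
  pairwise distinct within a library.
* **Construct layout** — fixed as `[barcode][gene][probe][UMI]` with a
  constant 20-nt probe adjacent to the UMI.  The layout is configurable;
  nothing downstream depends on it except UMI extraction, which is
  anchored on the probe.
* **Reads** — per base, independently: deletion with `del_rate`,
  substitution with `sub_rate`, and a single-base insertion after the base
  with `ins_rate` (defaults 0.06/0.02/0.02, i.e. 90% accuracy; the
  combined rate is capped at 0.2).  Strand is uniform; reverse-strand
  reads are reverse-complemented.  Errors are i.i.d. — there is no
  homopolymer-length dependence, no quality-score structure, and no
  chimera formation.  Real nanopore errors are *not* i.i.d.; the workflow
  element that addresses systematic (strand-consistent) errors is the
  per-strand support filter, which is retained and tested with injected
  strand-asymmetric artifacts.  Consequently, passing accuracy figures on
  simulated data demonstrate the correctness and statistical behaviour of
  the pipeline under its stated error regime, not the accuracy achievable
  on any particular real flow cell.

One caveat measured during development: because the simulator draws error
*events* while accuracy is *measured* as minimal edit distance, adjacent
events occasionally cancel, so the realized per-base edit rate sits ~3–4%
(relative) below the nominal rate at the 10% operating point.  Tests
account for this with an explicit band rather than pretending the two
quantities coincide.

### Clustering-efficiency grid

`simulate_clustering_efficiency` reproduces the UMI-design question: for a
grid of UMI lengths, error rates and library sizes, erroneous copies of
random UMIs are clustered and scored as *recollection* (fraction of
templates recovered as the majority label of some cluster) and
*homogeneity* (mean within-cluster majority fraction).  Each grid point
sets its threshold from ground truth — the midpoint between the mean
same-template and mean cross-template alignment scores — because the
plateau estimator (below) refuses, by design, to return a threshold for
very short UMIs where no stable regime exists, and the grid must cover
exactly those degenerate corners.  At 50-bp UMIs, recollection is 1.0
across error rates 0.05–0.15 at library size 1000, while 5-bp UMIs (a
1024-sequence space) collapse under birthday collisions — the rationale
for 50-bp tags.

## UMI extraction and clustering

* **Scoring** — Smith–Waterman local alignment with affine gaps (Gotoh),
  numba-compiled.  Defaults: match +1, mismatch −1, gap of length k costs
  −1·k (open −1, extend −1).  With unit scores the threshold is
  interpretable in base units: two error-free copies of a 50-bp UMI score
  50, two random 50-mers typically 8–14.
* **Extraction** — the probe is aligned locally against the read and its
  reverse complement; the better strand orients the read and the UMI is
  the L bases after the probe's end.  Extraction fails below an anchor
  score of 0.7 × match × probe-length, or when fewer than L − 5 bases
  remain.  At 10% read error ~8–9% of reads fail extraction (mostly ≥4
  errors inside the 20-nt probe); a fraction of a percent anchor on a
  spurious probe-like match inside the gene, producing junk UMIs that end
  up as sub-threshold singleton clusters and are dropped by the
  minimum-cluster-size rule.
* **Greedy clustering** — one pass over extractions in input order: the
  next unassigned read seeds a cluster and absorbs every unassigned read
  whose UMI scores ≥ threshold against the seed; a second pass then
  reassigns each read to its best-scoring seed.  The second pass exists
  because first-hit assignment occasionally captures reads of a template
  whose own seed appears later in the input; the repair keeps the O(k·n)
  complexity (k clusters, n reads) and determinism.  The output is a
  partition of the extracted reads.  Downstream, clusters below
  `min_reads` (default 15) are not called — support fractions from a
  handful of reads are unreliable — and at most `max_reads` (default 100)
  reads per cluster enter the consensus, since support saturates far
  below that.
* **Threshold estimation** — a subsample (default 500 UMIs) is clustered
  at every candidate threshold.  Cluster counts show three regimes: one
  merged cluster (threshold too low), a stable count near the true
  template number, and all-singletons (too high).  The two saturated
  regimes are trivially stable and are excluded (count = 1 or > 0.9 ×
  sample); within the remaining region the widest plateau (longest run of
  consecutive thresholds with < 5% relative change) is located and the
  midpoint of its longest strictly-constant stretch returned.  If no
  plateau of ≥ 3 thresholds exists the estimator raises "no stable
  threshold" — the honest answer for UMIs too short for the error rate.
  Diagnostics (same-template vs random-pair score distributions) are
  returned alongside.

## Consensus variant calling

Reads are aligned to the reference with edlib in infix mode (the whole
reference must align; read overhangs over barcode/probe/UMI are free), the
better of the two orientations wins, and the edit path is re-scored with
the configured match/mismatch/gap values; alignments scoring below 0.3 ×
match × reference-length are excluded from the pileup.

Calling is two-stage, a deliberate deviation from naive majority voting
over per-read edit operations:

1. **Consensus sequence.**  Per reference column, the majority allele over
   {reference base, observed substitutions, gap} is taken (ties keep the
   reference); insertions are included where a majority of reads carries
   an identical left-aligned inserted sequence.  The resulting consensus
   is diffed once against the reference with a global affine alignment
   whose scores (match +2, mismatch −1, gap open −3, extend −2) make one
   substitution strictly preferable to the equivalent
   deletion-plus-insertion.  This matters in two recurring situations
   where per-read edit paths are ambiguous: adjacent substitution pairs
   (AG→GA is one deletion plus one insertion at equal edit distance) and
   substitutions that extend a homopolymer (where any read that also
   carries a deletion error in the run flips to a representation deleting
   the mutated base).  Voting on operation identity splits the carriers of
   such mutations across representations and silently deflates their
   support below the pass threshold; diffing a single consensus hypothesis
   does not.
2. **Support.**  Each candidate's support fraction is measured per read in
   a ±10-base window: a read supports the candidate iff its bases over
   the window are strictly closer (edit distance) to the mutated reference
   than to the reference.  Support is reported overall and per strand.

Filters preserve the workflow's published semantics exactly: a call passes
with support *strictly greater than* 0.6; when both strands contribute ≥ 5
reads, each strand must individually support the call with ≥ 0.3
(depleting errors systematic to one read direction); and a variant with
more than 16 passed mutations is discarded wholesale.  Sub-majority pileup
events with ≥ 0.2 naive support are reported (not passed) so mixed
clusters remain visible in the support histogram; they are not
auto-removed.

Accuracy evaluation against simulator truth reports the per-base error of
the implied consensus (edit distance to the true template gene over total
template bases), the false-negative rate (planted mutations missing from
passed calls) and false-positive rate (spurious passed calls per planted
mutation).  At the standard operating point — 1250-bp gene, mean 3.5
mutations, 10% read error — the pipeline reaches per-base accuracy
> 99.99% at 50× and per-base error below 0.001% at 35×, with > 99% of
planted mutations recovered (see `scripts/acceptance.py`).

## Evolution analysis

* **Demultiplexing** — per cluster, each round barcode is aligned locally
  against the barcode-proximal window of up to 10 member reads (oriented
  using the strand from UMI extraction); the barcode with the highest
  median score wins if its margin over the runner-up is ≥ 4 score units,
  otherwise the cluster stays unassigned.  Median-over-reads makes the
  call robust to individual bad reads.
* **Deduplication** — variants are identical iff their nucleotide
  mutation sets are identical; per-round counts aggregate over clusters;
  the wild type is the empty set.  Variants whose calls include a
  frameshifting indel inside the CDS are kept but flagged untranslatable
  (they carry no amino-acid set and are excluded from network, founder
  and enrichment analyses rather than silently dropped).
* **Similarity network** — nodes are variants; edges connect pairs whose
  amino-acid mutation sets differ in ≤ `d_max` elements (symmetric
  difference; a metric).  Default `d_max` = 2: one acquisition step plus
  one spurious difference.  Lineage structure is read from connected
  components — reproducible, parameter-light — while the optional t-SNE
  layout (fixed seed 7, perplexity 30 clipped below the node count) is
  for display only and never feeds any downstream statistic.
* **Founder variants** — the core of a component is the intersection of
  its members' mutation sets; sub-lineages are reported by recursing on
  members that share an acquisition beyond the core (recursion capped at
  depth 10).
* **Positional enrichment** — restricted to variants persisting into the
  final round; per residue, the count-weighted mutation frequency in each
  round; the factor is (f_to + ε)/(f_from + ε).  The pseudocount ε keeps
  factors finite for residues absent from one round; it defaults to
  1/(total qualifying count over both rounds) and is exposed as a
  parameter because any fixed ε makes the factors exactly invariant under
  uniform rescaling of counts (frequencies are fractions), whereas the
  adaptive default is only asymptotically so.
* **Epistasis** — from relative activities (parent = 1): the focal
  mutation's effect alone, e₁ = act({m})/act(parent), versus its effect in
  a background, e₂ = act(B∪{m})/act(B).  *Sign* epistasis requires e₁−1
  and e₂−1 on opposite sides of zero with both 95% CIs excluding 1
  (Gaussian propagation of the reported ± half-widths; a sign call without
  CI support would over-claim).  *Magnitude* epistasis: same side, but the
  effects differ by more than 1.5-fold.  For mutation pairs (|B| = 1) the
  sign test is applied in both orientations — sign epistasis of a pair
  means the interaction flips the sign of at least one member's effect —
  which makes the classification symmetric under relabelling; the
  focal/background rule alone is not.

## Problem sizes and determinism

The validation suite runs the complete pipeline at 100 templates × 50
reads and 180 templates × 35 reads on a 1250-bp gene, and calibrates the
generator at 100,000 library members — sizes at which every statistical
claim the package makes is already well-resolved (e.g. the 3-standard-
error band on the mean mutation load is ±0.018 at n = 10⁵).  All
randomness flows through seeded numpy generators: identical seeds give
bit-identical libraries, reads and pipeline outputs, and the test suite
asserts byte-identical reruns of the whole pipeline.

## Known limitations

* i.i.d. error model: no homopolymer or k-mer context effects, no
  quality scores (qualities are parsed and ignored — calling is support-
  fraction based by design), no chimeras or PCR bias.
* The consensus caller assumes reads cover the full reference (amplicon
  sequencing); it is not a general-purpose variant caller for fragmented
  or genomic data.
* Demultiplexing assumes barcodes with healthy pairwise distance (the
  simulator enforces ≥ 10 differences); near-identical barcodes would
  need a stricter margin.
* Mixed clusters (two templates under one threshold) are surfaced via
  sub-majority support candidates but not automatically split.
* Untranslatable (frameshifted) consensus variants are flagged and
  excluded from protein-level analyses; their nucleotide-level records
  remain in the variant table.
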