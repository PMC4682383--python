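# Methods

## The problem

A single 16S rRNA amplicon read (~400 bp) covers only a fraction of the
~1.5 kb gene, which limits taxonomic resolution to genus level at best.
`stitch16s` implements a multi-primer strategy: six primer pairs (A–F,
named by their positions on the canonical 16S coordinate system —
8F-534R, 343F-798R, 517F-926R, 784F-1114R, 917F-1407R, 1099F-1541R) tile
the gene with overlapping amplicons.  Pooled reads are classified to
genera, and each genus's reads are assembled into a long, ideally
near-full-length, 16S sequence that supports species-level assignment.
Using several primers also hedges against primer bias: a taxon missed by
one primer is usually captured by another.

## Pipeline stages and their assumptions

1. **Demultiplex and trim** (`preprocess`).  Each read's 5' prefix is
   compared against all twelve primer sequences (IUPAC-aware Hamming
   distance, at most 2 mismatches; ties resolved by fewest mismatches,
   then panel order).  Reads matching a reverse primer are
   reverse-complemented so that assembly sees a single strand.
   Demultiplexing precedes trimming because trimming removes the primer
   bases: 25 bp are cut from both read ends and reads shorter than 200 bp
   after trimming are dropped.  The length filter applies to the
   *post-trim* length.

2. **Classification** (`classify`).  A word-based naive-Bayes classifier
   (8-mers) with the standard prior-smoothed estimator:
   `P(w) = (n(w)+0.5)/(N+1)` over all N training sequences and
   `P(w|G) = (m(w)+P(w))/(M+1)` within a genus of M sequences.  A read is
   assigned to the genus maximising the joint log likelihood of its
   distinct words; the confidence score is the percentage of 100
   bootstrap trials (each resampling ceil(W/8) of the read's W words with
   replacement) that agree.  Reads with score >= 80 are confident; genera
   with >= 10 confident reads are confident genera and proceed to
   assembly.  Exact numeric parity with any particular external
   classifier release is not attempted; the estimator above is the
   published standard.

3. **Per-genus assembly** (`assemble`).  Greedy overlap-consensus:
   contigs merge highest-identity-first while the best overlap is
   >= 100 bp at >= 98% identity (identity = matches / alignment columns,
   gap columns included; homopolymer-length disagreements are ordinary
   gap columns).  Overlap candidates come from shared 16-mer seeding with
   diagonal voting (at least 4 seed votes before alignment); the implied
   overlap is evaluated with edit-distance alignment (edlib).  When two
   contigs disagree over a merge the consensus of the contig with more
   member reads wins; after merging stops, every consensus is *polished*
   to the per-column pileup majority (all member reads re-aligned), which
   removes individual read errors that survived pairwise merging.
   Singleton reads remain singleton contigs.  The per-column A/C/G/T/gap
   counts produced by the final pileup drive all downstream rules.

   **Contig graph.**  Overlaps that are real but too short to merge are
   kept as directed edges: u -> v when u's suffix overlaps v's prefix by
   >= 40 bp at >= 95% identity.  40 bp is the span neighbouring amplicons
   need to support each other in this panel design; the edge identity is
   deliberately laxer than the merge identity because contig ends carry
   alignment-placement artifacts that a 90-odd-bp junction window would
   otherwise veto.  Edges store both the alignment-column overlap and the
   number of destination-prefix bases consumed, so concatenation splices
   exactly once even across indels.

4. **Post-processing** (`postprocess`).  Two repairs:
   *Bubble resolution* — branch contigs (two contigs sharing a
   predecessor and a successor) with mean pileup depth < 10 are
   discarded; each surviving source-to-sink path through the graph is
   emitted as one concatenated contig, copying shared segments per path;
   plain chains concatenate directly.  Concatenated chains are
   re-polished so junction columns settle on the majority of all
   contributing reads.  Multi-bubble components enumerate all path
   combinations (capped at 16 paths); a cyclic graph is an error.
   *Variant splitting* — columns whose second-most-frequent base has
   >= 10 supporting reads are flagged; base patterns over the flagged
   columns observed in single spanning reads are tallied; patterns with
   >= 10 supporting reads survive, and the contig is duplicated once per
   surviving pattern.  If no read spans all flagged columns the
   per-column majority is kept with a warning.

5. **Species assignment** (`identify`).  The longest contig of each genus
   is aligned locally (Smith–Waterman–Gotoh, match +2, mismatch −3, gap
   open 5, extend 2, first gap base costing 7) against every reference.
   The hit with the highest score — ties broken by higher identity, then
   subject id — assigns its species when identity >= 97% and the e-value
   is <= 0.01.  E-values use the Karlin–Altschul length-scaled form with
   lambda solved numerically from the scoring scheme at uniform base
   composition and K fixed at the conventional 0.41; the e-value is a
   coarse filter, the identity threshold is the contract.  The full DP is
   run for every subject (no heuristic seeding): reference sets here are
   small enough that exactness is worth more than speed.  Traceback
   tie-break: diagonal, then gap-in-subject, then gap-in-query.

6. **In-silico panel evaluation** (`insilico`).  ePCR: a pair amplifies a
   reference when the forward primer and the reverse primer's reverse
   complement match the plus strand with at most 2 mismatches each (no
   indels; IUPAC degeneracy never counts as a mismatch) and the product
   length is within the pair's insert range (450–550 bp for A and E,
   350–500 for B and F, 350–450 for C, 250–350 for D).  The vectorised
   scan is cross-checked against a naive positional rescan in the tests.
   Reference spans are located by infix alignment to a single canonical
   anchor sequence (a desk-scale substitute for a full multiple
   alignment; references above 35% anchor divergence are excluded and
   counted).  Sensitivity per primer = amplifiable / covering both
   binding sites.  Amplified segments of one reference are
   interval-merged when they overlap by >= 10 bp; the long-assembly
   fraction counts references whose merged run reaches 1000 bp, over
   references covering four consecutive primers' sites.  The
   panel-vs-single comparison restricts to references covering the
   27F/1492R sites and reports the percentage missed by all six pairs
   versus by the single near-full-length pair.

7. **Metrics** (`metrics`).  Primer bias: percentage of confident genera
   with no confident read from a given primer (integer percent).
   Composition profiles: per-sample percentages of confidently classified
   reads at a rank, top 15 taxa by cross-sample mean, remainder lumped as
   "others", headroom to 100% being the non-confident share.  The summary
   table reports, per sample: raw, trimmed and confident reads, total and
   confident genera, number of genera with an assembled (>= 2 reads)
   contig, genera whose longest contig reaches 1.5x and 2x the mean
   trimmed read length (lcl/mrl), and genera with a >= 97%-identity
   species call.  Text percentages round half-away-from-zero to one
   decimal; bias percentages to whole percent.

## The synthetic data generator

`simulate` makes the whole system testable without external data.

* **References.**  A fixed 1542 bp anchor carries conserved blocks seeded
  with universal-primer motifs at their nominal coordinates; the twelve
  default panel primers are read off the anchor (so panel, anchor and
  generator agree on coordinates; selected primers carry IUPAC degeneracy
  as real universal primers do).  Genera diverge from the anchor at 12%
  substitution plus 0.4% indels in the variable regions only; species
  within a genus add 1% further substitutions.  Site coordinates are
  tracked through the indels, so the simulator extracts amplicons from
  known coordinates and never calls the ePCR module it is used to
  validate.  Options: truncation of a fraction of references to partial
  spans (reference repositories are dominated by partials; used at 0.3
  for the survey database), and per-pair site-disruption rates (1–4
  substitutions in one binding site; at >= 3 amplification fails) that
  emulate the unequal universality of real panels.  The community
  database applies no disruption: test-community templates are
  amplifiable by the whole panel, which is the regime the pipeline's
  recovery claims address.

* **Reads.**  Each read draws a taxon by abundance and a primer by the
  taxon's efficiency row, sequences ~N(400, 30) bp (minimum 150) from a
  uniformly chosen amplicon end with the primer bases attached, then
  applies substitutions at 0.2%/base and homopolymer indels at 0.4% per
  run of length >= 2 — the characteristic pyrosequencing error mode.
  Qualities follow a cosmetic position-decay model; the pipeline never
  reads them.  Default efficiencies are deliberately non-uniform: one
  taxon follows the strongly skewed single-template pattern (38.3% of its
  reads from primer C, 3.1% from primer B), one drops primers E and F
  entirely (its reconstruction therefore stops around 1.1 kb), the rest
  draw from a Dirichlet(5) row.

* **What passing tests do not show.**  The generator has no chimeras, no
  flow-space error structure, no quality-dependent error rates, no
  contamination, and genus divergence is uniform rather than
  phylogenetically structured.  Recovery results on this generator bound
  the pipeline's behaviour under idealised library structure, not under
  real environmental communities.

## Problem sizes

The test suite and the acceptance script run a four-taxon community at
500 reads per taxon (2000 reads), an 8-genus x 3-species community
database, and a 40-genus x 3-species survey database (30% partial spans,
survey disruption rates) for the in-silico evaluation; cross-oracle
checks use 1000 random 60-mer alignment pairs, 1000 random interval sets
and 200 ePCR fixtures.  These sizes were chosen so the whole study runs
on a laptop in minutes while every rule's boundary (80/10/100/98%/10/10)
is exercised at realistic depth.

## Numerical and degenerate-input choices

* Greedy merge order: identity descending, then overlap length, then
  insertion order; all candidate ordering is independent of Python's
  per-process string hashing, so runs are reproducible across processes.
* Consensus ties (equal base counts) resolve by base order A<C<G<T and
  the column is flagged as ambiguous.
* A read shorter than the word size classifies as "unclassified", score
  0.  An empty read file aborts at the preprocess stage with a named
  error.  Zero confident genera make primer bias undefined (error).
* The single seeded generator per run is recorded in `run.json`; reruns
  with the same inputs and seed are byte-identical.

## Known limitations

* The assembler is a desk-scale greedy layout, not a flow-space
  assembler; branch emission relies on junction overlaps falling below
  the merge length, so variant structure with long shared flanks inside
  single amplicons can collapse into one contig (the variant-splitting
  step then recovers point differences only).
* The anchor-span method under-serves references more than ~35% diverged
  from the anchor; such references are excluded from sensitivity
  denominators and counted.
* E-values are order-of-magnitude estimates (fixed K, uniform base
  composition), adequate only as a filter at 0.01.
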