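# Methods

## Problem and model

`utriso` annotates and quantifies 3′UTR isoforms produced by alternative
polyadenylation (APA) for members of a clustered gene family — the motivating
case being mouse odorant-receptor (*Olfr*) genes, which sit in dense genomic
clusters and are lowly expressed in bulk olfactory-mucosa RNA-Seq because each
sensory neuron transcribes a single family member. Generic assemblers tend to
fragment or fuse the 3′ ends of such genes, so the package works directly on
per-base read coverage downstream of each stop codon.

The generative picture is nested isoforms: a gene with 3′ ends
`e₁ < e₂ < … < eₙ` (nt after the stop codon) and abundances `RA₁ … RAₙ`
produces expected coverage at UTR position `p` proportional to
`Σ_{i: eᵢ ≥ p} RAᵢ` — a non-increasing staircase. Detection finds the steps;
quantification inverts the staircase.

## Coordinates and currency

* All internal coordinates are 0-based half-open; GTF (1-based inclusive) and
  BED (0-based half-open) are converted at I/O boundaries.
* The stop anchor is the mRNA-orientation 3′ boundary of the stop codon;
  `utr_pos` 1 is the first transcribed base after it. Minus-strand genes are
  handled by reflecting coverage and reverse-complementing sequence into
  mRNA-sense before any analysis.
* One quantitative currency is used throughout: per-base depth sums
  ("counts"). Expression is depth summed over the CDS envelope; "counts/kb"
  is that sum per kb of CDS. A gene is *expressed* at ≥ 1 count and flagged
  `precision_ok` at ≥ 200 counts/kb (boundary inclusive; "at least" rather
  than "exceeds" was chosen and is documented here because the two readings
  differ only at the exact boundary).

## Gene models and mask

The CDS envelope of a gene is the union over all isoforms of CDS and
stop-codon features (maximal start-to-stop extent). Genes without CDS
features (most pseudogenes) are skipped with a log entry. Transcripts whose
stop anchors disagree must be resolved through the curation file
(`drop_transcript`/`drop_gene`); otherwise parsing fails listing the gene ids,
because a single anchor per gene is a hard invariant of everything downstream.
The curation file also supports `force_region_span` and `set_alt_locus`
(splitting a gene annotated at two distant loci into independent loci, default
gap 100 kb; each locus then receives independent 3′UTR calls).

Mask regions span from the proximal end of the closest upstream non-target
CDS to the proximal end of the closest downstream non-target CDS; a terminal
cluster with no flanking gene gets an arbitrary 25-kb margin. Gene density is
member CDS count per Mb of the flanking-to-flanking span.

## End detection

Coverage is projected into UTR coordinates and bounded by the earliest of the
20-kb scan cap, the mask boundary, and the nearest neighboring CDS edge.
Zero-coverage runs up to `merge_radius` (default 200 nt) are bridged — UTRs
are repeat-rich and drop out of unique alignment — while longer runs end the
scan.

Change points are found by recursive binary segmentation under a
piecewise-constant Poisson model. The candidate split in a segment is the
position minimizing the total Poisson negative log-likelihood (ties broken
toward the most downstream position, which favors longer proximal segments and
is deterministic). A split is accepted only when:

1. both children are at least `min_segment_len` = 100 nt (claims below the
   100-nt precision window would not be meaningful);
2. the downstream mean is *below* the upstream mean (3′ ends only);
3. downstream/upstream mean ratio ≤ `min_fold` (default 0.8; larger values
   admit shallower steps and therefore more isoforms);
4. the log-likelihood gain of the split exceeds a BIC-style penalty
   `split_penalty_factor × ln(L)` (default factor 2.0, `L` = scanned length).

Condition 4 is this package's own model-selection guard: the best split in a
segment is the maximum over hundreds of candidate positions, so without a
penalty the best-of-many noise fluctuation regularly passes the ratio test at
realistic depths and fabricates isoforms. A likelihood-gain threshold is the
standard remedy in binary segmentation; factor 2.0 keeps genuine steps of
ratio ≤ 0.8 at depths ≥ ~1 count/base while rejecting noise splits by a wide
margin. Setting `split_penalty_factor=0` restores the bare rule set.

The extinction end (last covered base) is always reported; `max_isoform`
(default 20) caps the number of segments. Detected ends inside the CDS cannot
occur by construction; ends < 100 nt after the stop are kept but flagged
`very_short`, and that flag propagates through the catalog and comparison
outputs because quantification of such short proximal segments is unreliable.

Zero-depth bases inside retained gaps count as zeros in segment means (no
imputation).

## PolyA sites and the isoform catalog

Ends of one gene closer than 100 nt merge by single linkage into one polyA
site; the merge is transitive, so a chained cluster may span ≥ 100 nt overall
(an exposed property, not a bug). "Less than" is strict: ends exactly 100 nt
apart stay separate. The site's representative length is its distal-most
member (the published pilot-gene table reports spans; downstream code needs
one length; distal-most is conservative for segment boundaries).

Isoform spans that overlap another gene are discarded as presumed fusion
transcripts: any overlap with a target-family neighbor's CDS (either strand),
or with a non-target CDS on the same strand — on *either* strand when coverage
is unstranded, since superposed antisense coverage is indistinguishable (the
tail-to-tail neighbor situation).

Ranked categories are a pure function of (rank, n): `sUTR` when n = 1,
otherwise `pUTR` for rank 1 and `dUTRk` for rank k+1, numbered by increasing
length. Genes with more than 5 isoforms remain in the catalog but are excluded
from summary statistics.

## PAS scanning

Sequences are processed in the DNA alphabet (AATAAA/ATTAAA for the canonical
RNA signals AAUAAA/AUUAAA), mRNA-sense. All overlapping exact matches are
reported. A canonical hexamer validates a site when its start is within
[−100, +100] nt (inclusive) of *any* member end of the merged site — the most
permissive reading consistent with the pilot-gene table, where signals match
either member of a merged pair. Variant hexamers are searched only upstream
([−100, 0]) and only for sites with no canonical match. The 16-variant list is
a configurable default (the common non-canonical mammalian signals); replace
it via `--variants` or the `variant_hexamers` argument.

## Quantification and profiles

Segment i runs between adjacent ends (segment 1 starts at the stop codon);
its mean depth is the cumulative-count difference over its length. Relative
abundances follow the subtraction formula `RAᵢ = (dᵢ − dᵢ₊₁)/d₁`,
`RAₙ = dₙ/d₁`. On noiseless nested coverage this is an exact inverse of the
generative staircase (the module's core identity test). Noise can invert
adjacent means; negative raw values are clamped to 0 and the vector
renormalized to sum 1 — raw values are preserved in the output so the clamp is
auditable. Whether the denominator is the mean depth or the raw summed counts
of segment 1 does not matter: the normalized vector is identical.

Profiles: P1 (single isoform), P2 (proximal > 80%), P3 (proximal ≤ 80% and
distal ranks ≥ 2 summing < 10%), P4 (otherwise). Boundaries are strict on
both thresholds. The thresholds are adopted as constants; the clustering
analysis that originally motivated them is not re-run.

## Cross-dataset comparison

Same-rank isoforms (positional alignment: rank 1 with rank 1, …) are
*conserved* between two datasets when lengths differ by < 200 nt (strict; an
absent annotation is never conserved). With 2 sexes × 2 series, per-rank
flags are: ROBUST (conserved in all pairwise comparisons), SEX-SPE (conserved
within each sex across series, not conserved between sexes within either
series) and EXP-SPE (the converse). The two specific flags are mutually
exclusive by construction (proved by truth-table enumeration in the tests).
A `convention="swapped"` switch exchanges the two labels, since published
wordings of these definitions disagree between main text and supplement; the
main-text reading is the default.

## 3′UTR introns

Junction records (12-column BED with block-encoded anchors, or 6-column TSV)
are filtered to depth > 1 (strict) with best-scoring deduplication. A junction
strictly inside an isoform's genomic UTR span is classified by
intron-retention coverage: mean interior depth ≤ `retention_threshold`
(default 1.0) ⇒ *obligatory* excision, above ⇒ *optional* (spliced and
unspliced forms coexist). The obligatory/optional rule is an operational
definition of this package — the distinction is real in the data but no
published rule exists — and the threshold is exposed.

## Synthetic data

The generator emulates the features the pipeline must survive: clustered
genes on both strands flanked by non-target genes, nested isoform structures
with stepwise coverage drops, planted canonical PAS hexamers near each true
end over a background scrubbed of canonical hexamers within ±110 nt of ends
(rejection sampling), per-base Poisson noise, optional exponential 3′
positional decay (`bias_per_kb`, default off), zero-coverage dropout
intervals, and planted 3′UTR introns with a retention fraction. All outputs
(FASTA, GTF, bedGraph, junction TSV, truth JSON) are byte-deterministic given
the seed.

Chosen defaults, fixed once:

* CDS length 939 nt — a typical single-exon odorant-receptor CDS.
* Stock-bundle depth 2000 counts/kb (2 counts/base). Published depth
  thresholds in *fragment* units (200 reads/kb at 75-nt reads) correspond to
  ~15× base coverage, so 2 counts/base is a conservative "well-expressed
  receptor" level.
* The precision experiment instead uses exactly 200 counts/kb, 500 genes,
  single ends with UTR lengths uniform in 500–3000 nt — the stated conditions
  for the 90%-recovery-within-100-nt operating point. At that depth the
  extinction end is essentially always within a few nt of the truth
  (the chance of 100 consecutive uncovered terminal bases is e⁻²⁰), so the
  measured rate sits near 100%, comfortably above the 90% bound.

What the generator does **not** model: fragment-level read placement (noise is
per-base, the granularity the pipeline consumes), library-preparation
strandedness artifacts, alignment multi-mapping, and sequence-dependent
coverage bias. Passing closure tests therefore demonstrate correctness of the
inference given the nested-staircase model, not robustness to every artifact
of real libraries.

## Numerical and degenerate-input choices

* Split-score ties: most downstream position; float ties use a 1e−9 tolerance.
* All-zero coverage vectors yield no ends; genes whose stop codon abuts the
  region edge are reported unannotatable.
* `d₁ = 0` (empty proximal segment) makes a gene unquantifiable — an error,
  not a silent zero.
* Duplicate isoform lengths after merging are impossible by the ≥ 100-nt site
  separation and are treated as a contract violation.
* Problem sizes in the test suite (five-gene stock bundle, 500-gene precision
  run, oracle arrays ≤ 2000 nt) were picked so every oracle comparison is
  exhaustive and the whole suite runs in seconds.

## Known limitations

* Binary segmentation is greedy; an adversarial staircase can in principle
  mask a boundary that a full dynamic program would find. The exhaustive
  oracle in the tests shares the greedy recursion (it verifies the
  implementation, not the greedy choice itself).
* Fusion discard uses CDS overlap only; 5′UTRs of neighbors are not modeled,
  so a fusion ending inside a neighbor's 5′UTR (annotated CDS-distal) would
  be missed.
* Unstranded data superpose antisense coverage; the stricter fusion rule
  mitigates but cannot resolve tail-to-tail overlaps.
* The expression rule counts depth sums, not fragments; at very low depth the
  two differ (a single long fragment contributes ~75 counts).
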