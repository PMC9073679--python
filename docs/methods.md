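# Methods

`mycohic` re-implements, as a tested library, the contact-analysis toolchain
used to study chromosome conformation in compact fungal genomes such as
*Neurospora crassa*: matrix construction and normalization from aligned Hi-C
pairs, chromatin-composition-weighted merging of enzyme-specific libraries,
cross-compartment contact quantification against histone-mark tracks,
heterochromatin boundary classification, and Hi-C-guided placement of
unassigned contigs. Every stage is exercised end to end on synthetic genomes
and contacts whose statistical structure matches the biological setting, so
the whole pipeline is testable without any external download.

## The synthetic genome

`simulate.GenomeSpec` describes a haploid multi-chromosome nuclear genome.
Defaults model the *Neurospora*-like setting at desk scale: 3 chromosomes of
2 Mb each. Each chromosome carries

- a centromere (120 kb, CenH3- and H3K9me3-marked) at its midpoint;
- two subtelomeres (40 kb each) marked by both H3K9me3 and H3K27me2/3,
  with ~20 tandem copies of the telomere repeat TTAGGG at each end
  (reverse-complemented at the left end);
- interspersed H3K9me3 blocks (10–60 kb) placed uniformly in the arms until
  total H3K9me3 coverage reaches `het_fraction`, default **0.1576** — the
  genome fraction of constitutive heterochromatin in wild-type *Neurospora*.
  The last block is size-capped so realized coverage stays within ±2
  percentage points of the target (in practice it lands within ±0.5).

Sequence is drawn i.i.d. per base with A+T fraction 0.70 inside
heterochromatin and 0.45 outside, reproducing the AT-richness that gives the
TTAA cutter (MseI-like) its heterochromatin bias and the GATC cutter
(DpnII-like) its euchromatin bias. Genes (1–3 kb, ~1.5 per 10 kb of
euchromatin) are assigned at most one mark each — H3K27ac, H3K4me3,
ASH1-style H3K36me2, or H3K27me2/3 — with configurable probabilities.

What the generator does *not* emulate: mapping error, fragment-level
religation chemistry, copy-number variation, polymer physics beyond the
weight model below. Passing tests therefore demonstrate correctness of the
analysis operations under the declared generative model, not performance on
real libraries.

## The contact model

Contacts are sampled from an explicit bin-pair weight (`ContactModel`):

    w(x, y) = decay(|x − y|) · compartment(x, y) · bundling(x, y)
              · capture(x) · capture(y)

- `decay(s) = s^(−α)` within a chromosome (default α = 1), with `s` clamped
  at ≥ 1 kb — products shorter than that are removed by valid-pair filters
  anyway. Between chromosomes the decay term is a constant chosen so the
  intra:inter contact ratio is ≈ 4:1 at unit multipliers.
- Compartment multipliers by H3K9me3 status of the two loci:
  `w_BB = 4` (heterochromatin bundling), `w_AA = 1`, `w_AB = 0.25`
  (occlusion of silent from active chromatin); the model requires
  `w_AB ≤ min(w_AA, w_BB)`.
- Inter-chromosomal bundling: centromere–centromere ×8, telomere–telomere
  ×6 (the Rabl-like clustering of the 7 centromeres and 14 telomeres).
- Capture bias per end: `(1 + d)^e` where `d` is the enzyme's site count
  within a 500 bp window, `e = 1` by default; a double digest multiplies the
  capture terms of both enzymes. An optional PCR term depletes AT-rich ends
  by `(1 − k·AT)^cycles`.
- `planted_loops`: explicit (gene interval, heterochromatin interval,
  strength) triples multiplying the corresponding bin rectangles, used to
  plant gene↔heterochromatin contacts with known truth.

Loci are sampled at 5 kb granularity (the bin-pair weight table is exact at
that scale; positions are uniform within bins) and positions are emitted as
pairs records. 5 kb is fine enough for every planted feature (blocks ≥ 10 kb,
loop anchors ≥ 1 kb rectangles are snapped to overlapping bins) while keeping
the weight table small; tests that probe 500 bp-scale structure pass
`sim_resolution=2000`. Everything is a pure function of (inputs, seed).

## Matrix pipeline

- **Filtering** removes exact-coordinate duplicates and intra-chromosomal
  pairs closer than `min_separation` (default 1 kb), and reports the
  fraction of records touching configured non-nuclear chromosomes (the
  organellar-ligation QC; near zero for in situ libraries).
- **Binning** assigns each mate by its 5′ position, `bin = floor(pos/res)`,
  so matrix mass equals the record count exactly; coarsening merges runs of
  bins per chromosome and conserves mass exactly.
- **Balancing** is Knight–Ruiz symmetric diagonal scaling: a Newton inner
  iteration (conjugate-gradient solves, matvec-only, so sparse matrices of
  any size work) with an alternating-scaling fallback after half the
  iteration budget. Convergence is declared when unmasked row sums agree
  with their mean to `tol = 1e-6` relative. The default mask removes
  zero-marginal bins plus bins below the 2nd percentile of nonzero
  marginals. On a ≥ 1 unmasked-bin-per-chromosome matrix that still fails to
  converge the error carries iteration diagnostics rather than returning
  partial weights.
- **Distance normalization**: the expected profile pools each
  intra-chromosomal diagonal genome-wide (mean over *all* bin pairs at that
  separation, observed or not) plus a scalar inter-chromosomal expectation;
  O/E divides entries by it. By construction every populated diagonal of
  O/E has mean 1. `log2_oe` applies a scale-free pseudocount of `1/n_bins`.
- **Comparison**: Pearson correlation of `log1p` counts over the union of
  nonzero supports within an optional distance window;
  `log2_compare` is the depth-normalized entrywise signed ratio with
  pseudocount `1/total mass`.

## Composition-weighted merging

Enzyme-specific libraries are merged at the valid-pair level: the
heterochromatin fraction `f` (H3K9me3 genome coverage, Σ(end−start)/genome
length) fixes the class quotas. With a fixed total, quotas are
`total·(1−f, f)` apportioned by largest remainder so they sum exactly;
otherwise the limiting class anchors (`quota_het = f/(1−f)·available_eu`).
Merging is concatenation with per-record class provenance — raw-count
additivity is exact, so merge-then-build equals build-then-add, and any
divergence between merged-fastq and averaged-matrix workflows can only
arise after balancing. Subsampling is uniform without replacement under an
explicit seed.

## Cross-compartment contact quantification

On a log2 O/E matrix (2.5 kb default), a bin is mark-enriched when the
track covers ≥ 50% of its bases (the coverage threshold is exposed; the
published rule was not printed, so a reproducible, oracle-checkable one was
chosen). A contact is an upper-triangle bin pair with log2(O/E) ≥ 2.5
(intra-chromosomal) or ≥ 3.5 (inter-chromosomal) and at least one end in
the source (H3K9me3) call; the far end is categorized per destination mark.
Both an overlapping tally (once per matching mark) and an exclusive tally
(precedence H3K9me3 > H3K27ac > H3K4me3 > H3K36me2 > not-enriched) are
reported, with a switch for whether source→source pairs stay in the
denominator, since the published analysis does not disambiguate either
choice. Raising either threshold can only shrink counts, and the exclusive
tally partitions the total — both are asserted as invariants.

Differential expression uses the plain fold-change rule on median-of-ratios
normalized counts with pseudocount 0.5: up if log2 FC ≥ 2, down if ≤ −2.
Note that planted 4-fold changes sit exactly at the threshold, so at any
nonzero dispersion roughly half of the affected genes fall on either side;
overall label agreement is the recovery metric.

## Boundary classification

Interspersed regions are H3K9me3 intervals of 5–200 kb overlapping neither
centromeres nor subtelomeres. For each region, each side's score is
log2(mean O/E + 0.05) between the 3 bins (configurable 2–5) immediately
outside the boundary and all region-internal bins at 500 bp resolution;
the background is the same statistic over all eu↔het bin pairs within
50 kb. A side is "increased" if its score exceeds background + δ
(δ = 0.5 log2 units; the source analysis was visual and gives no numeric
criterion). Mean-then-log is used rather than a mean of per-entry log
values because at desk-scale depth most 500 bp flank-internal pairs are
unobserved, and a dense log-mean would silently count them as O/E = 1;
for the same sparsity reason the 500 bp boundary matrix is distance-
normalized raw counts without KR balancing, which is applied at the
coarser quantification resolutions instead. Classification samples up to
100 regions uniformly without replacement under a seed and reports
both-sides / at-least-one-side / neither counts.

## Contig placement

- **Assignment**: score(contig, chromosome) = contact count normalized by
  the length product; best chromosome reported with the margin over the
  runner-up (margin < 1.5 ⇒ "ambiguous"; zero contacts ⇒ "unassigned").
- **Ordering** maximizes the sum of adjacent-pair contact weights over a
  linear order: exact permutation search to 8 contigs, greedy heaviest-edge
  chaining above; weights are length-normalized so big contigs do not
  swamp adjacency. Contact-based ordering is well-posed for co-inserted
  contigs at one locus; for contigs scattered megabases apart the linking
  weights are noise-dominated at 2×10⁵-pair depth, which is a property of
  the data, not the search.
- **Localization**: candidate positions are N-gap runs ≥ 1 kb (or every
  5 kb junction in no-gap mode); each candidate is scored by a matched
  filter — a `1/max(d, 1 kb)` kernel over the distances from the contig's
  target-side contact positions to the candidate gap edge. This is sharply
  peaked at the true locus and robust to decoy gaps nearby, where a plain
  flank-window count was not. Ties take the lowest coordinate, flagged.
- **Orientation** compares the power-law decay log-likelihoods of the two
  orientation hypotheses over contacts within 300 kb of the located
  insertion point ('unknown' below 20 informative pairs or a 0.05-per-pair
  margin). The likelihood formalizes "which orientation's profile matches
  the flanks better" and is markedly more reliable than the correlation
  sign at realistic depth.
- **Splicing** overwrites N bases from the insertion coordinate with the
  (possibly reverse-complemented) contig, retaining excess N, so sequence
  length is conserved and non-N content grows by exactly the placed
  lengths; AGP v2.1 records every component. On the synthetic
  scramble→simulate→place round trip (5 excised contigs, 2×10⁵ pairs) the
  corrected FASTA is byte-identical to the pre-scramble genome.

Telomere detection reports tandem runs of ≥ 5 unit copies (either strand)
within 1 kb of a sequence terminus. Collapsed-repeat copy estimation
supports a census mode (external total-copy bounds minus assembled copies)
and a coverage mode (enrichment × assembled), flooring at zero with a
warning.

## Problem sizes and tolerances

The test suite and the acceptance script run the full pipeline at desk
scale: 6 Mb genomes, 0.5–20 kb resolutions, 5×10⁴–2×10⁵ simulated pairs
per experiment — deep enough that every planted parameter is recovered
(decay slope −1 ± 0.1 at 10⁵ pairs; B–B over A–B O/E ordering at 5×10⁴;
100% contig assignment/localization at 2×10⁵) while the whole suite
completes in well under a minute of CPU. Replicate-likeness (Pearson of
log1p counts between two independent simulations of one model) is
evaluated at 20 kb bins over intra-chromosomal pairs within 2 Mb, where
depth per bin supports a stable statistic (r ≈ 0.84 at 2×10⁵ pairs; over
the full support at 10⁵ pairs shot noise on far low-count pairs caps r
near 0.65, which is expected behaviour, not failure). Genome-scale
published figures (replicate r of 0.86–0.92 at ~10⁸ reads, the 73/100 and
94/100 boundary classes, the 664,816/946,655 contact totals) depend on
real sequencing depth and serve as qualitative calibration only.

## Known limitations

- The bin-level sampler has no sub-bin structure; analyses below the
  simulation resolution see uniform positions within bins.
- KR balancing of extremely sparse matrices (500 bp bins at desk-scale
  depth) is refused rather than approximated.
- The DE rule is the thresholded fold change the source analysis reduces
  to; no dispersion modeling or hypothesis testing is performed.
- Orientation calling needs the decay gradient across the contig; contigs
  much shorter than the simulation resolution return 'unknown'.
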