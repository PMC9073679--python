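# mycohic

Hi-C contact analysis for compact fungal genomes — built around the
analysis problems posed by organisms like *Neurospora crassa*, where
AT-rich constitutive heterochromatin (H3K9me3) covers ~16% of the genome
and a single restriction enzyme cannot sample both compartments: a GATC
cutter (DpnII) sees euchromatin, a TTAA cutter (MseI) sees
heterochromatin, and a faithful genome-wide contact map requires merging
the two libraries in proportion to chromatin composition.

The package is aimed at researchers analyzing fungal (or other compact)
genome architecture who want a small, fully tested, scriptable toolchain
rather than a monolithic pipeline. It provides:

- **I/O** (`mycohic.io`) — FASTA, BED, a 7-column pairs dialect,
  sparse-triplet and dense contact-matrix formats, AGP v2.1; one 0-based
  half-open coordinate convention everywhere.
- **Synthetic data** (`mycohic.simulate`) — genomes with centromeres,
  subtelomeres, interspersed H3K9me3 blocks, telomere repeats, marked
  genes; Hi-C contacts drawn from an explicit weight model
  `w = s^(−α) · compartment · bundling · capture`, with plantable
  gene↔heterochromatin loops; assembly scrambling with known placement
  truth; WT/mutant expression counts with planted 4-fold changes.
- **Matrix core** (`mycohic.matrix`) — binning, coarsening, Knight–Ruiz
  balancing (`diag(w)·C·diag(w)` with equal row sums), observed/expected
  distance normalization, matrix correlation and log2 comparison,
  distance-decay curves.
- **Composition-weighted merging** (`mycohic.merge`) — read-level quotas
  `total·(1−f, f)` from the H3K9me3 coverage fraction `f`, exact
  largest-remainder apportionment, merge-then-build additivity.
- **Contact quantification** (`mycohic.enrichment`) — mark-enriched bin
  calls, counting of strong distance-normalized contacts
  (log2 O/E ≥ 2.5 intra / ≥ 3.5 inter) from H3K9me3 bins into destination
  marks, fold-change DE classification (|log2 FC| ≥ 2), overlap of DE
  genes with heterochromatin-contacting genes.
- **Boundary analysis** (`mycohic.boundaries`) — classify interspersed
  heterochromatic regions by elevated flank↔interior contacts.
- **Scaffold placement** (`mycohic.scaffold`) — assign unplaced contigs to
  chromosomes by normalized contact counts, order co-inserted contigs,
  localize insertion points in N-gaps, detect terminal TTAGGG repeats,
  bound collapsed-repeat copy numbers, and emit a corrected FASTA + AGP.
- **CLI** (`mycohic`) — subcommands (`simulate`, `filter`, `merge`,
  `build`, `balance`, `oe`, `correlate`, `compare`, `quantify`,
  `run-all`) over the library, with a YAML config and a checksummed run
  manifest.

## Worked example

Simulate a genome, build and balance a matrix, and quantify
heterochromatin-originating contacts:

```python
from mycohic.simulate import GenomeSpec, ContactModel, generate_genome, simulate_pairs
from mycohic.matrix import build_matrix, kr_balance, observed_over_expected, log2_oe
from mycohic.merge import coverage_fraction
from mycohic.enrichment import call_enriched_bins, quantify_cross_contacts

genome, tracks = generate_genome(GenomeSpec(seed=1))        # 3 x 2 Mb
print(f"H3K9me3 coverage: {coverage_fraction(tracks['H3K9me3'], genome):.4f}")

pairs = simulate_pairs(genome, tracks, ContactModel(seed=1),
                       ["GATC", "TTAA"], 100_000, seed=1)
mat = build_matrix(pairs, genome, resolution=2500)
l2 = log2_oe(observed_over_expected(kr_balance(mat).balanced()))

src = call_enriched_bins(tracks["H3K9me3"], l2.bins, 2500)
dests = [call_enriched_bins(tracks[m], l2.bins, 2500)
         for m in ("H3K9me3", "H3K27ac", "H3K4me3", "H3K36me2")]
summary = quantify_cross_contacts(l2, src, dests, thr_intra=2.5, thr_inter=3.5)
print(summary.exclusive[["destination", "count", "pct"]].to_string(index=False))
```

Output:

```
H3K9me3 coverage: 0.1576
 destination  count       pct
     H3K9me3   8379 80.901806
     H3K27ac     94  0.907599
     H3K4me3    101  0.975186
    H3K36me2    105  1.013807
not_enriched   1678 16.201603
```

The generator hits the configured heterochromatin fraction exactly; most
strong distance-normalized contacts from H3K9me3 bins end in other
H3K9me3 bins (heterochromatin bundling), with a small fraction reaching
mark-enriched euchromatin — the planted cross-compartment signal that the
quantifier is designed to measure.

The same pipeline runs from the shell:

```bash
mycohic run-all --seed 1 --out runs/demo
```

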