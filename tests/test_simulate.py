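"""Synthetic-data generator: coverage targets, determinism, planted structure."""

import numpy as np
import pandas as pd
import pytest

from mycohic.io import IntervalTrack, Genome
from mycohic.merge import coverage_fraction
from mycohic.simulate import (
    TELOMERE_UNIT,
    ContactModel,
    GenomeSpec,
    generate_genome,
    restriction_map,
    revcomp,
    scramble_assembly,
    simulate_expression,
    simulate_pairs,
)


class TestGenerateGenome:
    def test_h3k9me3_coverage_near_target(self, default_genome):
        genome, tracks = default_genome
        cov = coverage_fraction(tracks["H3K9me3"], genome)
        assert 0.1576 - 0.02 <= cov <= 0.1576 + 0.02

    def test_only_centromeres_when_no_interspersed_budget(self):
        # heterochromatin fraction exactly the centromere share, no subtelomeres
        spec = GenomeSpec(
            n_chroms=1,
            chrom_length_bp=1_000_000,
            het_fraction=0.12,
            centromere_size=120_000,
            subtelomere_size=0,
            seed=4,
        )
        genome, tracks = generate_genome(spec)
        pd.testing.assert_frame_equal(
            tracks["H3K9me3"].intervals, tracks["CenH3"].intervals
        )

    def test_same_seed_identical_sequences(self, small_spec):
        g1, _ = generate_genome(small_spec)
        g2, _ = generate_genome(small_spec)
        assert g1.sequences == g2.sequences

    def test_telomere_repeats_at_both_ends(self, small_genome):
        genome, _ = small_genome
        for chrom in genome.chrom_names:
            seq = genome.sequences[chrom]
            assert seq.endswith(TELOMERE_UNIT * 20)
            assert seq.startswith(revcomp(TELOMERE_UNIT * 20))

    def test_at_content_higher_in_heterochromatin(self, small_genome):
        genome, tracks = small_genome
        chrom = genome.chrom_names[0]
        seq = genome.sequences[chrom]
        het = tracks["interspersed_het"].intervals
        blk = het[het["chrom"] == chrom].iloc[0]
        hseq = seq[blk["start"] : blk["end"]]
        at_het = (hseq.count("A") + hseq.count("T")) / len(hseq)
        gaps = tracks["genes"].intervals
        g = gaps[gaps["chrom"] == chrom].iloc[0]
        eseq = seq[g["start"] : g["end"]]
        at_eu = (eseq.count("A") + eseq.count("T")) / len(eseq)
        assert at_het > at_eu + 0.1

    def test_infeasible_spec_rejected(self):
        with pytest.raises(ValueError):
            GenomeSpec(chrom_length_bp=50_000, het_block_size_range=(60_000, 80_000))


class TestRestrictionMap:
    def test_single_site_offset(self):
        g = Genome(
            chrom_names=["c"], chrom_lengths={"c": 8}, sequences={"c": "ACGATCGT"}
        )
        t = restriction_map(g, "GATC")
        assert t.intervals.values.tolist() == [["c", 2, 6]]

    def test_uniform_sequence_density_matches_expectation(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), size=1_000_000))
        g = Genome(chrom_names=["c"], chrom_lengths={"c": len(seq)}, sequences={"c": seq})
        n = len(restriction_map(g, "GATC"))
        expect = 1_000_000 / 256  # each 4-mer hits with probability 4^-4
        sd = np.sqrt(expect)
        assert abs(n - expect) < 3 * sd

    def test_at_rich_sequence_favors_ttaa_over_gatc(self):
        rng = np.random.default_rng(1)
        seq = "".join(
            rng.choice(list("ACGT"), size=1_000_000, p=[0.35, 0.15, 0.15, 0.35])
        )
        g = Genome(chrom_names=["c"], chrom_lengths={"c": len(seq)}, sequences={"c": seq})
        n_ttaa = len(restriction_map(g, "TTAA"))
        n_gatc = len(restriction_map(g, "GATC"))
        # binomial expectations: p(TTAA)=0.35^4 vs p(GATC)=0.35^2*0.15^2
        assert n_ttaa > n_gatc

    def test_non_palindromic_scans_both_strands(self):
        g = Genome(
            chrom_names=["c"], chrom_lengths={"c": 12}, sequences={"c": "AAGGCCTTCCAA"}
        )
        t = restriction_map(g, "GGCC")  # palindrome: one hit
        assert len(t) == 1
        t2 = restriction_map(g, "AAGG")  # non-palindromic; revcomp CCTT also present
        assert len(t2) == 2

    def test_empty_recognition_rejected(self, small_genome):
        with pytest.raises(ValueError):
            restriction_map(small_genome[0], "")

    def test_enzyme_site_asymmetry_between_compartments(self, small_genome):
        """TTAA sites concentrate in AT-rich heterochromatin, GATC outside."""
        genome, tracks = small_genome
        het = tracks["H3K9me3"]
        het_bp = het.total_bases()
        eu_bp = genome.total_length - het_bp

        def density_ratio(enz):
            sites = restriction_map(genome, enz)
            merged = het.intervals
            n_het = 0
            for row in sites.intervals.itertuples(index=False):
                sub = merged[merged["chrom"] == row.chrom]
                if ((sub["start"] <= row.start) & (sub["end"] > row.start)).any():
                    n_het += 1
            n_eu = len(sites) - n_het
            return (n_het / het_bp) / (n_eu / eu_bp)

        assert density_ratio("TTAA") > 1.3
        assert density_ratio("GATC") < 0.9


class TestSimulatePairs:
    def test_exact_pair_count_and_determinism(self, small_genome):
        genome, tracks = small_genome
        model = ContactModel(seed=3)
        p1 = simulate_pairs(genome, tracks, model, "GATC", 5000, seed=3)
        p2 = simulate_pairs(genome, tracks, model, "GATC", 5000, seed=3)
        assert len(p1) == 5000
        pd.testing.assert_frame_equal(p1.records, p2.records)

    def test_zero_pairs_rejected(self, small_genome):
        genome, tracks = small_genome
        with pytest.raises(ValueError):
            simulate_pairs(genome, tracks, ContactModel(), "GATC", 0)

    def test_bb_contact_fraction_exceeds_random_expectation(self, small_genome):
        """With w_BB=4 and TTAA capture bias, the fraction of pairs with both
        ends in H3K9me3 must exceed the squared genome coverage by >= 2x."""
        genome, tracks = small_genome
        model = ContactModel(w_BB=4.0, w_AB=0.25, seed=5)
        pairs = simulate_pairs(genome, tracks, model, "TTAA", 20_000, seed=5)
        het = tracks["H3K9me3"].intervals
        in_het = {}
        for chrom in genome.chrom_names:
            sub = het[het["chrom"] == chrom]
            in_het[chrom] = (sub["start"].to_numpy(), sub["end"].to_numpy())

        def hits(chrom_col, pos_col):
            out = np.zeros(len(pairs), bool)
            df = pairs.records
            for chrom, (s, e) in in_het.items():
                m = (df[chrom_col] == chrom).to_numpy()
                pos = df[pos_col].to_numpy()
                out |= m & np.any((pos[:, None] >= s) & (pos[:, None] < e), axis=1)
            return out

        both = hits("chrom1", "pos1") & hits("chrom2", "pos2")
        f = coverage_fraction(tracks["H3K9me3"], genome)
        assert both.mean() >= 2 * f**2

    def test_zero_site_enzyme_rejected(self, small_genome):
        genome, tracks = small_genome
        with pytest.raises(ValueError, match="zero sites"):
            simulate_pairs(genome, tracks, ContactModel(), "GCGCGCGCGCGCGC", 100)


class TestScrambleAssembly:
    def test_length_conservation_and_truth_rows(self, small_genome):
        genome, tracks = small_genome
        scr, contigs, truth = scramble_assembly(genome, tracks, 3, seed=7)
        assert scr.chrom_lengths == genome.chrom_lengths
        assert len(truth) == 3
        assert len(contigs.chrom_names) == 3

    def test_zero_excisions_identity(self, small_genome):
        genome, tracks = small_genome
        scr, contigs, truth = scramble_assembly(genome, tracks, 0, seed=7)
        assert scr is genome and len(truth) == 0

    def test_excised_bases_replaced_by_equal_n_runs(self, small_genome):
        genome, tracks = small_genome
        scr, contigs, truth = scramble_assembly(genome, tracks, 3, seed=7)
        for row in truth.table.itertuples(index=False):
            clen = contigs.chrom_lengths[row.contig]
            run = scr.sequences[row.chrom][row.coord : row.coord + clen]
            assert run == "N" * clen
            original = genome.sequences[row.chrom][row.coord : row.coord + clen]
            stored = contigs.sequences[row.contig]
            assert stored == (original if row.orientation == "+" else revcomp(original))

    def test_over_excision_rejected(self, small_genome):
        genome, tracks = small_genome
        with pytest.raises(ValueError, match="exceeds"):
            scramble_assembly(genome, tracks, 10_000, seed=0)


class TestSimulateExpression:
    def _contacting(self, tracks, n=40):
        marks = tracks["gene_marks"]
        genes = tracks["genes"].intervals["gene_id"]
        return [g for g in genes if marks.get(g) in ("H3K27ac", "H3K4me3", "H3K36me2")][:n]

    def test_low_dispersion_log2fc_limit(self, small_genome):
        _, tracks = small_genome
        contacting = self._contacting(tracks)
        wt, mut, truth = simulate_expression(
            tracks, contacting, fc=4, n_genes_affected=20, dispersion=0.0, seed=2,
            base_mean_range=(5000, 20000),
        )
        w = wt.set_index("gene")["count"]
        m = mut.set_index("gene")["count"]
        down = truth.index[truth == "down"]
        lfc = np.log2(m[down] / w[down])
        assert np.allclose(lfc, -2.0, atol=0.1)

    def test_no_affected_genes_all_unchanged(self, small_genome):
        _, tracks = small_genome
        wt, mut, truth = simulate_expression(
            tracks, self._contacting(tracks), fc=4, n_genes_affected=0, seed=2
        )
        assert (truth == "unchanged").all()

    def test_direction_follows_mark_class(self, small_genome):
        _, tracks = small_genome
        marks = tracks["gene_marks"]
        _, _, truth = simulate_expression(
            tracks, self._contacting(tracks), fc=4, n_genes_affected=20, seed=2
        )
        for g in truth.index[truth == "down"]:
            assert marks[g] in ("H3K27ac", "H3K4me3")
        for g in truth.index[truth == "up"]:
            assert marks[g] == "H3K36me2"

    def test_fold_change_at_most_one_rejected(self, small_genome):
        _, tracks = small_genome
        with pytest.raises(ValueError):
            simulate_expression(tracks, [], fc=1.0)
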