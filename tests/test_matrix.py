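"""Matrix core: construction, coarsening, KR balancing, O/E, comparisons."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from mycohic.io import PairsTable
from mycohic.matrix import (
    ContactMatrix,
    build_matrix,
    coarsen,
    contacts_per_site,
    correlate,
    distance_decay_curve,
    expected_profile,
    filter_pairs,
    fit_decay_slope,
    kr_balance,
    log2_compare,
    observed_over_expected,
)

from conftest import random_pairs_frame


def pairs_of(rows, genome):
    df = pd.DataFrame(
        rows, columns=["read_id", "chrom1", "pos1", "chrom2", "pos2", "strand1", "strand2"]
    )
    return PairsTable.from_dataframe(df, genome)


def make_matrix(dense, resolution=500, chroms=None):
    n = dense.shape[0]
    chroms = chroms or ["c1"] * n
    starts = []
    seen = {}
    for c in chroms:
        starts.append(seen.get(c, 0))
        seen[c] = seen.get(c, 0) + resolution
    bins = pd.DataFrame({"chrom": chroms, "start": starts})
    return ContactMatrix(
        resolution=resolution, bins=bins, counts=sp.csr_matrix(np.triu(dense))
    )


class TestFilterPairs:
    def test_exact_duplicates_collapse(self, toy_genome):
        rows = [
            ["r1", "c1", 100, "c1", 2000, "+", "-"],
            ["r2", "c1", 100, "c1", 2000, "+", "-"],
        ]
        out, rep = filter_pairs(pairs_of(rows, toy_genome), min_separation=0)
        assert len(out) == 1 and rep.n_duplicates == 1

    def test_short_range_intra_removed(self, toy_genome):
        rows = [["r1", "c1", 100, "c1", 300, "+", "-"]]
        out, rep = filter_pairs(pairs_of(rows, toy_genome), min_separation=1000)
        assert len(out) == 0 and rep.n_short_range == 1

    def test_dedup_matches_brute_force_set_union(self, toy_genome):
        df = random_pairs_frame(toy_genome, 10_000, seed=9)
        # plant ~5% duplicates
        dup = df.sample(500, random_state=0)
        df = pd.concat([df, dup], ignore_index=True)
        table = PairsTable.from_dataframe(df, toy_genome)
        out, rep = filter_pairs(table, min_separation=0)
        brute = {
            tuple(r)
            for r in table.records[
                ["chrom1", "pos1", "strand1", "chrom2", "pos2", "strand2"]
            ].itertuples(index=False)
        }
        assert len(out) == len(brute)

    def test_nonnuclear_fraction_reported(self, toy_genome):
        toy_genome.nonnuclear_names = {"c2"}
        rows = [
            ["r1", "c1", 100, "c1", 2000, "+", "-"],
            ["r2", "c1", 100, "c2", 200, "+", "-"],
        ]
        _, rep = filter_pairs(pairs_of(rows, toy_genome), genome=toy_genome)
        assert rep.frac_nonnuclear == 0.5
        toy_genome.nonnuclear_names = set()


class TestBuildMatrix:
    def test_single_record_off_diagonal_bin_pair(self, toy_genome):
        m = build_matrix(pairs_of([["r1", "c1", 100, "c1", 900, "+", "-"]], toy_genome),
                         toy_genome, 500)
        assert m.counts[0, 1] == 1 and m.total() == 1

    def test_both_mates_one_bin_diagonal(self, toy_genome):
        m = build_matrix(pairs_of([["r1", "c1", 100, "c1", 400, "+", "-"]], toy_genome),
                         toy_genome, 500)
        assert m.counts[0, 0] == 1

    def test_mass_equals_record_count(self, toy_genome):
        df = random_pairs_frame(toy_genome, 20_000, seed=2)
        table = PairsTable.from_dataframe(df, toy_genome)
        m = build_matrix(table, toy_genome, 500)
        assert m.total() == 20_000

    def test_oversized_resolution_rejected(self, toy_genome):
        with pytest.raises(ValueError):
            build_matrix(pairs_of([], toy_genome), toy_genome, 10_000)


class TestCoarsen:
    def test_factor_twenty_scales_resolution(self, toy_genome):
        df = random_pairs_frame(toy_genome, 100, seed=3)
        m = build_matrix(PairsTable.from_dataframe(df, toy_genome), toy_genome, 100)
        c = coarsen(m, 20)
        assert c.resolution == 2000

    def test_collapse_to_one_bin_per_chromosome(self, toy_genome):
        df = random_pairs_frame(toy_genome, 500, seed=4)
        m = build_matrix(PairsTable.from_dataframe(df, toy_genome), toy_genome, 500)
        c = coarsen(m, 100)  # >> bins per chromosome
        assert c.n_bins == 2 and c.total() == 500

    def test_composition_matches_single_step(self, toy_genome):
        df = random_pairs_frame(toy_genome, 2000, seed=5)
        m = build_matrix(PairsTable.from_dataframe(df, toy_genome), toy_genome, 100)
        c22 = coarsen(coarsen(m, 2), 2)
        c4 = coarsen(m, 4)
        assert c22.total() == c4.total() == 2000
        assert (abs(c22.counts - c4.counts)).nnz == 0


def sinkhorn_oracle(A, tol=1e-10, max_iter=100_000):
    """Brute-force alternating scaling on a dense symmetric matrix."""
    x = np.ones(A.shape[0])
    for _ in range(max_iter):
        r = x * (A @ x)
        if np.abs(r - 1).max() < tol:
            break
        x = x / np.sqrt(r)
    return x


class TestKrBalance:
    def test_already_balanced_matrix_is_fixed_point(self):
        # circulant symmetric: all row sums equal
        A = np.array([[2.0, 1, 1], [1, 2, 1], [1, 1, 2]])
        m = make_matrix(A)
        bal = kr_balance(m, mask_rule=lambda mm: np.zeros(3, bool))
        w = bal.weights
        assert np.allclose(w, w[0], rtol=1e-5)

    def test_weights_match_sinkhorn_oracle(self):
        rng = np.random.default_rng(7)
        A = rng.uniform(0.5, 3.0, (3, 3))
        A = (A + A.T) / 2
        m = make_matrix(A)
        bal = kr_balance(m, mask_rule=lambda mm: np.zeros(3, bool), tol=1e-8)
        x = sinkhorn_oracle(A)
        target = np.asarray(m.symmetric().sum(axis=1)).ravel().mean()
        assert np.allclose(bal.weights, x * np.sqrt(target), rtol=1e-5)

    def test_balanced_row_sums_equal(self):
        rng = np.random.default_rng(8)
        A = rng.uniform(0.1, 2.0, (10, 10))
        A = (A + A.T) / 2
        m = make_matrix(A)
        bal = kr_balance(m, mask_rule=lambda mm: np.zeros(10, bool), tol=1e-8)
        rows = np.asarray(bal.balanced().symmetric().sum(axis=1)).ravel()
        assert np.abs(rows - rows.mean()).max() / rows.mean() < 1e-6

    def test_zero_row_masked_rest_balances(self):
        A = np.array([[2.0, 1, 0], [1, 2, 0], [0, 0, 0]])
        m = make_matrix(A)
        bal = kr_balance(m)
        assert bal.mask[2] and bal.weights[2] == 0
        rows = np.asarray(bal.balanced().symmetric().sum(axis=1)).ravel()[:2]
        assert np.abs(rows - rows.mean()).max() / rows.mean() < 1e-6

    def test_fully_masked_matrix_rejected(self):
        m = make_matrix(np.zeros((3, 3)))
        with pytest.raises(ValueError):
            kr_balance(m)

    def test_idempotence(self):
        rng = np.random.default_rng(9)
        A = rng.uniform(0.5, 2.0, (6, 6))
        A = (A + A.T) / 2
        m = make_matrix(A)
        bal1 = kr_balance(m, mask_rule=lambda mm: np.zeros(6, bool), tol=1e-8)
        bal2 = kr_balance(bal1.balanced(), mask_rule=lambda mm: np.zeros(6, bool), tol=1e-8)
        w = bal2.weights / bal2.weights.mean()
        assert np.abs(w - 1).max() < 1e-4


class TestObservedOverExpected:
    def test_constant_diagonals_give_unit_oe(self):
        n = 6
        A = np.zeros((n, n))
        for d in range(n):
            A += np.diag(np.full(n - d, float(d + 1)), k=d)
        A = np.triu(A) + np.triu(A, 1).T
        m = make_matrix(A)
        oe = observed_over_expected(m)
        assert np.allclose(oe.counts[oe.counts != 0], 1.0)

    def test_every_populated_diagonal_has_mean_one(self, toy_genome):
        df = random_pairs_frame(toy_genome, 5000, seed=6)
        m = build_matrix(PairsTable.from_dataframe(df, toy_genome), toy_genome, 500)
        oe = observed_over_expected(m)
        coo = oe.counts.tocoo()
        cid = oe.chrom_ids
        intra = cid[coo.row] == cid[coo.col]
        d = coo.col[intra] - coo.row[intra]
        sums = np.bincount(d, weights=coo.data[intra])
        sizes = np.bincount(cid)
        npairs = np.zeros(sizes.max(), dtype=int)
        for s in sizes:
            npairs[:s] += s - np.arange(s)
        populated = sums > 0
        means = sums[populated] / npairs[: len(sums)][populated]
        assert np.allclose(means, 1.0, atol=1e-9)


class TestCorrelateAndCompare:
    def _mat(self, toy_genome, seed, n=5000):
        df = random_pairs_frame(toy_genome, n, seed=seed)
        return build_matrix(PairsTable.from_dataframe(df, toy_genome), toy_genome, 500)

    def test_self_correlation_is_one(self, toy_genome):
        m = self._mat(toy_genome, 1)
        assert correlate(m, m) == pytest.approx(1.0)

    def test_scaled_copy_correlates_perfectly(self, toy_genome):
        from dataclasses import replace

        m = self._mat(toy_genome, 1)
        m2 = replace(m, counts=(2.0 * m.counts).tocsr())
        assert correlate(m, m2) > 0.999

    def test_bin_table_mismatch_rejected(self, toy_genome, small_genome):
        m = self._mat(toy_genome, 1)
        g, _ = small_genome
        df = random_pairs_frame(g, 100, seed=1)
        other = build_matrix(PairsTable.from_dataframe(df, g), g, 500)
        with pytest.raises(ValueError):
            correlate(m, other)

    def test_log2_compare_identical_all_zero(self, toy_genome):
        m = self._mat(toy_genome, 2)
        diff = log2_compare(m, m)
        assert np.allclose(diff.counts.data, 0.0)

    def test_log2_compare_depth_invariant(self, toy_genome):
        from dataclasses import replace

        m = self._mat(toy_genome, 2)
        m2 = replace(m, counts=(2.0 * m.counts).tocsr())
        diff = log2_compare(m, m2, depth_normalize=True)
        assert np.allclose(diff.counts.data, 0.0, atol=1e-12)

    def test_log2_compare_doubled_entry_near_minus_one(self, toy_genome):
        from dataclasses import replace

        m = self._mat(toy_genome, 3, n=20_000)
        c2 = m.counts.tolil()
        i, j = 0, 1
        c2[i, j] = 2 * c2[i, j]
        m2 = replace(m, counts=c2.tocsr())
        diff = log2_compare(m, m2, depth_normalize=False, eps=1e-9)
        assert diff.counts[i, j] == pytest.approx(-1.0, abs=1e-6)


class TestDecayCurve:
    def test_constant_diagonal_matrix_flat_curve(self):
        n = 8
        A = np.full((n, n), 3.0)
        m = make_matrix(A)
        curve = distance_decay_curve(m)
        assert np.allclose(curve["mean_count"], 3.0)

    def test_curves_consistent_across_coarsening(self, toy_genome):
        df = random_pairs_frame(toy_genome, 50_000, seed=8)
        table = PairsTable.from_dataframe(df, toy_genome)
        m = build_matrix(table, toy_genome, 100)
        c = coarsen(m, 10)
        fine = distance_decay_curve(m)
        coarse = distance_decay_curve(c)
        # per-bp mean counts agree once fine distances are pooled to coarse bins
        fine_pooled = (
            fine.assign(g=fine["distance"] // 1000)
            .groupby("g")["mean_count"]
            .mean()
        )
        for row in coarse.itertuples(index=False):
            g = row.distance // 1000
            if g in fine_pooled.index and fine_pooled[g] > 0:
                # coarse bins hold 10x10 fine bin pairs
                assert row.mean_count == pytest.approx(100 * fine_pooled[g], rel=0.35)


class TestContactsPerSite:
    @pytest.mark.parametrize(
        "n_pairs,n_sites,expected",
        [(89_240_000, 136_425, 654), (16_690_000, 195_726, 85), (0, 100, 0)],
    )
    def test_reported_ratios(self, n_pairs, n_sites, expected):
        assert round(contacts_per_site(n_pairs, n_sites)) == expected

    def test_zero_sites_rejected(self):
        with pytest.raises(ValueError):
            contacts_per_site(100, 0)
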