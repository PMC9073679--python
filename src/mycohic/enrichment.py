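"""Epigenetic-mark contact quantification and fold-change gene classification.

Given a distance-normalized (log2 O/E) contact matrix and per-mark interval
tracks, this module calls mark-enriched bins, counts strong contacts that
originate in H3K9me3-enriched (constitutive heterochromatin) bins, and
categorizes the far end by destination mark — the cross-compartment
quantification behind claims like "euchromatic islands of H3K27ac / H3K4me3
/ ASH1-H3K36me2 contact silent chromatin".  It also implements the plain
fold-change rule used to call differentially expressed genes
(|log2 FC| >= 2 on normalized counts) and the overlap of DE genes with
heterochromatin-contacting genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import ContactMatrix

__all__ = [
    "MarkBinCall",
    "CrossContactSummary",
    "call_enriched_bins",
    "quantify_cross_contacts",
    "classify_de_genes",
    "overlap_contacting_genes",
    "genes_to_bins",
]

DEST_PRECEDENCE = ["H3K9me3", "H3K27ac", "H3K4me3", "H3K36me2", "not_enriched"]


@dataclass
class MarkBinCall:
    mark: str
    enriched: np.ndarray  # bool per bin, aligned to one bin table
    min_coverage_fraction: float = 0.5

    @property
    def n_enriched(self):
        return int(self.enriched.sum())


def call_enriched_bins(track, bins: pd.DataFrame, resolution: int, min_coverage_fraction=0.5) -> MarkBinCall:
    """A bin is mark-enriched iff the fraction of its bases covered by the
    (merged) track is at least `min_coverage_fraction`."""
    cov = np.zeros(len(bins))
    starts = bins["start"].to_numpy()
    by_chrom = {c: np.flatnonzero((bins["chrom"] == c).to_numpy()) for c in bins["chrom"].unique()}
    for row in track.intervals.itertuples(index=False):
        idx = by_chrom.get(row.chrom)
        if idx is None:
            continue
        s, e = row.start, row.end
        b0 = s // resolution
        b1 = (e - 1) // resolution
        for b in range(b0, b1 + 1):
            if b >= len(idx):
                break
            lo = max(s, b * resolution)
            hi = min(e, (b + 1) * resolution)
            cov[idx[b]] += hi - lo
    frac = cov / resolution
    return MarkBinCall(track.name, frac >= min_coverage_fraction, min_coverage_fraction)


@dataclass
class CrossContactSummary:
    source_mark: str
    thr_intra: float
    thr_inter: float
    total_contacts: int
    exclusive: pd.DataFrame  # columns: destination, intra, inter, count, pct
    overlapping: pd.DataFrame
    include_source_dest_in_total: bool = True

    def pct(self, destination: str) -> float:
        row = self.exclusive[self.exclusive["destination"] == destination]
        return float(row["pct"].iloc[0]) if len(row) else 0.0


def quantify_cross_contacts(
    log2_oe: ContactMatrix,
    source: MarkBinCall,
    dest_calls: list,
    thr_intra: float = 2.5,
    thr_inter: float = 3.5,
    include_source_dest_in_total: bool = True,
) -> CrossContactSummary:
    """Count strong distance-normalized contacts originating at source bins.

    A contact is an upper-triangle bin pair whose log2(O/E) meets the
    intra- or inter-chromosomal threshold and has at least one end in a
    source-enriched bin.  The far end is assigned to destination categories
    two ways: an overlapping tally (counted once per matching mark) and an
    exclusive tally with precedence H3K9me3 > H3K27ac > H3K4me3 > H3K36me2 >
    not-enriched.  Percentages are over all counted source contacts.
    """
    n = log2_oe.n_bins
    for call in [source] + dest_calls:
        if len(call.enriched) != n:
            raise ValueError(f"bin-table mismatch for call {call.mark!r}")
    coo = log2_oe.counts.tocoo()
    if coo.nnz and coo.data.min() >= 0 and coo.data.max() > 30:
        raise ValueError("matrix does not look log2-transformed (all-positive, huge)")
    chrom_ids = log2_oe.chrom_ids
    intra = chrom_ids[coo.row] == chrom_ids[coo.col]
    thr = np.where(intra, thr_intra, thr_inter)
    strong = coo.data >= thr
    src = source.enriched
    touch = src[coo.row] | src[coo.col]
    sel = strong & touch
    rows, cols, is_intra = coo.row[sel], coo.col[sel], intra[sel]
    # far end relative to the source anchor; if both ends are source bins the
    # destination is evaluated at the col end (the pair still counts once)
    anchor_is_row = src[rows]
    far = np.where(anchor_is_row, cols, rows)

    dest_map = {c.mark: c.enriched for c in dest_calls}
    marks = [m for m in DEST_PRECEDENCE[:-1] if m in dest_map]
    extra = [c.mark for c in dest_calls if c.mark not in marks]
    marks = marks + extra

    total = len(rows)
    if not include_source_dest_in_total and source.mark in dest_map:
        keep_tot = ~dest_map[source.mark][far]
        total = int(keep_tot.sum())

    def _tally(exclusive: bool):
        recs = []
        assigned = np.zeros(len(far), bool)
        for m in marks:
            hit = dest_map[m][far]
            if exclusive:
                hit = hit & ~assigned
                assigned |= hit
            recs.append((m, int((hit & is_intra).sum()), int((hit & ~is_intra).sum())))
        none_hit = ~assigned if exclusive else ~np.logical_or.reduce(
            [dest_map[m][far] for m in marks] or [np.zeros(len(far), bool)]
        )
        recs.append(
            ("not_enriched", int((none_hit & is_intra).sum()), int((none_hit & ~is_intra).sum()))
        )
        df = pd.DataFrame(recs, columns=["destination", "intra", "inter"])
        df["count"] = df["intra"] + df["inter"]
        denom = max(total, 1)
        df["pct"] = 100.0 * df["count"] / denom
        return df

    return CrossContactSummary(
        source_mark=source.mark,
        thr_intra=thr_intra,
        thr_inter=thr_inter,
        total_contacts=total,
        exclusive=_tally(True),
        overlapping=_tally(False),
        include_source_dest_in_total=include_source_dest_in_total,
    )


def classify_de_genes(
    wt_counts: pd.DataFrame,
    mut_counts: pd.DataFrame,
    log2fc_threshold: float = 2.0,
    norm: str = "median-of-ratios",
    pseudocount: float = 0.5,
):
    """Fold-change gene classification: up iff log2(mut/wt) >= threshold,
    down iff <= -threshold, after median-of-ratios depth normalization.

    Returns (up set, down set, unchanged set, per-gene table).
    """
    if wt_counts.empty or mut_counts.empty:
        raise ValueError("empty count table")
    wt = wt_counts.set_index("gene")["count"].astype(float)
    mut = mut_counts.set_index("gene")["count"].astype(float)
    if set(wt.index) != set(mut.index):
        raise ValueError("gene universes differ between conditions")
    mut = mut.reindex(wt.index)
    if norm == "median-of-ratios":
        mat = pd.DataFrame({"wt": wt, "mut": mut})
        logg = np.log(mat.replace(0, np.nan))
        ref = logg.mean(axis=1)
        ok = ref.notna()
        size = np.exp((logg[ok].sub(ref[ok], axis=0)).median(axis=0))
    elif norm == "total":
        tot = pd.Series({"wt": wt.sum(), "mut": mut.sum()})
        size = tot / tot.mean()
    else:
        raise ValueError(f"unknown normalization {norm!r}")
    wt_n = wt / size["wt"]
    mut_n = mut / size["mut"]
    lfc = np.log2((mut_n + pseudocount) / (wt_n + pseudocount))
    table = pd.DataFrame({"wt": wt_n, "mut": mut_n, "log2fc": lfc})
    up = set(table.index[lfc >= log2fc_threshold])
    down = set(table.index[lfc <= -log2fc_threshold])
    unchanged = set(table.index) - up - down
    return up, down, unchanged, table


def genes_to_bins(gene_track, bins: pd.DataFrame, resolution: int) -> dict:
    """Map each gene id to the set of bin indices it overlaps."""
    by_chrom = {c: np.flatnonzero((bins["chrom"] == c).to_numpy()) for c in bins["chrom"].unique()}
    out = {}
    for row in gene_track.intervals.itertuples(index=False):
        idx = by_chrom.get(row.chrom)
        if idx is None:
            continue
        b0, b1 = row.start // resolution, (row.end - 1) // resolution
        out[row.gene_id] = set(int(idx[b]) for b in range(b0, min(b1 + 1, len(idx))))
    return out


def overlap_contacting_genes(
    de_sets: dict,
    log2_oe: ContactMatrix,
    source: MarkBinCall,
    gene_track,
    thr_intra: float = 2.5,
    thr_inter: float = 3.5,
    gene_marks: dict = None,
) -> pd.DataFrame:
    """Genes that both contact H3K9me3-enriched bins (via a supra-threshold
    distance-normalized contact) and are differentially expressed.

    de_sets maps direction ("up"/"down") -> set of gene ids.  Output columns:
    gene, marks, direction, n_supporting_pairs.
    """
    coo = log2_oe.counts.tocoo()
    chrom_ids = log2_oe.chrom_ids
    intra = chrom_ids[coo.row] == chrom_ids[coo.col]
    thr = np.where(intra, thr_intra, thr_inter)
    src = source.enriched
    sel = (coo.data >= thr) & (src[coo.row] | src[coo.col])
    rows, cols = coo.row[sel], coo.col[sel]
    # partner bins of heterochromatin under the threshold rule
    partner_support = {}
    for r, c in zip(rows, cols):
        if src[r]:
            partner_support[c] = partner_support.get(c, 0) + 1
        if src[c]:
            partner_support[r] = partner_support.get(r, 0) + 1
    gene_bins = genes_to_bins(gene_track, log2_oe.bins, log2_oe.resolution)
    recs = []
    for direction, genes in de_sets.items():
        for g in sorted(genes):
            bins_g = gene_bins.get(g, set())
            n_pairs = sum(partner_support.get(b, 0) for b in bins_g)
            if n_pairs > 0:
                recs.append(
                    (g, (gene_marks or {}).get(g, ""), direction, n_pairs)
                )
    return pd.DataFrame(recs, columns=["gene", "marks", "direction", "n_supporting_pairs"])
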