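"""Heterochromatin boundary classification.

Interspersed constitutive-heterochromatin regions in compact fungal genomes
often show elevated contacts between the few bins immediately flanking the
region and the region's interior — a signature of the boundary associating
with internal heterochromatin, possibly limiting heterochromatin spread.
This module turns that visual inspection into an algorithm: for each
region, the mean distance-normalized contact (log2 O/E) between each flank
and the region interior is compared against a genome-wide euchromatin-to-
heterochromatin background, and regions are classified as increased on
both sides, one side, or neither.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .enrichment import MarkBinCall, call_enriched_bins
from .io import IntervalTrack
from .matrix import ContactMatrix

__all__ = [
    "BoundaryCall",
    "find_interspersed_regions",
    "boundary_contact_score",
    "classify_regions",
    "eu_het_background",
]


@dataclass
class BoundaryCall:
    chrom: str
    start: int
    end: int
    left_score: float  # mean flank-to-internal log2(O/E); nan = not evaluable
    right_score: float
    background: float
    delta: float
    left_increased: bool
    right_increased: bool

    @property
    def cls(self) -> str:
        n = int(self.left_increased) + int(self.right_increased)
        return {2: "both", 1: "one", 0: "neither"}[n]


def find_interspersed_regions(
    h3k9me3: IntervalTrack,
    centromeres: IntervalTrack,
    subtelomeres: IntervalTrack,
    min_len: int = 5_000,
    max_len: int = 200_000,
) -> pd.DataFrame:
    """H3K9me3 intervals within [min_len, max_len] that overlap neither a
    centromere nor a subtelomere."""
    excl = pd.concat([centromeres.intervals, subtelomeres.intervals], ignore_index=True)
    rows = []
    for row in h3k9me3.intervals.itertuples(index=False):
        if not (min_len <= row.end - row.start <= max_len):
            continue
        sub = excl[excl["chrom"] == row.chrom]
        if ((sub["start"] < row.end) & (sub["end"] > row.start)).any():
            continue
        rows.append((row.chrom, row.start, row.end))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def eu_het_background(
    oe: ContactMatrix, het_call: MarkBinCall, max_dist_bp: int = 50_000, log2_c: float = 0.05
) -> float:
    """log2 of the mean O/E over euchromatin<->heterochromatin bin pairs
    within max_dist_bp on the same chromosome — the comparison baseline for
    flank scores.  Operates on the linear O/E matrix; unobserved pairs count
    as zero, and the mean is taken before the log so that sparse matrices
    are handled without a per-entry pseudocount dominating."""
    coo = oe.counts.tocoo()
    chrom_ids = oe.chrom_ids
    het = het_call.enriched
    intra = chrom_ids[coo.row] == chrom_ids[coo.col]
    dist = (coo.col - coo.row) * oe.resolution
    cross = het[coo.row] != het[coo.col]
    sel = intra & cross & (dist > 0) & (dist <= max_dist_bp)
    total = float(coo.data[sel].sum())
    # combinatorial count of qualifying pairs (observed or not)
    max_d = max_dist_bp // oe.resolution
    n_pairs = 0
    for cid in np.unique(chrom_ids):
        h = het[chrom_ids == cid]
        for d in range(1, min(max_d, len(h) - 1) + 1):
            n_pairs += int((h[:-d] != h[d:]).sum())
    if n_pairs == 0:
        return 0.0
    return float(np.log2(total / n_pairs + log2_c))


def boundary_contact_score(
    oe: ContactMatrix,
    region,
    flank_bins: int = 3,
    background: float = 0.0,
    delta: float = 0.5,
    log2_c: float = 0.05,
) -> BoundaryCall:
    """Score one heterochromatic region's two boundaries.

    A side's score is log2 of the mean O/E between the `flank_bins` bins
    immediately outside that boundary and all region-internal bins
    (unobserved pairs count as zero); the side is "increased" iff
    score >= background + delta (delta in log2 units).  A region at a
    chromosome edge gets nan for the missing side and is classified from
    the evaluable one.  `oe` is the linear O/E matrix.
    """
    if not 2 <= flank_bins <= 5:
        raise ValueError("flank_bins must be in 2..5")
    chrom, start, end = region
    res = oe.resolution
    on_chrom = np.flatnonzero((oe.bins["chrom"] == chrom).to_numpy())
    if len(on_chrom) == 0:
        raise ValueError(f"chromosome {chrom!r} not in matrix")
    first = int(on_chrom[0])
    nb = len(on_chrom)
    b0 = start // res
    b1 = (end - 1) // res
    if b1 - b0 + 1 < 3:
        raise ValueError("region spans fewer than 3 bins at this resolution")
    internal = np.arange(first + b0, first + b1 + 1)
    left = np.arange(first + max(b0 - flank_bins, 0), first + b0)
    right = np.arange(first + b1 + 1, first + min(b1 + 1 + flank_bins, nb))
    sym = oe.symmetric()

    def _score(flank):
        if len(flank) == 0:
            return float("nan")
        total = float(sym[np.ix_(flank, internal)].sum())
        return float(np.log2(total / (len(flank) * len(internal)) + log2_c))

    ls, rs = _score(left), _score(right)
    li = bool(not np.isnan(ls) and ls >= background + delta)
    ri = bool(not np.isnan(rs) and rs >= background + delta)
    return BoundaryCall(chrom, start, end, ls, rs, background, delta, li, ri)


def classify_regions(calls: list, sample_n: int = 100, seed: int = 0):
    """Uniform sample (without replacement) of min(sample_n, len(calls))
    boundary calls and class counts over the sample."""
    if not calls:
        raise ValueError("no boundary calls to classify")
    rng = np.random.default_rng(seed)
    n = min(sample_n, len(calls))
    idx = sorted(rng.choice(len(calls), size=n, replace=False))
    sampled = [calls[i] for i in idx]
    n_both = sum(c.cls == "both" for c in sampled)
    n_one = sum(c.cls == "one" for c in sampled)
    n_neither = sum(c.cls == "neither" for c in sampled)
    summary = {
        "n_sampled": n,
        "n_both": n_both,
        "n_one_or_more": n_both + n_one,
        "n_neither": n_neither,
    }
    return summary, sampled
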