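"""Readers and writers for every external format the pipeline touches.

All in-memory coordinates are 0-based half-open; conversion to a dialect's
native convention (e.g. the 1-based positions of the pairs format) happens
only at the file boundary.  Formats covered: FASTA, BED3/6, a 7-column pairs
dialect (readID chrom1 pos1 chrom2 pos2 strand1 strand2), sparse-triplet and
homer-style dense contact matrices, AGP v2.1, and TSV count tables.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "FormatError",
    "Genome",
    "IntervalTrack",
    "PairsTable",
    "PlacementTable",
    "read_fasta",
    "write_fasta",
    "read_bed",
    "write_bed",
    "read_pairs",
    "write_pairs",
    "read_matrix",
    "write_matrix",
    "write_agp",
]

PAIRS_COLUMNS = ["read_id", "chrom1", "pos1", "chrom2", "pos2", "strand1", "strand2"]

_IUPAC = set("ACGTUWSMKRYBDHVN")


class FormatError(ValueError):
    """A file violates its declared format."""


@dataclass
class Genome:
    """A set of chromosomes: the coordinate frame for everything else.

    Attributes
    ----------
    chrom_names : list of str
        Chromosome identifiers in assembly order.
    chrom_lengths : dict
        Length in bp per chromosome, all > 0.
    sequences : dict or None
        Optional nucleotide strings (upper case), one per chromosome.
    gap_runs : list of (chrom, start, end)
        Maximal runs of N, 0-based half-open.
    nonnuclear_names : set of str
        Chromosomes flagged as organellar (e.g. the mitochondrial genome);
        drives the non-nuclear read-fraction QC.
    """

    chrom_names: list
    chrom_lengths: dict
    sequences: dict | None = None
    gap_runs: list = field(default_factory=list)
    nonnuclear_names: set = field(default_factory=set)

    def __post_init__(self):
        for name in self.chrom_names:
            if self.chrom_lengths.get(name, 0) <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length")
        if self.sequences is not None:
            for name, seq in self.sequences.items():
                if len(seq) != self.chrom_lengths[name]:
                    raise ValueError(
                        f"sequence length {len(seq)} != declared length "
                        f"{self.chrom_lengths[name]} for {name!r}"
                    )
        for chrom, start, end in self.gap_runs:
            if not (0 <= start < end <= self.chrom_lengths[chrom]):
                raise ValueError(f"gap run ({chrom},{start},{end}) out of bounds")
        if not self.nonnuclear_names <= set(self.chrom_names):
            raise ValueError("nonnuclear_names must be a subset of chrom_names")
        self._rank = {c: i for i, c in enumerate(self.chrom_names)}

    @property
    def total_length(self) -> int:
        return sum(self.chrom_lengths[c] for c in self.chrom_names)

    def nuclear_length(self) -> int:
        return sum(
            self.chrom_lengths[c]
            for c in self.chrom_names
            if c not in self.nonnuclear_names
        )

    def rank(self, chrom: str) -> int:
        return self._rank[chrom]


@dataclass
class IntervalTrack:
    """A named set of genomic intervals with BED semantics.

    Intervals are 0-based half-open, sorted by (chromosome rank where known,
    else name, then start), and non-overlapping after construction merges
    overlapping or book-ended input intervals.
    """

    name: str
    intervals: pd.DataFrame  # columns: chrom, start, end [, score, strand]

    @classmethod
    def from_records(cls, name, records, merge=True, genome=None):
        df = pd.DataFrame(records, columns=["chrom", "start", "end"][: len(records[0])] if records else ["chrom", "start", "end"])
        if df.empty:
            df = pd.DataFrame(columns=["chrom", "start", "end"])
        return cls.build(name, df, merge=merge, genome=genome)

    @classmethod
    def build(cls, name, df, merge=True, genome=None):
        df = df.copy()
        if len(df) and (df["start"] >= df["end"]).any():
            bad = df[df["start"] >= df["end"]].iloc[0]
            raise FormatError(
                f"interval with start >= end: {bad['chrom']}:{bad['start']}-{bad['end']}"
            )
        if genome is not None:
            unknown = set(df["chrom"]) - set(genome.chrom_names)
            if unknown:
                raise FormatError(f"unknown chromosome(s): {sorted(unknown)}")
            key = df["chrom"].map(genome.rank)
        else:
            key = df["chrom"]
        df = df.assign(_k=key).sort_values(["_k", "start"]).drop(columns="_k")
        df = df.reset_index(drop=True)
        if merge and len(df):
            df = _merge_intervals(df)
        return cls(name, df)

    def total_bases(self, exclude_chroms=()) -> int:
        df = self.intervals
        if exclude_chroms:
            df = df[~df["chrom"].isin(set(exclude_chroms))]
        return int((df["end"] - df["start"]).sum())

    def __len__(self):
        return len(self.intervals)


def _merge_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Coalesce overlapping/adjacent intervals per chromosome (sorted input)."""
    out = []
    for chrom, sub in df.groupby("chrom", sort=False):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        cur_s, cur_e = starts[0], ends[0]
        for s, e in zip(starts[1:], ends[1:]):
            if s <= cur_e:  # overlap or book-ended
                cur_e = max(cur_e, e)
            else:
                out.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        out.append((chrom, cur_s, cur_e))
    return pd.DataFrame(out, columns=["chrom", "start", "end"])


@dataclass
class PairsTable:
    """Deduplicated, canonically ordered aligned contact records.

    Records are stored with (chrom1, pos1) <= (chrom2, pos2) under the genome
    chromosome ordering (upper-triangle convention); mate fields swap
    together on canonicalization.
    """

    records: pd.DataFrame  # PAIRS_COLUMNS (+ optional provenance columns)
    metadata: dict = field(default_factory=dict)

    def __len__(self):
        return len(self.records)

    @classmethod
    def from_dataframe(cls, df, genome: Genome, metadata=None, validate=True):
        df = df.reset_index(drop=True).copy()
        if validate and len(df):
            for side in ("1", "2"):
                unknown = set(df[f"chrom{side}"]) - set(genome.chrom_names)
                if unknown:
                    raise FormatError(f"unknown chromosome(s): {sorted(unknown)}")
                lens = df[f"chrom{side}"].map(genome.chrom_lengths)
                bad = (df[f"pos{side}"] < 0) | (df[f"pos{side}"] >= lens)
                if bad.any():
                    row = df[bad].iloc[0]
                    raise FormatError(
                        f"position out of bounds: {row[f'chrom{side}']}:{row[f'pos{side}']}"
                    )
        df = canonicalize_pairs(df, genome)
        return cls(df, metadata or {})


def canonicalize_pairs(df: pd.DataFrame, genome: Genome) -> pd.DataFrame:
    """Swap mates so (chrom1,pos1) <= (chrom2,pos2) under genome ordering."""
    if not len(df):
        return df
    r1 = df["chrom1"].map(genome.rank).to_numpy()
    r2 = df["chrom2"].map(genome.rank).to_numpy()
    p1 = df["pos1"].to_numpy()
    p2 = df["pos2"].to_numpy()
    flip = (r1 > r2) | ((r1 == r2) & (p1 > p2))
    if flip.any():
        df = df.copy()
        for a, b in (("chrom1", "chrom2"), ("pos1", "pos2"), ("strand1", "strand2")):
            va, vb = df[a].to_numpy().copy(), df[b].to_numpy().copy()
            va[flip], vb[flip] = vb[flip], va[flip].copy()
            df[a], df[b] = va, vb
    return df


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path, nonnuclear_names=()) -> Genome:
    """Parse a FASTA file into a Genome with sequences and computed gap runs."""
    names, lengths, seqs = [], {}, {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in lengths:
            raise FormatError(f"duplicate sequence name {rec.id!r}")
        seq = str(rec.seq).upper()
        if len(seq) == 0:
            raise FormatError(f"record {rec.id!r} has length 0")
        bad = set(seq) - _IUPAC
        if bad:
            raise FormatError(
                f"non-IUPAC character(s) {sorted(bad)} in record {rec.id!r}"
            )
        names.append(rec.id)
        lengths[rec.id] = len(seq)
        seqs[rec.id] = seq
    if not names:
        raise FormatError("no records")
    gap_runs = []
    for name in names:
        for m in re.finditer(r"N+", seqs[name]):
            gap_runs.append((name, m.start(), m.end()))
    return Genome(
        chrom_names=names,
        chrom_lengths=lengths,
        sequences=seqs,
        gap_runs=gap_runs,
        nonnuclear_names=set(nonnuclear_names),
    )


def write_fasta(genome: Genome, path, width=80):
    if genome.sequences is None:
        raise ValueError("genome carries no sequences")
    with open(path, "w") as fh:
        for name in genome.chrom_names:
            fh.write(f">{name}\n")
            seq = genome.sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# BED


def read_bed(path, name=None, genome=None, merge=True) -> IntervalTrack:
    """Read a BED3+ file into a sorted, merged IntervalTrack."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"line {ln}: fewer than 3 tab-separated columns")
            rows.append((parts[0], int(parts[1]), int(parts[2])))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    return IntervalTrack.build(name or Path(path).stem, df, merge=merge, genome=genome)


def write_bed(track: IntervalTrack, path):
    track.intervals[["chrom", "start", "end"]].to_csv(
        path, sep="\t", header=False, index=False
    )


# ---------------------------------------------------------------------------
# pairs (4DN-style dialect; positions 1-based on disk, 0-based in memory)


def read_pairs(path, genome: Genome = None) -> PairsTable:
    header_chroms = {}
    meta = {}
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if line.startswith("#chromsize:"):
                    _, chrom, size = line.split()
                    header_chroms[chrom] = int(size)
                elif line.startswith("#genome:"):
                    meta["genome_id"] = line.split(None, 1)[1]
                elif line.startswith("#enzyme:"):
                    meta["enzyme"] = line.split(None, 1)[1]
                continue
            parts = line.split("\t")
            if len(parts) < 7:
                raise FormatError("pairs record with fewer than 7 columns")
            rows.append(parts[:7])
    if genome is None:
        if not header_chroms:
            raise FormatError("no #chromsize header and no genome supplied")
        genome = Genome(
            chrom_names=list(header_chroms), chrom_lengths=dict(header_chroms)
        )
    df = pd.DataFrame(
        rows, columns=["read_id", "chrom1", "pos1", "chrom2", "pos2", "strand1", "strand2"]
    )
    if len(df):
        df["pos1"] = df["pos1"].astype(np.int64) - 1  # to 0-based
        df["pos2"] = df["pos2"].astype(np.int64) - 1
    else:
        df = df.astype({"pos1": np.int64, "pos2": np.int64})
    df = df[PAIRS_COLUMNS]
    return PairsTable.from_dataframe(df, genome, metadata=meta)


def write_pairs(table: PairsTable, path, genome: Genome = None):
    with open(path, "w") as fh:
        fh.write("## pairs format v1.0\n")
        fh.write("#columns: readID chrom1 pos1 chrom2 pos2 strand1 strand2\n")
        if genome is not None:
            for c in genome.chrom_names:
                fh.write(f"#chromsize: {c} {genome.chrom_lengths[c]}\n")
        if "genome_id" in table.metadata:
            fh.write(f"#genome: {table.metadata['genome_id']}\n")
        if "enzyme" in table.metadata:
            fh.write(f"#enzyme: {table.metadata['enzyme']}\n")
        df = table.records
        for row in df.itertuples(index=False):
            fh.write(
                f"{row.read_id}\t{row.chrom1}\t{row.pos1 + 1}\t{row.chrom2}\t"
                f"{row.pos2 + 1}\t{row.strand1}\t{row.strand2}\n"
            )


# ---------------------------------------------------------------------------
# contact matrices (sparse-triplet with a bin-table header; homer-style dense)


def write_matrix(matrix, path, dialect="sparse-triplet"):
    from .matrix import ContactMatrix  # local import to avoid a cycle

    assert isinstance(matrix, ContactMatrix)
    if dialect == "sparse-triplet":
        with open(path, "w") as fh:
            fh.write(f"#resolution\t{matrix.resolution}\n")
            for i, (chrom, start) in enumerate(
                matrix.bins[["chrom", "start"]].itertuples(index=False)
            ):
                fh.write(f"#bin\t{i}\t{chrom}\t{start}\n")
            coo = sp.triu(matrix.counts).tocoo()
            order = np.lexsort((coo.col, coo.row))
            for i, j, v in zip(coo.row[order], coo.col[order], coo.data[order]):
                fh.write(f"{i}\t{j}\t{v:.10g}\n")
    elif dialect == "homer-dense":
        dense = matrix.dense()
        names = [
            f"{c}-{s}" for c, s in matrix.bins[["chrom", "start"]].itertuples(index=False)
        ]
        with open(path, "w") as fh:
            fh.write("HiCMatrix\tRegions\t" + "\t".join(names) + "\n")
            for name, row in zip(names, dense):
                fh.write(name + "\t" + name + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_matrix(path, dialect="sparse-triplet"):
    from .matrix import ContactMatrix

    if dialect == "sparse-triplet":
        resolution = None
        bin_rows, data = [], []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                if line.startswith("#resolution"):
                    resolution = int(line.split("\t")[1])
                elif line.startswith("#bin"):
                    _, idx, chrom, start = line.split("\t")
                    bin_rows.append((int(idx), chrom, int(start)))
                else:
                    i, j, v = line.split("\t")
                    data.append((int(i), int(j), float(v)))
        if resolution is None or not bin_rows:
            raise FormatError("missing resolution or bin table header")
        bin_rows.sort()
        bins = pd.DataFrame(
            [(c, s) for _, c, s in bin_rows], columns=["chrom", "start"]
        )
        n = len(bins)
        if data:
            ii, jj, vv = map(np.array, zip(*data))
            if ii.max() >= n or jj.max() >= n:
                raise FormatError("bin index in body exceeds header bin table")
        else:
            ii = jj = np.array([], dtype=int)
            vv = np.array([], dtype=float)
        counts = sp.coo_matrix((vv, (ii, jj)), shape=(n, n)).tocsr()
        return ContactMatrix(resolution=resolution, bins=bins, counts=counts)
    elif dialect == "homer-dense":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            names = header[2:]
            rows = []
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                rows.append([float(x) for x in parts[2:]])
        dense = np.array(rows)
        if dense.shape[0] != dense.shape[1] or dense.shape[0] != len(names):
            raise FormatError("dimension mismatch between header and body")
        if not np.allclose(dense, dense.T):
            raise FormatError("matrix not symmetric")
        chroms, starts = zip(*(n.rsplit("-", 1) for n in names))
        bins = pd.DataFrame({"chrom": chroms, "start": [int(s) for s in starts]})
        resolution = _infer_resolution(bins)
        counts = sp.csr_matrix(np.triu(dense))
        return ContactMatrix(resolution=resolution, bins=bins, counts=counts)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def _infer_resolution(bins):
    starts = bins["start"].to_numpy()
    diffs = np.diff(starts)
    diffs = diffs[diffs > 0]
    return int(diffs.min()) if len(diffs) else int(starts.max() or 1)


# ---------------------------------------------------------------------------
# placements / AGP


@dataclass
class PlacementTable:
    """Per-contig placement: chromosome, insertion coordinate, rank, orientation."""

    table: pd.DataFrame
    # columns: contig, chrom, coord, rank, orientation [, score, runner_up, flags]

    COLUMNS = ["contig", "chrom", "coord", "rank", "orientation"]

    def __len__(self):
        return len(self.table)

    def to_tsv(self, path):
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path):
        return cls(pd.read_csv(path, sep="\t"))


def write_agp(placements: PlacementTable, path, genome: Genome, contig_lengths: dict):
    """Emit AGP v2.1 describing each chromosome as flank/contig/flank components.

    Coordinates are per the corrected object: each placed contig replaces N
    bases at its insertion point (up to its own length), so flanking segments
    keep their original sequence.
    """
    lines = ["##agp-version\t2.1"]
    df = placements.table.sort_values(["chrom", "coord"])
    for chrom, sub in df.groupby("chrom", sort=False):
        coords = sub["coord"].to_numpy()
        if len(np.unique(coords)) != len(coords):
            raise FormatError(f"overlapping placements on {chrom}")
        pos = 0  # 0-based cursor in the corrected object
        part = 1
        for row in sub.itertuples(index=False):
            clen = contig_lengths[row.contig]
            if row.coord > pos:
                lines.append(
                    f"{chrom}\t{pos + 1}\t{row.coord}\t{part}\tW\t{chrom}_frag\t"
                    f"{pos + 1}\t{row.coord}\t+"
                )
                part += 1
            lines.append(
                f"{chrom}\t{row.coord + 1}\t{row.coord + clen}\t{part}\tW\t"
                f"{row.contig}\t1\t{clen}\t{row.orientation}"
            )
            part += 1
            pos = row.coord + clen
        total = genome.chrom_lengths[chrom]
        if pos < total:
            lines.append(
                f"{chrom}\t{pos + 1}\t{total}\t{part}\tW\t{chrom}_frag\t"
                f"{pos + 1}\t{total}\t+"
            )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
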