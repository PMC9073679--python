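"""Synthetic genomes, chromatin tracks, Hi-C contacts and expression counts.

The generator emulates the statistical structure of a compact fungal genome
such as *Neurospora crassa*: a haploid multi-chromosome nuclear genome in
which AT-rich constitutive heterochromatin (centromeres, subtelomeres, and
smaller interspersed blocks, all marked by H3K9me3) covers a configurable
fraction of the genome — 15.76% by default — while GC-richer euchromatin
carries genes decorated with activating (H3K27ac, H3K4me3) or repressive
(ASH1-catalyzed H3K36me2, H3K27me2/3) marks.

Contacts are drawn from an explicit weight model: power-law distance decay
within chromosomes, compartment affinity (B-B heterochromatin bundling),
inter-chromosomal centromere and telomere clustering, optional planted
gene<->heterochromatin loops, and a restriction-site-density capture bias
that reproduces the enzyme asymmetry between a GATC cutter (euchromatin-
biased) and a TTAA cutter (heterochromatin-biased).

Every operation is a pure function of its inputs and an explicit seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import Genome, IntervalTrack, PairsTable, PlacementTable

__all__ = [
    "GenomeSpec",
    "ContactModel",
    "generate_genome",
    "restriction_map",
    "simulate_pairs",
    "scramble_assembly",
    "scramble_adjacent",
    "liftover_to_scrambled",
    "simulate_expression",
    "TELOMERE_UNIT",
]

TELOMERE_UNIT = "TTAGGG"
_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class GenomeSpec:
    """Layout parameters for one synthetic genome.

    het_fraction is the target genome fraction inside H3K9me3 blocks
    (centromere + subtelomeres + interspersed); at_content_* are the A+T
    fractions used to draw sequence inside/outside heterochromatin;
    gene_density is the expected number of genes per 10 kb of euchromatin.
    """

    n_chroms: int = 3
    chrom_length_bp: int = 2_000_000
    het_fraction: float = 0.1576
    het_block_size_range: tuple = (10_000, 60_000)
    centromere_size: int = 120_000
    subtelomere_size: int = 40_000
    at_content_eu: float = 0.45
    at_content_het: float = 0.70
    gene_density: float = 1.5  # genes per 10 kb of euchromatin
    gene_length_range: tuple = (1_000, 3_000)
    mark_assignment_probs: dict = field(
        default_factory=lambda: {
            "H3K27ac": 0.25,
            "H3K4me3": 0.25,
            "H3K36me2": 0.25,
            "H3K27me2me3": 0.15,
        }
    )
    n_telomere_repeats: int = 20
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.het_fraction < 1:
            raise ValueError("het_fraction must be in [0, 1)")
        for a in (self.at_content_eu, self.at_content_het):
            if not 0 < a < 1:
                raise ValueError("AT contents must be in (0, 1)")
        if self.het_block_size_range[1] >= self.chrom_length_bp:
            raise ValueError("het blocks must be smaller than a chromosome")
        if sum(self.mark_assignment_probs.values()) > 1 + 1e-9:
            raise ValueError("mark probabilities sum above 1")


@dataclass
class ContactModel:
    """Weight model for sampling Hi-C contacts.

    w(x, y) = decay(|x - y|) * compartment(x, y) * bundling(x, y)
              * capture(x) * capture(y)

    decay(s) = s^(-alpha) within a chromosome (s clamped at >= 1 kb, below
    which real valid-pair filters discard products anyway) and a constant
    baseline between chromosomes, scaled so the intra:inter pair ratio is
    about 4:1 at unit multipliers.  Compartment multipliers w_AA/w_BB/w_AB
    apply by the H3K9me3 status of the two loci; w_cen / w_tel multiply
    inter-chromosomal centromere-centromere / telomere-telomere pairs.
    capture() is (1 + local restriction-site count)^capture_exponent in a
    window around each end.
    """

    alpha: float = 1.0
    w_AA: float = 1.0
    w_BB: float = 4.0
    w_AB: float = 0.25
    w_cen: float = 8.0
    w_tel: float = 6.0
    capture_window: int = 500
    capture_exponent: float = 1.0
    planted_loops: list = field(default_factory=list)  # (gene_iv, het_iv, strength)
    pcr_at_depletion: float = 0.0  # per-PCR-cycle AT penalty; 0 disables
    pcr_cycles: int = 0
    intra_inter_ratio: float = 4.0
    seed: int = 0

    def __post_init__(self):
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        for w in (self.w_AA, self.w_BB, self.w_AB, self.w_cen, self.w_tel):
            if w <= 0:
                raise ValueError("multipliers must be > 0")
        if self.w_AB > min(self.w_AA, self.w_BB):
            raise ValueError("w_AB must not exceed min(w_AA, w_BB)")


# ---------------------------------------------------------------------------
# genome generation


def _draw_seq(rng, n, at_content):
    # split AT and GC evenly within their class
    p = np.array(
        [at_content / 2, (1 - at_content) / 2, (1 - at_content) / 2, at_content / 2]
    )
    return rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=n, p=p)


def generate_genome(spec: GenomeSpec):
    """Generate a synthetic genome and its chromatin annotation tracks.

    Returns (genome, tracks) where tracks maps
    {"H3K9me3", "CenH3", "H3K27me2me3", "genes", "H3K27ac", "H3K4me3",
    "H3K36me2", "interspersed_het"} to IntervalTracks.  Realized H3K9me3
    coverage lands within about +-2 percentage points of het_fraction;
    chromosome ends carry tandem telomere repeats (TTAGGG on the right end,
    its reverse complement on the left).
    """
    rng = np.random.default_rng(spec.seed)
    L = spec.chrom_length_bp
    tel_len = spec.n_telomere_repeats * len(TELOMERE_UNIT)
    fixed_het = spec.centromere_size + 2 * spec.subtelomere_size
    target_het = spec.het_fraction * L
    inter_needed = max(0.0, target_het - fixed_het)
    if fixed_het > L * 0.8:
        raise ValueError("centromere + subtelomeres do not fit in a chromosome")

    names = [f"chr{i+1}" for i in range(spec.n_chroms)]
    seqs = {}
    k9, cenh3, k27, genes_rows = [], [], [], []
    inter_blocks = []
    mark_rows = {m: [] for m in spec.mark_assignment_probs}
    gene_marks = {}

    for chrom in names:
        # fixed features
        cen_start = L // 2 - spec.centromere_size // 2
        cen = (cen_start, cen_start + spec.centromere_size)
        subtel_l = (0, spec.subtelomere_size)
        subtel_r = (L - spec.subtelomere_size, L)
        het = [iv for iv in (subtel_l, cen, subtel_r) if iv[1] > iv[0]]
        # interspersed blocks: place until this chromosome's share is met
        placed = 0.0
        attempts = 0
        guard = 40_000  # keep clear of fixed blocks
        while placed < inter_needed and attempts < 2000:
            attempts += 1
            size = int(rng.integers(*spec.het_block_size_range))
            remaining = inter_needed - placed
            if remaining < size:  # cap the last block to keep coverage on target
                size = int(max(spec.het_block_size_range[0], remaining))
            pos = int(rng.integers(subtel_l[1] + guard, subtel_r[0] - guard - size))
            cand = (pos, pos + size)
            if all(cand[1] + 5000 < s or cand[0] > e + 5000 for s, e in het):
                het.append(cand)
                inter_blocks.append((chrom, *cand))
                placed += size
        if placed < inter_needed - spec.het_block_size_range[1]:
            raise ValueError("interspersed heterochromatin blocks cannot fit")
        het.sort()
        k9.extend((chrom, s, e) for s, e in het)
        cenh3.append((chrom, *cen))
        if spec.subtelomere_size > 0:
            k27.extend([(chrom, *subtel_l), (chrom, *subtel_r)])

        # genes in euchromatin gaps between het blocks
        gaps = []
        prev = 0
        for s, e in het:
            if s - prev > 10_000:
                gaps.append((prev, s))
            prev = e
        if L - prev > 10_000:
            gaps.append((prev, L))
        gi = 0
        for gs, ge in gaps:
            n_genes = rng.poisson(spec.gene_density * (ge - gs) / 10_000)
            if n_genes == 0:
                continue
            starts = np.sort(rng.integers(gs, ge - spec.gene_length_range[1], n_genes))
            last_end = -1
            for s in starts:
                glen = int(rng.integers(*spec.gene_length_range))
                if s <= last_end + 200:
                    continue
                gene_id = f"{chrom}_g{gi:04d}"
                gi += 1
                genes_rows.append((chrom, int(s), int(s + glen), gene_id))
                last_end = s + glen
                u = rng.random()
                acc = 0.0
                mark = None
                for m, p in spec.mark_assignment_probs.items():
                    acc += p
                    if u < acc:
                        mark = m
                        break
                gene_marks[gene_id] = mark
                if mark is not None:
                    mark_rows[mark].append((chrom, int(s), int(s + glen)))

        # sequence: euchromatic base, het blocks overwritten, telomere ends
        arr = _draw_seq(rng, L, spec.at_content_eu)
        for s, e in het:
            arr[s:e] = _draw_seq(rng, e - s, spec.at_content_het)
        seq = arr.tobytes().decode()
        right_tel = TELOMERE_UNIT * spec.n_telomere_repeats
        left_tel = revcomp(right_tel)
        seq = left_tel + seq[tel_len : L - tel_len] + right_tel
        seqs[chrom] = seq

    # facultative heterochromatin also covers the H3K27me2me3-assigned genes
    k27.extend(mark_rows.get("H3K27me2me3", []))

    genome = Genome(
        chrom_names=names,
        chrom_lengths={c: L for c in names},
        sequences=seqs,
    )
    gene_df = pd.DataFrame(genes_rows, columns=["chrom", "start", "end", "gene_id"])
    tracks = {
        "H3K9me3": IntervalTrack.build(
            "H3K9me3", pd.DataFrame(k9, columns=["chrom", "start", "end"]), genome=genome
        ),
        "CenH3": IntervalTrack.build(
            "CenH3", pd.DataFrame(cenh3, columns=["chrom", "start", "end"]), genome=genome
        ),
        "H3K27me2me3": IntervalTrack.build(
            "H3K27me2me3", pd.DataFrame(k27, columns=["chrom", "start", "end"]), genome=genome
        ),
        "genes": IntervalTrack(
            "genes", gene_df.sort_values(["chrom", "start"]).reset_index(drop=True)
        ),
        "interspersed_het": IntervalTrack.build(
            "interspersed_het",
            pd.DataFrame(inter_blocks, columns=["chrom", "start", "end"]),
            genome=genome,
        )
        if inter_blocks
        else IntervalTrack("interspersed_het", pd.DataFrame(columns=["chrom", "start", "end"])),
    }
    for m, rows in mark_rows.items():
        # the combined facultative track (subtelomeres + K27 gene clusters)
        # already owns the plain H3K27me2me3 key
        if m in tracks:
            m, rows = m + "_genes", rows
        tracks[m] = (
            IntervalTrack.build(
                m, pd.DataFrame(rows, columns=["chrom", "start", "end"]), genome=genome
            )
            if rows
            else IntervalTrack(m, pd.DataFrame(columns=["chrom", "start", "end"]))
        )
    tracks["gene_marks"] = gene_marks
    return genome, tracks


# ---------------------------------------------------------------------------
# restriction sites


def restriction_map(genome: Genome, recognition_seq: str) -> IntervalTrack:
    """All exact occurrences of a recognition sequence across the genome.

    Reverse-complement-palindromic sequences (GATC, TTAA) need only the
    forward scan; other sequences are scanned on both strands and the site
    lists merged positionally.
    """
    if not recognition_seq:
        raise ValueError("empty recognition sequence")
    recognition_seq = recognition_seq.upper()
    if set(recognition_seq) - set("ACGT"):
        raise ValueError("recognition sequence must be over ACGT")
    if genome.sequences is None:
        raise ValueError("genome carries no sequences")
    patterns = {recognition_seq}
    if revcomp(recognition_seq) != recognition_seq:
        patterns.add(revcomp(recognition_seq))
    rows = []
    k = len(recognition_seq)
    for chrom in genome.chrom_names:
        seq = genome.sequences[chrom]
        hits = set()
        for pat in patterns:
            start = seq.find(pat)
            while start != -1:
                hits.add(start)
                start = seq.find(pat, start + 1)
        rows.extend((chrom, h, h + k) for h in sorted(hits))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    return IntervalTrack(f"sites_{recognition_seq}", df)


def _site_positions(sites: IntervalTrack, chrom):
    sub = sites.intervals[sites.intervals["chrom"] == chrom]
    return sub["start"].to_numpy()


# ---------------------------------------------------------------------------
# contact simulation


def _coverage_per_bin(track: IntervalTrack, genome: Genome, res: int) -> np.ndarray:
    """Covered-base count per simulation bin, concatenated over chromosomes."""
    out = []
    for chrom in genome.chrom_names:
        n = -(-genome.chrom_lengths[chrom] // res)
        cov = np.zeros(n)
        sub = track.intervals[track.intervals["chrom"] == chrom]
        for s, e in sub[["start", "end"]].itertuples(index=False):
            b0, b1 = s // res, (e - 1) // res
            if b0 == b1:
                cov[b0] += e - s
            else:
                cov[b0] += (b0 + 1) * res - s
                cov[b0 + 1 : b1] += res
                cov[b1] += e - b1 * res
        out.append(cov)
    return np.concatenate(out)


def simulate_pairs(
    genome: Genome,
    tracks: dict,
    model: ContactModel,
    enzymes,
    n_pairs: int,
    seed: int = None,
    sim_resolution: int = 5000,
) -> PairsTable:
    """Sample `n_pairs` contacts from the weight model.

    Loci are sampled at `sim_resolution` granularity: the genome is tiled
    into bins, a full bin-pair weight table is built from the model, bin
    pairs are drawn from it and exact positions drawn uniformly within each
    bin.  Enzyme capture bias enters through per-bin restriction-site counts
    (per-end (1 + density)^capture_exponent).  `enzymes` is one recognition
    sequence or a list (a list emulates a double digest).
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    seed = model.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    if isinstance(enzymes, str):
        enzymes = [enzymes]
    res = sim_resolution

    chroms, starts = [], []
    for chrom in genome.chrom_names:
        n = -(-genome.chrom_lengths[chrom] // res)
        chroms.extend([chrom] * n)
        starts.extend(i * res for i in range(n))
    starts = np.array(starts)
    chrom_arr = np.array(chroms)
    cid = pd.factorize(chrom_arr, sort=False)[0]
    n_bins = len(starts)
    lengths = np.array([genome.chrom_lengths[c] for c in chrom_arr])
    bin_end = np.minimum(starts + res, lengths)

    # per-bin annotation
    is_het = _coverage_per_bin(tracks["H3K9me3"], genome, res) / res >= 0.5
    is_cen = _coverage_per_bin(tracks["CenH3"], genome, res) / res >= 0.5
    tel_window = 50_000
    is_tel = np.zeros(n_bins, bool)
    for chrom in genome.chrom_names:
        m = chrom_arr == chrom
        is_tel |= m & (starts < tel_window)
        is_tel |= m & (starts >= genome.chrom_lengths[chrom] - tel_window)

    # capture weight: product over enzymes of (1 + sites in window)^exponent
    capture = np.ones(n_bins)
    for enz in enzymes:
        sites = restriction_map(genome, enz)
        if len(sites) == 0:
            raise ValueError(f"enzyme {enz!r} has zero sites in the genome")
        dens = _coverage_per_bin(sites, genome, res) / len(enz)  # sites per bin
        dens *= (2 * model.capture_window) / res  # sites within the capture window
        capture *= (1.0 + dens) ** model.capture_exponent
    if model.pcr_at_depletion > 0 and model.pcr_cycles > 0 and genome.sequences:
        at = np.array(
            [
                (genome.sequences[c][s : s + res].count("A")
                 + genome.sequences[c][s : s + res].count("T")) / max(1, min(res, genome.chrom_lengths[c] - s))
                for c, s in zip(chrom_arr, starts)
            ]
        )
        capture *= (1.0 - model.pcr_at_depletion * at) ** model.pcr_cycles

    # pairwise weight table (upper triangle incl. diagonal)
    mid = (starts + bin_end) / 2.0
    dist = np.abs(mid[:, None] - mid[None, :])
    same = cid[:, None] == cid[None, :]
    decay = np.where(same, np.maximum(dist, 1000.0) ** (-model.alpha), 0.0)
    # inter baseline scaled for ~intra_inter_ratio:1 intra:inter mass
    intra_mass = np.triu(decay, 1).sum()
    n_inter = int((~same).sum() // 2)
    baseline = intra_mass / (model.intra_inter_ratio * max(n_inter, 1))
    W = np.where(same, decay, baseline)

    comp = np.where(
        is_het[:, None] & is_het[None, :],
        model.w_BB,
        np.where(~is_het[:, None] & ~is_het[None, :], model.w_AA, model.w_AB),
    )
    W = W * comp
    bundle = np.ones_like(W)
    bundle[np.ix_(is_cen, is_cen)] *= model.w_cen
    bundle[np.ix_(is_tel, is_tel)] *= model.w_tel
    W = np.where(same, W, W * bundle)
    W *= capture[:, None] * capture[None, :]

    for gene_iv, het_iv, strength in model.planted_loops:
        gi = _bins_overlapping(gene_iv, chrom_arr, starts, bin_end)
        hi = _bins_overlapping(het_iv, chrom_arr, starts, bin_end)
        W[np.ix_(gi, hi)] *= strength
        W[np.ix_(hi, gi)] *= strength

    iu, ju = np.triu_indices(n_bins)
    w = W[iu, ju].astype(np.float64)
    w[iu == ju] *= 0.5  # diagonal pairs have half the ordered-pair multiplicity
    p = w / w.sum()
    draw = rng.choice(len(w), size=n_pairs, replace=True, p=p)
    b1, b2 = iu[draw], ju[draw]
    span1 = np.maximum(bin_end[b1] - starts[b1], 1)
    span2 = np.maximum(bin_end[b2] - starts[b2], 1)
    pos1 = starts[b1] + rng.integers(0, span1)
    pos2 = starts[b2] + rng.integers(0, span2)
    strands = np.array(["+", "-"])
    df = pd.DataFrame(
        {
            "read_id": [f"sim{i:08d}" for i in range(n_pairs)],
            "chrom1": chrom_arr[b1],
            "pos1": pos1,
            "chrom2": chrom_arr[b2],
            "pos2": pos2,
            "strand1": strands[rng.integers(0, 2, n_pairs)],
            "strand2": strands[rng.integers(0, 2, n_pairs)],
        }
    )
    meta = {"enzyme": "+".join(enzymes), "genome_id": "synthetic", "seed": seed}
    return PairsTable.from_dataframe(df, genome, metadata=meta)


def _bins_overlapping(iv, chrom_arr, starts, bin_end):
    chrom, s, e = iv
    return np.flatnonzero((chrom_arr == chrom) & (bin_end > s) & (starts < e))


# ---------------------------------------------------------------------------
# assembly scrambling (contig-placement truth construction)


def scramble_assembly(genome: Genome, tracks: dict, n_excise: int, seed: int = 0):
    """Excise heterochromatic blocks into unplaced contigs with known truth.

    Each excised segment is replaced in situ by an equal-length N-run; the
    removed sequence is emitted as a contig under a fresh name, reverse-
    complemented with probability 1/2.  Returns (scrambled genome, contig
    genome, truth PlacementTable).
    """
    rng = np.random.default_rng(seed)
    blocks = tracks["interspersed_het"].intervals
    if n_excise > len(blocks):
        raise ValueError(
            f"n_excise={n_excise} exceeds the {len(blocks)} available blocks"
        )
    if n_excise == 0:
        return genome, None, PlacementTable(
            pd.DataFrame(columns=PlacementTable.COLUMNS)
        )
    pick = rng.choice(len(blocks), size=n_excise, replace=False)
    chosen = blocks.iloc[np.sort(pick)]
    seqs = dict(genome.sequences)
    contig_seqs = {}
    rows = []
    rank_counter = {}
    for i, row in enumerate(chosen.itertuples(index=False)):
        chrom, s, e = row.chrom, int(row.start), int(row.end)
        name = f"contig_{i+1}"
        seg = seqs[chrom][s:e]
        orient = "+" if rng.random() < 0.5 else "-"
        contig_seqs[name] = seg if orient == "+" else revcomp(seg)
        seqs[chrom] = seqs[chrom][:s] + "N" * (e - s) + seqs[chrom][e:]
        rank = rank_counter.get(chrom, 0)
        rank_counter[chrom] = rank + 1
        rows.append((name, chrom, s, rank, orient))
    scrambled = Genome(
        chrom_names=list(genome.chrom_names),
        chrom_lengths=dict(genome.chrom_lengths),
        sequences=seqs,
        gap_runs=_recompute_gaps(seqs, genome.chrom_names),
        nonnuclear_names=set(genome.nonnuclear_names),
    )
    contigs = Genome(
        chrom_names=list(contig_seqs),
        chrom_lengths={k: len(v) for k, v in contig_seqs.items()},
        sequences=contig_seqs,
    )
    truth = PlacementTable(pd.DataFrame(rows, columns=PlacementTable.COLUMNS))
    return scrambled, contigs, truth


def scramble_adjacent(genome: Genome, tracks: dict, n_segments: int, seed: int = 0):
    """Split the largest interspersed heterochromatin block into `n_segments`
    adjacent segments and excise each as its own contig (truth ranks follow
    genomic order) — the well-posed scenario for contact-based ordering."""
    rng = np.random.default_rng(seed)
    blocks = tracks["interspersed_het"].intervals
    if blocks.empty:
        raise ValueError("no interspersed blocks available")
    sizes = blocks["end"] - blocks["start"]
    big = blocks.iloc[int(sizes.idxmax())]
    chrom, s, e = big["chrom"], int(big["start"]), int(big["end"])
    if (e - s) // n_segments < 1000:
        raise ValueError("largest block too small to split")
    edges = np.linspace(s, e, n_segments + 1).astype(int)
    seqs = dict(genome.sequences)
    contig_seqs = {}
    rows = []
    for i in range(n_segments):
        a, b = int(edges[i]), int(edges[i + 1])
        name = f"contig_{i+1}"
        seg = seqs[chrom][a:b]
        orient = "+" if rng.random() < 0.5 else "-"
        contig_seqs[name] = seg if orient == "+" else revcomp(seg)
        rows.append((name, chrom, a, i, orient))
    seqs[chrom] = seqs[chrom][:s] + "N" * (e - s) + seqs[chrom][e:]
    scrambled = Genome(
        chrom_names=list(genome.chrom_names),
        chrom_lengths=dict(genome.chrom_lengths),
        sequences=seqs,
        gap_runs=_recompute_gaps(seqs, genome.chrom_names),
        nonnuclear_names=set(genome.nonnuclear_names),
    )
    contigs = Genome(
        chrom_names=list(contig_seqs),
        chrom_lengths={k: len(v) for k, v in contig_seqs.items()},
        sequences=contig_seqs,
    )
    truth = PlacementTable(pd.DataFrame(rows, columns=PlacementTable.COLUMNS))
    return scrambled, contigs, truth


def liftover_to_scrambled(
    pairs: PairsTable,
    truth: PlacementTable,
    contigs: Genome,
    scrambled: Genome,
) -> PairsTable:
    """Re-express pairs simulated on the true genome against the scrambled
    assembly: mates falling inside an excised block move to the contig's own
    coordinate system (respecting its recorded orientation), everything else
    keeps its coordinate.  This mimics mapping reads from the real genome to
    an assembly in which those segments are unplaced contigs.
    """
    df = pairs.records.copy()
    combined = Genome(
        chrom_names=list(scrambled.chrom_names) + list(contigs.chrom_names),
        chrom_lengths={**scrambled.chrom_lengths, **contigs.chrom_lengths},
    )
    for side in ("1", "2"):
        chrom = df[f"chrom{side}"].to_numpy().astype(object)
        pos = df[f"pos{side}"].to_numpy().copy()
        for row in truth.table.itertuples(index=False):
            clen = contigs.chrom_lengths[row.contig]
            inside = (chrom == row.chrom) & (pos >= row.coord) & (pos < row.coord + clen)
            if not inside.any():
                continue
            off = pos[inside] - row.coord
            if row.orientation == "-":
                off = clen - 1 - off
            pos[inside] = off
            chrom[inside] = row.contig
        df[f"chrom{side}"] = chrom
        df[f"pos{side}"] = pos
    return PairsTable.from_dataframe(df, combined, metadata=dict(pairs.metadata))


def _recompute_gaps(seqs, names):
    import re

    runs = []
    for name in names:
        for m in re.finditer(r"N+", seqs[name]):
            runs.append((name, m.start(), m.end()))
    return runs


# ---------------------------------------------------------------------------
# expression simulation


def simulate_expression(
    tracks: dict,
    contacting_genes,
    fc: float = 4.0,
    n_genes_affected: int = 20,
    dispersion: float = 0.05,
    seed: int = 0,
    base_mean_range=(50, 2000),
):
    """Paired WT / heterochromatin-mutant counts with planted fold changes.

    Among `contacting_genes` (genes contacting H3K9me3 chromatin), affected
    genes carrying H3K27ac or H3K4me3 are down fc-fold in the mutant and
    affected genes carrying ASH1-style H3K36me2 are up fc-fold; everything
    else is unchanged.  Counts are negative-binomial with var = m + d m^2
    (Poisson at dispersion 0).  Returns (wt DataFrame, mut DataFrame,
    truth labels Series indexed by gene).
    """
    if fc <= 1:
        raise ValueError("fc must be > 1")
    rng = np.random.default_rng(seed)
    genes = tracks["genes"].intervals["gene_id"].tolist()
    marks = tracks["gene_marks"]
    missing = set(contacting_genes) - set(genes)
    if missing:
        raise ValueError(f"contacting genes not in gene track: {sorted(missing)[:5]}")
    eligible_down = [g for g in contacting_genes if marks.get(g) in ("H3K27ac", "H3K4me3")]
    eligible_up = [g for g in contacting_genes if marks.get(g) == "H3K36me2"]
    n_down = min(n_genes_affected // 2, len(eligible_down))
    n_up = min(n_genes_affected - n_down, len(eligible_up))
    down = set(rng.choice(eligible_down, n_down, replace=False)) if n_down else set()
    up = set(rng.choice(eligible_up, n_up, replace=False)) if n_up else set()

    base = rng.uniform(np.log(base_mean_range[0]), np.log(base_mean_range[1]), len(genes))
    wt_mean = np.exp(base)
    mut_mean = wt_mean.copy()
    labels = []
    for i, g in enumerate(genes):
        if g in down:
            mut_mean[i] = wt_mean[i] / fc
            labels.append("down")
        elif g in up:
            mut_mean[i] = wt_mean[i] * fc
            labels.append("up")
        else:
            labels.append("unchanged")

    def _draw(means):
        if dispersion <= 0:
            return rng.poisson(means)
        r = 1.0 / dispersion
        p = r / (r + means)
        return rng.negative_binomial(r, p)

    wt = pd.DataFrame({"gene": genes, "count": _draw(wt_mean)})
    mut = pd.DataFrame({"gene": genes, "count": _draw(mut_mean)})
    truth = pd.Series(labels, index=genes, name="label")
    return wt, mut, truth
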