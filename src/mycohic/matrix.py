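"""Contact-matrix construction, filtering, coarsening, balancing and comparison.

A :class:`ContactMatrix` holds binned symmetric contact counts at a fixed
resolution as a sparse upper triangle, together with the bin table mapping
bin index -> (chromosome, start).  Balancing uses Knight-Ruiz symmetric
diagonal scaling; distance normalization divides each entry by the mean
count at the same genomic separation (observed over expected).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import Genome, PairsTable

__all__ = [
    "ContactMatrix",
    "ExpectedProfile",
    "FilterReport",
    "filter_pairs",
    "build_matrix",
    "coarsen",
    "kr_balance",
    "expected_profile",
    "observed_over_expected",
    "log2_oe",
    "correlate",
    "log2_compare",
    "distance_decay_curve",
    "fit_decay_slope",
    "contacts_per_site",
]


@dataclass
class ContactMatrix:
    resolution: int
    bins: pd.DataFrame  # columns: chrom, start
    counts: sp.csr_matrix  # upper triangle, bin_i <= bin_j
    weights: np.ndarray | None = None
    mask: np.ndarray | None = None  # True = excluded bin
    provenance: dict = field(default_factory=dict)
    signed: bool = False  # True for log-ratio / log-O-E matrices

    def __post_init__(self):
        # either-triangle storage: lower-triangle entries fold into the upper
        # triangle (callers must not pass a full symmetric matrix, which
        # would double off-diagonal mass)
        lower = sp.tril(self.counts, -1)
        self.counts = (sp.triu(self.counts) + lower.T).tocsr()
        if not self.signed and self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("negative contact counts")

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    @property
    def chrom_ids(self) -> np.ndarray:
        """Integer chromosome id per bin (in bin-table order)."""
        codes, _ = pd.factorize(self.bins["chrom"], sort=False)
        return codes

    def total(self) -> float:
        return float(self.counts.sum())

    def dense(self) -> np.ndarray:
        """Full symmetric dense matrix (diagonal counted once)."""
        u = self.counts.toarray()
        return u + u.T - np.diag(np.diag(u))

    def symmetric(self) -> sp.csr_matrix:
        u = self.counts
        d = sp.diags(u.diagonal())
        return (u + u.T - d).tocsr()

    def same_bins(self, other: "ContactMatrix") -> bool:
        return self.resolution == other.resolution and self.bins[
            ["chrom", "start"]
        ].equals(other.bins[["chrom", "start"]])

    def balanced(self) -> "ContactMatrix":
        """Matrix with counts replaced by diag(w) C diag(w)."""
        if self.weights is None:
            raise ValueError("matrix has no balancing weights")
        w = sp.diags(self.weights)
        return replace(self, counts=(w @ self.counts @ w).tocsr(), weights=None)


def bin_table(genome: Genome, resolution: int) -> pd.DataFrame:
    rows = []
    for chrom in genome.chrom_names:
        n = -(-genome.chrom_lengths[chrom] // resolution)
        rows.extend((chrom, i * resolution) for i in range(n))
    return pd.DataFrame(rows, columns=["chrom", "start"])


@dataclass
class FilterReport:
    n_input: int
    n_duplicates: int
    n_short_range: int
    n_output: int
    frac_nonnuclear: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])


def filter_pairs(pairs: PairsTable, min_separation=1000, dedup=True, genome: Genome = None):
    """Remove exact-coordinate duplicates and short-range intra-chromosomal pairs.

    Returns the filtered table and a QC report that also states the fraction
    of input records touching a non-nuclear chromosome (organellar-ligation
    QC; near zero in a clean in situ library).
    """
    df = pairs.records
    n_in = len(df)
    nonnuc = 0.0
    if genome is not None and genome.nonnuclear_names and n_in:
        touch = df["chrom1"].isin(genome.nonnuclear_names) | df["chrom2"].isin(
            genome.nonnuclear_names
        )
        nonnuc = float(touch.mean())
    n_dup = 0
    if dedup and n_in:
        keep = ~df.duplicated(
            subset=["chrom1", "pos1", "strand1", "chrom2", "pos2", "strand2"]
        )
        n_dup = int((~keep).sum())
        df = df[keep]
    n_short = 0
    if min_separation and len(df):
        short = (df["chrom1"] == df["chrom2"]) & (
            (df["pos2"] - df["pos1"]).abs() < min_separation
        )
        n_short = int(short.sum())
        df = df[~short]
    report = FilterReport(n_in, n_dup, n_short, len(df), nonnuc)
    out = PairsTable(df.reset_index(drop=True), dict(pairs.metadata))
    out.metadata.setdefault("filters", []).append(
        {"min_separation": min_separation, "dedup": dedup}
    )
    return out, report


def build_matrix(pairs: PairsTable, genome: Genome, resolution: int) -> ContactMatrix:
    """Bin canonical pairs into a symmetric contact matrix.

    Each record increments exactly one bin pair by 1; the bin of a mate is
    floor(pos / resolution) of its 5' position, so total matrix mass equals
    the number of records.
    """
    if resolution < 1:
        raise ValueError("resolution must be >= 1")
    if resolution > max(genome.chrom_lengths.values()):
        raise ValueError("resolution larger than the longest chromosome")
    bins = bin_table(genome, resolution)
    offsets = {}
    off = 0
    for chrom in genome.chrom_names:
        offsets[chrom] = off
        off += -(-genome.chrom_lengths[chrom] // resolution)
    df = pairs.records
    n = len(bins)
    if len(df):
        b1 = df["chrom1"].map(offsets).to_numpy() + df["pos1"].to_numpy() // resolution
        b2 = df["chrom2"].map(offsets).to_numpy() + df["pos2"].to_numpy() // resolution
        lo = np.minimum(b1, b2)
        hi = np.maximum(b1, b2)
        counts = sp.coo_matrix(
            (np.ones(len(df)), (lo, hi)), shape=(n, n)
        ).tocsr()
    else:
        counts = sp.csr_matrix((n, n))
    prov = {"resolution": resolution, **{k: v for k, v in pairs.metadata.items()}}
    return ContactMatrix(resolution=resolution, bins=bins, counts=counts, provenance=prov)


def coarsen(matrix: ContactMatrix, factor: int) -> ContactMatrix:
    """Merge bins per chromosome in runs of `factor`; counts are summed."""
    if factor < 2:
        raise ValueError("factor must be >= 2")
    chrom_ids = matrix.chrom_ids
    new_index = np.empty(matrix.n_bins, dtype=np.int64)
    new_rows = []
    nxt = 0
    for cid in np.unique(chrom_ids):
        idx = np.flatnonzero(chrom_ids == cid)
        groups = np.arange(len(idx)) // factor
        new_index[idx] = nxt + groups
        chrom = matrix.bins["chrom"].iloc[idx[0]]
        for g in range(groups[-1] + 1):
            start = matrix.bins["start"].iloc[idx[g * factor]]
            new_rows.append((chrom, start))
        nxt += groups[-1] + 1
    n_new = nxt
    coo = matrix.counts.tocoo()
    ri = new_index[coo.row]
    ci = new_index[coo.col]
    lo = np.minimum(ri, ci)
    hi = np.maximum(ri, ci)
    new_counts = sp.coo_matrix((coo.data, (lo, hi)), shape=(n_new, n_new))
    bins = pd.DataFrame(new_rows, columns=["chrom", "start"])
    return ContactMatrix(
        resolution=matrix.resolution * factor,
        bins=bins,
        counts=new_counts.tocsr(),
        provenance=dict(matrix.provenance),
    )


# ---------------------------------------------------------------------------
# Knight-Ruiz balancing


def default_mask(matrix: ContactMatrix, percentile=2.0) -> np.ndarray:
    """Exclude zero-marginal bins and bins below the given percentile of
    nonzero marginals (standard sparse-bin filtering)."""
    marg = np.asarray(matrix.symmetric().sum(axis=1)).ravel()
    mask = marg == 0
    nz = marg[~mask]
    if len(nz):
        thr = np.percentile(nz, percentile)
        mask |= marg < thr
    return mask


def kr_balance(
    matrix: ContactMatrix,
    mask_rule=default_mask,
    tol=1e-6,
    max_outer=1000,
) -> ContactMatrix:
    """Knight-Ruiz symmetric diagonal scaling.

    Finds per-bin weights w so that diag(w) C diag(w) has equal row sums over
    unmasked bins (within `tol`, relative).  Newton-style inner iterations
    with an alternating-scaling (Sinkhorn) fallback after max_outer/2 outer
    steps; masked bins get weight 0.
    """
    mask = mask_rule(matrix) if callable(mask_rule) else np.asarray(mask_rule, bool)
    if mask.all():
        raise ValueError("all bins masked; cannot balance")
    keep = ~mask
    A = matrix.symmetric()[np.ix_(keep, keep)].tocsr()
    n = A.shape[0]
    if np.asarray(A.sum(axis=1)).ravel().min() <= 0:
        raise ValueError("masked matrix still has a zero row; tighten mask_rule")

    x, iters, converged = _kr_newton(A, tol=tol, max_iter=max_outer // 2)
    if not converged:
        x, it2, converged = _sinkhorn(A, tol=tol, max_iter=max_outer, x0=x)
        iters += it2
    if not converged:
        raise RuntimeError(
            f"KR balancing did not converge in {iters} iterations "
            f"(residual row-sum spread above tol={tol})"
        )
    # scale so balanced row sums equal the mean raw row sum
    target = float(np.asarray(A.sum(axis=1)).ravel().mean())
    x = x * np.sqrt(target)
    weights = np.zeros(matrix.n_bins)
    weights[keep] = x
    return replace(matrix, weights=weights, mask=mask)


def _kr_newton(A, tol, max_iter, delta=0.1, Delta=3.0):
    """Knight-Ruiz inner-outer Newton iteration (CG inner solves via matvec)."""
    n = A.shape[0]
    e = np.ones(n)
    x = e.copy()
    g = 0.9
    etamax = 0.1
    eta = etamax
    stop_tol = tol * 0.5
    v = x * (A @ x)
    rk = 1 - v
    rho_km1 = rk @ rk
    rout = rho_km1
    rold = rout
    it = 0
    MVP = 0
    while rout > stop_tol**2 * n and it < max_iter:
        it += 1
        k = 0
        y = e.copy()
        innertol = max(eta**2 * rout, (tol * 0.5) ** 2 * n)
        rho_km1 = rk @ rk
        while rho_km1 > innertol:
            k += 1
            if k == 1:
                Z = rk / v
                p = Z.copy()
                rho_km1 = rk @ Z
            else:
                beta = rho_km1 / rho_km2
                p = Z + beta * p
            w = x * (A @ (x * p)) + v * p
            alpha = rho_km1 / (p @ w)
            ap = alpha * p
            ynew = y + ap
            if ynew.min() <= delta:
                if delta == 0:
                    break
                ind = ap < 0
                gamma = ((delta - y[ind]) / ap[ind]).min()
                y = y + gamma * ap
                break
            if ynew.max() >= Delta:
                ind = ynew > Delta
                gamma = ((Delta - y[ind]) / ap[ind]).min()
                y = y + gamma * ap
                break
            y = ynew
            rk = rk - alpha * w
            rho_km2 = rho_km1
            Z = rk / v
            rho_km1 = rk @ Z
            if k > 200:
                break
        x = x * y
        v = x * (A @ x)
        rk = 1 - v
        rho_km1 = rk @ rk
        rout = rho_km1
        MVP += k + 1
        rat = rout / rold
        rold = rout
        res_norm = np.sqrt(rout)
        eta = g * rat
        eta = max(min(eta, etamax), stop_tol / (2 * res_norm + 1e-300))
        if MVP > 50000:
            break
    rows = x * (A @ x)
    converged = _rowsum_spread(rows) < tol
    return x, it, converged


def _sinkhorn(A, tol, max_iter, x0=None):
    """Alternating-scaling fallback: x <- sqrt(x / (A x)) style updates."""
    n = A.shape[0]
    x = np.ones(n) if x0 is None else x0.copy()
    for it in range(1, max_iter + 1):
        r = x * (A @ x)
        if _rowsum_spread(r) < tol:
            return x, it, True
        x = x / np.sqrt(r)
    r = x * (A @ x)
    return x, max_iter, _rowsum_spread(r) < tol


def _rowsum_spread(rows):
    m = rows.mean()
    return np.abs(rows - m).max() / m if m > 0 else np.inf


# ---------------------------------------------------------------------------
# expected profile and O/E


@dataclass
class ExpectedProfile:
    distances: np.ndarray  # bp, ascending
    values: np.ndarray  # e(d) >= 0
    inter_expected: float

    def lookup(self, dist_bp):
        idx = np.searchsorted(self.distances, dist_bp)
        out = np.zeros(np.shape(idx), dtype=float)
        ok = (idx < len(self.distances)) & (
            self.distances[np.minimum(idx, len(self.distances) - 1)] == dist_bp
        )
        out[ok] = self.values[idx[ok]]
        return out


def expected_profile(matrix: ContactMatrix) -> ExpectedProfile:
    """Mean count per intra-chromosomal diagonal, pooled genome-wide, plus a
    scalar inter-chromosomal expectation."""
    chrom_ids = matrix.chrom_ids
    coo = matrix.counts.tocoo()
    intra = chrom_ids[coo.row] == chrom_ids[coo.col]
    d = coo.col[intra] - coo.row[intra]
    sums = np.bincount(d, weights=coo.data[intra])
    # number of possible intra pairs at each bin distance
    _, chrom_sizes = np.unique(chrom_ids, return_counts=True)
    max_d = chrom_sizes.max()
    npairs = np.zeros(max_d, dtype=np.int64)
    for size in chrom_sizes:
        ds = np.arange(size)
        npairs[: size] += size - ds
    if len(sums) < max_d:
        sums = np.pad(sums, (0, max_d - len(sums)))
    values = np.divide(sums[:max_d], npairs, out=np.zeros(max_d), where=npairs > 0)
    n_total_pairs = matrix.n_bins * (matrix.n_bins + 1) // 2
    n_intra_pairs = int(npairs.sum())
    n_inter = n_total_pairs - n_intra_pairs
    inter_sum = float(coo.data[~intra].sum())
    inter_expected = inter_sum / n_inter if n_inter else 0.0
    return ExpectedProfile(
        distances=np.arange(max_d) * matrix.resolution,
        values=values,
        inter_expected=inter_expected,
    )


def observed_over_expected(
    matrix: ContactMatrix, profile: ExpectedProfile = None
) -> ContactMatrix:
    """Divide each entry by its distance expectation (O/E); entries whose
    expectation is zero become zero."""
    if profile is None:
        profile = expected_profile(matrix)
    chrom_ids = matrix.chrom_ids
    coo = matrix.counts.tocoo()
    vals = coo.data.astype(float).copy()
    intra = chrom_ids[coo.row] == chrom_ids[coo.col]
    d = (coo.col[intra] - coo.row[intra]).astype(np.int64)
    e = profile.values[d]
    vi = np.zeros(intra.sum())
    np.divide(vals[intra], e, out=vi, where=e > 0)
    vals[intra] = vi
    if profile.inter_expected > 0:
        vals[~intra] = vals[~intra] / profile.inter_expected
    else:
        vals[~intra] = 0.0
    counts = sp.coo_matrix((vals, (coo.row, coo.col)), shape=coo.shape).tocsr()
    out = replace(matrix, counts=counts)
    out.provenance = {**matrix.provenance, "normalized": "observed/expected"}
    return out


def log2_oe(oe: ContactMatrix, pseudocount=None) -> ContactMatrix:
    """log2(O/E + c) - log2(1 + c) style transform stored densely-sparse:
    only stored (nonzero O/E) entries are transformed; c defaults to a small
    scale-free pseudocount of 1/n_bins."""
    c = pseudocount if pseudocount is not None else 1.0 / max(oe.n_bins, 1)
    coo = oe.counts.tocoo()
    vals = np.log2(coo.data + c)
    counts = sp.coo_matrix((vals, (coo.row, coo.col)), shape=coo.shape).tocsr()
    out = replace(oe, counts=counts, signed=True)
    out.provenance = {**oe.provenance, "transform": f"log2(x+{c:g})"}
    return out


# ---------------------------------------------------------------------------
# matrix comparison


def correlate(
    matA: ContactMatrix,
    matB: ContactMatrix,
    transform="log1p",
    min_dist=0,
    max_dist=None,
) -> float:
    """Pearson r between two matrices on the union of their nonzero supports,
    restricted to bin pairs within [min_dist, max_dist] genomic separation
    (inter-chromosomal pairs are included unless a distance window is set)."""
    if not matA.same_bins(matB):
        raise ValueError("bin tables differ")
    support = ((matA.counts != 0) + (matB.counts != 0)).tocoo()
    rows, cols = support.row, support.col
    chrom_ids = matA.chrom_ids
    intra = chrom_ids[rows] == chrom_ids[cols]
    dist = (cols - rows) * matA.resolution
    keep = np.ones(len(rows), bool)
    if min_dist:
        keep &= ~intra | (dist >= min_dist)
    if max_dist is not None:
        keep &= intra & (dist <= max_dist)
    rows, cols = rows[keep], cols[keep]
    a = np.asarray(matA.counts[rows, cols]).ravel()
    b = np.asarray(matB.counts[rows, cols]).ravel()
    if transform == "log1p":
        a, b = np.log1p(a), np.log1p(b)
    elif transform is not None and transform != "identity":
        a, b = transform(a), transform(b)
    if len(a) < 2 or a.std() == 0 or b.std() == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def log2_compare(
    matA: ContactMatrix, matB: ContactMatrix, depth_normalize=True, eps=None
) -> ContactMatrix:
    """Entrywise signed log2 ratio log2((a/sA + eps)/(b/sB + eps)) on the
    union of nonzero supports; sA, sB are total masses when depth_normalize."""
    if not matA.same_bins(matB):
        raise ValueError("bin tables differ")
    sA = matA.total() if depth_normalize else 1.0
    sB = matB.total() if depth_normalize else 1.0
    if eps is None:
        eps = 1.0 / max(sA, sB, 1.0)
    support = ((matA.counts != 0) + (matB.counts != 0)).tocoo()
    rows, cols = support.row, support.col
    a = np.asarray(matA.counts[rows, cols]).ravel() / sA
    b = np.asarray(matB.counts[rows, cols]).ravel() / sB
    vals = np.log2((a + eps) / (b + eps))
    counts = sp.coo_matrix((vals, (rows, cols)), shape=support.shape)
    out = ContactMatrix(
        resolution=matA.resolution,
        bins=matA.bins,
        counts=counts.tocsr(),
        provenance={"comparison": "log2_ratio", "depth_normalize": depth_normalize},
        signed=True,
    )
    return out


def distance_decay_curve(matrix: ContactMatrix, log_bins=False, n_log_bins=30):
    """Table of (distance, mean count) over intra-chromosomal diagonals."""
    prof = expected_profile(matrix)
    df = pd.DataFrame({"distance": prof.distances, "mean_count": prof.values})
    df = df[df["distance"] > 0]
    if log_bins:
        lo = max(df["distance"].min(), matrix.resolution)
        hi = df["distance"].max()
        edges = np.geomspace(lo, hi + 1, n_log_bins + 1)
        grp = np.digitize(df["distance"], edges)
        df = (
            df.assign(_g=grp)
            .groupby("_g")
            .agg(distance=("distance", "mean"), mean_count=("mean_count", "mean"))
            .reset_index(drop=True)
        )
    return df.reset_index(drop=True)


def fit_decay_slope(curve: pd.DataFrame, min_dist=None, max_dist=None) -> float:
    """Slope of log10(mean count) vs log10(distance) by least squares."""
    df = curve[(curve["mean_count"] > 0) & (curve["distance"] > 0)]
    if min_dist is not None:
        df = df[df["distance"] >= min_dist]
    if max_dist is not None:
        df = df[df["distance"] <= max_dist]
    x = np.log10(df["distance"].to_numpy())
    y = np.log10(df["mean_count"].to_numpy())
    slope, _ = np.polyfit(x, y, 1)
    return float(slope)


def contacts_per_site(n_valid_pairs: int, n_sites: int) -> float:
    """Mean Hi-C contacts per restriction site (display rounds to nearest int)."""
    if n_sites <= 0:
        raise ValueError("n_sites must be > 0")
    return n_valid_pairs / n_sites
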