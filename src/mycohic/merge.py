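"""Chromatin-composition-weighted merging of enzyme-specific contact datasets.

A GATC-cutter Hi-C library over-samples euchromatin and a TTAA-cutter
library over-samples AT-rich heterochromatin.  To build one dataset that
represents the genome's chromatin composition, reads are merged at the
valid-pair level in proportion to the genome fraction covered by H3K9me3
(the heterochromatin share): merge-then-build, never build-then-merge,
because averaging balanced matrices introduces bias that raw-count
addition does not.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import Genome, IntervalTrack, PairsTable

__all__ = [
    "MergeQuota",
    "coverage_fraction",
    "compute_quotas",
    "subsample_pairs",
    "merge_pairs",
]


@dataclass
class MergeQuota:
    het_fraction: float
    per_dataset_valid_counts: dict  # class -> available valid pairs
    quota_per_dataset: dict  # class -> pairs to take
    seed: int = 0

    def __post_init__(self):
        for k, q in self.quota_per_dataset.items():
            if q > self.per_dataset_valid_counts.get(k, 0):
                raise ValueError(f"quota for {k!r} exceeds available count")

    @property
    def total(self):
        return sum(self.quota_per_dataset.values())


def coverage_fraction(track: IntervalTrack, genome: Genome) -> float:
    """Fraction of the nuclear genome covered by a merged interval track:
    sum of (end - start) over the genome length, organellar chromosomes
    excluded from both numerator and denominator."""
    denom = genome.nuclear_length()
    if denom == 0:
        raise ValueError("empty genome")
    covered = track.total_bases(exclude_chroms=genome.nonnuclear_names)
    return covered / denom


def compute_quotas(
    valid_counts: dict, het_fraction: float, total: int = None, seed: int = 0
) -> MergeQuota:
    """Reads to take from the euchromatin-enzyme and heterochromatin-enzyme
    classes so the merge carries `het_fraction` heterochromatin-derived pairs.

    valid_counts maps {"eu": n, "het": n}.  With `total` given, quotas are
    total*(1-f, f) apportioned by largest remainder so they sum exactly to
    total; otherwise the limiting class anchors (quota_het =
    f/(1-f) * available_eu, or the symmetric form), capped at availability.
    """
    f = het_fraction
    avail_eu = valid_counts["eu"]
    avail_het = valid_counts["het"]
    if total is not None:
        raw = np.array([total * (1 - f), total * f])
        floors = np.floor(raw).astype(np.int64)
        rem = total - floors.sum()
        order = np.argsort(-(raw - floors))
        floors[order[:rem]] += 1
        q_eu, q_het = int(floors[0]), int(floors[1])
        if q_eu > avail_eu or q_het > avail_het:
            raise ValueError("requested total over-subscribes an available class")
    else:
        # anchor on whichever class limits the achievable total
        q_het_if_eu_anchor = int(round(f / (1 - f) * avail_eu))
        if q_het_if_eu_anchor <= avail_het:
            q_eu, q_het = avail_eu, q_het_if_eu_anchor
        else:
            q_eu, q_het = int(round((1 - f) / f * avail_het)), avail_het
        if q_eu > avail_eu:
            raise ValueError("both classes over-subscribed; infeasible fraction")
    return MergeQuota(
        het_fraction=f,
        per_dataset_valid_counts=dict(valid_counts),
        quota_per_dataset={"eu": q_eu, "het": q_het},
        seed=seed,
    )


def subsample_pairs(pairs: PairsTable, n: int, seed: int = 0) -> PairsTable:
    """Uniform sample of n records without replacement, deterministic under
    seed, returned in canonical (input) row order."""
    if n > len(pairs):
        raise ValueError(f"cannot sample {n} from {len(pairs)} records")
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(len(pairs), size=n, replace=False))
    return PairsTable(pairs.records.iloc[idx].reset_index(drop=True), dict(pairs.metadata))


def merge_pairs(*tables: PairsTable, classes=None) -> PairsTable:
    """Concatenate valid-pair tables (same genome), tagging each record with
    its source class so provenance survives into the matrix."""
    if not tables:
        raise ValueError("nothing to merge")
    gids = {t.metadata.get("genome_id") for t in tables if t.metadata.get("genome_id")}
    if len(gids) > 1:
        raise ValueError(f"genome mismatch across tables: {sorted(gids)}")
    if classes is None:
        classes = [t.metadata.get("enzyme", f"class{i}") for i, t in enumerate(tables)]
    frames = []
    for t, cls in zip(tables, classes):
        df = t.records.copy()
        df["source_class"] = cls
        frames.append(df)
    merged = pd.concat(frames, ignore_index=True)
    meta = {
        "genome_id": next(iter(gids)) if gids else None,
        "merged_from": {cls: len(t) for t, cls in zip(tables, classes)},
    }
    return PairsTable(merged, meta)
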