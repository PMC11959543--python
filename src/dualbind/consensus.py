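"""Replicate consensus peak building and occupancy normalization.

Summits are extended to fixed-width regions, close summits within a
dataset are merged, cross-replicate support (including a narrow-peak
fallback) defines the consensus, and per-sample occupancy is scaled by
the 90th percentile of that sample's RPKM distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from dualbind.intervals import (
    GenomicRegion,
    RegionSet,
    _OverlapIndex,
    merge_regions,
)

__all__ = [
    "OccupancyMatrix",
    "extend_summits",
    "merge_close_summits",
    "consensus_two_reps",
    "consensus_min_overlap",
    "normalize_occupancy",
]


@dataclass
class OccupancyMatrix:
    """Regions x samples occupancy with per-sample P90-scaled values.

    ``normalized[i, s] = rpkm[i, s] / P90(s)`` where P90 is the linearly
    interpolated 90th percentile of sample s over all regions.
    """

    rpkm: pd.DataFrame
    normalized: pd.DataFrame
    p90: pd.Series
    sample_meta: pd.DataFrame | None = None

    @property
    def regions(self) -> pd.Index:
        return self.rpkm.index

    @property
    def samples(self) -> pd.Index:
        return self.rpkm.columns


def extend_summits(
    summits: RegionSet,
    flank: int = 100,
    chrom_sizes: dict[str, int] | None = None,
) -> RegionSet:
    """Extend each summit to ``[summit-flank, summit+flank)``.

    Regions are truncated at chromosome edges (position 0 and, when
    ``chrom_sizes`` is given, the chromosome length) with a warning.
    """
    if flank <= 0:
        raise ValueError("flank must be positive")
    out = []
    truncated = 0
    for r in summits:
        if r.summit is None:
            raise ValueError(f"region {r.name or r.key()} has no summit")
        start = r.summit - flank
        end = r.summit + flank
        if start < 0:
            start = 0
            truncated += 1
        if chrom_sizes is not None and r.chrom in chrom_sizes:
            size = chrom_sizes[r.chrom]
            if end > size:
                end = size
                truncated += 1
        out.append(
            GenomicRegion(r.chrom, start, end, summit=r.summit, name=r.name,
                          score=r.score, summit_imputed=r.summit_imputed)
        )
    if truncated:
        warnings.warn(f"{truncated} region(s) truncated at chromosome edges")
    return RegionSet(out, summits.genome_id, f"extend_summits(flank={flank})")


def merge_close_summits(rs: RegionSet, min_dist: int = 200, flank: int = 100) -> RegionSet:
    """Merge summits of one dataset closer than ``min_dist`` bp.

    Summits are processed left to right per chromosome: whenever the next
    summit is < min_dist from the current one, the pair merges and the new
    summit is the (floor) midpoint of the two; the merged region is
    re-derived as summit +/- flank.  Iteration continues until no pair
    violates the rule; since midpoints only move rightward the result is
    deterministic and idempotent.
    """
    out = []
    for chrom, regs in sorted(rs.by_chrom().items()):
        for r in regs:
            if r.summit is None:
                raise ValueError(f"region {r.name or r.key()} has no summit")
        regs = sorted(regs, key=lambda r: r.summit)
        cur = regs[0].summit
        names = [regs[0].name] if regs[0].name else []
        for r in regs[1:]:
            if r.summit - cur < min_dist:
                cur = (cur + r.summit) // 2
                if r.name:
                    names.append(r.name)
            else:
                out.append(_summit_region(chrom, cur, flank, names))
                cur = r.summit
                names = [r.name] if r.name else []
        out.append(_summit_region(chrom, cur, flank, names))
    return RegionSet(out, rs.genome_id, f"merge_close_summits(min_dist={min_dist})")


def _summit_region(chrom: str, summit: int, flank: int, names: list) -> GenomicRegion:
    return GenomicRegion(
        chrom, max(0, summit - flank), summit + flank, summit=summit,
        name=",".join(names) if names else None,
    )


def consensus_two_reps(
    rep1: RegionSet,
    rep2: RegionSet,
    rep1_narrow: RegionSet | None = None,
    rep2_narrow: RegionSet | None = None,
) -> tuple[RegionSet, dict[tuple, str]]:
    """Two-replicate consensus with narrow-peak fallback.

    A rep1 summit region qualifies if it overlaps (>=1 bp) a rep2 summit
    region, or — fallback — a rep2 narrow peak; symmetrically for rep2.
    The consensus is the merged union of qualifying regions.  The second
    return value maps each qualifying region's key to the rule that
    admitted it ("summit" or "narrow").
    """
    idx2 = _OverlapIndex(rep2)
    idx1 = _OverlapIndex(rep1)
    idx2n = _OverlapIndex(rep2_narrow) if rep2_narrow is not None else None
    idx1n = _OverlapIndex(rep1_narrow) if rep1_narrow is not None else None

    qualifying = []
    admissions: dict[tuple, str] = {}
    for r in rep1:
        if idx2.overlaps(r):
            qualifying.append(r)
            admissions[r.key()] = "summit"
        elif idx2n is not None and idx2n.overlaps(r):
            qualifying.append(r)
            admissions[r.key()] = "narrow"
    for r in rep2:
        if idx1.overlaps(r):
            qualifying.append(r)
            admissions[r.key()] = "summit"
        elif idx1n is not None and idx1n.overlaps(r):
            qualifying.append(r)
            admissions[r.key()] = "narrow"
    if not qualifying:
        return RegionSet([], rep1.genome_id, "consensus_two_reps"), admissions
    consensus = merge_regions(RegionSet(qualifying, rep1.genome_id).canonicalize())
    consensus.provenance = "consensus_two_reps"
    return consensus, admissions


def consensus_min_overlap(reps: list[RegionSet], min_overlap: int) -> RegionSet:
    """Merged envelopes supported by >= ``min_overlap`` replicate sets.

    Support means >=1 bp overlap between the candidate envelope (built by
    merging the union of all replicate regions) and any region of that
    replicate set.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    if min_overlap > len(reps):
        raise ValueError(f"min_overlap {min_overlap} exceeds {len(reps)} replicates")
    pooled = RegionSet(
        [r for rep in reps for r in rep.regions], reps[0].genome_id
    ).canonicalize()
    if not len(pooled):
        return RegionSet([], provenance=f"consensus_min_overlap({min_overlap})")
    envelopes = merge_regions(pooled)
    indexes = [_OverlapIndex(rep) for rep in reps]
    kept = [
        env for env in envelopes
        if sum(ix.overlaps(env) for ix in indexes) >= min_overlap
    ]
    return RegionSet(kept, reps[0].genome_id, f"consensus_min_overlap({min_overlap})")


def normalize_occupancy(
    rpkm: pd.DataFrame, sample_meta: pd.DataFrame | None = None
) -> OccupancyMatrix:
    """Scale each sample by its 90th percentile (linear interpolation).

    Requires >= 10 regions and strictly positive P90 per sample.
    """
    if rpkm.shape[0] < 10:
        raise ValueError("need at least 10 regions for percentile normalization")
    if (rpkm.values < 0).any():
        raise ValueError("rpkm values must be non-negative")
    p90 = rpkm.apply(lambda col: float(np.percentile(col, 90)), axis=0)
    if (p90 <= 0).any():
        bad = list(p90.index[p90 <= 0])
        raise ValueError(f"degenerate dataset: P90 == 0 for sample(s) {bad}")
    normalized = rpkm / p90
    return OccupancyMatrix(rpkm=rpkm, normalized=normalized, p90=p90, sample_meta=sample_meta)
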