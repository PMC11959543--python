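"""Two-cistrome partitioning into exclusive/common categories, dominance
clusters by normalized-occupancy ratio, and ATAC accessibility calls."""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from dualbind.intervals import RegionSet, _OverlapIndex, merge_regions, overlap_partition
from dualbind.consensus import OccupancyMatrix

__all__ = [
    "BindingCluster",
    "AccessibilityCall",
    "common_set",
    "classify_dominance",
    "accessibility_categories",
    "atac_positive_fraction",
    "cluster_signal_summary",
    "overlap_percentage",
    "partition_total",
]

CLUSTER_LABELS = ("A-only", "A-dominant", "similarly-occupied", "B-dominant", "B-only")


@dataclass
class BindingCluster:
    """One of the five binding clusters; ``ratio`` (normalized A / B) is
    populated for the three common clusters only."""

    label: str
    regions: RegionSet
    ratio: dict[str, float] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.regions)


@dataclass
class AccessibilityCall:
    """Per-region accessibility category against two ATAC consensus sets."""

    categories: dict[str, str]

    def fractions(self) -> dict[str, float]:
        n = len(self.categories)
        return {
            c: sum(v == c for v in self.categories.values()) / n
            for c in ("open-both", "open-ligand-only", "open-vehicle-only", "closed-both")
        }


def common_set(a: RegionSet, b: RegionSet) -> tuple[RegionSet, RegionSet, RegionSet]:
    """Symmetric split of two consensus cistromes.

    Returns ``(a_only, common_merged, b_only)`` where the common set is the
    merged envelope of every a-region overlapping b and every b-region
    overlapping a (so common regions may exceed the uniform region width).
    """
    a_only, a_over, b_only, b_over = overlap_partition(a, b)
    pooled = RegionSet(list(a_over) + list(b_over), a.genome_id).canonicalize()
    common = (
        merge_regions(pooled) if len(pooled) else RegionSet([], a.genome_id, "common")
    )
    common.provenance = "common_merged"
    return a_only, common, b_only


def classify_dominance(
    common: RegionSet,
    occ: OccupancyMatrix,
    a_samples: list[str],
    b_samples: list[str],
    hi: float = 1.5,
    lo: float = 0.66,
) -> dict[str, BindingCluster]:
    """Split the common set into A-dominant / similarly-occupied / B-dominant.

    Per-region ratio = replicate-mean normalized A signal / B signal.
    Boundaries: ratio > hi -> A-dominant; ratio < lo -> B-dominant; the
    closed interval [lo, hi] -> similarly-occupied.  Zero B with nonzero A
    gives ratio +inf (A-dominant).  Regions with both signals zero are
    excluded with a warning.
    """
    if hi <= lo:
        raise ValueError("hi cutoff must exceed lo cutoff")
    a_mean = occ.normalized[a_samples].mean(axis=1)
    b_mean = occ.normalized[b_samples].mean(axis=1)
    buckets: dict[str, list] = {"A-dominant": [], "similarly-occupied": [], "B-dominant": []}
    ratios: dict[str, dict[str, float]] = {k: {} for k in buckets}
    unclassifiable = 0
    for i, r in enumerate(common):
        name = r.name or f"common{i}"
        a, b = float(a_mean.loc[name]), float(b_mean.loc[name])
        if a == 0 and b == 0:
            unclassifiable += 1
            continue
        ratio = math.inf if b == 0 else a / b
        if ratio > hi:
            label = "A-dominant"
        elif ratio < lo:
            label = "B-dominant"
        else:
            label = "similarly-occupied"
        buckets[label].append(r)
        ratios[label][name] = ratio
    if unclassifiable:
        warnings.warn(f"{unclassifiable} region(s) unclassifiable (zero signal in both factors)")
    return {
        label: BindingCluster(label, RegionSet(regs, common.genome_id, label), ratios[label])
        for label, regs in buckets.items()
    }


def accessibility_categories(
    binding: RegionSet, atac_vehicle: RegionSet, atac_ligand: RegionSet
) -> AccessibilityCall:
    """Assign each binding region to one of four accessibility categories
    by >=1 bp overlap with the vehicle / ligand ATAC consensus sets."""
    iv = _OverlapIndex(atac_vehicle)
    il = _OverlapIndex(atac_ligand)
    cats = {}
    for i, r in enumerate(binding):
        open_v = iv.overlaps(r)
        open_l = il.overlaps(r)
        cat = (
            "open-both" if open_v and open_l
            else "open-ligand-only" if open_l
            else "open-vehicle-only" if open_v
            else "closed-both"
        )
        cats[r.name or f"region{i}"] = cat
    return AccessibilityCall(cats)


def atac_positive_fraction(cluster: BindingCluster, atac: RegionSet) -> float:
    """Fraction of a cluster's regions overlapping ATAC-positive regions."""
    if len(cluster.regions) == 0:
        warnings.warn(f"cluster {cluster.label} is empty")
        return float("nan")
    idx = _OverlapIndex(atac)
    return sum(idx.overlaps(r) for r in cluster.regions) / len(cluster.regions)


def cluster_signal_summary(values: np.ndarray | list[float]) -> dict[str, float]:
    """Five-number box-plot summary with 1.5*IQR whiskers clamped to data."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        warnings.warn("empty cluster: no signal summary")
        return {}
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inliers = values[(values >= lo_fence) & (values <= hi_fence)]
    return {
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "whisker_lo": float(inliers.min()),
        "whisker_hi": float(inliers.max()),
    }


# --- bookkeeping used for reporting printed-count arithmetic ----------------


def overlap_percentage(n_common: int, n_cistrome: int) -> float:
    """Percentage of a cistrome accounted for by the common set."""
    if n_cistrome <= 0:
        raise ValueError("cistrome size must be positive")
    return 100.0 * n_common / n_cistrome


def partition_total(cluster_sizes: dict[str, int] | list[int]) -> int:
    """Total common-region count from the disjoint dominance partition."""
    sizes = list(cluster_sizes.values()) if isinstance(cluster_sizes, dict) else list(cluster_sizes)
    if any(s < 0 for s in sizes):
        raise ValueError("cluster sizes must be non-negative")
    return int(sum(sizes))
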