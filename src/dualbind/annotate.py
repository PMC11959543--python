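"""Binding-cluster <-> gene-set connections.

Nearest-gene annotation with regulation labels, TSS-window membership
(region center within TSS +/- half_width), and observed/expected
enrichment of clusters in gene-set windows.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from dualbind.intervals import GeneModel, RegionSet, nearest_feature

__all__ = [
    "annotate_closest",
    "windows_membership",
    "enrichment",
    "normalized_prevalence",
    "nonregulated_high_set",
]


def annotate_closest(
    clusters: dict[str, RegionSet],
    genes: list[GeneModel],
    gene_labels: dict[str, str],
    default_label: str = "not-regulated",
) -> pd.DataFrame:
    """Per-cluster proportions of regulation labels of the closest genes.

    Rows are clusters, columns labels; each row sums to 1 (empty clusters
    produce a warned all-NaN row).
    """
    all_labels = sorted(set(gene_labels.values()) | {default_label})
    rows = {}
    for label, rs in clusters.items():
        if len(rs) == 0:
            warnings.warn(f"cluster {label} is empty")
            rows[label] = {l: np.nan for l in all_labels}
            continue
        counts = dict.fromkeys(all_labels, 0)
        for gene_id, _dist in nearest_feature(rs, genes):
            lab = gene_labels.get(gene_id, default_label) if gene_id else default_label
            counts[lab] = counts.get(lab, 0) + 1
        n = len(rs)
        rows[label] = {l: c / n for l, c in counts.items()}
    return pd.DataFrame(rows).T


def windows_membership(
    gene_set: list[GeneModel],
    regions: RegionSet,
    half_width: int = 25_000,
) -> dict[str, list[str]]:
    """Per-gene list of member region names.

    A region is a member of a gene's window when its center lies within
    ``[TSS - half_width, TSS + half_width]`` (inclusive); a region may
    belong to several genes' windows.
    """
    by_chrom: dict[str, list] = {}
    for i, r in enumerate(regions):
        by_chrom.setdefault(r.chrom, []).append((r.center, r.name or f"region{i}"))
    for c in by_chrom:
        by_chrom[c].sort()
    out: dict[str, list[str]] = {}
    for g in gene_set:
        members = []
        for center, name in by_chrom.get(g.chrom, []):
            if g.tss - half_width <= center <= g.tss + half_width:
                members.append(name)
        out[g.gene_id] = members
    return out


def _set_member_names(
    gene_set: list[GeneModel], regions: RegionSet, half_width: int
) -> set[str]:
    membership = windows_membership(gene_set, regions, half_width)
    return {name for members in membership.values() for name in members}


def enrichment(
    clusters: dict[str, RegionSet],
    gene_sets: dict[str, list[GeneModel]],
    half_width: int = 25_000,
) -> pd.DataFrame:
    """Observed/expected enrichment of each cluster in each gene set's
    TSS windows.

    For a gene set, observed(cluster) counts that cluster's regions whose
    center falls in any window of the set; expected(cluster) distributes
    the set's total window-region count proportionally to cluster sizes,
    making the region-count-weighted mean ratio exactly 1.
    """
    all_regions = RegionSet(
        [r for rs in clusters.values() for r in rs.regions]
    )
    total = len(all_regions)
    if total == 0:
        raise ValueError("no clustered regions")
    name_to_cluster = {}
    for label, rs in clusters.items():
        for i, r in enumerate(rs):
            name_to_cluster[r.name or f"{label}:{i}"] = label

    records = []
    for set_name, genes in gene_sets.items():
        member_names = _set_member_names(genes, all_regions, half_width)
        observed = dict.fromkeys(clusters, 0)
        for name in member_names:
            observed[name_to_cluster[name]] += 1
        set_total = len(member_names)
        for label, rs in clusters.items():
            expected = set_total * len(rs) / total
            ratio = observed[label] / expected if expected > 0 else np.nan
            records.append(
                {
                    "cluster": label,
                    "gene_set": set_name,
                    "observed": observed[label],
                    "expected": expected,
                    "ratio": ratio,
                }
            )
    return pd.DataFrame(records)


def normalized_prevalence(
    common: RegionSet,
    gene_sets: dict[str, list[GeneModel]],
    all_regions: RegionSet,
    half_width: int = 25_000,
    significant_names: set[str] | None = None,
) -> dict[str, float]:
    """Per gene set: common-cluster member regions / all member regions.

    When ``significant_names`` is given, only common regions in that set
    (e.g. those with significantly induced MED1 signal) are counted in the
    numerator.  Zero-denominator cells come back as NaN.
    """
    common_names = {r.name for r in common if r.name}
    if significant_names is not None:
        common_names &= significant_names
    out = {}
    for set_name, genes in gene_sets.items():
        members = _set_member_names(genes, all_regions, half_width)
        if not members:
            out[set_name] = float("nan")
            continue
        out[set_name] = len(members & common_names) / len(members)
    return out


def nonregulated_high_set(
    genes: list[GeneModel],
    mean_vehicle_expression: pd.Series,
    regulated_ids: set[str],
    n: int = 250,
) -> list[GeneModel]:
    """Top-n non-regulated genes by mean vehicle expression."""
    candidates = [g for g in genes if g.gene_id not in regulated_ids]
    candidates.sort(
        key=lambda g: -float(mean_vehicle_expression.get(g.gene_id, 0.0))
    )
    return candidates[:n]
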