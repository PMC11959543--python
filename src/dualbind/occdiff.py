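"""Replicate-aware differential occupancy and the cooperative MED1 test.

A documented stand-in for the NB-GLM frameworks usually used here:
per-region Welch t-tests on log2(normalized count + 1) with BH control
across regions.  The cooperative MED1 test mirrors the per-region,
uncorrected FC > 1 & p <= 0.05 rule.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from dualbind.intervals import RegionSet, _OverlapIndex

__all__ = [
    "differential_occupancy",
    "med1_responsive",
    "med1_cooperative",
    "cooperative_composition",
]


def differential_occupancy(
    counts: pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Per-region Welch t-test of group A vs B on log2(count + 1).

    Returns columns ``log2_fc`` (mean A - mean B on the log2 scale),
    ``p``, ``fdr`` (BH across regions), and ``significant`` (fdr <= cutoff).
    Regions with zero variance in both groups and equal means get p = 1.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need >= 2 replicates per group")
    la = np.log2(counts[group_a].values.astype(float) + 1)
    lb = np.log2(counts[group_b].values.astype(float) + 1)
    log2_fc = la.mean(axis=1) - lb.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # constant rows
        res = stats.ttest_ind(la, lb, axis=1, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)
    # zero variance in both groups: equal means -> p=1, unequal -> p=0
    nan = np.isnan(p)
    p[nan & (log2_fc == 0)] = 1.0
    p[nan & (log2_fc != 0)] = 0.0
    q = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {"log2_fc": log2_fc, "p": p, "fdr": q, "significant": q <= fdr},
        index=counts.index,
    )


def med1_responsive(
    med1_regions: RegionSet,
    med1_diff: pd.DataFrame,
    clusters: dict[str, RegionSet],
    induced_only: bool = True,
) -> dict[str, float]:
    """Per-cluster fraction of regions overlapping significantly induced
    MED1 peaks (>=1 bp).  ``med1_diff`` is indexed by MED1 region name;
    induced means significant with positive log2 FC."""
    sig = med1_diff["significant"]
    if induced_only:
        sig = sig & (med1_diff["log2_fc"] > 0)
    sig_names = set(med1_diff.index[sig])
    sig_regions = RegionSet([r for r in med1_regions if r.name in sig_names])
    idx = _OverlapIndex(sig_regions)
    out = {}
    for label, rs in clusters.items():
        if len(rs) == 0:
            out[label] = float("nan")
            continue
        out[label] = sum(idx.overlaps(r) for r in rs) / len(rs)
    return out


def med1_cooperative(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Cooperative MED1 recruitment per region (no multiplicity correction).

    For each region the more effective single treatment is the one (A or D)
    with the larger replicate mean; an unpaired Welch t-test compares the
    combined-treatment replicates against it.  A region is cooperative iff
    FC (combined mean / single mean) > 1 AND p <= alpha.
    """
    a_cols = list(design.index[design["condition"] == "A"])
    d_cols = list(design.index[design["condition"] == "D"])
    c_cols = list(design.index[design["condition"] == "combined"])
    if min(len(a_cols), len(d_cols), len(c_cols)) < 2:
        raise ValueError("need >= 2 replicates per condition")
    A = counts[a_cols].values.astype(float)
    D = counts[d_cols].values.astype(float)
    C = counts[c_cols].values.astype(float)
    a_mean, d_mean, c_mean = A.mean(axis=1), D.mean(axis=1), C.mean(axis=1)
    use_a = a_mean >= d_mean
    single = np.where(use_a[:, None], A, D)
    single_mean = np.where(use_a, a_mean, d_mean)
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(C, single, axis=1, equal_var=False)
        fc = np.where(single_mean > 0, c_mean / single_mean, np.inf)
    p = np.asarray(res.pvalue, dtype=float)
    p[np.isnan(p)] = 1.0
    return pd.DataFrame(
        {
            "more_effective_single": np.where(use_a, "A", "D"),
            "fc": fc,
            "p": p,
            "cooperative": (fc > 1) & (p <= alpha),
        },
        index=counts.index,
    )


def cooperative_composition(
    coop_regions: RegionSet,
    categories: dict[str, RegionSet],
) -> pd.DataFrame:
    """Category proportions among regions overlapping cooperative MED1
    peaks, side by side with the whole-cistrome background proportions."""
    total_bg = sum(len(rs) for rs in categories.values())
    if total_bg == 0:
        raise ValueError("empty category sets")
    if len(coop_regions) == 0:
        warnings.warn("empty cooperative MED1 set: composition is all zeros")
    idx = _OverlapIndex(coop_regions) if len(coop_regions) else None
    overlapping = {
        label: (sum(idx.overlaps(r) for r in rs) if idx else 0)
        for label, rs in categories.items()
    }
    total_ov = sum(overlapping.values())
    rows = {}
    for label, rs in categories.items():
        rows[label] = {
            "cooperative_fraction": overlapping[label] / total_ov if total_ov else 0.0,
            "background_fraction": len(rs) / total_bg,
        }
    return pd.DataFrame(rows).T
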