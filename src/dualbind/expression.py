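"""Differential-expression gating and the cooperative-upregulation caller.

The DE gate runs four steps: low-expression filter, one-way ANOVA across
the four conditions with Benjamini-Hochberg adjustment, Tukey HSD per
ligand-vs-vehicle contrast, then 1.5 / 0.66 fold-change cutoffs.  The
cooperative caller compares the combined treatment to the more effective
single ligand (Welch t-test, ratio cutoff), restricted optionally to
protein-coding genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ExpressionMatrix",
    "cpm_normalize",
    "de_gate",
    "cooperative_caller",
    "fold_change_table",
    "gene_set_partition",
]

CONDITIONS = ("vehicle", "A", "D", "combined")


@dataclass
class ExpressionMatrix:
    """Genes x samples counts with a condition/replicate design.

    ``design`` is indexed by sample name with columns ``condition`` (one of
    vehicle/A/D/combined) and ``replicate``; ``biotype`` maps gene -> GTF
    gene_biotype.
    """

    counts: pd.DataFrame
    design: pd.DataFrame
    biotype: pd.Series | None = None

    def __post_init__(self) -> None:
        missing = set(CONDITIONS) - set(self.design["condition"])
        if missing:
            raise ValueError(f"design lacks condition(s): {sorted(missing)}")
        reps = self.design.groupby("condition").size()
        if (reps < 2).any():
            raise ValueError("every condition needs >= 2 replicates")
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")

    def samples_for(self, condition: str) -> list[str]:
        return list(self.design.index[self.design["condition"] == condition])


def cpm_normalize(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts-per-million library-size scaling."""
    libsize = counts.sum(axis=0)
    if (libsize <= 0).any():
        raise ValueError("zero library size")
    return counts / libsize * 1e6


def _condition_means(norm: pd.DataFrame, expr: ExpressionMatrix) -> pd.DataFrame:
    return pd.DataFrame(
        {c: norm[expr.samples_for(c)].mean(axis=1) for c in CONDITIONS}
    )


def de_gate(
    expr: ExpressionMatrix,
    fc_up: float = 1.5,
    fc_down: float = 0.66,
    alpha: float = 0.05,
    tukey_alpha: float = 0.05,
    min_mean: float = 1.0,
) -> pd.DataFrame:
    """Four-step DE gate; returns one row per gene.

    Columns: ``label`` in {none, A-only-up, D-only-up, both-up},
    ``down_A``/``down_D`` flags, per-contrast FCs (pseudocount 1),
    ANOVA p and BH-adjusted q, Tukey p per ligand contrast, and ``kept``
    (passed the low-expression filter).
    """
    norm = cpm_normalize(expr.counts)
    means = _condition_means(norm, expr)
    kept = (means >= min_mean).any(axis=1)

    genes = norm.index
    cond_samples = {c: expr.samples_for(c) for c in CONDITIONS}
    groups = {c: norm[cond_samples[c]].values for c in CONDITIONS}

    anova_p = np.full(len(genes), np.nan)
    idx_kept = np.flatnonzero(kept.values)
    if idx_kept.size:
        arrs = [groups[c][idx_kept] for c in CONDITIONS]
        with np.errstate(invalid="ignore", divide="ignore"):
            f, p = stats.f_oneway(*arrs, axis=1)
        p = np.where(np.isnan(p), 1.0, p)
        anova_p[idx_kept] = p
    anova_q = np.full(len(genes), np.nan)
    if idx_kept.size:
        anova_q[idx_kept] = multipletests(anova_p[idx_kept], method="fdr_bh")[1]

    fc_A = (means["A"] + 1) / (means["vehicle"] + 1)
    fc_D = (means["D"] + 1) / (means["vehicle"] + 1)
    fc_C = (means["combined"] + 1) / (means["vehicle"] + 1)

    # Tukey HSD for the ligand-vs-vehicle contrasts, vectorized via the
    # studentized range distribution (equivalent to scipy.stats.tukey_hsd)
    tukey_pA = np.full(len(genes), np.nan)
    tukey_pD = np.full(len(genes), np.nan)
    sig_anova = np.flatnonzero(kept.values & (anova_q < alpha))
    sig_A = np.zeros(len(genes), dtype=bool)
    sig_D = np.zeros(len(genes), dtype=bool)
    if sig_anova.size:
        k = len(CONDITIONS)
        ns = {c: groups[c].shape[1] for c in CONDITIONS}
        n_total = sum(ns.values())
        df = n_total - k
        sse = sum(
            ((groups[c][sig_anova] - groups[c][sig_anova].mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
            for c in CONDITIONS
        )
        mse = sse / df
        q_crit = stats.studentized_range.ppf(1 - tukey_alpha, k, df)
        for cond, p_arr, sig_arr in (("A", tukey_pA, sig_A), ("D", tukey_pD, sig_D)):
            diff = np.abs(
                groups[cond][sig_anova].mean(axis=1)
                - groups["vehicle"][sig_anova].mean(axis=1)
            )
            # Tukey-Kramer standard error for (possibly) unequal group sizes
            se = np.sqrt(mse / 2 * (1 / ns[cond] + 1 / ns["vehicle"]))
            with np.errstate(divide="ignore", invalid="ignore"):
                q = np.where(se > 0, diff / se, np.where(diff > 0, np.inf, 0.0))
            p_arr[sig_anova] = stats.studentized_range.sf(q, k, df)
            sig_arr[sig_anova] = q > q_crit

    up_A = sig_A & (fc_A.values >= fc_up)
    up_D = sig_D & (fc_D.values >= fc_up)
    down_A = sig_A & (fc_A.values <= fc_down)
    down_D = sig_D & (fc_D.values <= fc_down)

    label = np.where(
        up_A & up_D, "both-up",
        np.where(up_A, "A-only-up", np.where(up_D, "D-only-up", "none")),
    )
    return pd.DataFrame(
        {
            "label": label,
            "down_A": down_A,
            "down_D": down_D,
            "fc_A": fc_A.values,
            "fc_D": fc_D.values,
            "fc_combined": fc_C.values,
            "anova_p": anova_p,
            "anova_q": anova_q,
            "tukey_p_A": tukey_pA,
            "tukey_p_D": tukey_pD,
            "kept": kept.values,
        },
        index=genes,
    )


def cooperative_caller(
    expr: ExpressionMatrix,
    calls: pd.DataFrame,
    ratio_cut: float = 1.5,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Four-step cooperative-upregulation caller over the upregulated genes.

    For each gene upregulated by A or D: (1) the more effective single
    ligand has the larger replicate-mean normalized expression; (2) Welch
    t-test of combined vs that ligand's replicates must give p <= alpha;
    (3) combined/single mean ratio must be >= ratio_cut (ratio is +inf when
    the single-ligand mean is 0); (4) ``protein_coding`` flags the biotype
    subset.  Returns one row per candidate gene with a ``cooperative``
    flag.
    """
    norm = cpm_normalize(expr.counts)
    candidates = calls.index[calls["label"].isin(["A-only-up", "D-only-up", "both-up"])]
    a_cols = expr.samples_for("A")
    d_cols = expr.samples_for("D")
    c_cols = expr.samples_for("combined")

    rows = []
    for g in candidates:
        a_mean = float(norm.loc[g, a_cols].mean())
        d_mean = float(norm.loc[g, d_cols].mean())
        best = "A" if a_mean >= d_mean else "D"
        single_vals = norm.loc[g, a_cols if best == "A" else d_cols].values.astype(float)
        comb_vals = norm.loc[g, c_cols].values.astype(float)
        single_mean = single_vals.mean()
        ratio = np.inf if single_mean == 0 else comb_vals.mean() / single_mean
        p = _welch_p(comb_vals, single_vals)
        coding = (
            bool(expr.biotype.get(g) == "protein_coding")
            if expr.biotype is not None
            else True
        )
        rows.append(
            {
                "gene": g,
                "more_effective_single": best,
                "ratio": ratio,
                "t_p": p,
                "cooperative": bool(ratio >= ratio_cut and p <= alpha),
                "protein_coding": coding,
            }
        )
    out = pd.DataFrame(rows).set_index("gene") if rows else pd.DataFrame(
        columns=["more_effective_single", "ratio", "t_p", "cooperative", "protein_coding"]
    )
    return out


def _welch_p(a: np.ndarray, b: np.ndarray) -> float:
    if np.var(a) == 0 and np.var(b) == 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


def fold_change_table(expr: ExpressionMatrix) -> pd.DataFrame:
    """Per-gene FCs (pseudocount 1 on CPM means) for the four contrasts:
    A/vehicle, D/vehicle, combined/vehicle, combined/best-single."""
    norm = cpm_normalize(expr.counts)
    means = _condition_means(norm, expr)
    best_single = means[["A", "D"]].max(axis=1)
    return pd.DataFrame(
        {
            "fc_A": (means["A"] + 1) / (means["vehicle"] + 1),
            "fc_D": (means["D"] + 1) / (means["vehicle"] + 1),
            "fc_combined": (means["combined"] + 1) / (means["vehicle"] + 1),
            "fc_combined_vs_best_single": (means["combined"] + 1) / (best_single + 1),
        }
    )


def gene_set_partition(calls: pd.DataFrame) -> dict[str, list[str]]:
    """Disjoint up-sets (A-only/both/D-only) plus per-ligand down-sets."""
    return {
        "A-only-up": list(calls.index[calls["label"] == "A-only-up"]),
        "both-up": list(calls.index[calls["label"] == "both-up"]),
        "D-only-up": list(calls.index[calls["label"] == "D-only-up"]),
        "down-A": list(calls.index[calls["down_A"]]),
        "down-D": list(calls.index[calls["down_D"]]),
    }
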