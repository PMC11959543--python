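"""End-to-end orchestration: the standardized cistrome-pair re-analysis
and the full simulate -> consensus -> classify -> annotate -> cooperate ->
MED1/ATAC -> motif workflow with a reproducible manifest."""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict

import pandas as pd

from dualbind import annotate, classify, consensus, expression, motifs, occdiff
from dualbind.intervals import RegionSet, name_regions, write_bed, write_fasta
from dualbind.simulate import (
    SimulationConfig,
    StudyData,
    genes_to_gtf,
    simulate_study,
    standard_pwm_library,
)

__all__ = ["run_pair_analysis", "end_to_end"]


def run_pair_analysis(
    cistrome_a: RegionSet,
    cistrome_b: RegionSet,
    genome: dict[str, str],
    pwm_a: motifs.PWM,
    pwm_b: motifs.PWM,
    n_controls: int = 1000,
    target_fpr: float = 0.05,
    seed: int = 0,
) -> dict:
    """Standardized two-cistrome comparison.

    Produces cistrome sizes, symmetric overlap fractions, per-cistrome
    prevalence of each factor's motif, and motif co-occurrence in the
    common set.  Thresholds are calibrated on size-matched random controls
    drawn from ``genome``.
    """
    import numpy as np

    for label, rs in (("cistrome_a", cistrome_a), ("cistrome_b", cistrome_b)):
        if len(rs) == 0:
            raise ValueError(f"{label} is empty")
    a_only, common, b_only = classify.common_set(cistrome_a, cistrome_b)
    common = name_regions(common, "common")

    rng = np.random.default_rng(seed)
    sizes = [len(r) for r in cistrome_a] + [len(r) for r in cistrome_b]
    _, control_seqs = motifs.sample_control_regions(genome, sizes, n_controls, rng)
    report: dict = {
        "n_a": len(cistrome_a),
        "n_b": len(cistrome_b),
        "n_common": len(common),
        "pct_a_common": classify.overlap_percentage(len(common), len(cistrome_a))
        if len(common) else 0.0,
        "pct_b_common": classify.overlap_percentage(len(common), len(cistrome_b))
        if len(common) else 0.0,
    }
    hit_sets = {}
    for tag, pwm in (("a", pwm_a), ("b", pwm_b)):
        thr = motifs.calibrate_threshold(pwm, control_seqs, target_fpr)
        hits = motifs.map_motifs(pwm, genome, thr)
        hit_sets[tag] = hits
        report[f"threshold_{tag}"] = thr
        report[f"prevalence_{tag}_in_a"] = motifs.motif_prevalence(cistrome_a, hits)
        report[f"prevalence_{tag}_in_b"] = motifs.motif_prevalence(cistrome_b, hits)
    if len(common):
        _, fracs = motifs.cooccurrence(common, hit_sets["a"], hit_sets["b"])
        report["common_cooccurrence"] = fracs
    else:
        report["common_cooccurrence"] = None  # undefined without common regions
    return report


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _envelope_sites(region) -> list[str]:
    """Unique member site names recorded by merge provenance."""
    if not region.name:
        return []
    return sorted({n for n in region.name.split(",") if n})


def end_to_end(cfg: SimulationConfig, outdir: str) -> dict:
    """Simulate a study and run every downstream stage, writing TSV/JSON/BED
    outputs plus a manifest of file hashes and stage parameters."""
    os.makedirs(outdir, exist_ok=True)
    manifest: dict = {"config": asdict(cfg), "stages": [], "files": {}}

    def record(stage: str, **info) -> None:
        manifest["stages"].append({"stage": stage, **info})

    study = simulate_study(cfg)
    _write_inputs(study, outdir)
    record("simulate", seed=cfg.seed)

    # --- consensus per factor -------------------------------------------
    consensus_sets = {}
    for factor in ("A", "B"):
        reps = []
        for rep in (0, 1):
            ext = consensus.extend_summits(study.chip.summits[factor][rep])
            reps.append(consensus.merge_close_summits(ext))
        cons, _adm = consensus.consensus_two_reps(
            reps[0], reps[1], study.chip.narrows[factor][0], study.chip.narrows[factor][1]
        )
        consensus_sets[factor] = cons
        write_bed(cons, os.path.join(outdir, f"consensus_{factor}.bed"))
    record("consensus", n_A=len(consensus_sets["A"]), n_B=len(consensus_sets["B"]))

    # --- classification --------------------------------------------------
    a_only, common, b_only = classify.common_set(consensus_sets["A"], consensus_sets["B"])
    site_counts = study.chip.counts
    ligand_cols = {
        f: [c for c in site_counts.columns if c.startswith(f"{f}_ligand")]
        for f in ("A", "B")
    }
    env_counts = _quantify_envelopes(common, site_counts)
    occ = consensus.normalize_occupancy(env_counts)
    clusters3 = classify.classify_dominance(
        common, occ,
        a_samples=ligand_cols["A"], b_samples=ligand_cols["B"],
    )
    clusters5 = {
        "A-only": classify.BindingCluster("A-only", a_only),
        **clusters3,
        "B-only": classify.BindingCluster("B-only", b_only),
    }
    counts_json = {k: len(v) for k, v in clusters5.items()}
    record("classify", **counts_json)
    for label, cl in clusters5.items():
        write_bed(cl.regions, os.path.join(outdir, f"cluster_{label}.bed"))

    # --- expression & cooperative genes ----------------------------------
    expr = expression.ExpressionMatrix(
        study.expression.counts, study.expression.design, study.expression.biotype
    )
    calls = expression.de_gate(expr)
    coop = expression.cooperative_caller(expr, calls)
    calls.to_csv(os.path.join(outdir, "de_calls.tsv"), sep="\t")
    coop.to_csv(os.path.join(outdir, "cooperative_genes.tsv"), sep="\t")
    record(
        "expression",
        n_up=int((calls["label"] != "none").sum()),
        n_cooperative=int(coop["cooperative"].sum()) if len(coop) else 0,
    )

    # --- annotation -------------------------------------------------------
    genes = study.expression.genes
    gene_labels = {g: l for g, l in study.truth.gene_labels.items() if l != "none"}
    cluster_regions = {k: v.regions for k, v in clusters5.items()}
    named_clusters = {
        k: name_regions(v, f"{k}_") if any(r.name is None for r in v) else v
        for k, v in cluster_regions.items()
    }
    props = annotate.annotate_closest(named_clusters, genes, gene_labels)
    props.to_csv(os.path.join(outdir, "closest_gene_proportions.tsv"), sep="\t")
    up_sets = {
        lab: [g for g in genes if study.truth.gene_labels[g.gene_id] == lab]
        for lab in ("A-only", "both", "D-only")
    }
    enr = annotate.enrichment(named_clusters, up_sets)
    enr.to_csv(os.path.join(outdir, "enrichment.tsv"), sep="\t", index=False)
    record("annotate", n_gene_sets=len(up_sets))

    # --- MED1 -------------------------------------------------------------
    ma = study.med1_atac
    veh_cols = list(ma.med1_design.index[ma.med1_design["condition"] == "vehicle"])
    comb_cols = list(ma.med1_design.index[ma.med1_design["condition"] == "combined"])
    med1_diff = occdiff.differential_occupancy(ma.med1_counts, comb_cols, veh_cols)
    med1_coop = occdiff.med1_cooperative(ma.med1_counts, ma.med1_design)
    coop_names = set(med1_coop.index[med1_coop["cooperative"]])
    coop_regions = RegionSet(
        [
            _site_region(study, n)
            for n in sorted(coop_names)
            if study.truth.region_classes.get(n) != "noise"
        ]
    )
    composition = occdiff.cooperative_composition(
        coop_regions,
        {
            "A-only": a_only,
            "common": common,
            "B-only": b_only,
        },
    )
    med1_diff.to_csv(os.path.join(outdir, "med1_differential.tsv"), sep="\t")
    composition.to_csv(os.path.join(outdir, "med1_cooperative_composition.tsv"), sep="\t")
    record("med1", n_cooperative=int(med1_coop["cooperative"].sum()))

    # --- ATAC -------------------------------------------------------------
    atac_veh = consensus.consensus_min_overlap(ma.atac_peaks["vehicle"], 2)
    atac_lig = consensus.consensus_min_overlap(ma.atac_peaks["ligand"], 2)
    acc = classify.accessibility_categories(common, atac_veh, atac_lig)
    with open(os.path.join(outdir, "accessibility.json"), "w") as fh:
        json.dump(acc.fractions(), fh, indent=1)
    record("atac", **{k.replace("-", "_"): v for k, v in acc.fractions().items()})

    # --- motifs -----------------------------------------------------------
    lib = standard_pwm_library()
    import numpy as np

    rng = np.random.default_rng(cfg.seed + 7)
    sizes = [len(r) for r in common] or [200]
    _, controls = motifs.sample_control_regions(study.genome, sizes, 500, rng)
    motif_report = {}
    for mid in ("DR5", "DR3"):
        pwm = lib[mid]
        thr = motifs.calibrate_threshold(pwm, controls)
        hits = motifs.map_motifs(pwm, study.genome, thr)
        motif_report[mid] = {
            "threshold": thr,
            "n_hits": len(hits),
            "prevalence_common": motifs.motif_prevalence(common, hits) if len(common) else None,
        }
    with open(os.path.join(outdir, "motif_report.json"), "w") as fh:
        json.dump(motif_report, fh, indent=1)
    record("motifs", pwms=list(motif_report))

    for root, _dirs, files in os.walk(outdir):
        for f in sorted(files):
            if f == "manifest.json":
                continue
            p = os.path.join(root, f)
            manifest["files"][os.path.relpath(p, outdir)] = _sha256(p)
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def _site_region(study: StudyData, name: str):
    from dualbind.intervals import GenomicRegion

    chrom, pos = study.truth.site_summits[name]
    return GenomicRegion(chrom, max(0, pos - 100), pos + 100, name=name)


def _quantify_envelopes(common: RegionSet, site_counts: pd.DataFrame) -> pd.DataFrame:
    """Re-quantify signal on merged common envelopes by summing the member
    sites' counts (merge provenance carries the site names)."""
    rows = {}
    for i, r in enumerate(common):
        name = r.name or f"common{i}"
        sites = [s for s in _envelope_sites(r) if s in site_counts.index]
        if sites:
            rows[name] = site_counts.loc[sites].sum(axis=0)
        else:
            rows[name] = pd.Series(0.0, index=site_counts.columns)
    return pd.DataFrame(rows).T


def _write_inputs(study: StudyData, outdir: str) -> None:
    d = os.path.join(outdir, "inputs")
    os.makedirs(d, exist_ok=True)
    write_fasta(study.genome, os.path.join(d, "genome.fa"))
    for factor in ("A", "B"):
        for rep in (0, 1):
            write_bed(
                study.chip.summits[factor][rep],
                os.path.join(d, f"{factor}_rep{rep + 1}_summits.bed"),
            )
            write_bed(
                study.chip.narrows[factor][rep],
                os.path.join(d, f"{factor}_rep{rep + 1}_narrow.bed"),
            )
    study.chip.counts.to_csv(os.path.join(d, "chip_counts.tsv"), sep="\t")
    study.expression.counts.to_csv(os.path.join(d, "expression_counts.tsv"), sep="\t")
    study.med1_atac.med1_counts.to_csv(os.path.join(d, "med1_counts.tsv"), sep="\t")
    with open(os.path.join(d, "genes.gtf"), "w") as fh:
        fh.write(genes_to_gtf(study.expression.genes))
    with open(os.path.join(d, "ground_truth.json"), "w") as fh:
        fh.write(study.truth.to_json())
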