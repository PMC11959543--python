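"""Self-consistent synthetic study with known ground truth.

Generates a genome with planted motifs, two-factor replicate peak sets
with a controlled common/exclusive overlap structure and occupancy
ratios, negative-binomial expression counts with additive and
cooperative ligand effects, MED1-like occupancy with cooperative
regions, and ATAC peak sets whose openness tracks the binding category.

Each output artifact draws from its own named RNG substream, so adding
an artifact never perturbs the others; everything is bit-deterministic
under a fixed seed.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from dualbind.intervals import GeneModel, GenomicRegion, RegionSet
from dualbind.motifs import PWM, default_dr5_seed, derive_spacer_variant

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "ChipSim",
    "ExpressionSim",
    "Med1AtacSim",
    "StudyData",
    "make_ground_truth",
    "simulate_genome",
    "simulate_chipseq",
    "simulate_expression",
    "simulate_med1_atac",
    "simulate_study",
    "genes_to_gtf",
]

REGION_CLASSES = (
    "A-only", "common-A-dominant", "common-similar", "common-B-dominant",
    "B-only", "noise",
)
GENE_LABELS = ("none", "A-only", "D-only", "both", "cooperative")
MED1_LABELS = ("unresponsive", "A-responsive", "D-responsive", "cooperative")


@dataclass
class SimulationConfig:
    seed: int = 0
    # genome
    n_chroms: int = 2
    chrom_length: int = 2_800_000
    gc_content: float = 0.41
    motif_plan: dict = field(default_factory=dict)  # pwm_id -> planted count
    # binding sites
    n_common_a_dominant: int = 60
    n_common_similar: int = 70
    n_common_b_dominant: int = 30
    n_a_only: int = 60
    n_b_only: int = 60
    n_noise_peaks: int = 40  # per factor, each in exactly one replicate
    n_fallback_sites: int = 8  # per factor: narrow peak only in replicate 2
    site_spacing: int = 10_000
    summit_jitter_sd: float = 5.0
    # occupancy counts
    base_mean: float = 200.0
    background_mean: float = 8.0
    noise_peak_mean: float = 80.0
    ligand_effect: float = 3.0
    dispersion: float | None = 0.05  # NB dispersion; None -> deterministic means
    ratio_a_dominant: tuple = (2.0, 4.0)
    ratio_similar: tuple = (0.8, 1.25)
    # expression
    n_genes: int = 2000
    n_a_only_genes: int = 120
    n_d_only_genes: int = 60
    n_both_genes: int = 40
    n_coop_genes: int = 40
    expr_base_mean: float = 150.0
    expr_fc: float = 3.0
    coop_multiplier: float = 2.5
    expr_dispersion: float = 0.01
    low_expressed_fraction: float = 0.15
    noncoding_fraction: float = 0.1
    n_replicates: int = 3
    # MED1 / ATAC
    med1_base_mean: float = 100.0
    med1_fc: float = 2.5
    med1_coop_fc: float = 1.8
    p_coop_common: float = 0.35
    p_coop_exclusive: float = 0.05
    p_responsive: float = 0.5
    atac_open_mean: float = 100.0
    atac_closed_mean: float = 10.0
    p_open_common: float = 0.9
    p_open_exclusive: float = 0.5
    p_open_noise: float = 0.1

    def __post_init__(self) -> None:
        if not (0 < self.gc_content < 1):
            raise ValueError("gc_content must be in (0,1)")
        if self.coop_multiplier <= 1:
            raise ValueError("cooperative multiplier must exceed 1")
        for f in ("n_common_a_dominant", "n_common_similar", "n_common_b_dominant",
                  "n_a_only", "n_b_only", "n_noise_peaks", "n_genes"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be >= 0")


@dataclass
class GroundTruth:
    """True labels for every simulated entity."""

    region_classes: dict = field(default_factory=dict)   # site -> REGION_CLASSES
    site_summits: dict = field(default_factory=dict)     # site -> (chrom, pos)
    site_ratios: dict = field(default_factory=dict)      # common site -> true A/B ratio
    gene_labels: dict = field(default_factory=dict)      # gene -> GENE_LABELS
    med1_labels: dict = field(default_factory=dict)      # site -> MED1_LABELS
    open_regions: set = field(default_factory=set)       # accessible site names
    planted_motifs: list = field(default_factory=list)   # (chrom,start,end,pwm_id)

    def to_json(self) -> str:
        d = asdict(self)
        d["open_regions"] = sorted(self.open_regions)
        return json.dumps(d, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        d["open_regions"] = set(d["open_regions"])
        d["site_summits"] = {k: tuple(v) for k, v in d["site_summits"].items()}
        d["planted_motifs"] = [tuple(m) for m in d["planted_motifs"]]
        return cls(**d)


def _rng(seed: int, stream: str) -> np.random.Generator:
    """Named RNG substream: independent per artifact, stable across runs."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(zlib.crc32(stream.encode()),))
    )


def _nb(rng: np.random.Generator, mean, dispersion: float | None):
    """NB draws with Var = mu + dispersion*mu^2; deterministic when
    dispersion is None."""
    mean = np.asarray(mean, dtype=float)
    if dispersion is None:
        return np.round(mean)
    n = 1.0 / dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p).astype(float)


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------


def make_ground_truth(cfg: SimulationConfig) -> GroundTruth:
    """Lay out binding sites, draw true occupancy ratios, and assign gene
    and MED1 labels."""
    rng = _rng(cfg.seed, "truth")
    truth = GroundTruth()

    class_counts = [
        ("common-A-dominant", cfg.n_common_a_dominant),
        ("common-similar", cfg.n_common_similar),
        ("common-B-dominant", cfg.n_common_b_dominant),
        ("A-only", cfg.n_a_only),
        ("B-only", cfg.n_b_only),
    ]
    n_sites = sum(c for _, c in class_counts)
    capacity = cfg.n_chroms * (cfg.chrom_length // cfg.site_spacing - 1)
    if n_sites + 2 * cfg.n_noise_peaks > capacity:
        raise ValueError("site demand exceeds genome capacity; increase chrom_length")

    # grid slots, shuffled, with jittered in-slot placement
    slots = [
        (f"chrS{c + 1}", (i + 1) * cfg.site_spacing)
        for c in range(cfg.n_chroms)
        for i in range(cfg.chrom_length // cfg.site_spacing - 1)
    ]
    rng.shuffle(slots)
    labels = [lab for lab, cnt in class_counts for _ in range(cnt)]
    rng.shuffle(labels)
    counters: dict[str, int] = {}
    for lab, (chrom, pos) in zip(labels, slots):
        i = counters.get(lab, 0)
        counters[lab] = i + 1
        name = f"{_slug(lab)}{i:04d}"
        truth.region_classes[name] = lab
        truth.site_summits[name] = (chrom, int(pos + rng.integers(-300, 301)))
        if lab == "common-A-dominant":
            truth.site_ratios[name] = float(rng.uniform(*cfg.ratio_a_dominant))
        elif lab == "common-similar":
            truth.site_ratios[name] = float(rng.uniform(*cfg.ratio_similar))
        elif lab == "common-B-dominant":
            truth.site_ratios[name] = float(1.0 / rng.uniform(*cfg.ratio_a_dominant))

    # noise peaks occupy the next free slots
    free = slots[n_sites:]
    for k in range(cfg.n_noise_peaks):
        for factor in ("A", "B"):
            chrom, pos = free.pop()
            name = f"noise{factor}{k:04d}"
            truth.region_classes[name] = "noise"
            truth.site_summits[name] = (chrom, int(pos))

    _assign_med1_labels(cfg, truth, rng)
    _assign_gene_labels(cfg, truth, rng)
    _assign_accessibility(cfg, truth, rng)
    return truth


def _slug(label: str) -> str:
    return {
        "common-A-dominant": "comA",
        "common-similar": "comS",
        "common-B-dominant": "comB",
        "A-only": "aonly",
        "B-only": "bonly",
    }[label]


def _assign_med1_labels(cfg, truth, rng) -> None:
    for name, lab in truth.region_classes.items():
        if lab == "noise":
            truth.med1_labels[name] = "unresponsive"
            continue
        common = lab.startswith("common")
        p_coop = cfg.p_coop_common if common else cfg.p_coop_exclusive
        u = rng.uniform()
        if u < p_coop:
            truth.med1_labels[name] = "cooperative"
        elif u < p_coop + cfg.p_responsive:
            if lab in ("A-only", "common-A-dominant"):
                truth.med1_labels[name] = "A-responsive"
            elif lab in ("B-only", "common-B-dominant"):
                truth.med1_labels[name] = "D-responsive"
            else:
                truth.med1_labels[name] = "A-responsive" if rng.uniform() < 0.5 else "D-responsive"
        else:
            truth.med1_labels[name] = "unresponsive"


def _assign_gene_labels(cfg, truth, rng) -> None:
    n_reg = cfg.n_a_only_genes + cfg.n_d_only_genes + cfg.n_both_genes + cfg.n_coop_genes
    if n_reg > cfg.n_genes:
        raise ValueError("regulated gene demand exceeds n_genes")
    labels = (
        ["A-only"] * cfg.n_a_only_genes
        + ["D-only"] * cfg.n_d_only_genes
        + ["both"] * cfg.n_both_genes
        + ["cooperative"] * cfg.n_coop_genes
        + ["none"] * (cfg.n_genes - n_reg)
    )
    for i, lab in enumerate(labels):
        truth.gene_labels[f"gene{i:05d}"] = lab


def _assign_accessibility(cfg, truth, rng) -> None:
    for name, lab in truth.region_classes.items():
        if lab == "noise":
            p = cfg.p_open_noise
        elif lab.startswith("common"):
            p = cfg.p_open_common
        else:
            p = cfg.p_open_exclusive
        if rng.uniform() < p:
            truth.open_regions.add(name)


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------


def simulate_genome(
    cfg: SimulationConfig,
    pwms: dict[str, PWM] | None = None,
    positions: dict[str, list[tuple[str, int]]] | None = None,
) -> tuple[dict[str, str], list[tuple[str, int, int, str]]]:
    """i.i.d. background genome at the configured GC with motifs planted
    per-column from their PWMs at non-overlapping positions.

    ``cfg.motif_plan`` requests random placements per PWM id; ``positions``
    pins specific (chrom, start) placements.  Returns (genome, planted)
    where planted holds (chrom, start, end, pwm_id) per instance.
    """
    rng = _rng(cfg.seed, "genome")
    gc = cfg.gc_content
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    genome = {}
    for c in range(cfg.n_chroms):
        codes = rng.choice(4, size=cfg.chrom_length, p=p)
        genome[f"chrS{c + 1}"] = bytearray(lut[codes])

    if pwms is None:
        pwms = standard_pwm_library()
    planted: list[tuple[str, int, int, str]] = []
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in genome}

    def place(pwm: PWM, chrom: str, start: int) -> None:
        seq = _sample_from_pwm(pwm, rng)
        genome[chrom][start : start + len(pwm)] = seq.encode("ascii")
        occupied[chrom].append((start, start + len(pwm)))
        planted.append((chrom, start, start + len(pwm), pwm.id))

    if positions:
        for pwm_id, places in positions.items():
            for chrom, start in places:
                place(pwms[pwm_id], chrom, start)
    demand = sum(
        len(pwms[pid]) * cnt for pid, cnt in cfg.motif_plan.items()
    )
    if demand > 0.5 * cfg.n_chroms * cfg.chrom_length:
        raise ValueError("motif demand exceeds genome capacity")
    chroms = list(genome)
    for pwm_id, count in cfg.motif_plan.items():
        pwm = pwms[pwm_id]
        needed = count
        attempts = 0
        while needed > 0:
            attempts += 1
            if attempts > 100 * max(1, count):
                raise ValueError("motif demand exceeds genome capacity")
            chrom = chroms[rng.integers(len(chroms))]
            start = int(rng.integers(0, cfg.chrom_length - len(pwm)))
            if any(start < e and start + len(pwm) > s for s, e in occupied[chrom]):
                continue
            place(pwm, chrom, start)
            needed -= 1
    return {c: bytes(s).decode("ascii") for c, s in genome.items()}, planted


def _sample_from_pwm(pwm: PWM, rng: np.random.Generator) -> str:
    bases = "ACGT"
    return "".join(
        bases[rng.choice(4, p=row / row.sum())] for row in pwm.matrix
    )


def standard_pwm_library() -> dict[str, PWM]:
    """DR0-DR9 and IR0-IR9 derived from the default DR5 seed."""
    seed = default_dr5_seed()
    lib = {}
    for k in range(10):
        lib[f"DR{k}"] = derive_spacer_variant(seed, k, "direct") if k != 5 else seed
        lib[f"IR{k}"] = derive_spacer_variant(seed, k, "inverted")
    return lib


# ---------------------------------------------------------------------------
# ChIP-seq
# ---------------------------------------------------------------------------


@dataclass
class ChipSim:
    """Simulated two-factor ChIP study: per-factor replicate summit and
    narrow-peak sets plus a per-site count table."""

    summits: dict            # factor -> [RegionSet, RegionSet]
    narrows: dict            # factor -> [RegionSet, RegionSet]
    counts: pd.DataFrame     # sites x samples
    sample_meta: pd.DataFrame


def _site_means(cfg: SimulationConfig, truth: GroundTruth, name: str) -> tuple[float, float]:
    """(mu_A, mu_B) at ligand stimulation for one site."""
    lab = truth.region_classes[name]
    if lab == "A-only":
        return cfg.base_mean, cfg.background_mean
    if lab == "B-only":
        return cfg.background_mean, cfg.base_mean
    if lab == "noise":
        mu = cfg.noise_peak_mean
        return (mu, cfg.background_mean) if name.startswith("noiseA") else (cfg.background_mean, mu)
    # geometric split keeps the A and B marginal signal distributions
    # symmetric (equal P90s under a symmetric design) while the A/B mean
    # ratio equals the planted ratio exactly
    r = truth.site_ratios[name]
    return cfg.base_mean * np.sqrt(r), cfg.base_mean / np.sqrt(r)


def simulate_chipseq(cfg: SimulationConfig, truth: GroundTruth) -> ChipSim:
    """Emit replicate summit/narrow peak sets and the NB count table.

    True sites appear in both replicates with Gaussian summit jitter;
    noise peaks appear in exactly one replicate; fallback sites lack a
    summit in replicate 2 but carry a narrow peak there.
    """
    rng = _rng(cfg.seed, "chipseq")
    factor_sites = {"A": [], "B": []}
    for name, lab in truth.region_classes.items():
        if lab == "noise":
            factor_sites["A" if name.startswith("noiseA") else "B"].append(name)
        else:
            if lab != "B-only":
                factor_sites["A"].append(name)
            if lab != "A-only":
                factor_sites["B"].append(name)

    summits = {}
    narrows = {}
    for factor in ("A", "B"):
        true_sites = [s for s in factor_sites[factor] if truth.region_classes[s] != "noise"]
        fallback = set(true_sites[: cfg.n_fallback_sites])
        rep_summits = [[], []]
        rep_narrows = [[], []]
        for name in factor_sites[factor]:
            chrom, pos = truth.site_summits[name]
            is_noise = truth.region_classes[name] == "noise"
            reps = [int(rng.integers(2))] if is_noise else [0, 1]
            for rep in reps:
                s = pos if cfg.summit_jitter_sd == 0 else int(
                    round(pos + rng.normal(0, cfg.summit_jitter_sd))
                )
                s = max(1, s)
                if name in fallback and rep == 1:
                    # narrow peak without a called summit in replicate 2
                    rep_narrows[rep].append(
                        GenomicRegion(chrom, max(0, s - 150), s + 150, name=name)
                    )
                    continue
                rep_summits[rep].append(
                    GenomicRegion(chrom, s, s + 1, summit=s, name=name)
                )
                rep_narrows[rep].append(
                    GenomicRegion(chrom, max(0, s - 150), s + 150, name=name)
                )
        summits[factor] = [RegionSet(r).canonicalize() for r in rep_summits]
        narrows[factor] = [RegionSet(r).canonicalize() for r in rep_narrows]

    sites = sorted(truth.region_classes)
    samples = []
    meta = []
    for factor in ("A", "B"):
        for cond in ("vehicle", "ligand"):
            for rep in (1, 2):
                samples.append(f"{factor}_{cond}_rep{rep}")
                meta.append({"factor": factor, "condition": cond, "replicate": rep})
    mu = np.zeros((len(sites), len(samples)))
    for i, name in enumerate(sites):
        mu_a, mu_b = _site_means(cfg, truth, name)
        for j, m in enumerate(meta):
            base = mu_a if m["factor"] == "A" else mu_b
            mu[i, j] = base if m["condition"] == "ligand" else max(
                cfg.background_mean, base / cfg.ligand_effect
            )
    counts = pd.DataFrame(_nb(rng, mu, cfg.dispersion), index=sites, columns=samples)
    sample_meta = pd.DataFrame(meta, index=samples)
    return ChipSim(summits, narrows, counts, sample_meta)


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------


@dataclass
class ExpressionSim:
    counts: pd.DataFrame      # genes x 12 samples
    design: pd.DataFrame
    genes: list               # GeneModel, TSS placed near designated sites
    biotype: pd.Series


def _gene_condition_means(cfg, truth, rng, gene: str) -> tuple[dict[str, float], float]:
    lab = truth.gene_labels[gene]
    mu0 = float(rng.lognormal(np.log(cfg.expr_base_mean), 0.4))
    if lab == "none" and rng.uniform() < cfg.low_expressed_fraction:
        mu0 = float(rng.uniform(0.0, 0.5))  # excluded by the low-expression filter
    fc = cfg.expr_fc
    if lab == "none":
        means = dict(vehicle=mu0, A=mu0, D=mu0, combined=mu0)
    elif lab == "A-only":
        means = dict(vehicle=mu0, A=fc * mu0, D=mu0, combined=fc * mu0)
    elif lab == "D-only":
        means = dict(vehicle=mu0, A=mu0, D=fc * mu0, combined=fc * mu0)
    elif lab == "both":
        means = dict(vehicle=mu0, A=fc * mu0, D=fc * mu0, combined=fc * mu0)
    else:  # cooperative: single-ligand response plus supra-additive combined
        subtype = ("A", "D", "both")[int(rng.integers(3))]
        a = fc * mu0 if subtype in ("A", "both") else mu0
        d = fc * mu0 if subtype in ("D", "both") else mu0
        means = dict(vehicle=mu0, A=a, D=d, combined=cfg.coop_multiplier * max(a, d))
    return means, mu0


def simulate_expression(cfg: SimulationConfig, truth: GroundTruth) -> ExpressionSim:
    """NB expression counts for the 4x(n_replicates) design plus gene
    models whose TSS sit within +/-20 kb of class-matched binding sites."""
    rng = _rng(cfg.seed, "expression")
    genes = sorted(truth.gene_labels)
    conds = ("vehicle", "A", "D", "combined")
    samples = [f"{c}_{r + 1}" for c in conds for r in range(cfg.n_replicates)]
    design = pd.DataFrame(
        {
            "condition": [c for c in conds for _ in range(cfg.n_replicates)],
            "replicate": [r + 1 for _ in conds for r in range(cfg.n_replicates)],
        },
        index=samples,
    )
    mu = np.zeros((len(genes), len(samples)))
    for i, g in enumerate(genes):
        means, _ = _gene_condition_means(cfg, truth, rng, g)
        mu[i] = [means[c] for c in design["condition"]]
    counts = pd.DataFrame(
        _nb(rng, mu, cfg.expr_dispersion), index=genes, columns=samples
    )

    gene_models = _place_genes(cfg, truth, rng, genes)
    biotype = pd.Series({g.gene_id: g.biotype for g in gene_models})
    return ExpressionSim(counts, design, gene_models, biotype)


def _place_genes(cfg, truth, rng, genes) -> list[GeneModel]:
    """Regulated genes get TSS near a class-matched binding site so that
    window-based annotation has planted signal."""
    sites_by_class: dict[str, list[str]] = {}
    for name, lab in truth.region_classes.items():
        sites_by_class.setdefault(lab, []).append(name)
    for v in sites_by_class.values():
        v.sort()
    pools = {
        "A-only": sites_by_class.get("A-only", []) + sites_by_class.get("common-A-dominant", []),
        "D-only": sites_by_class.get("B-only", []) + sites_by_class.get("common-B-dominant", []),
        "both": sites_by_class.get("common-similar", []),
        "cooperative": [
            s for lab in ("common-similar", "common-A-dominant", "common-B-dominant")
            for s in sites_by_class.get(lab, [])
        ],
    }
    cursor = dict.fromkeys(pools, 0)
    models = []
    for g in genes:
        lab = truth.gene_labels[g]
        strand = "+" if rng.uniform() < 0.5 else "-"
        biotype = "protein_coding" if rng.uniform() >= cfg.noncoding_fraction else "lncRNA"
        if lab in pools and pools[lab]:
            pool = pools[lab]
            site = pool[cursor[lab] % len(pool)]
            cursor[lab] += 1
            chrom, pos = truth.site_summits[site]
            tss = int(np.clip(pos + rng.integers(-20_000, 20_001), 100, cfg.chrom_length - 100))
        else:
            chrom = f"chrS{int(rng.integers(cfg.n_chroms)) + 1}"
            tss = int(rng.integers(100, cfg.chrom_length - 100))
        models.append(GeneModel(g, g.upper(), chrom, strand, tss, biotype))
    return models


def genes_to_gtf(genes: list[GeneModel], gene_length: int = 1000) -> str:
    """Minimal GTF text with one ``gene`` line per model (1-based closed)."""
    lines = []
    for g in genes:
        if g.strand == "+":
            start0, end = g.tss, g.tss + gene_length
        else:
            start0, end = max(0, g.tss + 1 - gene_length), g.tss + 1
        attrs = (
            f'gene_id "{g.gene_id}"; gene_name "{g.gene_name}"; '
            f'gene_biotype "{g.biotype}";'
        )
        lines.append(
            "\t".join(
                [g.chrom, "sim", "gene", str(start0 + 1), str(end), ".", g.strand, ".", attrs]
            )
        )
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# MED1 / ATAC
# ---------------------------------------------------------------------------


@dataclass
class Med1AtacSim:
    med1_counts: pd.DataFrame   # sites x (4 conditions x n_replicates)
    med1_design: pd.DataFrame
    atac_peaks: dict            # condition -> [RegionSet, RegionSet]
    atac_counts: pd.DataFrame   # sites x {vehicle, ligand}


def simulate_med1_atac(cfg: SimulationConfig, truth: GroundTruth) -> Med1AtacSim:
    """MED1 counts following per-region truth labels and ATAC peak sets
    whose openness tracks the binding category."""
    rng = _rng(cfg.seed, "med1_atac")
    sites = sorted(truth.region_classes)
    conds = ("vehicle", "A", "D", "combined")
    samples = [f"med1_{c}_{r + 1}" for c in conds for r in range(cfg.n_replicates)]
    design = pd.DataFrame(
        {
            "condition": [c for c in conds for _ in range(cfg.n_replicates)],
            "replicate": [r + 1 for _ in conds for r in range(cfg.n_replicates)],
        },
        index=samples,
    )
    mm, fc, cfc = cfg.med1_base_mean, cfg.med1_fc, cfg.med1_coop_fc
    mu = np.zeros((len(sites), len(samples)))
    for i, name in enumerate(sites):
        lab = truth.med1_labels[name]
        cls = truth.region_classes[name]
        if lab == "unresponsive":
            means = dict(vehicle=mm, A=mm, D=mm, combined=mm)
        elif lab == "A-responsive":
            means = dict(vehicle=mm, A=fc * mm, D=mm, combined=fc * mm)
        elif lab == "D-responsive":
            means = dict(vehicle=mm, A=mm, D=fc * mm, combined=fc * mm)
        else:  # cooperative
            a = fc * mm if cls in ("A-only", "common-A-dominant", "common-similar") else mm
            d = fc * mm if cls in ("B-only", "common-B-dominant", "common-similar") else mm
            means = dict(vehicle=mm, A=a, D=d, combined=cfc * max(a, d))
        mu[i] = [means[c] for c in design["condition"]]
    med1_counts = pd.DataFrame(_nb(rng, mu, cfg.dispersion), index=sites, columns=samples)

    atac_peaks = {"vehicle": [[], []], "ligand": [[], []]}
    atac_mu = np.zeros((len(sites), 2))
    for i, name in enumerate(sites):
        is_open = name in truth.open_regions
        atac_mu[i] = cfg.atac_open_mean if is_open else cfg.atac_closed_mean
        if is_open:
            chrom, pos = truth.site_summits[name]
            for cond in ("vehicle", "ligand"):
                for rep in (0, 1):
                    jitter = int(rng.integers(-20, 21))
                    atac_peaks[cond][rep].append(
                        GenomicRegion(
                            chrom, max(0, pos - 200 + jitter), pos + 200 + jitter, name=name
                        )
                    )
    atac_counts = pd.DataFrame(
        _nb(rng, atac_mu, cfg.dispersion), index=sites, columns=["vehicle", "ligand"]
    )
    atac_sets = {
        cond: [RegionSet(r).canonicalize() for r in reps]
        for cond, reps in atac_peaks.items()
    }
    return Med1AtacSim(med1_counts, design, atac_sets, atac_counts)


# ---------------------------------------------------------------------------
# full study
# ---------------------------------------------------------------------------


@dataclass
class StudyData:
    cfg: SimulationConfig
    truth: GroundTruth
    genome: dict
    planted: list
    chip: ChipSim
    expression: ExpressionSim
    med1_atac: Med1AtacSim


def simulate_study(cfg: SimulationConfig) -> StudyData:
    """Run every simulator stage under named substreams of ``cfg.seed``."""
    truth = make_ground_truth(cfg)
    genome, planted = simulate_genome(cfg)
    truth.planted_motifs = planted
    chip = simulate_chipseq(cfg, truth)
    expr = simulate_expression(cfg, truth)
    ma = simulate_med1_atac(cfg, truth)
    return StudyData(cfg, truth, genome, planted, chip, expr, ma)
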