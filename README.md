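# dualbind

Analysis toolkit for paired nuclear-receptor cistromes: builds replicate
consensus peak sets, partitions two cistromes into exclusive/common
categories with occupancy-ratio dominance clusters, connects binding
clusters to regulated gene sets, calls cooperative transcriptional
induction and cooperative coactivator (MED1-like) recruitment, overlays
chromatin-accessibility categories, and maps direct/inverted-repeat
response elements with FPR-calibrated PWM score thresholds. A built-in
simulator generates a fully self-consistent synthetic study (genome with
planted motifs, replicate peak sets, negative-binomial expression and
occupancy counts) with known ground-truth labels for every caller.

## Package layout

| module | contents |
| --- | --- |
| `dualbind.intervals` | `GenomicRegion`/`RegionSet`/`GeneModel`, interval algebra (overlap partition, merge, nearest-TSS), BED/summit-BED/narrowPeak/GTF/FASTA/chrom-sizes IO |
| `dualbind.simulate` | `SimulationConfig`, `GroundTruth`, genome/ChIP/expression/MED1+ATAC simulators, `simulate_study` |
| `dualbind.consensus` | summit extension (±100 bp), <200 bp summit merging, two-replicate consensus with narrow-peak fallback, minOverlap consensus, P90 occupancy normalization |
| `dualbind.classify` | symmetric common-set construction, 1.5/0.66 dominance clustering, ATAC accessibility categories, box-plot summaries |
| `dualbind.annotate` | closest-gene regulation proportions, TSS ±25 kb window membership, observed/expected enrichment, normalized prevalence |
| `dualbind.expression` | CPM normalization, four-step DE gate (filter → ANOVA+BH → Tukey → 1.5/0.66 FC), cooperative-upregulation caller |
| `dualbind.occdiff` | Welch-on-log2 differential occupancy with BH, MED1 ligand responsiveness, cooperative MED1 test (FC>1 & p≤0.05), category composition |
| `dualbind.motifs` | PWM type, DRk/IRk spacer/orientation derivation, two-strand log2-odds scanning, control-set threshold calibration, genome-wide mapping, prevalence/co-occurrence, overlap-configuration classes |
| `dualbind.pipeline` / `dualbind.cli` | standardized cistrome-pair analysis, full end-to-end workflow with manifest, subcommand CLI |

## CLI

```sh
dualbind run-all --seed 1 --out out/            # simulate + full workflow
dualbind simulate --seed 1 --out study/         # synthetic study only
dualbind consensus --rep1 A_rep1_summits.bed --rep2 A_rep2_summits.bed --out consensus.bed
dualbind classify --cistrome-a A.bed --cistrome-b B.bed --counts counts.tsv --out clusters
dualbind de --counts expr.tsv --design design.tsv --out calls.tsv
dualbind cooperate --counts expr.tsv --design design.tsv --gtf genes.gtf --out coop.tsv
dualbind occdiff --counts med1.tsv --group-a c1,c2,c3 --group-b v1,v2,v3 --out diff.tsv
dualbind motif-derive --spacer 3 --out DR3.motif
dualbind motif-calibrate --pwm DR3.motif --genome genome.fa --out DR3_cal.motif
dualbind motif-map --pwm DR3_cal.motif --genome genome.fa --out hits.bed
dualbind motif-config --regions common.bed --dr3-hits dr3.bed --rare-hits rare.bed --out config.tsv
dualbind pair --cistrome-a A.bed --cistrome-b B.bed --genome genome.fa --out pair.json
```

All subcommands write machine-readable TSV/JSON; logs go to stderr.
`run-all` emits a `manifest.json` with SHA-256 of every output —
bit-identical across reruns with the same config and seed.

## Tests

```sh
python -m pytest -q tests/
```

The suite covers unit behavior per module, property tests for the
structural invariants (partition sums, merge idempotence, strand
symmetry, scale invariance), brute-force oracle equivalence for interval
and scanning operations, and parameter-recovery/null-calibration checks
against the simulator's ground truth. `tests/test_acceptance.py` holds
the acceptance criteria.

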