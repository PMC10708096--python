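# snpdiv

Toolkit for genome-wide SNP marker panel design and germplasm
genetic-diversity analysis, built around an 84-accession × 150-locus
workflow: panel selection from a variant file, genotype QC, diversity
statistics (He/Ho), duplicate/synonym detection by multilocus matching,
UPGMA clustering and PCoA, AMOVA and pairwise F_ST with permutation tests,
and model-based admixture inference (Gibbs sampling) with Evanno ΔK model
selection. A seeded simulator with verifiable ground truth (F-model
populations, clones, pedigree hybrids, injected defective loci) makes every
stage testable without external data.

## Layout

| module | what it does |
| --- | --- |
| `snpdiv.io_formats` | VCF subset, genotype CSV dialects, STRUCTURE two-row text, Newick, metadata CSV |
| `snpdiv.synthetic_data` | F-model genotype simulator, dense candidate VCF writer, deterministic 84×150 reference fixture |
| `snpdiv.panel_design` | MAF computation, flank isolation, per-bin evenly spaced panel selection |
| `snpdiv.qc_diversity` | sequential filter cascade, He/Ho summaries, multilocus matching |
| `snpdiv.distance_cluster` | allele-sharing distances, UPGMA, tree cutting, PCoA |
| `snpdiv.amova_fst` | distance-based AMOVA, pairwise F_ST (plus Weir–Cockerham θ), permutation p-values |
| `snpdiv.admixture` | admixture-model Gibbs sampler, K sweeps, Evanno ΔK, replicate alignment |
| `snpdiv.cli_pipeline` | end-to-end orchestration with a JSON run manifest |

The packaged accession metadata table lives at
`src/snpdiv/data/accessions.csv` (84 records).

## CLI

Every stage is a `snpdiv` subcommand; `--help` lists flags with defaults.

```sh
snpdiv simulate --n-accessions 84 --n-loci 150 --seed 1 --out-prefix out/sim
snpdiv design-panel --vcf candidates.vcf --quota 10 --flank 150 --maf-min 0.05 --out panel.csv
snpdiv qc --genotypes out/sim.genotypes.csv --out-prefix out/qc
snpdiv diversity --genotypes out/qc.filtered.csv --metadata meta.csv --out div.csv
snpdiv match --genotypes out/qc.filtered.csv --out synonyms.json
snpdiv tree --genotypes out/qc.filtered.csv --out upgma.nwk
snpdiv pcoa --genotypes out/qc.filtered.csv --out-prefix out/pcoa
snpdiv amova --genotypes out/qc.filtered.csv --metadata meta.csv --groups maturation --out amova.csv
snpdiv fst --genotypes out/qc.filtered.csv --metadata meta.csv --groups status --out fst.csv
snpdiv structure-sweep --genotypes out/qc.filtered.csv --k-min 1 --k-max 4 --reps 3 --seed 1 --out-prefix out/structure
snpdiv run --out out/full --seed 1      # whole pipeline on the packaged fixture
```

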