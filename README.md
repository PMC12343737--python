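# metasig

Somatic-mutation analysis toolkit for metastatic tumor cohorts: 96-channel
trinucleotide catalogs, de novo mutational-signature extraction (KL-NMF with
cophenetic rank selection), signature-activity molecular subtyping by
resampled consensus clustering, and survival / immunogenicity association
screens (Kaplan–Meier, log-rank, Efron Cox with Schoenfeld diagnostics,
Fisher/BH co-occurrence networks, CNV and ICI-response screens) — plus a
synthetic-cohort generator so every stage is testable with known ground
truth and no external data.

## Package layout

| module | contents |
| --- | --- |
| `metasig.io_cohort` | MAF-like / clinical / CNV / ICI readers, typed records, nonsynonymous filter |
| `metasig.catalog96` | channel classification, context resolution (column or FASTA), samples×96 catalog, TMB and tCw burden |
| `metasig.nmf_signatures` | KL multiplicative-update NMF, cophenetic rank selection, reference cosine matching, 25 % activity binarization |
| `metasig.consensus_cluster` | resampled Ward clustering on 1−Pearson distance, CDF/delta-area, subtype labels with stability flags |
| `metasig.survstats` | KM, log-rank, Cox PH (Efron ties), Schoenfeld PH test, logistic regression, rank tests, Fisher, BH |
| `metasig.genomic_screen` | recurrent genes, per-gene prognostic Cox, co-occurrence/mutual-exclusivity network, CNV screen, ICI response |
| `metasig.synthetic_cohort` | ground-truth cohort simulator (signatures, survival, gene pairs, CNVs, ICI arm) |
| `metasig.pipeline` / `metasig.cli` | YAML-config pipeline with hashed run manifest; `metasig` console entry point |

## CLI

```bash
metasig simulate --n-samples 150 --load-mean 200 --ici-n 100 --seed 7 --out cohort/
metasig catalog   --maf cohort/maf.tsv --clinical cohort/clinical.tsv --out catalog.tsv
metasig signatures --catalog catalog.tsv --auto-k --out-prefix sigs
metasig cluster   --exposures sigs.exposures.tsv --reps 1000 --out clusters.tsv
metasig survival  --clinical cohort/clinical.tsv
metasig screen    --maf cohort/maf.tsv --clinical cohort/clinical.tsv --cnv cohort/cnv.tsv --out-prefix screen
metasig run       --config config.yaml     # full workflow + manifest.json
metasig report    --run-dir metasig_run/
```

A minimal `config.yaml`:

```yaml
inputs:
  maf: cohort/maf.tsv
  clinical: cohort/clinical.tsv
  cnv: cohort/cnv.tsv        # optional
  ici: cohort/ici.tsv        # optional
nmf: {k_range: [2, 6], n_runs: 10, seed: 17}
cluster: {reps: 1000, p_item: 0.8, seed: 23}
screens: {adjust: [age, sex, tumor_type], ici_gene: PTPRT}
output_dir: metasig_run
```

Reruns with the same config and inputs reproduce byte-identical numeric
outputs; `manifest.json` records content hashes of every artifact.

## Reference signatures

`metasig/data/reference_signatures_example.tsv` is a **synthetic placeholder**
in the standard v2 probability-file layout (96 context rows × 30 signature
columns), shipped so the annotation step runs out of the box. For real
analyses point the `reference_signatures` config key (or
`ReferenceSignatures.from_tsv`) at the genuine COSMIC v2 probability file.

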