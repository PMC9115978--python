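# rohscan

Runs-of-homozygosity (ROH) analysis for diploid autosomal SNP-array cohorts:

- **genotype_io** — PLINK PED/MAP and BED/BIM/FAM (SNP-major) readers/writers,
  allele statistics, Hardy–Weinberg exact test, and a four-stage QC pass
  (sample call rate → variant call rate → HWE → MAF) with per-stage tallies.
- **roh** — sliding-window ROH scanner (50-SNP windows, ≤1 heterozygote and
  ≤5 missing calls per window, per-SNP qualifying threshold 0.01, gap /
  length / SNP-count / density segment filters), the minimum-SNP
  false-positive rule, length-class tables and chromosome coverage.
- **inbreeding** — F_HOM = (O−E)/(L−E) with cohort-frequency expectation,
  F_ROH = Σ L_ROH / L_auto per length class and total, Pearson correlation,
  per-breed summaries.
- **islands** — per-breed SNP incidence tracks, hotspot calling at an
  inclusive 40% threshold, two-group unique/shared SNP comparison, and
  interval annotation against BED or GFF3 features.
- **structure** — variance-standardised GRM with pairwise missing handling
  and deterministic PCA.
- **simulate** — synthetic multi-breed cohorts with exactly known ground
  truth: planted autozygous tracts over five length classes, shared island
  loci with deterministic carrier sets, group-level allele-frequency
  divergence, heterozygous genotyping errors and missingness. Planted
  tracts use heterozygous endpoint/guard SNPs so the default scanner
  recovers their boundaries exactly, which makes recovery metrics sharp.
- **cli** — a `rohscan` command chaining the stages through on-disk TSV and
  PLINK artifacts with per-stage manifests.

## CLI

Each stage reads the previous stage's artifacts from the same output
directory; `all` chains simulate-or-load → qc → roh → inbreed → islands →
pca → report.

```sh
cat > config.txt <<EOF
seed = 11
n_breeds = 10
individuals_per_breed = 30
breed_f = 0.15
group_divergence = 0.2
EOF
rohscan all --config config.txt --out out/
```

To analyse real PLINK data instead of a simulation, set `input_prefix`
(and `dialect = bed` or `dialect = pedmap`) plus `breed_map` (two-column
TSV: breed, group) in the config; QC thresholds (`max_variant_missing`,
`min_maf`, `max_sample_missing`, `hwe_p_floor`) and all scanner parameters
(`min_length_kb`, `min_snps`, `max_gap_kb`, `min_density_kb_per_snp`,
`window_snps`, `window_max_het`, `window_max_missing`, `window_threshold`)
can be overridden the same way.

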