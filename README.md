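# gvpid

Human identification from hair-shaft protein: detect genetically variant
peptides (GVPs) in peptide-spectrum-match (PSM) lists, impute the
corresponding non-synonymous SNP (nsSNP) alleles per subject, and estimate
how rare each imputed profile is in reference populations.

The pipeline:

1. **variant_reference** — builds a compact search database (each reference
   protein plus one extra copy carrying every common single-amino-acid
   polymorphism), digests proteins in silico with trypsin (cleavage after
   K/R, suppressed before P, configurable missed cleavages), and enumerates
   the allele-specific tryptic peptides with uniqueness and
   chemical-confusability annotations. Digestion always runs on the
   allele-substituted sequence, so substitutions that create or destroy
   cleavage sites produce correct per-allele peptide sets.
2. **io_formats** — readers/writers for PSM TSVs, genotype panels (VCF via
   cyvcf2 or individual-by-locus TSV), truth genotypes, the SNP annotation
   table, FASTA proteomes, the GVP catalog, and byte-deterministic JSON.
3. **gvp_filter** — seven pure, order-independent exclusion rules: engine
   score (X!Tandem log10(e) ≤ −2, Mascot expectation ≤ 0.05), precursor
   mass deviation (≤ 0.2 Da), population allele frequency (≥ 0.4% in at
   least one reference population), biological PTMs, chemically confusable
   substitutions (M→F, N→D, Q→E, C→S), peptide uniqueness, and
   alternative-allele diagnostic fragment ions (singly charged b/y ladders,
   monoisotopic, fixed carbamidomethyl-C).
4. **imputation** — collapses filtered detections into per-subject
   gene-level allele combinations (at most one observation per allele per
   gene) and validates them against truth genotypes (TP/FP/FN/TN,
   sensitivity, PPV, FDR; failed truth calls are excluded).
5. **profile_stats** — carrier counting of allele combinations in a panel,
   the Jeffreys estimate (x + ½)/(n + 1), product-rule profile
   probabilities in log space, parametric-bootstrap 90% CIs, and
   cross-population likelihood ratios.
6. **synthetic_data** — generates every input with known ground truth:
   HWE genotype panels (optional within-gene haplotype mode), subject
   genotypes, filter-passing PSMs with configurable per-GVP sensitivity
   and false-positive rate, and decoy PSMs that each violate exactly one
   exclusion rule.

## CLI

All stages are wired through one `gvpid` command; every run writes a
`manifest.json` (command, config, input digests, seed, version) and
outputs are byte-deterministic for fixed inputs.

```sh
gvpid simulate --seed 7 --out sim --subjects 20            # toy study
gvpid build-db --proteome sim/proteome.fasta --snps sim/snps.tsv --out db
gvpid filter   --psms sim/psms.tsv --catalog db/catalog.tsv \
               --snps sim/snps.tsv --out filt
gvpid impute   --detections filt/detections.tsv --out imp
gvpid validate --profiles imp/profiles.json --truth sim/truth.tsv \
               --catalog db/catalog.tsv --snps sim/snps.tsv --out val
gvpid prob     --profiles imp/profiles.json --snps sim/snps.tsv \
               --panel EUR=sim/panel_EUR.vcf --panel AFR=sim/panel_AFR.tsv \
               --seed 11 --out prob
```

`filter`/`validate` accept `--config` pointing at a flat `key=value` file
(keys: `xtandem_loge_max`, `mascot_expect_max`, `precursor_tol_da`,
`freq_threshold`, `fragment_tol_da`, `biological_mods`, `exclusion_pairs`,
`populations`); CLI flags override file values.

## Conventions

- Protein positions and peptide spans are 1-based inclusive.
- I and L are distinct residues in matching.
- X!Tandem scores are stored as log10(e); Mascot as linear expectation.
- Carrier counting: an individual counts toward x if their diploid
  genotype contains every detected allele (zygosity is never asserted
  from peptide evidence).
- Missing genotypes shrink both x and n per gene (complete-case).
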