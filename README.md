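# lethalhap

Detection and validation of recessive-lethal haplotypes affecting stillbirth
and fertility in dairy cattle populations.

The package implements the full inference chain on phased genotypes,
pedigree and breeding records:

- **`lethalhap.hhd`** — homozygous haplotype deficiency (HHD) scan: fixed
  marker windows over phased haplotypes, expected homozygote counts and
  zero-homozygote probabilities under random mating (`(1 - p^2)^N`) and
  under carrier matings (`0.75^k` over qualifying carrier-sire x
  carrier-dam / carrier-MGS matings), plus a Hardy-Weinberg / log R
  deletion screen.
- **`lethalhap.effects`** — haplotype validation models: logistic
  regression of calf survival on the conceptus homozygosity probability
  (0.25 for carrier sire x carrier dam, 0.125 via the maternal grand sire),
  and a pedigree mixed model of NRR56 (56-day non-return rate) on mating
  type with closed-form recessive-lethal failure expectations.
- **`lethalhap.mixed`** — pedigree mixed-model engine: sparse A-inverse
  (Henderson/Quaas rules with inbreeding, optional unknown-parent groups),
  AI-REML with EM fallback, BLUP via Henderson's MME (including the
  maternal-direct stillbirth model), corrected phenotypes
  (EBV + PE + mean residual) and heritability formulas.
- **`lethalhap.gwas`** — marker/sample QC, allele-count-standardised GRM,
  two-stage linear mixed-model association on corrected phenotypes,
  Bonferroni / suggestive thresholds, LD (r²) and HHD co-location, genomic
  inflation factors, Manhattan/QQ plots.
- **`lethalhap.traits`** — derivation of stillbirth, CR, CI, IFL, AIS,
  NRR56 and infertility phenotypes from raw calving/insemination records
  with all record-editing filters.
- **`lethalhap.synthetic`** — gene-drop simulator: AI half-sib pedigrees,
  phased genotypes with embedded recessive lethals riding founder tag
  haplotypes, and calving/insemination records whose failure and stillbirth
  processes respond to the planted lethals.
- **`lethalhap.data_io`** — phased VCF / haplotype-matrix readers and
  writers, pedigree and record CSVs, results TSVs, YAML config.

## Command-line use

```sh
# simulate a synthetic dataset
lethalhap simulate --preset desk --seed 1 --out-dir data/

# scan for homozygous haplotype deficiency
lethalhap hhd-scan --genotypes data/genotypes.vcf --pedigree data/pedigree.csv \
    --window-length 25 --min-freq 0.05 --out hhd.tsv

# derive phenotypes and test haplotype effects
lethalhap derive-traits --trait nrr56 --calvings data/calvings.csv \
    --inseminations data/inseminations.csv --out nrr56.tsv
lethalhap effects --genotypes data/genotypes.vcf --pedigree data/pedigree.csv \
    --calvings data/calvings.csv --hhd-table hhd.tsv --window-length 25 --out sb_effects.tsv
lethalhap nrr56 --genotypes data/genotypes.vcf --pedigree data/pedigree.csv \
    --calvings data/calvings.csv --inseminations data/inseminations.csv \
    --hhd-table hhd.tsv --window-length 25 --out nrr_effects.tsv

# corrected phenotypes and GWAS
lethalhap blup --calvings data/calvings.csv --pedigree data/pedigree.csv --out ystar.tsv
lethalhap gwas --genotypes data/genotypes.vcf --phenotypes ystar.tsv --out gwas.tsv
```

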