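# gen2vcf

Streaming converter from Oxford/IMPUTE **GEN** genotype-probability files to
BGZF-compressed, tabix-indexable **VCF** carrying, for every sample at every
variant:

- **GT** — the best-guess genotype (the genotype with maximum posterior
  probability),
- **GP** — the three genotype posterior probabilities
  P(0/0), P(0/1), P(1/1),
- **DS** — the imputed ALT-allele dosage.

## Why

Genotype imputation with the IMPUTE family of tools writes its output as GEN
text: per line, 5 or 6 variant metadata columns followed by a probability
triple P(AA), P(AB), P(BB) for each diploid sample. Most association-testing
software (EPACTS, RAREMETAL, anything VCF-native) instead wants a VCF with an
imputed dosage per genotype, and the dosage-based association test is the
standard choice for imputed data. Stitching that conversion together from
general-purpose tools takes several passes over what can be a very large
file. `gen2vcf` does the whole conversion in one streaming pass — memory use
is independent of the number of variants — and speaks standard input/output
so it drops into shell pipelines (e.g. behind a BGEN-to-GEN converter, in
front of an association tool).

With allele A as the reference allele and allele B as the coded (alternate)
allele, the dosage is the expected ALT-allele count of the genotype
distribution:

```
DS = 0 · P(AA) + 1 · P(AB) + 2 · P(BB),   DS ∈ [0, 2]
```

and GT is `argmax{P(AA), P(AB), P(BB)}` rendered as `0/0`, `0/1` or `1/1`
(ties break to the lower genotype index; an all-zero triple is the GEN
convention for a missing genotype and renders as `./.:.:.`).

## Worked example

Generate a tiny synthetic GEN + sample fixture and convert it:

```sh
python -c "from gen2vcf.fixtures import FixtureSpec, generate_fixture; \
           generate_fixture(FixtureSpec(n_variants=3, n_samples=2, seed=7), '.')"
gen2vcf --gen fixture_s7_v3_n2.gen --sample fixture_s7_v3_n2.sample --out demo.vcf.gz
```

The input's first line is

```
1 snp1 rs1 1283 T G 0.546 0.002 0.453 0.406 0.212 0.382
```

i.e. chromosome 1, position 1283, alleles T/G, then two probability triples.
The command logs to stderr

```
gen2vcf INFO: conversion finished: records=3 samples=2 missing_genotypes=0
clamped_dosages=0 clamped_probabilities=0 malformed_lines=0 blank_lines=0
index_written=True
```

and writes `demo.vcf.gz` plus `demo.vcf.gz.tbi`. `zcat demo.vcf.gz` shows

```
##fileformat=VCFv4.2
##fileDate=20260920
##FORMAT=<ID=GT,Number=1,Type=String,Description="Best-guess genotype (maximum posterior probability)">
##FORMAT=<ID=GP,Number=G,Type=Float,Description="Genotype posterior probabilities P(0/0), P(0/1), P(1/1)">
##FORMAT=<ID=DS,Number=1,Type=Float,Description="Imputed ALT-allele dosage: P(0/1) + 2*P(1/1)">
##source=gen2vcf 1.0.0
#CHROM	POS	ID	REF	ALT	QUAL	FILTER	INFO	FORMAT	ind1	ind2
1	1283	rs1	T	G	.	.	.	GT:GP:DS	0/0:0.546,0.002,0.453:0.908	0/0:0.406,0.212,0.382:0.976
1	1470	rs2	G	T	.	.	.	GT:GP:DS	1/1:0.137,0.394,0.470:1.334	1/1:0.359,0.042,0.599:1.240
1	1675	rs3	T	A	.	.	.	GT:GP:DS	1/1:0.374,0.177,0.449:1.075	1/1:0.055,0.044,0.901:1.846
```

Reading the first sample of the first record: P(AA)=0.546 is the largest
probability, so GT is `0/0`; DS = 0.002 + 2·0.453 = 0.908 expected copies of
the G allele. Sample names (`ind1`, `ind2`) come from the `ID_2` column of
the `.sample` file.

Pipelines work the same way with `-`:

```sh
zcat chr1.gen.gz | gen2vcf --gen - --out - | bcftools stats -
```

Useful flags: `--chr` (required for 5-column GEN input, which has no
chromosome column), `--precision` (decimals for GP/DS, default 3),
`--gt-threshold` (blank GT when the best probability is below the threshold;
GP and DS are kept), `--renormalize` (rescale each triple to sum to 1),
`--lenient` (clamp/skip instead of abort), `--no-index`, `--no-date`
(reproducible, byte-identical output), `--id-policy auto|rsid|varid`.

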