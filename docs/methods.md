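# Methods

## The conversion

Input is GEN text as written by IMPUTE-family imputation tools: one line per
biallelic variant, whitespace-delimited, with 5 or 6 leading metadata columns
followed by three genotype posterior probabilities per diploid sample. The
two metadata layouts in circulation are

| layout | columns |
|---|---|
| 6-column | `chrom varid rsid pos allele_a allele_b` |
| 5-column | `varid rsid pos allele_a allele_b` |

The layouts are mutually exclusive by arithmetic: a line with `t` tokens has
`t ≡ 2 (mod 3)` under the 5-column layout and `t ≡ 0 (mod 3)` under the
6-column one, so the dialect is detected from the first data line and then
enforced. `t ≡ 1 (mod 3)` fits neither and is rejected. Because the 5-column
layout carries no chromosome, converting it requires an explicit `--chr`
label; for 6-column input `--chr` overrides the file's column.

Allele A is taken as the VCF REF allele and allele B as ALT. Per sample, from
the triple (P(AA), P(AB), P(BB)):

- **missingness** — a triple whose component sum is below `missing_eps`
  (default 1e-6) is the GEN encoding of a missing genotype ("0 0 0") and
  renders as `./.:.:.`;
- **DS** — the expected ALT-allele count `P(AB) + 2·P(BB)`, clamped into
  [0, 2] with a counted clamp if an unnormalized triple pushes it outside;
- **GT** — the argmax of the triple, ties broken toward the lower genotype
  index (0/0 < 0/1 < 1/1) for determinism; if the maximum probability is
  below `gt_threshold` the call is blanked to `./.` while GP and DS are kept,
  since hard-call filtering is a policy choice that should not destroy the
  probabilistic information;
- **GP** — the triple itself, passed through verbatim by default.

The whole pipeline is a single pass: parse a line, derive N sample fields,
append one VCF line to the output, discard. Peak memory is a constant plus
one record regardless of variant count, which is what makes the converter
usable on biobank-scale files and inside shell pipelines (stdin/stdout are
first-class; logging goes to stderr only).

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `precision` | 3 | decimal places for GP and DS. IMPUTE prints 3-decimal probabilities; more digits would be false precision. Fixed-point, round-half-to-even, never exponent notation. |
| `gt_threshold` | 0 | minimum posterior for a hard call; 0 means always call. |
| `renormalize` | off | divide each triple by its sum before computing GP/DS. Off by default: the file's values are the data; the [0, 2] dosage bound is instead enforced by a counted clamp. With renormalization on, clamping can never fire. |
| `missing_eps` | 1e-6 | missingness cutoff on the component sum. |
| `strict` | on | abort on malformed lines / out-of-range probabilities; `--lenient` clamps and skips with counters instead. Values in (1, 1+1e-6] are treated as print-rounding noise and clamped to 1 even in strict mode. |
| `id_policy` | auto | VCF ID column: rsid unless it is "." or empty, then varid, then `chrom:pos_ref_alt`. |

Probability bounds carry a tolerance of 1e-6 because 3-decimal printing means
triples routinely fail to sum to exactly 1.

## Output conventions

VCF 4.2. GP is emitted as linear probabilities (not phred-scaled) in genotype
order P(0/0), P(0/1), P(1/1), declared `Number=G`; DS is `Number=1`. QUAL,
FILTER and INFO are "." — GEN carries no such data. Input order is preserved
(no sorting buffer); a tabix index is built only for BGZF file output and is
refused — after the VCF itself has been completely written — when the records
turn out not to be coordinate-sorted. Duplicate positions or IDs pass through
unchanged, as VCF permits. Sample names come from the `.sample` file
(`ID_2` by default, selectable), or are synthesized as `sample_1..N` when no
sample file is given. The `##fileDate` line is the only run-dependent byte of
the output and can be suppressed with `--no-date` for byte-exact
reproducibility.

## Synthetic fixtures

`gen2vcf.fixtures.generate_fixture` emulates the relevant surface of real
IMPUTE output: per sample a probability triple drawn from a flat Dirichlet
over the 2-simplex, printed with 3 decimals (so printed triples, like real
ones, need not sum to exactly 1), a configurable fraction of genotypes
written as the missing code "0 0 0", strictly increasing positions, random
SNP alleles, and both metadata dialects. Identical spec + seed gives
byte-identical files. Each fixture carries a truth table computed from the
rounded, as-written values — the converter can only see the file, so truth
derived from pre-rounding draws would be unfair.

What the generator does **not** emulate: linkage-disequilibrium structure,
realistic imputation-quality profiles (INFO/r²), chromosome X or other
non-diploid ploidy, multi-character indel alleles, and real cohort sample
metadata. Passing tests therefore demonstrate format- and formula-level
correctness of the conversion, not anything about imputation quality on real
data — the conversion is purely per-genotype, so this is the appropriate
scope.

`fixtures.oracle_convert` is a deliberately naive whole-file-in-memory
re-implementation of the same conversion, written separately from the
streaming modules. Tests require the streaming CLI output to be
byte-identical to it across seeded random fixtures of both dialects.

## Numerical choices

- Dosage and argmax are computed in double precision on the parsed values;
  rounding happens only at rendering.
- Rendering uses Python's fixed-point float formatting (round-half-to-even),
  so a value re-parsed at the stated precision re-renders to the same bytes.
- Exact argmax ties go to the lower genotype index; a uniform triple
  (1/3, 1/3, 1/3) calls 0/0.
- Renormalization of an effectively-zero triple is a
  `DegenerateTriple` error rather than silently producing NaNs; such triples
  should have been classified missing upstream.
- An empty input stream is not an error: it yields a header-only VCF.

## Test problem sizes

The deeper end-to-end checks run at deliberately moderate scale: the
oracle-equivalence suite uses 20 random fixtures up to 200 variants × 20
samples, the truth-table round trip 1,000 × 50, the memory check 20,000 ×
100 against 1,000 × 100 (peak RSS sampled from `/proc/self/statm` in a fresh
subprocess per run, since the conversion itself is the thing measured), and
the scaled conversion check 1,000 variants × 1,000 samples. These sizes keep
the suite quick while still being one to two orders of magnitude above
anything that could pass by buffering accidents.

## Known limitations

- BGEN input is out of scope by design; the supported route is piping an
  external BGEN→GEN converter (e.g. QCTOOL) into stdin.
- No handling of haploid or mixed-ploidy data (chromosome X).
- No BCF output, record sorting, deduplication or liftover; the converter
  preserves input order and leaves dataset curation to dedicated tools.
- Indexing requires coordinate-sorted input; unsorted input still converts
  but is not indexed.
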