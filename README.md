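# m3vcfkit

Block-wise unique-haplotype (M3VCF) compression of phased VCF genotypes,
with a staged parallel conversion pipeline and the analytic timing model
behind it.

## The problem

Genotype imputation engines in the Minimac family consume reference panels
in M3VCF, a compact haplotype-block format, rather than raw VCF. Converting
a large phased VCF into M3VCF — and simply loading large VCFs — is a
real bottleneck once panels reach millions of markers and thousands of
samples: the work is dominated by text parsing and by the haplotype
deduplication itself, and a naive converter reads, compresses, and writes
strictly one block after another.

`m3vcfkit` provides:

* a streaming **VCF reader/writer** (plain or gzip) that parses only the
  GT and, optionally, DS FORMAT fields, record by record or in blocks with
  the parsing fanned out across worker threads;
* the **M3VCF codec**: for each block of `l` consecutive bi-allelic SNPs,
  the `2N` sample haplotypes are deduplicated into `u` unique
  *representative* haplotypes plus a per-haplotype index map. Because
  nearby markers are in strong linkage disequilibrium, `u ≪ 2N` in real
  panels. The transform is lossless: decompressing reproduces every phased
  genotype exactly;
* a **staged pipeline executor** — one reader, `q` parse workers, `p`
  compress workers, one ordered writer with bounded in-flight memory — so
  the read, compress and write stages of successive blocks overlap;
* the **analytic performance model** of that pipeline as executable
  formulas, and a seeded **synthetic VCF generator** for testing without
  any external dataset.

## The model in brief

For a dataset of `m` markers in `n = ⌈m/l⌉` blocks with per-block stage
times `T_read = T_load + T_parse`, `T_compress`, `T_write`:

* sequential workflow: `T_old = n·(T_read + T_compress + T_write)`
* pipelined workflow (compress-dominated idealization):
  `T_new = T_read + n·T_compress + T_write`
* workflow savings: `T1 = (n−1)·(T_read + T_write)`
* `p`-thread compression: `T_compress/p`, saving `T2 = (p−1)·T_compress/p`
* `q`-thread parsing: `T_load + T_parse/q`, saving `T3 = (q−1)·T_parse/q`
* total: `Ts = T1 + T2 + T3`
* thread saturation: Amdahl's law `S = 1 / ((1−α) + α/p)` for
  parallelizable fraction `α`.

In step counts: a pipelined `s`-stage schedule finishes `n` blocks in
`n + s − 1` steps instead of `n·s` — 3 records through read/compress/write
take 5 steps instead of 9. Complexity-wise the conversion remains linear in
the input (`O_total = O_read + O_compress + O_write`); the pipeline and the
thread pools change constants, not the asymptotics.

## Worked example

```bash
$ python - <<'EOF'
from m3vcfkit import FixtureSpec, generate_vcf
generate_vcf(FixtureSpec(n_samples=10, n_markers=20, seed=1), "panel.vcf")
EOF
$ m3vcfkit compress panel.vcf -O m -o panel.m3vcf.gz
compress: 20 markers read, 20 compressed, 0 rejected, 2 blocks written (0.00s)
$ m3vcfkit convert panel.m3vcf.gz -O M -o panel.back.vcf
convert: 2 blocks read, 20 markers written (0.00s)
```

The 20 markers fall into 2 blocks of the default `--buffer-size 10`;
`panel.back.vcf` carries exactly the genotypes of `panel.vcf`. `-O m`
writes gzip output, `-O M` plain text; input compression is auto-detected.
Records that are not phased bi-allelic SNPs abort the run unless
`--skip-invalid` drops and counts them.

The model subcommand prints every formula above for chosen parameters:

```bash
$ m3vcfkit model --markers 30 --block-size 10 --t-load 1 --t-parse 1 \
    --t-compress 3 --t-write 1 -p 4 -q 4 --alpha 0.9
blocks n = ceil(m/l)                            3
sequential time n(T_read+T_compress+T_write)    18
pipelined time T_read + n*T_compress + T_write  12
T1 workflow savings (n-1)(T_read+T_write)       6
...
Ts total savings T1+T2+T3                       9
Amdahl speedup (alpha=0.9, p=4)                 3.07692
steps sequential (n blocks, 3 stages)           9
steps pipelined (n blocks, 3 stages)            5
```

Library usage mirrors the CLI:

```python
from m3vcfkit import CompressArgs, vcf_to_m3vcf
summary = vcf_to_m3vcf(CompressArgs("panel.vcf", "panel.m3vcf.gz", buffer_size=10))
print(summary.markers_compressed, summary.blocks_written)  # 20 2
```

## The M3VCF dialect

The on-disk M3VCF layout was never formally specified; the dialect written
here is a reverse-documented convention (see `m3vcf_codec` module docs):
per block, one header line carries `VARIANTS=l;REPS=u` and each sample's
two representative indices as `a|b`; then `l` variant lines each carry a
`u`-character {0,1} string giving every representative's allele at that
marker. Interoperability with Minimac4 binaries is not promised. Adjacent
blocks are non-overlapping by default; `--overlap-boundary` reproduces the
historical Minimac3 convention of sharing one boundary marker between
blocks.

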