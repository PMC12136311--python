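# Methods

## Haplotype-block compression

A block is a run of `l` consecutive bi-allelic SNPs over `N` phased diploid
samples. Sample `s` contributes two haplotypes: positions `2s` (the left,
`allele_a`, side of each `a|b` genotype, in marker order) and `2s+1` (the
right side). The codec deduplicates the `2N` length-`l` {0,1} vectors into
`u` unique representatives and stores the representative matrix plus the
index map `hap_map`. Representatives are numbered by first occurrence over
the `hap_map` scan, so `hap_map[0] == 0` always; this order is arbitrary in
principle but fixing it makes output bytes deterministic and the invariant
cheap to test. Decompression is exact inversion — the transform is lossless
for GT. Dosage (DS) values are read from VCF when requested but are never
stored in M3VCF and never fabricated on decompression: the format carries
haplotypes only, and a dosage reconstructed from hard genotypes would be
`allele_a + allele_b`, which the consumer can compute without our help.

Eligibility is strict: exactly one ALT allele, single-base REF/ALT over
A/C/G/T, every genotype phased with alleles in {0,1}. Anything else aborts
the conversion by default; `skip_invalid` drops such records, counts them
per reason, and re-blocks the survivors so every block except the last
holds exactly `buffer_size` markers. Strictness is the default because
silently phasing `a/b` as `a|b`, or silently dropping markers, corrupts the
haplotype structure an imputation panel depends on. Missing genotypes
(`./.`) are likewise an error by default and a logged skip in permissive
mode — haplotype compression has no representation for them. Haploid and
polyploid calls are unsupported.

## Block boundaries

Blocks are non-overlapping runs of `buffer_size` markers (default 10); the
final block may be shorter and is never padded. The historical Minimac3
M3VCF shares one boundary marker between adjacent blocks to preserve
imputation-state continuity; that convention is available behind
`overlap_boundary`. Overlapped files need no extra flag on decompression:
block headers carry 1-based global marker ranges (`<BLOCK:first-last>`),
and a block whose range begins at or before the previously written marker
simply has its duplicated leading markers skipped. Increasing the block
size reduces per-block synchronization overhead at the cost of coarser
load balancing; for marker-rich, sample-poor files a larger block size
distributes work more evenly.

## Pipeline executor

Conversion runs as staged concurrency: one reader, `q` parse workers, `p`
compress workers, one writer. Workers are threads; the stage callables are
pure per block, so the contract — concurrent `compress_fn` invocations,
output written exactly once in ascending block order, bounded in-flight
blocks — does not depend on shared-memory specifics. Ordering is restored
by a reorder buffer keyed by block index; backpressure is a counting
semaphore of `capacity` permits acquired by the reader and released by the
writer, so a stalled sink stops the reader after at most `capacity` blocks.
Parallel parsing lives *inside* the read stage (raw lines are fetched
serially, then parsed in `n_workers` contiguous chunks and reassembled by
chunk index), which is where it belongs conceptually: parsing is the
expensive phase of reading, not an independent pipeline stage.

Error policy is fail-fast with drain: on any stage failure the reader stops
admitting blocks, in-flight work completes, every block preceding the
failure is written, and the first error by block order is raised with its
block index and stage. Partial output stays on disk but the conversion
summary reports `status="error"`.

Auto-resolution of `0`-valued settings: `p = max(1, CPUs − 2)` (one core
each reserved for reader and writer), `q = max(1, min(p, CPUs/2))`,
queue capacity `2·max(p, q)` blocks, or
`⌊memory_limit / typical_block_bytes⌋` when an explicit byte budget is
given. The memory limit is interpreted in bytes and converted to a block
capacity; this is the simplest semantics consistent with a bounded-queue
design.

Every run records a `StageTrace`: per block and stage, start/finish values
of a monotonic event counter. Ticks are causal ordering evidence, not
durations, so trace-based assertions are hardware-independent. The
`perf_model.replay_unit_time` helper re-schedules a trace under unit stage
times and bounded lanes per stage; for a complete pipelined run it
reproduces the step-count model's `n + stages − 1` make-span, tying the
executor to the analytic model without wall-clock measurement.

## Timing model

The executable model (module `perf_model`) is the idealized algebra of the
three optimizations: workflow pipelining (`T1`), multi-threaded compression
(`T2`), multi-threaded parsing (`T3`), their sum `Ts`, and Amdahl's law for
saturation. Two deliberate numerical choices:

* `n = ⌈m/l⌉`, so remainder blocks are covered; when `l` divides `m` this
  is the exact quotient the algebra assumes.
* the pipelined time is the literal compress-dominated form
  `T_read + n·T_compress + T_write`, not a max-based general make-span. The
  literal form is what `T1`'s definition assumes, and the identity
  `time_sequential − time_pipelined == savings_workflow` holds exactly
  under it. The model therefore slightly understates pipelined time for
  workloads where reading or writing, not compression, is the bottleneck;
  it is a documentation and sanity-check tool, not a fitted predictor, and
  no attempt is made to calibrate it against measured wall-clock times.

All times are non-negative reals in arbitrary consistent units; the model
is scale-free. The identity tests use dyadic-rational times (integer
multiples of 1/64), which are exactly representable in binary floating
point, so the algebraic identity can be asserted bit-exactly rather than to
a tolerance.

## Synthetic data

The generator (`fixtures`) emulates a phased reference panel: per marker, a
minor-allele frequency is drawn uniformly from `maf_range` (default
0.05–0.5, avoiding near-monomorphic sites that make blocks trivially
compressible); a founder pool of `n_founder_haplotypes` haplotypes is drawn
Bernoulli(MAF) per marker; each sample haplotype is a founder drawn with
replacement. The pool is what creates haplotype redundancy — the property
the codec exploits — and bounds the unique-haplotype count of any block by
the pool size, giving tests a constructive oracle. A large pool approaches
the i.i.d. worst case `u = 2N`. Defect records (multi-allelic, indel,
missing genotype, unphased) are injected at seeded positions, one defect
per record, and recorded in a manifest that doubles as ground truth for
filter tests. Emitted dosages equal the allele sum plus optional bounded
noise clipped to [0, 2].

What the generator does **not** emulate: recombination maps and realistic
LD decay along the chromosome, pedigree structure, genotyping error, and
missingness patterns correlated with frequency. Passing tests therefore
demonstrate correctness of parsing, compression and scheduling — exact
losslessness, oracle agreement, determinism — not compression-ratio claims
on real panels, where `u` depends on LD structure the founder pool only
crudely approximates.

## Problem sizes in tests

The test suite runs everything at desk scale: losslessness on 20 seeded
fixtures from 50×10 up to 1,000 markers × 200 samples across block sizes
{1, 7, 10, 64} and worker counts {1, 4}; dedup oracle agreement on 500
random blocks with 2N ≤ 64 and l ≤ 16; model identities on 1,000 random
workloads. These sizes exercise every boundary (single-marker blocks,
remainder blocks, worker counts above and below block counts) while keeping
the whole suite around a minute on one CPU.

## Known limitations

* The M3VCF dialect is a reverse-documented convention; byte compatibility
  with m3vcftools/Minimac4 output is not attempted and interop is untested.
* Workers are Python threads: scheduling contracts (ordering, backpressure,
  determinism) are fully exercised, but CPU-bound stages contend for the
  interpreter lock, so wall-clock scaling with `p` is not expected from the
  pure-Python codec and is not claimed or measured anywhere.
* No tabix/BGZF virtual-offset indexing; gzip members are read as plain
  streams (BGZF files are readable since BGZF is valid gzip).
* Multi-allelic sites are rejected, never split or normalized; imputation
  itself is out of scope.
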