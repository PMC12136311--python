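"""M3VCF haplotype-block codec: compress, decompress, serialize.

M3VCF is the compact haplotype format consumed by Minimac-family imputation
engines.  Instead of storing the full genotype matrix, each block of l
consecutive bi-allelic SNPs stores only the u *unique* haplotypes observed
across the 2N sample haplotypes, plus a per-haplotype index map.  Because
nearby markers are in strong linkage disequilibrium, u is typically far
below 2N, which is where the compression comes from.  The transform is
lossless for phased GT data: decompress(compress(block)) reproduces every
genotype exactly.

Only bi-allelic SNPs with fully phased, complete genotypes are accepted;
:func:`is_eligible` classifies records and names the first failed
condition.

File dialect (one text stream, optionally gzip-wrapped):

* header: the source VCF's ``##`` lines, a ``##M3VCF.version=`` line, then
  the usual ``#CHROM ... FORMAT s1...sN`` column line;
* per block, one block-header line: CHROM, POS of the first marker,
  ID ``<BLOCK:first-last>`` (1-based global marker indices), REF/ALT/QUAL/
  FILTER ``.``, INFO ``VARIANTS=l;REPS=u``, an empty FORMAT column, then N
  sample columns ``a|b`` holding the 0-based representative indices of the
  sample's two haplotypes;
* then l variant lines: CHROM, POS, ID, REF, ALT, three ``.`` columns, and
  one final column with a u-character {0,1} string — character r is the
  allele of representative r at this marker.
"""

from __future__ import annotations

import gzip
import logging
import os
from dataclasses import dataclass, field
from typing import Iterator, Optional, TextIO

import numpy as np

from . import pipeline as _pipeline
from . import vcf_io
from .vcf_io import (
    FileMode,
    Genotype,
    GenotypeBlock,
    ParseFields,
    MissingPolicy,
    VariantRecord,
    VcfHeader,
)

logger = logging.getLogger("m3vcfkit")

M3VCF_VERSION_TAG = "m3vcfkit-0.1"
_BASES = frozenset("ACGT")


class CodecError(Exception):
    """A record or block violates the codec's preconditions."""


class M3vcfFormatError(Exception):
    """A serialized M3VCF stream is malformed or truncated."""


# ---------------------------------------------------------------------------
# Eligibility
# ---------------------------------------------------------------------------

def is_eligible(record: VariantRecord) -> tuple[bool, Optional[str]]:
    """Classify a record for M3VCF compression.

    Eligible records are bi-allelic SNPs (single-base REF and ALT over
    A/C/G/T) whose every genotype is phased with alleles in {0, 1}.
    Returns ``(True, None)`` or ``(False, reason)`` naming the first
    failed condition.
    """
    if len(record.alt) != 1:
        return False, "multi-allelic"
    ref, alt = record.ref, record.alt[0]
    if len(ref) != 1 or len(alt) != 1 or ref not in _BASES or alt not in _BASES:
        return False, "not a SNP"
    for g in record.genotypes:
        if not g.phased:
            return False, "unphased"
        if g.allele_a > 1 or g.allele_b > 1:
            return False, "non-binary allele"
    return True, None


# ---------------------------------------------------------------------------
# Block compression / decompression
# ---------------------------------------------------------------------------

@dataclass(eq=False)
class HaplotypeBlock:
    """Compressed form of a GenotypeBlock.

    ``rep_haplotypes`` is the u x l {0,1} matrix of unique haplotypes, in
    order of first occurrence over the hap_map scan (so hap_map[0] == 0);
    ``hap_map`` maps sample s's two haplotypes (positions 2s and 2s+1) to
    representative row indices.
    """

    chrom: str
    variant_sites: list[tuple[int, str, str, str]]  # (pos, id, ref, alt)
    n_samples: int
    rep_haplotypes: np.ndarray  # shape (u, l), dtype uint8
    hap_map: list[int]
    first_marker_index: Optional[int] = None  # 1-based global index
    last_marker_index: Optional[int] = None

    @property
    def u(self) -> int:
        return int(self.rep_haplotypes.shape[0])

    @property
    def n_markers(self) -> int:
        return len(self.variant_sites)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, HaplotypeBlock):
            return NotImplemented
        return (
            self.chrom == other.chrom
            and self.variant_sites == other.variant_sites
            and self.n_samples == other.n_samples
            and self.hap_map == other.hap_map
            and np.array_equal(self.rep_haplotypes, other.rep_haplotypes)
        )


def compress_block(block: GenotypeBlock) -> HaplotypeBlock:
    """Deduplicate the 2N haplotypes of a block of l eligible markers.

    Sample s contributes haplotype 2s (allele_a across the block's markers,
    in order) and haplotype 2s+1 (allele_b).  Representatives are numbered
    by first occurrence scanning hap_map left to right.
    """
    records = block.records
    if not records:
        raise CodecError("cannot compress an empty block")
    n_samples = records[0].n_samples
    for rec in records:
        ok, reason = is_eligible(rec)
        if not ok:
            raise CodecError(f"record at {rec.chrom}:{rec.pos} is ineligible: {reason}")
        if rec.n_samples != n_samples:
            raise CodecError(
                f"record at {rec.chrom}:{rec.pos} has {rec.n_samples} samples, "
                f"block started with {n_samples}"
            )
    l = len(records)
    # haps[2s] = allele_a of sample s across markers; haps[2s+1] = allele_b
    haps = np.empty((2 * n_samples, l), dtype=np.uint8)
    for j, rec in enumerate(records):
        for s, g in enumerate(rec.genotypes):
            haps[2 * s, j] = g.allele_a
            haps[2 * s + 1, j] = g.allele_b

    seen: dict[bytes, int] = {}
    hap_map: list[int] = []
    rep_rows: list[np.ndarray] = []
    for row in haps:
        key = row.tobytes()
        idx = seen.get(key)
        if idx is None:
            idx = len(rep_rows)
            seen[key] = idx
            rep_rows.append(row)
        hap_map.append(idx)

    return HaplotypeBlock(
        chrom=records[0].chrom,
        variant_sites=[(r.pos, r.id, r.ref, r.alt[0]) for r in records],
        n_samples=n_samples,
        rep_haplotypes=np.vstack(rep_rows),
        hap_map=hap_map,
        first_marker_index=block.first_marker_index,
        last_marker_index=(
            block.first_marker_index + l - 1 if block.first_marker_index else None
        ),
    )


def decompress_block(hblock: HaplotypeBlock, block_index: int = 0) -> GenotypeBlock:
    """Reconstruct the genotype block: allele of sample s at marker j is
    rep_haplotypes[hap_map[2s]][j] / [2s+1][j], always phased.

    Dosages are never fabricated; M3VCF carries haplotypes only.
    """
    u = hblock.u
    if len(hblock.hap_map) != 2 * hblock.n_samples:
        raise CodecError(
            f"corrupt block: hap_map has {len(hblock.hap_map)} entries for "
            f"{hblock.n_samples} samples"
        )
    for r in hblock.hap_map:
        if not 0 <= r < u:
            raise CodecError(f"corrupt block: representative index {r} out of range [0,{u})")
    reps = hblock.rep_haplotypes
    records: list[VariantRecord] = []
    for j, (pos, vid, ref, alt) in enumerate(hblock.variant_sites):
        genotypes = [
            Genotype(int(reps[hblock.hap_map[2 * s], j]), int(reps[hblock.hap_map[2 * s + 1], j]), True)
            for s in range(hblock.n_samples)
        ]
        records.append(
            VariantRecord(hblock.chrom, pos, vid, ref, [alt], ".", ".", ".", genotypes)
        )
    return GenotypeBlock(
        records=records,
        block_index=block_index,
        first_marker_index=hblock.first_marker_index,
    )


# ---------------------------------------------------------------------------
# M3VCF serialization
# ---------------------------------------------------------------------------

class M3vcfWriter:
    """Writes the M3VCF dialect; tracks global marker indices across blocks."""

    def __init__(self, path: str, file_mode: FileMode, header: VcfHeader):
        self._fh: TextIO = vcf_io.open_text_sink(path, file_mode)
        self.path = path
        self.header = header
        self.next_marker_index = 1  # 1-based global position of the next new marker
        self.blocks_written = 0
        self._closed = False
        for meta in header.meta_lines:
            self._fh.write(meta + "\n")
        self._fh.write(f"##M3VCF.version={M3VCF_VERSION_TAG}\n")
        self._fh.write(header.column_line() + "\n")

    def write_block(self, hblock: HaplotypeBlock) -> None:
        if hblock.n_samples != self.header.n_samples:
            raise CodecError(
                f"block has {hblock.n_samples} samples, header declares {self.header.n_samples}"
            )
        l, u = hblock.n_markers, hblock.u
        first = hblock.first_marker_index or self.next_marker_index
        last = first + l - 1
        self.next_marker_index = last + 1
        sample_cols = [
            f"{hblock.hap_map[2 * s]}|{hblock.hap_map[2 * s + 1]}"
            for s in range(hblock.n_samples)
        ]
        head = [
            hblock.chrom,
            str(hblock.variant_sites[0][0]),
            f"<BLOCK:{first}-{last}>",
            ".",
            ".",
            ".",
            ".",
            f"VARIANTS={l};REPS={u}",
            "",  # FORMAT column deliberately empty in block headers
        ]
        self._fh.write("\t".join(head + sample_cols) + "\n")
        reps = hblock.rep_haplotypes
        for j, (pos, vid, ref, alt) in enumerate(hblock.variant_sites):
            hap_string = "".join("1" if reps[r, j] else "0" for r in range(u))
            self._fh.write(
                "\t".join([hblock.chrom, str(pos), vid, ref, alt, ".", ".", ".", hap_string])
                + "\n"
            )
        self.blocks_written += 1

    def close(self) -> None:
        if not self._closed:
            self._fh.close()
            self._closed = True

    def __enter__(self) -> "M3vcfWriter":
        return self

    def __exit__(self, *exc) -> None:
        self.close()


class M3vcfReader:
    """Reads the M3VCF dialect block by block."""

    def __init__(self, path: str, file_mode: Optional[FileMode] = None):
        if not os.path.isfile(path):
            raise M3vcfFormatError(f"the m3vcf file:{path}, open error (no such file)")
        mode = file_mode or vcf_io.detect_file_mode(path)
        opener = gzip.open if mode is FileMode.GZ else open
        self._fh: TextIO = opener(path, "rt", encoding="utf-8")  # type: ignore[operator]
        self.path = path
        self.file_mode = mode
        self.header: Optional[VcfHeader] = None
        self._closed = False

    def read_header(self) -> VcfHeader:
        meta: list[str] = []
        while True:
            try:
                line = self._fh.readline()
            except (OSError, EOFError, UnicodeDecodeError) as e:
                raise M3vcfFormatError(f"{self.path}: unreadable ({e})") from e
            if not line:
                raise M3vcfFormatError(f"{self.path}: no #CHROM column line before EOF")
            line = line.rstrip("\n")
            if line.startswith("##"):
                if not line.startswith("##M3VCF.version="):
                    meta.append(line)
                continue
            if not line.startswith("#CHROM"):
                raise M3vcfFormatError(f"{self.path}: malformed header line {line[:40]!r}")
            cols = line.split("\t")
            if len(cols) < vcf_io.N_FIXED + 1:
                raise M3vcfFormatError(f"{self.path}: column line has no sample columns")
            self.header = VcfHeader(meta_lines=meta, sample_ids=cols[vcf_io.N_FIXED :])
            return self.header

    def read_block(self) -> Optional[HaplotypeBlock]:
        """Read the next block, or None at end of file."""
        if self.header is None:
            raise M3vcfFormatError("read_header must be called before read_block")
        line = self._fh.readline()
        while line and not line.strip():
            line = self._fh.readline()
        if not line:
            return None
        fields = line.rstrip("\n").split("\t")
        n = self.header.n_samples
        if len(fields) != vcf_io.N_FIXED + n:
            raise M3vcfFormatError(
                f"{self.path}: block header has {len(fields)} fields, expected {vcf_io.N_FIXED + n}"
            )
        chrom, _pos, block_id, _r, _a, _q, _f, info = fields[:8]
        try:
            kv = dict(item.split("=", 1) for item in info.split(";"))
            l, u = int(kv["VARIANTS"]), int(kv["REPS"])
        except (ValueError, KeyError):
            raise M3vcfFormatError(f"{self.path}: bad block INFO {info!r}") from None
        first_idx = last_idx = None
        if block_id.startswith("<BLOCK:") and block_id.endswith(">"):
            try:
                lo, hi = block_id[7:-1].split("-")
                first_idx, last_idx = int(lo), int(hi)
            except ValueError:
                raise M3vcfFormatError(f"{self.path}: bad block id {block_id!r}") from None
        hap_map: list[int] = []
        for col in fields[vcf_io.N_FIXED :]:
            try:
                a_s, b_s = col.split("|")
                hap_map.extend((int(a_s), int(b_s)))
            except ValueError:
                raise M3vcfFormatError(f"{self.path}: bad sample haplotype column {col!r}") from None

        sites: list[tuple[int, str, str, str]] = []
        reps = np.empty((u, l), dtype=np.uint8)
        for j in range(l):
            vline = self._fh.readline()
            if not vline:
                raise M3vcfFormatError(
                    f"{self.path}: truncated block (expected {l} variant lines, got {j})"
                )
            vf = vline.rstrip("\n").split("\t")
            if len(vf) != 9:
                raise M3vcfFormatError(f"{self.path}: variant line has {len(vf)} fields, expected 9")
            hap_string = vf[8]
            if len(hap_string) != u or set(hap_string) - {"0", "1"}:
                raise M3vcfFormatError(
                    f"{self.path}: representative string {hap_string!r} does not match REPS={u}"
                )
            try:
                pos = int(vf[1])
            except ValueError:
                raise M3vcfFormatError(f"{self.path}: bad POS {vf[1]!r}") from None
            sites.append((pos, vf[2], vf[3], vf[4]))
            for r in range(u):
                reps[r, j] = hap_string[r] == "1"
        return HaplotypeBlock(
            chrom=chrom,
            variant_sites=sites,
            n_samples=n,
            rep_haplotypes=reps,
            hap_map=hap_map,
            first_marker_index=first_idx,
            last_marker_index=last_idx,
        )

    def iter_blocks(self) -> Iterator[HaplotypeBlock]:
        while (b := self.read_block()) is not None:
            yield b

    def close(self) -> None:
        if not self._closed:
            self._fh.close()
            self._closed = True

    def __enter__(self) -> "M3vcfReader":
        return self

    def __exit__(self, *exc) -> None:
        self.close()


def write_m3vcf_block(hblock: HaplotypeBlock, sink: M3vcfWriter) -> None:
    """Append one block to an open writer (header must already be written)."""
    sink.write_block(hblock)


def read_m3vcf_block(source: M3vcfReader) -> Optional[HaplotypeBlock]:
    """Read the next block from an open reader, or None at EOF."""
    return source.read_block()


# ---------------------------------------------------------------------------
# Whole-file conversion
# ---------------------------------------------------------------------------

@dataclass
class CompressArgs:
    """Arguments for VCF -> M3VCF conversion (0 = optimized default)."""

    input_path: str
    output_path: str
    input_mode: Optional[FileMode] = None  # None = auto-detect
    output_mode: FileMode = FileMode.GZ
    buffer_size: int = 0  # markers per block; 0 -> 10
    thread_num: int = 0
    memory_limit: int = 0  # bytes
    skip_invalid: bool = False
    overlap_boundary: bool = False
    force: bool = False


@dataclass
class ConvertArgs:
    """Arguments for M3VCF -> VCF conversion."""

    input_path: str
    output_path: str
    input_mode: Optional[FileMode] = None
    output_mode: FileMode = FileMode.GZ
    thread_num: int = 0
    memory_limit: int = 0
    force: bool = False


@dataclass
class CompressSummary:
    markers_read: int = 0
    markers_compressed: int = 0
    markers_rejected: int = 0
    rejected_by_reason: dict[str, int] = field(default_factory=dict)
    blocks_written: int = 0
    status: str = "ok"
    message: str = ""


@dataclass
class ConvertSummary:
    blocks_read: int = 0
    markers_written: int = 0
    status: str = "ok"
    message: str = ""


def _resolve_config(thread_num: int, buffer_size: int, memory_limit: int) -> _pipeline.PipelineConfig:
    return _pipeline.resolve_auto(
        _pipeline.PipelineConfig(
            p=thread_num, q=thread_num, buffer_size=buffer_size, memory_limit=memory_limit
        )
    )


def vcf_to_m3vcf(args: CompressArgs) -> CompressSummary:
    """Compress a VCF into M3VCF through the staged pipeline.

    Ineligible records (non-bi-allelic, non-SNP, unphased) abort the run by
    default; with ``skip_invalid`` they are dropped, counted per reason, and
    the remaining eligible markers are re-blocked so every block except the
    last holds exactly ``buffer_size`` markers.
    """
    summary = CompressSummary()
    cfg = _resolve_config(args.thread_num, args.buffer_size, args.memory_limit)
    bs = cfg.buffer_size
    overlap = args.overlap_boundary and bs >= 2
    try:
        if os.path.exists(args.output_path) and not args.force:
            raise CodecError(f"output file exists: {args.output_path} (use force to overwrite)")
        in_mode = args.input_mode or vcf_io.detect_file_mode(args.input_path)
        missing = MissingPolicy.SKIP if args.skip_invalid else MissingPolicy.ERROR
        with vcf_io.open_vcf(args.input_path, in_mode, ParseFields.GT, missing) as stream:
            header = stream.read_header()
            with M3vcfWriter(args.output_path, args.output_mode, header) as writer:

                def blocks() -> Iterator[GenotypeBlock]:
                    """Assemble eligible records into blocks of exactly bs markers."""
                    buf: list[VariantRecord] = []
                    first_idx = 1
                    out_idx = 0
                    while True:
                        raw = stream.read_block(bs, cfg.q)
                        if raw is None:
                            break
                        summary.markers_read += raw.num_data_lines
                        for rec in raw.records:
                            if args.skip_invalid:
                                ok, reason = is_eligible(rec)
                                if not ok:
                                    summary.markers_rejected += 1
                                    summary.rejected_by_reason[reason] = (
                                        summary.rejected_by_reason.get(reason, 0) + 1
                                    )
                                    logger.info(
                                        "skipping ineligible record %s:%s (%s)",
                                        rec.chrom, rec.pos, reason,
                                    )
                                    continue
                            buf.append(rec)
                            if len(buf) == bs:
                                yield GenotypeBlock(buf, out_idx, first_idx)
                                out_idx += 1
                                if overlap:
                                    first_idx += bs - 1
                                    buf = [buf[-1]]
                                else:
                                    first_idx += bs
                                    buf = []
                    # remainder block, never padded; under overlap a lone
                    # carried-over boundary marker is not re-emitted
                    if buf and not (overlap and len(buf) == 1 and out_idx > 0):
                        yield GenotypeBlock(buf, out_idx, first_idx)

                missing_before = stream.n_skipped_missing
                _pipeline.run_pipeline(
                    source=blocks(),
                    parse_fn=lambda b: b,
                    compress_fn=compress_block,
                    sink=writer.write_block,
                    config=cfg,
                )
                if args.skip_invalid and stream.n_skipped_missing > missing_before:
                    n_miss = stream.n_skipped_missing - missing_before
                    summary.markers_read += n_miss
                    summary.markers_rejected += n_miss
                    summary.rejected_by_reason["missing-genotype"] = (
                        summary.rejected_by_reason.get("missing-genotype", 0) + n_miss
                    )
                summary.blocks_written = writer.blocks_written
        # under overlap a shared boundary marker is stored twice but counts once
        summary.markers_compressed = summary.markers_read - summary.markers_rejected
    except Exception as e:  # noqa: BLE001 - reported through the summary contract
        summary.status = "error"
        summary.message = f"vcffile:[{args.input_path}] compressed error! {e}"
        logger.debug(summary.message)
        return summary
    return summary


def m3vcf_to_vcf(args: ConvertArgs) -> ConvertSummary:
    """Decompress an M3VCF back to a VCF with FORMAT 'GT'.

    Blocks written with the shared-boundary (overlap) convention are
    detected from their global marker-index ranges and the duplicated
    first marker of each non-initial block is emitted only once.
    """
    summary = ConvertSummary()
    try:
        if os.path.exists(args.output_path) and not args.force:
            raise CodecError(f"output file exists: {args.output_path} (use force to overwrite)")
        with M3vcfReader(args.input_path, args.input_mode) as reader:
            header = reader.read_header()
            cfg = _resolve_config(args.thread_num, 0, args.memory_limit)
            with vcf_io.open_text_sink(args.output_path, args.output_mode) as out:
                for meta in header.meta_lines:
                    out.write(meta + "\n")
                out.write(header.column_line() + "\n")
                last_global_idx = 0

                def write_block(item: tuple[Optional[int], GenotypeBlock]) -> None:
                    nonlocal last_global_idx
                    first_idx, gblock = item
                    records = gblock.records
                    if first_idx is not None and first_idx <= last_global_idx:
                        records = records[last_global_idx - first_idx + 1 :]
                    for rec in records:
                        out.write(vcf_io.format_record(rec) + "\n")
                    summary.markers_written += len(records)
                    if first_idx is not None:
                        last_global_idx = max(last_global_idx, first_idx + len(gblock.records) - 1)

                def source() -> Iterator[HaplotypeBlock]:
                    while (b := reader.read_block()) is not None:
                        summary.blocks_read += 1
                        yield b

                _pipeline.run_pipeline(
                    source=source(),
                    parse_fn=lambda b: b,
                    compress_fn=lambda hb: (hb.first_marker_index, decompress_block(hb)),
                    sink=write_block,
                    config=cfg,
                )
    except Exception as e:  # noqa: BLE001
        summary.status = "error"
        summary.message = f"m3vcffile:[{args.input_path}] convert error! {e}"
        logger.debug(summary.message)
        return summary
    return summary
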