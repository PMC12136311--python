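"""Streaming VCF reader/writer with parallel FORMAT parsing.

Reads VCF v4.x text (plain or gzip), keeping only the fields that
haplotype-block compression needs: the nine fixed site columns plus the
per-sample GT (genotype) and, optionally, DS (dosage) FORMAT values.
Records can be consumed one line at a time or in blocks; within a block
the raw lines are read serially ("Reading Data" phase) and then parsed
across a pool of workers ("Parsing" phase), with file order restored so
the result is byte-identical for any worker count.
"""

from __future__ import annotations

import gzip
import io
import logging
import os
import threading
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from enum import Enum, Flag, auto
from typing import Iterable, Iterator, Optional, TextIO

logger = logging.getLogger("m3vcfkit")

_FIXED_COLUMNS = ("#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT")
N_FIXED = 9


class FileMode(Enum):
    """Physical encoding of a VCF/M3VCF stream: gzip-wrapped or plain text."""

    GZ = "GZ"
    NORMAL = "NORMAL"


class ParseFields(Flag):
    """Which FORMAT fields to extract per sample. GT is mandatory; DS optional."""

    GT = auto()
    DS = auto()


class MissingPolicy(Enum):
    """What to do with records containing missing genotypes ('./.', '.|.')."""

    ERROR = "error"
    SKIP = "skip"


class VcfError(Exception):
    """Base class for VCF reading/writing failures."""


class VcfOpenError(VcfError):
    pass


class VcfHeaderError(VcfError):
    pass


class VcfFormatError(VcfError):
    """Byte-level format problem (e.g. GZ mode on a non-gzip file)."""


class VcfParseError(VcfError):
    """A data line failed to parse; carries the 1-based line number."""

    def __init__(self, message: str, line_number: Optional[int] = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class MissingGenotypeError(VcfParseError):
    """A sample genotype is missing ('.'); rejected unless the stream skips."""


@dataclass(frozen=True, slots=True)
class Genotype:
    """One diploid call: two allele indices (0 = REF) and phase status."""

    allele_a: int
    allele_b: int
    phased: bool

    def __str__(self) -> str:
        sep = "|" if self.phased else "/"
        return f"{self.allele_a}{sep}{self.allele_b}"


@dataclass(slots=True)
class VariantRecord:
    """One parsed VCF data line: site fields plus per-sample GT and optional DS."""

    chrom: str
    pos: int
    id: str
    ref: str
    alt: list[str]
    qual: str
    filter: str
    info: str
    genotypes: list[Genotype]
    dosages: Optional[list[float]] = None

    @property
    def n_samples(self) -> int:
        return len(self.genotypes)


@dataclass(slots=True)
class GenotypeBlock:
    """An ordered run of consecutive records sharing one sample set.

    The unit of work moved through the conversion pipeline.  ``block_index``
    is the block's position in file order; ``first_marker_index`` (when set)
    is the 1-based global index of the block's first marker, used by the
    overlap-boundary convention.
    """

    records: list[VariantRecord]
    block_index: int = 0
    first_marker_index: Optional[int] = None

    @property
    def num_data_lines(self) -> int:
        return len(self.records)

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class VcfHeader:
    """Meta lines ('##...', verbatim, newline-stripped) and the sample roster."""

    meta_lines: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        if len(self.sample_ids) < 1:
            raise VcfHeaderError("header declares zero sample columns")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise VcfHeaderError("duplicate sample ids in header")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def column_line(self) -> str:
        return "\t".join(_FIXED_COLUMNS + tuple(self.sample_ids))


def parse_record(
    line: str,
    n_samples: int,
    parse_fields: ParseFields,
    line_number: Optional[int] = None,
) -> VariantRecord:
    """Parse one tab-separated VCF data line.

    Only GT (always) and DS (when requested and present in the record's
    FORMAT) are extracted; all other FORMAT fields are skipped.  GT may sit
    at any position within FORMAT.  Missing genotypes raise
    :class:`MissingGenotypeError`.
    """
    fields = line.rstrip("\n").rstrip("\r").split("\t")
    if len(fields) != N_FIXED + n_samples:
        raise VcfParseError(
            f"expected {N_FIXED + n_samples} columns, found {len(fields)}", line_number
        )
    chrom, pos_s, vid, ref, alt_s, qual, filt, info, fmt = fields[:N_FIXED]
    try:
        pos = int(pos_s)
    except ValueError:
        raise VcfParseError(f"POS is not an integer: {pos_s!r}", line_number) from None
    alt = alt_s.split(",")

    fmt_keys = fmt.split(":")
    try:
        gt_idx = fmt_keys.index("GT")
    except ValueError:
        raise VcfParseError("FORMAT lacks GT", line_number) from None
    ds_idx: Optional[int] = None
    if ParseFields.DS in parse_fields and "DS" in fmt_keys:
        ds_idx = fmt_keys.index("DS")

    n_alt = len(alt)
    genotypes: list[Genotype] = []
    dosages: Optional[list[float]] = [] if ds_idx is not None else None
    for col in fields[N_FIXED:]:
        parts = col.split(":")
        gt = parts[gt_idx]
        if "|" in gt:
            phased = True
            a_s, _, b_s = gt.partition("|")
        elif "/" in gt:
            phased = False
            a_s, _, b_s = gt.partition("/")
        else:
            raise VcfParseError(f"malformed GT token {gt!r}", line_number)
        if a_s == "." or b_s == ".":
            raise MissingGenotypeError(f"missing genotype {gt!r}", line_number)
        try:
            a, b = int(a_s), int(b_s)
        except ValueError:
            raise VcfParseError(f"malformed GT token {gt!r}", line_number) from None
        if a < 0 or b < 0 or a > n_alt or b > n_alt:
            raise VcfParseError(
                f"allele index out of range in GT {gt!r} (ALT has {n_alt} allele(s))",
                line_number,
            )
        genotypes.append(Genotype(a, b, phased))
        if ds_idx is not None:
            if ds_idx >= len(parts):
                raise VcfParseError("sample column lacks the DS field", line_number)
            try:
                dosages.append(float(parts[ds_idx]))  # type: ignore[union-attr]
            except ValueError:
                raise VcfParseError(
                    f"DS token is not a number: {parts[ds_idx]!r}", line_number
                ) from None

    return VariantRecord(chrom, pos, vid, ref, alt, qual, filt, info, genotypes, dosages)


class VcfStream:
    """An open VCF file: header, cursor, and parse settings.

    Obtain via :func:`open_vcf`; use as a context manager or call
    :meth:`close` / :func:`close_stream`.  Records cannot be read before
    :meth:`read_header`.
    """

    def __init__(
        self,
        path: str,
        file_mode: FileMode,
        parse_fields: ParseFields,
        missing: MissingPolicy = MissingPolicy.ERROR,
    ):
        self.path = path
        self.file_mode = file_mode
        self.parse_fields = parse_fields
        self.missing = missing
        self.header: Optional[VcfHeader] = None
        self.n_skipped_missing = 0
        self._line_no = 0  # 1-based number of the last line consumed
        self._block_counter = 0
        self._closed = False
        try:
            if file_mode is FileMode.GZ:
                self._fh: TextIO = gzip.open(path, "rt", encoding="utf-8")
            else:
                self._fh = open(path, "rt", encoding="utf-8")
        except OSError as e:
            raise VcfOpenError(f"the vcf file:{path}, open error ({e})") from e

    # -- low-level ---------------------------------------------------------

    def _readline(self) -> str:
        try:
            line = self._fh.readline()
        except (OSError, EOFError, UnicodeDecodeError) as e:
            raise VcfFormatError(f"{self.path}: not readable in {self.file_mode.value} mode ({e})") from e
        if line:
            self._line_no += 1
        return line

    # -- API ----------------------------------------------------------------

    def read_header(self) -> VcfHeader:
        """Consume meta lines and the #CHROM column line; store and return the header."""
        if self.header is not None:
            raise VcfHeaderError("header already read")
        meta: list[str] = []
        while True:
            line = self._readline()
            if not line:
                raise VcfHeaderError(f"{self.path}: no #CHROM column line before EOF")
            line = line.rstrip("\n").rstrip("\r")
            if line.startswith("##"):
                meta.append(line)
                continue
            if not line.startswith("#CHROM"):
                raise VcfHeaderError(
                    f"{self.path}: expected #CHROM column line, found {line[:40]!r}"
                )
            cols = line.split("\t")
            if len(cols) < N_FIXED + 1:
                raise VcfHeaderError(f"{self.path}: column line has no sample columns")
            if tuple(cols[:N_FIXED]) != _FIXED_COLUMNS:
                raise VcfHeaderError(
                    f"{self.path}: malformed column line (fixed columns are {cols[:N_FIXED]})"
                )
            self.header = VcfHeader(meta_lines=meta, sample_ids=cols[N_FIXED:])
            return self.header

    def _require_header(self) -> VcfHeader:
        if self.header is None:
            raise VcfHeaderError("read_header must be called before reading records")
        return self.header

    def read_record(self) -> Optional[VariantRecord]:
        """Return the next record in file order, or None at end of file.

        With a SKIP missing policy, records containing missing genotypes are
        dropped (counted in ``n_skipped_missing``) and reading continues.
        """
        header = self._require_header()
        while True:
            line = self._readline()
            if not line:
                return None
            if not line.strip():
                continue
            try:
                return parse_record(line, header.n_samples, self.parse_fields, self._line_no)
            except MissingGenotypeError as e:
                if self.missing is MissingPolicy.SKIP:
                    self.n_skipped_missing += 1
                    logger.warning("skipping record with missing genotype: %s", e)
                    continue
                raise

    def read_block(self, num_lines: int, n_workers: int = 1) -> Optional[GenotypeBlock]:
        """Read up to ``num_lines`` records as one block, or None at EOF.

        Raw lines are read serially, then parsed across ``n_workers``
        contiguous chunks; record order equals file order regardless of
        worker scheduling.  Any parse error aborts the whole block.
        """
        if num_lines < 1:
            raise ValueError("num_lines must be >= 1")
        if n_workers < 1:
            raise ValueError("n_workers must be >= 1")
        header = self._require_header()

        raw: list[tuple[int, str]] = []  # (line number, text)
        while len(raw) < num_lines:
            line = self._readline()
            if not line:
                break
            if not line.strip():
                continue
            raw.append((self._line_no, line))
        if not raw:
            return None

        skip = self.missing is MissingPolicy.SKIP

        def parse_chunk(chunk: list[tuple[int, str]]) -> list[VariantRecord]:
            out = []
            for ln, text in chunk:
                try:
                    out.append(parse_record(text, header.n_samples, self.parse_fields, ln))
                except MissingGenotypeError as e:
                    if not skip:
                        raise
                    with self._skip_lock:
                        self.n_skipped_missing += 1
                    logger.warning("skipping record with missing genotype: %s", e)
            return out

        if n_workers == 1 or len(raw) == 1:
            records = parse_chunk(raw)
        else:
            k = min(n_workers, len(raw))
            step = -(-len(raw) // k)  # ceil
            chunks = [raw[i : i + step] for i in range(0, len(raw), step)]
            with ThreadPoolExecutor(max_workers=k, thread_name_prefix="vcf-parse") as pool:
                parsed = list(pool.map(parse_chunk, chunks))
            records = [r for chunk in parsed for r in chunk]
        if not records:
            # every line in this window was skipped; try the next window
            return self.read_block(num_lines, n_workers)
        block = GenotypeBlock(records=records, block_index=self._block_counter)
        self._block_counter += 1
        return block

    _skip_lock = threading.Lock()

    def iter_records(self) -> Iterator[VariantRecord]:
        while (rec := self.read_record()) is not None:
            yield rec

    def close(self) -> None:
        """Release the file handle; safe to call more than once."""
        if not self._closed:
            self._fh.close()
            self._closed = True

    @property
    def closed(self) -> bool:
        return self._closed

    def __enter__(self) -> "VcfStream":
        return self

    def __exit__(self, *exc) -> None:
        self.close()


def open_vcf(
    path: str,
    file_mode: FileMode,
    parse_fields: ParseFields = ParseFields.GT,
    missing: MissingPolicy = MissingPolicy.ERROR,
) -> VcfStream:
    """Open a VCF for reading. ``parse_fields`` must include GT."""
    if ParseFields.GT not in parse_fields:
        raise ValueError("parse_fields must include GT (DS alone is not supported)")
    if not os.path.isfile(path):
        raise VcfOpenError(f"the vcf file:{path}, open error (no such file)")
    return VcfStream(path, file_mode, parse_fields, missing)


def detect_file_mode(path: str) -> FileMode:
    """GZ if the file starts with the gzip magic bytes, else by suffix, else NORMAL."""
    try:
        with open(path, "rb") as fh:
            magic = fh.read(2)
        if magic == b"\x1f\x8b":
            return FileMode.GZ
    except OSError:
        pass
    return FileMode.GZ if path.endswith(".gz") else FileMode.NORMAL


class _GzTextSink(io.TextIOWrapper):
    """Text wrapper over a gzip member that also closes the raw file."""

    def __init__(self, gz: gzip.GzipFile, raw):
        super().__init__(gz, encoding="utf-8")
        self._raw = raw

    def close(self) -> None:
        try:
            super().close()
        finally:
            if not self._raw.closed:
                self._raw.close()


def open_text_sink(path: str, file_mode: FileMode) -> TextIO:
    """Open ``path`` for text writing, plain or gzip.

    Gzip output is written with a zeroed mtime and no embedded filename so
    identical content always yields identical bytes.
    """
    if file_mode is FileMode.NORMAL:
        return open(path, "wt", encoding="utf-8")
    raw = open(path, "wb")
    gz = gzip.GzipFile(filename="", fileobj=raw, mode="wb", mtime=0)
    return _GzTextSink(gz, raw)


def format_record(record: VariantRecord, with_ds: bool = False) -> str:
    """Render one record as a VCF data line (FORMAT = GT or GT:DS)."""
    fmt = "GT"
    cols = [
        record.chrom,
        str(record.pos),
        record.id,
        record.ref,
        ",".join(record.alt),
        record.qual,
        record.filter,
        record.info,
    ]
    if with_ds and record.dosages is not None:
        fmt = "GT:DS"
        samples = [f"{g}:{d:g}" for g, d in zip(record.genotypes, record.dosages)]
    else:
        samples = [str(g) for g in record.genotypes]
    return "\t".join(cols + [fmt] + samples)


def write_vcf(
    records: Iterable[VariantRecord],
    header: VcfHeader,
    path: str,
    file_mode: FileMode,
    with_ds: bool = False,
) -> int:
    """Write a header plus data lines; returns the number of data lines written."""
    n = 0
    with open_text_sink(path, file_mode) as fh:
        for meta in header.meta_lines:
            fh.write(meta + "\n")
        fh.write(header.column_line() + "\n")
        for rec in records:
            if rec.n_samples != header.n_samples:
                raise VcfError(
                    f"record at {rec.chrom}:{rec.pos} has {rec.n_samples} samples, "
                    f"header declares {header.n_samples}"
                )
            fh.write(format_record(rec, with_ds=with_ds) + "\n")
            n += 1
    return n


def close_stream(stream: VcfStream) -> None:
    """Close a stream; double-close is a no-op."""
    stream.close()


def release_block(block: GenotypeBlock) -> None:
    """Drop a block's records so their memory can be reclaimed; idempotent."""
    block.records.clear()


def release_record(record: VariantRecord) -> None:
    """Drop a record's per-sample payload; idempotent."""
    record.genotypes = []
    record.dosages = None
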