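"""Paired FASTQ/FASTA input and output.

Supports the dialects the merger must accept: 4-line FASTQ or FASTA,
dual-file or interleaved pairing, raw or gzip-compressed streams, and
Phred+33 / Phred+64 quality encodings with autodetection.  Reading is
streaming: memory use is constant in the number of reads.
"""

from __future__ import annotations

import gzip
import io
import re
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import BinaryIO, Iterable, Iterator, Optional, Sequence, Union

ASCII33 = "ascii33"
ASCII64 = "ascii64"

#: Quality assigned to FASTA records, which carry no qualities of their own.
DEFAULT_FASTA_QUALITY = 30
#: Input qualities are clamped here; bounds the error-probability table.
QUALITY_CEILING = 60

_GZIP_MAGIC = b"\x1f\x8b"
_SEQ_RE = re.compile(r"[ACGTN]+\Z")
_MATE_SUFFIX_RE = re.compile(r"/[12]$")

Source = Union[str, Path, BinaryIO]


class FastqFormatError(ValueError):
    """Malformed or truncated FASTQ/FASTA input."""


class PairSyncError(ValueError):
    """Mate identifiers do not correspond, or records cannot be paired."""


class AmbiguousEncodingError(ValueError):
    """Quality sample is consistent with both Phred+33 and Phred+64."""


class QualityRangeError(ValueError):
    """Quality score outside the encodable range for the chosen encoding."""


@dataclass(frozen=True, slots=True)
class Read:
    """A sequencing read: header, upper-case sequence over {A,C,G,T,N},
    and per-base Phred qualities stored compactly as ``bytes``."""

    id: str
    seq: str
    qual: bytes

    def __post_init__(self) -> None:
        if not isinstance(self.qual, bytes):
            object.__setattr__(self, "qual", bytes(self.qual))
        if not self.seq:
            raise ValueError(f"empty sequence for read {self.id!r}")
        if _SEQ_RE.fullmatch(self.seq) is None:
            bad = re.search(r"[^ACGTN]", self.seq)
            raise ValueError(
                f"illegal character {self.seq[bad.start()]!r} at position "
                f"{bad.start()} in read {self.id!r}"
            )
        if len(self.qual) != len(self.seq):
            raise ValueError(
                f"sequence/quality length mismatch for read {self.id!r}: "
                f"{len(self.seq)} vs {len(self.qual)}"
            )
        if self.qual and max(self.qual) > QUALITY_CEILING:
            raise ValueError(
                f"quality above ceiling {QUALITY_CEILING} in read {self.id!r}"
            )

    def __len__(self) -> int:
        return len(self.seq)


def pair_key(header: str) -> str:
    """Normalize a read header for mate matching: keep the token before the
    first whitespace and strip a trailing ``/1`` or ``/2``."""
    token = header.split(None, 1)[0] if header else header
    return _MATE_SUFFIX_RE.sub("", token)


@dataclass(frozen=True, slots=True)
class ReadPair:
    """A read pair as sequenced (read 2 not yet reverse-complemented)."""

    r1: Read
    r2: Read

    def __post_init__(self) -> None:
        k1, k2 = pair_key(self.r1.id), pair_key(self.r2.id)
        if k1 != k2:
            raise PairSyncError(
                f"mismatched pair ids: {self.r1.id!r} vs {self.r2.id!r}"
            )


def detect_quality_encoding(sample: Iterable[Union[str, bytes]]) -> str:
    """Decide between Phred+33 and Phred+64 from raw quality lines.

    Any codepoint below 59 forces ``ascii33`` (impossible as Phred+64);
    all codepoints >= 64 with at least one above 74 (quality > 41 under
    Phred+33, which real instruments do not emit) indicates ``ascii64``.
    Raises :class:`AmbiguousEncodingError` when neither rule fires; callers
    default to ``ascii33`` with a warning.
    """
    lo, hi = 255, 0
    seen = False
    for line in sample:
        data = line.encode("ascii") if isinstance(line, str) else line
        if not data:
            continue
        seen = True
        lo = min(lo, min(data))
        hi = max(hi, max(data))
    if not seen:
        raise ValueError("no non-empty quality lines in sample")
    if lo < 59:
        return ASCII33
    if lo >= 64 and hi > 74:
        return ASCII64
    raise AmbiguousEncodingError(
        f"quality codepoints in [{lo},{hi}] are legal under both encodings"
    )


def _open_binary(src: Source) -> tuple[io.BufferedReader, bool]:
    """Return a peekable binary reader over *src*; flag whether we own it."""
    if isinstance(src, (str, Path)):
        return open(src, "rb"), True
    raw = src
    if isinstance(raw, io.BufferedReader):
        return raw, False
    return io.BufferedReader(raw), False  # type: ignore[arg-type]


def _maybe_gunzip(handle: io.BufferedReader) -> io.BufferedReader:
    if handle.peek(2)[:2] == _GZIP_MAGIC:
        return io.BufferedReader(gzip.GzipFile(fileobj=handle, mode="rb"))
    return handle


# A raw record prior to quality decoding: (header, seq, qual_line_or_None).
_RawRecord = tuple[str, str, Optional[bytes]]


def _iter_raw_records(handle: io.BufferedReader, label: str) -> Iterator[_RawRecord]:
    first = handle.peek(1)[:1]
    if first == b"@":
        yield from _iter_fastq(handle, label)
    elif first == b">":
        yield from _iter_fasta(handle, label)
    elif first == b"":
        return
    else:
        raise FastqFormatError(
            f"{label}: unrecognized format (first byte {first!r})"
        )


def _iter_fastq(handle: io.BufferedReader, label: str) -> Iterator[_RawRecord]:
    index = 0
    while True:
        head = handle.readline()
        if not head:
            return
        lines = [head, handle.readline(), handle.readline(), handle.readline()]
        if not lines[3]:
            raise FastqFormatError(f"{label}: truncated record at index {index}")
        head, seq, plus, qual = (ln.rstrip(b"\r\n") for ln in lines)
        if not head.startswith(b"@"):
            raise FastqFormatError(
                f"{label}: record {index} does not start with '@'"
            )
        if not plus.startswith(b"+"):
            raise FastqFormatError(
                f"{label}: record {index} missing '+' separator line"
            )
        if len(seq) != len(qual):
            raise FastqFormatError(
                f"{label}: record {index} sequence/quality length mismatch"
            )
        yield head[1:].decode("ascii"), seq.decode("ascii").upper(), qual
        index += 1


def _iter_fasta(handle: io.BufferedReader, label: str) -> Iterator[_RawRecord]:
    header: Optional[str] = None
    chunks: list[str] = []
    index = 0
    for line in handle:
        line = line.rstrip(b"\r\n")
        if line.startswith(b">"):
            if header is not None:
                if not chunks:
                    raise FastqFormatError(
                        f"{label}: empty record at index {index}"
                    )
                yield header, "".join(chunks), None
                index += 1
            header = line[1:].decode("ascii")
            chunks = []
        elif header is None:
            raise FastqFormatError(f"{label}: sequence before first '>' header")
        else:
            chunks.append(line.decode("ascii").upper())
    if header is not None:
        if not chunks:
            raise FastqFormatError(f"{label}: empty record at index {index}")
        yield header, "".join(chunks), None


_ENCODING_SAMPLE = 100


def _decode_records(
    records: Iterator[_RawRecord],
    label: str,
    encoding: Optional[str],
    fasta_quality: int,
) -> Iterator[Read]:
    """Decode qualities, autodetecting the Phred offset from a buffered
    sample of the first records when *encoding* is None."""
    buffer: list[_RawRecord] = []
    if encoding is None:
        for rec in records:
            buffer.append(rec)
            if len(buffer) >= _ENCODING_SAMPLE:
                break
        qlines = [q for (_h, _s, q) in buffer if q is not None]
        if not qlines:
            encoding = ASCII33  # FASTA input: offset irrelevant
        else:
            try:
                encoding = detect_quality_encoding(qlines)
            except AmbiguousEncodingError:
                warnings.warn(
                    f"{label}: quality encoding undecidable, assuming Phred+33",
                    stacklevel=3,
                )
                encoding = ASCII33
    offset = 33 if encoding == ASCII33 else 64
    index = 0
    for source in (buffer, records):
        for header, seq, qline in source:
            if qline is None:
                qual = bytes([fasta_quality]) * len(seq)
            else:
                lo = min(qline)
                if lo < offset:
                    raise FastqFormatError(
                        f"{label}: record {index} quality codepoint {lo} below "
                        f"offset {offset}"
                    )
                qual = bytes(
                    min(c - offset, QUALITY_CEILING) for c in qline
                )
            try:
                yield Read(header, seq, qual)
            except ValueError as exc:
                raise FastqFormatError(f"{label}: record {index}: {exc}") from exc
            index += 1


def read_single(
    source: Source,
    *,
    encoding: Optional[str] = None,
    fasta_quality: int = DEFAULT_FASTA_QUALITY,
) -> Iterator[Read]:
    """Stream individual reads from a FASTQ/FASTA source (gzip-transparent)."""
    handle, owned = _open_binary(source)
    label = getattr(source, "name", None) or str(source)
    try:
        stream = _maybe_gunzip(handle)
        yield from _decode_records(
            _iter_raw_records(stream, label), label, encoding, fasta_quality
        )
    finally:
        if owned:
            handle.close()


def read_pairs(
    source1: Source,
    source2: Optional[Source] = None,
    *,
    interleaved: bool = False,
    encoding: Optional[str] = None,
    fasta_quality: int = DEFAULT_FASTA_QUALITY,
) -> Iterator[ReadPair]:
    """Stream read pairs from dual files or a single interleaved file.

    Pairs are yielded in file order.  In interleaved mode records 2k and
    2k+1 form pair k; an odd record count is an error.  In dual-file mode
    the files must have equal record counts and corresponding headers.
    """
    if interleaved:
        if source2 is not None:
            raise ValueError("interleaved mode takes a single source")
        it = read_single(source1, encoding=encoding, fasta_quality=fasta_quality)
        index = 0
        while True:
            r1 = next(it, None)
            if r1 is None:
                return
            r2 = next(it, None)
            if r2 is None:
                raise PairSyncError(
                    f"odd record count in interleaved input "
                    f"(read {r1.id!r} at record {2 * index} has no mate)"
                )
            yield ReadPair(r1, r2)
            index += 1
    else:
        if source2 is None:
            raise ValueError("dual-file mode needs two sources")
        it1 = read_single(source1, encoding=encoding, fasta_quality=fasta_quality)
        it2 = read_single(source2, encoding=encoding, fasta_quality=fasta_quality)
        index = 0
        while True:
            r1 = next(it1, None)
            r2 = next(it2, None)
            if r1 is None and r2 is None:
                return
            if r1 is None or r2 is None:
                short = "first" if r1 is None else "second"
                raise PairSyncError(
                    f"{short} input exhausted at pair index {index}"
                )
            yield ReadPair(r1, r2)
            index += 1


def _max_quality(encoding: str) -> int:
    return 126 - (33 if encoding == ASCII33 else 64)


class ReadWriter:
    """Incremental FASTQ/FASTA writer over a binary sink.

    gzip output is written with ``mtime=0`` so identical content yields
    identical bytes on every run.
    """

    def __init__(
        self,
        sink: Source,
        *,
        format: str = "fastq",
        encoding: str = ASCII33,
        gzip_out: bool = False,
    ) -> None:
        if format not in ("fastq", "fasta"):
            raise ValueError(f"unknown format {format!r}")
        if encoding not in (ASCII33, ASCII64):
            raise ValueError(f"unknown encoding {encoding!r}")
        self.format = format
        self.encoding = encoding
        self._offset = 33 if encoding == ASCII33 else 64
        self._qmax = _max_quality(encoding)
        self.count = 0
        if isinstance(sink, (str, Path)):
            self._raw: BinaryIO = open(sink, "wb")
            self._owned = True
        else:
            self._raw = sink
            self._owned = False
        if gzip_out:
            self._handle: BinaryIO = gzip.GzipFile(
                fileobj=self._raw, mode="wb", mtime=0
            )
        else:
            self._handle = self._raw
        self._gzipped = gzip_out

    def write(self, read: Read) -> None:
        if self.format == "fastq":
            if read.qual and max(read.qual) > self._qmax:
                raise QualityRangeError(
                    f"quality above {self._qmax} not encodable as "
                    f"{self.encoding} (read {read.id!r})"
                )
            qline = bytes(c + self._offset for c in read.qual)
            self._handle.write(
                b"@" + read.id.encode("ascii") + b"\n"
                + read.seq.encode("ascii") + b"\n+\n" + qline + b"\n"
            )
        else:
            self._handle.write(
                b">" + read.id.encode("ascii") + b"\n"
                + read.seq.encode("ascii") + b"\n"
            )
        self.count += 1

    def close(self) -> None:
        if self._gzipped:
            self._handle.close()
        if self._owned:
            self._raw.close()
        elif not self._gzipped:
            self._handle.flush()

    def __enter__(self) -> "ReadWriter":
        return self

    def __exit__(self, *exc) -> None:
        self.close()


def write_reads(
    reads: Iterable[Read],
    sink: Source,
    *,
    format: str = "fastq",
    encoding: str = ASCII33,
    gzip_out: bool = False,
) -> int:
    """Write reads to *sink*; returns the number written.

    For materialized sequences, qualities are range-checked up front so an
    error produces no output at all.
    """
    if isinstance(reads, Sequence) and format == "fastq":
        qmax = _max_quality(encoding)
        for read in reads:
            if read.qual and max(read.qual) > qmax:
                raise QualityRangeError(
                    f"quality above {qmax} not encodable as {encoding} "
                    f"(read {read.id!r})"
                )
    with ReadWriter(
        sink, format=format, encoding=encoding, gzip_out=gzip_out
    ) as writer:
        for read in reads:
            writer.write(read)
        return writer.count
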