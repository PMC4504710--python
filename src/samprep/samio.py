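"""Streaming reader/writer for SAM text.

The reader yields records lazily so pipelines never need the whole file in
memory just to parse it; the header is fully parsed before the first record
is produced.  Gzip-compressed input is accepted transparently (detected by
magic bytes).  Writing an opened stream back out with no intervening
modification reproduces the input byte-for-byte.
"""

from __future__ import annotations

import gzip
import io
import os
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Iterator, Union

from .model import SamAlignment, SamFormatError, SamHeader

Source = Union[str, Path, IO[str], IO[bytes]]


@dataclass
class RecordStream:
    """A parsed header plus a lazy sequence of alignment records."""

    header: SamHeader
    records: Iterator[SamAlignment]

    def __iter__(self) -> Iterator[SamAlignment]:
        return self.records


def _open_text(source: Source) -> IO[str]:
    if isinstance(source, (str, Path)):
        raw = open(source, "rb")
        if raw.read(2) == b"\x1f\x8b":
            raw.seek(0)
            return io.TextIOWrapper(gzip.GzipFile(fileobj=raw), newline="")
        raw.seek(0)
        return io.TextIOWrapper(raw, newline="")
    if isinstance(source, io.TextIOBase):
        return source  # type: ignore[return-value]
    # binary stream (possibly unseekable, e.g. a pipe): peek for gzip magic
    buffered = io.BufferedReader(source)  # type: ignore[arg-type]
    if buffered.peek(2)[:2] == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.GzipFile(fileobj=buffered), newline="")
    return io.TextIOWrapper(buffered, newline="")


def open_sam(source: Source) -> RecordStream:
    """Open a SAM file (path, text stream, or binary/gzip stream).

    The header is consumed eagerly; records are yielded on demand in file
    order.  Malformed header or alignment lines raise
    :class:`~samprep.model.SamFormatError` naming the line number.
    """
    stream = _open_text(source)
    header_lines: list[str] = []
    first_record: str | None = None
    lineno = 0
    for line in stream:
        lineno += 1
        if line.startswith("@"):
            header_lines.append(line)
        else:
            first_record = line
            break
    try:
        header = SamHeader.parse(header_lines)
    except SamFormatError as exc:
        raise SamFormatError(f"in header: {exc}") from exc

    def _records() -> Iterator[SamAlignment]:
        n = lineno
        if first_record is not None:
            yield _parse_record(first_record, n)
            for line in stream:
                n += 1
                yield _parse_record(line, n)
        stream.close()

    return RecordStream(header=header, records=_records())


def _parse_record(line: str, lineno: int) -> SamAlignment:
    stripped = line.rstrip("\n")
    if not stripped:
        raise SamFormatError(f"blank line {lineno} in alignment section")
    try:
        return SamAlignment.from_line(stripped)
    except SamFormatError as exc:
        raise SamFormatError(f"line {lineno}: {exc}") from exc


def read_sam(source: Source) -> tuple[SamHeader, list[SamAlignment]]:
    """Read an entire SAM file into memory."""
    stream = open_sam(source)
    return stream.header, list(stream.records)


def write_sam(
    header: SamHeader,
    records: Iterable[SamAlignment],
    sink: Source,
) -> int:
    """Serialize header then records to *sink*; return the record count.

    A path ending in ``.gz`` is gzip-compressed.  Lines are LF-terminated.
    """
    if isinstance(sink, (str, Path)):
        if str(sink).endswith(".gz"):
            with gzip.open(sink, "wt", newline="") as fh:
                return _write(header, records, fh)
        with open(sink, "w", newline="") as fh:
            return _write(header, records, fh)
    return _write(header, records, sink)  # type: ignore[arg-type]


def _write(header: SamHeader, records: Iterable[SamAlignment], fh: IO[str]) -> int:
    for line in header.to_lines():
        fh.write(line + "\n")
    count = 0
    for rec in records:
        fh.write(rec.to_line() + "\n")
        count += 1
    return count
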