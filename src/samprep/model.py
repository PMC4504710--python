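"""Domain model for SAM headers and alignment records.

The SAM text format is tab-separated: zero or more ``@``-prefixed header
lines (``@HD``, ``@SQ``, ``@RG``, ``@PG``, ``@CO``) followed by alignment
lines with 11 mandatory columns and optional ``TAG:TYPE:VALUE`` fields.
Everything in this package operates on the two classes defined here.

Two properties drive the design:

* **Byte fidelity.**  ``parse`` followed by ``serialize`` reproduces the
  input byte-for-byte — header line order, attribute order within a line,
  optional-field order, unknown tags.  Pipelines are validated by textual
  comparison of outputs, so untouched content must never be rewritten.
* **1-based coordinates.**  Positions are kept exactly as SAM prints them;
  no 0-based conversion is exposed anywhere.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional


class SamFormatError(ValueError):
    """A line or record violates the SAM text contract."""


# -- flag bits ---------------------------------------------------------------

FLAG_PAIRED = 0x1
FLAG_PROPER_PAIR = 0x2
FLAG_UNMAPPED = 0x4
FLAG_MATE_UNMAPPED = 0x8
FLAG_REVERSE = 0x10
FLAG_MATE_REVERSE = 0x20
FLAG_FIRST_OF_PAIR = 0x40
FLAG_SECOND_OF_PAIR = 0x80
FLAG_SECONDARY = 0x100
FLAG_QC_FAIL = 0x200
FLAG_DUPLICATE = 0x400
FLAG_SUPPLEMENTARY = 0x800


# -- CIGAR -------------------------------------------------------------------

_CIGAR_TOKEN = re.compile(r"(\d+)([MIDNSHP=X])")

#: operations that consume reference bases
REF_CONSUMING_OPS = frozenset("MDN=X")
#: operations that consume query (read) bases
QUERY_CONSUMING_OPS = frozenset("MIS=X")
CLIP_OPS = frozenset("SH")


@dataclass(frozen=True)
class CigarOp:
    """One CIGAR operation: a positive length and an op code (MIDNSHP=X)."""

    length: int
    op: str

    def __str__(self) -> str:
        return f"{self.length}{self.op}"


def parse_cigar(cigar: str) -> list[CigarOp]:
    """Parse a CIGAR string into operations.

    Raises :class:`SamFormatError` on ``"*"`` or malformed input; the parse
    is strict so that re-serialization is exactly the input.
    """
    if cigar == "*" or not cigar:
        raise SamFormatError(f"CIGAR {cigar!r} has no operations")
    ops = [CigarOp(int(n), op) for n, op in _CIGAR_TOKEN.findall(cigar)]
    if "".join(map(str, ops)) != cigar:
        raise SamFormatError(f"malformed CIGAR {cigar!r}")
    return ops


def cigar_reference_length(ops: Iterable[CigarOp]) -> int:
    """Number of reference bases consumed (M/D/N/=/X)."""
    return sum(o.length for o in ops if o.op in REF_CONSUMING_OPS)


def cigar_query_length(ops: Iterable[CigarOp]) -> int:
    """Number of read bases accounted for, soft clips included (M/I/S/=/X)."""
    return sum(o.length for o in ops if o.op in QUERY_CONSUMING_OPS)


# -- alignment records -------------------------------------------------------


@dataclass
class SamAlignment:
    """One SAM alignment line.

    The 11 mandatory columns are stored typed (``pos``, ``flag`` etc. as
    integers); optional fields as an ordered list of ``(tag, type, value)``
    with the value kept as its raw text, so unknown or duplicate tags
    round-trip verbatim.
    """

    qname: str
    flag: int
    rname: str
    pos: int
    mapq: int
    cigar: str
    rnext: str
    pnext: int
    tlen: int
    seq: str
    qual: str
    tags: list[tuple[str, str, str]] = field(default_factory=list)

    # -- parsing / serialization --

    @classmethod
    def from_line(cls, line: str) -> "SamAlignment":
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 11:
            raise SamFormatError(
                f"alignment line has {len(fields)} fields, expected >= 11"
            )
        tags = []
        for raw in fields[11:]:
            parts = raw.split(":", 2)
            if len(parts) != 3 or len(parts[0]) != 2 or len(parts[1]) != 1:
                raise SamFormatError(f"malformed optional field {raw!r}")
            tags.append((parts[0], parts[1], parts[2]))
        try:
            aln = cls(
                qname=fields[0],
                flag=int(fields[1]),
                rname=fields[2],
                pos=int(fields[3]),
                mapq=int(fields[4]),
                cigar=fields[5],
                rnext=fields[6],
                pnext=int(fields[7]),
                tlen=int(fields[8]),
                seq=fields[9],
                qual=fields[10],
                tags=tags,
            )
        except ValueError as exc:
            raise SamFormatError(f"bad numeric column: {exc}") from exc
        if aln.flag < 0:
            raise SamFormatError("flag must be non-negative")
        if aln.seq != "*" and aln.qual != "*" and len(aln.seq) != len(aln.qual):
            raise SamFormatError(
                f"SEQ/QUAL length mismatch for {aln.qname!r}: "
                f"{len(aln.seq)} vs {len(aln.qual)}"
            )
        return aln

    def to_line(self) -> str:
        parts = [
            self.qname,
            str(self.flag),
            self.rname,
            str(self.pos),
            str(self.mapq),
            self.cigar,
            self.rnext,
            str(self.pnext),
            str(self.tlen),
            self.seq,
            self.qual,
        ]
        parts.extend(f"{t}:{ty}:{v}" for t, ty, v in self.tags)
        return "\t".join(parts)

    def copy(self) -> "SamAlignment":
        return SamAlignment(
            self.qname, self.flag, self.rname, self.pos, self.mapq,
            self.cigar, self.rnext, self.pnext, self.tlen, self.seq,
            self.qual, list(self.tags),
        )

    # -- flag predicates --

    @property
    def is_paired(self) -> bool:
        return bool(self.flag & FLAG_PAIRED)

    @property
    def is_unmapped(self) -> bool:
        return bool(self.flag & FLAG_UNMAPPED)

    @property
    def is_mate_unmapped(self) -> bool:
        return bool(self.flag & FLAG_MATE_UNMAPPED)

    @property
    def is_reverse(self) -> bool:
        return bool(self.flag & FLAG_REVERSE)

    @property
    def is_secondary(self) -> bool:
        return bool(self.flag & FLAG_SECONDARY)

    @property
    def is_supplementary(self) -> bool:
        return bool(self.flag & FLAG_SUPPLEMENTARY)

    @property
    def is_duplicate(self) -> bool:
        return bool(self.flag & FLAG_DUPLICATE)

    # -- optional fields --

    def get_tag(self, tag: str) -> Optional[tuple[str, str]]:
        """Return ``(type, value)`` for the first occurrence of *tag*."""
        for t, ty, v in self.tags:
            if t == tag:
                return ty, v
        return None

    def set_tag(self, tag: str, vtype: str, value: str) -> None:
        """Set *tag*, replacing the first occurrence in place or appending."""
        for i, (t, _, _) in enumerate(self.tags):
            if t == tag:
                self.tags[i] = (tag, vtype, value)
                return
        self.tags.append((tag, vtype, value))

    def del_tag(self, tag: str) -> None:
        self.tags = [t for t in self.tags if t[0] != tag]

    # -- coordinates --

    def unclipped_position(self) -> tuple[int, str]:
        """Unclipped 5' mapping coordinate and strand.

        For the forward strand this is ``pos`` pushed back over leading
        soft/hard clips; for the reverse strand it is the rightmost
        reference base plus trailing clips.  Differently-clipped copies of
        the same source molecule therefore share this coordinate, which is
        why duplicate keys are built from it.
        """
        if self.is_unmapped or self.cigar == "*":
            raise SamFormatError(
                f"unclipped position undefined for unmapped record {self.qname!r}"
            )
        ops = parse_cigar(self.cigar)
        if self.is_reverse:
            end = self.pos + cigar_reference_length(ops) - 1
            for o in reversed(ops):
                if o.op not in CLIP_OPS:
                    break
                end += o.length
            return end, "reverse"
        start = self.pos
        for o in ops:
            if o.op not in CLIP_OPS:
                break
            start -= o.length
        return start, "forward"


def flag_predicates(aln: SamAlignment) -> dict[str, bool]:
    """All standard flag-bit predicates of a record as a dict."""
    return {
        "is_paired": aln.is_paired,
        "is_unmapped": aln.is_unmapped,
        "is_mate_unmapped": aln.is_mate_unmapped,
        "is_reverse": aln.is_reverse,
        "is_secondary": aln.is_secondary,
        "is_supplementary": aln.is_supplementary,
        "is_duplicate": aln.is_duplicate,
    }


# -- header ------------------------------------------------------------------

HeaderFields = list[tuple[str, str]]


@dataclass
class SamHeader:
    """Parsed SAM header preserving line and attribute order.

    ``lines`` holds ``(record_type, payload)`` pairs in file order, where
    ``record_type`` is the two-letter code without ``@`` and payload is an
    ordered list of ``(tag, value)`` pairs — except for ``CO`` lines, whose
    payload is the raw comment text.  Serialization reconstructs the input
    byte-for-byte when nothing mutated the header.
    """

    lines: list[tuple[str, object]] = field(default_factory=list)

    @classmethod
    def parse(cls, raw_lines: Iterable[str]) -> "SamHeader":
        header = cls()
        for lineno, line in enumerate(raw_lines, start=1):
            line = line.rstrip("\n")
            if not line.startswith("@") or len(line) < 3:
                raise SamFormatError(f"malformed header line {lineno}: {line!r}")
            code = line[1:3]
            if code == "CO":
                header.lines.append(("CO", line[4:] if len(line) > 3 else ""))
                continue
            fields: HeaderFields = []
            for chunk in line.split("\t")[1:]:
                tag, sep, value = chunk.partition(":")
                if not sep:
                    raise SamFormatError(
                        f"malformed header field {chunk!r} on line {lineno}"
                    )
                fields.append((tag, value))
            header.lines.append((code, fields))
        header.validate()
        return header

    def validate(self) -> None:
        names = [name for name, _, _ in self.sequence_dictionary]
        if len(names) != len(set(names)):
            raise SamFormatError("duplicate sequence names in @SQ lines")
        ids = [
            self.fields_get(f, "ID") for code, f in self.lines if code == "RG"
        ]
        if len(ids) != len(set(ids)):
            raise SamFormatError("duplicate read-group IDs in @RG lines")

    @staticmethod
    def fields_get(fields: object, tag: str) -> Optional[str]:
        for t, v in fields:  # type: ignore[union-attr]
            if t == tag:
                return v
        return None

    # -- serialization --

    def to_lines(self) -> list[str]:
        out = []
        for code, payload in self.lines:
            if code == "CO":
                out.append(f"@CO\t{payload}")
            else:
                out.append(
                    "@" + code + "".join(f"\t{t}:{v}" for t, v in payload)
                )
        return out

    def copy(self) -> "SamHeader":
        h = SamHeader()
        for code, payload in self.lines:
            h.lines.append((code, payload if code == "CO" else list(payload)))
        return h

    # -- views --

    @property
    def sequence_dictionary(self) -> list[tuple[str, int, HeaderFields]]:
        """Ordered ``(name, length, extra attribute pairs)`` per @SQ line."""
        entries = []
        for code, fields in self.lines:
            if code != "SQ":
                continue
            name = self.fields_get(fields, "SN")
            length = self.fields_get(fields, "LN")
            if name is None or length is None:
                raise SamFormatError("@SQ line missing SN or LN")
            extras = [(t, v) for t, v in fields if t not in ("SN", "LN")]
            entries.append((name, int(length), extras))
        return entries

    @property
    def read_groups(self) -> list[HeaderFields]:
        return [list(fields) for code, fields in self.lines if code == "RG"]

    @property
    def sort_order(self) -> Optional[str]:
        for code, fields in self.lines:
            if code == "HD":
                return self.fields_get(fields, "SO")
        return None

    def reference_index(self, rname: str) -> Optional[int]:
        """Position of *rname* in the sequence dictionary, or None."""
        if rname == "*":
            return None
        for i, (name, _, _) in enumerate(self.sequence_dictionary):
            if name == rname:
                return i
        return None

    def reference_index_map(self) -> dict[str, int]:
        """Name → dictionary index, for per-record hot paths."""
        return {
            name: i for i, (name, _, _) in enumerate(self.sequence_dictionary)
        }

    # -- mutation --

    def _replace_block(self, code: str, new_lines: list[tuple[str, object]]) -> None:
        """Replace all lines of *code* with *new_lines* at the position of
        the first old one (appended at the end if none existed)."""
        first = next(
            (i for i, (c, _) in enumerate(self.lines) if c == code), None
        )
        kept = [entry for entry in self.lines if entry[0] != code]
        if first is None:
            first = len(kept)
        else:
            first = min(first, len(kept))
        self.lines = kept[:first] + new_lines + kept[first:]

    def set_sort_order(self, order: str) -> None:
        """Set the SO tag on @HD, creating the line if absent."""
        for i, (code, fields) in enumerate(self.lines):
            if code == "HD":
                updated = [
                    (t, order if t == "SO" else v) for t, v in fields
                ]
                if self.fields_get(fields, "SO") is None:
                    updated.append(("SO", order))
                self.lines[i] = ("HD", updated)
                return
        self.lines.insert(0, ("HD", [("VN", "1.6"), ("SO", order)]))

    def set_read_groups(self, groups: list[HeaderFields]) -> None:
        for g in groups:
            if not self.fields_get(g, "ID"):
                raise SamFormatError("read group without ID")
        self._replace_block("RG", [("RG", list(g)) for g in groups])
        self.validate()

    def set_sequence_dictionary(
        self, entries: list[tuple[str, int, HeaderFields]]
    ) -> None:
        new = []
        for name, length, extras in entries:
            fields: HeaderFields = [("SN", name), ("LN", str(length))]
            fields.extend(extras)
            new.append(("SQ", fields))
        self._replace_block("SQ", new)
        self.validate()

    def add_program(self, pg_id: str, fields: HeaderFields) -> None:
        """Append one @PG line (ID first, remaining fields in given order)."""
        self.lines.append(("PG", [("ID", pg_id)] + list(fields)))


def reference_index(header: SamHeader, rname: str) -> Optional[int]:
    """Functional form of :meth:`SamHeader.reference_index`."""
    return header.reference_index(rname)
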