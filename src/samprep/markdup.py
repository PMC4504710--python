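"""PCR duplicate marking as a single-pass memoized filter.

Picard detects duplicates in three passes: sort by position, group reads
sharing a position and keep the best-scoring one, rewrite the file marking
the rest.  Here the same semantics are produced in one pass with
best-record memoization tables:

* a **fragment table** keyed by :class:`EndKey` — (library, reference
  index, unclipped 5' coordinate, strand) — holding the best fragment seen
  so far at that position;
* a **pair table** keyed by :class:`PairKey` — the two end keys of a
  complete read pair, canonically ordered — holding the best pair;
* a **pending-mates map** qname → first-seen end, so pairs are scored when
  the second mate arrives.

When a record collides with a table entry, the worse of the two (lower
score; on ties, larger qname) is marked immediately and the better one
kept in the table, so marking needs no sorted input and its result is
invariant under any permutation of the records.

Three semantic rules, matching Picard:

* among complete pairs sharing a PairKey, exactly the best pair survives;
* among fragments sharing an EndKey, exactly the best survives — unless a
  complete pair has an end at that key, in which case *all* fragments
  there are marked (pair trumps fragment);
* pair ends are never marked because of fragments.

A finalize hook (run after the last record) downgrades still-pending reads
whose mate never appeared to fragments, and applies the pair-trumps-
fragment rule; only then are all verdicts final.  Unmapped, secondary and
supplementary records are exempt: never marked, never able to mark others.
Marking touches flag bit 0x400 and nothing else; any pre-existing 0x400
bits are cleared first, so the result is a pure function of positions and
scores.
"""

from __future__ import annotations

from typing import Callable, NamedTuple, Optional

from .engine import PreparationStep
from .model import (
    FLAG_DUPLICATE,
    FLAG_FIRST_OF_PAIR,
    FLAG_MATE_UNMAPPED,
    FLAG_PAIRED,
    FLAG_SECOND_OF_PAIR,
    FLAG_SECONDARY,
    FLAG_SUPPLEMENTARY,
    FLAG_UNMAPPED,
    SamAlignment,
    SamFormatError,
    SamHeader,
)

#: minimum base quality that contributes to a record's duplicate score
SCORE_MIN_QUALITY = 15

#: default library for records with no RG tag or whose @RG line has no LB
DEFAULT_LIBRARY = "unknown"

#: optional field stamped on split copies of region-spanning pair ends;
#: such records act as pair-end-presence markers and are exempt otherwise
PROVENANCE_TAG = "sp"

EXEMPT_MASK = FLAG_UNMAPPED | FLAG_SECONDARY | FLAG_SUPPLEMENTARY


class EndKey(NamedTuple):
    """Duplicate key of one read end."""

    library: str
    ref_index: int
    position: int  # unclipped 5' coordinate
    reverse: bool


class PairKey(NamedTuple):
    """Symmetric key of a complete read pair (smaller EndKey first)."""

    first: EndKey
    second: EndKey

    @classmethod
    def of(cls, a: EndKey, b: EndKey) -> "PairKey":
        return cls(a, b) if a <= b else cls(b, a)


def dup_score(qual: str) -> int:
    """Sum of phred base qualities >= 15; 0 for ``"*"`` (Picard's score)."""
    if qual == "*":
        return 0
    total = 0
    for ch in qual:
        q = ord(ch) - 33
        if q >= SCORE_MIN_QUALITY:
            total += q
    return total


def record_score(rec: SamAlignment) -> int:
    return dup_score(rec.qual)


def preference_key(score: int, qname: str) -> tuple[int, str]:
    """Sort key under which the *preferred* record is minimal.

    Higher score wins; on equal scores the lexicographically smaller qname
    wins.  Both the single-pass tables and any reference implementation
    must use this exact ordering for results to be order-invariant.
    """
    return (-score, qname)


def classify(rec: SamAlignment, mate_present: Callable[[SamAlignment], bool]) -> str:
    """Duplicate-marking role of a record: ``exempt``/``pair_end``/``fragment``.

    ``mate_present`` supplies the end-of-stream knowledge of whether the
    record's primary mate actually occurs in the input.
    """
    if rec.flag & EXEMPT_MASK:
        return "exempt"
    if (
        rec.flag & FLAG_PAIRED
        and not rec.flag & FLAG_MATE_UNMAPPED
        and mate_present(rec)
    ):
        return "pair_end"
    return "fragment"


def library_lookup(header: SamHeader) -> dict[str, str]:
    """RG ID → LB library name from the header (missing LB → default)."""
    table = {}
    for fields in header.read_groups:
        rg_id = SamHeader.fields_get(fields, "ID")
        lb = SamHeader.fields_get(fields, "LB")
        table[rg_id] = lb if lb else DEFAULT_LIBRARY
    return table


def end_key(
    rec: SamAlignment, ref_index: dict[str, int], libraries: dict[str, str]
) -> EndKey:
    pos, strand = rec.unclipped_position()
    rg = rec.get_tag("RG")
    library = libraries.get(rg[1], DEFAULT_LIBRARY) if rg else DEFAULT_LIBRARY
    try:
        idx = ref_index[rec.rname]
    except KeyError:
        raise SamFormatError(
            f"record {rec.qname!r} mapped to unknown contig {rec.rname!r}"
        ) from None
    return EndKey(library, idx, pos, strand == "reverse")


class _FragEntry:
    __slots__ = ("best", "best_score", "pair_present")

    def __init__(self) -> None:
        self.best: Optional[SamAlignment] = None
        self.best_score = 0
        self.pair_present = False


class DuplicateTable:
    """Shared best-record tables; updates converge regardless of order."""

    def __init__(self, ref_index: dict[str, int], libraries: dict[str, str]):
        self.ref_index = ref_index
        self.libraries = libraries
        self.fragments: dict[EndKey, _FragEntry] = {}
        self.pairs: dict[PairKey, tuple[int, str, SamAlignment, SamAlignment]] = {}
        self.pending: dict[str, tuple[SamAlignment, EndKey]] = {}
        self.seen: set[tuple[str, int]] = set()

    # -- record routing --

    def add(self, rec: SamAlignment) -> None:
        rec.flag &= ~FLAG_DUPLICATE
        if rec.get_tag(PROVENANCE_TAG) is not None:
            # split copy of a spanning pair end: only asserts pair presence
            if not rec.flag & EXEMPT_MASK:
                self._assert_pair_present(
                    end_key(rec, self.ref_index, self.libraries)
                )
            return
        if rec.flag & EXEMPT_MASK:
            return
        identity = (rec.qname, rec.flag & (FLAG_FIRST_OF_PAIR | FLAG_SECOND_OF_PAIR))
        if identity in self.seen:
            raise SamFormatError(
                f"two primary records named {rec.qname!r} with the same "
                "first/second-of-pair flags"
            )
        self.seen.add(identity)
        key = end_key(rec, self.ref_index, self.libraries)
        if rec.flag & FLAG_PAIRED and not rec.flag & FLAG_MATE_UNMAPPED:
            mate = self.pending.pop(rec.qname, None)
            if mate is None:
                self.pending[rec.qname] = (rec, key)
            else:
                self._add_pair(mate[0], mate[1], rec, key)
        else:
            self._add_fragment(rec, key)

    # -- table updates (compare-and-swap with deterministic preference) --

    def _add_fragment(self, rec: SamAlignment, key: EndKey) -> None:
        entry = self.fragments.setdefault(key, _FragEntry())
        if entry.pair_present:
            rec.flag |= FLAG_DUPLICATE
            return
        score = record_score(rec)
        if entry.best is None:
            entry.best, entry.best_score = rec, score
        elif preference_key(score, rec.qname) < preference_key(
            entry.best_score, entry.best.qname
        ):
            entry.best.flag |= FLAG_DUPLICATE
            entry.best, entry.best_score = rec, score
        else:
            rec.flag |= FLAG_DUPLICATE

    def _assert_pair_present(self, key: EndKey) -> None:
        entry = self.fragments.setdefault(key, _FragEntry())
        if not entry.pair_present:
            entry.pair_present = True
            if entry.best is not None:
                entry.best.flag |= FLAG_DUPLICATE
                entry.best = None

    def _add_pair(
        self, a: SamAlignment, akey: EndKey, b: SamAlignment, bkey: EndKey
    ) -> None:
        self._assert_pair_present(akey)
        self._assert_pair_present(bkey)
        pkey = PairKey.of(akey, bkey)
        score = record_score(a) + record_score(b)
        incumbent = self.pairs.get(pkey)
        if incumbent is None:
            self.pairs[pkey] = (score, a.qname, a, b)
            return
        inc_score, inc_qname, inc_a, inc_b = incumbent
        if preference_key(score, a.qname) < preference_key(inc_score, inc_qname):
            inc_a.flag |= FLAG_DUPLICATE
            inc_b.flag |= FLAG_DUPLICATE
            self.pairs[pkey] = (score, a.qname, a, b)
        else:
            a.flag |= FLAG_DUPLICATE
            b.flag |= FLAG_DUPLICATE

    # -- end of stream --

    def finalize(self) -> None:
        """Downgrade mateless pending reads to fragments.

        Pending entries are replayed through the fragment table; the
        deterministic preference makes the outcome independent of replay
        order.
        """
        pending, self.pending = self.pending, {}
        for rec, key in pending.values():
            self._add_fragment(rec, key)


def mark_duplicates() -> PreparationStep:
    """Preparation step setting flag 0x400 per Picard's duplicate semantics.

    Marks, never removes; records need not be sorted.  Use the
    :func:`~samprep.steps.remove_duplicates` output step to drop marked
    records at write-out instead.
    """

    def header_stage(header: SamHeader, state: dict):
        table = DuplicateTable(header.reference_index_map(), library_lookup(header))
        state.setdefault("finalizers", []).append(table.finalize)

        def worker_stage():
            # the tables are shared across workers by design; updates are
            # order-invariant, so no worker-local state is needed
            def record_stage(rec: SamAlignment) -> bool:
                table.add(rec)
                return True

            return record_stage

        return worker_stage

    return PreparationStep(name="mark-duplicates", header_stage=header_stage)
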