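"""Whole-set sorting with deterministic tie-breaking.

Coordinate order sorts by (sequence-dictionary index of RNAME, POS); records
whose RNAME is ``"*"`` sort after everything else.  Placed-unmapped records
(flag 0x4 set but coordinates borrowed from the mate) sort at their stated
coordinate, as samtools and Picard do.  Ties keep input order (the sort is
stable), so results do not depend on worker scheduling.  Sorting happens in
memory; there is no external-merge fallback.
"""

from __future__ import annotations

from typing import Iterable

from .model import SamAlignment, SamFormatError, SamHeader

ORDERS = ("coordinate", "queryname")


def sort_records(
    header: SamHeader,
    records: Iterable[SamAlignment],
    order: str = "coordinate",
) -> list[SamAlignment]:
    """Return *records* reordered; sets the header's SO tag to *order*.

    The output is a permutation of the input.  A mapped record whose RNAME
    is missing from the sequence dictionary raises
    :class:`~samprep.model.SamFormatError` naming the record.
    """
    if order not in ORDERS:
        raise ValueError(f"unknown sort order {order!r}")
    records = list(records)
    if order == "queryname":
        out = sorted(records, key=lambda r: r.qname)
    else:
        index = header.reference_index_map()

        def key(rec: SamAlignment):
            if rec.rname == "*":
                return (1, 0, 0)
            try:
                return (0, index[rec.rname], rec.pos)
            except KeyError:
                raise SamFormatError(
                    f"record {rec.qname!r} mapped to {rec.rname!r}, "
                    "absent from the sequence dictionary"
                ) from None

        out = sorted(records, key=key)
    header.set_sort_order(order)
    return out
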