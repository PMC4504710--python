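"""Concrete preparation steps, each packaged as a three-level filter.

These are the record-level operations that standard practice runs as
separate SAMtools/Picard invocations: removing unmapped reads, filtering
on mapping quality and flag consistency, replacing read groups, and
replacing/filtering the sequence dictionary.  Each returns a
:class:`~samprep.engine.PreparationStep` and touches only the fields its
contract names.
"""

from __future__ import annotations

import shlex
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

from .engine import Pipeline, PreparationStep
from .markdup import mark_duplicates
from .model import (
    FLAG_DUPLICATE,
    FLAG_MATE_UNMAPPED,
    FLAG_UNMAPPED,
    HeaderFields,
    SamAlignment,
    SamFormatError,
    SamHeader,
)
from .samio import open_sam


@dataclass
class ReadGroupSpec:
    """Attribute pairs for one @RG line; ID is mandatory."""

    fields: HeaderFields = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.id:
            raise SamFormatError("read-group spec requires a non-empty ID")

    @property
    def id(self) -> Optional[str]:
        return SamHeader.fields_get(self.fields, "ID")

    @classmethod
    def parse(cls, text: str) -> "ReadGroupSpec":
        """Parse ``"ID:grp1 SM:sample1 LB:lib1 ..."`` (space-separated)."""
        pairs: HeaderFields = []
        for chunk in shlex.split(text):
            tag, sep, value = chunk.partition(":")
            if not sep or len(tag) != 2:
                raise SamFormatError(f"malformed read-group attribute {chunk!r}")
            pairs.append((tag, value))
        return cls(fields=pairs)


def filter_unmapped() -> PreparationStep:
    """Drop records whose flag has the unmapped bit (0x4) set."""

    def header_stage(header: SamHeader, state: dict):
        def worker_stage():
            def record_stage(rec: SamAlignment) -> bool:
                return (rec.flag & FLAG_UNMAPPED) == 0

            return record_stage

        return worker_stage

    return PreparationStep(name="filter-unmapped-reads", header_stage=header_stage)


def filter_erroneous_mapping(
    min_mapq: int = 0, require_consistent_flags: bool = True
) -> PreparationStep:
    """Drop mapped records below *min_mapq* and flag/field contradictions.

    With *require_consistent_flags*, a record whose flag claims mapped but
    whose RNAME is ``"*"`` or POS is 0 is dropped, and vice versa (flag
    claims unmapped while RNAME and POS are set).
    """
    if not 0 <= min_mapq <= 255:
        raise ValueError("min_mapq must be in [0, 255]")

    def header_stage(header: SamHeader, state: dict):
        def worker_stage():
            def record_stage(rec: SamAlignment) -> bool:
                unmapped_flag = bool(rec.flag & FLAG_UNMAPPED)
                if not unmapped_flag and rec.mapq < min_mapq:
                    return False
                if require_consistent_flags:
                    placed = rec.rname != "*" and rec.pos != 0
                    if not unmapped_flag and not placed:
                        return False
                    if unmapped_flag and placed:
                        return False
                return True

            return record_stage

        return worker_stage

    return PreparationStep(name="filter-erroneous-mapping", header_stage=header_stage)


def replace_read_groups(spec: Union[ReadGroupSpec, str]) -> PreparationStep:
    """Replace all @RG lines with *spec* and point every record's RG at it."""
    if isinstance(spec, str):
        spec = ReadGroupSpec.parse(spec)
    rg_id = spec.id

    def header_stage(header: SamHeader, state: dict):
        header.set_read_groups([list(spec.fields)])

        def worker_stage():
            def record_stage(rec: SamAlignment) -> bool:
                rec.set_tag("RG", "Z", rg_id)
                return True

            return record_stage

        return worker_stage

    return PreparationStep(name="replace-read-groups", header_stage=header_stage)


def load_sequence_dictionary(path: Union[str, Path]) -> list[tuple[str, int, HeaderFields]]:
    """Read a sequence dictionary from a SAM-header-style file (@SQ lines)."""
    return open_sam(path).header.sequence_dictionary


def replace_reference_sequences(
    new_dictionary: list[tuple[str, int, HeaderFields]],
) -> PreparationStep:
    """Replace the sequence dictionary, dropping records on removed contigs.

    A surviving record whose mate's contig was removed gets RNEXT ``"*"``,
    PNEXT 0, the mate-unmapped bit set and TLEN zeroed.  If the relative
    order of retained contigs changed, the execution is flagged as
    requiring a re-sort (``ExecutionReport.resort_required``).
    """
    names = [name for name, _, _ in new_dictionary]
    if len(names) != len(set(names)):
        raise SamFormatError("new sequence dictionary has duplicate names")
    name_set = set(names)

    def header_stage(header: SamHeader, state: dict):
        old_retained = [
            name
            for name, _, _ in header.sequence_dictionary
            if name in name_set
        ]
        new_retained = [name for name in names if name in old_retained]
        if old_retained != new_retained:
            state["resort_required"] = True
        header.set_sequence_dictionary(new_dictionary)

        def worker_stage():
            def record_stage(rec: SamAlignment) -> bool:
                if rec.rname != "*" and rec.rname not in name_set:
                    return False
                mate_ref = rec.rname if rec.rnext == "=" else rec.rnext
                if mate_ref != "*" and mate_ref not in name_set:
                    rec.rnext = "*"
                    rec.pnext = 0
                    rec.tlen = 0
                    rec.flag |= FLAG_MATE_UNMAPPED
                return True

            return record_stage

        return worker_stage

    return PreparationStep(
        name="replace-reference-sequences", header_stage=header_stage
    )


def remove_duplicates() -> PreparationStep:
    """Output step: drop records carrying the duplicate bit (0x400)."""

    def header_stage(header: SamHeader, state: dict):
        def worker_stage():
            def record_stage(rec: SamAlignment) -> bool:
                return (rec.flag & FLAG_DUPLICATE) == 0

            return record_stage

        return worker_stage

    return PreparationStep(name="remove-duplicates", header_stage=header_stage)


def add_program_record(
    pg_id: str, fields: Optional[HeaderFields] = None
) -> PreparationStep:
    """Append one @PG line to the header (no per-record work)."""

    def header_stage(header: SamHeader, state: dict):
        header.add_program(pg_id, fields or [])
        return None

    return PreparationStep(name="add-program-record", header_stage=header_stage)


# -- the three standard preparation protocols --------------------------------

_DEFAULT_RG = "ID:group1 LB:lib1 PL:ILLUMINA PU:unit1 SM:sample1"


def protocol_pipeline(
    name: str,
    read_group: str = _DEFAULT_RG,
    dictionary: Optional[list[tuple[str, int, HeaderFields]]] = None,
) -> list[object]:
    """The three GATK-practice preparation protocols as stage lists.

    Returns an ordered list whose items are either a
    :class:`~samprep.engine.PreparationStep` or the marker ``("sort",
    order)``.  ``basic1`` is sort + mark duplicates; ``support3`` adds
    read-group replacement; ``jp`` is the five-step pipeline (filter
    unmapped/erroneous reads, mark duplicates, replace read groups,
    replace the sequence dictionary, sort).
    """
    if name == "basic1":
        return [mark_duplicates(), ("sort", "coordinate")]
    if name == "support3":
        return [
            mark_duplicates(),
            replace_read_groups(read_group),
            ("sort", "coordinate"),
        ]
    if name == "jp":
        stages: list[object] = [
            filter_unmapped(),
            filter_erroneous_mapping(min_mapq=1),
            mark_duplicates(),
            replace_read_groups(read_group),
        ]
        if dictionary is not None:
            stages.append(replace_reference_sequences(dictionary))
        stages.append(("sort", "coordinate"))
        return stages
    raise ValueError(f"unknown protocol {name!r}")


def stages_to_pipeline(stages: list[object]) -> Pipeline:
    """Fold a protocol stage list into one single-pass :class:`Pipeline`."""
    pipeline = Pipeline()
    for stage in stages:
        if isinstance(stage, PreparationStep):
            pipeline.steps.append(stage)
        elif isinstance(stage, tuple) and stage[0] == "sort":
            pipeline.whole_set_operation = f"sort_{stage[1]}"
        else:
            raise ValueError(f"unknown stage {stage!r}")
    return pipeline
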