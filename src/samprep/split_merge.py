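"""Split a SAM file by genomic region and merge results back.

A *region* is one sequence-dictionary contig.  The splitter writes one file
per contig, one file for *spanning pairs* (complete pairs whose two ends
map to different contigs), and one for unmapped records, such that marking
duplicates separately per file and merging gives exactly the result of
marking the whole file:

* pairs confined to one region, and fragments, go to that region's file;
* both records of a spanning pair go to the spanning file, so every pair
  is complete in the file that scores it;
* each record of a spanning pair is *also* copied into its own region's
  file, stamped with the provenance tag ``sp:i:1``.  The copy exists so
  fragments co-located with a spanning pair end still lose by the
  pair-trumps-fragment rule; duplicate marking treats it as a pair-end
  presence marker and merge discards it, keeping the spanning file's
  version of the record authoritative.

A flag-paired read whose mate is missing from the file is a fragment, so
it is routed to its region's file even when RNEXT names another contig;
the splitter determines mate presence before routing.  Every output file
carries the full original header, so each is a self-contained SAM file.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

from .model import (
    FLAG_FIRST_OF_PAIR,
    FLAG_MATE_UNMAPPED,
    FLAG_PAIRED,
    FLAG_SECOND_OF_PAIR,
    FLAG_SECONDARY,
    FLAG_SUPPLEMENTARY,
    FLAG_UNMAPPED,
    SamAlignment,
    SamFormatError,
)
from .samio import RecordStream, read_sam, write_sam
from .sorting import sort_records
from .markdup import PROVENANCE_TAG

MANIFEST_NAME = "split_manifest.txt"
SPANNING = "spanning"
UNMAPPED = "unmapped"

_NOT_PRIMARY = FLAG_SECONDARY | FLAG_SUPPLEMENTARY


@dataclass
class SplitPlan:
    """Assignment of targets to file names inside an output directory."""

    region_files: dict[str, str] = field(default_factory=dict)
    spanning_file: str = f"{SPANNING}.sam"
    unmapped_file: str = f"{UNMAPPED}.sam"

    @classmethod
    def for_contigs(cls, contigs: list[str]) -> "SplitPlan":
        return cls(
            region_files={name: f"region_{i:03d}_{name}.sam"
                          for i, name in enumerate(contigs)}
        )


def _is_pair_end_candidate(rec: SamAlignment) -> bool:
    return bool(
        rec.flag & FLAG_PAIRED
        and not rec.flag & (FLAG_UNMAPPED | FLAG_MATE_UNMAPPED | _NOT_PRIMARY)
    )


def _complete_pair_qnames(records: list[SamAlignment]) -> set[str]:
    """qnames whose two primary mapped ends are both present in the input."""
    ends: dict[str, int] = {}
    for rec in records:
        if _is_pair_end_candidate(rec):
            ends[rec.qname] = ends.get(rec.qname, 0) | (
                rec.flag & (FLAG_FIRST_OF_PAIR | FLAG_SECOND_OF_PAIR)
            )
    both = FLAG_FIRST_OF_PAIR | FLAG_SECOND_OF_PAIR
    return {q for q, bits in ends.items() if bits == both}


def split(
    stream: RecordStream, out_dir: Union[str, Path], plan: SplitPlan | None = None
) -> Path:
    """Split *stream* into per-region/spanning/unmapped files under *out_dir*.

    Returns the manifest path.  The manifest records the original record
    count and every target, so :func:`merge` can verify completeness.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    header = stream.header
    contigs = [name for name, _, _ in header.sequence_dictionary]
    if not contigs:
        raise SamFormatError("cannot split: empty sequence dictionary")
    if plan is None:
        plan = SplitPlan.for_contigs(contigs)

    records = list(stream.records)
    complete = _complete_pair_qnames(records)

    buckets: dict[str, list[SamAlignment]] = {name: [] for name in contigs}
    spanning: list[SamAlignment] = []
    unmapped: list[SamAlignment] = []

    for rec in records:
        if rec.flag & FLAG_UNMAPPED or rec.rname == "*":
            unmapped.append(rec)
            continue
        if rec.rname not in buckets:
            raise SamFormatError(
                f"record {rec.qname!r} mapped to {rec.rname!r}, "
                "absent from the sequence dictionary"
            )
        if _is_pair_end_candidate(rec) and rec.qname in complete:
            mate_ref = rec.rname if rec.rnext == "=" else rec.rnext
            if mate_ref != rec.rname:
                spanning.append(rec)
                copy = rec.copy()
                copy.set_tag(PROVENANCE_TAG, "i", "1")
                buckets[rec.rname].append(copy)
                continue
        buckets[rec.rname].append(rec)

    manifest_lines = [f"records\t{len(records)}"]
    for name in contigs:
        path = out_dir / plan.region_files[name]
        write_sam(header, buckets[name], path)
        manifest_lines.append(f"region\t{name}\t{plan.region_files[name]}")
    write_sam(header, spanning, out_dir / plan.spanning_file)
    manifest_lines.append(f"{SPANNING}\t-\t{plan.spanning_file}")
    write_sam(header, unmapped, out_dir / plan.unmapped_file)
    manifest_lines.append(f"{UNMAPPED}\t-\t{plan.unmapped_file}")

    manifest = out_dir / MANIFEST_NAME
    manifest.write_text("".join(line + "\n" for line in manifest_lines))
    return manifest


def read_manifest(path: Union[str, Path]) -> tuple[int, list[str]]:
    """Return (original record count, target file names) from a manifest."""
    count = None
    files = []
    for line in Path(path).read_text().splitlines():
        parts = line.split("\t")
        if parts[0] == "records":
            count = int(parts[1])
        elif parts[0] in ("region", SPANNING, UNMAPPED):
            files.append(parts[2])
        else:
            raise SamFormatError(f"malformed manifest line {line!r}")
    if count is None:
        raise SamFormatError("manifest missing record count")
    return count, files


def merge(in_dir: Union[str, Path], output: Union[str, Path]) -> int:
    """Merge split target files back into one coordinate-sorted SAM file.

    Provenance-marked copies are discarded (the spanning file's version of
    each spanning-pair record is authoritative, whatever flags the copies
    acquired); provenance tags are stripped.  Errors if the merged record
    count does not match the manifest, or targets disagree on the
    sequence dictionary.
    """
    in_dir = Path(in_dir)
    expected, files = read_manifest(in_dir / MANIFEST_NAME)
    header = None
    merged: list[SamAlignment] = []
    for name in files:
        path = in_dir / name
        if not path.exists():
            raise SamFormatError(f"manifest names missing target {name!r}")
        file_header, records = read_sam(path)
        if header is None:
            header = file_header
        elif (
            file_header.sequence_dictionary != header.sequence_dictionary
        ):
            raise SamFormatError(
                f"target {name!r} has a different sequence dictionary"
            )
        for rec in records:
            if rec.get_tag(PROVENANCE_TAG) is not None:
                continue
            merged.append(rec)
    assert header is not None
    if len(merged) != expected:
        raise SamFormatError(
            f"merge produced {len(merged)} records, manifest says {expected}"
        )
    merged = sort_records(header, merged, "coordinate")
    return write_sam(header, merged, output)
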