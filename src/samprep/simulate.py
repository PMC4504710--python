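"""Deterministic synthetic SAM files and independent reference oracles.

The generator emulates the workload classes duplicate marking and
split/merge depend on: proper pairs, unpaired fragments, PCR duplicates
(same unclipped 5' positions and strands, fresh qname, perturbed or
identical base qualities), soft-clipped reads, cross-contig pairs, pairs
with a deleted mate, and unmapped reads.  Sequences are random bases, not
drawn from a reference genome, and there is no error model: positions and
qualities are what the algorithms consume, so that is what is controlled.

The oracles are deliberately naive re-implementations used only to check
the single-pass engine: a three-phase collect/select/mark duplicate
marker, and a sequential multi-pass pipeline runner that serializes to a
temporary file between steps (the standard practice the single-pass
architecture replaces).  They share only the score and tie-break
definitions with the production code.
"""

from __future__ import annotations

import random
import re
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Union

from .engine import Pipeline, PreparationStep, run_pipeline
from .markdup import DEFAULT_LIBRARY, dup_score, preference_key
from .model import (
    FLAG_FIRST_OF_PAIR,
    FLAG_MATE_REVERSE,
    FLAG_MATE_UNMAPPED,
    FLAG_PAIRED,
    FLAG_PROPER_PAIR,
    FLAG_REVERSE,
    FLAG_SECOND_OF_PAIR,
    FLAG_SECONDARY,
    FLAG_SUPPLEMENTARY,
    FLAG_UNMAPPED,
    SamAlignment,
    SamHeader,
)
from .samio import read_sam, write_sam

READ_LENGTH = 80
_BASES = "ACGT"


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic SAM file.

    ``duplicate_rate`` is the fraction of pairs/fragments that receive a
    PCR copy; ``cross_region_rate`` the fraction of pairs with mates on
    different contigs; ``clip_rate`` the fraction of read ends with random
    soft clips; ``missing_mate_rate`` the fraction of pairs whose second
    mate is deleted after duplication decisions.  Identical spec + seed
    give byte-identical output.
    """

    seed: int = 0
    contigs: tuple[tuple[str, int], ...] = (
        ("chr1", 100_000),
        ("chr2", 80_000),
        ("chr3", 60_000),
    )
    n_pairs: int = 150
    n_fragments: int = 40
    n_unmapped: int = 10
    duplicate_rate: float = 0.3
    cross_region_rate: float = 0.1
    clip_rate: float = 0.3
    missing_mate_rate: float = 0.05

    def __post_init__(self) -> None:
        if min(self.n_pairs, self.n_fragments, self.n_unmapped) < 0:
            raise ValueError("counts must be >= 0")
        for rate in (
            self.duplicate_rate,
            self.cross_region_rate,
            self.clip_rate,
            self.missing_mate_rate,
        ):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must be in [0, 1]")
        for name, length in self.contigs:
            if length < 4 * READ_LENGTH:
                raise ValueError(f"contig {name!r} too short for reads")


def _qual(rng: random.Random) -> str:
    # phred 2-40 uniform: low enough that score ties occur at small n
    return "".join(chr(33 + rng.randint(2, 40)) for _ in range(READ_LENGTH))


def _seq(rng: random.Random) -> str:
    return "".join(rng.choice(_BASES) for _ in range(READ_LENGTH))


def _clips(rng: random.Random, clip_rate: float) -> tuple[int, int]:
    lead = rng.randint(1, 12) if rng.random() < clip_rate else 0
    trail = rng.randint(1, 12) if rng.random() < clip_rate else 0
    if lead + trail > READ_LENGTH - 20:
        return 0, 0
    return lead, trail


def _make_end(
    rng: random.Random,
    qname: str,
    contig: str,
    unclipped5: int,
    reverse: bool,
    flag: int,
    clip_rate: float,
) -> SamAlignment:
    """Build one mapped read end with the given unclipped 5' coordinate."""
    lead, trail = _clips(rng, clip_rate)
    matched = READ_LENGTH - lead - trail
    if reverse:
        flag |= FLAG_REVERSE
        pos = unclipped5 - matched + 1 - trail
    else:
        pos = unclipped5 + lead
    cigar = (f"{lead}S" if lead else "") + f"{matched}M" + (f"{trail}S" if trail else "")
    mapq = 0 if rng.random() < 0.08 else rng.randint(20, 60)
    rec = SamAlignment(
        qname=qname,
        flag=flag,
        rname=contig,
        pos=pos,
        mapq=mapq,
        cigar=cigar,
        rnext="*",
        pnext=0,
        tlen=0,
        seq=_seq(rng),
        qual=_qual(rng),
        tags=[("RG", "Z", "rg1"), ("NM", "i", str(rng.randint(0, 4)))],
    )
    if rng.random() < 0.15:  # unknown tag: round-trip stress
        rec.set_tag("XZ", "Z", f"syn{rng.randint(0, 999)}")
    return rec


def _link_mates(a: SamAlignment, b: SamAlignment) -> None:
    for rec, mate in ((a, b), (b, a)):
        rec.rnext = "=" if mate.rname == rec.rname else mate.rname
        rec.pnext = mate.pos
        if mate.flag & FLAG_REVERSE:
            rec.flag |= FLAG_MATE_REVERSE
    if a.rname == b.rname:
        left, right = (a, b) if a.pos <= b.pos else (b, a)
        span = (
            right.pos
            + sum(int(n) for n, op in re.findall(r"(\d+)([MDN=X])", right.cigar))
            - left.pos
        )
        left.tlen, right.tlen = span, -span
    else:
        a.tlen = b.tlen = 0


@dataclass(frozen=True)
class _Molecule:
    """Source coordinates of one template; PCR copies share these."""

    contig1: str
    u5_1: int
    rev1: bool
    contig2: Optional[str] = None
    u5_2: Optional[int] = None
    rev2: Optional[bool] = None


def generate_records(spec: FixtureSpec) -> tuple[SamHeader, list[SamAlignment]]:
    """Generate the header and records for *spec* (deterministic)."""
    rng = random.Random(spec.seed)
    header = SamHeader.parse(
        ["@HD\tVN:1.6\tSO:unknown"]
        + [f"@SQ\tSN:{name}\tLN:{length}" for name, length in spec.contigs]
        + ["@RG\tID:rg1\tLB:lib1\tPL:ILLUMINA\tSM:sample1",
           "@CO\tsynthetic reads for pipeline testing"]
    )
    contigs = list(spec.contigs)
    serial = 0

    def next_name(kind: str) -> str:
        nonlocal serial
        serial += 1
        return f"syn{kind}{serial:06d}"

    def random_u5(contig_len: int) -> int:
        return rng.randint(2 * READ_LENGTH, contig_len - 2 * READ_LENGTH)

    records: list[SamAlignment] = []

    def emit_pair(mol: _Molecule, template: Optional[tuple[str, str]]) -> tuple:
        qname = next_name("p")
        f1 = FLAG_PAIRED | FLAG_FIRST_OF_PAIR
        f2 = FLAG_PAIRED | FLAG_SECOND_OF_PAIR
        if mol.contig1 == mol.contig2:
            f1 |= FLAG_PROPER_PAIR
            f2 |= FLAG_PROPER_PAIR
        r1 = _make_end(rng, qname, mol.contig1, mol.u5_1, mol.rev1, f1, spec.clip_rate)
        r2 = _make_end(rng, qname, mol.contig2, mol.u5_2, mol.rev2, f2, spec.clip_rate)
        if template is not None:
            # exact qual copy with some probability: forces score ties
            if rng.random() < 0.35:
                r1.qual, r2.qual = template
        records.extend((r1, r2))
        return r1, r2

    pair_templates: list[tuple[_Molecule, tuple[str, str]]] = []
    for _ in range(spec.n_pairs):
        c1, len1 = rng.choice(contigs)
        if rng.random() < spec.cross_region_rate and len(contigs) > 1:
            c2, len2 = rng.choice([c for c in contigs if c[0] != c1])
            u1, u2 = random_u5(len1), random_u5(len2)
            rev1, rev2 = rng.random() < 0.5, rng.random() < 0.5
        else:
            c2, len2 = c1, len1
            u1 = random_u5(len1)
            u2 = min(u1 + rng.randint(120, 320), len1 - READ_LENGTH)
            rev1, rev2 = False, True
        mol = _Molecule(c1, u1, rev1, c2, u2, rev2)
        r1, r2 = emit_pair(mol, None)
        pair_templates.append((mol, (r1.qual, r2.qual)))

    for mol, quals in pair_templates:
        if rng.random() < spec.duplicate_rate:
            emit_pair(mol, quals)

    frag_templates: list[tuple[_Molecule, str]] = []
    for _ in range(spec.n_fragments):
        c, length = rng.choice(contigs)
        mol = _Molecule(c, random_u5(length), rng.random() < 0.5)
        rec = _make_end(
            rng, next_name("f"), mol.contig1, mol.u5_1, mol.rev1, 0, spec.clip_rate
        )
        records.append(rec)
        frag_templates.append((mol, rec.qual))

    for mol, qual in frag_templates:
        if rng.random() < spec.duplicate_rate:
            rec = _make_end(
                rng, next_name("f"), mol.contig1, mol.u5_1, mol.rev1, 0, spec.clip_rate
            )
            if rng.random() < 0.35:
                rec.qual = qual
            records.append(rec)

    for _ in range(spec.n_unmapped):
        records.append(
            SamAlignment(
                qname=next_name("u"),
                flag=FLAG_UNMAPPED,
                rname="*",
                pos=0,
                mapq=0,
                cigar="*",
                rnext="*",
                pnext=0,
                tlen=0,
                seq=_seq(rng),
                qual=_qual(rng),
                tags=[("RG", "Z", "rg1")],
            )
        )

    # pair up mate fields, then delete some second mates
    by_name: dict[str, list[SamAlignment]] = {}
    for rec in records:
        by_name.setdefault(rec.qname, []).append(rec)
    doomed: set[int] = set()
    for recs in by_name.values():
        if len(recs) == 2:
            _link_mates(recs[0], recs[1])
            if rng.random() < spec.missing_mate_rate:
                doomed.add(id(recs[1]))
    records = [rec for rec in records if id(rec) not in doomed]

    rng.shuffle(records)
    return header, records


def generate(spec: FixtureSpec, path: Union[str, Path]) -> Path:
    """Write the fixture for *spec* to *path* and return the path."""
    header, records = generate_records(spec)
    write_sam(header, records, path)
    return Path(path)


# -- oracles -----------------------------------------------------------------

_EXEMPT = FLAG_UNMAPPED | FLAG_SECONDARY | FLAG_SUPPLEMENTARY
_CIG = re.compile(r"(\d+)([MIDNSHP=X])")


def _oracle_unclipped(rec: SamAlignment) -> tuple[int, bool]:
    """Unclipped 5' coordinate + strand, computed independently."""
    ops = _CIG.findall(rec.cigar)
    if rec.flag & FLAG_REVERSE:
        end = rec.pos - 1
        for n, op in ops:
            if op in "MDN=X":
                end += int(n)
        i = len(ops) - 1
        while i >= 0 and ops[i][1] in "SH":
            end += int(ops[i][0])
            i -= 1
        return end, True
    start = rec.pos
    for n, op in ops:
        if op not in "SH":
            break
        start -= int(n)
    return start, False


def oracle_mark_duplicates(
    header: SamHeader, records: Iterable[SamAlignment]
) -> set[tuple[str, int]]:
    """Three-phase reference duplicate marker.

    Collects everything, determines complete pairs, groups by key, and
    selects survivors per group — the multi-pass structure the single-pass
    table replaces.  Returns the marked set as ``(qname, first/second-of-
    pair bits)`` pairs.  Shares only :func:`~samprep.markdup.dup_score` and
    :func:`~samprep.markdup.preference_key` with the production path.
    """
    records = list(records)
    ref_index = {
        name: i for i, (name, _, _) in enumerate(header.sequence_dictionary)
    }
    libraries = {}
    for fields in header.read_groups:
        rg = SamHeader.fields_get(fields, "ID")
        lb = SamHeader.fields_get(fields, "LB")
        libraries[rg] = lb if lb else DEFAULT_LIBRARY

    def lib_of(rec: SamAlignment) -> str:
        tag = rec.get_tag("RG")
        return libraries.get(tag[1], DEFAULT_LIBRARY) if tag else DEFAULT_LIBRARY

    def key_of(rec: SamAlignment) -> tuple:
        pos, rev = _oracle_unclipped(rec)
        return (lib_of(rec), ref_index[rec.rname], pos, rev)

    # phase 1: collect candidates, determine which pairs are complete
    eligible = [
        r
        for r in records
        if not r.flag & _EXEMPT and r.get_tag("sp") is None
    ]
    pair_bits: dict[str, int] = {}
    for rec in eligible:
        if rec.flag & FLAG_PAIRED and not rec.flag & FLAG_MATE_UNMAPPED:
            pair_bits[rec.qname] = pair_bits.get(rec.qname, 0) | (
                rec.flag & (FLAG_FIRST_OF_PAIR | FLAG_SECOND_OF_PAIR)
            )
    complete = {
        q
        for q, bits in pair_bits.items()
        if bits == FLAG_FIRST_OF_PAIR | FLAG_SECOND_OF_PAIR
    }

    # split copies of spanning pair ends assert pair presence at their key
    pair_end_keys: set[tuple] = set()
    for rec in records:
        if rec.get_tag("sp") is not None and not rec.flag & _EXEMPT:
            pair_end_keys.add(key_of(rec))

    pairs: dict[str, list[SamAlignment]] = {}
    fragments: list[SamAlignment] = []
    for rec in eligible:
        if (
            rec.flag & FLAG_PAIRED
            and not rec.flag & FLAG_MATE_UNMAPPED
            and rec.qname in complete
        ):
            pairs.setdefault(rec.qname, []).append(rec)
        else:
            fragments.append(rec)

    marked: set[tuple[str, int]] = set()

    def ends_of(rec: SamAlignment) -> tuple[str, int]:
        return (rec.qname, rec.flag & (FLAG_FIRST_OF_PAIR | FLAG_SECOND_OF_PAIR))

    # phase 2a: group complete pairs by their symmetric key, keep the best
    pair_groups: dict[tuple, list[tuple[int, str, list[SamAlignment]]]] = {}
    for qname, recs in pairs.items():
        k1, k2 = key_of(recs[0]), key_of(recs[1])
        pkey = (k1, k2) if k1 <= k2 else (k2, k1)
        score = dup_score(recs[0].qual) + dup_score(recs[1].qual)
        pair_groups.setdefault(pkey, []).append((score, qname, recs))
        pair_end_keys.add(k1)
        pair_end_keys.add(k2)
    for group in pair_groups.values():
        group.sort(key=lambda item: preference_key(item[0], item[1]))
        for _, _, recs in group[1:]:
            marked.update(ends_of(r) for r in recs)

    # phase 2b: group fragments; any pair end at the key marks them all
    frag_groups: dict[tuple, list[tuple[int, str, SamAlignment]]] = {}
    for rec in fragments:
        frag_groups.setdefault(key_of(rec), []).append(
            (dup_score(rec.qual), rec.qname, rec)
        )
    for fkey, group in frag_groups.items():
        group.sort(key=lambda item: preference_key(item[0], item[1]))
        survivors = 0 if fkey in pair_end_keys else 1
        for _, _, rec in group[survivors:]:
            marked.add(ends_of(rec))

    return marked


def oracle_sequential_pipeline(
    source: Union[str, Path],
    stages: list[object],
    workdir: Optional[Union[str, Path]] = None,
) -> Path:
    """Run *stages* as separate single-step passes with intermediate files.

    This is the standard-practice baseline: each stage is its own full
    pipeline execution, serialized to a temporary SAM file, whose output
    feeds the next stage.  Returns the final file's path.
    """
    from .samio import open_sam
    from .steps import stages_to_pipeline

    if workdir is None:
        workdir = tempfile.mkdtemp(prefix="samprep_seq_")
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    current = Path(source)
    for i, stage in enumerate(stages):
        nxt = workdir / f"stage_{i:02d}.sam"
        run_pipeline(open_sam(current), stages_to_pipeline([stage]), nxt)
        current = nxt
    return current
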