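"""Split-by-region / merge: routing, completeness, marking invariance."""

import pytest

from samprep import (
    FixtureSpec,
    Pipeline,
    SamFormatError,
    generate,
    mark_duplicates,
    open_sam,
    read_sam,
    merge,
    run_pipeline,
    split,
    write_sam,
)
from samprep.model import FLAG_DUPLICATE
from samprep.split_merge import MANIFEST_NAME, read_manifest

from conftest import make_aln, make_header


def _pair(qname, c1, p1, c2, p2):
    r1 = make_aln(qname=qname, flag=0x1 | 0x40 | 0x20, rname=c1, pos=p1,
                  rnext="=" if c1 == c2 else c2, pnext=p2)
    r2 = make_aln(qname=qname, flag=0x1 | 0x80 | 0x10, rname=c2, pos=p2,
                  rnext="=" if c1 == c2 else c1, pnext=p1)
    return r1, r2


def _split_dir(tmp_path, header, records):
    src = tmp_path / "in.sam"
    write_sam(header, records, src)
    out = tmp_path / "splits"
    split(open_sam(src), out)
    return out


def _read_target(out_dir, name_part):
    count, files = read_manifest(out_dir / MANIFEST_NAME)
    for f in files:
        if name_part in f:
            return read_sam(out_dir / f)[1]
    raise AssertionError(name_part)


def test_same_region_pair_goes_to_one_region_file(tmp_path):
    header = make_header()
    out = _split_dir(tmp_path, header, list(_pair("p", "chr1", 100, "chr1", 400)))
    assert len(_read_target(out, "chr1")) == 2
    assert _read_target(out, "spanning") == []


def test_spanning_pair_copied_into_both_regions(tmp_path):
    header = make_header()
    out = _split_dir(tmp_path, header, list(_pair("p", "chr1", 100, "chr2", 400)))
    spanning = _read_target(out, "spanning")
    assert len(spanning) == 2 and not any(r.get_tag("sp") for r in spanning)
    chr1 = _read_target(out, "chr1")
    chr2 = _read_target(out, "chr2")
    assert len(chr1) == len(chr2) == 1
    assert chr1[0].get_tag("sp") == ("i", "1")
    assert chr2[0].get_tag("sp") == ("i", "1")


def test_fragment_goes_to_its_region_only(tmp_path):
    header = make_header()
    out = _split_dir(tmp_path, header, [make_aln(qname="f", rname="chr2")])
    assert len(_read_target(out, "chr2")) == 1
    assert _read_target(out, "chr1") == []
    assert _read_target(out, "spanning") == []


def test_missing_mate_routed_as_fragment_not_spanning(tmp_path):
    header = make_header()
    r1, _ = _pair("widow", "chr1", 100, "chr2", 400)
    out = _split_dir(tmp_path, header, [r1])  # mate never written
    assert _read_target(out, "spanning") == []
    assert len(_read_target(out, "chr1")) == 1


def test_unmapped_records_get_their_own_target(tmp_path):
    header = make_header()
    u = make_aln(qname="u", flag=4, rname="*", pos=0, cigar="*")
    out = _split_dir(tmp_path, header, [u])
    assert len(_read_target(out, "unmapped")) == 1


def test_split_completeness_counts(tmp_path):
    path = generate(FixtureSpec(seed=5, cross_region_rate=0.3), tmp_path / "f.sam")
    _, records = read_sam(path)
    out = tmp_path / "splits"
    split(open_sam(path), out)
    count, files = read_manifest(out / MANIFEST_NAME)
    assert count == len(records)
    total = sum(len(read_sam(out / f)[1]) for f in files)
    spanning = len(_read_target(out, "spanning"))
    assert total == count + spanning  # each spanning record exists twice


def test_split_then_merge_is_identity_on_record_multisets(tmp_path):
    path = generate(FixtureSpec(seed=7, cross_region_rate=0.25), tmp_path / "f.sam")
    _, records = read_sam(path)
    out = tmp_path / "splits"
    split(open_sam(path), out)
    merged = tmp_path / "merged.sam"
    n = merge(out, merged)
    _, after = read_sam(merged)
    assert n == len(records)
    assert sorted(r.to_line() for r in after) == sorted(r.to_line() for r in records)


def test_split_requires_sequence_dictionary(tmp_path):
    src = tmp_path / "nodict.sam"
    src.write_text("@HD\tVN:1.6\n")
    with pytest.raises(SamFormatError, match="dictionary"):
        split(open_sam(src), tmp_path / "out")


def test_merge_keeps_spanning_originals_flags(tmp_path):
    """A copy marked in a region file never overrides the spanning
    original's flags."""
    header = make_header()
    out = _split_dir(tmp_path, header, list(_pair("p", "chr1", 100, "chr2", 400)))
    # simulate a per-region step marking the copy
    count, files = read_manifest(out / MANIFEST_NAME)
    for f in files:
        if "chr1" in f:
            h, recs = read_sam(out / f)
            for r in recs:
                r.flag |= FLAG_DUPLICATE
            write_sam(h, recs, out / f)
    merged = tmp_path / "merged.sam"
    merge(out, merged)
    _, after = read_sam(merged)
    assert all(not r.flag & FLAG_DUPLICATE for r in after)


def _mark_each_target(out_dir):
    count, files = read_manifest(out_dir / MANIFEST_NAME)
    for f in files:
        marked = out_dir / f"marked_{f}"
        run_pipeline(
            open_sam(out_dir / f), Pipeline(steps=[mark_duplicates()]), marked
        )
        (out_dir / f).write_bytes(marked.read_bytes())
        marked.unlink()


@pytest.mark.parametrize("seed", [101, 202, 303, 404])
def test_per_region_marking_then_merge_equals_whole_file(tmp_path, seed):
    """The headline guarantee, with frequent cross-region pairs and
    colliding fragments at spanning-pair positions."""
    spec = FixtureSpec(
        seed=seed,
        n_pairs=80,
        n_fragments=40,
        duplicate_rate=0.5,
        cross_region_rate=0.3,
        clip_rate=0.3,
        missing_mate_rate=0.1,
    )
    path = generate(spec, tmp_path / "f.sam")
    out = tmp_path / "splits"
    split(open_sam(path), out)
    _mark_each_target(out)
    merged = tmp_path / "merged.sam"
    merge(out, merged)

    whole = tmp_path / "whole.sam"
    run_pipeline(
        open_sam(path),
        Pipeline(steps=[mark_duplicates()], whole_set_operation="sort_coordinate"),
        whole,
    )
    _, a = read_sam(merged)
    _, b = read_sam(whole)
    assert len(a) == len(b)
    assert sorted(r.to_line() for r in a) == sorted(r.to_line() for r in b)


def test_merge_detects_missing_target(tmp_path):
    header = make_header()
    out = _split_dir(tmp_path, header, [make_aln()])
    count, files = read_manifest(out / MANIFEST_NAME)
    (out / files[0]).unlink()
    with pytest.raises(SamFormatError, match="missing target"):
        merge(out, tmp_path / "m.sam")
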