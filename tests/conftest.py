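import pytest

from samprep import FixtureSpec, SamAlignment, SamHeader, generate


def make_aln(**kwargs) -> SamAlignment:
    """An alignment record with sensible defaults, overridable per test."""
    defaults = dict(
        qname="read1",
        flag=0,
        rname="chr1",
        pos=100,
        mapq=60,
        cigar="100M",
        rnext="*",
        pnext=0,
        tlen=0,
        seq="A" * 100,
        qual=chr(33 + 30) * 100,
        tags=[],
    )
    defaults.update(kwargs)
    return SamAlignment(**defaults)


def make_header(contigs=(("chr1", 100000), ("chr2", 80000))) -> SamHeader:
    return SamHeader.parse(
        ["@HD\tVN:1.6\tSO:unknown"]
        + [f"@SQ\tSN:{n}\tLN:{l}" for n, l in contigs]
        + ["@RG\tID:rg1\tLB:lib1\tSM:sample1"]
    )


@pytest.fixture
def fixture_sam(tmp_path):
    """A default synthetic SAM file on disk."""
    return generate(FixtureSpec(seed=42), tmp_path / "fixture.sam")
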