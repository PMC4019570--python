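import numpy as np
import pytest

from otg.model import AlignedRead, ReferenceGenome, parse_cigar


def make_read(
    name="r1",
    chrom="chr1",
    pos=0,
    strand="+",
    cigar="10M",
    seq=None,
    quals=None,
    score=200,
    mapq=60,
):
    ops = parse_cigar(cigar)
    qlen = sum(o.length for o in ops if o.op in "MIS=X")
    if seq is None:
        seq = "A" * qlen
    if quals is None:
        quals = (30,) * len(seq)
    return AlignedRead(
        name=name,
        chrom=chrom,
        pos=pos,
        strand=strand,
        mapq=mapq,
        cigar=ops,
        seq=seq,
        quals=tuple(quals),
        alignment_score=score,
    )


@pytest.fixture
def mk_read():
    return make_read


@pytest.fixture
def flat_ref():
    """All-A 1 kb single-chromosome reference."""
    return ReferenceGenome({"chr1": "A" * 1000})


@pytest.fixture
def rng():
    return np.random.default_rng(42)
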