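"""Core domain types: CIGAR ops, aligned reads, reference genomes, regions, variants.

All coordinates are 0-based half-open internally.  Conversion to the 1-based
conventions of SAM and VCF happens only at file boundaries (see :mod:`otg.io`).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator, Mapping

#: SAM operation codes in BAM integer order.
CIGAR_OPS = "MIDNSHP=X"

#: Operations that consume query (read) bases.
QUERY_OPS = frozenset("MIS=X")

#: Operations that consume reference bases.
REF_OPS = frozenset("MDN=X")

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")


@dataclass(frozen=True)
class CigarOp:
    """One CIGAR element: an operation code and a positive length."""

    op: str
    length: int

    def __post_init__(self) -> None:
        if self.op not in CIGAR_OPS:
            raise ValueError(f"unknown CIGAR op {self.op!r}")
        if self.length < 1:
            raise ValueError(f"CIGAR length must be >= 1, got {self.length}")

    def __str__(self) -> str:
        return f"{self.length}{self.op}"


def parse_cigar(text: str) -> tuple[CigarOp, ...]:
    """Parse a CIGAR string like ``"20M5D30M"`` into a tuple of ops."""
    if text in ("", "*"):
        return ()
    ops = tuple(CigarOp(m.group(2), int(m.group(1))) for m in _CIGAR_RE.finditer(text))
    if "".join(str(o) for o in ops) != text:
        raise ValueError(f"malformed CIGAR string {text!r}")
    return ops


def cigar_str(cigar: tuple[CigarOp, ...]) -> str:
    return "".join(str(o) for o in cigar) or "*"


def reference_span(cigar: tuple[CigarOp, ...]) -> int:
    """Number of reference bases consumed by the CIGAR."""
    return sum(o.length for o in cigar if o.op in REF_OPS)


def query_length(cigar: tuple[CigarOp, ...]) -> int:
    """Number of query bases consumed by the CIGAR (includes soft clips)."""
    return sum(o.length for o in cigar if o.op in QUERY_OPS)


@dataclass
class AlignedRead:
    """A single mapped (or unmapped) read with its alignment score.

    ``alignment_score`` mirrors the integer ``AS`` tag; reads missing the tag
    get ``float("-inf")`` so score-based filtering still has a total order.
    """

    name: str
    chrom: str
    pos: int  # 0-based leftmost reference coordinate
    strand: str  # "+" or "-"
    mapq: int
    cigar: tuple[CigarOp, ...]
    seq: str
    quals: tuple[int, ...]
    alignment_score: float
    is_mapped: bool = True

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.is_mapped:
            qlen = query_length(self.cigar)
            if qlen != len(self.seq) or qlen != len(self.quals):
                raise ValueError(
                    f"read {self.name}: CIGAR consumes {qlen} query bases but "
                    f"seq has {len(self.seq)} and quals {len(self.quals)}"
                )

    @property
    def reference_end(self) -> int:
        """0-based exclusive rightmost reference coordinate."""
        return self.pos + reference_span(self.cigar)

    @property
    def is_reverse(self) -> bool:
        return self.strand == "-"

    def copy(self, **changes) -> "AlignedRead":
        from dataclasses import replace

        return replace(self, **changes)


@dataclass(frozen=True)
class Region:
    """0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty region {self.chrom}:{self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end

    def overlaps_read(self, read: AlignedRead) -> bool:
        return (
            read.chrom == self.chrom
            and read.pos < self.end
            and read.reference_end > self.start
        )


def in_regions(chrom: str, pos: int, regions) -> bool:
    """True if (chrom, pos) falls inside any region; None region set means everywhere."""
    if regions is None:
        return True
    return any(r.contains(chrom, pos) for r in regions)


@dataclass(frozen=True)
class VariantCall:
    """A biallelic SNP call.

    Equality/hashing is on (chrom, pos, ref, alt, genotype) so call sets can be
    compared; depth and alt_fraction are carried as annotations only.
    """

    chrom: str
    pos: int  # 0-based
    ref_allele: str
    alt_allele: str
    genotype: str | None = None  # "het", "hom" or None when unknown
    depth: int = field(default=0, compare=False)
    alt_fraction: float = field(default=0.0, compare=False)

    def __post_init__(self) -> None:
        if self.ref_allele not in "ACGT" or self.alt_allele not in "ACGT":
            raise ValueError(
                f"alleles must be single A/C/G/T bases, got "
                f"{self.ref_allele!r}>{self.alt_allele!r}"
            )
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles must differ")
        if self.genotype not in (None, "het", "hom"):
            raise ValueError(f"genotype must be het/hom/None, got {self.genotype!r}")
        if not 0.0 <= self.alt_fraction <= 1.0:
            raise ValueError(f"alt_fraction out of [0,1]: {self.alt_fraction}")

    @property
    def site(self) -> tuple[str, int, str]:
        """Site-level identity: (chrom, pos, alt)."""
        return (self.chrom, self.pos, self.alt_allele)


class ReferenceGenome:
    """In-memory reference: chromosome name -> upper-case base string."""

    def __init__(self, sequences: Mapping[str, str]):
        self._seqs = {name: seq.upper() for name, seq in sequences.items()}

    @property
    def chroms(self) -> list[str]:
        return list(self._seqs)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    def length(self, chrom: str) -> int:
        return len(self._seqs[chrom])

    def lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self._seqs.items()}

    def base(self, chrom: str, pos: int) -> str:
        seq = self._seqs[chrom]
        if not 0 <= pos < len(seq):
            raise IndexError(f"position {pos} outside {chrom} (length {len(seq)})")
        return seq[pos]

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Bases of the half-open interval [start, end); always end-start long."""
        seq = self._seqs[chrom]
        if start < 0 or end > len(seq) or start > end:
            raise IndexError(f"interval {chrom}:{start}-{end} outside reference")
        return seq[start:end]

    def sequence(self, chrom: str) -> str:
        return self._seqs[chrom]

    def regions(self) -> list[Region]:
        """Whole-chromosome regions, in genome order."""
        return [Region(c, 0, len(s)) for c, s in self._seqs.items()]

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(self._seqs.items())
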