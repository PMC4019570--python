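"""Minimal pileup-frequency SNP caller.

A deliberately simple downstream consumer for the RDAST -> AOS pipeline: at
each column it computes per-allele fractions over quality-passing base
observations and emits at most one biallelic SNP.  Columns with gap evidence
above ``max_gap_fraction`` are treated as indel-ambiguous and skipped, which
emulates how haplotype-based callers shy away from gapped sites (and is what
makes AOS's false-negative reduction observable here).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .aos import GAP, PileupColumn
from .model import VariantCall


@dataclass(frozen=True)
class CallerConfig:
    min_depth: int = 8
    min_alt_fraction: float = 0.2
    min_base_quality: int = 10
    hom_fraction: float = 0.75
    #: columns whose gap fraction exceeds this are skipped as indel-ambiguous
    max_gap_fraction: float = 0.0

    def __post_init__(self) -> None:
        if not 0 < self.min_alt_fraction < self.hom_fraction <= 1:
            raise ValueError(
                "need 0 < min_alt_fraction < hom_fraction <= 1, got "
                f"{self.min_alt_fraction} / {self.hom_fraction}"
            )
        if not 0 <= self.max_gap_fraction <= 1:
            raise ValueError("max_gap_fraction must be in [0, 1]")


def _qualifying(col: PileupColumn, min_base_quality: int):
    return [
        o
        for o in col.observations
        if o.read_base is not None
        and (o.base_quality is None or o.base_quality >= min_base_quality)
    ]


def allele_fraction(
    col: PileupColumn, allele: str, min_base_quality: int = 10
) -> float:
    """Percentage of quality-passing base observations carrying ``allele``.

    Gap observations never enter the numerator or denominator (a depth-11
    column with 3 G reads yields 27.27...).
    """
    obs = _qualifying(col, min_base_quality)
    if not obs:
        raise ValueError(
            f"no qualifying base observations at {col.chrom}:{col.ref_pos}"
        )
    return 100.0 * sum(1 for o in obs if o.read_base == allele) / len(obs)


def call_column(col: PileupColumn, config: CallerConfig) -> VariantCall | None:
    """Call at most one SNP from a column, or None."""
    if col.ref_base not in "ACGT":
        return None
    obs = _qualifying(col, config.min_base_quality)
    depth = len(obs)
    if depth < config.min_depth:
        return None
    total = len(col.observations)
    gaps = sum(1 for o in col.observations if o.category == GAP)
    if total and gaps / total > config.max_gap_fraction:
        return None
    counts: dict[str, int] = {}
    for o in obs:
        if o.read_base in "ACGT" and o.read_base != col.ref_base:
            counts[o.read_base] = counts.get(o.read_base, 0) + 1
    if not counts:
        return None
    # highest count wins; ties broken by lexicographic base order
    alt = min(counts, key=lambda b: (-counts[b], b))
    fraction = counts[alt] / depth
    if fraction < config.min_alt_fraction:
        return None
    genotype = "hom" if fraction >= config.hom_fraction else "het"
    return VariantCall(
        chrom=col.chrom,
        pos=col.ref_pos,
        ref_allele=col.ref_base,
        alt_allele=alt,
        genotype=genotype,
        depth=depth,
        alt_fraction=fraction,
    )


def call_snps(
    pileup: Iterable[PileupColumn], config: CallerConfig | None = None
) -> set[VariantCall]:
    """Deterministic SNP calls over a pileup stream."""
    config = config or CallerConfig()
    calls: set[VariantCall] = set()
    for col in pileup:
        call = call_column(col, config)
        if call is not None:
            calls.add(call)
    return calls
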