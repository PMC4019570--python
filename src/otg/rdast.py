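"""RDAST: duplicate removal by alignment-score threshold.

Reads sharing a 5' mapped reference coordinate (and strand) form a duplicate
group.  Within each group, every read whose alignment score exceeds the
threshold is kept; if none passes, the single highest-scoring read is kept so
no genomic position loses all its coverage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

from .model import AlignedRead, reference_span


@dataclass(frozen=True)
class DuplicateKey:
    """Strand-resolved 5'-end identity of a mapped read.

    Forward reads: leftmost aligned reference coordinate.  Reverse reads: the
    last reference base consumed by the CIGAR (clips consume no reference, so
    trimming never shifts the key).
    """

    chrom: str
    five_prime_pos: int
    strand: str


@dataclass
class DuplicateGroup:
    key: DuplicateKey
    members: list[AlignedRead]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("duplicate group must be non-empty")


@dataclass(frozen=True)
class RdastConfig:
    """AS-threshold configuration.  Default threshold is 160.

    ``keep_at_or_above`` switches the keep rule from strict ``>`` to ``>=``
    for sensitivity analysis.
    """

    as_threshold: int = 160
    keep_at_or_above: bool = False

    def __post_init__(self) -> None:
        if self.as_threshold < 0:
            raise ValueError("as_threshold must be >= 0")

    def passes(self, score: float) -> bool:
        if self.keep_at_or_above:
            return score >= self.as_threshold
        return score > self.as_threshold


@dataclass
class RdastStats:
    reads_in: int = 0
    reads_kept: int = 0
    reads_removed: int = 0
    groups: int = 0
    fallback_groups: int = 0

    @property
    def duplication_rate(self) -> float:
        return self.reads_removed / self.reads_in if self.reads_in else 0.0

    def as_dict(self) -> dict:
        return {
            "reads_in": self.reads_in,
            "reads_kept": self.reads_kept,
            "reads_removed": self.reads_removed,
            "duplication_rate": self.duplication_rate,
            "groups": self.groups,
            "fallback_groups": self.fallback_groups,
        }


def duplicate_key(read: AlignedRead) -> DuplicateKey:
    """The fixed 5'-end grouping key of a mapped read."""
    if not read.is_mapped or not read.cigar:
        raise ValueError(f"read {read.name} is unmapped or has no CIGAR")
    if read.is_reverse:
        pos = read.pos + reference_span(read.cigar) - 1
    else:
        pos = read.pos
    return DuplicateKey(read.chrom, pos, read.strand)


def group_duplicates(reads: Iterable[AlignedRead]) -> Iterator[DuplicateGroup]:
    """Group a coordinate-sorted stream by duplicate key.

    Groups are emitted per chromosome in key order.  Every input read lands in
    exactly one group; singletons are valid groups.
    """
    buckets: dict[DuplicateKey, list[AlignedRead]] = {}
    current_chrom: str | None = None
    for read in reads:
        if read.chrom != current_chrom:
            yield from _flush(buckets)
            buckets = {}
            current_chrom = read.chrom
        buckets.setdefault(duplicate_key(read), []).append(read)
    yield from _flush(buckets)


def _flush(buckets: dict[DuplicateKey, list[AlignedRead]]) -> Iterator[DuplicateGroup]:
    for key in sorted(buckets, key=lambda k: (k.five_prime_pos, k.strand)):
        yield DuplicateGroup(key, buckets[key])


def rdast_filter(
    group: DuplicateGroup, config: RdastConfig
) -> tuple[list[AlignedRead], list[AlignedRead]]:
    """Split a group into (kept, removed).

    Keeps every member whose score passes the threshold; with no passer, keeps
    the single member of maximal score (ties broken by smallest read name) so
    the group always contributes at least one read.
    """
    kept = [r for r in group.members if config.passes(r.alignment_score)]
    if not kept:
        best = min(group.members, key=lambda r: (-r.alignment_score, r.name))
        kept = [best]
    kept_ids = {id(r) for r in kept}
    removed = [r for r in group.members if id(r) not in kept_ids]
    return kept, removed


def run_rdast(
    reads: Iterable[AlignedRead], config: RdastConfig | None = None
) -> tuple[list[AlignedRead], RdastStats]:
    """Filter a sorted read stream; returns (sorted kept reads, stats).

    Idempotent: a second pass removes nothing, because surviving groups either
    consist only of passers or of a single fallback read.
    """
    config = config or RdastConfig()
    stats = RdastStats()
    kept_all: list[AlignedRead] = []
    chrom_order: dict[str, int] = {}
    for group in group_duplicates(reads):
        chrom_order.setdefault(group.key.chrom, len(chrom_order))
        stats.groups += 1
        stats.reads_in += len(group.members)
        kept, removed = rdast_filter(group, config)
        if not any(config.passes(r.alignment_score) for r in group.members):
            stats.fallback_groups += 1
        stats.reads_kept += len(kept)
        stats.reads_removed += len(removed)
        kept_all.extend(kept)
    kept_all.sort(key=lambda r: (chrom_order[r.chrom], r.pos, r.name))
    return kept_all, stats


def brute_force_rdast(
    reads: Sequence[AlignedRead], config: RdastConfig
) -> set[str]:
    """Quadratic oracle: names of the reads RDAST should keep.

    All-pairs grouping (no sorting assumptions) followed by the literal keep
    rule; used only to cross-check :func:`run_rdast` on small instances.
    """
    groups: list[list[AlignedRead]] = []
    for read in reads:
        key = duplicate_key(read)
        for grp in groups:
            if duplicate_key(grp[0]) == key:
                grp.append(read)
                break
        else:
            groups.append([read])
    kept: set[str] = set()
    for grp in groups:
        passers = [r for r in grp if config.passes(r.alignment_score)]
        if passers:
            kept.update(r.name for r in passers)
        else:
            best_score = max(r.alignment_score for r in grp)
            best = sorted(r.name for r in grp if r.alignment_score == best_score)[0]
            kept.add(best)
    return kept
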