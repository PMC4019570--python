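"""AOS: alignment optimization around homopolymer gap errors.

Every reference column is examined.  At a column where some read disagrees
with the reference (mismatch or gap), two gates are applied:

1. homopolymer confirmation — the column must sit in (or, optionally, right
   next to) a run of >= ``min_homopolymer`` identical bases, either in the
   reference or in a covering read;
2. gap-ratio test — gaps must make up a non-zero fraction of the column's
   observations that is strictly below ``gap_ratio_threshold``.

Gaps at columns passing both gates are "improper" and are removed: in repair
mode insertions are excised and deletions converted back to reference bases
(so the read's reference span never moves); in drop mode the whole read is
discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

from .model import AlignedRead, CigarOp, ReferenceGenome, Region

CONCORDANT = "concordant"
DISCORDANT = "discordant"
GAP = "gap"


@dataclass(slots=True)
class Observation:
    """One read's contribution to a pileup column.

    A read with an insertion contributes two observations at the anchor
    column: its aligned base and a gap observation of kind "insertion".
    """

    read: AlignedRead
    category: str  # concordant | discordant | gap
    gap_kind: str = "none"  # none | deletion | insertion
    read_base: str | None = None
    base_quality: int | None = None
    query_pos: int | None = None  # index into read.seq for base observations

    def __post_init__(self) -> None:
        if (self.category == GAP) != (self.gap_kind != "none"):
            raise ValueError("gap category and gap_kind must agree")


@dataclass(slots=True)
class PileupColumn:
    chrom: str
    ref_pos: int
    ref_base: str
    observations: list[Observation] = field(default_factory=list)

    @property
    def depth(self) -> int:
        """Base observations only (gaps excluded)."""
        return sum(1 for o in self.observations if o.category != GAP)


@dataclass(frozen=True)
class GapEvent:
    """An improper gap flagged for removal: one I/D CIGAR op of one read."""

    chrom: str
    ref_pos: int
    kind: str  # deletion | insertion


@dataclass(frozen=True)
class AosConfig:
    min_homopolymer: int = 3
    gap_ratio_threshold: float = 0.2
    mode: str = "repair"  # repair | drop
    include_adjacent_runs: bool = True

    def __post_init__(self) -> None:
        if self.min_homopolymer < 2:
            raise ValueError("min_homopolymer must be >= 2")
        if not 0 < self.gap_ratio_threshold <= 1:
            raise ValueError("gap_ratio_threshold must be in (0, 1]")
        if self.mode not in ("repair", "drop"):
            raise ValueError(f"mode must be repair or drop, got {self.mode!r}")


@dataclass
class AosStats:
    columns_examined: int = 0
    columns_homopolymer_confirmed: int = 0
    improper_gap_events: int = 0
    reads_repaired: int = 0
    reads_dropped: int = 0

    def as_dict(self) -> dict:
        return {
            "columns_examined": self.columns_examined,
            "columns_homopolymer_confirmed": self.columns_homopolymer_confirmed,
            "improper_gap_events": self.improper_gap_events,
            "reads_repaired": self.reads_repaired,
            "reads_dropped": self.reads_dropped,
        }


# ---------------------------------------------------------------------------
# Pileup construction


def _add_read_observations(
    read: AlignedRead, columns: dict[int, PileupColumn], ref: ReferenceGenome
) -> None:
    chrom = read.chrom
    refseq = ref.sequence(chrom)
    rpos = read.pos
    qpos = 0
    for op in read.cigar:
        if op.op in "M=X":
            for i in range(op.length):
                col = _column(columns, chrom, rpos + i, refseq)
                base = read.seq[qpos + i]
                col.observations.append(
                    Observation(
                        read=read,
                        category=CONCORDANT if base == col.ref_base else DISCORDANT,
                        read_base=base,
                        base_quality=read.quals[qpos + i] if read.quals else None,
                        query_pos=qpos + i,
                    )
                )
            rpos += op.length
            qpos += op.length
        elif op.op == "D":
            for i in range(op.length):
                col = _column(columns, chrom, rpos + i, refseq)
                col.observations.append(
                    Observation(read=read, category=GAP, gap_kind="deletion")
                )
            rpos += op.length
        elif op.op == "I":
            # anchored to the reference column immediately left of the insertion
            anchor = rpos - 1
            if anchor >= read.pos:
                col = _column(columns, chrom, anchor, refseq)
                col.observations.append(
                    Observation(read=read, category=GAP, gap_kind="insertion")
                )
            qpos += op.length
        elif op.op == "N":
            rpos += op.length
        elif op.op == "S":
            qpos += op.length
        # H and P consume nothing we track


def _column(
    columns: dict[int, PileupColumn], chrom: str, pos: int, refseq: str
) -> PileupColumn:
    col = columns.get(pos)
    if col is None:
        col = PileupColumn(chrom, pos, refseq[pos])
        columns[pos] = col
    return col


def build_pileup(
    reads: Iterable[AlignedRead],
    ref: ReferenceGenome,
    region: Region | None = None,
) -> Iterator[PileupColumn]:
    """Stream pileup columns (position-sorted) from a sorted read stream.

    Deletions contribute a gap observation at each deleted column; an
    insertion contributes a gap observation at the column left of the
    insertion point; soft clips contribute nothing.
    """
    columns: dict[int, PileupColumn] = {}
    current_chrom: str | None = None
    for read in reads:
        if read.chrom not in ref:
            raise KeyError(f"read {read.name}: chromosome {read.chrom!r} not in reference")
        if read.chrom != current_chrom:
            yield from _flush_columns(columns, None, region)
            columns = {}
            current_chrom = read.chrom
        yield from _flush_columns(columns, read.pos, region)
        _add_read_observations(read, columns, ref)
    yield from _flush_columns(columns, None, region)


def _flush_columns(
    columns: dict[int, PileupColumn], before: int | None, region: Region | None
) -> Iterator[PileupColumn]:
    ready = sorted(p for p in columns if before is None or p < before)
    for pos in ready:
        col = columns.pop(pos)
        if region is None or region.contains(col.chrom, col.ref_pos):
            yield col


# ---------------------------------------------------------------------------
# Column gates


def column_is_triggered(col: PileupColumn) -> bool:
    """True iff any observation disagrees with the reference (mismatch or gap)."""
    return any(o.category != CONCORDANT for o in col.observations)


def _run_length_at(seq: str, pos: int) -> int:
    """Length of the maximal run of identical characters containing seq[pos]."""
    base = seq[pos]
    left = pos
    while left > 0 and seq[left - 1] == base:
        left -= 1
    right = pos
    while right + 1 < len(seq) and seq[right + 1] == base:
        right += 1
    return right - left + 1


def _adjacent_run_lengths(seq: str, pos: int) -> list[int]:
    runs = []
    if pos > 0 and seq[pos - 1] != seq[pos]:
        runs.append(_run_length_at(seq, pos - 1))
    if pos + 1 < len(seq) and seq[pos + 1] != seq[pos]:
        runs.append(_run_length_at(seq, pos + 1))
    return runs


def has_homopolymer_context(
    col: PileupColumn,
    ref: ReferenceGenome,
    min_len: int = 3,
    include_adjacent: bool = True,
) -> bool:
    """Homopolymer confirmation gate.

    True iff the examined column lies in a run of >= ``min_len`` identical
    bases in the reference, or a covering read carries such a run through its
    base at the column.  With ``include_adjacent``, a qualifying run
    immediately flanking the column also counts (covers undercalls at a run
    boundary).
    """
    refseq = ref.sequence(col.chrom)
    if _run_length_at(refseq, col.ref_pos) >= min_len:
        return True
    if include_adjacent and any(
        n >= min_len for n in _adjacent_run_lengths(refseq, col.ref_pos)
    ):
        return True
    for obs in col.observations:
        if obs.read_base is None or obs.query_pos is None:
            continue
        if _run_length_at(obs.read.seq, obs.query_pos) >= min_len:
            return True
        if include_adjacent and any(
            n >= min_len for n in _adjacent_run_lengths(obs.read.seq, obs.query_pos)
        ):
            return True
    return False


def gap_ratio(col: PileupColumn) -> float:
    """Fraction of the column's observations that are gaps."""
    if not col.observations:
        raise ValueError(f"empty pileup column at {col.chrom}:{col.ref_pos}")
    gaps = sum(1 for o in col.observations if o.category == GAP)
    return gaps / len(col.observations)


def classify_improper_gaps(
    col: PileupColumn, ref: ReferenceGenome, config: AosConfig | None = None
) -> list[tuple[AlignedRead, GapEvent]]:
    """All gap events at the column, iff both AOS gates pass; else empty."""
    config = config or AosConfig()
    if not col.observations or not column_is_triggered(col):
        return []
    if not has_homopolymer_context(
        col, ref, config.min_homopolymer, config.include_adjacent_runs
    ):
        return []
    ratio = gap_ratio(col)
    if not 0 < ratio < config.gap_ratio_threshold:
        return []
    return [
        (o.read, GapEvent(col.chrom, col.ref_pos, o.gap_kind))
        for o in col.observations
        if o.category == GAP
    ]


# ---------------------------------------------------------------------------
# Read repair


def _locate_op(read: AlignedRead, event: GapEvent) -> int:
    """Index of the CIGAR op containing the event; raises if not found."""
    rpos = read.pos
    for i, op in enumerate(read.cigar):
        if op.op in "MDN=X":
            if event.kind == "deletion" and op.op == "D" and rpos <= event.ref_pos < rpos + op.length:
                return i
            rpos += op.length
        elif op.op == "I" and event.kind == "insertion" and rpos - 1 == event.ref_pos:
            return i
    raise ValueError(
        f"read {read.name}: no {event.kind} op at {event.chrom}:{event.ref_pos}"
    )


def _query_offset(cigar: Sequence[CigarOp], op_index: int) -> int:
    return sum(o.length for o in cigar[:op_index] if o.op in "MIS=X")


def _ref_offset(cigar: Sequence[CigarOp], op_index: int) -> int:
    return sum(o.length for o in cigar[:op_index] if o.op in "MDN=X")


def _merge_matches(cigar: list[CigarOp]) -> tuple[CigarOp, ...]:
    merged: list[CigarOp] = []
    for op in cigar:
        if merged and merged[-1].op == op.op:
            merged[-1] = CigarOp(op.op, merged[-1].length + op.length)
        else:
            merged.append(op)
    return tuple(merged)


def repair_read(
    read: AlignedRead,
    events: Sequence[GapEvent],
    ref: ReferenceGenome,
    mode: str = "repair",
) -> AlignedRead | None:
    """Remove improper gaps from one read.

    Repair mode edits the alignment in place: insertion ops are excised from
    seq/quals; deletion ops become matches, with the deleted reference bases
    filled in at the minimum of the flanking base qualities.  The read's
    reference span is unchanged by both edits.  Drop mode returns None.
    """
    if not events:
        return read
    if mode == "drop":
        return None
    op_indices = sorted({_locate_op(read, e) for e in events}, reverse=True)
    cigar = list(read.cigar)
    seq = read.seq
    quals = list(read.quals)
    for i in op_indices:
        op = cigar[i]
        q = _query_offset(cigar, i)
        if op.op == "I":
            seq = seq[:q] + seq[q + op.length :]
            del quals[q : q + op.length]
            del cigar[i]
        elif op.op == "D":
            r = read.pos + _ref_offset(cigar, i)
            fill = ref.fetch(read.chrom, r, r + op.length)
            left_q = quals[q - 1] if q > 0 else None
            right_q = quals[q] if q < len(quals) else None
            flanks = [x for x in (left_q, right_q) if x is not None]
            fill_q = min(flanks) if flanks else 0
            seq = seq[:q] + fill + seq[q:]
            quals[q:q] = [fill_q] * op.length
            cigar[i] = CigarOp("M", op.length)
        else:  # pragma: no cover - guarded by _locate_op
            raise ValueError(f"cannot repair op {op}")
    repaired = read.copy(
        cigar=_merge_matches(cigar), seq=seq, quals=tuple(quals)
    )
    if repaired.reference_end != read.reference_end:
        raise AssertionError("repair changed the reference span")
    return repaired


# ---------------------------------------------------------------------------
# Whole-stream driver


def run_aos(
    reads: Iterable[AlignedRead],
    ref: ReferenceGenome,
    config: AosConfig | None = None,
    region: Region | None = None,
    max_passes: int = 5,
) -> tuple[list[AlignedRead], AosStats]:
    """Apply AOS to a sorted read stream; returns (sorted output reads, stats).

    Repairs preserve each read's position and reference span, so output order
    is stable.  Because a repair rewrites read bases, it can occasionally
    create fresh read-side homopolymer context at a neighbouring column, so
    the scan is repeated until no improper gaps remain (rarely more than two
    passes); the result is therefore idempotent.  Stats are accumulated over
    all passes, with column counters taken from the first.
    """
    config = config or AosConfig()
    stats = AosStats()
    out, first = _aos_pass(reads, ref, config, region)
    stats.columns_examined = first.columns_examined
    stats.columns_homopolymer_confirmed = first.columns_homopolymer_confirmed
    stats.improper_gap_events = first.improper_gap_events
    stats.reads_repaired = first.reads_repaired
    stats.reads_dropped = first.reads_dropped
    passes = 1
    while first.improper_gap_events and passes < max_passes:
        out, first = _aos_pass(out, ref, config, region)
        stats.improper_gap_events += first.improper_gap_events
        stats.reads_repaired += first.reads_repaired
        stats.reads_dropped += first.reads_dropped
        passes += 1
    return out, stats


def _aos_pass(
    reads: Iterable[AlignedRead],
    ref: ReferenceGenome,
    config: AosConfig,
    region: Region | None,
) -> tuple[list[AlignedRead], AosStats]:
    stats = AosStats()
    out: list[AlignedRead] = []
    chrom_order: dict[str, int] = {}
    pending = list(reads)
    events_by_read: dict[int, list[GapEvent]] = {}
    for read in pending:
        chrom_order.setdefault(read.chrom, len(chrom_order))

    for col in build_pileup(pending, ref, region):
        stats.columns_examined += 1
        if not column_is_triggered(col):
            continue
        if not has_homopolymer_context(
            col, ref, config.min_homopolymer, config.include_adjacent_runs
        ):
            continue
        stats.columns_homopolymer_confirmed += 1
        ratio = gap_ratio(col)
        if not 0 < ratio < config.gap_ratio_threshold:
            continue
        for obs in col.observations:
            if obs.category == GAP:
                stats.improper_gap_events += 1
                events_by_read.setdefault(id(obs.read), []).append(
                    GapEvent(col.chrom, col.ref_pos, obs.gap_kind)
                )

    for read in pending:
        events = events_by_read.get(id(read))
        if not events:
            out.append(read)
            continue
        repaired = repair_read(read, events, ref, config.mode)
        if repaired is None:
            stats.reads_dropped += 1
        else:
            stats.reads_repaired += 1
            out.append(repaired)
    out.sort(key=lambda r: (chrom_order.get(r.chrom, 0), r.pos, r.name))
    return out, stats
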