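"""Ion-semiconductor-style read simulator with ground truth.

Generates a homopolymer-enriched reference, plants biallelic SNPs on a
diploid donor, and emits variable-length single-end reads pre-aligned to
their true origin.  Each sequencing template is expanded into a PCR-duplicate
pile whose members share the template's 5' mapped coordinate and its
pre-amplification errors, with further per-copy errors on top.  Gap errors
(homopolymer over/undercalls, default 1 per 100 aligned bases) are biased
into runs of >= 3 identical bases.  Per-read alignment scores are computed
from the true alignment with a configurable scoring scheme, so error-laden
duplicates score lower — which is exactly what makes score-threshold
duplicate filtering effective downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as otg_io
from .model import AlignedRead, CigarOp, ReferenceGenome, Region, VariantCall

BASES = "ACGT"


@dataclass(frozen=True)
class SimulationConfig:
    genome_length: int = 100_000
    n_chroms: int = 1
    gc_fraction: float = 0.5
    #: probability that a base repeats its predecessor (0 = i.i.d. bases)
    homopolymer_enrichment: float = 0.15
    n_snps: int = 100
    het_fraction: float = 0.5
    read_length_mean: int = 200
    read_length_sd: int = 30
    read_length_min: int = 50
    depth_target: float = 30.0
    per_base_gap_error_rate: float = 0.01
    per_base_substitution_rate: float = 0.002
    #: shared (pre-amplification) error rates, sampled once per template
    pcr_substitution_rate: float = 0.002
    pcr_gap_error_rate: float = 0.001
    #: probability a gap error is placed inside a homopolymer run (>= 3)
    homopolymer_gap_bias: float = 0.9
    #: P parameter of the geometric pile-size distribution (mean pile = 1/p)
    duplicate_group_geometric_p: float = 0.35
    #: mean 3'-trim of duplicate copies (geometric); first copy is untrimmed.
    #: Heavy trimming makes duplicate scores fall below a fixed AS threshold,
    #: which is what score-based duplicate filtering relies on.
    copy_trim_geometric_p: float = 0.008
    score_match: int = 1
    score_mismatch: int = -2
    score_gap_open: int = -3
    score_gap_extend: int = -1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "gc_fraction",
            "homopolymer_enrichment",
            "het_fraction",
            "per_base_gap_error_rate",
            "per_base_substitution_rate",
            "pcr_substitution_rate",
            "pcr_gap_error_rate",
            "homopolymer_gap_bias",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {value}")
        if self.genome_length <= 0:
            raise ValueError("genome_length must be positive")
        if not 0 < self.duplicate_group_geometric_p <= 1:
            raise ValueError("duplicate_group_geometric_p must be in (0,1]")


@dataclass
class TruthSet:
    """Planted variants plus per-read provenance."""

    snps: set[VariantCall]
    reads: pd.DataFrame = field(default_factory=pd.DataFrame)


@dataclass
class SimulatedDataset:
    reference: ReferenceGenome
    donor: "DonorGenome"
    reads: list[AlignedRead]
    truth: TruthSet
    config: SimulationConfig


# ---------------------------------------------------------------------------
# Reference


def simulate_reference(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> ReferenceGenome:
    """Random reference with tunable GC and homopolymer-run enrichment.

    With enrichment h, each base repeats its predecessor with probability h
    and is otherwise drawn i.i.d. from the GC-weighted base distribution, so
    h = 0 recovers the i.i.d. geometric run-length law.
    """
    rng = rng or np.random.default_rng(config.seed)
    if config.genome_length <= 0:
        raise ValueError("genome_length must be positive")
    per_chrom = config.genome_length // config.n_chroms
    gc = config.gc_fraction
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seqs: dict[str, str] = {}
    base_codes = np.frombuffer(BASES.encode(), dtype=np.uint8)
    for i in range(config.n_chroms):
        n = per_chrom if i < config.n_chroms - 1 else config.genome_length - per_chrom * (config.n_chroms - 1)
        draws = rng.choice(4, size=n, p=probs)
        if config.homopolymer_enrichment > 0:
            repeat = rng.random(n) < config.homopolymer_enrichment
            repeat[0] = False
            idx = np.arange(n)
            idx[repeat] = 0
            source = np.maximum.accumulate(idx)  # last non-repeat position
            draws = draws[source]
        seqs[f"chr{i + 1}"] = base_codes[draws].tobytes().decode()
    return ReferenceGenome(seqs)


# ---------------------------------------------------------------------------
# Donor


class DonorGenome:
    """Diploid donor: two haplotype sequences per chromosome."""

    def __init__(self, haplotypes: dict[str, tuple[str, str]]):
        self._haps = haplotypes

    def haplotype(self, chrom: str, index: int) -> str:
        return self._haps[chrom][index]

    @property
    def chroms(self) -> list[str]:
        return list(self._haps)


def plant_variants(
    ref: ReferenceGenome,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[DonorGenome, set[VariantCall]]:
    """Place ``n_snps`` biallelic SNPs uniformly; het sites go on one haplotype."""
    rng = rng or np.random.default_rng(config.seed)
    total = sum(ref.lengths().values())
    if config.n_snps >= total:
        raise ValueError("n_snps must be smaller than the genome")
    offsets = rng.choice(total, size=config.n_snps, replace=False)
    offsets.sort()
    boundaries: list[tuple[str, int, int]] = []
    cursor = 0
    for chrom, length in ref.lengths().items():
        boundaries.append((chrom, cursor, cursor + length))
        cursor += length
    haps = {chrom: [list(ref.sequence(chrom)), list(ref.sequence(chrom))] for chrom in ref.chroms}
    truth: set[VariantCall] = set()
    for offset in offsets:
        chrom, start, _ = next(b for b in boundaries if b[1] <= offset < b[2])
        pos = int(offset - start)
        ref_base = ref.base(chrom, pos)
        if ref_base not in BASES:
            continue
        alt = rng.choice([b for b in BASES if b != ref_base])
        is_het = rng.random() < config.het_fraction
        if is_het:
            hap = int(rng.integers(2))
            haps[chrom][hap][pos] = alt
        else:
            haps[chrom][0][pos] = alt
            haps[chrom][1][pos] = alt
        truth.add(
            VariantCall(
                chrom=chrom,
                pos=pos,
                ref_allele=ref_base,
                alt_allele=str(alt),
                genotype="het" if is_het else "hom",
            )
        )
    donor = DonorGenome(
        {chrom: ("".join(h[0]), "".join(h[1])) for chrom, h in haps.items()}
    )
    return donor, truth


# ---------------------------------------------------------------------------
# Reads


class _ChromData:
    """Per-(chrom, haplotype) arrays used to build reads in O(#events)."""

    def __init__(self, chrom: str, hap_seq: str, ref_seq: str):
        self.chrom = chrom
        self.seq = hap_seq
        hap = np.frombuffer(hap_seq.encode(), dtype=np.uint8)
        refa = np.frombuffer(ref_seq.encode(), dtype=np.uint8)
        self.ref_codes = refa
        self.mismatch_cum = np.concatenate(
            [[0], np.cumsum(hap != refa, dtype=np.int64)]
        )
        # positions inside homopolymer runs of length >= 3 in the haplotype
        n = len(hap)
        run_id = np.concatenate([[0], np.cumsum(hap[1:] != hap[:-1])])
        run_sizes = np.bincount(run_id)
        self.hp_positions = np.flatnonzero(run_sizes[run_id] >= 3)


def _sample_positions(
    rng: np.random.Generator,
    n: int,
    start: int,
    end: int,
    data: _ChromData,
    bias: float,
) -> list[int]:
    """Error positions inside (start, end-1), homopolymer-biased."""
    lo, hi = start + 1, end - 1  # exclusive of both alignment edges
    if hi <= lo or n <= 0:
        return []
    left = np.searchsorted(data.hp_positions, lo)
    right = np.searchsorted(data.hp_positions, hi)
    hp = data.hp_positions[left:right]
    out = []
    for _ in range(n):
        if len(hp) and rng.random() < bias:
            out.append(int(hp[rng.integers(len(hp))]))
        else:
            out.append(int(rng.integers(lo, hi)))
    return out


def _build_read(
    data: _ChromData,
    start: int,
    end: int,
    events: dict[int, tuple],
    config: SimulationConfig,
) -> tuple[tuple[CigarOp, ...], str, int]:
    """Assemble (cigar, seq, alignment_score) for the interval [start, end).

    ``events`` maps haplotype positions to ("sub", alt) | ("del",) | ("ins",).
    Deletions falling on the first or last aligned position are ignored so the
    alignment never starts or ends in a D op.
    """
    hap = data.seq
    parts: list[str] = []
    ops: list[CigarOp] = []
    sub_adjust = 0  # correction to the haplotype-vs-reference mismatch count
    cursor = start

    def emit(op: str, length: int) -> None:
        if ops and ops[-1].op == op:
            ops[-1] = CigarOp(op, ops[-1].length + length)
        else:
            ops.append(CigarOp(op, length))

    for pos in sorted(p for p in events if start <= p < end):
        kind = events[pos]
        if pos > cursor:
            emit("M", pos - cursor)
            parts.append(hap[cursor:pos])
        elif pos < cursor:  # pragma: no cover - events are distinct positions
            continue
        hap_mismatch = int(data.mismatch_cum[pos + 1] - data.mismatch_cum[pos])
        if kind[0] == "sub":
            alt = kind[1]
            emit("M", 1)
            parts.append(alt)
            sub_adjust += int(ord(alt) != data.ref_codes[pos]) - hap_mismatch
        elif kind[0] == "del":
            if pos in (start, end - 1):
                emit("M", 1)
                parts.append(hap[pos])
            else:
                emit("D", 1)
                sub_adjust -= hap_mismatch
        elif kind[0] == "ins":
            emit("M", 1)
            parts.append(hap[pos])
            emit("I", 1)
            parts.append(hap[pos])
        cursor = pos + 1
    if cursor < end:
        emit("M", end - cursor)
        parts.append(hap[cursor:end])

    mismatches = int(data.mismatch_cum[end] - data.mismatch_cum[start]) + sub_adjust
    m_bases = sum(o.length for o in ops if o.op == "M")
    score = config.score_match * (m_bases - mismatches)
    score += config.score_mismatch * mismatches
    for op in ops:
        if op.op in "ID":
            score += config.score_gap_open + config.score_gap_extend * (op.length - 1)
    return tuple(ops), "".join(parts), score


def simulate_reads(
    donor: DonorGenome,
    ref: ReferenceGenome,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[AlignedRead], TruthSet]:
    """Emit sorted, pre-aligned duplicate-pile reads plus per-read provenance."""
    rng = rng or np.random.default_rng(config.seed)
    if config.depth_target <= 0:
        raise ValueError("depth_target must be positive")
    lengths = ref.lengths()
    total_len = sum(lengths.values())
    mean_pile = 1.0 / config.duplicate_group_geometric_p
    # expected 3'-trim of a duplicate copy: E[min(T-1, L-min_len)], T ~ Geom(p)
    p_trim = config.copy_trim_geometric_p
    max_trim = max(config.read_length_mean - config.read_length_min, 0)
    mean_trim = (1 - p_trim) * (1 - (1 - p_trim) ** max_trim) / p_trim
    copy_len = config.read_length_mean - mean_trim
    bases_per_template = config.read_length_mean + (mean_pile - 1) * copy_len
    n_templates = max(
        1, int(round(config.depth_target * total_len / bases_per_template))
    )
    chrom_names = list(lengths)
    chrom_weights = np.array([lengths[c] for c in chrom_names], dtype=float)
    chrom_weights /= chrom_weights.sum()
    data_cache: dict[tuple[str, int], _ChromData] = {}

    reads: list[AlignedRead] = []
    provenance: list[dict] = []
    for tid in range(n_templates):
        chrom = chrom_names[rng.choice(len(chrom_names), p=chrom_weights)]
        clen = lengths[chrom]
        tlen = int(
            np.clip(
                rng.normal(config.read_length_mean, config.read_length_sd),
                config.read_length_min,
                clen,
            )
        )
        start = int(rng.integers(0, clen - tlen + 1))
        end = start + tlen
        strand = "-" if rng.random() < 0.5 else "+"
        hap_idx = int(rng.integers(2))
        key = (chrom, hap_idx)
        if key not in data_cache:
            data_cache[key] = _ChromData(
                chrom, donor.haplotype(chrom, hap_idx), ref.sequence(chrom)
            )
        data = data_cache[key]

        shared = _draw_errors(
            rng, data, start, end, config.pcr_substitution_rate,
            config.pcr_gap_error_rate, config,
        )
        pile = int(rng.geometric(config.duplicate_group_geometric_p))
        for copy in range(pile):
            trim = 0 if copy == 0 else min(int(rng.geometric(config.copy_trim_geometric_p)) - 1, tlen - config.read_length_min)
            trim = max(trim, 0)
            if strand == "+":
                cstart, cend = start, end - trim
            else:
                cstart, cend = start + trim, end
            own = _draw_errors(
                rng, data, cstart, cend, config.per_base_substitution_rate,
                config.per_base_gap_error_rate, config,
            )
            events = dict(shared)
            for pos, ev in own.items():
                events.setdefault(pos, ev)
            events = {p: e for p, e in events.items() if cstart <= p < cend}
            cigar, seq, score = _build_read(data, cstart, cend, events, config)
            name = f"t{tid:07d}.{copy}"
            quals = tuple(int(q) for q in rng.integers(25, 38, size=len(seq)))
            reads.append(
                AlignedRead(
                    name=name,
                    chrom=chrom,
                    pos=cstart,
                    strand=strand,
                    mapq=60,
                    cigar=cigar,
                    seq=seq,
                    quals=quals,
                    alignment_score=score,
                )
            )
            provenance.append(
                {
                    "name": name,
                    "template": tid,
                    "group": tid,
                    "chrom": chrom,
                    "five_prime": start if strand == "+" else end - 1,
                    "strand": strand,
                    "haplotype": hap_idx,
                    "n_shared_errors": len(shared),
                    "n_copy_errors": len(own),
                }
            )
    order = {c: i for i, c in enumerate(chrom_names)}
    pairs = sorted(
        zip(reads, provenance), key=lambda rp: (order[rp[0].chrom], rp[0].pos, rp[0].name)
    )
    reads = [r for r, _ in pairs]
    provenance = [p for _, p in pairs]
    return reads, TruthSet(snps=set(), reads=pd.DataFrame(provenance))


def _draw_errors(
    rng: np.random.Generator,
    data: _ChromData,
    start: int,
    end: int,
    sub_rate: float,
    gap_rate: float,
    config: SimulationConfig,
) -> dict[int, tuple]:
    events: dict[int, tuple] = {}
    length = end - start
    n_subs = int(rng.binomial(length, sub_rate)) if sub_rate > 0 else 0
    for _ in range(n_subs):
        pos = int(rng.integers(start, end))
        current = data.seq[pos]
        alt = str(rng.choice([b for b in BASES if b != current]))
        events.setdefault(pos, ("sub", alt))
    n_gaps = int(rng.binomial(length, gap_rate)) if gap_rate > 0 else 0
    for pos in _sample_positions(
        rng, n_gaps, start, end, data, config.homopolymer_gap_bias
    ):
        kind = ("del",) if rng.random() < 0.5 else ("ins",)
        events.setdefault(pos, kind)
    return events


# ---------------------------------------------------------------------------
# Whole-dataset convenience


def simulate_dataset(
    config: SimulationConfig, out_dir: str | Path | None = None
) -> SimulatedDataset:
    """Reference + donor + reads + truth, optionally written to ``out_dir``.

    Files written: ref.fa, reads.sam, truth.vcf, truth_reads.tsv, target.bed.
    Byte-identical under a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    ref = simulate_reference(config, rng)
    donor, truth_snps = plant_variants(ref, config, rng)
    reads, truth = simulate_reads(donor, ref, config, rng)
    truth.snps = truth_snps
    dataset = SimulatedDataset(ref, donor, reads, truth, config)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        otg_io.write_fasta(ref, out / "ref.fa")
        otg_io.write_alignments(reads, ref, out / "reads.sam")
        otg_io.write_variants(truth_snps, out / "truth.vcf", ref)
        truth.reads.to_csv(out / "truth_reads.tsv", sep="\t", index=False)
        otg_io.write_regions(ref.regions(), out / "target.bed")
    return dataset
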