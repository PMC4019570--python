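"""Readers and writers for SAM/BAM, FASTA, BED and VCF.

SAM/BAM and VCF are handled by pysam, FASTA by Biopython.  Coordinates are
converted to the internal 0-based half-open convention on the way in and back
to the native conventions on the way out.  Only primary, mapped alignments are
surfaced; secondary/supplementary/unmapped records are dropped with a logged
count.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import (
    AlignedRead,
    CigarOp,
    CIGAR_OPS,
    ReferenceGenome,
    Region,
    VariantCall,
    cigar_str,
    in_regions,
)

log = logging.getLogger(__name__)

NO_SCORE = float("-inf")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> ReferenceGenome:
    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
    if not seqs:
        raise ValueError(f"no sequences found in {path}")
    return ReferenceGenome(seqs)


def write_fasta(ref: ReferenceGenome, path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=chrom, description="") for chrom, seq in ref]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# SAM/BAM


def _sam_mode(path: str | Path, write: bool) -> str:
    suffix = Path(path).suffix.lower()
    if write:
        return "wb" if suffix == ".bam" else "w"
    return "rb" if suffix == ".bam" else "r"


def _to_aligned_read(rec: pysam.AlignedSegment) -> AlignedRead:
    cigar = tuple(
        CigarOp(CIGAR_OPS[op], length) for op, length in (rec.cigartuples or ())
    )
    if rec.has_tag("AS"):
        score: float = int(rec.get_tag("AS"))
    else:
        score = NO_SCORE
    quals = tuple(rec.query_qualities) if rec.query_qualities is not None else ()
    return AlignedRead(
        name=rec.query_name,
        chrom=rec.reference_name,
        pos=rec.reference_start,
        strand="-" if rec.is_reverse else "+",
        mapq=rec.mapping_quality,
        cigar=cigar,
        seq=rec.query_sequence or "",
        quals=quals,
        alignment_score=score,
    )


def read_alignments(
    path: str | Path, region: Region | None = None
) -> Iterator[AlignedRead]:
    """Stream mapped primary alignments from a coordinate-sorted SAM/BAM.

    Enforces sorted order (raises on a decreasing position, naming the
    offending record).  Secondary/supplementary/unmapped records and reads
    without an AS tag are counted and logged.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    dropped = 0
    no_as = 0
    last: tuple[int, int] | None = None
    with pysam.AlignmentFile(str(path), _sam_mode(path, write=False)) as fh:
        for rec in fh:
            if rec.is_unmapped:
                dropped += 1
                continue
            if rec.is_secondary or rec.is_supplementary:
                dropped += 1
                continue
            key = (rec.reference_id, rec.reference_start)
            if last is not None and key < last:
                raise ValueError(
                    f"{path} is not coordinate-sorted: record {rec.query_name!r} "
                    f"at {rec.reference_name}:{rec.reference_start + 1} follows a "
                    f"later position"
                )
            last = key
            read = _to_aligned_read(rec)
            if read.alignment_score == NO_SCORE:
                no_as += 1
            if region is not None and not region.overlaps_read(read):
                continue
            yield read
    if dropped:
        log.info("%s: dropped %d unmapped/secondary/supplementary records", path, dropped)
    if no_as:
        log.warning("%s: %d reads lack an AS tag (scored -inf)", path, no_as)


def make_sam_header(contigs: Mapping[str, int] | ReferenceGenome) -> dict:
    if isinstance(contigs, ReferenceGenome):
        contigs = contigs.lengths()
    return {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": name, "LN": length} for name, length in contigs.items()],
    }


def read_sam_header(path: str | Path) -> dict:
    with pysam.AlignmentFile(str(path), _sam_mode(path, write=False)) as fh:
        return fh.header.to_dict()


def write_alignments(
    reads: Iterable[AlignedRead],
    header: dict | Mapping[str, int] | ReferenceGenome,
    path: str | Path,
) -> int:
    """Write reads to SAM (or BAM, by extension).  Input must be sorted.

    Returns the number of records written.
    """
    if not (isinstance(header, dict) and "SQ" in header):
        header = make_sam_header(header)
    hdr = pysam.AlignmentHeader.from_dict(header)
    order = {sq["SN"]: i for i, sq in enumerate(header["SQ"])}
    n = 0
    last: tuple[int, int] | None = None
    with pysam.AlignmentFile(str(path), _sam_mode(path, write=True), header=hdr) as out:
        for read in reads:
            key = (order[read.chrom], read.pos)
            if last is not None and key < last:
                raise ValueError(
                    f"unsorted read stream: {read.name!r} at "
                    f"{read.chrom}:{read.pos + 1} follows a later position"
                )
            last = key
            rec = pysam.AlignedSegment(hdr)
            rec.query_name = read.name
            rec.reference_name = read.chrom
            rec.reference_start = read.pos
            rec.mapping_quality = read.mapq
            rec.cigarstring = cigar_str(read.cigar)
            rec.query_sequence = read.seq
            rec.query_qualities = pysam.qualitystring_to_array(
                "".join(chr(q + 33) for q in read.quals)
            )
            rec.flag = 16 if read.is_reverse else 0
            if read.alignment_score != NO_SCORE:
                rec.set_tag("AS", int(read.alignment_score))
            out.write(rec)
            n += 1
    return n


# ---------------------------------------------------------------------------
# BED


def read_regions(path: str | Path) -> list[Region]:
    """Parse a BED file (0-based half-open); overlapping intervals are merged."""
    raw: list[Region] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: BED line has <3 columns")
            try:
                raw.append(Region(fields[0], int(fields[1]), int(fields[2])))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    raw.sort(key=lambda r: (r.chrom, r.start, r.end))
    merged: list[Region] = []
    overlaps = 0
    for region in raw:
        if merged and merged[-1].chrom == region.chrom and region.start <= merged[-1].end:
            overlaps += 1
            prev = merged.pop()
            merged.append(Region(prev.chrom, prev.start, max(prev.end, region.end)))
        else:
            merged.append(region)
    if overlaps:
        log.warning("%s: merged %d overlapping/adjacent BED intervals", path, overlaps)
    return merged


def write_regions(regions: Sequence[Region], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\n")


# ---------------------------------------------------------------------------
# VCF


def read_variants(
    path: str | Path, region_set: Sequence[Region] | None = None
) -> set[VariantCall]:
    """Read SNPs from a VCF into a set of :class:`VariantCall`.

    Multi-allelic records are split per alt; non-SNP alleles are skipped with a
    logged count.  VCF's 1-based positions become 0-based.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    calls: set[VariantCall] = set()
    skipped = 0
    try:
        vcf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:
        raise ValueError(f"cannot parse VCF {path}: {exc}") from exc
    with vcf:
        for rec in vcf:
            pos = rec.pos - 1
            genotype = _record_genotype(rec)
            depth = _record_depth(rec)
            for alt in rec.alts or ():
                if len(rec.ref) != 1 or len(alt) != 1 or rec.ref not in "ACGT" or alt not in "ACGT":
                    skipped += 1
                    continue
                if not in_regions(rec.chrom, pos, region_set):
                    continue
                af = _info_field(rec, "AF")
                frac = float(af[0] if isinstance(af, tuple) else af) if af is not None else 0.0
                calls.add(
                    VariantCall(
                        chrom=rec.chrom,
                        pos=pos,
                        ref_allele=rec.ref,
                        alt_allele=alt,
                        genotype=genotype,
                        depth=depth,
                        alt_fraction=frac,
                    )
                )
    if skipped:
        log.info("%s: skipped %d non-SNP alleles", path, skipped)
    return calls


def _record_genotype(rec) -> str | None:
    for sample in rec.samples.values():
        gt = sample.get("GT")
        if gt is None or all(a is None for a in gt):
            return None
        alleles = {a for a in gt if a is not None}
        return "het" if len(alleles) > 1 else "hom"
    return None


def _info_field(rec, key):
    # pysam raises on INFO keys absent from the header, not just the record
    try:
        return rec.info.get(key)
    except (KeyError, ValueError):
        return None


def _record_depth(rec) -> int:
    dp = _info_field(rec, "DP")
    if dp is None:
        for sample in rec.samples.values():
            dp = sample.get("DP")
            break
    return int(dp) if dp is not None else 0


def write_variants(
    calls: Iterable[VariantCall],
    path: str | Path,
    contigs: Mapping[str, int] | ReferenceGenome,
) -> int:
    """Write SNP calls as a sorted VCF (1-based on disk)."""
    if isinstance(contigs, ReferenceGenome):
        contigs = contigs.lengths()
    header = pysam.VariantHeader()
    for name, length in contigs.items():
        header.contigs.add(name, length=length)
    header.info.add("DP", 1, "Integer", "Total observation depth at the site")
    header.info.add("AF", 1, "Float", "Alternate allele fraction")
    header.formats.add("GT", 1, "String", "Genotype")
    header.add_sample("SAMPLE")
    ordered = sorted(
        calls, key=lambda c: (list(contigs).index(c.chrom), c.pos, c.alt_allele)
    )
    n = 0
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for call in ordered:
            rec = out.new_record(
                contig=call.chrom,
                start=call.pos,
                stop=call.pos + 1,
                alleles=(call.ref_allele, call.alt_allele),
            )
            rec.info["DP"] = call.depth
            rec.info["AF"] = call.alt_fraction
            if call.genotype is not None:
                rec.samples["SAMPLE"]["GT"] = (0, 1) if call.genotype == "het" else (1, 1)
            out.write(rec)
            n += 1
    return n
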