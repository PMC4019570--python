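"""Call-set evaluation: FP/FN rates, overlap, consensus, Ti/Tv, het/hom,
known-sites rate, sensitivity/specificity and the depth-saturation procedure.

Site-level comparisons use the (chrom, pos, alt) key; detection for the FN
rate uses (chrom, pos) (a control site counts as detected if any call lands
on it); consensus is the genotype-level comparison at sites present in both
sets.  All rates are percentages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .aos import AosConfig, build_pileup, run_aos
from .caller import CallerConfig, call_snps
from .model import AlignedRead, ReferenceGenome, Region, VariantCall, in_regions
from .rdast import RdastConfig, run_rdast

TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}

SPECIFICITY_DEFINITION = (
    "specificity = 100 - fp_rate: percentage of emitted calls whose site "
    "(chrom, pos, alt) is present in the positive truth set"
)


def _restrict(calls: Iterable[VariantCall], regions) -> set[VariantCall]:
    return {c for c in calls if in_regions(c.chrom, c.pos, regions)}


def _sites(calls: Iterable[VariantCall]) -> set[tuple]:
    return {c.site for c in calls}


def _positions(calls: Iterable[VariantCall]) -> set[tuple]:
    return {(c.chrom, c.pos) for c in calls}


def fp_rate(
    calls: set[VariantCall],
    control: set[VariantCall],
    region_set: Sequence[Region] | None = None,
) -> float:
    """Percent of calls whose site is absent from the control set."""
    calls = _restrict(calls, region_set)
    if not calls:
        raise ValueError("empty call set after region restriction")
    control_sites = _sites(_restrict(control, region_set))
    missing = sum(1 for c in calls if c.site not in control_sites)
    return 100.0 * missing / len(calls)


def fn_rate(
    calls: set[VariantCall],
    control: set[VariantCall],
    region_set: Sequence[Region] | None = None,
) -> float:
    """Percent of control sites (within regions) not detected by any call."""
    control = _restrict(control, region_set)
    if not control:
        raise ValueError("empty control set after region restriction")
    called_positions = _positions(_restrict(calls, region_set))
    missed = sum(
        1 for pos in _positions(control) if pos not in called_positions
    )
    return 100.0 * missed / len(_positions(control))


def overlap(
    calls: set[VariantCall],
    control: set[VariantCall],
    region_set: Sequence[Region] | None = None,
) -> float:
    """Percent of calls whose site is present in the control set (100 - FP rate)."""
    return 100.0 - fp_rate(calls, control, region_set)


def db_rate(calls: set[VariantCall], known_sites: set[VariantCall]) -> float:
    """Percent of calls at known sites."""
    if not calls:
        raise ValueError("empty call set")
    known = _sites(known_sites)
    return 100.0 * sum(1 for c in calls if c.site in known) / len(calls)


def titv_ratio(calls: set[VariantCall]) -> float | None:
    """Transitions / transversions, or None when there are no transversions."""
    ti = sum(1 for c in calls if (c.ref_allele, c.alt_allele) in TRANSITIONS)
    tv = len(calls) - ti
    return ti / tv if tv else None


def het_hom_ratio(calls: set[VariantCall]) -> float | None:
    het = sum(1 for c in calls if c.genotype == "het")
    hom = sum(1 for c in calls if c.genotype == "hom")
    return het / hom if hom else None


def consensus(
    calls: set[VariantCall], genotyped: set[VariantCall]
) -> float | None:
    """Genotype concordance (percent) at positions present in both sets.

    Only pairs where both records carry a genotype participate; None when no
    position is shared.
    """
    by_pos_calls = {(c.chrom, c.pos): c for c in calls if c.genotype}
    by_pos_ctrl = {(c.chrom, c.pos): c for c in genotyped if c.genotype}
    shared = by_pos_calls.keys() & by_pos_ctrl.keys()
    if not shared:
        return None
    agree = sum(
        1
        for p in shared
        if by_pos_calls[p].genotype == by_pos_ctrl[p].genotype
        and by_pos_calls[p].alt_allele == by_pos_ctrl[p].alt_allele
    )
    return 100.0 * agree / len(shared)


def sensitivity_specificity(
    calls: set[VariantCall],
    truth_positive: set[VariantCall],
    truth_negative_sites: int | None = None,
) -> tuple[float, float]:
    """(sensitivity %, specificity %) against a positive truth set.

    Sensitivity: percent of truth sites detected by a call at (chrom, pos, alt).
    Specificity: with ``truth_negative_sites`` given, the classical
    TN / (TN + FP); otherwise the call-set definition recorded in
    :data:`SPECIFICITY_DEFINITION` (100 - FP rate over the emitted calls).
    """
    if not truth_positive:
        raise ValueError("empty positive truth set")
    truth_sites = _sites(truth_positive)
    call_sites = _sites(calls)
    detected = len(truth_sites & call_sites)
    sensitivity = 100.0 * detected / len(truth_sites)
    false_pos = len(call_sites - truth_sites)
    if truth_negative_sites is not None:
        if truth_negative_sites <= 0:
            raise ValueError("truth_negative_sites must be positive")
        tn = truth_negative_sites - false_pos
        specificity = 100.0 * tn / truth_negative_sites
    else:
        specificity = 100.0 * (1 - false_pos / len(call_sites)) if call_sites else 100.0
    return sensitivity, specificity


@dataclass
class EvalReport:
    """Bundle of call-set quality metrics plus the definitions used."""

    total_snps: int
    db_rate: float | None = None
    titv: float | None = None
    het_hom: float | None = None
    fn_rate: float | None = None
    fp_rate: float | None = None
    overlap_with_control: float | None = None
    consensus: float | None = None
    metadata: dict = field(default_factory=dict)

    ROW_LABELS = {
        "total_snps": "Total SNP number",
        "db_rate": "db rate",
        "titv": "Ti/Tv",
        "het_hom": "Het/hom",
        "fn_rate": "FN rate",
        "fp_rate": "FP rate",
        "overlap_with_control": "Overlap with control",
        "consensus": "Consensus",
    }

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (label, getattr(self, attr))
            for attr, label in self.ROW_LABELS.items()
        ]
        return pd.DataFrame(rows, columns=["metric", "value"], dtype=object)

    def to_tsv(self, path) -> None:
        rows = []
        for attr, label in self.ROW_LABELS.items():
            value = getattr(self, attr)
            if value is None:
                text = "NA"
            elif isinstance(value, float):
                text = f"{value:.4f}"
            else:
                text = str(value)
            rows.append((label, text))
        pd.DataFrame(rows, columns=["metric", "value"]).to_csv(
            path, sep="\t", index=False
        )


def evaluate(
    calls: set[VariantCall],
    wgs_control: set[VariantCall] | None = None,
    genotyping_control: set[VariantCall] | None = None,
    known_sites: set[VariantCall] | None = None,
    region_set: Sequence[Region] | None = None,
) -> EvalReport:
    """Compute the full metric bundle; metrics without a control are None."""
    calls = _restrict(calls, region_set)
    report = EvalReport(
        total_snps=len(calls),
        titv=titv_ratio(calls) if calls else None,
        het_hom=het_hom_ratio(calls) if calls else None,
        metadata={"specificity_definition": SPECIFICITY_DEFINITION},
    )
    if calls and wgs_control is not None:
        report.fp_rate = fp_rate(calls, wgs_control, region_set)
        report.overlap_with_control = overlap(calls, wgs_control, region_set)
    if genotyping_control:
        report.fn_rate = fn_rate(calls, genotyping_control, region_set)
        report.consensus = consensus(calls, genotyping_control)
    if calls and known_sites is not None:
        report.db_rate = db_rate(calls, known_sites)
    return report


# ---------------------------------------------------------------------------
# Pipeline helper + saturation


def run_calling_pipeline(
    reads: Sequence[AlignedRead],
    ref: ReferenceGenome,
    rdast_config: RdastConfig | None = None,
    aos_config: AosConfig | None = None,
    caller_config: CallerConfig | None = None,
    region: Region | None = None,
    use_rdast: bool = True,
    use_aos: bool = True,
) -> tuple[set[VariantCall], dict]:
    """RDAST -> AOS -> caller over in-memory reads; stage toggles for ablation."""
    stats: dict = {}
    stage = list(reads)
    if use_rdast:
        stage, rdast_stats = run_rdast(stage, rdast_config or RdastConfig())
        stats["rdast"] = rdast_stats.as_dict()
    if use_aos:
        stage, aos_stats = run_aos(stage, ref, aos_config or AosConfig(), region)
        stats["aos"] = aos_stats.as_dict()
    calls = call_snps(
        build_pileup(stage, ref, region), caller_config or CallerConfig()
    )
    return calls, stats


def mean_depth(reads: Iterable[AlignedRead], ref: ReferenceGenome) -> float:
    aligned = sum(sum(op.length for op in r.cigar if op.op in "M=X") for r in reads)
    genome = sum(ref.lengths().values())
    return aligned / genome if genome else 0.0


def saturation_curve(
    reads: Sequence[AlignedRead],
    ref: ReferenceGenome,
    truth: set[VariantCall],
    depth_grid: Sequence[float],
    rdast_config: RdastConfig | None = None,
    aos_config: AosConfig | None = None,
    caller_config: CallerConfig | None = None,
    region: Region | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Random depth subsampling: rerun the pipeline at each target depth.

    Returns a table of (target_depth, mean_depth, total_snps, fp, fn), one row
    per grid point, deterministic under a fixed seed.
    """
    if list(depth_grid) != sorted(depth_grid):
        raise ValueError("depth_grid must be increasing")
    available = mean_depth(reads, ref)
    rng = np.random.default_rng(seed)
    rows = []
    for target in depth_grid:
        if target > available:
            target = available
        fraction = target / available if available else 0.0
        if fraction >= 1.0:
            subsample = list(reads)
        else:
            mask = rng.random(len(reads)) < fraction
            subsample = [r for r, m in zip(reads, mask) if m]
        if not subsample or target == 0:
            rows.append(
                {"target_depth": target, "mean_depth": 0.0, "total_snps": 0,
                 "fp": 0, "fn": len(truth)}
            )
            continue
        calls, _ = run_calling_pipeline(
            subsample, ref, rdast_config, aos_config, caller_config, region
        )
        truth_sites = _sites(truth)
        call_sites = _sites(calls)
        rows.append(
            {
                "target_depth": target,
                "mean_depth": mean_depth(subsample, ref),
                "total_snps": len(calls),
                "fp": len(call_sites - truth_sites),
                "fn": len(truth_sites - call_sites),
            }
        )
    return pd.DataFrame(rows)
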