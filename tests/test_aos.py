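from itertools import groupby, product

import pytest

from otg.aos import (
    AosConfig,
    GapEvent,
    build_pileup,
    classify_improper_gaps,
    column_is_triggered,
    gap_ratio,
    has_homopolymer_context,
    repair_read,
    run_aos,
)
from otg.model import ReferenceGenome
from otg.simulate import SimulationConfig, simulate_dataset
from tests.conftest import make_read


def column_at(columns, pos):
    return next(c for c in columns if c.ref_pos == pos)


class TestBuildPileup:
    def test_matching_read_all_concordant(self):
        ref = ReferenceGenome({"chr1": "ACGTACGTAC"})
        read = make_read(cigar="10M", seq="ACGTACGTAC")
        cols = list(build_pileup([read], ref))
        assert len(cols) == 10
        assert all(c.observations[0].category == "concordant" for c in cols)
        assert [c.ref_pos for c in cols] == list(range(10))

    def test_deletion_columns_carry_gap_observations(self):
        # 4M2D4M: hand CIGAR walk puts deletion gaps at span offsets 4 and 5
        ref = ReferenceGenome({"chr1": "ACGTACGTAC"})
        read = make_read(cigar="4M2D4M", seq="ACGTGTAC")
        cols = list(build_pileup([read], ref))
        assert len(cols) == 10
        for pos in (4, 5):
            (obs,) = column_at(cols, pos).observations
            assert obs.category == "gap" and obs.gap_kind == "deletion"
        assert column_at(cols, 3).observations[0].category == "concordant"

    def test_insertion_anchored_left(self):
        # 5M1I5M: insertion-gap observation attached to column 4
        ref = ReferenceGenome({"chr1": "ACGTACGTAC"})
        read = make_read(cigar="5M1I5M", seq="ACGTAGCGTAC")
        cols = list(build_pileup([read], ref))
        anchor = column_at(cols, 4)
        kinds = [(o.category, o.gap_kind) for o in anchor.observations]
        assert ("gap", "insertion") in kinds
        assert ("concordant", "none") in kinds  # the M base is also observed
        assert all(
            all(o.category != "gap" for o in column_at(cols, p).observations)
            for p in range(10) if p != 4
        )

    def test_soft_clips_contribute_nothing(self):
        ref = ReferenceGenome({"chr1": "ACGTACGTAC"})
        read = make_read(cigar="3S4M", seq="TTTACGT")
        cols = list(build_pileup([read], ref))
        assert [c.ref_pos for c in cols] == [0, 1, 2, 3]

    def test_missing_chromosome_raises(self):
        ref = ReferenceGenome({"chr1": "ACGT"})
        read = make_read(chrom="chrX", cigar="4M", seq="ACGT")
        with pytest.raises(KeyError):
            list(build_pileup([read], ref))

    def test_mismatch_base_discordant(self):
        ref = ReferenceGenome({"chr1": "AAAA"})
        read = make_read(cigar="4M", seq="AAGA")
        cols = list(build_pileup([read], ref))
        assert column_at(cols, 2).observations[0].category == "discordant"


class TestTrigger:
    def test_all_concordant_not_triggered(self):
        ref = ReferenceGenome({"chr1": "AAAA"})
        cols = list(build_pileup([make_read(cigar="4M", seq="AAAA")], ref))
        assert not any(column_is_triggered(c) for c in cols)

    def test_gap_triggers(self):
        ref = ReferenceGenome({"chr1": "AAAAA"})
        cols = list(build_pileup([make_read(cigar="2M1D2M", seq="AAAA")], ref))
        assert column_is_triggered(column_at(cols, 2))

    def test_discordant_triggers(self):
        ref = ReferenceGenome({"chr1": "ACGT"})
        reads = [make_read(name=f"r{i}", cigar="4M", seq="ACGT") for i in range(8)]
        reads += [make_read(name=f"g{i}", cigar="4M", seq="AGGT") for i in range(3)]
        cols = list(build_pileup(reads, ref))
        assert column_is_triggered(column_at(cols, 1))


def _runs(seq):
    out, i = [], 0
    for base, grp in groupby(seq):
        n = len(list(grp))
        out.append((i, i + n, base))
        i += n
    return out


def _oracle_context(seq, pos, min_len, include_adjacent):
    for start, end, _ in _runs(seq):
        if end - start < min_len:
            continue
        if start <= pos < end:
            return True
        if include_adjacent and (end == pos or start == pos + 1):
            return True
    return False


class TestHomopolymerContext:
    def _column(self, window, triplet):
        ref = ReferenceGenome({"chr1": window})
        read = make_read(pos=1, cigar="3M", seq=triplet)
        cols = list(build_pileup([read], ref))
        return column_at(cols, 2), ref

    def test_reference_run_confirms(self):
        col, ref = self._column("TAAAG", "ACA")
        assert has_homopolymer_context(col, ref)

    def test_read_run_confirms(self):
        # reference has no run; the read carries GGG through the column
        col, ref = self._column("ACGTA", "GGG")
        assert has_homopolymer_context(col, ref)

    def test_no_run_anywhere(self):
        col, ref = self._column("ACGTA", "CTA")
        assert not has_homopolymer_context(col, ref)

    @pytest.mark.parametrize("include_adjacent", [True, False])
    def test_exhaustive_against_run_length_oracle(self, include_adjacent):
        bases = "ACGT"
        for window in map("".join, product(bases, repeat=5)):
            for triplet in map("".join, product(bases, repeat=3)):
                col, ref = self._column(window, triplet)
                expected = _oracle_context(
                    window, 2, 3, include_adjacent
                ) or _oracle_context(triplet, 1, 3, include_adjacent)
                got = has_homopolymer_context(
                    col, ref, min_len=3, include_adjacent=include_adjacent
                )
                assert got == expected, (window, triplet)


class TestGapRatio:
    def _pileup_with_gaps(self, n_total, n_gap):
        ref = ReferenceGenome({"chr1": "A" * 20})
        reads = [
            make_read(name=f"c{i}", cigar="9M", seq="A" * 9)
            for i in range(n_total - n_gap)
        ]
        reads += [
            make_read(name=f"g{i}", cigar="4M1D4M", seq="A" * 8)
            for i in range(n_gap)
        ]
        reads.sort(key=lambda r: r.name)
        cols = list(build_pileup(reads, ref))
        return column_at(cols, 4)

    def test_no_gaps(self):
        assert gap_ratio(self._pileup_with_gaps(10, 0)) == 0.0

    def test_one_in_ten(self):
        assert gap_ratio(self._pileup_with_gaps(10, 1)) == pytest.approx(0.1)

    def test_empty_column_raises(self):
        from otg.aos import PileupColumn

        with pytest.raises(ValueError):
            gap_ratio(PileupColumn("chr1", 0, "A", []))

    @pytest.mark.parametrize("n_total,n_gap", [(5, 2), (20, 7), (8, 8)])
    def test_matches_count_oracle(self, n_total, n_gap):
        col = self._pileup_with_gaps(n_total, n_gap)
        assert gap_ratio(col) == pytest.approx(n_gap / n_total)


class TestClassify:
    def _gap_column(self, n_total, n_gap, refseq="A" * 20):
        ref = ReferenceGenome({"chr1": refseq})
        reads = [
            make_read(name=f"c{i}", cigar="9M", seq=refseq[:9])
            for i in range(n_total - n_gap)
        ]
        reads += [
            make_read(name=f"g{i}", cigar="4M1D4M", seq=refseq[:4] + refseq[5:9])
            for i in range(n_gap)
        ]
        reads.sort(key=lambda r: r.name)
        cols = list(build_pileup(reads, ref))
        return column_at(cols, 4), ref

    def test_improper_gap_returned(self):
        col, ref = self._gap_column(10, 1)
        events = classify_improper_gaps(col, ref, AosConfig())
        assert len(events) == 1
        read, event = events[0]
        assert read.name == "g0"
        assert event == GapEvent("chr1", 4, "deletion")

    def test_high_ratio_retained(self):
        col, ref = self._gap_column(10, 5)
        assert classify_improper_gaps(col, ref, AosConfig()) == []

    def test_exactly_threshold_retained(self):
        # "under 0.2" is strict: ratio 0.2 keeps the gap
        col, ref = self._gap_column(10, 2)
        assert classify_improper_gaps(col, ref, AosConfig()) == []

    def test_non_homopolymer_column_untouched(self):
        col, ref = self._gap_column(10, 1, refseq="ACGTACGTACGTACGTACGT")
        assert classify_improper_gaps(col, ref, AosConfig()) == []

    def test_all_gap_column_never_improper(self):
        col, ref = self._gap_column(3, 3)
        assert gap_ratio(col) == 1.0
        assert classify_improper_gaps(col, ref, AosConfig()) == []


class TestRepair:
    def test_deletion_becomes_match_with_min_flank_quality(self):
        ref = ReferenceGenome({"chr1": "CCCCACCCC"})
        read = make_read(
            cigar="4M1D4M", seq="CCCCCCCC", quals=(30, 30, 30, 12, 25, 30, 30, 30)
        )
        repaired = repair_read(read, [GapEvent("chr1", 4, "deletion")], ref)
        assert [str(o) for o in repaired.cigar] == ["9M"]
        assert repaired.seq == "CCCCACCCC"  # gains the reference A
        assert repaired.quals[4] == 12  # min of flanking 12 and 25
        assert repaired.reference_end == read.reference_end

    def test_insertion_excised(self):
        ref = ReferenceGenome({"chr1": "AAAAAAAAAA"})
        read = make_read(cigar="5M1I5M", seq="AAAAAGAAAAA")
        repaired = repair_read(read, [GapEvent("chr1", 4, "insertion")], ref)
        assert [str(o) for o in repaired.cigar] == ["10M"]
        assert repaired.seq == "A" * 10
        assert repaired.reference_end == read.reference_end

    def test_no_events_identity(self, flat_ref):
        read = make_read(cigar="10M")
        assert repair_read(read, [], flat_ref) is read

    def test_drop_mode(self, flat_ref):
        read = make_read(cigar="4M1D4M", seq="A" * 8)
        assert repair_read(read, [GapEvent("chr1", 4, "deletion")], flat_ref, "drop") is None

    def test_unlocatable_event_raises(self, flat_ref):
        read = make_read(cigar="10M")
        with pytest.raises(ValueError, match="no deletion op"):
            repair_read(read, [GapEvent("chr1", 4, "deletion")], flat_ref)

    def test_multi_event_repair_keeps_span(self):
        ref = ReferenceGenome({"chr1": "G" * 30})
        read = make_read(
            cigar="5M1D5M1I5M", seq="G" * 16, quals=(20,) * 16
        )
        events = [GapEvent("chr1", 5, "deletion"), GapEvent("chr1", 10, "insertion")]
        repaired = repair_read(read, events, ref)
        assert [str(o) for o in repaired.cigar] == ["16M"]
        assert repaired.reference_end == read.reference_end


class TestRunAos:
    def _improper_gap_scenario(self):
        refseq = "ACGT" + "AAAA" + "CGTCGTACGATG"
        ref = ReferenceGenome({"chr1": refseq})
        clean = [
            make_read(name=f"c{i}", cigar="16M", seq=refseq[:16]) for i in range(9)
        ]
        gapped = make_read(name="gap", cigar="5M1D10M", seq=refseq[:5] + refseq[6:16])
        reads = sorted(clean + [gapped], key=lambda r: r.name)
        return ref, reads

    def test_repairs_planted_improper_gap_and_is_idempotent(self):
        ref, reads = self._improper_gap_scenario()
        out, stats = run_aos(reads, ref, AosConfig())
        assert stats.improper_gap_events == 1
        assert stats.reads_repaired == 1 and stats.reads_dropped == 0
        assert len(out) == len(reads)  # conservation in repair mode
        again, stats2 = run_aos(out, ref, AosConfig())
        assert stats2.improper_gap_events == 0
        assert again == out

    def test_untouched_reads_identical(self):
        ref, reads = self._improper_gap_scenario()
        out, _ = run_aos(reads, ref, AosConfig())
        by_name = {r.name: r for r in out}
        for read in reads:
            if read.name != "gap":
                assert by_name[read.name] is read  # bit-identical objects

    def test_drop_mode_removes_read(self):
        ref, reads = self._improper_gap_scenario()
        out, stats = run_aos(reads, ref, AosConfig(mode="drop"))
        assert stats.reads_dropped == 1
        assert len(out) == len(reads) - 1
        assert all(r.name != "gap" for r in out)

    def test_majority_gap_retained(self):
        # a real 1-base deletion present in 60% of reads stays put
        refseq = "ACGTAAAACGTCGTAC"
        ref = ReferenceGenome({"chr1": refseq})
        gapped = [
            make_read(name=f"g{i}", cigar="5M1D10M", seq=refseq[:5] + refseq[6:16])
            for i in range(6)
        ]
        clean = [
            make_read(name=f"c{i}", cigar="16M", seq=refseq[:16]) for i in range(4)
        ]
        reads = sorted(gapped + clean, key=lambda r: r.name)
        out, stats = run_aos(reads, ref, AosConfig())
        assert stats.improper_gap_events == 0
        assert out == reads

    def test_reference_span_preserved_on_simulated_data(self):
        dataset = simulate_dataset(
            SimulationConfig(genome_length=20_000, n_snps=20, depth_target=15, seed=11)
        )
        out, stats = run_aos(dataset.reads, dataset.reference, AosConfig())
        assert stats.improper_gap_events > 0  # scenario actually exercises AOS
        assert len(out) == len(dataset.reads)
        before = {r.name: (r.pos, r.reference_end) for r in dataset.reads}
        for read in out:
            assert before[read.name] == (read.pos, read.reference_end)

    def test_idempotent_on_simulated_data(self):
        dataset = simulate_dataset(
            SimulationConfig(genome_length=10_000, n_snps=10, depth_target=15, seed=5)
        )
        out, _ = run_aos(dataset.reads, dataset.reference, AosConfig())
        _, stats2 = run_aos(out, dataset.reference, AosConfig())
        assert stats2.improper_gap_events == 0
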