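"""SNP selection, calling, filtering, frequency, transfer, classification."""

import itertools

import pytest

from chromosurvey import snp, synthio
from chromosurvey.seqio import HomologyMatch, ReadRecord, SamAlignment
from chromosurvey.snp import (
    SiteCall,
    SNPConfig,
    call_variants,
    classify_shared,
    filter_variants,
    select_5b_transcripts,
    snp_frequency,
    transfer_positions,
)


def _match(q, s="b5read", evalue=1e-31, pident=98.0, bitscore=500.0):
    return HomologyMatch(q, s, pident, 200, evalue=evalue, bitscore=bitscore)


class TestSelectTranscripts:
    def test_evalue_just_above_cutoff_excluded(self):
        assert select_5b_transcripts([_match("t1", evalue=1e-29)]) == set()

    def test_boundary_included(self):
        assert select_5b_transcripts([_match("t1", evalue=1e-31, pident=98.0)]) == {"t1"}

    def test_empty_table(self):
        assert select_5b_transcripts([]) == set()

    def test_homoeolog_risk_flagged_on_multiple_strong_matches(self):
        matches = [_match("t1"), _match("t1", s="b5read2"), _match("t2")]
        assert snp.homoeolog_risk_flags(matches) == {"t1"}


def _aln(read_id, target, start, seq):
    pairs = [(i + 1, start + i) for i in range(len(seq))]
    return SamAlignment(read_id, target, start, pairs, read_sequence=seq)


class TestCallVariants:
    TRANSCRIPTS = {"t1": "AAAAAAAAAA"}

    def test_concordant_reads_no_variants(self):
        alns = [_aln(f"r{i}", "t1", 1, "AAAAAAAAAA") for i in range(4)]
        assert call_variants(alns, self.TRANSCRIPTS) == []

    def test_majority_differing_base_called(self):
        alns = [_aln(f"r{i}", "t1", 3, "GGG") for i in range(4)]
        alns.append(_aln("r4", "t1", 3, "AGG"))
        calls = call_variants(alns, self.TRANSCRIPTS)
        call = next(c for c in calls if c.position == 3)
        assert call.depth == 5
        assert call.read_consensus_base == "G"
        assert call.allele_counts == {"G": 4, "A": 1}

    def test_majority_tie_emits_no_call(self):
        alns = [
            _aln("r0", "t1", 5, "G"),
            _aln("r1", "t1", 5, "G"),
            _aln("r2", "t1", 5, "T"),
            _aln("r3", "t1", 5, "T"),
        ]
        assert call_variants(alns, self.TRANSCRIPTS) == []

    def test_alignment_to_unselected_transcript_rejected(self):
        with pytest.raises(ValueError, match="unselected"):
            call_variants([_aln("r0", "t2", 1, "A")], self.TRANSCRIPTS, {"t1"})


class TestFilterVariants:
    def _call(self, pos, depth, tid="t1"):
        return SiteCall(tid, pos, "A", "G", depth, {"G": depth})

    @pytest.mark.parametrize(
        "depth,kept", [(2, False), (3, True), (10, True), (11, False)]
    )
    def test_depth_boundaries(self, depth, kept):
        retained = filter_variants([self._call(100, depth)])
        assert bool(retained) == kept

    def test_proximity_removes_both_members(self):
        calls = [self._call(100, 5), self._call(102, 5), self._call(110, 5)]
        retained = filter_variants(calls)
        assert [c.position for c in retained] == [110]

    def test_single_snp_retained(self):
        assert len(filter_variants([self._call(50, 5)])) == 1

    def test_proximity_is_per_transcript(self):
        calls = [self._call(100, 5, "t1"), self._call(102, 5, "t2")]
        assert len(filter_variants(calls)) == 2

    def test_idempotent(self):
        calls = [self._call(p, 5) for p in (10, 12, 30, 33, 50)]
        once = filter_variants(calls)
        assert filter_variants(once) == once

    def test_matches_brute_force_pair_removal(self):
        import numpy as np

        rng = np.random.default_rng(2)
        for _ in range(20):
            positions = sorted(set(int(p) for p in rng.integers(1, 60, size=12)))
            calls = [self._call(p, 5) for p in positions]
            retained = {c.position for c in filter_variants(calls)}
            expected = {
                p
                for p in positions
                if all(q == p or abs(q - p) > 3 for q in positions)
            }
            assert retained == expected


class TestFrequency:
    def test_simple_ratio(self):
        calls = [SiteCall("t1", i * 10, "A", "G", 5, {"G": 5}) for i in range(1, 11)]
        assert snp_frequency(calls, {"t1": 10_000}) == 1_000.0

    def test_doubling_transcripts_doubles_frequency(self):
        calls = [SiteCall("t1", 100, "A", "G", 5, {"G": 5})]
        f1 = snp_frequency(calls, {"t1": 1_000})
        f2 = snp_frequency(calls, {"t1": 1_000, "t2": 1_000})
        assert f2 == 2 * f1

    def test_zero_snps_reported_absent(self):
        assert snp_frequency([], {"t1": 1_000}) is None


class TestTransferPositions:
    def _snp(self, pos, tid="t1"):
        return SiteCall(tid, pos, "A", "G", 5, {"G": 5})

    def test_identical_transcripts_identity_map(self):
        seq = "ACGTACGTACGTACGTACGTACGTACGTACGTACGTACGT"
        res = transfer_positions(
            [self._snp(10)], {"t1": seq}, {"u1": seq}, [_match("t1", "u1")]
        )
        assert res[0].other_position == 10
        assert res[0].other_base == seq[9]

    def test_upstream_insertion_shifts_position(self):
        tr = "ACGTACGTACGTACGTACGTACGTACGTACGT"
        other = tr[:5] + "TT" + tr[5:]  # 2-base insertion after position 5
        res = transfer_positions(
            [self._snp(20)], {"t1": tr}, {"u1": other}, [_match("t1", "u1")]
        )
        assert res[0].other_position == 22
        assert res[0].other_base == tr[19]

    def test_position_in_deletion_flagged_uncovered(self):
        tr = "ACGTACGTACGTGGGGGGGGGGACGTACGTACGTACGTAC"
        other = tr[:12] + tr[22:]  # positions 13-22 deleted in the other sample
        res = transfer_positions(
            [self._snp(16)], {"t1": tr}, {"u1": other}, [_match("t1", "u1")]
        )
        assert not res[0].covered
        assert res[0].other_position is None

    def test_ambiguous_multi_match_uses_best_bitscore_and_flags(self):
        seq = "ACGTACGTACGTACGTACGTACGTACGTACGT"
        matches = [
            _match("t1", "u1", bitscore=900.0),
            _match("t1", "u2", bitscore=400.0),
        ]
        res = transfer_positions(
            [self._snp(8)], {"t1": seq}, {"u1": seq, "u2": seq}, matches
        )
        assert res[0].other_transcript_id == "u1"
        assert res[0].ambiguous


class TestClassifyShared:
    def test_group1_example(self):
        s = classify_shared("C", "C", "T", "T", "T")
        assert s.group == 1

    def test_group3_worked_example(self):
        # drought and control TR both carry T at the position; TTD carries G;
        # the chromosome reads carry C -> all three distinct
        s = classify_shared("T", "T", "G", "G", "C")
        assert s.group == 3
        assert s.consistent and s.coverage_ok

    def test_group2_definition(self):
        s = classify_shared("A", "A", "A", "A", "G")
        assert s.group == 2

    def test_inconsistent_conditions_no_group(self):
        s = classify_shared("A", "C", "A", "A", "G")
        assert not s.consistent
        assert s.group is None

    def test_missing_coverage_no_group(self):
        s = classify_shared("A", "A", None, "A", "G")
        assert not s.coverage_ok
        assert s.group is None

    def test_groups_partition_all_triples_with_tr_differing_from_b5(self):
        # brute force over all 4^3 base triples: on consistent, covered
        # inputs the three groups are mutually exclusive, and exhaustive
        # whenever TR differs from the chromosome base
        bases = "ACGT"
        for tr, ttd, b5 in itertools.product(bases, repeat=3):
            s = classify_shared(tr, tr, ttd, ttd, b5)
            groups = [
                tr != ttd and ttd == b5,
                tr == ttd and tr != b5,
                tr != ttd and ttd != b5 and tr != b5,
            ]
            assert sum(groups) <= 1
            if tr != b5:
                assert sum(groups) == 1
                assert s.group == groups.index(True) + 1
            elif s.group is not None:
                assert groups[s.group - 1]


class TestEndToEndPlantedVariants:
    def test_recall_and_filter_exactness(self, default_chromosome):
        config, chromosome, truth = default_chromosome
        trio, planted = synthio.generate_transcript_trio(
            truth, chromosome, variant_density=1 / 500, seed=31
        )
        tr = {r.id: r.sequence for r in trio["TR-drought"]}
        reads = synthio.simulate_transcript_reads(chromosome, truth, depth=6, seed=32)
        alignments = snp.map_reads_to_transcripts(reads, tr)
        calls = call_variants(alignments, tr)
        retained = filter_variants(calls)
        planted_positions = {(v.transcript_id, v.position) for v in planted}
        called_positions = {(c.transcript_id, c.position) for c in retained}
        in_bounds = {
            (c.transcript_id, c.position)
            for c in calls
            if 3 <= c.depth <= 10
        } & planted_positions
        # no calls at unplanted positions (reads are edit-free)
        assert called_positions <= planted_positions
        recall = len(called_positions & in_bounds) / len(in_bounds)
        assert recall >= 0.95

    def test_planted_frequency_recovered(self, default_chromosome):
        config, chromosome, truth = default_chromosome
        trio, planted = synthio.generate_transcript_trio(
            truth, chromosome, variant_density=1 / 1000, seed=33
        )
        tr = {r.id: r.sequence for r in trio["TR-drought"]}
        reads = synthio.simulate_transcript_reads(chromosome, truth, depth=6, seed=34)
        retained = filter_variants(
            call_variants(snp.map_reads_to_transcripts(reads, tr), tr)
        )
        freq = snp_frequency(retained, {t: len(s) for t, s in tr.items()})
        planted_unique = {(v.transcript_id, v.position) for v in planted}
        planted_freq = sum(len(s) for s in tr.values()) / len(planted_unique)
        assert freq == pytest.approx(planted_freq, rel=0.15)

    def test_planted_group3_archetype_classified_end_to_end(self, default_chromosome):
        config, chromosome, truth = default_chromosome
        trio, planted = synthio.generate_transcript_trio(
            truth, chromosome, variant_density=1 / 400,
            group_proportions=(0.0, 0.0, 1.0), seed=35,
        )
        tr = {r.id: r.sequence for r in trio["TR-drought"]}
        ttd = {r.id: r.sequence for r in trio["TTD-drought"]}
        reads = synthio.simulate_transcript_reads(chromosome, truth, depth=6, seed=36)
        retained = filter_variants(
            call_variants(snp.map_reads_to_transcripts(reads, tr), tr)
        )
        transfers = transfer_positions(
            retained, tr, ttd, synthio.transcript_match_table(trio)
        )
        groups = [
            classify_shared(
                c.transcript_base, c.transcript_base,
                t.other_base, t.other_base, c.read_consensus_base,
            ).group
            for c, t in zip(retained, transfers)
        ]
        assert groups and set(groups) == {3}
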