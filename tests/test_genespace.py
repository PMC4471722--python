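"""Gene-space filters, RBH resolution, dedup, models and extrapolation."""


import pytest

from chromosurvey import genespace, synthio
from chromosurvey.genespace import (
    FilterProfile,
    MappedSegment,
    build_gene_models,
    classify_gene_space,
    deduplicate_singletons,
    filter_matches,
    genic_fraction,
    genome_gene_estimate,
    protein_to_cds_interval,
    reciprocal_best_hits,
)
from chromosurvey.seqio import HomologyMatch, ReadRecord


def _m(q, s, evalue=1e-10, bitscore=100.0, pident=95.0, ppos=95.0, align_len=100,
       sstart=1, send=100):
    return HomologyMatch(q, s, pident, align_len, evalue=evalue, bitscore=bitscore,
                         ppos=ppos, sstart=sstart, send=send)


class TestFilterMatches:
    PROFILE = FilterProfile("proteome", 1e-6, 30, min_ppos=75.0)

    def test_evalue_above_cutoff_removed(self):
        assert filter_matches([_m("q", "s", evalue=1e-5)], self.PROFILE) == []

    def test_boundary_values_retained(self):
        kept = filter_matches(
            [_m("q", "s", evalue=1e-6, align_len=30, ppos=75.0)], self.PROFILE
        )
        assert len(kept) == 1

    def test_empty_input(self):
        assert filter_matches([], self.PROFILE) == []

    def test_pident_profile(self):
        profile = FilterProfile("unigene", 1e-30, 90, min_pident=98.0)
        kept = filter_matches(
            [_m("q", "s", evalue=1e-31, pident=98.0), _m("q", "s2", evalue=1e-31, pident=97.9)],
            profile,
        )
        assert [m.subject_id for m in kept] == ["s"]

    def test_missing_ppos_is_error(self):
        match = HomologyMatch("q", "s", 95.0, 100, evalue=1e-10)
        with pytest.raises(ValueError, match="ppos"):
            filter_matches([match], self.PROFILE)

    def test_exactly_one_similarity_threshold(self):
        with pytest.raises(ValueError):
            FilterProfile("x", 1e-6, 30)
        with pytest.raises(ValueError):
            FilterProfile("x", 1e-6, 30, min_ppos=75.0, min_pident=98.0)


class TestReciprocalBestHits:
    def test_symmetric_pair_retained(self):
        pairs = reciprocal_best_hits([_m("q1", "s1")], [_m("s1", "q1")])
        assert pairs == [("q1", "s1")]

    def test_asymmetric_pair_discarded(self):
        fwd = [_m("q1", "s1")]
        rev = [_m("s1", "q2", evalue=1e-20), _m("s1", "q1", evalue=1e-10)]
        assert reciprocal_best_hits(fwd, rev) == []

    def test_bitscore_breaks_evalue_tie(self):
        fwd = [
            _m("q1", "s1", evalue=1e-10, bitscore=100.0),
            _m("q1", "s2", evalue=1e-10, bitscore=90.0),
        ]
        rev = [_m("s1", "q1"), _m("s2", "q1")]
        assert reciprocal_best_hits(fwd, rev) == [("q1", "s1")]

    def test_symmetry_under_role_swap(self):
        fwd = [_m("q1", "s1"), _m("q2", "s2"), _m("q2", "s1", evalue=1e-5)]
        rev = [_m("s1", "q1"), _m("s2", "q2")]
        ab = set(reciprocal_best_hits(fwd, rev))
        ba = {(s, q) for q, s in reciprocal_best_hits(rev, fwd)}
        assert ab == ba

    def test_exhaustive_pair_check_oracle(self):
        # brute force: every (q,s) where s is q's best and q is s's best
        fwd = [
            _m("q1", "s1", evalue=1e-30), _m("q1", "s2", evalue=1e-10),
            _m("q2", "s2", evalue=1e-40), _m("q3", "s1", evalue=1e-50),
        ]
        rev = [
            _m("s1", "q3", evalue=1e-50), _m("s1", "q1", evalue=1e-20),
            _m("s2", "q2", evalue=1e-35),
        ]
        def best(matches, q):
            cands = [m for m in matches if m.query_id == q]
            return min(cands, key=lambda m: (m.evalue, -m.bitscore, m.subject_id)).subject_id
        expected = {
            (q, best(fwd, q))
            for q in {"q1", "q2", "q3"}
            if best(rev, best(fwd, q)) == q
        }
        assert set(reciprocal_best_hits(fwd, rev)) == expected


class TestDeduplicateSingletons:
    def test_identical_subject_interval_collapsed(self):
        a = _m("sing1", "P1", sstart=10, send=50, align_len=120)
        b = _m("sing2", "P1", sstart=10, send=50, align_len=100)
        kept = deduplicate_singletons([a, b])
        assert [m.query_id for m in kept] == ["sing1"]

    def test_near_identical_intervals_both_kept(self):
        a = _m("sing1", "P1", sstart=10, send=50)
        b = _m("sing2", "P1", sstart=10, send=51)
        assert len(deduplicate_singletons([a, b])) == 2

    def test_single_record_unchanged(self):
        a = _m("sing1", "P1")
        assert deduplicate_singletons([a]) == [a]

    def test_contigs_never_removed(self):
        a = _m("contig1", "P1", sstart=10, send=50)
        b = _m("contig2", "P1", sstart=10, send=50)
        kept = deduplicate_singletons([a, b], contig_ids={"contig1", "contig2"})
        assert len(kept) == 2


class TestClassifyGeneSpace:
    def test_all_four_proteomes_is_conserved_four_way(self):
        hits = {ref: [_m("lcn1", f"{ref}_p")] for ref in genespace.PROTEOME_PRECEDENCE}
        evidence, venn = classify_gene_space(hits)
        assert evidence[0].classification == "conserved"
        assert venn[frozenset(genespace.PROTEOME_PRECEDENCE)] == 1

    def test_unigene_only_is_non_conserved(self):
        evidence, venn = classify_gene_space({"unigene": [_m("lcn1", "ug1")]})
        assert evidence[0].classification == "non_conserved"
        assert sum(venn.values()) == 0

    def test_planted_ortholog_design_recovered_exactly(self, default_chromosome):
        config, chromosome, truth = default_chromosome
        genes = [ref[4:] for _s, _e, ref, _sp in truth.gene_loci]
        specs = {
            "brachypodium": {g: (f"Bd_{g}", "1", 1000) for g in genes},
            "rice": {g: (f"Os_{g}", "3", 1000) for g in genes[:5]},
        }
        tables = synthio.emit_match_tables(truth, specs, seed=1)
        retained = {
            ref: genespace.filter_matches(
                pair["forward"], genespace.DEFAULT_PROFILES[ref]
            )
            for ref, pair in tables.items()
        }
        _evidence, venn = classify_gene_space(retained)
        assert venn[frozenset({"brachypodium", "rice"})] == 5
        assert venn[frozenset({"brachypodium"})] == len(genes) - 5

    def test_rbh_filter_removes_planted_decoy(self, default_chromosome):
        config, chromosome, truth = default_chromosome
        genes = [ref[4:] for _s, _e, ref, _sp in truth.gene_loci]
        specs = {"brachypodium": {g: (f"Bd_{g}", "1", 1000) for g in genes}}
        with_decoy = synthio.emit_match_tables(
            truth, specs, seed=1, decoys=[("brachypodium", genes[0], "Bd_decoy")]
        )["brachypodium"]
        pairs = reciprocal_best_hits(with_decoy["forward"], with_decoy["reverse"])
        assert (genes[0], "Bd_decoy") not in pairs
        # every non-decoy planted ortholog remains a reciprocal pair
        assert {(g, f"Bd_{g}") for g in genes[1:]} <= set(pairs)


class TestBuildGeneModels:
    def test_gap_fill_between_segments(self):
        segs = [
            MappedSegment("s1", "P1", 1, 50, "A" * 50),
            MappedSegment("s2", "P1", 101, 150, "C" * 50),
        ]
        (model,) = build_gene_models(segs, {"P1": 150})
        assert model.model_sequence == "A" * 50 + "n" * 50 + "C" * 50
        assert model.covered_len == 100
        assert not model.conflict

    def test_single_full_length_segment(self):
        segs = [MappedSegment("s1", "P1", 1, 10, "ACGTACGTAC")]
        (model,) = build_gene_models(segs, {"P1": 10})
        assert model.model_sequence == "ACGTACGTAC"

    def test_overlap_trimmed_with_conflict_flag(self):
        segs = [
            MappedSegment("long", "P1", 1, 60, "A" * 60),
            MappedSegment("short", "P1", 51, 80, "G" * 30),
        ]
        (model,) = build_gene_models(segs, {"P1": 100})
        # the longer segment wins positions 51-60; the shorter is trimmed
        assert model.model_sequence[:60] == "A" * 60
        assert model.model_sequence[60:80] == "G" * 20
        assert model.conflict  # trimmed region disagreed

    def test_agreeing_overlap_no_conflict(self):
        segs = [
            MappedSegment("a", "P1", 1, 60, "A" * 60),
            MappedSegment("b", "P1", 51, 80, "A" * 10 + "C" * 20),
        ]
        (model,) = build_gene_models(segs, {"P1": 100})
        assert not model.conflict

    def test_segment_beyond_reference_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            build_gene_models(
                [MappedSegment("s", "P1", 90, 120, "A" * 31)], {"P1": 100}
            )

    def test_source_bases_conserved(self):
        segs = [
            MappedSegment("s1", "P1", 1, 40, "A" * 40),
            MappedSegment("s2", "P1", 61, 100, "C" * 40),
        ]
        (model,) = build_gene_models(segs, {"P1": 100})
        non_gap = [b for b in model.model_sequence if b != "n"]
        assert sorted(non_gap) == sorted("A" * 40 + "C" * 40)

    def test_precedence_anchors_on_brachypodium(self):
        hits = {
            "rice": _m("lcn1", "Os_p"),
            "brachypodium": _m("lcn1", "Bd_p"),
        }
        ref_set, match = genespace.assign_reference(hits)
        assert ref_set == "brachypodium"

    def test_protein_coordinates_to_cds(self):
        assert protein_to_cds_interval(1, 10) == (1, 30)
        assert protein_to_cds_interval(5, 5) == (13, 15)


class TestExtrapolation:
    def test_survey_scale_genic_fraction(self):
        coding_len, fraction = genic_fraction(4_818, 2_000, 840e6)
        assert fraction == 1.15
        assert coding_len == pytest.approx(9.636e6)

    def test_zero_models(self):
        assert genic_fraction(0, 2_000, 840e6)[1] == 0.0

    def test_simple_fraction(self):
        assert genic_fraction(100, 1_000, 1e6)[1] == 10.0

    def test_genome_wide_estimate_exceeds_68800(self):
        _len, fraction = genic_fraction(4_818, 2_000, 840e6)
        assert genome_gene_estimate(fraction, 12e9, 2_000) >= 68_800

    def test_estimate_linear_in_genome_size(self):
        e1 = genome_gene_estimate(1.15, 12e9, 2_000)
        e2 = genome_gene_estimate(1.15, 24e9, 2_000)
        assert e2 == 2 * e1

    def test_degenerate_unit_case(self):
        assert genome_gene_estimate(100.0, 2_000, 2_000) == 1


def test_internal_mapper_reconstructs_planted_genes(default_chromosome):
    config, chromosome, truth = default_chromosome
    cds_by_id = {ref: chromosome[s - 1 : e] for s, e, ref, _sp in truth.gene_loci}
    # fragments covering each gene with a gap in the middle
    fragments = []
    for ref, seq in cds_by_id.items():
        third = len(seq) // 3
        fragments.append(ReadRecord(f"{ref}_f1", seq[:third]))
        fragments.append(ReadRecord(f"{ref}_f2", seq[2 * third :]))
    segments = genespace.map_sequences_to_cds(fragments, cds_by_id)
    models = build_gene_models(segments, {r: len(s) for r, s in cds_by_id.items()})
    assert len(models) == len(cds_by_id)
    for model in models:
        seq = cds_by_id[model.reference_protein_id]
        assert model.covered_len >= 2 * (len(seq) // 3)
        assert "n" in model.model_sequence
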