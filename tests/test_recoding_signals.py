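from __future__ import annotations

import numpy as np
import pytest

from _oracles import agp_oracle, slippery_mismatch_oracle
from conftest import random_rna
from victoriscan.genome_io import GenomeRecord, Interval
from victoriscan.recoding_signals import (
    find_agp_rich,
    junction_window,
    scan_facilitators,
    scan_slippery,
    scan_utr_motifs,
    slippery_mismatches,
)


class TestSlipperyConsensus:
    def test_perfect_heptamer(self):
        rec = GenomeRecord(id="x", sequence="AAAUUUA")
        (hit,) = scan_slippery(rec, Interval(1, 7), max_mismatch=0)
        assert hit.heptamer == "AAAUUUA"
        assert hit.mismatches == 0

    def test_near_consensus_slippery_like(self):
        # the study's slippery-like heptamer: position 3 violates X XX
        rec = GenomeRecord(id="x", sequence="CCAAAAU")
        (hit,) = scan_slippery(rec, Interval(1, 7), max_mismatch=1)
        assert hit.heptamer == "CCAAAAU"
        assert hit.mismatches == 1

    def test_mismatch_zero_iff_consensus(self):
        assert slippery_mismatches("GGGCCCA") == 0
        assert slippery_mismatches("GGGCCCG") == 0  # Z is unrestricted
        assert slippery_mismatches("GGACCCA") == 1
        assert slippery_mismatches("GAACCAA") == 2

    def test_base_class_restrictions_opt_in(self):
        # classical stricter pattern: restrict Z; GGGCCCG then costs 1
        assert slippery_mismatches("GGGCCCG", z_bases="ACU") == 1

    @pytest.mark.parametrize("seed", range(10))
    def test_mismatch_formula_matches_majority_oracle(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(200):
            h = random_rna(rng, 7)
            assert slippery_mismatches(h) == slippery_mismatch_oracle(h)

    def test_exhaustive_window_matches_oracle(self):
        rng = np.random.default_rng(7)
        seq = random_rna(rng, 200)
        rec = GenomeRecord(id="r", sequence=seq)
        for mm in (0, 1, 2):
            hits = scan_slippery(rec, Interval(1, 200), max_mismatch=mm)
            expected = sorted(
                (slippery_mismatch_oracle(seq[s : s + 7]), s + 1)
                for s in range(0, 194)
                if slippery_mismatch_oracle(seq[s : s + 7]) <= mm
            )
            got = [(h.mismatches, h.interval.start) for h in hits]
            assert got == expected

    def test_tolerance_monotonicity(self, paper_record, paper_layout):
        win = junction_window(paper_layout)
        strict = scan_slippery(paper_record, win, max_mismatch=0)
        loose = scan_slippery(paper_record, win, max_mismatch=1)
        as_tuples = lambda hits: {
            (h.interval, h.heptamer, h.mismatches) for h in hits
        }
        assert as_tuples(strict) <= as_tuples(loose)

    def test_window_too_short_errors(self, paper_record):
        with pytest.raises(ValueError, match="shorter than 7"):
            scan_slippery(paper_record, Interval(1, 6))

    def test_planted_hit_on_paper_genome(self, paper_record, paper_layout):
        hits = scan_slippery(
            paper_record, junction_window(paper_layout), max_mismatch=1,
            orf_frame_anchor=paper_layout.orf1.start,
        )
        planted = [h for h in hits if h.interval == Interval(2555, 2561)]
        assert len(planted) == 1
        assert planted[0].heptamer == "CCAAAAU"
        assert planted[0].mismatches == 1
        # heptamer nt 2-7 form two ORF1-frame codons -> start phase 2
        assert planted[0].phase_note == 2


class TestFacilitators:
    def test_uaaug_spanning_stop_is_frame_consistent(self):
        # ...GAU AAU GGC... with UAA as the in-phase stop triplet
        rec = GenomeRecord(id="x", sequence="GAUAAUGGC")
        stop = Interval(3, 5)  # the UAA triplet
        hits = scan_facilitators(rec, stop, window_nt=5)
        (hit,) = [h for h in hits if h.motif == "UAAUG"]
        assert hit.interval == Interval(3, 7)
        assert hit.stop_frame_consistent

    def test_auga_alone(self):
        rec = GenomeRecord(id="x", sequence="AUGAC")
        hits = scan_facilitators(rec, Interval(2, 4), window_nt=5)
        (hit,) = [h for h in hits if h.motif == "AUGA"]
        assert hit.interval == Interval(1, 4)

    def test_paper_genome_has_no_facilitators(self, paper_record, paper_layout, paper_signals):
        assert paper_signals.facilitators == ()
        assert (
            scan_facilitators(paper_record, paper_layout.orf1.stop_codon) == []
        )

    def test_out_of_phase_motif_flagged_inconsistent(self):
        rec = GenomeRecord(id="x", sequence="CGAUAAUGGCUAA")
        stop = Interval(11, 13)  # true stop; UAA at 4-6 is off-phase by 1
        hits = scan_facilitators(rec, stop, window_nt=10)
        uaaug = [h for h in hits if h.motif == "UAAUG"]
        assert uaaug and not uaaug[0].stop_frame_consistent


class TestUtrMotifs:
    def test_planted_motifs_and_distance(self, paper_record, paper_layout):
        hits = scan_utr_motifs(paper_record, paper_layout)
        by_id = {h.motif_id: h for h in hits}
        octamer = by_id["AGGGUUCC"]
        assert octamer.interval == Interval(204, 211)
        assert octamer.distance_to_orf1_start == 55
        extended = by_id["AGGGUUCCGUUGAUC"]
        assert extended.interval.contains(octamer.interval)

    def test_absent_motif_gives_empty(self, paper_record, paper_layout):
        assert scan_utr_motifs(paper_record, paper_layout, ["ACGUACGUAC"]) == []

    def test_hits_restricted_to_utr5(self, paper_record, paper_layout):
        for h in scan_utr_motifs(paper_record, paper_layout):
            assert paper_layout.utr5.contains(h.interval)


class TestCoordinateFidelity:
    def test_reextracted_sequences_match_stored(self, paper_record, paper_layout, paper_signals):
        for h in paper_signals.slippery:
            assert paper_record.subseq(h.interval) == h.heptamer
        for h in paper_signals.utr_motifs:
            assert paper_record.subseq(h.interval) == h.motif_id
        for h in paper_signals.facilitators:
            assert paper_record.subseq(h.interval) == h.motif


class TestAgpRich:
    def test_fully_rich_protein(self):
        (region,) = find_agp_rich("AAAAAGGGGG", window_aa=5, threshold=0.8)
        assert region.interval == Interval(1, 10)
        assert region.fraction == 1.0

    def test_all_leucine_empty(self):
        assert find_agp_rich("L" * 40, window_aa=5, threshold=0.5) == []

    def test_short_protein_warns_and_returns_empty(self):
        with pytest.warns(UserWarning, match="shorter than window"):
            assert find_agp_rich("AAG", window_aa=5, threshold=0.5) == []

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_sliding_window_oracle(self, seed):
        rng = np.random.default_rng(seed)
        protein = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=120))
        got = [
            (r.interval.start, r.interval.end, r.fraction)
            for r in find_agp_rich(protein, window_aa=10, threshold=0.6)
        ]
        expected = agp_oracle(protein, window=10, threshold=0.6)
        assert got == pytest.approx(expected)

    def test_planted_cp_tail_detected(self, paper_record, paper_layout, paper_truth):
        from victoriscan.protein_products import translate

        cp = translate(paper_record, paper_layout.orf1.coding_interval)
        regions = find_agp_rich(cp, window_aa=20, threshold=0.5)
        assert regions, "expected an Ala/Gly/Pro-rich C-terminal region"
        planted = paper_truth.agp_region_aa
        assert any(r.interval.overlaps(planted) for r in regions)
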