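from __future__ import annotations

import numpy as np
import pytest

from victoriscan.genome_io import Interval
from victoriscan.orf_annotator import annotate
from victoriscan.pmf_evidence import build_frame_index, map_peptides
from victoriscan.recoding_signals import (
    junction_window,
    scan_facilitators,
    scan_slippery,
    scan_utr_motifs,
)
from victoriscan.synthetic_data import (
    GenomeParams,
    generate_genome,
    make_pseudoknot_fixture,
    random_custom_params,
    simulate_pmf,
)


class TestGenerateGenome:
    def test_paper_layout_geometry(self, paper_record, paper_truth):
        assert paper_record.length == 5120
        assert paper_truth.utr5.length == 266
        assert paper_truth.orf1 == Interval(267, 2564)
        assert paper_truth.bridge == Interval(2565, 2886)
        assert paper_truth.orf2 == Interval(2887, 5043)
        assert paper_truth.utr3.length == 77

    def test_determinism(self):
        a, _ = generate_genome("paper_layout", seed=17)
        b, _ = generate_genome("paper_layout", seed=17)
        assert a.sequence == b.sequence

    def test_seeds_differ(self):
        a, _ = generate_genome("paper_layout", seed=1)
        b, _ = generate_genome("paper_layout", seed=2)
        assert a.sequence != b.sequence

    def test_annotation_closure(self, paper_record, paper_truth):
        """Re-annotating the generated genome reproduces every truth
        coordinate exactly (the backbone invariant of the generator)."""
        layout = annotate(paper_record)
        assert layout.utr5 == paper_truth.utr5
        assert layout.orf1.interval == paper_truth.orf1
        assert layout.bridge == paper_truth.bridge
        assert layout.orf2.interval == paper_truth.orf2
        assert layout.utr3 == paper_truth.utr3
        assert layout.orf1.frame == paper_truth.orf1_frame
        assert layout.orf2.frame == paper_truth.orf2_frame

    def test_infeasible_params_rejected(self):
        with pytest.raises(ValueError):
            GenomeParams(orf1_nt=100)  # not a multiple of 3
        with pytest.raises(ValueError):
            # motif would not fit inside the 5'UTR
            generate_genome(
                "custom",
                GenomeParams(utr5_len=20, utr_motif_start=15),
                seed=0,
            )

    def test_custom_facilitator_planted_and_found(self):
        params = GenomeParams(facilitator="UAAUG", peptide_anchor=None)
        record, truth = generate_genome("custom", params, seed=3)
        layout = truth.to_layout()
        hits = scan_facilitators(record, layout.orf1.stop_codon)
        assert len(hits) == 1
        assert hits[0].motif == "UAAUG"
        assert hits[0].interval == truth.facilitator_interval
        assert hits[0].stop_frame_consistent

    @pytest.mark.parametrize("seed", range(1, 101))
    def test_planted_signals_recovered_across_random_layouts(self, seed):
        """For 100 random custom layouts, the planted slippery heptamer,
        facilitator (when planted) and 5'UTR motif are each recovered by
        their scanners at the planted coordinates."""
        rng = np.random.default_rng([seed, 77])
        params = random_custom_params(rng)
        record, truth = generate_genome("custom", params, seed=seed)
        layout = truth.to_layout()

        slips = scan_slippery(record, junction_window(layout), max_mismatch=1)
        assert any(
            h.interval == truth.slippery_interval
            and h.heptamer == truth.slippery_heptamer
            for h in slips
        )
        motifs = scan_utr_motifs(record, layout)
        assert any(m.interval == truth.utr_motif_interval for m in motifs)
        facs = scan_facilitators(record, layout.orf1.stop_codon)
        if truth.facilitator is None:
            assert facs == []
        else:
            assert [f.interval for f in facs] == [truth.facilitator_interval]


class TestPlantedPseudoknot:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_bridge_cassette_detected_by_structure_search(self, seed):
        """A pseudoknot cassette planted in the bridge is detected at the
        planted coordinates when the whole bridge is searched (ranking
        against the 322-nt random background is not asserted)."""
        from victoriscan.rna_structure import pseudoknot_candidates

        params = GenomeParams(plant_pseudoknot=True, pseudoknot_arm=7)
        record, truth = generate_genome("custom", params, seed=seed)
        arms = truth.pseudoknot_arms
        assert arms is not None
        window = Interval(truth.bridge.start, truth.bridge.end)
        candidates = pseudoknot_candidates(record, window, min_pairs=4, max_span=80)

        def matches_planted(pk):
            found = {
                "stem1_arm5": pk.stem1.arm5,
                "stem1_arm3": pk.stem1.arm3,
                "stem2_arm5": pk.stem2.arm5,
                "stem2_arm3": pk.stem2.arm3,
            }
            return all(
                found[k].intersection(arms[k]) is not None
                and found[k].intersection(arms[k]).length >= 0.8 * arms[k].length
                for k in arms
            )

        assert any(matches_planted(pk) for pk in candidates)

    def test_cassette_must_fit_in_bridge(self):
        with pytest.raises(ValueError, match="does not fit"):
            GenomeParams(
                plant_pseudoknot=True, bridge_len=60,
                pseudoknot_offset=40, peptide_anchor=None,
            )


class TestSimulatePmf:
    def test_separate_peptides_map_to_generating_regions(
        self, paper_record, paper_truth, paper_layout, paper_index
    ):
        peptides, _ = simulate_pmf(
            paper_record, paper_truth, "separate", n_peptides=25, seed=2
        )
        matches, unmatched = map_peptides(peptides, paper_index, paper_layout)
        assert unmatched == []
        assert {m.region for m in matches} <= {"ORF1", "ORF2"}

    def test_zero_contamination_zero_unmatched(
        self, paper_record, paper_truth, paper_layout, paper_index
    ):
        peptides, _ = simulate_pmf(
            paper_record, paper_truth, "separate",
            n_peptides=20, seed=3, contamination_rate=0.0,
        )
        _, unmatched = map_peptides(peptides, paper_index, paper_layout)
        assert unmatched == []

    def test_contamination_injects_unmatchable_decoys(
        self, paper_record, paper_truth, paper_layout, paper_index
    ):
        peptides, pmf_truth = simulate_pmf(
            paper_record, paper_truth, "separate",
            n_peptides=20, seed=3, contamination_rate=0.2,
        )
        assert len(pmf_truth.decoys) == 4
        _, unmatched = map_peptides(peptides, paper_index, paper_layout)
        assert {p.sequence for p in unmatched} == set(pmf_truth.decoys)

    def test_fixed_seed_reproducible(self, paper_record, paper_truth):
        a, _ = simulate_pmf(paper_record, paper_truth, "separate", 30, seed=8)
        b, _ = simulate_pmf(paper_record, paper_truth, "separate", 30, seed=8)
        assert [p.sequence for p in a] == [p.sequence for p in b]

    def test_fusion_scenario_requires_open_bridge(self, paper_record, paper_truth):
        with pytest.raises(ValueError, match="bridge_frame1_open"):
            simulate_pmf(paper_record, paper_truth, "fusion", 10, seed=1)

    def test_fusion_scenario_band_is_chain_mass(self):
        params = GenomeParams(bridge_frame1_open=True)
        record, truth = generate_genome("custom", params, seed=6)
        peptides, pmf_truth = simulate_pmf(record, truth, "fusion", 25, seed=1)
        (chain,) = pmf_truth.true_products
        # chain mass must exceed both separate products together minus water
        assert pmf_truth.band_mass_da > 150_000
        assert all(len(p.sequence) >= 6 for p in peptides)


class TestPseudoknotFixture:
    def test_truth_arms_are_complementary(self):
        seq, truth = make_pseudoknot_fixture(seed=2)
        comp = {"A": "U", "U": "A", "G": "C", "C": "G"}
        for a5_key, a3_key in [
            ("stem1_arm5", "stem1_arm3"),
            ("stem2_arm5", "stem2_arm3"),
        ]:
            a5, a3 = truth[a5_key], truth[a3_key]
            s5 = seq[a5.start - 1 : a5.end]
            s3 = seq[a3.start - 1 : a3.end]
            assert s3 == "".join(comp[c] for c in reversed(s5))
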