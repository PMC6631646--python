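from __future__ import annotations

import numpy as np
import pytest

from conftest import random_rna
from victoriscan.genome_io import GenomeRecord, Interval
from victoriscan.pmf_evidence import (
    VERDICT_BRIDGE_EXTENDED,
    VERDICT_FUSION,
    VERDICT_INCONCLUSIVE,
    VERDICT_SEPARATE,
    Peptide,
    adjudicate,
    build_frame_index,
    digest,
    map_peptides,
    read_peptide_tsv,
    write_matches_tsv,
)
from victoriscan.protein_products import model_products, translate
from victoriscan.synthetic_data import simulate_pmf


class TestDigest:
    @pytest.mark.parametrize(
        "protein,expected",
        [
            ("MKRAPK", ["MK", "R", "APK"]),  # cleave after K2 and R3
            ("AAA", ["AAA"]),               # no site
            ("AKPA", ["AKPA"]),             # K before P suppressed
        ],
    )
    def test_rule_examples(self, protein, expected):
        assert [p.sequence for p in digest(protein)] == expected

    def test_missed_cleavages_concatenate_adjacent(self):
        got = [p.sequence for p in digest("MKRAPK", missed_cleavages=1)]
        assert got == ["MK", "MKR", "R", "RAPK", "APK"]

    def test_conservation_of_residues(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            protein = "".join(
                rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=int(rng.integers(5, 80)))
            )
            assert "".join(p.sequence for p in digest(protein)) == protein

    @pytest.mark.parametrize("missed", [0, 1, 2])
    def test_matches_pyteomics_rule_oracle(self, missed):
        parser = pytest.importorskip("pyteomics.parser")
        rng = np.random.default_rng(4)
        for _ in range(20):
            protein = "".join(
                rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=int(rng.integers(10, 120)))
            )
            mine = {p.sequence for p in digest(protein, missed_cleavages=missed)}
            theirs = parser.cleave(protein, r"[KR](?!P)", missed_cleavages=missed)
            assert mine == set(theirs)


class TestFrameIndex:
    def test_frame1_translation_and_backmap(self):
        rec = GenomeRecord(id="x", sequence="AUGGCA")
        idx = build_frame_index(rec)
        assert idx.frames[1] == "MA"
        assert idx.codon_interval(1, 2) == Interval(4, 6)

    def test_three_frames_by_default_six_with_reverse(self):
        rec = GenomeRecord(id="x", sequence="AUGGCAUCG")
        assert set(build_frame_index(rec).frames) == {1, 2, 3}
        assert set(build_frame_index(rec, include_reverse=True).frames) == {
            1, 2, 3, -1, -2, -3,
        }

    def test_stops_become_sentinel(self):
        rec = GenomeRecord(id="x", sequence="AUGUAAGCA")
        idx = build_frame_index(rec)
        assert idx.frames[1] == "M*A"

    @pytest.mark.parametrize("seed", range(5))
    def test_backmap_roundtrips_through_translate(self, seed):
        rng = np.random.default_rng(seed)
        rec = GenomeRecord(id="r", sequence=random_rna(rng, 120))
        idx = build_frame_index(rec)
        for frame, aa in idx.frames.items():
            for i, residue in enumerate(aa, start=1):
                codon_iv = idx.codon_interval(frame, i)
                back = translate(
                    rec, codon_iv, allow_internal_stop=True
                ) or "*"  # a lone stop codon translates to the sentinel
                assert back == residue


class TestMapPeptides:
    def test_unmatched_peptide_listed(self, paper_index, paper_layout):
        matches, unmatched = map_peptides(
            [Peptide("WWWWWWWWCCC")], paper_index, paper_layout
        )
        assert matches == [] and len(unmatched) == 1

    def test_bridge_peptide_printed_coordinates(self, paper_index, paper_layout):
        """The bridge peptide maps in frame 1 at map positions 2593-2622."""
        matches, _ = map_peptides(
            [Peptide("TASDLDLYLK")], paper_index, paper_layout
        )
        (m,) = matches
        assert m.frame == 1
        assert m.genome_interval == Interval(2593, 2622)
        assert m.region == "bridge"
        assert m.genome_interval.length == 3 * len(m.peptide.sequence)

    def test_multi_frame_placement_reported_twice(self):
        # MAW planted in frame 1 and frame 2
        seq = "AUGGCGUGG" + "U" + "AUGGCGUGG" + "UU"
        rec = GenomeRecord(id="m", sequence=seq)
        idx = build_frame_index(rec)
        matches, _ = map_peptides([Peptide("MAW")], idx)
        assert len(matches) == 2
        assert {m.frame for m in matches} == {1, 2}

    def test_coordinate_fidelity(self, paper_record, paper_truth, paper_index, paper_layout):
        peptides, _ = simulate_pmf(
            paper_record, paper_truth, "separate", n_peptides=40, seed=9
        )
        matches, unmatched = map_peptides(peptides, paper_index, paper_layout)
        assert unmatched == []
        for m in matches:
            back = translate(paper_record, m.genome_interval, allow_internal_stop=True)
            assert back == m.peptide.sequence

    def test_stop_sentinel_breaks_matches(self):
        rec = GenomeRecord(id="x", sequence="AUGGCGUAAUGGGCG")
        idx = build_frame_index(rec)
        matches, unmatched = map_peptides([Peptide("MAWA")], idx)
        assert matches == []


class TestAdjudicate:
    @pytest.fixture()
    def separate_setup(self, paper_record, paper_truth, paper_layout, paper_signals, paper_index):
        peptides, pmf_truth = simulate_pmf(
            paper_record, paper_truth, "separate", n_peptides=30, seed=5
        )
        matches, _ = map_peptides(peptides, paper_index, paper_layout)
        products = model_products(paper_record, paper_layout, paper_signals)
        return matches, pmf_truth, products

    def test_separate_scenario_verdict(self, separate_setup):
        matches, pmf_truth, products = separate_setup
        summary = adjudicate(matches, pmf_truth.band_mass_da, products)
        assert summary.verdict == VERDICT_SEPARATE
        assert "rule 1 fired" in summary.rationale

    def test_fusion_band_mass_gives_fusion_verdict(self, separate_setup, paper_record, paper_layout, paper_signals):
        matches, _, products = separate_setup
        fusion_mass = next(
            p.mass_da for p in products if p.strategy == "fusion_readthrough"
        )
        summary = adjudicate(matches, fusion_mass, products)
        assert summary.verdict == VERDICT_FUSION

    def test_orf1_only_peptides_inconclusive(self, paper_record, paper_layout, paper_signals, paper_index):
        cp = translate(paper_record, paper_layout.orf1.coding_interval)
        peptides = [
            p for p in digest(cp) if len(p.sequence) >= 6
        ][:10]
        matches, _ = map_peptides(peptides, paper_index, paper_layout)
        products = model_products(paper_record, paper_layout, paper_signals)
        summary = adjudicate(matches, 80_000.0, products)
        assert summary.verdict == VERDICT_INCONCLUSIVE

    def test_empty_matches_inconclusive_with_warning(self, separate_setup):
        _, pmf_truth, products = separate_setup
        summary = adjudicate([], pmf_truth.band_mass_da, products)
        assert summary.verdict == VERDICT_INCONCLUSIVE
        assert "warning" in summary.rationale

    def test_counts_are_per_region_and_frame(self, separate_setup):
        matches, pmf_truth, products = separate_setup
        summary = adjudicate(matches, pmf_truth.band_mass_da, products)
        assert sum(summary.counts.values()) == len(matches)
        assert any(k.startswith("ORF1/") for k in summary.counts)
        assert any(k.startswith("ORF2/") for k in summary.counts)


class TestPeptideTsv:
    def test_round_trip(self, tmp_path, paper_index, paper_layout):
        p = tmp_path / "peps.tsv"
        p.write_text("sequence\nTASDLDLYLK\nWWWWWWWWCC\n")
        peptides = read_peptide_tsv(p)
        assert [x.sequence for x in peptides] == ["TASDLDLYLK", "WWWWWWWWCC"]
        matches, unmatched = map_peptides(peptides, paper_index, paper_layout)
        out = tmp_path / "matches.tsv"
        write_matches_tsv(matches, unmatched, out)
        lines = out.read_text().splitlines()
        assert lines[1].split("\t") == [
            "TASDLDLYLK", "1", "2593", "2622", "bridge",
        ]
        assert lines[2].endswith("unmatched")

    def test_invalid_residue_cites_line(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("ABCDE1\n")
        with pytest.raises(ValueError, match="line 1"):
            read_peptide_tsv(p)
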