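import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from relict.alignment import CodonAlignment, ProteinAlignment
from relict.genetics import translate_codon
from relict.lesion_scan import (
    DEFAULT_PON1_CATALOG,
    SiteCatalog,
    compute_site_conservation,
    detect_coding_lesions,
    detect_critical_site_substitutions,
    map_reference_coordinates,
    scan_alignment,
)


def _toy_cds(codons: list[str]) -> str:
    return "".join(codons)


class TestCoordinateMapping:
    def test_gapless_alignment_identity(self):
        prot = ProteinAlignment({"ref": "MKTW", "a": "MQTW"}, ref_species="ref")
        mapping = map_reference_coordinates(prot)
        assert set(mapping) == {1, 2, 3, 4}
        assert mapping[2] == {"ref": "K", "a": "Q"}

    def test_gap_maps_to_explicit_gap_state(self):
        prot = ProteinAlignment({"ref": "MKT", "q": "M-T"}, ref_species="ref")
        mapping = map_reference_coordinates(prot)
        assert mapping[2]["q"] == "-"

    def test_reference_gaps_do_not_get_positions(self):
        # insertion in query: reference has a gap column
        prot = ProteinAlignment({"ref": "MK-T", "q": "MKQT"}, ref_species="ref")
        mapping = map_reference_coordinates(prot)
        assert len(mapping) == 3
        assert mapping[3] == {"ref": "T", "q": "T"}

    def test_missing_reference_rejected(self):
        prot = ProteinAlignment({"a": "MKT"})
        with pytest.raises(ValueError):
            map_reference_coordinates(prot, "nope")


class TestCodingLesions:
    @pytest.fixture()
    def toy(self):
        # 6 codons: ATG AAA TGC GGG CCC TAA (terminal stop)
        ref = _toy_cds(["ATG", "AAA", "TGC", "GGG", "CCC", "TAA"])
        return ref

    def test_identity_query_clean(self, toy):
        aln = CodonAlignment({"ref": toy, "q": toy}, ref_species="ref")
        assert detect_coding_lesions(aln) == []

    def test_premature_stop_at_definition_position(self):
        codons = ["ATG"] + ["AAA"] * 354
        ref = _toy_cds(codons)
        q = codons.copy()
        q[49] = "TAA"  # codon 50
        aln = CodonAlignment({"ref": ref, "q": _toy_cds(q)}, ref_species="ref")
        lesions = detect_coding_lesions(aln)
        assert [(l.kind, l.ref_position, l.detail) for l in lesions] == [
            ("premature_stop", 50, "TAA")
        ]

    def test_terminal_stop_is_not_a_lesion(self, toy):
        aln = CodonAlignment({"ref": toy, "q": toy}, ref_species="ref")
        assert detect_coding_lesions(aln) == []

    def test_two_nt_deletion_reports_codon_34(self):
        codons = ["ATG"] + ["AAA"] * 100
        ref = _toy_cds(codons)
        q = list(ref)
        # delete CDS nucleotides 100-101 (1-based) -> codon 34
        q[99] = "-"
        q[100] = "-"
        aln = CodonAlignment({"ref": ref, "q": "".join(q)}, ref_species="ref")
        lesions = detect_coding_lesions(aln)
        assert [(l.kind, l.ref_position) for l in lesions] == [("frameshift", 34)]
        assert "2 nt" in lesions[0].detail

    def test_in_frame_deletion_is_not_a_frameshift(self):
        codons = ["ATG"] + ["AAA"] * 20
        ref = _toy_cds(codons)
        q = list(ref)
        for i in range(30, 33):  # whole codon 11
            q[i] = "-"
        aln = CodonAlignment({"ref": ref, "q": "".join(q)}, ref_species="ref")
        assert detect_coding_lesions(aln) == []

    def test_compensating_gaps_still_two_frameshifts(self):
        codons = ["ATG"] + ["AAA"] * 20
        ref = _toy_cds(codons)
        q = list(ref)
        q[10] = "-"   # 1-nt gap
        q[40] = "-"   # another 1-nt gap; jointly frame-restoring
        aln = CodonAlignment({"ref": ref, "q": "".join(q)}, ref_species="ref")
        lesions = detect_coding_lesions(aln)
        assert [l.kind for l in lesions] == ["frameshift", "frameshift"]

    def test_frameshift_insertion_in_query(self):
        # reference has a 1-column gap; query has sequence there
        ref = "ATGAAA-TGCGGG"
        q = "ATGAAACTGCGGG"
        # pad to multiple of 3 aligned columns: 13 -> add 2 more ref codons
        ref += "AATAA"
        q += "AATAA"
        aln = CodonAlignment({"ref": ref, "q": q}, ref_species="ref")
        lesions = detect_coding_lesions(aln)
        assert [l.kind for l in lesions] == ["frameshift"]
        assert "insertion" in lesions[0].detail

    def test_internal_reference_stop_rejected(self):
        ref = _toy_cds(["ATG", "TAA", "AAA", "TGC"])
        aln = CodonAlignment({"ref": ref, "q": ref}, ref_species="ref")
        with pytest.raises(ValueError, match="internal stop"):
            detect_coding_lesions(aln)

    def test_synonymous_changes_do_not_alter_calls(self):
        codons = ["ATG"] + ["AAA"] * 60
        ref = _toy_cds(codons)
        q = codons.copy()
        q[30] = "TAA"  # lesion at codon 31
        q_syn = q.copy()
        q_syn[10] = "AAG"  # synonymous Lys codon elsewhere
        a1 = CodonAlignment({"ref": ref, "q": _toy_cds(q)}, ref_species="ref")
        a2 = CodonAlignment({"ref": ref, "q": _toy_cds(q_syn)}, ref_species="ref")
        calls1 = [(l.kind, l.ref_position) for l in detect_coding_lesions(a1)]
        calls2 = [(l.kind, l.ref_position) for l in detect_coding_lesions(a2)]
        assert calls1 == calls2 == [("premature_stop", 31)]


class TestCriticalSites:
    def test_default_catalog_is_the_ten_major_sites(self):
        positions = sorted(e.ref_position for e in DEFAULT_PON1_CATALOG)
        assert positions == [71, 117, 134, 155, 184, 192, 202, 222, 270, 304]
        by_pos = {e.ref_position: e.ref_residue for e in DEFAULT_PON1_CATALOG}
        assert by_pos[270] == "N" and by_pos[184] == "H" and by_pos[192] == "R"

    def _panel(self, n_res=320):
        ref = ["A"] * n_res
        for e in DEFAULT_PON1_CATALOG:
            ref[e.ref_position - 1] = e.ref_residue
        return "".join(ref)

    def test_matching_species_clean(self):
        ref = self._panel()
        prot = ProteinAlignment({"human": ref, "dog": ref}, ref_species="human")
        assert detect_critical_site_substitutions(prot) == []

    def test_sea_otter_like_substitution_at_calcium_site(self):
        ref = self._panel()
        otter = list(ref)
        otter[269] = "S"  # non-N at site 270
        prot = ProteinAlignment({"human": ref, "sea_otter": "".join(otter)}, ref_species="human")
        lesions = [l for l in detect_critical_site_substitutions(prot) if l.species == "sea_otter"]
        assert [(l.ref_position, l.detail) for l in lesions] == [(270, "S")]
        assert "calcium" in lesions[0].annotation

    def test_beaver_like_substitution_at_active_site(self):
        ref = self._panel()
        beaver = list(ref)
        beaver[183] = "Q"  # non-H at 184
        prot = ProteinAlignment({"human": ref, "beaver": "".join(beaver)}, ref_species="human")
        lesions = [l for l in detect_critical_site_substitutions(prot) if l.species == "beaver"]
        assert [(l.ref_position, l.detail) for l in lesions] == [(184, "Q")]

    def test_catalog_position_beyond_reference(self):
        prot = ProteinAlignment({"human": "MKT", "q": "MKT"}, ref_species="human")
        with pytest.raises(ValueError, match="beyond"):
            detect_critical_site_substitutions(prot, SiteCatalog.from_pairs([(10, "W")]))

    def test_deleted_site_reported_as_deleted(self):
        ref = self._panel()
        q = list(ref)
        q[269] = "-"
        prot = ProteinAlignment({"human": ref, "q": "".join(q)}, ref_species="human")
        lesions = [l for l in detect_critical_site_substitutions(prot) if l.species == "q"]
        assert [(l.ref_position, l.detail) for l in lesions] == [(270, "deleted")]

    def test_catalog_tsv_round_trip(self, tmp_path):
        path = tmp_path / "catalog.tsv"
        DEFAULT_PON1_CATALOG.write_tsv(path)
        back = SiteCatalog.read_tsv(path)
        assert back == DEFAULT_PON1_CATALOG


class TestConservation:
    def _prot(self, residues: list[str]):
        seqs = {f"s{i}": r for i, r in enumerate(residues)}
        seqs["ref"] = residues[0]
        return ProteinAlignment(seqs, ref_species="ref")

    def test_all_identical_is_one(self):
        prot = self._prot(["R"] * 5)
        assert compute_site_conservation(prot, 1, [f"s{i}" for i in range(5)]) == 1.0

    def test_three_of_four_sharing_consensus(self):
        prot = self._prot(["R", "R", "R", "K"])
        assert compute_site_conservation(prot, 1, ["s0", "s1", "s2", "s3"]) == pytest.approx(0.75)

    def test_terrestrial_panel_17_of_20(self):
        # R conserved in 85% of a 20-species terrestrial panel (site 192 style)
        residues = ["R"] * 17 + ["K", "Q", "H"]
        prot = self._prot(residues)
        group = [f"s{i}" for i in range(20)]
        assert compute_site_conservation(prot, 1, group) == pytest.approx(0.85)

    def test_empty_group_rejected(self):
        prot = self._prot(["R", "R"])
        with pytest.raises(ValueError):
            compute_site_conservation(prot, 1, [])

    def test_gaps_count_as_mismatching(self):
        prot = self._prot(["R", "R", "-", "-"])
        assert compute_site_conservation(prot, 1, ["s0", "s1", "s2", "s3"]) == pytest.approx(0.5)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.permutations(list(range(6))))
    def test_permutation_invariance(self, perm):
        residues = ["R", "R", "K", "R", "Q", "R"]
        prot = self._prot(residues)
        group = [f"s{i}" for i in range(6)]
        base = compute_site_conservation(prot, 1, group)
        assert compute_site_conservation(prot, 1, [group[i] for i in perm]) == base

    def test_monotone_as_mismatches_added(self):
        values = []
        for extra in range(4):
            residues = ["R"] * 5 + ["K"] * extra
            prot = self._prot(residues)
            group = [f"s{i}" for i in range(len(residues))]
            values.append(compute_site_conservation(prot, 1, group))
        assert values == sorted(values, reverse=True)


class TestSpliceSites:
    # two exons 1..9 and 20..28 with a canonical GT..AG intron between
    GOOD = "ATGAAAGGG" + "GT" + "CCCCCC" + "AG" + "A" + "AAATTTGGG" + "AA"
    EXONS = [(1, 9), (20, 28)]

    def test_canonical_intron_clean(self):
        from relict.lesion_scan import detect_splice_disruptions

        assert detect_splice_disruptions({"sp": self.GOOD}, self.EXONS) == []

    def test_mutated_donor_detected(self):
        from relict.lesion_scan import detect_splice_disruptions

        bad = self.GOOD[:9] + "AT" + self.GOOD[11:]
        lesions = detect_splice_disruptions({"sp": bad}, self.EXONS)
        assert [(l.kind, l.ref_position) for l in lesions] == [("splice_disruption", 1)]
        assert "donor" in lesions[0].detail

    def test_mutated_acceptor_detected(self):
        from relict.lesion_scan import detect_splice_disruptions

        bad = self.GOOD[:17] + "AC" + self.GOOD[19:]
        lesions = detect_splice_disruptions({"sp": bad}, self.EXONS)
        assert [l.detail for l in lesions] == ["acceptor AC"]

    def test_reference_species_not_checked(self):
        from relict.lesion_scan import detect_splice_disruptions

        bad = self.GOOD[:9] + "AT" + self.GOOD[11:]
        assert detect_splice_disruptions({"ref": bad}, self.EXONS, ref_species="ref") == []

    def test_overlapping_exons_rejected(self):
        from relict.lesion_scan import detect_splice_disruptions

        with pytest.raises(ValueError):
            detect_splice_disruptions({"sp": self.GOOD}, [(1, 9), (5, 12)])


class TestScanIntegration:
    def test_summary_flags_consistent_with_lists(self):
        codons = ["ATG"] + ["AAA"] * 99
        ref = "".join(codons)
        q = codons.copy()
        q[20] = "TGA"
        aln = CodonAlignment({"ref": ref, "q": "".join(q), "clean": ref}, ref_species="ref")
        catalog = SiteCatalog.from_pairs([(5, translate_codon("AAA"))])
        report = scan_alignment(aln, catalog)
        summary = report.summary()
        assert summary["q"]["any_lesion"] is True
        assert summary["clean"]["any_lesion"] is False
        assert summary["clean"]["any_critical_sub"] is False
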