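"""Cleavage-site scanning, mature-peptide excision and PTM annotation."""

import pytest

from npevo.family_rules import (
    FAMILY_IDS,
    REFERENCE_PEPTIDES,
    CleavageMotif,
    load_family_rules,
    rule_for,
)
from npevo.prohormone_processing import (
    DegeneratePeptideError,
    PeptideNotFoundError,
    Precursor,
    annotate_ptms,
    build_reference_precursor,
    excise_mature_peptide,
    process_precursor,
    read_precursor_fasta,
    scan_cleavage_sites,
    write_precursor_fasta,
)


def _prec(residues, signal_end=0, **kw):
    return Precursor(id="t", residues=residues, signal_end=signal_end, **kw)


class TestScan:
    @pytest.mark.parametrize(
        "residues,motifs,expected",
        [
            ("AAKRAA", {"KR"}, [(2, 4, "KR")]),
            # longest-match precedence at a locus
            ("AARKRAA", {"KR", "RKR"}, [(2, 5, "RKR")]),
            ("AADEAA", {"KR"}, []),
            # non-overlapping, left to right
            ("KRKR", {"KR"}, [(0, 2, "KR"), (2, 4, "KR")]),
        ],
    )
    def test_matches(self, residues, motifs, expected):
        sites = scan_cleavage_sites(_prec(residues), motifs)
        assert [(s.start, s.end, s.motif) for s in sites] == expected

    def test_sites_inside_signal_peptide_excluded(self):
        sites = scan_cleavage_sites(_prec("KRAAKRAA", signal_end=4), {"KR"})
        assert [(s.start, s.end) for s in sites] == [(4, 6)]

    def test_site_residues_equal_motif(self):
        prec = _prec("AAKKRAA")
        for site in scan_cleavage_sites(prec, {"KKR", "KR"}):
            assert prec.residues[site.start : site.end] == site.motif


class TestExcision:
    def test_ccap_toy_precursor(self):
        residues = (
            "M" + "A" * 19            # 20-residue synthetic signal
            + "S" * 25                 # propeptide
            + "KR" + "PFCNAFTGC" + "G" + "KKR" + "ADDE"
        )
        prec = _prec(residues, signal_end=20, family_id="CCAP")
        pep = process_precursor(prec, rule_for("CCAP"))
        assert pep.core == "PFCNAFTGC"
        assert pep.amidated
        assert prec.residues[pep.start : pep.end] == pep.core

    def test_ctdh_core_is_31_residues(self):
        core = "GLDLGLSRGFSGSQAAKHLMGLAAANYAGGP"
        residues = "M" + "A" * 19 + "TTTT" + "KR" + core + "G" + "RRRR" + "SEE"
        pep = process_precursor(_prec(residues, 20, family_id="CT-DH"))
        assert pep.core == core
        assert len(pep.core) == 31

    def test_astcc_runs_to_precursor_end(self):
        core = "GQQKGRVYWRCYFNAVTCF"
        residues = "M" + "A" * 19 + "DDDD" + "RR" + core
        pep = excise_mature_peptide(_prec(residues, 20), rule_for("AST-CC"))
        assert pep.core == core
        assert pep.c_site.motif == "precursor_end"
        assert pep.end == len(residues)

    def test_no_candidate_segment_raises_with_flank_diagnostic(self):
        residues = "M" + "A" * 30
        with pytest.raises(PeptideNotFoundError, match="C-flank"):
            excise_mature_peptide(_prec(residues, 20), rule_for("proctolin"))

    def test_degenerate_segment_raises(self):
        residues = "M" + "A" * 19 + "NL" + "R" + "PPP"
        with pytest.raises(DegeneratePeptideError):
            excise_mature_peptide(_prec(residues, 20), rule_for("proctolin"))

    def test_excision_is_deterministic(self):
        prec, _ = build_reference_precursor("SIFamide")
        a = process_precursor(prec)
        b = process_precursor(prec)
        assert a == b

    def test_in_core_basic_residue_does_not_truncate(self):
        # AST-CCC's Lys4 matches the monobasic-K C-flank but lacks the Gly donor
        pep = process_precursor(*_ref("AST-CCC"))
        assert pep.core == "SYWKQCAFNAVSCF"

    def test_crfdh_without_n_flank_is_low_confidence(self):
        # earwig-style precursor missing the N-flank KR
        core = "PSLSIVNQTDVLRQSLLLEQARSAMR"
        residues = "M" + "A" * 19 + core + "G" + "RKR" + "SEE"
        pep = excise_mature_peptide(_prec(residues, 20), rule_for("CRF-DH"))
        assert pep.low_confidence
        assert pep.core == core


def _ref(family):
    prec, _ = build_reference_precursor(family)
    return prec, rule_for(family)


class TestPTMs:
    def test_gly_before_c_flank_marks_amidation(self):
        residues = "M" + "A" * 19 + "NPFLY" + "G" + "KR" + "SD"
        prec = _prec(residues, 20)
        pep = annotate_ptms(
            excise_mature_peptide(prec, rule_for("SIFamide")), prec, rule_for("SIFamide")
        )
        assert pep.amidated
        assert pep.core == "NPFLY"

    def test_corazonin_gln_converts_to_pglu(self):
        pep = process_precursor(*_ref("corazonin"))
        assert pep.core == "QTFQYSRGWTN"
        assert pep.pglu and pep.amidated

    def test_proctolin_has_no_amidation_site(self):
        pep = process_precursor(*_ref("proctolin"))
        assert pep.core == "RYLPT"
        assert not pep.amidated and not pep.pglu

    def test_missing_gly_in_amidated_family_warns_not_errors(self):
        residues = "M" + "A" * 19 + "NPFLY" + "KR" + "SD"
        prec = _prec(residues, 20)
        pep = process_precursor(prec, rule_for("SIFamide"))
        assert not pep.amidated
        assert "amide signal missing" in pep.warnings


class TestGoldenTable:
    """Each family's default rule recovers its printed reference peptide."""

    @pytest.mark.parametrize("family", FAMILY_IDS)
    def test_reference_precursor_roundtrip(self, family):
        prec, expected = build_reference_precursor(family)
        pep = process_precursor(prec)
        assert pep.core == expected
        ref = REFERENCE_PEPTIDES[family]
        assert prec.residues[pep.start : pep.end] == expected
        if ref.complete:
            assert not any(c in pep.core for c in "X?")

    def test_unresolved_core_only_in_incomplete_precursors(self):
        for family in FAMILY_IDS:
            prec, _ = build_reference_precursor(family)
            pep = process_precursor(prec)
            if any(c in pep.core for c in "X?"):
                assert not prec.complete


class TestIO:
    def test_fasta_header_dialect_roundtrip(self, tmp_path):
        prec, _ = build_reference_precursor("MS")
        path = tmp_path / "ms.fasta"
        write_precursor_fasta([prec], path)
        (back,) = read_precursor_fasta(path)
        assert back == prec

    def test_illegal_residue_rejected(self):
        with pytest.raises(ValueError, match="position 2"):
            _prec("AAZAA")
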