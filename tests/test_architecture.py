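import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ecckit.architecture import (
    KYTE_DOOLITTLE,
    ChargedMotif,
    annotate_ecc,
    assign_heptad_register,
    detect_acylation,
    extract_ccvx,
    find_cc_end,
    find_edvid,
    find_ploop,
    find_polar_stretch,
    find_preploop,
    hydropathy_profile,
    locate_charged_motif,
    predict_helix_blocks,
)
from ecckit.seqio import SequenceRecord

AA = "ACDEFGHIKLMNPQRSTVWY"


def rec(seq, rid="x"):
    return SequenceRecord(id=rid, residues=seq)


class TestHydropathy:
    @pytest.mark.parametrize(
        "seq,expected",
        [("VVV", [4.2]), ("GGG", [-0.4])],
    )
    def test_single_window_lookup(self, seq, expected):
        prof = hydropathy_profile(rec(seq), window=3)
        assert prof.values == pytest.approx(expected)

    def test_length_contract(self):
        prof = hydropathy_profile(rec("MGGCSAKLVD"), window=3)
        assert len(prof.values) == 10 - 2

    def test_bad_windows(self):
        with pytest.raises(ValueError):
            hydropathy_profile(rec("MG"), window=3)
        with pytest.raises(ValueError):
            hydropathy_profile(rec("MGCA"), window=2)

    @settings(max_examples=50, deadline=None)
    @given(
        st.text(alphabet=AA, min_size=3, max_size=80),
        st.sampled_from([3, 5, 7]),
    )
    def test_matches_brute_force_window_mean(self, seq, window):
        if window > len(seq):
            return
        prof = hydropathy_profile(rec(seq), window=window)
        expected = [
            sum(KYTE_DOOLITTLE[aa] for aa in seq[i : i + window]) / window
            for i in range(len(seq) - window + 1)
        ]
        assert prof.values == pytest.approx(expected)


class TestHelixPrediction:
    def test_poly_ala_block_detected(self):
        seq = "P" * 10 + "A" * 30 + "P" * 10
        spans = predict_helix_blocks(rec(seq))
        assert len(spans) == 1
        assert abs(spans[0].start - 11) <= 2 and abs(spans[0].end - 40) <= 2

    def test_all_proline_has_no_helix(self):
        assert predict_helix_blocks(rec("P" * 40)) == []

    def test_user_track_overrides_heuristic(self):
        seq = "P" * 30
        track = [5 <= i + 1 <= 20 for i in range(30)]
        spans = predict_helix_blocks(rec(seq), tracks=track)
        assert [(s.start, s.end) for s in spans] == [(5, 20)]


class TestHeptadRegister:
    def _oracle_frame(self, seg):
        best, best_count = 0, -1
        for frame in range(7):
            c = sum(
                1
                for i, aa in enumerate(seg)
                if aa in "LIV" and (i - frame) % 7 in (0, 3)
            )
            if c > best_count:
                best, best_count = frame, c
        return best

    def test_planted_hydrophobics_land_on_a_d(self):
        seq = "LAAIAAA" * 2
        spans = predict_helix_blocks(rec(seq), tracks=[True] * 14)
        register = assign_heptad_register(rec(seq), spans)
        for i, aa in enumerate(seq):
            if aa in "LI":
                assert register[i] in "ad"

    def test_no_hydrophobics_tie_breaks_to_frame_zero(self):
        seq = "A" * 14
        spans = predict_helix_blocks(rec(seq), tracks=[True] * 14)
        register = assign_heptad_register(rec(seq), spans)
        assert register == "abcdefg" * 2

    def test_outside_helices_is_dots(self):
        seq = "LAAIAAA" * 2 + "PPPP"
        spans = predict_helix_blocks(rec(seq), tracks=[True] * 14 + [False] * 4)
        register = assign_heptad_register(rec(seq), spans)
        assert register[14:] == "...."

    @settings(max_examples=50, deadline=None)
    @given(st.text(alphabet=AA, min_size=8, max_size=40))
    def test_frame_matches_exhaustive_search(self, seg):
        spans = predict_helix_blocks(rec(seg), tracks=[True] * len(seg))
        register = assign_heptad_register(rec(seg), spans)
        frame = self._oracle_frame(seg)
        assert register[0] == "abcdefg"[(0 - frame) % 7]


class TestMotifs:
    def test_edvid_exact_hit(self):
        hit = find_edvid(rec("AAEDVIDAA"))
        assert (hit.start, hit.end, hit.mismatches) == (3, 7, 0)
        assert hit.end - hit.start + 1 == 5

    def test_edvid_mismatch_handling(self):
        assert find_edvid(rec("AAEDVIEAA")) is None
        hit = find_edvid(rec("AAEDVIEAA"), max_mismatch=1)
        assert hit.mismatches == 1

    def test_polar_stretch_threshold(self):
        edvid = find_edvid(rec("SSTTNNQQDD" + "EDVID"))
        hit = find_polar_stretch(rec("SSTTNNQQDD" + "EDVID"), edvid)
        assert (hit.start, hit.end) == (1, 10)
        seq = "LLLLLLLLLL" + "EDVID"
        assert find_polar_stretch(rec(seq), find_edvid(rec(seq))) is None
        # exactly 8 polar of 10 is a hit at the default threshold
        seq = "SSTTNNQQLL" + "EDVID"
        assert find_polar_stretch(rec(seq), find_edvid(rec(seq))) is not None
        seq = "SSTTNNQLLL" + "EDVID"
        assert find_polar_stretch(rec(seq), find_edvid(rec(seq))) is None

    def test_polar_stretch_needs_10_upstream_residues(self):
        seq = "SSTT" + "EDVID"
        assert find_polar_stretch(rec(seq), find_edvid(rec(seq))) is None

    @pytest.mark.parametrize(
        "seq,found",
        [
            ("VGAAAAAAAAIAAAL", True),
            ("IGAAAAAAAALAAAL", True),
            ("VGAAAAAAAAAAAAL", False),
        ],
    )
    def test_preploop_pattern(self, seq, found):
        hit = find_preploop(rec(seq))
        if found:
            assert hit.start == 1 and hit.end == 15
        else:
            assert hit is None

    def test_ploop_canonical_walker_a(self):
        hit = find_ploop(rec("AAAGMGGLGKTTAA"))
        assert hit.matched_text == "GMGGLGKT"
        assert hit.start == 4

    def test_ploop_absent(self):
        assert find_ploop(rec("AAAAAAAA")) is None

    def test_ploop_leftmost_after_offset(self):
        seq = "GMGGLGKTT" + "AAA" + "GMGGLGKTT"
        assert find_ploop(rec(seq)).start == 1
        assert find_ploop(rec(seq), after=2).start == 13


class TestChargedMotif:
    def test_all_charged_window(self):
        seq = "A" * 88 + "EEDKRDEKE" + "NA" + "VG" + "A" * 20
        cm = locate_charged_motif(rec(seq), vg_position=100)
        assert (cm.start, cm.end) == (89, 97)
        assert cm.charged_fraction == 1.0
        assert (cm.n_acidic, cm.n_basic) == (6, 3)

    def test_uncharged_window(self):
        seq = "A" * 120
        cm = locate_charged_motif(rec(seq), vg_position=100)
        assert cm.charged_fraction == 0.0

    def test_window_always_9_residues(self):
        cm = locate_charged_motif(rec("A" * 50), vg_position=20)
        assert cm.end - cm.start + 1 == 9

    def test_boundary_error_near_n_terminus(self):
        with pytest.raises(ValueError, match="upstream"):
            locate_charged_motif(rec("A" * 50), vg_position=10)


class TestCcEndAndCcvx:
    def test_cc_end_is_last_a_d_hydrophobic(self):
        seq = "LAAIAAALAAIAAA"
        spans = predict_helix_blocks(rec(seq), tracks=[True] * len(seq))
        register = assign_heptad_register(rec(seq), spans)
        pos = find_cc_end(rec(seq), register, spans)
        assert pos == 11  # the last I on a d position
        assert pos <= spans[-1].end

    def test_cc_end_absent_without_hydrophobics(self):
        seq = "A" * 14
        spans = predict_helix_blocks(rec(seq), tracks=[True] * 14)
        register = assign_heptad_register(rec(seq), spans)
        assert find_cc_end(rec(seq), register, spans) is None

    def test_ccvx_arithmetic_and_canonical_flag(self):
        seq = "A" * 200
        charged = ChargedMotif(start=138, end=146, n_acidic=0, n_basic=0, charged_fraction=0.0)
        assert extract_ccvx(rec(seq), 120, charged) == (121, 137, True)
        wide = ChargedMotif(start=160, end=168, n_acidic=0, n_basic=0, charged_fraction=0.0)
        s, e, canonical = extract_ccvx(rec(seq), 120, wide)
        assert (e - s + 1, canonical) == (39, False)
        with pytest.raises(ValueError):
            extract_ccvx(rec(seq), 140, charged)


class TestAcylation:
    @pytest.mark.parametrize(
        "seq,myr,palm",
        [("MGGCS", True, True), ("MAGCS", False, True), ("MGGAS", True, False)],
    )
    def test_flags(self, seq, myr, palm):
        flags = detect_acylation(rec(seq))
        assert flags == {"myristoylation": myr, "palmitoylation": palm}


class TestAnnotateEcc:
    def test_all_proline_yields_bare_annotation(self):
        ann = annotate_ecc(rec("P" * 60))
        assert ann.helices == []
        assert ann.cc_end is None and ann.ccvx is None
        assert ann.ecc_boundary == 60  # no P-loop: boundary falls at the end

    def test_feature_order_invariant_on_panel(self, canonical_panel):
        records, _ = canonical_panel
        for r in records:
            annotate_ecc(r).check_feature_order()  # raises on violation

    def test_deleting_edvid_only_affects_edvid(self, group_d_fixture):
        record, truth, ann = group_d_fixture
        s, e = truth["edvid"]
        mutated = record.residues[: s - 1] + "AAAAA" + record.residues[e:]
        ann2 = annotate_ecc(rec(mutated, "noEDVID"))
        assert ann2.motif("EDVID") is None
        assert ann2.motif("preploop").start == ann.motif("preploop").start
        assert ann2.cc_end == ann.cc_end
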