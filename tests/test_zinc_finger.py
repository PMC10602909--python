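import random

import pytest

from pbscreen.seq_core import protein, revcomp
from pbscreen.pbs_catalog import PBSMotif
from pbscreen.zinc_finger import (
    RecognitionCode,
    ZincFinger,
    ZincFingerArray,
    extract_fingerprint,
    find_c2h2,
    fingerprint_similarity,
    fingerprints_to_tsv,
    motif_vs_pbs,
    predict_motif,
)
from pbscreen import synthetic_data as syn
from conftest import ZIF268_FINGER1
from oracles import enumerate_fingerprint_similarity, best_motif_match_fraction


def _array(*fingerprints):
    fingers = tuple(
        ZincFinger(index=i + 1, start=i * 30 + 1, end=i * 30 + 21,
                   motif_seq="C" * 21, fingerprint=fp)
        for i, fp in enumerate(fingerprints)
    )
    return ZincFingerArray(protein_id="toy", fingers=fingers)


class TestFindC2H2:
    def test_zif268_finger_detected_with_rder_fingerprint(self):
        zfa = find_c2h2(protein("zif268_f1", ZIF268_FINGER1))
        assert len(zfa) == 1
        assert zfa.fingers[0].fingerprint == "RDER"

    def test_poly_alanine_has_no_fingers(self):
        assert len(find_c2h2(protein("polyA", "A" * 120))) == 0

    def test_constructed_arrays_detected_exactly(self, code):
        rng = random.Random(13)
        fps = sorted(fp for fp, _ in code.items())
        for n in (1, 3, 8):
            chosen = [fps[rng.randrange(len(fps))] for _ in range(n)]
            seq = syn.build_zf_protein("p", chosen)
            zfa = find_c2h2(seq)
            assert len(zfa) == n
            assert list(zfa.fingerprints) == chosen
            # spans are ascending and non-overlapping, and each motif is a
            # literal subsequence of the protein
            spans = [(f.start, f.end) for f in zfa.fingers]
            assert all(a[1] < b[0] for a, b in zip(spans, spans[1:]))
            for f in zfa.fingers:
                assert seq.residues[f.start - 1 : f.end] == f.motif_seq

    def test_fingerprint_residues_come_from_the_spacer(self):
        rng = random.Random(17)
        aas = "ADEFGIKLMNPQRSTVWY"
        for _ in range(200):
            spacer = "".join(rng.choice(aas) for _ in range(12))
            seq = protein("p", "GG" + "C" + "AB"[0] * 2 + "C" + spacer + "H" + "QRT" + "H")
            zfa = find_c2h2(seq)
            assert len(zfa) == 1
            fp = zfa.fingers[0].fingerprint
            assert fp == extract_fingerprint(spacer)
            assert all(r in spacer for r in fp)

    def test_all_alanine_spacer_gives_aaaa(self):
        assert extract_fingerprint("A" * 12) == "AAAA"

    def test_dna_input_rejected(self):
        from pbscreen.seq_core import dna
        with pytest.raises(ValueError):
            find_c2h2(dna("d", "ACGT"))


class TestFingerprintSimilarity:
    def test_identical_arrays_are_100(self):
        a = _array("RDER", "QSTN", "EETR")
        assert fingerprint_similarity(a, a) == 100.0

    def test_disjoint_residue_sets_are_0(self):
        a = _array("RRRR", "EEEE")
        b = _array("QQQQ", "TTTT")
        assert fingerprint_similarity(a, b) == 0.0

    def test_symmetry(self):
        a = _array("RDER", "QSTN")
        b = _array("RDEQ", "QSTN", "AAAA")
        assert fingerprint_similarity(a, b) == fingerprint_similarity(b, a)

    def test_extra_fingers_dilute_similarity(self):
        a = _array("RDER")
        b = _array("RDER", "QQQQ", "TTTT")
        assert fingerprint_similarity(a, b) == pytest.approx(100.0 * 4 / 12)

    def test_matches_exhaustive_monotone_matching(self):
        """DP over fingers equals brute force for all <=3-finger pairs."""
        rng = random.Random(23)
        alphabet = "RQET"  # reduced alphabet: collisions are common
        for _ in range(150):
            fa = ["".join(rng.choice(alphabet) for _ in range(4))
                  for _ in range(rng.randint(1, 3))]
            fb = ["".join(rng.choice(alphabet) for _ in range(4))
                  for _ in range(rng.randint(1, 3))]
            got = fingerprint_similarity(_array(*fa), _array(*fb))
            assert got == pytest.approx(enumerate_fingerprint_similarity(fa, fb))

    def test_empty_array_rejected(self):
        a = _array("RDER")
        empty = ZincFingerArray(protein_id="e", fingers=())
        with pytest.raises(ValueError):
            fingerprint_similarity(a, empty)


class TestRecognitionCode:
    def test_canonical_zif268_entry(self):
        assert RecognitionCode.canonical().lookup("RDER") == "GCG"

    def test_complete_code_inverts_every_triplet(self, code):
        for b1 in "ACGT":
            for b2 in "ACGT":
                for b3 in "ACGT":
                    tri = b1 + b2 + b3
                    assert code.lookup(code.fingerprint_for_triplet(tri)) == tri

    def test_tsv_round_trip(self, tmp_path, code):
        path = tmp_path / "code.tsv"
        code.save_tsv(path)
        back = RecognitionCode.load_tsv(path)
        assert dict(back.items()) == dict(code.items())


class TestPredictMotif:
    def test_single_known_finger_gives_its_triplet(self, code):
        motif = predict_motif(_array("RDER"), code)
        assert motif.consensus == "GCG"

    def test_unknown_fingerprints_emit_nnn_with_flag(self, code):
        motif = predict_motif(_array("WWWW", "YYYY"), code)
        assert motif.consensus == "NNNNNN"
        assert motif.all_unknown
        assert set(motif.unknown_fingers) == {1, 2}

    def test_triplets_emitted_in_reverse_finger_order(self, code):
        fp_tgg = code.fingerprint_for_triplet("TGG")
        fp_gca = code.fingerprint_for_triplet("GCA")
        motif = predict_motif(_array(fp_tgg, fp_gca), code)
        assert motif.consensus == "GCA" + "TGG"

    def test_planted_binder_round_trip(self, code, pro_motif):
        """Fingerprints inverted from a PBS predict that PBS exactly."""
        fps = syn.binder_fingerprints(pro_motif, code, window=(0, 9))
        zfa = find_c2h2(syn.build_zf_protein("binder", fps))
        motif = predict_motif(zfa, code)
        assert motif.consensus == pro_motif.consensus[:9]
        assert motif_vs_pbs(motif, pro_motif).fraction == 1.0

    def test_finger_subset_selection(self, code):
        fp = code.fingerprint_for_triplet("ACG")
        motif = predict_motif(_array("RDER", fp), code, fingers=[2])
        assert motif.consensus == "ACG"
        with pytest.raises(ValueError):
            predict_motif(_array("RDER"), code, fingers=[5])


class TestMotifVsPBS:
    def test_exact_prefix_match(self, pro_motif):
        m = motif_vs_pbs(pro_motif.consensus[:9], pro_motif)
        assert (m.offset, m.strand, m.fraction) == (0, "+", 1.0)

    def test_all_n_motif_is_flagged_zero(self, pro_motif):
        m = motif_vs_pbs("N" * 9, pro_motif)
        assert m.fraction == 0.0 and m.undefined

    def test_minus_strand_match_found(self, pro_motif):
        m = motif_vs_pbs(revcomp(pro_motif.consensus)[:9], pro_motif)
        assert m.strand == "-" and m.fraction == 1.0

    def test_matches_brute_force_scan(self, pro_motif):
        rng = random.Random(31)
        for _ in range(60):
            k = rng.choice([3, 6, 9, 12, 21])
            consensus = "".join(rng.choice("ACGTN") for _ in range(k))
            got = motif_vs_pbs(consensus, pro_motif).fraction
            want = best_motif_match_fraction(
                consensus, pro_motif.consensus, revcomp(pro_motif.consensus)
            )
            assert got == pytest.approx(want), consensus

    def test_strand_symmetry(self, code, pro_motif):
        """Comparing on '-' equals comparing the revcomp motif on '+'."""
        rng = random.Random(37)
        for _ in range(20):
            consensus = "".join(rng.choice("ACGT") for _ in range(9))
            direct = motif_vs_pbs(consensus, pro_motif).fraction
            flipped = motif_vs_pbs(revcomp(consensus), pro_motif).fraction
            assert direct == pytest.approx(flipped)


def test_fingerprint_tsv_export(tmp_path):
    zfa = find_c2h2(protein("zif268_f1", ZIF268_FINGER1))
    out = tmp_path / "fp.tsv"
    fingerprints_to_tsv([zfa], out)
    lines = out.read_text().splitlines()
    assert lines[0].startswith("protein_id")
    assert lines[1].split("\t")[-1] == "RDER"
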