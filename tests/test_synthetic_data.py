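import json
import math

import numpy as np
import pytest

from pbscreen.pbs_catalog import scan_pbs
from pbscreen.zinc_finger import find_c2h2, motif_vs_pbs, predict_motif
from pbscreen.ltr_dating import date_ltr_pairs
from pbscreen import synthetic_data as syn


class TestDeterminism:
    def test_identical_seeds_give_identical_genomes(self):
        a = syn.simulate_genome(9, n_ervs=3, genome_len=20_000)
        b = syn.simulate_genome(9, n_ervs=3, genome_len=20_000)
        assert a.genome.residues == b.genome.residues
        assert a.ervs == b.ervs
        c = syn.simulate_genome(10, n_ervs=3, genome_len=20_000)
        assert c.genome.residues != a.genome.residues

    def test_identical_seeds_give_identical_bundles(self):
        t1 = syn.simulate_all(4).truth_json()
        t2 = syn.simulate_all(4).truth_json()
        assert t1 == t2


class TestGenome:
    def test_age_zero_gives_identical_ltr_pair(self):
        sim = syn.simulate_genome(1, n_ervs=1, genome_len=5000, ages_myr=[0.0])
        p = sim.ltr_pairs()[0]
        assert p.ltr5.residues == p.ltr3.residues

    def test_mean_recovered_age_close_to_planted(self):
        """Across seeds, 10-Myr LTR pairs date to 10 +/- binomial error."""
        recovered = [
            date_ltr_pairs(
                syn.simulate_genome(
                    200 + s, n_ervs=1, genome_len=5000, ages_myr=[10.0]
                ).ltr_pairs()
            )[0].age_myr
            for s in range(50)
        ]
        assert abs(np.mean(recovered) - 10.0) < 1.5

    def test_planted_pbs_recovered_exactly_by_scanner(self, catalog):
        sim = syn.simulate_genome(3, n_ervs=4, genome_len=30_000, pbs_mismatches=1)
        hits = scan_pbs(sim.genome, catalog, max_mismatch=1)
        found = {(h.start, h.trna_id, h.mismatches) for h in hits}
        for e in sim.ervs:
            assert (e.pbs_start, e.pbs_type, 1) in found

    def test_pbs_mismatches_avoid_first_nine_nt(self, catalog, pro_motif):
        sim = syn.simulate_genome(6, n_ervs=5, genome_len=40_000, pbs_mismatches=3)
        for e in sim.ervs:
            assert e.pbs_seq[:9] == pro_motif.consensus[:9]
            diff = sum(1 for a, b in zip(e.pbs_seq, pro_motif.consensus) if a != b)
            assert diff == 3

    def test_infeasible_packing_rejected(self):
        with pytest.raises(ValueError):
            syn.simulate_genome(1, n_ervs=10, genome_len=10_000)

    def test_erv_layout_invariants(self):
        sim = syn.simulate_genome(12)
        for e in sim.ervs:
            assert e.ltr5_end - e.ltr5_start == e.ltr3_end - e.ltr3_start
            assert e.pbs_start == e.ltr5_end  # PBS immediately downstream
            assert e.pbs_end - e.pbs_start == 18
            assert sim.genome.residues[e.pbs_start : e.pbs_end] == e.pbs_seq
        starts = sorted((e.start, e.end) for e in sim.ervs)
        assert all(a[1] <= b[0] for a, b in zip(starts, starts[1:]))


class TestPanel:
    def test_binder_round_trip_matches_pbs_exactly(self, bundle):
        panel = bundle.panel
        binder = next(p for p in panel.proteins if p.id == panel.binder_id)
        motif = predict_motif(find_c2h2(binder), panel.code)
        assert motif_vs_pbs(motif, panel.pbs).fraction == 1.0

    def test_decoy_motifs_all_below_half(self, bundle):
        panel = bundle.panel
        for p in panel.proteins:
            if p.id == panel.binder_id:
                continue
            motif = predict_motif(find_c2h2(p), panel.code)
            assert motif_vs_pbs(motif, panel.pbs).fraction < 0.5, p.id

    def test_scanner_finds_exactly_the_constructed_fingers(self, bundle):
        panel = bundle.panel
        for p in panel.proteins:
            zfa = find_c2h2(p)
            assert zfa.fingerprints == panel.fingerprints[p.id], p.id


class TestPeaks:
    def test_binder_covers_most_pbs_and_decoys_near_expectation(self, bundle):
        from pbscreen.peak_overlap import count_overlaps

        pbs = bundle.genome_sim.pbs_truth
        n_pbs = len(pbs)
        sim = bundle.peak_sim
        binder_rep = count_overlaps(sim.peaks[bundle.panel.binder_id], pbs)
        assert binder_rep.n_overlapping_peaks >= math.ceil(0.8 * n_pbs)
        # decoy overlaps: n_peaks x coverage fraction, within 3 SD
        genome_len = len(bundle.genome_sim.genome)
        mean_width = 300
        p_hit = n_pbs * (mean_width + 18) / genome_len
        decoy_total = sum(
            count_overlaps(sim.peaks[d], pbs).n_overlapping_peaks
            for d in sim.peaks
            if d != bundle.panel.binder_id
        )
        n_decoy_peaks = sum(
            len(sim.peaks[d]) for d in sim.peaks if d != bundle.panel.binder_id
        )
        expect = n_decoy_peaks * p_hit
        sd = math.sqrt(n_decoy_peaks * p_hit * (1 - p_hit))
        assert abs(decoy_total - expect) <= 3 * sd + 1

    def test_empty_decoy_set_is_valid(self, bundle):
        sim = syn.simulate_peaks(
            1,
            binder_id="b",
            decoy_ids=[],
            pbs_intervals=bundle.genome_sim.pbs_truth,
            genome_len=len(bundle.genome_sim.genome),
        )
        assert set(sim.peaks) == {"b"}

    def test_peak_widths_and_scores_in_declared_ranges(self, bundle):
        sim = bundle.peak_sim
        for kzfp, peaks in sim.peaks.items():
            for p in peaks:
                assert 200 <= p.end - p.start <= 400
                hi = 1000
                lo = 600 if kzfp == bundle.panel.binder_id else 100
                assert lo <= p.score <= hi


class TestStandins:
    def test_znf506_standin_has_8_fingers_in_201_419(self, standins):
        info = standins["ZNF506_standin"]
        seq = info["sequence"]
        assert len(seq) == 419
        zfa = find_c2h2(seq)
        assert len(zfa) == info["n_fingers"] == 8
        lo, hi = info["zf_array_span"]
        assert all(lo <= f.start and f.end <= hi for f in zfa.fingers)

    def test_standins_are_deterministic(self, standins):
        again = syn.standin_reference_proteins()
        for k in standins:
            assert again[k]["sequence"].residues == standins[k]["sequence"].residues


class TestFileEmission:
    def test_simulate_all_writes_complete_file_set(self, tmp_path):
        bundle = syn.simulate_all(2, out_dir=tmp_path)
        expected = {
            "genome.fa",
            "trnas.fa",
            "kzfps.fa",
            "ervs.bed",
            "ltrs.bed",
            "pbs_truth.bed",
            "orthologs.tsv",
            "divergence_times.tsv",
            "recognition_code.tsv",
            "truth.json",
        }
        assert expected <= {p.name for p in tmp_path.iterdir()}
        assert len(list((tmp_path / "peaks").glob("*.bed"))) == 20
        truth = json.loads((tmp_path / "truth.json").read_text())
        assert truth["binder_id"] == bundle.panel.binder_id
        assert len(truth["ervs"]) == 8
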