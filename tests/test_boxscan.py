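"""PWM model, candidate scan, terminal stem, k-turn and classifier."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from snoguide import boxscan
from snoguide import synthetic_data as synth
from tests.conftest import expected_scan_coords, make_genes


class TestBoxModel:
    def test_consensus_box_d_score_closed_form(self, box_model):
        # 4 consensus positions at weight 0.91 over uniform background:
        # 4 * log2(0.91 / 0.25) = 7.456 bits
        score = boxscan.pwm_score(box_model.logodds_box_d, "CUGA")
        assert score == pytest.approx(4 * np.log2(0.91 / 0.25), abs=1e-9)

    def test_consensus_is_maximal(self, box_model):
        best = boxscan.pwm_score(box_model.logodds_box_d, "CUGA")
        for kmer in ("AUGA", "CUGU", "GGGG", "CCGA", "UUGA"):
            assert boxscan.pwm_score(box_model.logodds_box_d, kmer) < best

    def test_random_kmer_expected_score_negative(self, box_model):
        # expected log-odds of background-drawn k-mers is -KL < 0 (Jensen)
        rng = np.random.default_rng(0)
        kmers = ["".join(rng.choice(list("ACGU"), 4)) for _ in range(2000)]
        scores = [boxscan.pwm_score(box_model.logodds_box_d, k) for k in kmers]
        assert np.mean(scores) < 0

    def test_invalid_weight_rejected(self):
        with pytest.raises(ValueError):
            boxscan.build_box_model(consensus_weight=0.4)


class TestScan:
    def test_planted_gene_found_at_annotated_boxes(self, rrna, box_model):
        gene = synth.generate_snorna_gene((rrna, 500), seed=11, sno_id="g")
        genome = synth.assemble_genome([gene], seed=12)
        cands = boxscan.scan_candidates(genome, box_model)
        locus = genome.truth_loci[0]
        exp_c, exp_d = expected_scan_coords(genome, locus)
        at_boxes = [c for c in cands
                    if c.box_c_start == exp_c and c.box_d_start == exp_d
                    and c.strand == locus.strand]
        assert len(at_boxes) == 1
        cand = at_boxes[0]
        assert cand.start < locus.end and locus.start < cand.end
        assert cand.combined_box_score > 9
        assert cand.kturn_ok

    def test_roundtrip_all_usages_both_strands(self, rrna, box_model):
        for seed in range(5):
            genome = synth.assemble_genome(make_genes(rrna, seed), seed=seed)
            cands = boxscan.scan_candidates(genome, box_model)
            for locus in genome.truth_loci:
                exp_c, exp_d = expected_scan_coords(genome, locus)
                assert sum(c.box_c_start == exp_c and c.box_d_start == exp_d
                           and c.strand == locus.strand for c in cands) == 1

    def test_distance_filter_drops_out_of_window_pairs(self, box_model):
        # box C and box D separated by 105 nt: no candidate
        filler = "CCTCC" * 50
        genome = filler[:20] + "ATGATGA" + filler[:98] + "CTGA" + filler[:30]
        assert boxscan.scan_candidates(genome, box_model) == []
        # same boxes at distance 70: one candidate
        genome = filler[:20] + "ATGATGA" + filler[:63] + "CTGA" + filler[:30]
        cands = boxscan.scan_candidates(genome, box_model)
        assert any(c.strand == "+" and c.cd_distance == 70 for c in cands)

    def test_empty_genome_rejected(self, box_model):
        with pytest.raises(ValueError):
            boxscan.scan_candidates("", box_model)


class TestTerminalStem:
    def test_five_bp_stem_scores_two(self):
        #   5'-AAAAAGGGCC [boxC ... boxD] GGCCCAAAAA-3'
        # the GGGCC/GGCCC flanks form a 5 bp stem -> score 5 - 3 = 2
        seq = "AAAAAGGGCC" + "ATGATGA" + "T" * 59 + "CTGA" + "GGCCCAAAAA"
        assert boxscan.terminal_stem_score(seq, 10, 76) == 2

    def test_no_complementary_run_scores_zero(self):
        seq = "AAAAAAAAAA" + "ATGATGA" + "T" * 59 + "CTGA" + "AAAAAAAAAA"
        assert boxscan.terminal_stem_score(seq, 10, 76) == 0

    def test_absent_stem_does_not_disqualify(self, rrna, box_model):
        # a stemless planted gene must still clear the classifier with
        # expression evidence: the stem is never a prerequisite
        gene = synth.generate_snorna_gene((rrna, 500), stem_len=0, seed=13,
                                          sno_id="g")
        genome = synth.assemble_genome([gene], seed=14)
        cands = boxscan.scan_candidates(genome, box_model)
        locus = genome.truth_loci[0]
        exp_c, exp_d = expected_scan_coords(genome, locus)
        cand = next(c for c in cands if c.box_c_start == exp_c
                    and c.box_d_start == exp_d)
        score, bona = boxscan.total_classifier_score(cand, 15)
        assert bona


class TestKturn:
    @pytest.mark.parametrize("box_c, box_d, expected", [
        ("AUGAUGA", "CUGA", True),
        ("AUGAUGA", "CUCA", False),   # GA of box D destroyed
        ("GUGAUGA", "AUGA", True),    # AUGA variant keeps the GA
        ("AUCAUGA", "CUGA", False),   # GA of box C destroyed
    ])
    def test_ga_dinucleotides(self, box_c, box_d, expected):
        assert boxscan.kturn_check(box_c, box_d) is expected


class TestClassifier:
    def _candidate(self, box_c_score, box_d_score, ts=0):
        return boxscan.SnoCandidate(
            id="x", strand="+", box_c_start=0, box_d_start=70,
            box_c_score=box_c_score, box_d_score=box_d_score,
            start=0, end=74, ts_score=ts)

    def test_expression_flips_bona_fide(self):
        cand = self._candidate(8.0, 8.0)
        assert boxscan.total_classifier_score(cand, 15) == (31.0, True)
        assert boxscan.total_classifier_score(cand, -15) == (1.0, False)

    def test_gate_level_box_score_cannot_reach_threshold_unexpressed(self):
        # combined boxes at the gate (9) plus a maximal stem can never
        # reach 29 without the +15 expression term
        cand = self._candidate(4.5, 4.5, ts=7)
        score, bona = boxscan.total_classifier_score(cand, -15)
        assert score < 29 and not bona

    def test_unset_expression_rejected(self):
        with pytest.raises(ValueError):
            boxscan.total_classifier_score(self._candidate(8, 8), None)

    @given(st.floats(0, 15), st.floats(0, 15), st.integers(0, 7))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_each_component(self, c, d, ts):
        base, _ = boxscan.total_classifier_score(self._candidate(c, d, ts), 15)
        up_c, _ = boxscan.total_classifier_score(self._candidate(c + 1, d, ts), 15)
        up_ts, _ = boxscan.total_classifier_score(self._candidate(c, d, ts + 1), 15)
        assert up_c >= base and up_ts >= base


def test_scan_matches_bruteforce_on_short_sequence(rrna, box_model):
    """Exhaustive pair enumeration oracle on a <2 kb sequence."""
    gene = synth.generate_snorna_gene((rrna, 500), seed=21, sno_id="g")
    genome = synth.assemble_genome([gene], spacer=400, seed=22)
    seq = genome.sequence
    params = boxscan.ScanParams()
    got = {(c.strand, c.box_c_start, c.box_d_start)
           for c in boxscan.scan_candidates(seq, box_model, params)}
    expect = set()
    from snoguide.seqs import revcomp_dna
    for strand in "+-":
        scanned = seq if strand == "+" else revcomp_dna(seq)
        c_scores = boxscan.scan_pwm(scanned, box_model.logodds_box_c)
        d_scores = boxscan.scan_pwm(scanned, box_model.logodds_box_d)
        raw = [(c, d, c_scores[c] + d_scores[d])
               for c in range(len(c_scores)) for d in range(len(d_scores))
               if c_scores[c] > 0 and d_scores[d] > 0
               and params.min_cd_distance <= d - c <= params.max_cd_distance
               and c_scores[c] + d_scores[d] > params.min_box_score]
        by_c = {}
        for c, d, s in raw:
            if c not in by_c or (s, d) > (by_c[c][1], by_c[c][0]):
                by_c[c] = (d, s)
        by_d = {}
        for c, (d, s) in by_c.items():
            if d not in by_d or (s, -c) > (by_d[d][1], -by_d[d][0]):
                by_d[d] = (c, s)
        expect |= {(strand, c, d) for d, (c, _) in by_d.items()}
    assert got == expect
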