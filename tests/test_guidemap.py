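"""Box location, +5-rule duplex search, stacking model and CD/OR labels."""
import numpy as np
import pytest

from snoguide import guidemap, synthetic_data as synth
from snoguide.guidemap import (GuideParams, StackingModel, best_duplex,
                               locate_boxes)
from snoguide.ribomethseq import MethylationCall
from snoguide.seqs import is_gu, pairs, revcomp_rna


def _call(position, rrna_name="rRNA"):
    return MethylationCall(rrna_name, position, "N", 1.0, 0.0, "full")


def brute_force_best_duplex(sno, rna, position, box_start, register=5,
                            flank=10, min_len=7, max_mismatch=1,
                            model=StackingModel()):
    """Enumerate every ungapped antiparallel alignment satisfying the
    filters; independent of the implementation's windowed search."""
    a0 = box_start - register
    best = None
    for jl in range(-flank, 1):
        for jr in range(0, flank + 1):
            cols = range(jl, jr + 1)
            ok = True
            for j in cols:
                si, ri = a0 - j, position + j
                if not (0 <= si <= box_start - register + (register - 1)
                        and si < box_start and 1 <= ri <= len(rna)):
                    ok = False
                    break
            if not ok:
                continue
            status = [pairs(rna[position + j - 1], sno[a0 - j]) for j in cols]
            if not (status[0] and status[-1] and status[-jl]):
                continue
            mism = status.count(False)
            if mism > max_mismatch or len(status) < min_len:
                continue
            top = rna[position + jl - 1: position + jr]
            bottom = "".join(sno[a0 - j] for j in cols)
            mfe = model.duplex_energy(top, bottom, status)
            key = (-len(status), mfe, jl)
            if best is None or key < best[0]:
                best = (key, (len(status), mism, jl, jr))
    return None if best is None else best[1]


class TestLocateBoxes:
    def test_planted_offsets_recovered(self, rrna):
        for seed in range(10):
            usage = ("D", "Dprime", "both")[seed % 3]
            target = [(rrna, 300), (rrna, 800)] if usage == "both" else (rrna, 300)
            gene = synth.generate_snorna_gene(target, box_usage=usage,
                                              duplex_len=10, seed=seed, sno_id="g")
            found = locate_boxes(gene.sequence)
            assert found.box_c == gene.box_c_start
            assert found.box_d == gene.box_d_start
            if gene.box_dprime_start is not None:
                assert found.box_dprime == gene.box_dprime_start

    def test_missing_box_d_is_an_error(self):
        seq = "ATGATGA" + "CCTCC" * 12
        with pytest.raises(ValueError):
            locate_boxes(seq)

    def test_internal_cuga_reported_as_dprime(self):
        seq = ("CCGCC" + "AUGAUGA" + "CCUCC" * 3 + "CUGA" + "CCUCC" * 6 +
               "CUGA" + "CCGCC")
        found = locate_boxes(seq)
        assert found.box_dprime is not None
        assert seq[found.box_dprime:found.box_dprime + 4] == "CUGA"
        assert found.box_dprime < found.box_d


class TestBestDuplex:
    def test_planted_duplex_recovered_exactly(self, rrna):
        gene = synth.generate_snorna_gene((rrna, 500), duplex_len=10,
                                          seed=3, sno_id="g")
        hit = best_duplex(gene.sequence, rrna.sequence, 500, gene.box_d_start)
        assert hit is not None
        assert (hit.duplex_len, hit.n_mismatch) == (10, 0)

    def test_six_bp_complement_rejected(self):
        # antisense of only 6 nt: below the 7 bp duplex floor
        rna = "G" * 40 + "AAGGCAUCCAA" + "G" * 40
        anti = revcomp_rna("GCAUCC")        # pairs rRNA 44..49 -> 6 bp max
        sno = "CCGCC" + "AUGAUGA" + "C" * 40 + "G" + anti + "CUGA" + "C" * 10 + "GGCGG"
        box_d = sno.index("CUGA", 50)
        assert best_duplex(sno, rna, 45, box_d) is None

    def test_mismatch_budget_enforced(self):
        rna = "G" * 40 + "CAAGGCAUCCAAUC" + "G" * 40
        window = rna[40:52]                  # 12 nt target, positions 41..52
        anti = list(revcomp_rna(window))
        # anchor pairs position 45 (5th upstream of box D)
        sno_perfect = "CCGCC" + "AUGAUGA" + "C" * 38 + "UU" + "".join(anti) + "CUGA" + "GGCGG"
        box_d = len(sno_perfect) - 9
        hit = best_duplex(sno_perfect, rna, 45, box_d)
        assert hit is not None and hit.n_mismatch == 0 and hit.duplex_len >= 12
        # one internal mismatch: still accepted, flagged
        anti1 = anti.copy()
        anti1[3] = {"A": "C", "C": "A", "G": "A", "U": "C"}[anti1[3]]
        sno1 = "CCGCC" + "AUGAUGA" + "C" * 38 + "UU" + "".join(anti1) + "CUGA" + "GGCGG"
        hit1 = best_duplex(sno1, rna, 45, box_d)
        assert hit1 is not None and hit1.n_mismatch == 1
        # two internal mismatches: rejected (or shrinks below 7 bp)
        anti2 = anti1.copy()
        anti2[8] = {"A": "C", "C": "A", "G": "A", "U": "C"}[anti2[8]]
        sno2 = "CCGCC" + "AUGAUGA" + "C" * 38 + "UU" + "".join(anti2) + "CUGA" + "GGCGG"
        hit2 = best_duplex(sno2, rna, 45, box_d)
        assert hit2 is None or (hit2.n_mismatch <= 1 and hit2.duplex_len < 12)

    def test_register_anchoring(self, rrna):
        """The target nt sits opposite exactly the 5th nt upstream of box D."""
        gene = synth.generate_snorna_gene((rrna, 700), duplex_len=12,
                                          seed=8, sno_id="g")
        hit = best_duplex(gene.sequence, rrna.sequence, 700, gene.box_d_start)
        lo, hi = hit.rrna_interval
        assert lo <= 700 <= hi
        anchor_sno = gene.box_d_start - 5
        assert hit.sno_interval[0] <= anchor_sno < hit.sno_interval[1]
        # antiparallel register: rRNA position+j pairs snoRNA anchor-j
        j = 700 - lo
        assert hit.sno_interval[1] - 1 == anchor_sno + j

    def test_matches_bruteforce_on_random_instances(self, rrna):
        rng = np.random.default_rng(42)
        n_checked = 0
        for _ in range(1000):
            sno = "".join(rng.choice(list("ACGU"), size=60))
            box_d = 50
            position = int(rng.integers(11, rrna.length - 11))
            got = best_duplex(sno, rrna.sequence, position, box_d)
            expect = brute_force_best_duplex(sno, rrna.sequence, position, box_d)
            if expect is None:
                assert got is None
            else:
                assert got is not None
                assert (got.duplex_len, got.n_mismatch) == expect[:2]
                assert (got.rrna_interval[0] - position,
                        got.rrna_interval[1] - position) == expect[2:]
                n_checked += 1
        assert n_checked > 10     # sanity: hits do occur at random


class TestStackingModel:
    def test_wc_stacks_negative_initiation_positive(self):
        m = StackingModel()
        assert all(v < 0 for v in m.wc_stacks.values())
        assert m.initiation > 0

    def test_appending_wc_pair_never_raises_energy(self):
        m = StackingModel()
        rng = np.random.default_rng(1)
        wc = {"A": "U", "U": "A", "G": "C", "C": "G"}
        for _ in range(200):
            top = "".join(rng.choice(list("ACGU"), size=8))
            bottom = "".join(wc[b] for b in top)
            base = m.duplex_energy(top, bottom, [True] * 8)
            extra = str(rng.choice(list("ACGU")))
            longer = m.duplex_energy(top + extra, bottom + wc[extra],
                                     [True] * 9)
            assert longer <= base

    def test_gu_duplex_never_below_wc_version(self):
        m = StackingModel()
        rng = np.random.default_rng(2)
        for _ in range(200):
            top = "".join(rng.choice(list("ACGU"), size=9))
            wc = {"A": "U", "U": "A", "G": "C", "C": "G"}
            bottom = list(wc[b] for b in top)
            gu_bottom = bottom.copy()
            sites = [i for i, b in enumerate(top) if b == "G"]
            if not sites:
                continue
            for i in sites[:2]:
                gu_bottom[i] = "U"            # G-C -> G·U wobble
            e_wc = m.duplex_energy(top, "".join(bottom), [True] * 9)
            e_gu = m.duplex_energy(top, "".join(gu_bottom), [True] * 9)
            assert e_gu >= e_wc


class TestAssignGuides:
    def test_planted_cohort_fully_guided(self, rrna):
        genes, calls = [], []
        for i, (position, usage) in enumerate(
                [(200, "D"), (500, "Dprime"), (800, "D")]):
            genes.append(synth.generate_snorna_gene(
                (rrna, position), box_usage=usage, duplex_len=10,
                seed=60 + i, sno_id=f"g{i}"))
            calls.append(_call(position))
        snos = [(g.id, g.sequence) for g in genes]
        assignments, labels, unguided = guidemap.assign_guides(
            snos, calls, {rrna.name: rrna.sequence})
        assert unguided == []
        recovered = {(a.snorna_id, a.position, a.box_used) for a in assignments}
        planted = {(g.id, t.position, t.box) for g in genes for t in g.targets}
        assert planted <= recovered
        assert all(lbl.startswith("CD") for lbl in labels.values())

    def test_dual_box_gene_yields_both_assignments(self, rrna):
        gene = synth.generate_snorna_gene([(rrna, 400), (rrna, 900)],
                                          box_usage="both", duplex_len=10,
                                          seed=70, sno_id="dual")
        assignments, labels, unguided = guidemap.assign_guides(
            [("dual", gene.sequence)], [_call(400), _call(900)],
            {rrna.name: rrna.sequence})
        by_box = {(a.position, a.box_used) for a in assignments}
        assert (900, "D") in by_box and (400, "Dprime") in by_box
        assert labels["dual"] == "CD1"

    def test_scrambled_decoys_become_orphans(self, rrna):
        genes = [synth.generate_snorna_gene((rrna, 250 + 300 * i),
                                            duplex_len=10, seed=80 + i,
                                            sno_id=f"g{i}") for i in range(2)]
        rng = np.random.default_rng(5)
        decoys = []
        for i, base in enumerate(genes):
            seq = list(base.sequence)
            lo = base.box_d_start - 10
            anti = [seq[k] for k in range(lo, base.box_d_start)]
            rng.shuffle(anti)
            seq[lo:base.box_d_start] = anti    # scramble the antisense element
            decoys.append((f"decoy{i}", "".join(seq)))
        snos = [(g.id, g.sequence) for g in genes] + decoys
        calls = [_call(250), _call(550)]
        assignments, labels, unguided = guidemap.assign_guides(
            snos, calls, {rrna.name: rrna.sequence})
        orphans = {sid for sid, lbl in labels.items() if lbl.startswith("OR")}
        assert orphans == {"decoy0", "decoy1"}
        assert unguided == []

    def test_plus_six_register_used_only_as_fallback(self, rrna):
        # a gene planted for position p also satisfies the +6 register for
        # p+1; a call at p+1 alone must come back flagged register=6
        gene = synth.generate_snorna_gene((rrna, 600), duplex_len=12,
                                          seed=90, sno_id="g")
        assignments, _, unguided = guidemap.assign_guides(
            [("g", gene.sequence)], [_call(601)], {rrna.name: rrna.sequence})
        assert unguided == []
        assert {a.register for a in assignments} == {6}
        # with the +5 site called, the +5 assignment wins and no +6 is tried
        assignments5, _, _ = guidemap.assign_guides(
            [("g", gene.sequence)], [_call(600)], {rrna.name: rrna.sequence})
        assert {a.register for a in assignments5} == {5}

    def test_no_bulges_in_any_assignment(self, rrna):
        """Ungapped by construction: paired intervals have equal lengths."""
        genes = [synth.generate_snorna_gene((rrna, 300 + 250 * i),
                                            duplex_len=8 + i, seed=95 + i,
                                            sno_id=f"g{i}") for i in range(4)]
        snos = [(g.id, g.sequence) for g in genes]
        calls = [_call(300 + 250 * i) for i in range(4)]
        assignments, _, _ = guidemap.assign_guides(
            snos, calls, {rrna.name: rrna.sequence})
        for a in assignments:
            sno_span = a.sno_interval[1] - a.sno_interval[0]
            rrna_span = a.rrna_interval[1] - a.rrna_interval[0] + 1
            assert sno_span == rrna_span == a.duplex_len


class TestDuplexSummary:
    def _assignment(self, length, mfe=-10.0, box="D"):
        return guidemap.GuideAssignment("s", box, 5, "rRNA", 100, length,
                                        0, 0, mfe, (0, length), (95, 95 + length - 1))

    def test_single_duplex(self):
        s = guidemap.duplex_summary([self._assignment(10)])
        assert s["mean_duplex_len"] == 10
        assert (s["min_duplex_len"], s["max_duplex_len"]) == (10, 10)

    def test_mean_and_range(self):
        s = guidemap.duplex_summary([self._assignment(8), self._assignment(12)])
        assert s["mean_duplex_len"] == 10
        assert (s["min_duplex_len"], s["max_duplex_len"]) == (8, 12)

    def test_planted_cohort_lengths_within_design_range(self, rrna):
        assignments = []
        for i, dl in enumerate(range(7, 16)):
            gene = synth.generate_snorna_gene((rrna, 150 + 180 * i),
                                              duplex_len=dl, seed=100 + i,
                                              sno_id=f"g{i}")
            hit = best_duplex(gene.sequence, rrna.sequence, 150 + 180 * i,
                              gene.box_d_start, snorna_id=gene.id)
            assignments.append(hit)
        s = guidemap.duplex_summary(assignments)
        assert 7 <= s["min_duplex_len"] and s["max_duplex_len"] <= 15

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            guidemap.duplex_summary([])
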