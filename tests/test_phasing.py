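"""Phasing score, chi-square test, locus calling and trigger
assignment."""

import math

import numpy as np
import pytest

from srnaome import core, phasing
from srnaome._seq import revcomp
from srnaome.phasing import PositionInfo


def _registers_from(positions, lib="lib", tag="T" * 21):
    """Build a RegisterTable from {chrom: {pos: abundance}}."""
    out = {}
    for chrom, d in positions.items():
        out[chrom] = {}
        for pos, ab in d.items():
            info = PositionInfo(total=ab, per_library={lib: ab},
                                tags={tag}, plus=ab)
            out[chrom][pos] = info
    return out


class TestRegisters:
    def _table(self, reads, genome):
        table = core.TagTable()
        table.add_library("lib", reads)
        table.hits = core.map_exact(list(reads), genome)
        return table

    def test_minus_strand_two_nt_offset_shares_register(self, rng):
        plus21 = "".join("ACGT"[c] for c in rng.integers(0, 4, 21))
        genome = {"c1": "A" * 100 + plus21
                  + "".join("ACGT"[c] for c in rng.integers(0, 4, 100))}
        # minus read whose 5' end sits at p + 2 = 102+... :
        # its window is genome[p-18 : p+3); 5' end coordinate p+2
        p = 100
        minus = revcomp(genome["c1"][p - 18:p + 3])
        table = self._table({plus21: 5, minus: 3}, genome)
        regs = phasing.collect_21nt_registers(table)
        assert regs["c1"][p].total == 8
        assert regs["c1"][p].plus == 5 and regs["c1"][p].minus == 3

    def test_non_21nt_tags_excluded(self, rng):
        genome = {"c1": "".join("ACGT"[c] for c in rng.integers(0, 4, 200))}
        t22 = genome["c1"][50:72]
        table = self._table({t22: 9}, genome)
        assert phasing.collect_21nt_registers(table) == {}

    def test_planted_plus_locus_single_register(self, small_bundle,
                                                small_result):
        regs = phasing.collect_21nt_registers(small_result.table)
        locus = next(p for p in small_bundle.truth.planted_phas
                     if p.strand == "+" and len(p.registers) == 1)
        reg = locus.registers[0]
        for k in range(len(reg.phasirnas)):
            pos = reg.phase_start + 21 * k
            assert pos in regs[locus.chromosome]
            assert pos % 21 == reg.register

    def test_planted_minus_locus_round_trip(self, small_bundle,
                                            small_result):
        """Minus-strand phasiRNAs pool into one register class under
        the 2-nt offset convention."""
        regs = phasing.collect_21nt_registers(small_result.table)
        locus = next(p for p in small_bundle.truth.planted_phas
                     if p.strand == "-")
        reg = locus.registers[0]
        classes = set()
        for k in range(len(reg.phasirnas)):
            pos = reg.phase_start - 21 * k
            assert pos in regs[locus.chromosome]
            classes.add(pos % 21)
        assert classes == {reg.register}


class TestPhasingScore:
    def test_fewer_than_three_cycles_scores_zero(self):
        assert phasing.phasing_score(100, 0, 2) == 0.0
        assert phasing.phasing_score(100, 0, 0) == 0.0

    def test_closed_form_below_threshold(self):
        score = phasing.phasing_score(10, 0, 5)
        assert score == pytest.approx(3 * math.log(101))
        assert score < 15

    def test_closed_form_flagged(self):
        score = phasing.phasing_score(50, 2, 9)
        assert score == pytest.approx(7 * math.log(1 + 500 / 3))
        assert score >= 15

    def test_matches_direct_evaluation_on_windows(self, small_result):
        regs = phasing.collect_21nt_registers(small_result.table)
        windows = phasing.score_windows(regs, threshold=0.1)
        for w in windows[:50]:
            expected = 0.0 if w.k < 3 else (w.k - 2) * math.log(
                1 + 10 * w.sum_phased / (1 + w.sum_unphased))
            assert w.score == pytest.approx(expected)


class TestChiSquare:
    def test_strong_enrichment_significant(self):
        stat, p, sig = phasing.chi_square_phase_test(80, 100)
        expected = (80 - 100 / 21) ** 2 / (100 / 21) \
            + (20 - 2000 / 21) ** 2 / (2000 / 21)
        assert stat == pytest.approx(expected)
        assert sig and p < 1e-10

    def test_depletion_never_significant(self):
        _, _, sig = phasing.chi_square_phase_test(0, 100)
        assert not sig

    def test_exact_expectation_scores_zero(self):
        stat, p, sig = phasing.chi_square_phase_test(100 / 21, 100)
        assert stat == pytest.approx(0.0) and not sig

    def test_p_matches_erfc_oracle(self):
        """1-dof chi-square survival equals erfc(sqrt(x/2))."""
        for in_phase, total in ((10, 100), (30, 200), (8, 21), (50, 300)):
            stat, p, _ = phasing.chi_square_phase_test(in_phase, total)
            assert abs(p - math.erfc(math.sqrt(stat / 2))) < 1e-9


class TestLocusCalling:
    def _qualifying(self, tag="T" * 21):
        return {"lib": frozenset({tag})}

    def _clean_positions(self, start=1000, cycles=10, ab=50):
        pos = {start + 21 * k: ab for k in range(cycles)}
        return {"c1": pos}

    def test_clean_locus_called(self):
        regs = _registers_from(self._clean_positions())
        loci = phasing.call_phas_loci(regs, self._qualifying())
        assert len(loci) == 1
        locus = loci[0]
        assert locus.start == 1000 and locus.end == 1000 + 210
        assert locus.register == 1000 % 21

    def test_te_overlap_suppresses(self):
        from intervaltree import IntervalTree
        regs = _registers_from(self._clean_positions())
        te = {"c1": IntervalTree()}
        te["c1"][1100:1150] = "TE"
        assert phasing.call_phas_loci(regs, self._qualifying(), te) == []

    def test_too_few_qualifying_windows_suppresses(self):
        regs = _registers_from(self._clean_positions())
        # no in-register tag qualifies under the top-5 % rule
        loci = phasing.call_phas_loci(regs,
                                      {"lib": frozenset({"G" * 21})})
        assert loci == []

    def test_score_threshold_dominates(self):
        regs = _registers_from(self._clean_positions())
        assert phasing.call_phas_loci(regs, self._qualifying(),
                                      threshold=1e3) == []

    def test_register_shift_invariance(self):
        regs = _registers_from(self._clean_positions(start=1000))
        shifted = _registers_from(self._clean_positions(start=1021))
        a = phasing.call_phas_loci(regs, self._qualifying())
        b = phasing.call_phas_loci(shifted, self._qualifying())
        assert len(a) == len(b) == 1
        assert b[0].start - a[0].start == 21
        assert b[0].end - a[0].end == 21
        assert a[0].register == b[0].register  # 21-nt shift: same class

    def test_strand_symmetry_of_locus_calls(self, rng):
        """Reverse-complementing genome and reads yields mirrored loci."""
        n = 5000
        start, cycles = 1000, 10
        phas = ["".join("ACGT"[c] for c in rng.integers(0, 4, 21))
                for _ in range(cycles)]
        genome_fwd = {"c1": "".join(
            "ACGT"[c] for c in rng.integers(0, 4, start)) + "".join(phas)
            + "".join("ACGT"[c] for c in rng.integers(0, 4,
                                                      n - start - 210))}
        genome_rev = {"c1": revcomp(genome_fwd["c1"])}
        reads = {p: 50 for p in phas}

        def call(genome):
            table = core.TagTable()
            table.add_library("lib", reads)
            table.hits = core.map_exact(list(reads), genome)
            regs = phasing.collect_21nt_registers(table)
            qual = {"lib": frozenset(reads)}
            return phasing.call_phas_loci(regs, qual)

        fwd = call(genome_fwd)
        rev = call(genome_rev)
        assert len(fwd) == len(rev) == 1
        # mirror map on the register axis: x -> n - 3 - x
        assert rev[0].end - rev[0].start == fwd[0].end - fwd[0].start
        assert rev[0].start == n - 3 - (fwd[0].end - 21) \
            or abs((n - 3 - (fwd[0].end - 21)) - rev[0].start) % 21 == 0


class TestTriggers:
    def test_planted_triggers_in_phase(self, small_bundle, small_result):
        truth = small_bundle.truth
        seq2id = {v: k for k, v in small_result.final_matures.items()}
        for locus in truth.planted_phas:
            for reg in locus.registers:
                mature = next(m.mature for m in truth.planted_mirnas
                              if m.mirna_id == reg.trigger_id)
                mid = seq2id.get(mature)
                if mid is None:
                    continue
                called = [l for l in small_result.phas_loci
                          if l.chromosome == locus.chromosome
                          and l.register == reg.register
                          and l.start < locus.end and l.end > locus.start]
                assert called, reg.register_id
                assert any(t.mirna_id == mid and t.in_phase
                           for t in called[0].triggers), reg.register_id

    def test_off_register_cleavage_reported_out_of_phase(
            self, small_result):
        for locus in small_result.phas_loci:
            for t in locus.triggers:
                in_phase = (t.cleavage_coordinate - locus.start) % 21 == 0
                assert t.in_phase == in_phase

    def test_dual_register_locus_reports_both(self, small_bundle,
                                              small_result):
        dual = next(p for p in small_bundle.truth.planted_phas
                    if len(p.registers) == 2)
        called = [l for l in small_result.phas_loci
                  if l.chromosome == dual.chromosome
                  and l.start < dual.end and l.end > dual.start]
        assert {l.register for l in called} == \
            {r.register for r in dual.registers}
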