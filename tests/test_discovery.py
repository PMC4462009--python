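"""Hairpin excision, candidacy criteria, scoring and family recovery."""

import numpy as np
import pytest
from intervaltree import IntervalTree

from srnaome import core, discovery as disc
from srnaome._seq import revcomp
from srnaome.simulate import plant_hairpin


def _table_with(seqs_counts, genome):
    table = core.TagTable()
    table.add_library("lib", dict(seqs_counts))
    table.hits = core.map_exact(list(seqs_counts), genome)
    return table


def _random_genome(rng, n=6000):
    return {"c1": "".join("ACGT"[c] for c in rng.integers(0, 4, n))}


class TestExcision:
    def test_multihit_tag_yields_no_windows(self, rng):
        unit = "ACGTTGCAAGCTTGACCAAGT"
        spacer = "".join("ACGT"[c] for c in rng.integers(0, 4, 40))
        genome = {"c1": (spacer + unit) * 45}
        table = _table_with({unit: 10}, genome)
        assert len(table.hits[unit]) == 45
        assert disc.excise_candidate_regions(table, genome) == []

    def test_ncrna_overlap_discards_window(self, rng):
        mature = "".join("ACGT"[c] for c in rng.integers(0, 4, 21))
        prec, m_off, _, _ = plant_hairpin(mature, rng, 1)
        pad = "".join("ACGT"[c] for c in rng.integers(0, 4, 400))
        genome = {"c1": pad + prec + pad}
        table = _table_with({mature: 10}, genome)
        ncrna = {"c1": IntervalTree()}
        ncrna["c1"][len(pad):len(pad) + len(prec)] = "rRNA"
        assert disc.excise_candidate_regions(table, genome, ncrna) == []
        assert len(disc.excise_candidate_regions(table, genome)) >= 1

    def test_window_contains_planted_precursor(self, small_bundle,
                                               small_result):
        table = small_result.table
        genome = small_bundle.genome
        windows = disc.excise_candidate_regions(table, genome)
        for m in small_bundle.truth.planted_mirnas:
            containing = [
                w for w in windows
                if w.chromosome == m.chromosome and w.strand == m.strand
                and w.start <= m.precursor_start
                and w.end >= m.precursor_end]
            assert containing, m.mirna_id


class TestEvaluate:
    def _window_for(self, mature, genome, table):
        windows = disc.excise_candidate_regions(table, genome)
        return next(w for w in windows if w.mature == mature)

    def test_planted_precursor_accepted(self, rng):
        mature = "".join("ACGT"[c] for c in rng.integers(0, 4, 21))
        prec, m_off, s_off, star = plant_hairpin(mature, rng, 1)
        pad = "".join("ACGT"[c] for c in rng.integers(0, 4, 300))
        genome = {"c1": pad + prec + pad}
        table = _table_with({mature: 100}, genome)
        w = self._window_for(mature, genome, table)
        cand, reason = disc.evaluate_precursor(w, genome, {mature})
        assert reason is None
        m_lo, m_hi = cand.mature_genomic
        assert (m_lo, m_hi) == (len(pad) + m_off,
                                len(pad) + m_off + len(mature))
        s_lo, s_hi = cand.star_genomic
        assert abs(s_lo - (len(pad) + s_off)) <= 2
        assert abs(s_hi - (len(pad) + s_off + len(star))) <= 2

    def test_low_expression_rejected(self, rng):
        mature = "".join("ACGT"[c] for c in rng.integers(0, 4, 21))
        prec, *_ = plant_hairpin(mature, rng, 1)
        pad = "".join("ACGT"[c] for c in rng.integers(0, 4, 300))
        genome = {"c1": pad + prec + pad}
        table = _table_with({mature: 100}, genome)
        w = self._window_for(mature, genome, table)
        cand, reason = disc.evaluate_precursor(w, genome, qualifying=set())
        assert cand is None and reason == "expression"

    def test_five_duplex_mismatches_rejected(self, rng):
        mature = "".join("ACGT"[c] for c in rng.integers(0, 4, 21))
        L = len(mature)
        core_arm = list(revcomp(mature[:L - 2]))
        comp = {"A": "T", "T": "A", "G": "C", "C": "G"}
        wob = {"T": "G", "G": "T"}
        for j in (3, 6, 9, 12, 15):     # five non-pairing star positions
            partner = mature[L - 3 - j]
            bad = next(b for b in "ACGT"
                       if b != comp[partner]
                       and wob.get(partner) != b)
            core_arm[j] = bad
        star = "".join(core_arm) + "AA"
        prec = mature + "TCTCTCTCTCTCTCTC" + star
        pad = "".join("ACGT"[c] for c in rng.integers(0, 4, 300))
        genome = {"c1": pad + prec + pad}
        table = _table_with({mature: 100}, genome)
        windows = disc.excise_candidate_regions(table, genome)
        results = [disc.evaluate_precursor(w, genome, {mature})
                   for w in windows if w.mature == mature]
        assert all(cand is None for cand, _ in results)

    def test_minus_strand_candidate_maps_back(self, rng):
        mature = "".join("ACGT"[c] for c in rng.integers(0, 4, 21))
        prec, m_off, _, _ = plant_hairpin(mature, rng, 1)
        pad = "".join("ACGT"[c] for c in rng.integers(0, 4, 300))
        genome = {"c1": pad + revcomp(prec) + pad}
        table = _table_with({mature: 100}, genome)
        w = self._window_for(mature, genome, table)
        assert w.strand == "-"
        cand, reason = disc.evaluate_precursor(w, genome, {mature})
        assert reason is None
        m_lo, m_hi = cand.mature_genomic
        assert revcomp(genome["c1"][m_lo:m_hi]) == mature


class TestScoring:
    def test_concentrated_reads_beat_uniform(self):
        concentrated = disc.candidate_score(90, 10, 0, 1.0)
        uniform = disc.candidate_score(40, 10, 50, 1.0)
        assert concentrated > uniform

    def test_fully_paired_dominates_same_reads(self):
        assert disc.candidate_score(50, 5, 0, 1.0) > \
            disc.candidate_score(50, 5, 0, 0.7)

    def test_single_candidate_is_retained(self, rng):
        mature = "".join("ACGT"[c] for c in rng.integers(0, 4, 21))
        prec, *_ = plant_hairpin(mature, rng, 1)
        pad = "".join("ACGT"[c] for c in rng.integers(0, 4, 300))
        genome = {"c1": pad + prec + pad}
        table = _table_with({mature: 100}, genome)
        result = disc.discover(table, genome, {mature})
        assert len(result.accepted) == 1
        final = disc.select_final_matures(result, classes={})
        assert final == {mature}    # novel, at the 95th pct of itself

    def test_adding_reads_never_unaccepts(self, rng):
        mature = "".join("ACGT"[c] for c in rng.integers(0, 4, 21))
        prec, *_ = plant_hairpin(mature, rng, 1)
        pad = "".join("ACGT"[c] for c in rng.integers(0, 4, 300))
        genome = {"c1": pad + prec + pad}
        for count in (10, 100, 10_000):
            table = _table_with({mature: count}, genome)
            result = disc.discover(table, genome, {mature})
            assert [c.mature for c in result.accepted] == [mature]


class TestFamilyRecovery:
    def test_all_loci_of_final_mature_recovered(self, rng):
        mature = "".join("ACGT"[c] for c in rng.integers(0, 4, 21))
        pieces = []
        for _ in range(3):
            prec, *_ = plant_hairpin(mature, rng, 1)
            pieces.append("".join("ACGT"[c]
                                  for c in rng.integers(0, 4, 300)))
            pieces.append(prec)
        pieces.append("".join("ACGT"[c] for c in rng.integers(0, 4, 300)))
        genome = {"c1": "".join(pieces)}
        table = _table_with({mature: 100}, genome)
        result = disc.discover(table, genome, {mature})
        calls = disc.recover_family_precursors({mature}, result.accepted)
        assert len(calls) == 3

    def test_dropped_mature_yields_no_calls(self, small_result):
        calls = disc.recover_family_precursors(set(),
                                               small_result.discovery.accepted)
        assert calls == []

    def test_recovery_harness_on_small_bundle(self, small_bundle,
                                              small_result):
        truth = small_bundle.truth.mature_sequences
        found = set(small_result.final_matures.values())
        assert len(truth & found) >= 0.9 * len(truth)
        false = found - truth
        assert len(false) <= 0.1 * max(1, len(found))
        # every recovered mature has at least one precursor call
        with_calls = {c.candidate.mature
                      for c in small_result.precursor_calls}
        assert found <= with_calls
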