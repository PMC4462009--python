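"""The synthetic-data generator: determinism, planted-element
consistency, sampling statistics."""

import math

import numpy as np
import pytest

from srnaome._seq import revcomp
from srnaome.fold import max_pair_structure
from srnaome.simulate import (PackingError, SimulationConfig, build_genome,
                              plant_hairpin, plant_phas_locus,
                              simulate_degradome, simulate_srna_libraries,
                              write_bundle, degradome_references)
from srnaome import degradome as dg


class TestBuildGenome:
    def test_empty_truth_when_nothing_planted(self):
        cfg = SimulationConfig(seed=3, genome_length=120_000, n_mirnas=0,
                               n_phas_loci=0, library_depth=1000,
                               noise_pool_size=50, contaminant_pool_size=50)
        bundle = build_genome(cfg)
        assert bundle.truth.planted_mirnas == []
        assert bundle.truth.planted_phas == []

    def test_same_seed_reproduces_identical_files(self, small_config,
                                                  tmp_path):
        a, b = tmp_path / "a", tmp_path / "b"
        for out in (a, b):
            bundle = build_genome(small_config)
            write_bundle(bundle, out)
            simulate_srna_libraries(bundle, out / "libraries")
            simulate_degradome(bundle, outpath=out / "degradome.fa")
        files_a = sorted(p.relative_to(a) for p in a.rglob("*")
                         if p.is_file())
        files_b = sorted(p.relative_to(b) for p in b.rglob("*")
                         if p.is_file())
        assert files_a == files_b
        for rel in files_a:
            assert (a / rel).read_bytes() == (b / rel).read_bytes(), rel

    def test_planted_coordinates_within_bounds(self, small_bundle):
        for m in small_bundle.truth.planted_mirnas:
            clen = len(small_bundle.genome[m.chromosome])
            assert 0 <= m.precursor_start < m.precursor_end <= clen
            assert m.precursor_start <= m.mature_start < m.mature_end \
                <= m.precursor_end
        for p in small_bundle.truth.planted_phas:
            clen = len(small_bundle.genome[p.chromosome])
            assert 0 <= p.start < p.end <= clen + 21
            assert (p.end - p.start) % 21 == 0

    def test_every_planted_sequence_findable_in_genome(self, small_bundle):
        for m in small_bundle.truth.planted_mirnas:
            chrom = small_bundle.genome[m.chromosome]
            prec = chrom[m.precursor_start:m.precursor_end]
            if m.strand == "-":
                prec = revcomp(prec)
            assert m.mature in prec and m.star in prec

    def test_all_context_classes_planted(self, small_bundle):
        contexts = {m.context for m in small_bundle.truth.planted_mirnas}
        assert {"intergenic", "intron", "exon", "3UTR"} <= contexts

    def test_infeasible_packing_raises(self):
        with pytest.raises(PackingError):
            build_genome(SimulationConfig(seed=1, genome_length=5_000,
                                          n_mirnas=20, n_phas_loci=5))


class TestPlantHairpin:
    def test_perfect_duplex_pairs_fully(self, rng):
        mature = "".join("ACGT"[c] for c in rng.integers(0, 4, 21))
        prec, m_off, s_off, star = plant_hairpin(mature, rng,
                                                 mismatches_in_duplex=0)
        _, _, partner = max_pair_structure(prec)
        # every duplex position (all but the 2-nt 3' overhang) pairs
        # into the star arm at its intended partner
        L = len(mature)
        for i in range(L - 2):
            assert partner[m_off + i] == s_off + (L - 3 - i)

    def test_two_mismatches_leave_two_unpaired(self, rng):
        mature = "".join("ACGT"[c] for c in rng.integers(0, 4, 24))
        prec, m_off, s_off, star = plant_hairpin(mature, rng,
                                                 mismatches_in_duplex=2)
        _, _, partner = max_pair_structure(prec)
        L = len(mature)
        intended = sum(1 for i in range(L - 2)
                       if partner[m_off + i] == s_off + (L - 3 - i))
        assert intended == L - 2 - 2

    def test_length_bounds_rejected(self, rng):
        with pytest.raises(ValueError):
            plant_hairpin("A" * 17, rng)
        with pytest.raises(ValueError):
            plant_hairpin("A" * 26, rng)

    def test_precursor_stays_under_window(self, rng):
        for _ in range(5):
            mature = "".join("ACGT"[c] for c in rng.integers(0, 4, 25))
            prec, *_ = plant_hairpin(mature, rng, mismatches_in_duplex=1)
            assert len(prec) <= 250


class TestPlantPhasLocus:
    def test_phasirnas_tile_without_gaps(self, rng):
        trig = "".join("ACGT"[c] for c in rng.integers(0, 4, 21))
        locus = plant_phas_locus(trig, cycles=10, strand="+", rng=rng)
        reg = locus["registers"][0]
        assert len(reg["phasirnas"]) == 10
        block = locus["block"]
        for k, p in enumerate(reg["phasirnas"]):
            assert len(p) == 21
            assert block[reg["t_start"] + 21 * k:
                         reg["t_start"] + 21 * (k + 1)] == p

    def test_cleavage_congruent_to_register(self, small_bundle):
        for locus in small_bundle.truth.planted_phas:
            for reg in locus.registers:
                assert (reg.cleavage - reg.phase_start) % 21 == 0
                assert reg.cleavage % 21 == reg.register

    def test_too_few_cycles_rejected(self, rng):
        with pytest.raises(ValueError):
            plant_phas_locus("ACGT" * 5 + "A", cycles=2, strand="+",
                             rng=rng)

    def test_trigger_site_is_reverse_complement(self, small_bundle):
        """The genome around each planted register start carries the
        trigger's binding site."""
        truth = small_bundle.truth
        for locus in truth.planted_phas:
            chrom = small_bundle.genome[locus.chromosome]
            for reg in locus.registers:
                trig = next(m.mature for m in truth.planted_mirnas
                            if m.mirna_id == reg.trigger_id)
                lt = len(trig)
                if locus.strand == "+":
                    c0 = reg.phase_start
                    site = chrom[c0 - (lt - 10):c0 + 10]
                else:
                    e5 = reg.phase_start + 2
                    site = revcomp(chrom[e5 - 10 + 1:e5 + (lt - 10) + 1])
                assert site == revcomp(trig)


class TestLibrarySimulation:
    def test_zero_noise_reads_are_all_planted(self):
        cfg = SimulationConfig(seed=5, genome_length=200_000, n_mirnas=4,
                               n_phas_loci=1, n_dual_register=0,
                               library_depth=5_000, noise_fraction=0.0,
                               contaminant_fraction=0.0)
        bundle = build_genome(cfg)
        libs, _ = simulate_srna_libraries(bundle)
        planted = bundle.truth.planted_sequences
        for counts in libs.values():
            assert set(counts) <= planted

    def test_counts_follow_binomial_sampling(self, small_bundle,
                                             small_libraries):
        """Observed counts sit within 4 standard deviations of the
        multinomial expectation."""
        truth = small_bundle.truth
        cfg = small_bundle.config
        lib = cfg.libraries[0]
        weights = {}
        for m in truth.planted_mirnas:
            if m.abundance.get(lib, 0) > 0:
                weights[m.mature] = m.abundance[lib]
                weights[m.star] = m.star_abundance[lib]
        total_w = sum(weights.values())
        # phasiRNA weights are jittered at sampling time; bound their
        # contribution from the truth table instead of reproducing it
        for locus in truth.planted_phas:
            w = locus.abundance.get(lib, 0)
            total_w += w * sum(len(r.phasirnas) for r in locus.registers)
        n_planted = cfg.library_depth \
            - round(cfg.library_depth * cfg.noise_fraction)
        for m in truth.planted_mirnas[:4]:
            if m.mature not in weights:
                continue
            p = weights[m.mature] / total_w
            expected = n_planted * p
            sd = math.sqrt(n_planted * p * (1 - p))
            observed = small_libraries[lib].get(m.mature, 0)
            assert abs(observed - expected) < 4.5 * sd

    def test_contamination_recovered_within_half_percent(
            self, small_bundle, small_libraries):
        from srnaome.core import contamination_fraction
        cfg = small_bundle.config
        lib = cfg.contaminated_library
        frac = contamination_fraction(small_libraries[lib],
                                      small_bundle.contaminant_genome)
        assert abs(frac - 100 * cfg.contaminant_fraction) < 0.5

    def test_star_abundance_is_duplex_asymmetric(self, small_bundle):
        for m in small_bundle.truth.planted_mirnas:
            for lib, w in m.abundance.items():
                assert 0.05 * w <= m.star_abundance[lib] <= 0.20 * w


class TestDegradomeSimulation:
    def test_zero_noise_positions_equal_planted_set(self, small_bundle):
        counts = simulate_degradome(small_bundle, peak_height=50,
                                    noise_per_position=0)
        refs = degradome_references(small_bundle)
        signatures = dg.map_degradome_tags(counts, refs)
        expected = set()
        for t in small_bundle.truth.planted_targets:
            expected.add((t.transcript_id, t.cleavage_position))
        for m in small_bundle.truth.planted_mirnas:
            _, m5, s5, _ = small_bundle.precursor_reference(m)
            expected.add((f"prec_{m.mirna_id}", m5 + 1))
            expected.add((f"prec_{m.mirna_id}", s5 + 1))
        observed = {(tid, pos) for tid, sigs in signatures.items()
                    for pos, c in sigs.items() if c > 0}
        assert expected <= observed
        # any other full-height signature must be a precursor-boundary
        # tag re-mapping into its host transcript (exonic/3'UTR hosts
        # carry the precursor within the spliced transcript)
        boundary_tags = set()
        for m in small_bundle.truth.planted_mirnas:
            seq, m5, s5, _ = small_bundle.precursor_reference(m)
            boundary_tags.add(seq[m5:m5 + 20])
            boundary_tags.add(seq[s5:s5 + 20])
        for tid, pos in observed - expected:
            if signatures[tid][pos] >= 50:
                assert refs[tid][pos - 1:pos + 19] in boundary_tags

    def test_empty_truth_empty_tags(self):
        cfg = SimulationConfig(seed=3, genome_length=120_000, n_mirnas=0,
                               n_phas_loci=0)
        bundle = build_genome(cfg)
        counts = simulate_degradome(bundle, peak_height=50,
                                    noise_per_position=0)
        assert counts == {}

    def test_peak_must_exceed_noise(self, small_bundle):
        with pytest.raises(ValueError):
            simulate_degradome(small_bundle, peak_height=2,
                               noise_per_position=2)
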