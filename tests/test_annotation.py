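"""Catalog classification, family clustering, conservation, genomic
localization, organ distribution and transcript support."""

import itertools

import numpy as np
import pandas as pd
import pytest

from srnaome import annotation as ann
from srnaome._seq import revcomp


class TestClassify:
    def test_exact_match_is_known(self):
        cat = {"miR1": "ACGTACGTACGTACGTACGTA"}
        assert ann.classify_against_catalog("ACGTACGTACGTACGTACGTA",
                                            cat) == "known"

    def test_single_mismatch_is_unclassified(self):
        cat = {"miR1": "ACGTACGTACGTACGTACGTA"}
        assert ann.classify_against_catalog("ACGTACGTACGTACGTACGTC",
                                            cat) == "unclassified"

    def test_u_t_canonicalization(self):
        cat = {"miR1": "ACGUACGUACGUACGUACGUA"}
        assert ann.classify_against_catalog("ACGTACGTACGTACGTACGTA",
                                            cat) == "known"


class TestIdentity:
    def test_identical_sequences(self):
        s = "ACGTACGTACGTACGTACGTA"
        assert ann.ungapped_identity(s, s) == 1.0

    def test_three_mismatches_cross_threshold(self, rng):
        a = "".join("ACGT"[c] for c in rng.integers(0, 4, 21))
        b = list(a)
        for p in (3, 9, 15):
            b[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[b[p]]
        ident = ann.ungapped_identity(a, "".join(b))
        assert ident >= 18 / 21 >= ann.IDENTITY_THRESHOLD

    def test_five_mismatches_below_threshold(self):
        # fixed sequences so shifted offsets cannot rescue identity
        a = "ACGTACGTACGTACGTACGTA"
        b = "AAGTAAGTAAGTAAGTAAGTC"
        ident = ann.ungapped_identity(a, b)
        assert ident < ann.IDENTITY_THRESHOLD


class TestFamilies:
    def test_identical_matures_share_cluster(self):
        fam = ann.cluster_families(
            {"ACGTACGTACGTACGTACGTA": 10.0,
             "ACGTACGTACGTACGTACGTA".lower().upper(): 5.0}, {})
        assert fam.n_families == 1

    def test_known_family_contains_catalog_representative(self, rng):
        mature = "".join("ACGT"[c] for c in rng.integers(0, 4, 21))
        iso = list(mature)
        iso[5] = {"A": "C", "C": "G", "G": "T", "T": "A"}[iso[5]]
        iso = "".join(iso)
        cat = {"pvu-miR1": mature}
        fam = ann.cluster_families({mature: 100.0, iso: 50.0}, cat)
        assert fam.classes[mature] == "known"
        assert fam.classes[iso] == "isomiR"
        assert fam.family_of[mature] == fam.family_of[iso] == "pvu-miR1"

    def test_families_partition_the_mature_set(self, small_result):
        fams = small_result.families
        matures = set(fams.family_of)
        seen = set()
        for fam, members in fams.members.items():
            for m in members:
                assert m not in seen
                seen.add(m)
        assert matures <= seen

    def test_unrelated_sequences_found_novel_families(self):
        fam = ann.cluster_families(
            {"ACGTACGTACGTACGTACGTA": 5.0,
             "GGGGCCCCTTTTAAAAGGGGC": 3.0}, {})
        assert fam.n_families == 2
        assert set(fam.classes.values()) == {"novel"}


class TestConservation:
    def _naive(self, mature, genome):
        return any(mature in seq or revcomp(mature) in seq
                   for seq in genome.values())

    def test_matches_naive_substring_oracle(self, rng):
        genomes = {}
        for sp in ("spA", "spB", "spC"):
            genomes[sp] = {"c": "".join(
                "ACGT"[c] for c in rng.integers(0, 4, 20_000))}
        matures = [genomes["spA"]["c"][500:521],
                   revcomp(genomes["spB"]["c"][100:122]),
                   "".join("ACGT"[c] for c in rng.integers(0, 4, 21))]
        mat = ann.conservation_scan(matures, genomes)
        for m in matures:
            for sp in genomes:
                assert mat.loc[m, sp] == self._naive(m, genomes[sp])

    def test_species_specific_flags_all_false_rows(self, rng):
        genomes = {"spA": {"c": "A" * 1000}}
        mature = "CGTCGTCGTCGTCGTCGTCGT"
        mat = ann.conservation_scan([mature], genomes)
        assert ann.species_specific(mat) == [mature]

    def test_reverse_complement_counts_as_present(self, rng):
        mature = "".join("ACGT"[c] for c in rng.integers(0, 4, 21))
        genomes = {"spA": {"c": "A" * 50 + revcomp(mature) + "A" * 50}}
        mat = ann.conservation_scan([mature], genomes)
        assert bool(mat.loc[mature, "spA"])


def _toy_annotation():
    annot = ann.Annotation()
    # gene on +: exon1 [100,300) with 5'UTR [100,160), intron [300,500),
    # exon2 [500,700), intron [700,900), exon3 [900,1200) with 3'UTR
    # [1050,1200)
    annot.add_gene("g1", "c1", 100, 1200, "+",
                   exons=[(100, 300), (500, 700), (900, 1200)],
                   five_utr=[(100, 160)], three_utr=[(1050, 1200)])
    return annot


class TestLocalize:
    def test_intron_sense(self):
        ctx = ann.localize_precursor("p1", "c1", 350, 450, "+",
                                     _toy_annotation())
        assert (ctx.category, ctx.host_gene, ctx.orientation) == \
            ("intron", "g1", "sense")

    def test_intron_antisense(self):
        ctx = ann.localize_precursor("p1", "c1", 350, 450, "-",
                                     _toy_annotation())
        assert ctx.orientation == "antisense"

    def test_intergenic(self):
        ctx = ann.localize_precursor("p1", "c1", 2000, 2100, "+",
                                     _toy_annotation())
        assert (ctx.category, ctx.host_gene, ctx.orientation) == \
            ("intergenic", None, "n/a")

    def test_three_utr_precedence_over_exon(self):
        ctx = ann.localize_precursor("p1", "c1", 1060, 1150, "+",
                                     _toy_annotation())
        assert ctx.category == "3UTR"

    def test_five_utr_precedence(self):
        ctx = ann.localize_precursor("p1", "c1", 105, 150, "+",
                                     _toy_annotation())
        assert ctx.category == "5UTR"

    def test_malformed_hierarchy_raises(self):
        annot = ann.Annotation()
        with pytest.raises(ValueError, match="exon"):
            annot.add_gene("bad", "c1", 100, 200, "+",
                           exons=[(150, 400)])


class TestOrganDistribution:
    def test_all_organ_and_specific_classes(self):
        libs = ["flower", "leaf", "root", "seedling", "nodule"]
        presence = pd.DataFrame(
            [[True] * 5,
             [False, False, False, False, True]],
            index=["m1", "m2"], columns=libs)
        venn, specific = ann.organ_distribution(presence)
        assert venn[tuple(sorted(libs))] == 1
        assert venn[("nodule",)] == 1
        assert specific == ["m2"]

    def test_venn_counts_match_exhaustive_enumeration(self, rng):
        libs = [f"L{i}" for i in range(5)]
        presence = pd.DataFrame(rng.random((10, 5)) < 0.5,
                                index=[f"m{i}" for i in range(10)],
                                columns=libs)
        venn, _ = ann.organ_distribution(presence)
        # brute force over every non-empty region
        expected = {}
        for _, row in presence.iterrows():
            key = tuple(sorted(l for l in libs if row[l]))
            if key:
                expected[key] = expected.get(key, 0) + 1
        assert venn == expected
        assert sum(venn.values()) == int((presence.sum(axis=1) > 0).sum())


class TestTranscriptSupport:
    TX = [("t1", "c1", 100, 1000, "+")]

    def test_contained_same_strand(self):
        assert ann.precursor_transcript_support("c1", 200, 400, "+",
                                                self.TX)

    def test_half_overlap_is_not_support(self):
        assert not ann.precursor_transcript_support("c1", 900, 1100, "+",
                                                    self.TX)

    def test_antisense_is_not_support(self):
        assert not ann.precursor_transcript_support("c1", 200, 400, "-",
                                                    self.TX)
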