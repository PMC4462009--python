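"""Mature miRNA annotation: known/isomiR/novel classification, family
clustering, cross-species conservation, genomic-context localization,
organ distribution and transcript support.

Classification is exact: a mature is "known" only when it matches a
reference-catalog sequence at full length with no mismatches (U/T
canonicalized).  Families are greedy identity clusters at >= 84.2 %
identity, where identity is matches over the length of the shorter
sequence under the best ungapped offset alignment; an unclassified
mature clustering with a catalog member becomes an isomiR of that
family, and catalog-free clusters found novel families.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

from ._seq import canonical, revcomp
from .core import ExactIndex

IDENTITY_THRESHOLD = 0.842

CONTEXT_PRECEDENCE = ("5UTR", "3UTR", "exon", "intron", "intergenic")


# ---------------------------------------------------------------------------
# classification and families
# ---------------------------------------------------------------------------

def classify_against_catalog(mature: str, catalog: Mapping[str, str]
                             ) -> str:
    """'known' iff the full-length mature matches a catalog entry exactly."""
    seq = canonical(mature)
    for ref in catalog.values():
        if canonical(ref) == seq:
            return "known"
    return "unclassified"


def ungapped_identity(a: str, b: str) -> float:
    """Matches over the shorter length, best ungapped offset."""
    a, b = canonical(a), canonical(b)
    if len(a) > len(b):
        a, b = b, a
    short, long_ = a, b
    best = 0
    for off in range(-(len(short) - 1), len(long_)):
        matches = sum(
            1 for i in range(len(short))
            if 0 <= off + i < len(long_) and short[i] == long_[off + i]
        )
        best = max(best, matches)
    return best / len(short)


@dataclass
class FamilyResult:
    family_of: dict[str, str]          # mature sequence -> family id
    members: dict[str, list[str]]      # family id -> member sequences
    classes: dict[str, str]            # mature sequence -> known/isomiR/novel

    @property
    def n_families(self) -> int:
        return len(self.members)


def cluster_families(matures: Mapping[str, float],
                     catalog: Mapping[str, str],
                     identity_threshold: float = IDENTITY_THRESHOLD
                     ) -> FamilyResult:
    """Greedy family clustering of matures together with catalog
    representatives.

    ``matures`` maps mature sequences to an abundance used for the
    deterministic seeding order (longest first, then most abundant,
    then lexicographic).  Catalog entries seed with infinite abundance
    so families of known miRNAs are anchored on the reference.
    """
    cat_seqs: dict[str, str] = {}
    for name, seq in catalog.items():
        cat_seqs.setdefault(canonical(seq), name)
    entries = [(seq, float("inf"), cat_seqs[seq]) for seq in cat_seqs]
    entries += [(canonical(s), float(a), None) for s, a in matures.items()
                if canonical(s) not in cat_seqs]
    entries.sort(key=lambda e: (-len(e[0]), -e[1], e[0]))

    reps: list[tuple[str, str]] = []     # (representative seq, family id)
    assign: dict[str, str] = {}
    fam_members: dict[str, list[str]] = {}
    novel_counter = itertools.count(1)
    for seq, _, cat_name in entries:
        placed = None
        for rep_seq, fam in reps:
            if ungapped_identity(seq, rep_seq) >= identity_threshold:
                placed = fam
                break
        if placed is None:
            placed = cat_name if cat_name is not None \
                else f"novelFam{next(novel_counter):03d}"
            reps.append((seq, placed))
            fam_members[placed] = []
        assign[seq] = placed
        fam_members[placed].append(seq)

    catalog_families = {assign[seq] for seq in cat_seqs}
    classes: dict[str, str] = {}
    for s in matures:
        seq = canonical(s)
        fam = assign[seq]
        if seq in cat_seqs:
            classes[s] = "known"
        elif fam in catalog_families:
            classes[s] = "isomiR"
        else:
            classes[s] = "novel"
    family_of = {s: assign[canonical(s)] for s in matures}
    members = {f: [s for s in ms if f == assign[s]]
               for f, ms in fam_members.items()}
    return FamilyResult(family_of=family_of, members=members, classes=classes)


# ---------------------------------------------------------------------------
# conservation
# ---------------------------------------------------------------------------

def conservation_scan(matures: Iterable[str],
                      genomes: Mapping[str, Mapping[str, str]]
                      ) -> pd.DataFrame:
    """Presence matrix: entry (mature, species) is True iff the mature
    occurs exactly, full length, on either strand of that genome."""
    matures = list(matures)
    data = {}
    for species, genome in genomes.items():
        index = ExactIndex(genome)
        data[species] = [index.occurs(m) for m in matures]
    return pd.DataFrame(data, index=matures)


def species_specific(conservation: pd.DataFrame) -> list[str]:
    """Matures absent from every scanned (non-self) genome."""
    return list(conservation.index[~conservation.any(axis=1)])


# ---------------------------------------------------------------------------
# genomic localization
# ---------------------------------------------------------------------------

@dataclass
class GenomicContext:
    precursor_id: str
    category: str                  # intergenic / intron / exon / 3UTR / 5UTR
    host_gene: str | None
    orientation: str               # sense / antisense / n/a


@dataclass
class Annotation:
    """Gene/exon/UTR hierarchy with interval indexes per chromosome."""

    genes: dict[str, IntervalTree] = field(default_factory=dict)
    exons: dict[str, IntervalTree] = field(default_factory=dict)
    five_utr: dict[str, IntervalTree] = field(default_factory=dict)
    three_utr: dict[str, IntervalTree] = field(default_factory=dict)
    gene_strand: dict[str, str] = field(default_factory=dict)

    def add_gene(self, gene_id: str, chromosome: str, start: int, end: int,
                 strand: str,
                 exons: Sequence[tuple[int, int]] = (),
                 five_utr: Sequence[tuple[int, int]] = (),
                 three_utr: Sequence[tuple[int, int]] = ()) -> None:
        for s, e in exons:
            if s < start or e > end:
                raise ValueError(
                    f"malformed hierarchy: exon [{s}, {e}) outside "
                    f"gene {gene_id} [{start}, {end})")
        for s, e in list(five_utr) + list(three_utr):
            if not any(es <= s and e <= ee for es, ee in exons):
                raise ValueError(
                    f"malformed hierarchy: UTR [{s}, {e}) outside exons "
                    f"of gene {gene_id}")
        self.genes.setdefault(chromosome, IntervalTree())[start:end] = gene_id
        for s, e in exons:
            self.exons.setdefault(chromosome, IntervalTree())[s:e] = gene_id
        for s, e in five_utr:
            self.five_utr.setdefault(chromosome, IntervalTree())[s:e] = gene_id
        for s, e in three_utr:
            self.three_utr.setdefault(chromosome, IntervalTree())[s:e] = gene_id
        self.gene_strand[gene_id] = strand

    @classmethod
    def from_genes(cls, genes) -> "Annotation":
        ann = cls()
        for g in genes:
            ann.add_gene(g.gene_id, g.chromosome, g.start, g.end, g.strand,
                         exons=g.exons, five_utr=g.five_utr,
                         three_utr=g.three_utr)
        return ann

    @classmethod
    def from_gff3(cls, path) -> "Annotation":
        cols = ["chrom", "source", "type", "start", "end", "score",
                "strand", "frame", "attrs"]
        df = pd.read_csv(path, sep="\t", comment="#", names=cols,
                         dtype={"chrom": str})

        def attr(row, key):
            for part in str(row).split(";"):
                if part.startswith(key + "="):
                    return part.split("=", 1)[1]
            return None

        genes = {}
        for _, row in df.iterrows():
            if row["type"] == "gene":
                gid = attr(row["attrs"], "ID")
                genes[gid] = {"chrom": row["chrom"],
                              "start": int(row["start"]) - 1,
                              "end": int(row["end"]),
                              "strand": row["strand"], "exons": [],
                              "five": [], "three": [], "tid": None}
        tid_to_gid = {}
        for _, row in df.iterrows():
            if row["type"] == "mRNA":
                tid = attr(row["attrs"], "ID")
                gid = attr(row["attrs"], "Parent")
                if gid in genes:
                    tid_to_gid[tid] = gid
        for _, row in df.iterrows():
            parent = attr(row["attrs"], "Parent")
            gid = tid_to_gid.get(parent, parent)
            if gid not in genes:
                continue
            iv = (int(row["start"]) - 1, int(row["end"]))
            if row["type"] == "exon":
                genes[gid]["exons"].append(iv)
            elif row["type"] == "five_prime_UTR":
                genes[gid]["five"].append(iv)
            elif row["type"] == "three_prime_UTR":
                genes[gid]["three"].append(iv)
        ann = cls()
        for gid, g in genes.items():
            ann.add_gene(gid, g["chrom"], g["start"], g["end"], g["strand"],
                         exons=sorted(g["exons"]), five_utr=g["five"],
                         three_utr=g["three"])
        return ann


def localize_precursor(precursor_id: str, chromosome: str, start: int,
                       end: int, strand: str,
                       annotation: Annotation) -> GenomicContext:
    """Genomic context of a precursor, decided by the feature containing
    its midpoint, with precedence 5UTR > 3UTR > exon > intron >
    intergenic."""
    mid = (start + end) // 2
    point = slice(mid, mid + 1)

    def hit(trees):
        tree = trees.get(chromosome)
        if tree is None:
            return None
        ivs = tree[point.start:point.stop]
        return next(iter(ivs)).data if ivs else None

    gene = hit(annotation.genes)
    for category, trees in (("5UTR", annotation.five_utr),
                            ("3UTR", annotation.three_utr),
                            ("exon", annotation.exons)):
        g = hit(trees)
        if g is not None:
            orient = "sense" if annotation.gene_strand[g] == strand \
                else "antisense"
            return GenomicContext(precursor_id, category, g, orient)
    if gene is not None:
        orient = "sense" if annotation.gene_strand[gene] == strand \
            else "antisense"
        return GenomicContext(precursor_id, "intron", gene, orient)
    return GenomicContext(precursor_id, "intergenic", None, "n/a")


# ---------------------------------------------------------------------------
# organ distribution and transcript support
# ---------------------------------------------------------------------------

def organ_distribution(presence: pd.DataFrame
                       ) -> tuple[dict[tuple[str, ...], int], list[str]]:
    """Venn class counts over library combinations plus the
    organ-specific mature list.

    ``presence`` is a boolean matrix (matures x libraries) built from
    the top-5 % expression rule.  Returns ({sorted library tuple:
    count} over non-empty regions, matures present in exactly one
    library).
    """
    venn: dict[tuple[str, ...], int] = {}
    specific: list[str] = []
    libs = list(presence.columns)
    for mature, row in presence.iterrows():
        active = tuple(sorted(l for l in libs if row[l]))
        if not active:
            continue
        venn[active] = venn.get(active, 0) + 1
        if len(active) == 1:
            specific.append(mature)
    return venn, specific


def presence_matrix(matures: Iterable[str],
                    qualifying_by_library: Mapping[str, frozenset[str]]
                    ) -> pd.DataFrame:
    matures = list(matures)
    return pd.DataFrame(
        {lib: [m in q for m in matures]
         for lib, q in qualifying_by_library.items()},
        index=matures)


def precursor_transcript_support(
    chromosome: str, start: int, end: int, strand: str,
    expressed_transcripts: Iterable[tuple[str, str, int, int, str]],
) -> bool:
    """True iff an expressed transcript fully contains the precursor on
    the same strand.  Transcripts are (id, chrom, start, end, strand)."""
    for _, chrom, ts, te, tstrand in expressed_transcripts:
        if chrom == chromosome and tstrand == strand \
                and ts <= start and end <= te:
            return True
    return False
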