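"""Synthetic genome, annotation, small RNA and degradome simulator.

Builds a toy multi-chromosome genome with planted miRNA hairpin
precursors (in intergenic, intronic, exonic and 3'UTR contexts), planted
21-nt-phased siRNA loci with in-phase trigger sites, miRNA target sites
in spliced transcripts, ncRNA and transposable-element decoy
annotations, multi-library collapsed small RNA reads and degradome
5'-end tags — together with a machine-readable truth table, so every
pipeline stage can be tested without downloads.

The generator's defaults emulate the study design the pipeline was
written for: five organ libraries (flower, leaf, root, seedling,
nodule), ~5e5 reads each, 20 % background degradation noise, and a
bacterial contaminant present only in the nodule library.

Everything is deterministic for a fixed ``SimulationConfig.seed``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from ._seq import canonical, revcomp, write_fasta, pairs as base_pairs

ORGAN_NAMES = ("flower", "leaf", "root", "seedling", "nodule")

MIN_MATURE = 18
MAX_MATURE = 25
MAX_PRECURSOR = 250
MIN_LOOP_LEN = 8
MAX_LOOP_LEN = 60
MIN_PHAS_CYCLES = 3
PHASE = 21
DEGRADOME_TAG_LEN = 20
PRECURSOR_PAD = 10   # degradome reference window padding around precursors


class PackingError(ValueError):
    """Raised when planted elements cannot fit in the requested genome."""


@dataclass
class SimulationConfig:
    seed: int = 1
    genome_length: int = 2_000_000
    n_chromosomes: int = 2
    gc_fraction: float = 0.42
    n_mirnas: int = 20
    n_phas_loci: int = 5
    n_libraries: int = 5
    library_depth: int = 500_000
    noise_fraction: float = 0.2
    contaminant_fraction: float = 0.083
    phas_cycles: int = 10
    # generator conventions (see docs/methods.md)
    noise_pool_size: int = 1000
    contaminant_pool_size: int = 800
    contaminant_genome_length: int = 100_000
    n_dual_register: int = 1
    library_names: tuple[str, ...] | None = None

    def __post_init__(self):
        for name in ("genome_length", "n_chromosomes", "n_mirnas",
                     "n_phas_loci", "n_libraries", "library_depth",
                     "phas_cycles"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("gc_fraction", "noise_fraction", "contaminant_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.noise_fraction + self.contaminant_fraction > 1.0:
            raise ValueError("noise + contaminant fractions exceed 1")

    @property
    def libraries(self) -> tuple[str, ...]:
        if self.library_names is not None:
            return tuple(self.library_names)
        if self.n_libraries == 5:
            return ORGAN_NAMES
        return tuple(f"lib{i + 1}" for i in range(self.n_libraries))

    @property
    def contaminated_library(self) -> str | None:
        libs = self.libraries
        return libs[-1] if libs and self.contaminant_fraction > 0 else None


# ---------------------------------------------------------------------------
# truth records
# ---------------------------------------------------------------------------

@dataclass
class PlantedMirna:
    mirna_id: str
    mature: str
    star: str
    chromosome: str
    precursor_start: int      # 0-based half-open genomic
    precursor_end: int
    strand: str
    mature_start: int
    mature_end: int
    star_start: int
    star_end: int
    context: str              # intergenic / intron / exon / 3UTR
    host_gene: str | None
    orientation: str          # sense / antisense / n/a
    arm: str                  # 5p / 3p
    catalog_class: str        # known / isomir / novel (by construction)
    abundance: dict[str, float] = field(default_factory=dict)
    star_abundance: dict[str, float] = field(default_factory=dict)


@dataclass
class PlantedRegister:
    register_id: str
    trigger_id: str
    phase_start: int          # register-index-space genomic coordinate
    cleavage: int             # == phase_start by construction
    register: int             # phase_start mod 21
    phasirnas: list[str] = field(default_factory=list)


@dataclass
class PlantedPhas:
    locus_id: str
    chromosome: str
    start: int                # phased interval, 0-based half-open
    end: int
    strand: str
    registers: list[PlantedRegister]
    abundance: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if (self.end - self.start) % PHASE != 0:
            raise ValueError("phas interval length must be a multiple of 21")


@dataclass
class PlantedTarget:
    mirna_id: str
    transcript_id: str
    site_start: int           # 0-based on the spliced transcript
    site_end: int
    cleavage_position: int    # 1-based transcript coordinate


@dataclass
class TruthTable:
    planted_mirnas: list[PlantedMirna] = field(default_factory=list)
    planted_phas: list[PlantedPhas] = field(default_factory=list)
    planted_targets: list[PlantedTarget] = field(default_factory=list)
    contaminant_read_count: dict[str, int] = field(default_factory=dict)

    @property
    def mature_sequences(self) -> set[str]:
        return {m.mature for m in self.planted_mirnas}

    @property
    def planted_sequences(self) -> set[str]:
        out = {m.mature for m in self.planted_mirnas}
        out |= {m.star for m in self.planted_mirnas}
        for locus in self.planted_phas:
            for reg in locus.registers:
                out |= set(reg.phasirnas)
        return out


# ---------------------------------------------------------------------------
# feature containers for annotation output
# ---------------------------------------------------------------------------

@dataclass
class GeneModel:
    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str
    exons: list[tuple[int, int]]          # genomic, 0-based half-open
    five_utr: list[tuple[int, int]]
    three_utr: list[tuple[int, int]]
    transcript: str                        # spliced, 5'->3'
    expressed: bool = True


@dataclass
class SyntheticBundle:
    config: SimulationConfig
    genome: dict[str, str]
    genes: list[GeneModel]
    ncrna: list[tuple[str, int, int, str, str]]   # chrom, s, e, strand, type
    te: list[tuple[str, int, int, str]]           # chrom, s, e, strand
    truth: TruthTable
    catalog: dict[str, str]
    contaminant_genome: dict[str, str]

    @property
    def transcripts(self) -> dict[str, str]:
        return {g.gene_id + ".1": g.transcript for g in self.genes}

    @property
    def expressed_transcripts(self) -> list[tuple[str, int, int, str, str]]:
        """(transcript_id, chrom, start, end, strand) genomic spans of
        transcripts with expression evidence."""
        return [
            (g.gene_id + ".1", g.chromosome, g.start, g.end, g.strand)
            for g in self.genes if g.expressed
        ]

    def precursor_reference(self, planted: PlantedMirna
                            ) -> tuple[str, int, int, int]:
        """Padded, strand-oriented precursor window for degradome work.

        Returns (sequence, mature 5' offset, star 5' offset, pad).
        """
        chrom = self.genome[planted.chromosome]
        s = max(0, planted.precursor_start - PRECURSOR_PAD)
        e = min(len(chrom), planted.precursor_end + PRECURSOR_PAD)
        seq = chrom[s:e]
        if planted.strand == "+":
            mature5 = planted.mature_start - s
            star5 = planted.star_start - s
        else:
            seq = revcomp(seq)
            mature5 = e - planted.mature_end
            star5 = e - planted.star_end
        return seq, mature5, star5, planted.precursor_start - s


# ---------------------------------------------------------------------------
# low-level builders
# ---------------------------------------------------------------------------

def random_dna(rng: np.random.Generator, n: int, gc: float = 0.42) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=p)])


def _non_pairing_base(rng: np.random.Generator, partner: str) -> str:
    choices = [b for b in "ACGT" if not base_pairs(b, partner)]
    return choices[rng.integers(len(choices))]


def plant_hairpin(mature: str, rng: np.random.Generator,
                  mismatches_in_duplex: int = 0, arm: str = "5p",
                  loop_len: int | None = None
                  ) -> tuple[str, int, int, str]:
    """Construct a stem-loop precursor around a mature sequence.

    The star arm is the reverse complement of the mature duplex region
    (all but its last two bases) with ``mismatches_in_duplex`` planted
    non-pairing positions, arranged so that the mature/star duplex
    carries 2-nt 3' overhangs on both strands.  Returns (precursor
    sequence, mature offset, star offset, star sequence); the precursor
    is guaranteed <= 250 nt.
    """
    mature = canonical(mature)
    L = len(mature)
    if not MIN_MATURE <= L <= MAX_MATURE:
        raise ValueError(f"mature must be {MIN_MATURE}-{MAX_MATURE} nt, got {L}")
    if mismatches_in_duplex > 4:
        raise ValueError("at most 4 duplex mismatches are supported")
    if arm not in ("5p", "3p"):
        raise ValueError("arm must be '5p' or '3p'")

    # The generator's contract is that folding the precursor yields the
    # planted mature/star duplex; random loops, overhangs and mismatch
    # placements can offer the maximum-pairing folder equal-or-better
    # alternative pairings, so the construction is rejection-sampled
    # until the fold reproduces the duplex.
    from .fold import max_pair_structure   # local import, avoids cycle

    needed = (L - 2) - mismatches_in_duplex
    best = None
    for _ in range(200):
        core = list(revcomp(mature[: L - 2]))  # core[j] pairs mature[L-3-j]
        if mismatches_in_duplex:
            # keep mismatches off the duplex ends: the stem stays anchored
            pos = rng.choice(np.arange(2, len(core) - 2),
                             size=mismatches_in_duplex, replace=False)
            for j in sorted(int(p) for p in pos):
                core[j] = _non_pairing_base(rng, mature[L - 3 - j])
        overhang = "".join(
            _non_pairing_base(rng, mature[k]) for k in (L - 2, L - 1)
        )
        star = "".join(core) + overhang
        n_loop = int(loop_len if loop_len is not None
                     else rng.integers(MIN_LOOP_LEN, MAX_LOOP_LEN + 1))
        loop = random_dna(rng, n_loop)
        if arm == "5p":
            precursor = mature + loop + star
            mature_off, star_off = 0, L + n_loop
        else:
            precursor = star + loop + mature
            star_off, mature_off = 0, L + n_loop
        assert len(precursor) <= MAX_PRECURSOR
        _, _, partner = max_pair_structure(precursor)
        intended = sum(
            1 for i in range(L - 2)
            if partner[mature_off + i] == star_off + (L - 3 - i)
        )
        if best is None or intended > best[0]:
            best = (intended, precursor, mature_off, star_off, star)
        if intended >= needed:
            break
    _, precursor, mature_off, star_off, star = best
    return precursor, mature_off, star_off, star


def plant_phas_locus(trigger: str, cycles: int, strand: str,
                     rng: np.random.Generator,
                     extra_trigger: str | None = None
                     ) -> dict:
    """Build the transcript-oriented sequence of a phasiRNA locus.

    The block starts with a binding site complementary to ``trigger``;
    the predicted cleavage coordinate (the base opposite trigger
    position 10) is the first base of the phased register, and 21-nt
    phasiRNAs tile the block from there.  With ``extra_trigger`` a
    second site is placed downstream so its register is shifted by
    +31 nt (a distinct modulo-21 register on the same interval).

    Returns a dict with the block sequence and transcript-relative
    register bookkeeping; genomic placement happens in
    :func:`build_genome`.
    """
    if cycles < MIN_PHAS_CYCLES:
        raise ValueError(
            f"phasiRNA detection needs >= {MIN_PHAS_CYCLES} cycles, got {cycles}")
    if strand not in "+-":
        raise ValueError("strand must be '+' or '-'")
    trigger = canonical(trigger)
    lt = len(trigger)
    site = revcomp(trigger)
    c0 = lt - 10                       # first base of the phased register
    registers = [{"trigger": trigger, "t_start": c0}]
    tail_len = PHASE * cycles - (lt - c0)
    block = site + random_dna(rng, max(0, tail_len))
    if extra_trigger is not None:
        extra_trigger = canonical(extra_trigger)
        le = len(extra_trigger)
        c1 = c0 + PHASE + 10           # distinct register (+31 ≡ +10 mod 21)
        s1 = c1 - (le - 10)
        need = c1 + PHASE * cycles - len(block)
        if need > 0:
            block += random_dna(rng, need)
        block = block[:s1] + revcomp(extra_trigger) + block[s1 + le:]
        registers.append({"trigger": extra_trigger, "t_start": c1})
    # phasiRNA sequences are the 21-nt tiles of the final block
    for reg in registers:
        reg["phasirnas"] = [
            block[reg["t_start"] + PHASE * k: reg["t_start"] + PHASE * (k + 1)]
            for k in range(cycles)
        ]
        assert all(len(p) == PHASE for p in reg["phasirnas"])
        assert (reg["t_start"] - registers[0]["t_start"]) % PHASE in (0, 10)
    return {"block": block, "registers": registers, "cycles": cycles,
            "strand": strand}


# ---------------------------------------------------------------------------
# genome assembly
# ---------------------------------------------------------------------------

def _mature_classes(n: int) -> list[str]:
    """Catalog-class labels: half known, a fifth isomiR, the rest novel."""
    n_known = n // 2
    n_iso = n // 5
    return ["known"] * n_known + ["isomir"] * n_iso \
        + ["novel"] * (n - n_known - n_iso)


def _mirna_contexts(n: int) -> list[str]:
    base = ["intron", "exon", "3UTR", "intron"]
    ctx = base[:n]
    ctx += ["intergenic"] * (n - len(ctx))
    return ctx


def build_genome(config: SimulationConfig) -> SyntheticBundle:
    """Assemble the synthetic genome and truth table.

    Planted elements are laid out as non-overlapping blocks separated by
    random spacers; coordinates are exact and recorded in the truth
    table.  Raises :class:`PackingError` when the requested elements do
    not fit in ``genome_length``.
    """
    rng = np.random.default_rng([config.seed, 11])
    n_mir = config.n_mirnas
    classes = _mature_classes(n_mir)
    contexts = _mirna_contexts(n_mir)

    # -- mature sequences and hairpins (transcript-oriented) ----------
    matures: list[str] = []
    while len(matures) < n_mir:
        L = int(rng.choice([20, 21, 21, 21, 22, 22, 24]))
        seq = random_dna(rng, L, config.gc_fraction)
        if seq not in matures:
            matures.append(seq)
    hairpins = []
    for i, mature in enumerate(matures):
        arm = "3p" if i % 7 == 3 else "5p"
        # real plant duplexes essentially always carry mismatches; a
        # mismatch also keeps the star arm from being an exact
        # substring of the mature's target sites
        mm = [1, 2, 1, 3, 2, 1][i % 6]
        prec, m_off, s_off, star = plant_hairpin(
            mature, rng, mismatches_in_duplex=mm, arm=arm)
        hairpins.append({
            "mature": mature, "star": star, "precursor": prec,
            "m_off": m_off, "s_off": s_off, "arm": arm,
            "context": contexts[i], "cls": classes[i],
        })

    # -- phasiRNA locus blocks ----------------------------------------
    phas_blocks = []
    for j in range(config.n_phas_loci):
        trig = matures[j % max(1, n_mir)] if n_mir else random_dna(rng, 21)
        extra = None
        if j < config.n_dual_register and n_mir > 1:
            extra = matures[(j + n_mir // 2) % n_mir]
        strand = "+" if (j % 2 == 0 or extra is not None) else "-"
        # dual-phase loci carry two interleaved 21-nt registers whose
        # reads mutually count as off-register; they need the longer
        # span seen in real dual-phase loci (~17 cycles) to present
        # clean nine-cycle windows for each register
        cycles = config.phas_cycles + (7 if extra is not None else 0)
        phas_blocks.append(plant_phas_locus(
            trig, cycles, strand, rng, extra_trigger=extra))
        phas_blocks[-1]["triggers"] = [trig] + ([extra] if extra else [])

    # -- gene models (transcript-oriented parts) ----------------------
    hosted = [h for h in hairpins if h["context"] != "intergenic"]
    n_genes = n_mir + len(hosted) + 8 if n_mir else 6
    gene_parts = []
    target_assignments: dict[int, int] = {}   # gene index -> mirna index
    host_assignments: dict[int, int] = {}     # gene index -> hairpin index
    gi = 0
    for hi, h in enumerate(hairpins):
        if h["context"] != "intergenic":
            host_assignments[gi] = hi
            gi += 1
    for mi in range(n_mir):
        target_assignments[gi] = mi
        gi += 1
    n_genes = max(n_genes, gi + 2)

    for g in range(n_genes):
        u5 = int(rng.integers(60, 121))
        cds1 = int(rng.integers(80, 181))
        intron1 = int(rng.integers(150, 301))
        exon2 = int(rng.integers(170, 251))
        intron2 = int(rng.integers(150, 301))
        cds3 = int(rng.integers(80, 151))
        u3 = int(rng.integers(100, 181))
        strand = "+" if rng.random() < 0.5 else "-"
        part = {
            "u5": u5, "cds1": cds1, "intron1": intron1, "exon2": exon2,
            "intron2": intron2, "cds3": cds3, "u3": u3, "strand": strand,
            "host": host_assignments.get(g), "target": target_assignments.get(g),
        }
        hi = part["host"]
        if hi is not None:
            plen = len(hairpins[hi]["precursor"])
            ctx = hairpins[hi]["context"]
            if ctx == "intron":
                part["intron1"] = max(part["intron1"], plen + 40)
            elif ctx == "exon":
                part["exon2"] = max(part["exon2"], plen + 60)
            elif ctx == "3UTR":
                part["u3"] = max(part["u3"], plen + 30)
        gene_parts.append(part)

    # -- ncRNA and TE decoy blocks ------------------------------------
    ncrna_blocks = [(int(rng.integers(90, 301)),
                     ("rRNA", "tRNA", "snoRNA")[k % 3],
                     "+" if rng.random() < 0.5 else "-")
                    for k in range(5)]
    te_blocks = [(int(rng.integers(300, 1201)),
                  "+" if rng.random() < 0.5 else "-") for _ in range(8)]

    # -- pack blocks into chromosomes ---------------------------------
    blocks: list[tuple[str, object]] = []
    for g, part in enumerate(gene_parts):
        blocks.append(("gene", part))
    for hi, h in enumerate(hairpins):
        if h["context"] == "intergenic":
            blocks.append(("mirna", hi))
    for pj, pb in enumerate(phas_blocks):
        blocks.append(("phas", pj))
    for nb in ncrna_blocks:
        blocks.append(("ncrna", nb))
    for tb in te_blocks:
        blocks.append(("te", tb))

    def block_length(kind, payload) -> int:
        if kind == "gene":
            p = payload
            return (p["u5"] + p["cds1"] + p["intron1"] + p["exon2"]
                    + p["intron2"] + p["cds3"] + p["u3"])
        if kind == "mirna":
            return len(hairpins[payload]["precursor"])
        if kind == "phas":
            return len(phas_blocks[payload]["block"])
        if kind in ("ncrna", "te"):
            return payload[0]
        raise AssertionError(kind)

    n_chrom = max(1, config.n_chromosomes)
    chrom_len = config.genome_length // n_chrom
    chrom_blocks: list[list] = [[] for _ in range(n_chrom)]
    chrom_used = [0] * n_chrom
    min_spacer = 30
    for idx, (kind, payload) in enumerate(blocks):
        c = idx % n_chrom
        chrom_blocks[c].append((kind, payload))
        chrom_used[c] += block_length(kind, payload) + min_spacer
    for c in range(n_chrom):
        if chrom_used[c] + min_spacer > chrom_len:
            raise PackingError(
                f"genome_length={config.genome_length} too small: chr{c + 1} "
                f"needs {chrom_used[c] + min_spacer} bases for "
                f"{len(chrom_blocks[c])} planted blocks")

    genome: dict[str, str] = {}
    genes: list[GeneModel] = []
    ncrna_out, te_out = [], []
    truth = TruthTable()
    mir_done: dict[int, PlantedMirna] = {}

    for c in range(n_chrom):
        name = f"chr{c + 1}"
        this_len = chrom_len if c < n_chrom - 1 else \
            config.genome_length - chrom_len * (n_chrom - 1)
        free = this_len - sum(block_length(k, p) for k, p in chrom_blocks[c])
        nb = len(chrom_blocks[c])
        # random spacer split with a floor
        w = rng.dirichlet(np.ones(nb + 1))
        spacers = (w * (free - min_spacer * (nb + 1))).astype(int) + min_spacer
        pieces: list[str] = []
        pos = 0

        def emit(seq: str) -> int:
            nonlocal pos
            start = pos
            pieces.append(seq)
            pos += len(seq)
            return start

        for b, (kind, payload) in enumerate(chrom_blocks[c]):
            emit(random_dna(rng, int(spacers[b]), config.gc_fraction))
            if kind == "gene":
                g0 = pos
                gene = _emit_gene(name, g0, payload, hairpins, matures,
                                  rng, config, emit, truth, mir_done)
                genes.append(gene)
            elif kind == "mirna":
                hi = payload
                h = hairpins[hi]
                strand = "+" if hi % 3 != 2 else "-"
                seq = h["precursor"] if strand == "+" else revcomp(h["precursor"])
                g0 = emit(seq)
                mir_done[hi] = _mirna_record(
                    hi, h, name, g0, strand, None, "n/a")
            elif kind == "phas":
                pj = payload
                pb = phas_blocks[pj]
                seq = pb["block"] if pb["strand"] == "+" else revcomp(pb["block"])
                g0 = emit(seq)
                _record_phas(truth, pj, pb, name, g0, matures, mir_done,
                             hairpins)
            elif kind == "ncrna":
                length, nctype, strand = payload
                g0 = emit(random_dna(rng, length, config.gc_fraction))
                ncrna_out.append((name, g0, g0 + length, strand, nctype))
            elif kind == "te":
                length, strand = payload
                g0 = emit(random_dna(rng, length, config.gc_fraction))
                te_out.append((name, g0, g0 + length, strand))
        emit(random_dna(rng, this_len - pos, config.gc_fraction))
        genome[name] = "".join(pieces)
        assert len(genome[name]) == this_len

    for hi in sorted(mir_done):
        truth.planted_mirnas.append(mir_done[hi])

    _assign_abundances(truth, config, rng)

    catalog = _build_catalog(truth, rng)
    contaminant = {"contig1": random_dna(
        np.random.default_rng([config.seed, 23]),
        config.contaminant_genome_length, 0.55)}

    bundle = SyntheticBundle(
        config=config, genome=genome, genes=genes, ncrna=ncrna_out,
        te=te_out, truth=truth, catalog=catalog,
        contaminant_genome=contaminant)
    _check_consistency(bundle)
    return bundle


def _mirna_record(hi, h, chrom, g0, strand, host_gene, orientation
                  ) -> PlantedMirna:
    plen = len(h["precursor"])
    lm, ls = len(h["mature"]), len(h["star"])
    if strand == "+":
        ms, me = g0 + h["m_off"], g0 + h["m_off"] + lm
        ss, se = g0 + h["s_off"], g0 + h["s_off"] + ls
    else:
        ms, me = g0 + plen - h["m_off"] - lm, g0 + plen - h["m_off"]
        ss, se = g0 + plen - h["s_off"] - ls, g0 + plen - h["s_off"]
    return PlantedMirna(
        mirna_id=f"mir{hi + 1:03d}", mature=h["mature"], star=h["star"],
        chromosome=chrom, precursor_start=g0, precursor_end=g0 + plen,
        strand=strand, mature_start=ms, mature_end=me,
        star_start=ss, star_end=se, context=h["context"],
        host_gene=host_gene, orientation=orientation, arm=h["arm"],
        catalog_class=h["cls"])


def _emit_gene(chrom, g0, part, hairpins, matures, rng, config, emit,
               truth, mir_done) -> GeneModel:
    """Build one gene block (possibly hosting a precursor and/or a
    planted target site) and emit its genomic sequence."""
    hi = part["host"]
    mi = part["target"]
    strand = part["strand"]

    u5 = random_dna(rng, part["u5"], config.gc_fraction)
    cds1 = random_dna(rng, part["cds1"], config.gc_fraction)
    intron1 = random_dna(rng, part["intron1"], config.gc_fraction)
    exon2 = random_dna(rng, part["exon2"], config.gc_fraction)
    intron2 = random_dna(rng, part["intron2"], config.gc_fraction)
    cds3 = random_dna(rng, part["cds3"], config.gc_fraction)
    u3 = random_dna(rng, part["u3"], config.gc_fraction)

    prec_t_off = None     # transcript-oriented offset of precursor in block
    prec_sense = True
    if hi is not None:
        h = hairpins[hi]
        pseq = h["precursor"]
        prec_sense = not (h["context"] == "intron" and hi % 5 == 4)
        ins = pseq if prec_sense else revcomp(pseq)
        if h["context"] == "intron":
            intron1 = intron1[:20] + ins + intron1[20 + len(ins):]
            prec_t_off = part["u5"] + part["cds1"] + 20
        elif h["context"] == "exon":
            exon2 = exon2[:20] + ins + exon2[20 + len(ins):]
            prec_t_off = part["u5"] + part["cds1"] + part["intron1"] + 20
        elif h["context"] == "3UTR":
            u3 = u3[:10] + ins + u3[10 + len(ins):]
            prec_t_off = (part["u5"] + part["cds1"] + part["intron1"]
                          + part["exon2"] + part["intron2"] + part["cds3"] + 10)

    site_t_off = None
    if mi is not None:
        site = revcomp(matures[mi])
        off = max(30, part["exon2"] - len(site) - 40)
        exon2 = exon2[:off] + site + exon2[off + len(site):]
        site_t_off = off   # within exon2

    block_t = u5 + cds1 + intron1 + exon2 + intron2 + cds3 + u3
    B = len(block_t)
    gseq = block_t if strand == "+" else revcomp(block_t)
    emit(gseq)

    def to_genomic(ts: int, te: int) -> tuple[int, int]:
        if strand == "+":
            return g0 + ts, g0 + te
        return g0 + B - te, g0 + B - ts

    e1 = (0, part["u5"] + part["cds1"])
    i1_end = e1[1] + len(intron1)
    e2 = (i1_end, i1_end + len(exon2))
    i2_end = e2[1] + part["intron2"]
    e3 = (i2_end, i2_end + part["cds3"] + len(u3))
    exons_t = [e1, e2, e3]
    five_t = [(0, part["u5"])]
    three_t = [(e3[1] - len(u3), e3[1])]

    transcript = block_t[e1[0]:e1[1]] + block_t[e2[0]:e2[1]] \
        + block_t[e3[0]:e3[1]]
    gene_id = f"g{chrom}_{g0}"
    gene = GeneModel(
        gene_id=gene_id, chromosome=chrom, start=g0, end=g0 + B,
        strand=strand,
        exons=sorted(to_genomic(*t) for t in exons_t),
        five_utr=[to_genomic(*t) for t in five_t],
        three_utr=[to_genomic(*t) for t in three_t],
        transcript=transcript,
        expressed=(g0 % 7 != 0) if hi is None else True,
    )

    if hi is not None and prec_t_off is not None:
        h = hairpins[hi]
        pstrand = strand if prec_sense else ("-" if strand == "+" else "+")
        pg0, _ = to_genomic(prec_t_off, prec_t_off + len(h["precursor"]))
        mir_done[hi] = _mirna_record(
            hi, h, chrom, pg0, pstrand, gene_id,
            "sense" if prec_sense else "antisense")

    if mi is not None and site_t_off is not None:
        lsite = len(matures[mi])
        t_site = (e1[1] - e1[0]) + site_t_off     # spliced transcript offset
        truth.planted_targets.append(PlantedTarget(
            mirna_id=f"mir{mi + 1:03d}", transcript_id=gene_id + ".1",
            site_start=t_site, site_end=t_site + lsite,
            cleavage_position=t_site + lsite - 10 + 1,
        ))
    return gene


def _record_phas(truth, pj, pb, chrom, g0, matures, mir_done, hairpins):
    block = pb["block"]
    B = len(block)
    strand = pb["strand"]
    registers = []
    starts, ends = [], []
    for r, reg in enumerate(pb["registers"]):
        t0 = reg["t_start"]
        n = len(reg["phasirnas"]) * PHASE
        if strand == "+":
            phase_start = g0 + t0
            phasirnas = reg["phasirnas"]
            starts.append(g0 + t0)
            ends.append(g0 + t0 + n)
        else:
            # transcript index t maps to genomic g0 + B - 1 - t; a
            # phasiRNA's 5' end sits at the genomic end of its window
            # and its register index is (5' end - 2)
            first5 = g0 + B - 1 - t0
            phase_start = first5 - 2
            phasirnas = reg["phasirnas"]
            starts.append(g0 + B - (t0 + n))
            ends.append(g0 + B - t0)
        trig_seq = reg["trigger"]
        trig_id = next(
            (f"mir{k + 1:03d}" for k, m in enumerate(matures) if m == trig_seq),
            "external")
        registers.append(PlantedRegister(
            register_id=f"phas{pj + 1:02d}r{r + 1}", trigger_id=trig_id,
            phase_start=phase_start, cleavage=phase_start,
            register=phase_start % PHASE, phasirnas=list(phasirnas)))
    span = max(ends) - min(starts)
    truth.planted_phas.append(PlantedPhas(
        locus_id=f"phas{pj + 1:02d}", chromosome=chrom,
        start=min(starts),
        end=min(starts) + -(-span // PHASE) * PHASE,
        strand=strand, registers=registers))


def _assign_abundances(truth: TruthTable, config: SimulationConfig,
                       rng: np.random.Generator) -> None:
    libs = config.libraries
    n = len(libs)
    if n == 0:
        return
    novel_seen = 0
    for i, m in enumerate(truth.planted_mirnas):
        if m.catalog_class == "known":
            chosen = list(libs)
        elif m.catalog_class == "isomir":
            k = max(1, (n + 1) // 2)
            chosen = [libs[(i + t) % n] for t in range(k)]
        else:
            novel_seen += 1
            if novel_seen <= 2:
                chosen = [libs[i % n]]      # organ-specific novels
            else:
                chosen = [libs[(i + t) % n] for t in range(min(2, n))]
        for lib in chosen:
            w = float(rng.uniform(0.6, 1.4))
            m.abundance[lib] = w
            m.star_abundance[lib] = w * float(rng.uniform(0.05, 0.20))
    for j, locus in enumerate(truth.planted_phas):
        k = min(3, n)
        for t in range(k):
            locus.abundance[libs[(j + t) % n]] = float(rng.uniform(0.2, 0.4))


def _build_catalog(truth: TruthTable, rng: np.random.Generator
                   ) -> dict[str, str]:
    """miRBase-style reference catalog implied by the planted classes.

    Known matures appear verbatim; isomiR matures get a family
    representative two substitutions away; plus a few decoy entries.
    Sequences are written as RNA (U) to exercise canonicalization.
    """
    catalog: dict[str, str] = {}
    fam = 0
    for m in truth.planted_mirnas:
        if m.catalog_class == "known":
            fam += 1
            catalog[f"pvu-miR{fam:04d}"] = m.mature.replace("T", "U")
        elif m.catalog_class == "isomir":
            fam += 1
            seq = list(m.mature)
            pos = rng.choice(len(seq) - 4, size=2, replace=False) + 2
            for p in sorted(int(x) for x in pos):
                seq[p] = _non_pairing_base(rng, revcomp(seq[p]))
            catalog[f"pvu-miR{fam:04d}"] = "".join(seq).replace("T", "U")
    for d in range(5):
        fam += 1
        catalog[f"ath-miR{fam:04d}"] = random_dna(rng, 21).replace("T", "U")
    return catalog


def _check_consistency(bundle: SyntheticBundle) -> None:
    """Every planted sequence must be findable verbatim in the genome."""
    for m in bundle.truth.planted_mirnas:
        chrom = bundle.genome[m.chromosome]
        prec = chrom[m.precursor_start:m.precursor_end]
        if m.strand == "-":
            prec = revcomp(prec)
        assert m.mature in prec and m.star in prec, m.mirna_id
        g_m = chrom[m.mature_start:m.mature_end]
        assert (g_m if m.strand == "+" else revcomp(g_m)) == m.mature
    for locus in bundle.truth.planted_phas:
        chrom = bundle.genome[locus.chromosome]
        for reg in locus.registers:
            for k, p in enumerate(reg.phasirnas):
                if locus.strand == "+":
                    s = reg.phase_start + PHASE * k
                    assert chrom[s:s + PHASE] == p, reg.register_id
                else:
                    e5 = reg.phase_start + 2 - PHASE * k
                    assert revcomp(chrom[e5 - PHASE + 1:e5 + 1]) == p, \
                        reg.register_id
    for t in bundle.truth.planted_targets:
        tr = {g.gene_id + ".1": g.transcript for g in bundle.genes}
        seq = tr[t.transcript_id][t.site_start:t.site_end]
        mature = next(m.mature for m in bundle.truth.planted_mirnas
                      if m.mirna_id == t.mirna_id)
        assert seq == revcomp(mature), t.mirna_id


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

def _planted_footprints(bundle: SyntheticBundle) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {c: IntervalTree() for c in bundle.genome}
    for m in bundle.truth.planted_mirnas:
        s = max(0, m.precursor_start - 40)
        trees[m.chromosome][s:m.precursor_end + 40] = "mirna"
    for locus in bundle.truth.planted_phas:
        s = max(0, locus.start - 40)
        trees[locus.chromosome][s:locus.end + 40] = "phas"
    # gene bodies stay eligible for degradation noise
    return trees


def simulate_srna_libraries(bundle: SyntheticBundle,
                            outdir: str | Path | None = None
                            ) -> tuple[dict[str, dict[str, int]], pd.DataFrame]:
    """Sample collapsed small RNA libraries from the planted truth.

    Planted reads are multinomial at each library's planted budget;
    background noise is drawn from a per-library pool of genome
    substrings ("degradation hotspots") that never overlap a planted
    element; the designated contaminated library additionally carries
    reads copied from the contaminant genome.  Returns ({library:
    {sequence: count}}, sampled-count table).
    """
    config = bundle.config
    truth = bundle.truth
    footprints = _planted_footprints(bundle)
    planted_seqs = truth.planted_sequences
    chrom_names = list(bundle.genome)
    chrom_lens = np.array([len(bundle.genome[c]) for c in chrom_names], float)

    libraries: dict[str, dict[str, int]] = {}
    rows = []
    for li, lib in enumerate(config.libraries):
        rng = np.random.default_rng([config.seed, 101 + li])
        seqs: list[str] = []
        weights: list[float] = []
        for m in truth.planted_mirnas:
            if m.abundance.get(lib, 0) > 0:
                seqs.append(m.mature)
                weights.append(m.abundance[lib])
                seqs.append(m.star)
                weights.append(m.star_abundance[lib])
        for locus in truth.planted_phas:
            w = locus.abundance.get(lib, 0)
            if w > 0:
                for reg in locus.registers:
                    for p in reg.phasirnas:
                        seqs.append(p)
                        weights.append(w * float(rng.uniform(0.8, 1.2)))
        depth = config.library_depth
        contaminated = lib == config.contaminated_library
        n_contam = int(round(depth * config.contaminant_fraction)) \
            if contaminated else 0
        n_noise = int(round(depth * config.noise_fraction))
        n_planted = depth - n_noise - n_contam

        counts: dict[str, int] = {}
        if seqs and n_planted > 0:
            w = np.array(weights) / np.sum(weights)
            sampled = rng.multinomial(n_planted, w)
            for s, c in zip(seqs, sampled):
                if c:
                    counts[s] = counts.get(s, 0) + int(c)

        if n_noise > 0:
            pool = _noise_pool(bundle, rng, config.noise_pool_size,
                               footprints, planted_seqs,
                               chrom_names, chrom_lens)
            w = rng.uniform(0.5, 1.5, size=len(pool))
            sampled = rng.multinomial(n_noise, w / w.sum())
            for s, c in zip(pool, sampled):
                if c:
                    counts[s] = counts.get(s, 0) + int(c)

        if n_contam > 0:
            cseq = bundle.contaminant_genome["contig1"]
            pool = []
            while len(pool) < config.contaminant_pool_size:
                L = int(rng.integers(18, 26))
                s0 = int(rng.integers(0, len(cseq) - L))
                frag = cseq[s0:s0 + L]
                if frag not in planted_seqs:
                    pool.append(frag)
            w = rng.uniform(0.5, 1.5, size=len(pool))
            sampled = rng.multinomial(n_contam, w / w.sum())
            for s, c in zip(pool, sampled):
                if c:
                    counts[s] = counts.get(s, 0) + int(c)
        truth.contaminant_read_count[lib] = n_contam
        libraries[lib] = counts
        for s, c in counts.items():
            rows.append((lib, s, c))

    table = pd.DataFrame(rows, columns=["library", "sequence", "count"])
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for lib, counts in libraries.items():
            recs = [(f"tag{i}_x{c}", s)
                    for i, (s, c) in enumerate(sorted(counts.items()))]
            write_fasta(outdir / f"{lib}.fa", recs)
        table.to_csv(outdir / "expected_counts.tsv", sep="\t", index=False)
    return libraries, table


def _noise_pool(bundle, rng, size, footprints, planted_seqs,
                chrom_names, chrom_lens) -> list[str]:
    pool: list[str] = []
    p = chrom_lens / chrom_lens.sum()
    guard = 0
    while len(pool) < size:
        guard += 1
        if guard > size * 50:
            raise RuntimeError("noise pool rejection sampling stalled")
        ci = int(rng.choice(len(chrom_names), p=p))
        chrom = chrom_names[ci]
        L = int(rng.integers(18, 26))
        s0 = int(rng.integers(0, int(chrom_lens[ci]) - L))
        if footprints[chrom][s0:s0 + L]:
            continue
        frag = bundle.genome[chrom][s0:s0 + L]
        if rng.random() < 0.5:
            frag = revcomp(frag)
        if frag in planted_seqs or "N" in frag:
            continue
        pool.append(frag)
    return pool


# ---------------------------------------------------------------------------
# degradome simulation
# ---------------------------------------------------------------------------

def degradome_references(bundle: SyntheticBundle) -> dict[str, str]:
    """Sense-strand reference set for degradome mapping: spliced
    transcripts plus padded precursor windows."""
    refs = dict(bundle.transcripts)
    for m in bundle.truth.planted_mirnas:
        seq, _, _, _ = bundle.precursor_reference(m)
        refs[f"prec_{m.mirna_id}"] = seq
    return refs


def simulate_degradome(bundle: SyntheticBundle, peak_height: int = 50,
                       noise_per_position: int = 0,
                       outpath: str | Path | None = None
                       ) -> dict[str, int]:
    """Generate collapsed degradome 5'-end tags.

    For each planted target a peak of ``peak_height`` tags starts at the
    cleavage position; for each planted precursor, peaks at the mature
    and star 5' boundaries; every other reference position carries
    ``noise_per_position`` tags.  Tag length is 20 nt.
    """
    if noise_per_position >= peak_height:
        raise ValueError("peak_height must exceed noise_per_position")
    refs = degradome_references(bundle)
    peak_positions: dict[str, set[int]] = {r: set() for r in refs}
    counts: dict[str, int] = {}

    def add(ref_id: str, pos0: int, n: int) -> None:
        seq = refs[ref_id][pos0:pos0 + DEGRADOME_TAG_LEN]
        if len(seq) == DEGRADOME_TAG_LEN and n > 0:
            counts[seq] = counts.get(seq, 0) + n

    for t in bundle.truth.planted_targets:
        pos0 = t.cleavage_position - 1
        peak_positions[t.transcript_id].add(pos0)
        add(t.transcript_id, pos0, peak_height)
    for m in bundle.truth.planted_mirnas:
        ref_id = f"prec_{m.mirna_id}"
        _, mature5, star5, _ = bundle.precursor_reference(m)
        for pos0 in (mature5, star5):
            peak_positions[ref_id].add(pos0)
            add(ref_id, pos0, peak_height)
    if noise_per_position > 0:
        for ref_id, seq in refs.items():
            for pos0 in range(len(seq) - DEGRADOME_TAG_LEN + 1):
                if pos0 not in peak_positions[ref_id]:
                    add(ref_id, pos0, noise_per_position)
    if outpath is not None:
        recs = [(f"deg{i}_x{c}", s)
                for i, (s, c) in enumerate(sorted(counts.items()))]
        write_fasta(outpath, recs)
    return counts


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def write_bundle(bundle: SyntheticBundle, outdir: str | Path) -> None:
    """Write the bundle as plain-text standard formats (FASTA, GFF3,
    BED6, TSV) plus truth tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(outdir / "genome.fa", bundle.genome.items())
    write_fasta(outdir / "contaminant.fa", bundle.contaminant_genome.items())
    write_fasta(outdir / "catalog.fa", bundle.catalog.items())
    write_fasta(outdir / "transcripts.fa", bundle.transcripts.items())

    with open(outdir / "annotation.gff3", "w") as fh:
        fh.write("##gff-version 3\n")
        for g in bundle.genes:
            tid = g.gene_id + ".1"
            fh.write(_gff_row(g.chromosome, "gene", g.start, g.end, g.strand,
                              f"ID={g.gene_id}"))
            fh.write(_gff_row(g.chromosome, "mRNA", g.start, g.end, g.strand,
                              f"ID={tid};Parent={g.gene_id}"))
            for s, e in g.exons:
                fh.write(_gff_row(g.chromosome, "exon", s, e, g.strand,
                                  f"Parent={tid}"))
            for s, e in g.five_utr:
                fh.write(_gff_row(g.chromosome, "five_prime_UTR", s, e,
                                  g.strand, f"Parent={tid}"))
            for s, e in g.three_utr:
                fh.write(_gff_row(g.chromosome, "three_prime_UTR", s, e,
                                  g.strand, f"Parent={tid}"))
        for chrom, s, e, strand, nctype in bundle.ncrna:
            fh.write(_gff_row(chrom, nctype, s, e, strand,
                              f"ID={nctype}_{chrom}_{s}"))
    with open(outdir / "te.bed", "w") as fh:
        for i, (chrom, s, e, strand) in enumerate(bundle.te):
            fh.write(f"{chrom}\t{s}\t{e}\tTE{i + 1}\t0\t{strand}\n")
    pd.DataFrame(
        bundle.expressed_transcripts,
        columns=["transcript_id", "chromosome", "start", "end", "strand"],
    ).to_csv(outdir / "expressed_transcripts.tsv", sep="\t", index=False)

    mir_rows = [asdict(m) for m in bundle.truth.planted_mirnas]
    for r in mir_rows:
        r["abundance"] = json.dumps(r["abundance"])
        r["star_abundance"] = json.dumps(r["star_abundance"])
    pd.DataFrame(mir_rows).to_csv(outdir / "truth_mirnas.tsv", sep="\t",
                                  index=False)
    phas_rows = []
    for locus in bundle.truth.planted_phas:
        for reg in locus.registers:
            phas_rows.append({
                "locus_id": locus.locus_id, "chromosome": locus.chromosome,
                "start": locus.start, "end": locus.end,
                "strand": locus.strand, "register_id": reg.register_id,
                "trigger_id": reg.trigger_id, "phase_start": reg.phase_start,
                "cleavage": reg.cleavage, "register": reg.register,
                "phasirnas": ",".join(reg.phasirnas),
                "abundance": json.dumps(locus.abundance),
            })
    pd.DataFrame(phas_rows).to_csv(outdir / "truth_phas.tsv", sep="\t",
                                   index=False)
    pd.DataFrame([asdict(t) for t in bundle.truth.planted_targets]).to_csv(
        outdir / "truth_targets.tsv", sep="\t", index=False)


def _gff_row(chrom, ftype, start0, end0, strand, attrs) -> str:
    return (f"{chrom}\tsrnaome_sim\t{ftype}\t{start0 + 1}\t{end0}\t.\t"
            f"{strand}\t.\t{attrs}\n")
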