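"""End-to-end orchestration of the small-RNAome stages behind a single
declarative configuration.

Stage order: core (collapse + map + profiles) -> discovery -> annotation
-> targets -> degradome -> phasiRNA -> reports.  Every threshold the
method uses is a named configuration key with the method's default
value, so a default run is the canonical analysis; every output is a
plain-text table (TSV/GFF3/BED/JSON) and a manifest records input and
output checksums so re-runs are verifiable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from intervaltree import IntervalTree

from ._seq import read_fasta, iter_reads, revcomp
from . import core, discovery as disc, annotation as ann
from . import degradome as deg, phasing, reports, targets as tgt

NCRNA_TYPES = {"rRNA", "tRNA", "snoRNA", "snRNA", "ncRNA"}
PRECURSOR_DEGRADOME_PAD = 10


@dataclass
class Thresholds:
    """Named method parameters; defaults are the canonical analysis."""

    window: int = 250
    max_hits: int = 40
    mature_min: int = 18
    mature_max: int = 25
    expression_quantile: float = 0.05
    score_percentile: float = 0.95
    identity: float = 0.842
    target_cutoff: float = 3.0
    trigger_cutoff: float = 5.0
    degradome_p: float = 0.05
    phase_score: float = 15.0
    chi_p: float = 0.01
    min_windows: int = 3


@dataclass
class PipelineConfig:
    genome: str
    libraries: dict[str, str]
    annotation: str | None = None
    te: str | None = None
    catalog: str | None = None
    degradome: str | None = None
    contaminant: str | None = None
    transcripts: str | None = None
    expressed_transcripts: str | None = None
    conservation_genomes: dict[str, str] = field(default_factory=dict)
    seed: int = 1
    n_shuffles: int = 100
    thresholds: Thresholds = field(default_factory=Thresholds)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        thr = Thresholds(**raw.pop("thresholds", {}))
        return cls(thresholds=thr, **raw)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    def validate(self) -> None:
        for label, p in [("genome", self.genome),
                         *[(f"library {k}", v)
                           for k, v in self.libraries.items()]]:
            if p and not Path(p).exists():
                raise FileNotFoundError(f"missing input: {label} -> {p}")


@dataclass
class PrecursorCall:
    precursor_id: str
    candidate: disc.HairpinCandidate
    mature_id: str
    mature_class: str
    family: str
    context: ann.GenomicContext | None = None
    transcript_support: bool = False
    degradome_support: bool = False
    processing_p: float = 1.0


@dataclass
class PipelineResult:
    table: core.TagTable
    profiles: list[core.LibraryProfile]
    qualifying_by_library: dict[str, frozenset[str]]
    contamination: dict[str, float]
    discovery: disc.DiscoveryResult
    families: ann.FamilyResult | None
    mature_ids: dict[str, str]                # sequence -> id
    final_matures: dict[str, str]             # id -> sequence
    mature_classes: dict[str, str]            # sequence -> class
    precursor_calls: list[PrecursorCall]
    presence: pd.DataFrame | None
    venn: dict | None
    conservation: pd.DataFrame | None
    target_alignments: list[tgt.DuplexAlignment]
    signatures: deg.Signatures
    cleavage_calls: list[deg.CleavageCall]
    phas_loci: list[phasing.PhasLocus]
    summary: dict


# ---------------------------------------------------------------------------
# input readers
# ---------------------------------------------------------------------------

def read_ncrna_trees(gff3_path: str | Path
                     ) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    with open(gff3_path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) >= 8 and f[2] in NCRNA_TYPES:
                trees.setdefault(f[0], IntervalTree())[
                    int(f[3]) - 1:int(f[4])] = f[2]
    return trees


def read_te_trees(bed_path: str | Path) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    with open(bed_path) as fh:
        for line in fh:
            if not line.strip():
                continue
            f = line.split("\t")
            trees.setdefault(f[0], IntervalTree())[int(f[1]):int(f[2])] = \
                f[3] if len(f) > 3 else "TE"
    return trees


def read_expressed_transcripts(path: str | Path
                               ) -> list[tuple[str, str, int, int, str]]:
    df = pd.read_csv(path, sep="\t")
    return [tuple(r) for r in df[
        ["transcript_id", "chromosome", "start", "end", "strand"]
    ].itertuples(index=False)]


# ---------------------------------------------------------------------------
# the run
# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig,
                 outdir: str | Path | None = None) -> PipelineResult:
    """Run every stage from file inputs; write outputs and a manifest
    when ``outdir`` is given."""
    config.validate()
    genome = read_fasta(config.genome)
    library_counts = {}
    for lib, path in config.libraries.items():
        counts, stats = core.collapse_reads(iter_reads(path), lib)
        library_counts[lib] = (counts, stats)
    catalog = read_fasta(config.catalog) if config.catalog else {}
    ncrna = read_ncrna_trees(config.annotation) if config.annotation else {}
    te = read_te_trees(config.te) if config.te else {}
    annotation = ann.Annotation.from_gff3(config.annotation) \
        if config.annotation else None
    transcripts = read_fasta(config.transcripts) if config.transcripts else {}
    expressed = read_expressed_transcripts(config.expressed_transcripts) \
        if config.expressed_transcripts else []
    degradome_counts = {}
    if config.degradome:
        degradome_counts, _ = core.collapse_reads(
            iter_reads(config.degradome), "degradome", min_len=15, max_len=36)
    contaminant = read_fasta(config.contaminant) if config.contaminant else {}
    conservation_genomes = {
        name: read_fasta(path)
        for name, path in config.conservation_genomes.items()}
    result = run_in_memory(
        genome=genome, library_counts=library_counts, catalog=catalog,
        ncrna=ncrna, te=te, annotation=annotation, transcripts=transcripts,
        expressed_transcripts=expressed, degradome_counts=degradome_counts,
        contaminant=contaminant, conservation_genomes=conservation_genomes,
        seed=config.seed, n_shuffles=config.n_shuffles,
        thresholds=config.thresholds)
    if outdir is not None:
        write_outputs(result, Path(outdir), config)
    return result


def run_in_memory(
    genome: Mapping[str, str],
    library_counts: Mapping[str, tuple[dict[str, int], core.CollapseStats]],
    catalog: Mapping[str, str] | None = None,
    ncrna: Mapping[str, IntervalTree] | None = None,
    te: Mapping[str, IntervalTree] | None = None,
    annotation: ann.Annotation | None = None,
    transcripts: Mapping[str, str] | None = None,
    expressed_transcripts: list | None = None,
    degradome_counts: Mapping[str, int] | None = None,
    contaminant: Mapping[str, str] | None = None,
    conservation_genomes: Mapping[str, Mapping[str, str]] | None = None,
    seed: int = 1,
    n_shuffles: int = 100,
    thresholds: Thresholds | None = None,
) -> PipelineResult:
    """Run every stage on in-memory inputs (the library API; the file
    based :func:`run_pipeline` is a wrapper)."""
    thr = thresholds or Thresholds()
    catalog = catalog or {}
    transcripts = dict(transcripts or {})
    expressed_transcripts = expressed_transcripts or []
    degradome_counts = degradome_counts or {}

    # -- core ----------------------------------------------------------
    table = core.TagTable()
    for lib, (counts, stats) in library_counts.items():
        table.add_library(lib, counts, stats)
    table.hits = core.map_exact(table.sequences, genome)
    profiles = core.build_profiles(table, thr.expression_quantile)
    qualifying = {
        lib: core.expression_rank_threshold(
            table, lib, thr.expression_quantile)[1]
        for lib in table.libraries}
    qualifying_union = set().union(*qualifying.values()) \
        if qualifying else set()
    contamination = {}
    if contaminant:
        for lib in table.libraries:
            col = table.counts[lib]
            contamination[lib] = core.contamination_fraction(
                {s: int(c) for s, c in col.items() if c > 0}, contaminant)

    # -- discovery -----------------------------------------------------
    result = disc.discover(table, genome, qualifying_union, ncrna,
                           percentile=thr.score_percentile)

    # -- annotation ----------------------------------------------------
    mature_abundance = {
        c.mature: table.pooled_count(c.mature) for c in result.accepted}
    families = ann.cluster_families(mature_abundance, catalog,
                                    thr.identity) if mature_abundance \
        else None
    classes = families.classes if families else {}
    final_set = disc.select_final_matures(result, classes)
    calls_raw = disc.recover_family_precursors(final_set, result.accepted)

    order = sorted(final_set,
                   key=lambda s: (-table.pooled_count(s), s))
    mature_ids = {seq: f"m{idx + 1:04d}" for idx, seq in enumerate(order)}
    final_matures = {mid: seq for seq, mid in mature_ids.items()}
    precursor_calls: list[PrecursorCall] = []
    for i, cand in enumerate(sorted(
            calls_raw, key=lambda c: (c.chromosome, c.precursor_start))):
        mid = mature_ids[cand.mature]
        call = PrecursorCall(
            precursor_id=f"pre{i + 1:04d}", candidate=cand,
            mature_id=mid, mature_class=classes.get(cand.mature, "novel"),
            family=families.family_of.get(cand.mature, "") if families
            else "")
        if annotation is not None:
            call.context = ann.localize_precursor(
                call.precursor_id, cand.chromosome, cand.precursor_start,
                cand.precursor_end, cand.strand, annotation)
        call.transcript_support = ann.precursor_transcript_support(
            cand.chromosome, cand.precursor_start, cand.precursor_end,
            cand.strand, expressed_transcripts)
        precursor_calls.append(call)

    presence = venn = None
    if final_matures:
        presence = ann.presence_matrix(
            [mature_ids[s] for s in order],
            {lib: frozenset(mature_ids[s] for s in order if s in q)
             for lib, q in qualifying.items()})
        venn_counts, specific = ann.organ_distribution(presence)
        venn = {"classes": {"+".join(k): v for k, v in venn_counts.items()},
                "organ_specific": specific}
    conservation = None
    if conservation_genomes and final_matures:
        conservation = ann.conservation_scan(
            [final_matures[m] for m in sorted(final_matures)],
            conservation_genomes)

    # -- targets -------------------------------------------------------
    target_alignments = tgt.scan_transcripts(
        final_matures, transcripts, cutoff=thr.target_cutoff,
        inclusive=False) if transcripts and final_matures else []

    # -- degradome -----------------------------------------------------
    signatures: deg.Signatures = {}
    cleavage_calls: list[deg.CleavageCall] = []
    if degradome_counts:
        refs = dict(transcripts)
        prec_refs: dict[str, PrecursorCall] = {}
        for call in precursor_calls:
            cand = call.candidate
            chrom = genome[cand.chromosome]
            lo = max(0, cand.precursor_start - PRECURSOR_DEGRADOME_PAD)
            hi = min(len(chrom), cand.precursor_end + PRECURSOR_DEGRADOME_PAD)
            seq = chrom[lo:hi]
            if cand.strand == "-":
                seq = revcomp(seq)
            refs[call.precursor_id] = seq
            prec_refs[call.precursor_id] = call
        signatures = deg.map_degradome_tags(degradome_counts, refs)
        for pid, call in prec_refs.items():
            cand = call.candidate
            chrom = genome[cand.chromosome]
            lo = max(0, cand.precursor_start - PRECURSOR_DEGRADOME_PAD)
            hi = min(len(chrom), cand.precursor_end + PRECURSOR_DEGRADOME_PAD)
            if cand.strand == "+":
                m5 = cand.mature_genomic[0] - lo
                s5 = cand.star_genomic[0] - lo
            else:
                m5 = hi - cand.mature_genomic[1]
                s5 = hi - cand.star_genomic[1]
            ok, p = deg.validate_precursor_processing(
                hi - lo, m5, s5, signatures.get(pid, {}),
                alpha=thr.degradome_p)
            call.degradome_support = ok
            call.processing_p = p
        if transcripts and final_matures:
            cleavage_calls = deg.call_cleavage_targets(
                final_matures, transcripts,
                {t: s for t, s in signatures.items() if t in transcripts},
                n_shuffles=n_shuffles, seed=seed,
                cutoff=thr.target_cutoff, alpha=thr.degradome_p)

    # -- phasiRNA ------------------------------------------------------
    registers = phasing.collect_21nt_registers(table)
    phas_loci = phasing.call_phas_loci(
        registers, qualifying, te, expressed_transcripts,
        threshold=thr.phase_score, chi_alpha=thr.chi_p,
        min_windows=thr.min_windows)
    phasing.assign_triggers(phas_loci, final_matures, genome,
                            cutoff=thr.trigger_cutoff)

    class_counts: dict[str, int] = {}
    for seq in final_set:
        cls = classes.get(seq, "novel")
        class_counts[cls] = class_counts.get(cls, 0) + 1
    summary = {
        "n_libraries": len(table.libraries),
        "n_unique_tags": int(len(table.sequences)),
        "n_candidate_windows": len(result.rejections)
        + len(result.accepted),
        "n_accepted_candidates": len(result.accepted),
        "score_threshold": result.score_threshold,
        "n_final_matures": len(final_matures),
        "mature_class_counts": class_counts,
        "n_precursor_calls": len(precursor_calls),
        "n_target_alignments": len(target_alignments),
        "n_cleavage_calls": len(cleavage_calls),
        "n_phas_loci": len(phas_loci),
        "n_phas_triggered_in_phase": sum(
            1 for l in phas_loci if any(t.in_phase for t in l.triggers)),
    }
    return PipelineResult(
        table=table, profiles=profiles, qualifying_by_library=qualifying,
        contamination=contamination, discovery=result, families=families,
        mature_ids=mature_ids, final_matures=final_matures,
        mature_classes=classes, precursor_calls=precursor_calls,
        presence=presence, venn=venn, conservation=conservation,
        target_alignments=target_alignments, signatures=signatures,
        cleavage_calls=cleavage_calls, phas_loci=phas_loci, summary=summary)


# ---------------------------------------------------------------------------
# outputs
# ---------------------------------------------------------------------------

def write_outputs(res: PipelineResult, outdir: Path,
                  config: PipelineConfig | None = None) -> dict:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    res.table.to_frame().to_csv(outdir / "tags.tsv", sep="\t")
    reports.library_stats_table(res.profiles).to_csv(
        outdir / "report_library_stats.tsv", sep="\t")
    with open(outdir / "hits.bed", "w") as fh:
        for i, seq in enumerate(res.table.sequences):
            for h in res.table.hits.get(seq, ()):
                fh.write(f"{h.chromosome}\t{h.start}\t{h.end}\ttag{i}\t"
                         f"{res.table.pooled_count(seq)}\t{h.strand}\n")

    rej = pd.DataFrame(
        [(r.window.chromosome, r.window.start, r.window.end,
          r.window.strand, r.window.mature, r.reason, round(r.score, 4))
         for r in res.discovery.rejections],
        columns=["chromosome", "start", "end", "strand", "mature",
                 "reason", "score"])
    rej.to_csv(outdir / "rejections.tsv", sep="\t", index=False)

    with open(outdir / "precursors.gff3", "w") as fh:
        fh.write("##gff-version 3\n")
        for call in res.precursor_calls:
            c = call.candidate
            attrs = (f"ID={call.precursor_id};mature={call.mature_id};"
                     f"class={call.mature_class};family={call.family};"
                     f"score={c.score:.3f}")
            fh.write(f"{c.chromosome}\tsrnaome\tpre_miRNA\t"
                     f"{c.precursor_start + 1}\t{c.precursor_end}\t.\t"
                     f"{c.strand}\t.\t{attrs}\n")
            m_lo, m_hi = c.mature_genomic
            s_lo, s_hi = c.star_genomic
            fh.write(f"{c.chromosome}\tsrnaome\tmiRNA\t{m_lo + 1}\t{m_hi}"
                     f"\t.\t{c.strand}\t.\tParent={call.precursor_id}\n")
            fh.write(f"{c.chromosome}\tsrnaome\tmiRNA_star\t{s_lo + 1}\t"
                     f"{s_hi}\t.\t{c.strand}\t.\t"
                     f"Parent={call.precursor_id}\n")
    with open(outdir / "precursors.fa", "w") as fh:
        for call in res.precursor_calls:
            fh.write(f">{call.precursor_id} {call.mature_id}\n"
                     f"{call.candidate.sequence}\n")

    mature_rows = []
    for mid, seq in sorted(res.final_matures.items()):
        row = {"mature_id": mid, "sequence": seq,
               "class": res.mature_classes.get(seq, "novel"),
               "family": res.families.family_of.get(seq, "")
               if res.families else "",
               "n_genome_hits": res.table.n_genome_hits(seq),
               "pooled_count": res.table.pooled_count(seq)}
        if res.presence is not None and mid in res.presence.index:
            for lib in res.presence.columns:
                row[f"present_{lib}"] = bool(res.presence.loc[mid, lib])
        if res.conservation is not None and seq in res.conservation.index:
            for sp in res.conservation.columns:
                row[f"conserved_{sp}"] = bool(res.conservation.loc[seq, sp])
        mature_rows.append(row)
    pd.DataFrame(mature_rows).to_csv(outdir / "matures.tsv", sep="\t",
                                     index=False)

    ctx_rows = [
        {"precursor_id": c.precursor_id, "class": c.mature_class,
         "category": c.context.category if c.context else "intergenic",
         "host_gene": (c.context.host_gene or "") if c.context else "",
         "orientation": c.context.orientation if c.context else "n/a",
         "transcript_support": c.transcript_support,
         "degradome_support": c.degradome_support,
         "processing_p": round(c.processing_p, 6)}
        for c in res.precursor_calls]
    pd.DataFrame(ctx_rows).to_csv(outdir / "context.tsv", sep="\t",
                                  index=False)
    if res.venn is not None:
        with open(outdir / "venn.json", "w") as fh:
            json.dump(res.venn, fh, indent=1, sort_keys=True)

    pd.DataFrame(
        [(a.mirna_id, a.transcript_id, a.start + 1, a.end, a.expectation,
          a.cleavage_position, a.alignment) for a in res.target_alignments],
        columns=["mirna_id", "transcript_id", "site_start", "site_end",
                 "expectation", "cleavage_position", "alignment"],
    ).to_csv(outdir / "targets.tsv", sep="\t", index=False)

    pd.DataFrame(
        [(c.mirna_id, c.transcript_id, c.cleavage_position,
          c.peak_abundance, c.category, c.p_value)
         for c in res.cleavage_calls],
        columns=["mirna_id", "transcript_id", "cleavage_position",
                 "peak_abundance", "category", "p_value"],
    ).to_csv(outdir / "cleavage.tsv", sep="\t", index=False)

    phas_rows = []
    with open(outdir / "phas.gff3", "w") as gff:
        gff.write("##gff-version 3\n")
        for i, locus in enumerate(res.phas_loci):
            lid = f"PHAS{i + 1:03d}"
            gff.write(f"{locus.chromosome}\tsrnaome\tphased_siRNA_locus\t"
                      f"{locus.start + 1}\t{locus.end}\t"
                      f"{locus.max_score:.2f}\t{locus.strand_bias}\t.\t"
                      f"ID={lid};register={locus.register}\n")
            phas_rows.append({
                "locus_id": lid, "chromosome": locus.chromosome,
                "start": locus.start, "end": locus.end,
                "register": locus.register,
                "max_score": round(locus.max_score, 3),
                "chi_square": round(locus.chi_square, 3),
                "chi_p": locus.chi_p,
                "n_top5_windows": locus.n_top5_windows,
                "libraries": ",".join(sorted(locus.libraries_expressed)),
                "host_transcript": locus.host_transcript or "",
                "triggers": ";".join(
                    f"{t.mirna_id}@{t.cleavage_coordinate}"
                    f"(e={t.expectation:.1f},"
                    f"{'in' if t.in_phase else 'out'})"
                    for t in locus.triggers),
            })
    pd.DataFrame(phas_rows).to_csv(outdir / "phas.tsv", sep="\t",
                                   index=False)

    classes_per_precursor = [c.mature_class for c in res.precursor_calls]
    contexts_per_precursor = [
        c.context.category if c.context else "intergenic"
        for c in res.precursor_calls]
    reports.class_context_table(
        classes_per_precursor, contexts_per_precursor,
        {res.mature_ids[s]: cls for s, cls in res.mature_classes.items()
         if s in res.mature_ids},
    ).to_csv(outdir / "report_class_context.tsv", sep="\t")
    if res.presence is not None:
        id_classes = {mid: res.mature_classes.get(seq, "novel")
                      for mid, seq in res.final_matures.items()}
        reports.organ_distribution_report(res.presence, id_classes).to_csv(
            outdir / "report_organ.tsv", sep="\t")

    manifest = {
        "config": asdict(config) if config else None,
        "summary": res.summary,
        "checksums": {
            p.name: hashlib.sha256(p.read_bytes()).hexdigest()
            for p in sorted(outdir.glob("*"))
            if p.is_file() and p.name != "manifest.json"},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
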