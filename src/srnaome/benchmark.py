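"""Recovery harness: run the full pipeline on a synthetic bundle with
planted truth and score sensitivity, false-discovery rate, trigger
phasing and degradome recovery against the truth table."""

from __future__ import annotations

from intervaltree import IntervalTree

from . import annotation as ann
from . import pipeline as pl
from .core import CollapseStats
from .simulate import (SimulationConfig, build_genome, simulate_degradome,
                       simulate_srna_libraries)


def run_recovery(config: SimulationConfig | None = None,
                 n_shuffles: int = 100,
                 degradome_peak: int = 50,
                 degradome_noise: int = 1) -> dict:
    """Simulate, run every stage, and score recovery against the truth.

    Returns (metrics dict, bundle, pipeline result).  The simulation
    seed comes from ``config.seed`` and drives every random choice.
    """
    config = config or SimulationConfig()
    bundle = build_genome(config)
    libraries, _ = simulate_srna_libraries(bundle)
    degradome_counts = simulate_degradome(bundle, degradome_peak,
                                          degradome_noise)
    ncrna: dict[str, IntervalTree] = {}
    for chrom, s, e, _strand, nctype in bundle.ncrna:
        ncrna.setdefault(chrom, IntervalTree())[s:e] = nctype
    te: dict[str, IntervalTree] = {}
    for chrom, s, e, _strand in bundle.te:
        te.setdefault(chrom, IntervalTree())[s:e] = "TE"
    result = pl.run_in_memory(
        genome=bundle.genome,
        library_counts={
            lib: (c, CollapseStats(lib, sum(c.values())))
            for lib, c in libraries.items()},
        catalog=bundle.catalog, ncrna=ncrna, te=te,
        annotation=ann.Annotation.from_genes(bundle.genes),
        transcripts=bundle.transcripts,
        expressed_transcripts=bundle.expressed_transcripts,
        degradome_counts=degradome_counts,
        contaminant=bundle.contaminant_genome,
        seed=config.seed, n_shuffles=n_shuffles)
    return score_recovery(bundle, result), bundle, result


def score_recovery(bundle, result) -> dict:
    truth = bundle.truth
    found = set(result.final_matures.values())
    planted = truth.mature_sequences

    n_true = len(planted & found)
    n_false = len(found - planted)

    seq_to_id = {seq: mid for mid, seq in result.final_matures.items()}
    n_registers = n_registers_found = n_triggers_in_phase = 0
    matched_loci: set[int] = set()
    for locus in truth.planted_phas:
        for reg in locus.registers:
            n_registers += 1
            trigger_seq = next(
                m.mature for m in truth.planted_mirnas
                if m.mirna_id == reg.trigger_id)
            trigger_id = seq_to_id.get(trigger_seq)
            for li, called in enumerate(result.phas_loci):
                if called.chromosome == locus.chromosome \
                        and called.register == reg.register \
                        and called.start < locus.end \
                        and called.end > locus.start:
                    n_registers_found += 1
                    matched_loci.add(li)
                    if any(t.mirna_id == trigger_id and t.in_phase
                           for t in called.triggers):
                        n_triggers_in_phase += 1
                    break
    n_false_loci = len(result.phas_loci) - len(matched_loci)

    call_map = {(c.transcript_id, c.cleavage_position): c
                for c in result.cleavage_calls}
    n_targets_cat0 = sum(
        1 for t in truth.planted_targets
        if (c := call_map.get((t.transcript_id, t.cleavage_position)))
        is not None and c.category == 0 and c.p_value <= 0.05)

    n_validated = sum(1 for c in result.precursor_calls
                      if c.degradome_support)

    def pct(a, b):
        return 100.0 * a / b if b else 0.0

    return {
        "n_planted_mirnas": len(planted),
        "n_recovered_mirnas": n_true,
        "n_false_mirnas": n_false,
        "mirna_sensitivity_pct": pct(n_true, len(planted)),
        "mirna_fdr_pct": pct(n_false, max(1, len(found))),
        "n_planted_phas_registers": n_registers,
        "n_recovered_phas_registers": n_registers_found,
        "n_false_phas_loci": n_false_loci,
        "phas_sensitivity_pct": pct(n_registers_found, n_registers),
        "phas_fdr_pct": pct(n_false_loci, max(1, len(result.phas_loci))),
        "triggers_in_phase_pct": pct(n_triggers_in_phase, n_registers),
        "n_planted_targets": len(truth.planted_targets),
        "n_targets_category0": n_targets_cat0,
        "targets_category0_pct": pct(n_targets_cat0,
                                     len(truth.planted_targets)),
        "n_precursor_calls": len(result.precursor_calls),
        "n_degradome_validated": n_validated,
        "contamination_pct": result.contamination.get(
            bundle.config.contaminated_library, 0.0),
    }
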