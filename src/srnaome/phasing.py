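"""Detection of 21-nt phased siRNA (phasiRNA) loci and trigger
assignment.

21-nt reads are pooled on a register axis: a plus-strand read is
indexed by its 5'-end coordinate, a minus-strand read by its 5'-end
coordinate minus 2 — the 2-nt 3' overhang left by Dicer — so that the
two strands of one phased duplex fall in the same modulo-21 register
class.  A nine-cycle (189-nt) window starting at an occupied position
is scored

    score = (k - 2) * ln(1 + 10 * sum_phased / (1 + sum_unphased))

for k >= 3 occupied in-register cycle positions (0 otherwise), where
sum_phased is the read abundance at in-register positions of the window
and sum_unphased the abundance everywhere else in the window.  Windows
scoring >= 15 are merged per register into candidate loci, which must
additionally pass a one-sided chi-square enrichment test (p < 0.01), have
at least 3 in-register positions whose tags rank in the top 5 % of a
library, and not overlap a transposable element.

Trigger assignment scans the locus-spanning sequence in both
orientations with every mature miRNA at expectation <= 5; an assignment
is in phase when its predicted cleavage coordinate is congruent to the
locus phase start modulo 21 (zero tolerance).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
from scipy import stats

from ._seq import revcomp
from .core import TagTable
from .targets import TRIGGER_CUTOFF, scan_transcripts

PHASE = 21
WINDOW_CYCLES = 9
WINDOW_LEN = PHASE * WINDOW_CYCLES     # 189 nt
SCORE_THRESHOLD = 15.0
CHI_ALPHA = 0.01
MIN_TOP5_WINDOWS = 3
MINUS_STRAND_OFFSET = 2
TRIGGER_PAD = 90


@dataclass
class PositionInfo:
    """Pooled 21-nt read abundance at one register-axis position."""

    total: int = 0
    per_library: dict[str, int] = field(default_factory=dict)
    tags: set[str] = field(default_factory=set)
    plus: int = 0
    minus: int = 0


RegisterTable = dict[str, dict[int, PositionInfo]]


def collect_21nt_registers(table: TagTable) -> RegisterTable:
    """Register-axis abundance of all exactly-21-nt mapped tags."""
    registers: RegisterTable = {}
    for seq in table.sequences:
        if len(seq) != PHASE:
            continue
        hits = table.hits.get(seq, ())
        if not hits:
            continue
        counts = table.counts.loc[seq]
        pooled = int(counts.sum())
        if pooled == 0:
            continue
        for hit in hits:
            if hit.strand == "+":
                pos = hit.start
            else:
                pos = (hit.end - 1) - MINUS_STRAND_OFFSET
            chrom = registers.setdefault(hit.chromosome, {})
            info = chrom.setdefault(pos, PositionInfo())
            info.total += pooled
            info.tags.add(seq)
            if hit.strand == "+":
                info.plus += pooled
            else:
                info.minus += pooled
            for lib, c in counts.items():
                if c > 0:
                    info.per_library[lib] = info.per_library.get(lib, 0) \
                        + int(c)
    return registers


def phasing_score(sum_phased: float, sum_unphased: float, k: int) -> float:
    """Nine-cycle phasing score; 0 for fewer than 3 occupied cycles."""
    if k < 3:
        return 0.0
    return (k - 2) * math.log(1 + 10 * sum_phased / (1 + sum_unphased))


@dataclass
class PhaseWindow:
    chromosome: str
    window_start: int
    register: int
    sum_phased: int
    sum_unphased: int
    k: int
    score: float


def score_windows(registers: RegisterTable,
                  threshold: float = SCORE_THRESHOLD
                  ) -> list[PhaseWindow]:
    """Score a nine-cycle window at every occupied position; return the
    windows whose score reaches the threshold."""
    flagged: list[PhaseWindow] = []
    for chrom, positions in registers.items():
        occupied = np.array(sorted(positions), dtype=np.int64)
        totals = np.array([positions[p].total for p in occupied],
                          dtype=np.int64)
        for i, p in enumerate(occupied):
            j = int(np.searchsorted(occupied, p + WINDOW_LEN, side="left"))
            win_pos = occupied[i:j]
            win_tot = totals[i:j]
            in_reg = (win_pos - p) % PHASE == 0
            k = int(in_reg.sum())
            sp = int(win_tot[in_reg].sum())
            su = int(win_tot[~in_reg].sum())
            score = phasing_score(sp, su, k)
            if score >= threshold:
                flagged.append(PhaseWindow(
                    chromosome=chrom, window_start=int(p),
                    register=int(p) % PHASE, sum_phased=sp,
                    sum_unphased=su, k=k, score=score))
    return flagged


def chi_square_phase_test(in_phase: float, total: float,
                          alpha: float = CHI_ALPHA
                          ) -> tuple[float, float, bool]:
    """One-sided goodness-of-fit of in-phase abundance against the
    uniform expectation N/21 (1 degree of freedom).

    Returns (statistic, p, significant); only enrichment (observed
    in-phase above expectation) can be significant.
    """
    if total <= 0:
        return 0.0, 1.0, False
    exp_in = total / PHASE
    exp_out = total - exp_in
    out = total - in_phase
    stat = (in_phase - exp_in) ** 2 / exp_in + (out - exp_out) ** 2 / exp_out
    p = float(stats.chi2.sf(stat, df=1))
    return float(stat), p, bool(in_phase > exp_in and p < alpha)


@dataclass
class TriggerAssignment:
    mirna_id: str
    cleavage_coordinate: int     # register-axis genomic coordinate
    expectation: float
    in_phase: bool


@dataclass
class PhasLocus:
    chromosome: str
    start: int                   # register-axis, trimmed to occupied
    end: int                     # in-register positions (last + 21)
    register: int
    max_score: float
    chi_square: float
    chi_p: float
    n_top5_windows: int
    in_te: bool
    libraries_expressed: set[str]
    strand_bias: str             # '+', '-' or '.' for mixed
    host_transcript: str | None = None
    triggers: list[TriggerAssignment] = field(default_factory=list)

    @property
    def n_cycles(self) -> int:
        return (self.end - self.start) // PHASE


def call_phas_loci(
    registers: RegisterTable,
    qualifying_by_library: Mapping[str, frozenset[str]],
    te: Mapping[str, object] | None = None,
    transcripts: Iterable[tuple[str, str, int, int, str]] = (),
    threshold: float = SCORE_THRESHOLD,
    chi_alpha: float = CHI_ALPHA,
    min_windows: int = MIN_TOP5_WINDOWS,
) -> list[PhasLocus]:
    """Merge flagged windows into loci and apply the locus filters.

    Filter order: phasing score, chi-square, top-5 % window count, TE
    overlap.  ``te`` maps chromosomes to interval trees; ``transcripts``
    are (id, chrom, start, end, strand) spans used for host assignment.
    """
    flagged = score_windows(registers, threshold)
    loci: list[PhasLocus] = []
    groups: dict[tuple[str, int], list[PhaseWindow]] = {}
    for w in flagged:
        groups.setdefault((w.chromosome, w.register), []).append(w)
    for (chrom, register), wins in sorted(groups.items()):
        wins.sort(key=lambda w: w.window_start)
        merged: list[list[PhaseWindow]] = [[wins[0]]]
        for w in wins[1:]:
            if w.window_start <= merged[-1][-1].window_start + WINDOW_LEN:
                merged[-1].append(w)
            else:
                merged.append([w])
        positions = registers[chrom]
        for cluster in merged:
            span_lo = cluster[0].window_start
            span_hi = cluster[-1].window_start + WINDOW_LEN
            in_reg = [p for p in positions
                      if span_lo <= p < span_hi and (p - register) % PHASE == 0]
            if not in_reg:
                continue
            start = min(in_reg)
            end = max(in_reg) + PHASE
            # extend along contiguous occupied in-register positions:
            # leading/trailing cycles can fall outside flagged windows
            # when neighbouring registers contribute off-phase mass
            while start - PHASE in positions:
                start -= PHASE
            while end in positions:
                end += PHASE
            locus = _build_locus(chrom, start, end, register, cluster,
                                 positions, qualifying_by_library,
                                 te, transcripts, chi_alpha)
            if locus is not None and locus.n_top5_windows >= min_windows \
                    and not locus.in_te:
                loci.append(locus)
    return loci


def _build_locus(chrom, start, end, register, cluster, positions,
                 qualifying_by_library, te, transcripts, chi_alpha
                 ) -> PhasLocus | None:
    in_phase_total = 0
    out_total = 0
    n_top5 = 0
    libraries: set[str] = set()
    plus = minus = 0
    for p, info in positions.items():
        if not start <= p < end:
            continue
        if (p - register) % PHASE == 0:
            in_phase_total += info.total
            plus += info.plus
            minus += info.minus
            libraries |= {lib for lib, c in info.per_library.items() if c > 0}
            if any(tag in qual for tag in info.tags
                   for qual in qualifying_by_library.values()):
                n_top5 += 1
        else:
            out_total += info.total
    total = in_phase_total + out_total
    stat, p_value, significant = chi_square_phase_test(
        in_phase_total, total, alpha=chi_alpha)
    if not significant:
        return None
    in_te = False
    if te is not None:
        tree = te.get(chrom)
        in_te = bool(tree is not None and tree[start:end])
    host = None
    mid = (start + end) // 2
    for tid, tchrom, ts, te_, _strand in transcripts:
        if tchrom == chrom and ts <= mid < te_:
            host = tid
            break
    bias = "+" if minus == 0 else "-" if plus == 0 else "."
    return PhasLocus(
        chromosome=chrom, start=start, end=end, register=register,
        max_score=max(w.score for w in cluster),
        chi_square=stat, chi_p=p_value, n_top5_windows=n_top5,
        in_te=in_te, libraries_expressed=libraries, strand_bias=bias,
        host_transcript=host)


def assign_triggers(
    loci: list[PhasLocus],
    matures: Mapping[str, str],
    genome: Mapping[str, str],
    cutoff: float = TRIGGER_CUTOFF,
) -> None:
    """Scan each locus-spanning sequence for phase-triggering miRNAs.

    Both orientations are scanned (a phased locus is double-stranded);
    every alignment with expectation <= cutoff yields a
    TriggerAssignment with its register-axis cleavage coordinate and an
    exact in-phase flag relative to the locus start.
    """
    if not matures:
        return
    for locus in loci:
        chrom_seq = genome[locus.chromosome]
        lo = max(0, locus.start - TRIGGER_PAD)
        hi = min(len(chrom_seq), locus.end + TRIGGER_PAD)
        plus_seq = chrom_seq[lo:hi]
        for orient, seq in (("+", plus_seq), ("-", revcomp(plus_seq))):
            hits = scan_transcripts(matures, {"locus": seq},
                                    cutoff=cutoff, inclusive=True)
            for aln in hits:
                if orient == "+":
                    cleav_axis = lo + aln.cleavage_position - 1
                else:
                    # cleavage base in genomic coordinates, then shifted
                    # by the minus-strand register convention
                    cleav_genomic = hi - aln.cleavage_position
                    cleav_axis = cleav_genomic - MINUS_STRAND_OFFSET
                locus.triggers.append(TriggerAssignment(
                    mirna_id=aln.mirna_id,
                    cleavage_coordinate=cleav_axis,
                    expectation=aln.expectation,
                    in_phase=(cleav_axis - locus.start) % PHASE == 0))


def phase_score_track(registers: RegisterTable, chromosome: str,
                      start: int, end: int) -> list[tuple[int, float]]:
    """(position, score) pairs over a region — the per-locus phase-score
    profile used for locus figures."""
    out = []
    positions = registers.get(chromosome, {})
    occupied = sorted(positions)
    for p in occupied:
        if start <= p < end:
            win = [q for q in occupied if p <= q < p + WINDOW_LEN]
            in_reg = [q for q in win if (q - p) % PHASE == 0]
            sp = sum(positions[q].total for q in in_reg)
            su = sum(positions[q].total for q in win) - sp
            out.append((p, phasing_score(sp, su, len(in_reg))))
    return out
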