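"""miRNA precursor discovery: hairpin excision, folding, duplex
evaluation, scoring and the candidacy filters.

A mapped tag (16-36 nt, fewer than 40 genome hits, not overlapping an
annotated ncRNA) nominates candidate windows of at most 250 nt around
each of its hits.  Excision is duplex-guided: within the window the tag
must have a reverse-complementary partner arm (G:U wobble counts as
pairing) — a necessary condition for the downstream duplex criterion —
and the excised window spans tag, partner and a short flank.  Windows
whose ungapped partner leaves at most 4 positions unpaired are folded
with the maximum-base-pairing folder and evaluated against the plant
miRNA annotation criteria; windows with a weaker partner (up to 6
unpaired) are not folded but are still scored, forming the background
candidate pool over which the novel-mature score-percentile rule
operates.

Acceptance criteria (all must hold):
  (a) mature length 18-25 nt;
  (b) mature in the top 5 % of the most expressed mapped tags of at
      least one library;
  (c) the mature lies entirely on one arm (no mature base pairs with
      another mature base);
  (d) a star arm exists — the duplex partner from the structure,
      reported with 2-nt 3' overhangs;
  (e) at most 4 unpaired mature positions within the duplex and no
      bulge larger than 2 nt;
  (f) at least 60 % of precursor bases paired within the stem.
Rejections carry the first failed criterion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
from numba import njit

from ._seq import encode, revcomp
from .core import GenomeHit, TagTable
from .fold import MIN_FOLD_LEN, _CAN_PAIR, max_pair_structure

MAX_WINDOW = 250
MAX_GENOME_HITS = 40
MIN_MATURE, MAX_MATURE = 18, 25
# the ungapped screen counts the duplex's 2-nt overhang edges as
# unpaired, so its budgets sit 2 above the duplex criterion's
SCREEN_LOOSE = 8    # windows kept for the background score pool
SCREEN_FOLD = 6     # windows that proceed to folding/evaluation
FLANK = 15
MIN_LOOP = 3
DUPLEX_OVERHANG = 2
MAX_UNPAIRED_MATURE = 4
MAX_BULGE = 2
MIN_STEM_PAIRED = 0.60
SCORE_PERCENTILE = 0.95


@dataclass
class CandidateWindow:
    chromosome: str
    strand: str
    start: int                # genomic, 0-based half-open, <=250 nt
    end: int
    mature: str
    mature_off: int           # offset of the tag in the oriented window
    partner_off: int          # offset of the ungapped partner arm
    screen_mismatches: int
    mature_on_5p: bool        # tag arm precedes the partner arm

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class HairpinCandidate:
    window: CandidateWindow
    sequence: str             # oriented precursor (trimmed to the stem span)
    structure: str            # dot-bracket of the precursor span
    precursor_start: int      # genomic
    precursor_end: int
    mature_off: int           # within the precursor span
    star_off: int
    star_len: int
    paired_mature: int
    score: float = 0.0
    mature_reads: int = 0
    star_reads: int = 0
    other_reads: int = 0

    @property
    def mature(self) -> str:
        return self.window.mature

    @property
    def chromosome(self) -> str:
        return self.window.chromosome

    @property
    def strand(self) -> str:
        return self.window.strand

    def genomic_arm(self, off: int, length: int) -> tuple[int, int]:
        """Map a precursor-span offset to genomic coordinates."""
        if self.strand == "+":
            return self.precursor_start + off, self.precursor_start + off + length
        return self.precursor_end - off - length, self.precursor_end - off

    @property
    def mature_genomic(self) -> tuple[int, int]:
        return self.genomic_arm(self.mature_off, len(self.mature))

    @property
    def star_genomic(self) -> tuple[int, int]:
        return self.genomic_arm(self.star_off, self.star_len)


@dataclass
class Rejection:
    window: CandidateWindow
    reason: str
    score: float = 0.0


@dataclass
class DiscoveryResult:
    accepted: list[HairpinCandidate]
    rejections: list[Rejection]
    all_scores: np.ndarray        # accepted + background candidate scores
    score_threshold: float


class ReadStartIndex:
    """5'-end positions and pooled counts of mapped tags, per
    (chromosome, strand); used to attribute reads to precursor arms."""

    def __init__(self, table: TagTable) -> None:
        buckets: dict[tuple[str, str], dict[int, int]] = {}
        for seq in table.sequences:
            pooled = table.pooled_count(seq)
            for hit in table.hits.get(seq, ()):
                five = hit.start if hit.strand == "+" else hit.end - 1
                key = (hit.chromosome, hit.strand)
                buckets.setdefault(key, {})
                buckets[key][five] = buckets[key].get(five, 0) + pooled
        self._pos: dict[tuple[str, str], np.ndarray] = {}
        self._cum: dict[tuple[str, str], np.ndarray] = {}
        for key, d in buckets.items():
            pos = np.array(sorted(d), dtype=np.int64)
            counts = np.array([d[p] for p in pos], dtype=np.int64)
            self._pos[key] = pos
            self._cum[key] = np.concatenate([[0], np.cumsum(counts)])

    def reads_between(self, chromosome: str, strand: str,
                      lo: int, hi: int) -> int:
        """Pooled count of tag 5' ends in [lo, hi)."""
        key = (chromosome, strand)
        if key not in self._pos:
            return 0
        pos = self._pos[key]
        a = np.searchsorted(pos, lo, side="left")
        b = np.searchsorted(pos, hi, side="left")
        return int(self._cum[key][b] - self._cum[key][a])


@njit(cache=True)
def _best_partner(tag, region, tag_off, max_mm, pairable):  # pragma: no cover
    """Best ungapped antiparallel partner arm of ``tag`` in ``region``.

    Returns (left_off, left_mm, right_off, right_mm); offsets are -1
    when no partner with <= max_mm unpaired positions exists on that
    side.  The partner must be separated from the tag by at least a
    minimal loop.
    """
    L = tag.shape[0]
    R = region.shape[0]
    bl_o, bl_mm = -1, max_mm + 1
    br_o, br_mm = -1, max_mm + 1
    hi_left = tag_off - MIN_LOOP - L
    for o in range(0, hi_left + 1):
        mm = 0
        for j in range(L):
            if not pairable[tag[j], region[o + L - 1 - j]]:
                mm += 1
                if mm >= bl_mm:
                    break
        if mm < bl_mm:
            bl_mm, bl_o = mm, o
    for o in range(tag_off + L + MIN_LOOP, R - L + 1):
        mm = 0
        for j in range(L):
            if not pairable[tag[j], region[o + L - 1 - j]]:
                mm += 1
                if mm >= br_mm:
                    break
        if mm < br_mm:
            br_mm, br_o = mm, o
    return bl_o, bl_mm, br_o, br_mm


def excise_candidate_regions(
    table: TagTable,
    genome: Mapping[str, str],
    ncrna: Mapping[str, object] | None = None,
    max_hits: int = MAX_GENOME_HITS,
    max_window: int = MAX_WINDOW,
) -> list[CandidateWindow]:
    """Candidate windows for every eligible mapped tag.

    ``ncrna`` maps chromosome names to interval trees of annotated
    ncRNAs; windows overlapping any such feature are discarded.
    """
    windows: list[CandidateWindow] = []
    seen: set[tuple] = set()
    for seq in table.sequences:
        L = len(seq)
        if not MIN_MATURE <= L <= MAX_MATURE:
            continue
        hits = table.hits.get(seq, ())
        if not hits or len(hits) >= max_hits:
            continue
        tag_codes = encode(seq)
        for hit in hits:
            chrom_seq = genome[hit.chromosome]
            ext = max_window - L
            lo = max(0, hit.start - ext)
            hi = min(len(chrom_seq), hit.end + ext)
            region = chrom_seq[lo:hi]
            if hit.strand == "+":
                oregion = region
                tag_off = hit.start - lo
            else:
                oregion = revcomp(region)
                tag_off = hi - hit.end
            bl_o, bl_mm, br_o, br_mm = _best_partner(
                tag_codes, encode(oregion), tag_off, SCREEN_LOOSE, _CAN_PAIR)
            for off, mm, on5p in ((br_o, br_mm, True), (bl_o, bl_mm, False)):
                if off < 0:
                    continue
                span_lo = min(tag_off, off)
                span_hi = max(tag_off + L, off + L)
                flank = min(FLANK, (max_window - (span_hi - span_lo)) // 2)
                w_lo = max(0, span_lo - flank)
                w_hi = min(len(oregion), span_hi + flank)
                if hit.strand == "+":
                    g_lo, g_hi = lo + w_lo, lo + w_hi
                    m_off = tag_off - w_lo
                    p_off = off - w_lo
                else:
                    g_lo, g_hi = hi - w_hi, hi - w_lo
                    m_off = tag_off - w_lo
                    p_off = off - w_lo
                if ncrna is not None:
                    tree = ncrna.get(hit.chromosome)
                    if tree is not None and tree[g_lo:g_hi]:
                        continue
                key = (hit.chromosome, hit.strand, g_lo, g_hi, m_off)
                if key in seen:
                    continue
                seen.add(key)
                windows.append(CandidateWindow(
                    chromosome=hit.chromosome, strand=hit.strand,
                    start=g_lo, end=g_hi, mature=seq, mature_off=m_off,
                    partner_off=p_off, screen_mismatches=int(mm),
                    mature_on_5p=bool(on5p)))
    return windows


def _oriented_window_seq(window: CandidateWindow,
                         genome: Mapping[str, str]) -> str:
    seq = genome[window.chromosome][window.start:window.end]
    return seq if window.strand == "+" else revcomp(seq)


def evaluate_precursor(
    window: CandidateWindow,
    genome: Mapping[str, str],
    qualifying: set[str],
    folder: Callable[[str], tuple[str, int, list[int]]] = max_pair_structure,
) -> tuple[HairpinCandidate | None, str | None]:
    """Fold a candidate window and apply the candidacy criteria.

    ``qualifying`` is the union over libraries of top-5 % expressed
    mapped tags.  Returns (candidate, None) on acceptance or
    (None, reason) with the first failed criterion.
    """
    mature = window.mature
    L = len(mature)
    if not MIN_MATURE <= L <= MAX_MATURE:
        return None, "length"
    if mature not in qualifying:
        return None, "expression"
    wseq = _oriented_window_seq(window, genome)
    if len(wseq) < MIN_FOLD_LEN:
        return None, "window_too_short"
    cand, reason = _evaluate_fold(window, wseq, 0, len(wseq), folder)
    if cand is None:
        # flanking sequence can distort the maximum-pairing fold; retry
        # on the window trimmed to the screened duplex span
        lo = max(0, min(window.mature_off, window.partner_off) - 2)
        hi = min(len(wseq),
                 max(window.mature_off, window.partner_off) + L + 2)
        if hi - lo >= MIN_FOLD_LEN and (lo > 0 or hi < len(wseq)):
            cand2, _ = _evaluate_fold(window, wseq, lo, hi, folder)
            if cand2 is not None:
                return cand2, None
    return cand, reason


def _evaluate_fold(window: CandidateWindow, wseq: str, lo: int, hi: int,
                   folder) -> tuple[HairpinCandidate | None, str | None]:
    """Fold ``wseq[lo:hi]`` and apply the structural criteria; all
    coordinates stay in full-window space."""
    L = len(window.mature)
    _, _, sub_partner = folder(wseq[lo:hi])
    partner = [-1] * len(wseq)
    for i, p in enumerate(sub_partner):
        if p != -1:
            partner[lo + i] = p + lo
    m0 = window.mature_off
    # duplex region excludes the mature's own 2-nt 3' overhang
    duplex_hi = m0 + L - DUPLEX_OVERHANG
    pairs = {i: partner[i] for i in range(m0, m0 + L) if partner[i] != -1}
    if not pairs:
        return None, "duplex"
    if any(m0 <= p < m0 + L for i, p in pairs.items() if i < duplex_hi):
        return None, "self_pairing"
    # the duplex is the dominant stem: the longest chain of mature/star
    # pairs with antiparallel geometry and bounded asymmetry; stray
    # long-range pairs added by the maximum-pairing fold are treated as
    # unpaired rather than as extra stems
    ordered = sorted((i, p) for i, p in pairs.items()
                     if i < duplex_hi and not m0 <= p < m0 + L)
    if not ordered:
        return None, "duplex"
    chain = _best_stem_chain(ordered)
    if len(chain) <= 2:
        return None, "multi_stem" if len(ordered) > 2 else "duplex"
    unpaired = (duplex_hi - m0) - len(chain)
    if unpaired > MAX_UNPAIRED_MATURE:
        # distinguish a bulged/forked stem from plain missing pairing
        reason = "bulge" if len(ordered) - len(chain) > MAX_UNPAIRED_MATURE \
            else "duplex"
        return None, reason
    ps = [p for _, p in chain]
    pmin, pmax = min(ps), max(ps)
    # a real stem-loop needs a loop between the arms
    if not (pmin >= m0 + L + MIN_LOOP or pmax < m0 - MIN_LOOP):
        return None, "no_loop"
    star_lo = pmin
    star_hi = min(len(wseq), pmax + 1 + DUPLEX_OVERHANG)
    span_lo = min(m0, star_lo)
    span_hi = max(m0 + L, star_hi)
    paired_in_span = sum(
        1 for i in range(span_lo, span_hi) if partner[i] != -1)
    if paired_in_span / (span_hi - span_lo) < MIN_STEM_PAIRED:
        return None, "stem_pairing"
    if window.strand == "+":
        g_lo = window.start + span_lo
        g_hi = window.start + span_hi
    else:
        g_lo = window.end - span_hi
        g_hi = window.end - span_lo
    cand = HairpinCandidate(
        window=window,
        sequence=wseq[span_lo:span_hi],
        structure=_substructure(partner, span_lo, span_hi),
        precursor_start=g_lo, precursor_end=g_hi,
        mature_off=m0 - span_lo,
        star_off=star_lo - span_lo,
        star_len=star_hi - star_lo,
        paired_mature=len(pairs),
    )
    return cand, None


def _best_stem_chain(ordered: list[tuple[int, int]]
                     ) -> list[tuple[int, int]]:
    """Longest antiparallel chain of (mature index, partner) pairs with
    bounded bulges.

    Consecutive chain members must have strictly decreasing partners
    and a mature/star gap asymmetry of at most ``MAX_BULGE`` with each
    side gap bounded by the unpaired-mature budget (O(n^2) DP, n <= 25).
    """
    n = len(ordered)
    best = [1] * n
    prev = [-1] * n
    for j in range(n):
        ij, pj = ordered[j]
        for i in range(j):
            ii, pi = ordered[i]
            gap_m = ij - ii - 1
            gap_s = pi - pj - 1
            if pj < pi and gap_s >= 0 \
                    and abs(gap_s - gap_m) <= MAX_BULGE \
                    and gap_m <= MAX_UNPAIRED_MATURE \
                    and best[i] + 1 > best[j]:
                best[j] = best[i] + 1
                prev[j] = i
    end = int(np.argmax(best))
    chain = []
    while end != -1:
        chain.append(ordered[end])
        end = prev[end]
    return chain[::-1]


def _substructure(partner: list[int], lo: int, hi: int) -> str:
    out = []
    for i in range(lo, hi):
        p = partner[i]
        if p == -1 or not lo <= p < hi:
            out.append(".")
        else:
            out.append("(" if p > i else ")")
    return "".join(out)


SCORE_FLANK = 30


def count_arm_reads(cand: HairpinCandidate, reads: ReadStartIndex,
                    slop: int = 2, flank: int = SCORE_FLANK) -> None:
    """Attribute pooled read counts to the mature arm, star arm and the
    rest of the precursor plus a ``flank`` margin (5'-end within
    ``slop`` of the arm 5' end counts as that arm).

    Reads in the flank count as "other": a genuine pre-miRNA has no
    small RNA production immediately around it, whereas a siRNA locus
    masquerading as a hairpin is surrounded by reads, which drives its
    concentration score down.  Both strands of the flanked region
    contribute to "other"."""
    chrom, strand = cand.chromosome, cand.strand
    m_lo, m_hi = cand.mature_genomic
    s_lo, s_hi = cand.star_genomic
    m5 = m_lo if strand == "+" else m_hi - 1
    s5 = s_lo if strand == "+" else s_hi - 1
    cand.mature_reads = reads.reads_between(chrom, strand, m5 - slop,
                                            m5 + slop + 1)
    cand.star_reads = reads.reads_between(chrom, strand, s5 - slop,
                                          s5 + slop + 1)
    total = sum(
        reads.reads_between(chrom, s, cand.precursor_start - flank,
                            cand.precursor_end + flank)
        for s in "+-")
    cand.other_reads = max(0, total - cand.mature_reads - cand.star_reads)


def candidate_score(mature_reads: int, star_reads: int, other_reads: int,
                    paired_fraction: float) -> float:
    """Read-concentration log-odds plus a pairing bonus.

    A transparent surrogate for a probabilistic precursor score: reads
    concentrated on the mature/star duplex raise it, reads on the loop
    or flanks lower it, and a fully paired mature adds up to 2.
    """
    return float(
        np.log2((mature_reads + star_reads + 1) / (other_reads + 1))
        + 2.0 * paired_fraction
    )


def score_candidates(accepted: list[HairpinCandidate],
                     background_scores: np.ndarray | list[float] = (),
                     percentile: float = SCORE_PERCENTILE
                     ) -> tuple[np.ndarray, float]:
    """Score accepted candidates and derive the novel-retention threshold.

    The threshold is the ``percentile`` quantile of *all* candidate
    scores — accepted plus the background pool of excised-but-unfolded
    windows — so that it tracks the full candidate population the way
    a top-5 % score cutoff does.
    """
    for cand in accepted:
        cand.score = candidate_score(
            cand.mature_reads, cand.star_reads, cand.other_reads,
            cand.paired_mature / len(cand.mature))
    scores = np.array([c.score for c in accepted], dtype=float)
    pool = np.concatenate([scores, np.asarray(background_scores, dtype=float)])
    if pool.size == 0:
        return scores, float("inf")
    threshold = float(np.quantile(pool, percentile))
    return scores, threshold


def dedupe_overlapping(accepted: list[HairpinCandidate]
                       ) -> list[HairpinCandidate]:
    """One candidate per overlapping precursor cluster: best score,
    then more mature-arm reads, then the 5' arm."""
    by_key = sorted(
        accepted,
        key=lambda c: (c.chromosome, c.strand, c.precursor_start))
    out: list[HairpinCandidate] = []
    cluster: list[HairpinCandidate] = []

    def flush():
        if cluster:
            best = min(cluster, key=lambda c: (
                -c.score, -c.mature_reads, not c.window.mature_on_5p,
                c.precursor_start))
            out.append(best)

    for cand in by_key:
        if cluster and (cand.chromosome, cand.strand) == (
                cluster[-1].chromosome, cluster[-1].strand) \
                and cand.precursor_start < max(c.precursor_end
                                               for c in cluster):
            cluster.append(cand)
        else:
            flush()
            cluster = [cand]
    flush()
    return out


def recover_family_precursors(final_matures: set[str],
                              accepted: list[HairpinCandidate]
                              ) -> list[HairpinCandidate]:
    """All accepted candidates whose mature is in the final set,
    regardless of the score percentile."""
    return [c for c in accepted if c.mature in final_matures]


def discover(table: TagTable, genome: Mapping[str, str],
             qualifying: set[str],
             ncrna: Mapping[str, object] | None = None,
             folder: Callable = max_pair_structure,
             percentile: float = SCORE_PERCENTILE) -> DiscoveryResult:
    """Run the full discovery stage on a mapped tag table."""
    windows = excise_candidate_regions(table, genome, ncrna)
    reads = ReadStartIndex(table)
    accepted: list[HairpinCandidate] = []
    rejections: list[Rejection] = []
    background: list[float] = []
    for window in windows:
        if window.screen_mismatches <= SCREEN_FOLD:
            cand, reason = evaluate_precursor(window, genome, qualifying,
                                              folder)
            if cand is not None:
                count_arm_reads(cand, reads)
                accepted.append(cand)
                continue
        else:
            reason = "weak_duplex"
        # background score from the ungapped screen
        L = len(window.mature)
        m5 = window.start + window.mature_off if window.strand == "+" \
            else window.end - window.mature_off - 1
        m_reads = reads.reads_between(window.chromosome, window.strand,
                                      m5 - 2, m5 + 3)
        pf = (L - window.screen_mismatches) / L
        score = candidate_score(m_reads, 0, 0, pf)
        background.append(score)
        rejections.append(Rejection(window, reason, score))
    accepted = dedupe_overlapping(accepted)
    scores, threshold = score_candidates(accepted, background, percentile)
    return DiscoveryResult(accepted, rejections, scores, threshold)


def select_final_matures(result: DiscoveryResult,
                         classes: Mapping[str, str]) -> set[str]:
    """Final mature set: known and isomiR matures passing all filters,
    novel matures additionally requiring best score >= the percentile
    threshold."""
    best: dict[str, float] = {}
    for cand in result.accepted:
        best[cand.mature] = max(best.get(cand.mature, -np.inf), cand.score)
    final = set()
    for mature, score in best.items():
        cls = classes.get(mature, "novel")
        if cls in ("known", "isomiR", "isomir") or \
                score >= result.score_threshold:
            final.add(mature)
    return final
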