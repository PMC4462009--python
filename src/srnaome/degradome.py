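"""Degradome (PARE) analysis: mapping of 5'-end tags, validation of
precursor processing, and miRNA-guided cleavage calls with a
shuffle-based p-value.

Degradome tags are the first ~20 nt of uncapped transcript 5' ends; a
sharp signature at the position opposite miRNA positions 10/11
evidences miRNA-guided slicing, and signatures at the mature/star 5'
boundaries of a precursor evidence DCL processing.  Tags map exactly
and sense-only.

Cleavage calls are assigned the standard degradome categories:
  0  peak > 1 read and the unique transcript maximum
  1  equal to the maximum, not unique
  2  above the median of nonzero positions, below the maximum
  3  more than 1 read, at or below the median
  4  exactly 1 read
and a p-value from dinucleotide-preserving shuffles of the miRNA:
p = (1 + #shuffles achieving an alignment at least as good anywhere on
the transcript with a same-or-better category at its predicted slice
site) / (1 + n_shuffles).  Calls with p <= 0.05 are retained.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from ._seq import canonical
from .targets import (DuplexAlignment, TARGET_CUTOFF, scan_transcripts)

PROCESSING_WINDOW = 1      # +/- nt around a boundary
MIN_BOUNDARY_READS = 5
PROCESSING_ALPHA = 0.05
CLEAVAGE_ALPHA = 0.05

Signatures = dict[str, dict[int, int]]   # transcript -> {1-based pos: count}


def map_degradome_tags(tags: Mapping[str, int],
                       transcripts: Mapping[str, str]) -> Signatures:
    """Per-transcript histograms of tag 5'-end positions (1-based).

    Exact matching, sense strand only; a tag matching several positions
    or transcripts contributes its count to each.
    """
    by_len: dict[int, dict[str, int]] = {}
    for seq, count in tags.items():
        seq = canonical(seq)
        by_len.setdefault(len(seq), {})[seq] = \
            by_len.get(len(seq), {}).get(seq, 0) + count
    signatures: Signatures = {tid: {} for tid in transcripts}
    canon = {tid: canonical(s) for tid, s in transcripts.items()}
    for L, group in by_len.items():
        index: dict[str, list[tuple[str, int]]] = {}
        for tid, seq in canon.items():
            for off in range(len(seq) - L + 1):
                index.setdefault(seq[off:off + L], []).append((tid, off))
        for tag, count in group.items():
            for tid, off in index.get(tag, ()):
                pos = off + 1
                signatures[tid][pos] = signatures[tid].get(pos, 0) + count
    return signatures


def validate_precursor_processing(
    precursor_length: int,
    mature5_offset: int,
    star5_offset: int,
    signatures: Mapping[int, int],
    window: int = PROCESSING_WINDOW,
    min_reads: int = MIN_BOUNDARY_READS,
    alpha: float = PROCESSING_ALPHA,
) -> tuple[bool, float]:
    """Binomial test for processing signatures at duplex boundaries.

    Boundary reads B are signatures within ``window`` nt of the mature
    or star 5' end (offsets 0-based on the precursor reference); under
    the null they are a uniform share p0 = (#boundary positions) /
    (precursor length) of the total T.  Validated iff the one-sided
    binomial tail P(X >= B) <= alpha and B >= min_reads.
    """
    total = sum(signatures.values())
    if total == 0:
        return False, 1.0
    boundary_pos = set()
    for off in (mature5_offset, star5_offset):
        for d in range(-window, window + 1):
            pos = off + 1 + d
            if 1 <= pos <= precursor_length:
                boundary_pos.add(pos)
    B = sum(c for p, c in signatures.items() if p in boundary_pos)
    p0 = len(boundary_pos) / precursor_length
    p_value = float(stats.binom.sf(B - 1, total, p0))
    return (p_value <= alpha and B >= min_reads), p_value


def dinucleotide_shuffle(seq: str, rng: np.random.Generator,
                         max_tries: int = 200) -> str:
    """Dinucleotide-preserving shuffle (random Eulerian walk over the
    dinucleotide multigraph, retried until all edges are consumed)."""
    seq = canonical(seq)
    if len(seq) < 3:
        return seq
    for _ in range(max_tries):
        edges: dict[str, list[str]] = {}
        for a, b in zip(seq, seq[1:]):
            edges.setdefault(a, []).append(b)
        for a in edges:
            rng.shuffle(edges[a])
        out = [seq[0]]
        node = seq[0]
        ok = True
        for _ in range(len(seq) - 1):
            nxt = edges.get(node)
            if not nxt:
                ok = False
                break
            node = nxt.pop()
            out.append(node)
        if ok:
            return "".join(out)
    return seq   # degenerate composition; identity preserves dinucleotides


@dataclass
class CleavageCall:
    alignment: DuplexAlignment
    peak_abundance: int
    category: int
    p_value: float

    @property
    def mirna_id(self) -> str:
        return self.alignment.mirna_id

    @property
    def transcript_id(self) -> str:
        return self.alignment.transcript_id

    @property
    def cleavage_position(self) -> int:
        return self.alignment.cleavage_position


def signature_category(peak: int, tx_signatures: Mapping[int, int]) -> int:
    """Degradome category of a signature of height ``peak`` relative to
    all signatures on the transcript."""
    if peak <= 0:
        raise ValueError("category undefined for a zero signature")
    values = list(tx_signatures.values())
    mx = max(values)
    if peak == 1:
        return 4
    if peak == mx:
        return 0 if values.count(mx) == 1 else 1
    med = float(np.median(values))
    return 2 if peak > med else 3


def call_cleavage_targets(
    mirnas: Mapping[str, str],
    transcripts: Mapping[str, str],
    signatures: Signatures,
    n_shuffles: int = 100,
    seed: int = 0,
    cutoff: float = TARGET_CUTOFF,
    alpha: float = CLEAVAGE_ALPHA,
) -> list[CleavageCall]:
    """Identify miRNA-guided cleavage targets supported by degradome
    signatures; retain calls with shuffle p-value <= alpha."""
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    alignments = scan_transcripts(mirnas, transcripts, cutoff=cutoff,
                                  inclusive=False)
    calls: list[CleavageCall] = []
    for ai, aln in enumerate(sorted(
            alignments, key=lambda a: (a.mirna_id, a.transcript_id, a.start))):
        tx_sigs = signatures.get(aln.transcript_id, {})
        peak = tx_sigs.get(aln.cleavage_position, 0)
        if peak == 0:
            continue
        category = signature_category(peak, tx_sigs)
        rng = np.random.default_rng([seed, 7919, ai])
        tseq = {aln.transcript_id: transcripts[aln.transcript_id]}
        successes = 0
        for _ in range(n_shuffles):
            shuffled = dinucleotide_shuffle(mirnas[aln.mirna_id], rng)
            null_hits = scan_transcripts(
                {"shuffled": shuffled}, tseq,
                cutoff=aln.expectation, inclusive=True)
            for nh in null_hits:
                null_peak = tx_sigs.get(nh.cleavage_position, 0)
                if null_peak > 0 and \
                        signature_category(null_peak, tx_sigs) <= category:
                    successes += 1
                    break
        p_value = (1 + successes) / (1 + n_shuffles)
        if p_value <= alpha:
            calls.append(CleavageCall(aln, peak, category, p_value))
    return calls


def tplot_table(transcript_id: str, transcript_length: int,
                signatures: Signatures,
                calls: list[CleavageCall] | None = None) -> pd.DataFrame:
    """Target-plot data: per-position degradome abundance with predicted
    cleavage sites flagged."""
    sigs = signatures.get(transcript_id, {})
    predicted = {c.cleavage_position for c in (calls or ())
                 if c.transcript_id == transcript_id}
    rows = [(pos, sigs.get(pos, 0), pos in predicted)
            for pos in range(1, transcript_length + 1)]
    return pd.DataFrame(rows, columns=["position", "abundance", "predicted"])
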