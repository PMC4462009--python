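"""Shared small-RNA substrate: read collapsing, exact genome mapping,
RPM normalization, library statistics, top-5 % presence calls and the
contaminant screen.

Every downstream stage (hairpin discovery, phasiRNA detection, organ
distribution) consumes the :class:`TagTable` built here.  Mapping is
exact (no mismatches, both strands), matching the study design where
alignments were run without mismatch; mismatch tolerance is explicitly
out of scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from ._seq import canonical, is_valid, percent, revcomp

MIN_TAG_LEN = 16
MAX_TAG_LEN = 36

_SEED_K = 16


@dataclass(frozen=True)
class GenomeHit:
    """One exact occurrence of a tag in the genome (0-based, half-open)."""

    chromosome: str
    start: int
    end: int
    strand: str

    def __post_init__(self):
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad hit interval [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")


@dataclass
class CollapseStats:
    """Bookkeeping from one library's collapsing pass."""

    library: str
    total_raw: int = 0
    n_too_short: int = 0
    n_too_long: int = 0
    n_invalid: int = 0


@dataclass
class LibraryProfile:
    name: str
    total_raw: int
    total_mapped: int
    mapped_fraction: int
    unique_tags: int
    top5_threshold_count: int


class TagTable:
    """Collapsed unique tags with per-library counts and genome hits.

    ``counts`` is a DataFrame indexed by tag sequence with one integer
    column per library.  After :func:`map_exact`, ``hits`` maps each
    sequence to its list of :class:`GenomeHit` and ``n_genome_hits``
    is populated (0 for unmapped-but-retained tags).
    """

    def __init__(self) -> None:
        self.counts = pd.DataFrame(dtype=np.int64)
        self.hits: dict[str, list[GenomeHit]] = {}
        self.stats: dict[str, CollapseStats] = {}

    # -- construction -------------------------------------------------

    def add_library(self, library: str, counts: Mapping[str, int],
                    stats: CollapseStats | None = None) -> None:
        col = pd.Series(counts, dtype=np.int64, name=library)
        self.counts = self.counts.join(col, how="outer") if not self.counts.empty \
            else col.to_frame()
        self.counts = self.counts.fillna(0).astype(np.int64)
        self.stats[library] = stats or CollapseStats(library, int(col.sum()))

    @property
    def libraries(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def sequences(self) -> pd.Index:
        return self.counts.index

    def n_genome_hits(self, seq: str) -> int:
        return len(self.hits.get(seq, ()))

    def is_mapped(self, seq: str) -> bool:
        return bool(self.hits.get(seq))

    def pooled_count(self, seq: str) -> int:
        return int(self.counts.loc[seq].sum()) if seq in self.counts.index else 0

    def total_mapped(self, library: str) -> int:
        mapped = [s for s in self.counts.index if self.is_mapped(s)]
        return int(self.counts.loc[mapped, library].sum())

    def to_frame(self) -> pd.DataFrame:
        """Flat per-tag table (sequence, per-library counts, rpm, hits)."""
        df = self.counts.copy()
        df["n_genome_hits"] = [self.n_genome_hits(s) for s in df.index]
        for lib in self.libraries:
            total = self.total_mapped(lib)
            if total > 0:
                df[f"rpm_{lib}"] = [
                    normalize_rpm(int(c), total) if self.is_mapped(s) else 0.0
                    for s, c in df[lib].items()
                ]
        df.index.name = "sequence"
        return df


def collapse_reads(reads: Iterable[str], library: str,
                   min_len: int = MIN_TAG_LEN,
                   max_len: int = MAX_TAG_LEN) -> tuple[dict[str, int], CollapseStats]:
    """Collapse a read stream into {sequence: count}.

    Reads shorter than ``min_len`` or longer than ``max_len`` are dropped
    and counted; reads with non-nucleotide characters are skipped and
    counted.  The result is independent of input order.
    """
    stats = CollapseStats(library)
    counts: dict[str, int] = {}
    for read in reads:
        stats.total_raw += 1
        seq = canonical(read)
        if not is_valid(seq):
            stats.n_invalid += 1
            continue
        if len(seq) < min_len:
            stats.n_too_short += 1
            continue
        if len(seq) > max_len:
            stats.n_too_long += 1
            continue
        counts[seq] = counts.get(seq, 0) + 1
    return counts, stats


class ExactIndex:
    """Seed-and-verify exact matcher over a sequence set (plus strand).

    Seeds are 16-mers encoded as 32-bit integers; occurrences of a query
    on the minus strand are found by searching its reverse complement.
    """

    def __init__(self, sequences: Mapping[str, str]) -> None:
        self.names = list(sequences)
        self.seqs = [canonical(sequences[n]) for n in self.names]
        codes_all, owners, offsets = [], [], []
        for idx, seq in enumerate(self.seqs):
            n = len(seq)
            if n < _SEED_K:
                continue
            enc = np.frombuffer(seq.encode(), dtype=np.uint8)
            code2 = np.full(n, 4, dtype=np.int64)
            for b, v in zip(b"ACGT", range(4)):
                code2[enc == b] = v
            valid = code2 < 4
            kmers = np.zeros(n - _SEED_K + 1, dtype=np.int64)
            ok = np.ones(n - _SEED_K + 1, dtype=bool)
            for t in range(_SEED_K):
                kmers = (kmers << 2) | code2[t : n - _SEED_K + 1 + t]
                ok &= valid[t : n - _SEED_K + 1 + t]
            pos = np.nonzero(ok)[0]
            codes_all.append(kmers[pos])
            owners.append(np.full(pos.shape[0], idx, dtype=np.int32))
            offsets.append(pos.astype(np.int64))
        if codes_all:
            codes = np.concatenate(codes_all)
            own = np.concatenate(owners)
            off = np.concatenate(offsets)
            order = np.argsort(codes, kind="stable")
            self._codes = codes[order]
            self._own = own[order]
            self._off = off[order]
        else:
            self._codes = np.empty(0, dtype=np.int64)
            self._own = np.empty(0, dtype=np.int32)
            self._off = np.empty(0, dtype=np.int64)

    def _seed_hits(self, seed: str):
        code = 0
        for c in seed:
            v = "ACGT".find(c)
            if v < 0:
                return ()
            code = (code << 2) | v
        lo = np.searchsorted(self._codes, code, side="left")
        hi = np.searchsorted(self._codes, code, side="right")
        return zip(self._own[lo:hi], self._off[lo:hi])

    def find_plus(self, query: str) -> list[tuple[str, int]]:
        """All plus-strand occurrence (name, start) pairs of ``query``."""
        if len(query) < _SEED_K:
            # rare path: brute scan (queries are >=16 nt in the pipeline)
            out = []
            for name, seq in zip(self.names, self.seqs):
                start = seq.find(query)
                while start != -1:
                    out.append((name, start))
                    start = seq.find(query, start + 1)
            return out
        out = []
        for own, off in self._seed_hits(query[:_SEED_K]):
            seq = self.seqs[own]
            start = int(off)
            if seq[start : start + len(query)] == query:
                out.append((self.names[own], start))
        return out

    def occurs(self, query: str) -> bool:
        """Exact occurrence on either strand."""
        q = canonical(query)
        return bool(self.find_plus(q)) or bool(self.find_plus(revcomp(q)))


def map_exact(tags: Iterable[str], genome: Mapping[str, str],
              index: ExactIndex | None = None) -> dict[str, list[GenomeHit]]:
    """Map each tag exactly to both strands of the genome.

    Every occurrence is reported; tags with zero hits get an empty list
    (retained, flagged unmapped).  No hit-count cutoff is applied here —
    the <40-hit rule is a miRNA-candidacy filter downstream.
    """
    index = index or ExactIndex(genome)
    hits: dict[str, list[GenomeHit]] = {}
    for tag in tags:
        seq = canonical(tag)
        found = [
            GenomeHit(name, start, start + len(seq), "+")
            for name, start in index.find_plus(seq)
        ]
        found += [
            GenomeHit(name, start, start + len(seq), "-")
            for name, start in index.find_plus(revcomp(seq))
        ]
        found.sort(key=lambda h: (h.chromosome, h.start, h.strand))
        hits[tag] = found
    return hits


def normalize_rpm(count: int, total_mapped: int) -> float:
    """Reads-per-million: count * 1e6 / total mapped reads of the library."""
    if total_mapped <= 0:
        raise ValueError("total_mapped must be positive for RPM normalization")
    return count * 1_000_000 / total_mapped


def mapped_fraction(total_raw: int, total_mapped: int) -> int:
    """Integer percent of mapped reads, rounded half away from zero."""
    if total_raw < 0 or total_mapped < 0 or total_mapped > total_raw:
        raise ValueError("need 0 <= total_mapped <= total_raw")
    return percent(total_mapped, total_raw)


def expression_rank_threshold(table: TagTable, library: str,
                              quantile: float = 0.05
                              ) -> tuple[int, frozenset[str]]:
    """Top-quantile presence rule over distinct mapped tags of a library.

    Tags are ranked by raw count descending; the qualifying rank bound is
    ``ceil(quantile * n_distinct_mapped)`` and every tag whose count ties
    the count at that rank qualifies.  Returns (minimum qualifying count,
    qualifying sequence set).
    """
    col = table.counts[library]
    mapped_mask = np.fromiter(
        (table.is_mapped(s) for s in col.index), dtype=bool, count=len(col))
    mapped = col[(col > 0) & mapped_mask]
    if mapped.empty:
        return 0, frozenset()
    counts = np.sort(mapped.to_numpy())[::-1]
    bound = max(1, math.ceil(quantile * counts.shape[0]))
    threshold = int(counts[bound - 1])
    qualifying = frozenset(mapped.index[mapped >= threshold])
    return threshold, qualifying


def present(table: TagTable, seq: str, library: str,
            quantile: float = 0.05) -> bool:
    """Presence predicate: is ``seq`` in the library's top-quantile tags."""
    threshold, qualifying = expression_rank_threshold(table, library, quantile)
    return seq in qualifying


def contamination_fraction(counts: Mapping[str, int],
                           contaminant_genome: Mapping[str, str]) -> float:
    """Percent of reads (count-weighted) occurring exactly in the
    contaminant genome on either strand."""
    total = sum(counts.values())
    if total == 0:
        return 0.0
    index = ExactIndex(contaminant_genome)
    matched = sum(c for seq, c in counts.items() if index.occurs(seq))
    return 100.0 * matched / total


def build_profiles(table: TagTable, quantile: float = 0.05
                   ) -> list[LibraryProfile]:
    """Per-library statistics table (raw, mapped, % mapped, unique tags)."""
    profiles = []
    for lib in table.libraries:
        stats = table.stats[lib]
        col = table.counts[lib]
        total_mapped = table.total_mapped(lib)
        thr, _ = expression_rank_threshold(table, lib, quantile)
        profiles.append(LibraryProfile(
            name=lib,
            total_raw=stats.total_raw,
            total_mapped=total_mapped,
            mapped_fraction=mapped_fraction(stats.total_raw, total_mapped)
            if stats.total_raw else 0,
            unique_tags=int((col > 0).sum()),
            top5_threshold_count=thr,
        ))
    return profiles
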