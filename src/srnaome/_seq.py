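"""Shared sequence utilities: alphabet handling, encoding, FASTA helpers.

All pipeline logic works on DNA-alphabet uppercase strings; RNA input (U)
is canonicalized to T on entry so catalog matching and genome mapping are
alphabet-agnostic.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_BASES = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# integer codes used by the numba kernels
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


def canonical(seq: str) -> str:
    """Uppercase and map U->T."""
    return seq.upper().replace("U", "T")


def is_valid(seq: str) -> bool:
    return bool(seq) and set(seq) <= VALID_BASES


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


_CODE_LUT = np.full(128, 4, dtype=np.int8)
for _b, _c in _CODE.items():
    _CODE_LUT[ord(_b)] = _c


def encode(seq: str) -> np.ndarray:
    """Encode A/C/G/T/N as int8 codes 0..4."""
    return _CODE_LUT[np.frombuffer(seq.encode(), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return "".join("ACGTN"[c] for c in codes)


def pairs(a: str, b: str) -> bool:
    """Watson-Crick or G:U wobble pair between two bases."""
    s = frozenset((a, b))
    return s in _PAIR_SETS


_PAIR_SETS = frozenset(
    {frozenset("AT"), frozenset("GC"), frozenset("GT")}
)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered {name: canonical sequence} dict."""
    return {
        rec.id: canonical(str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]]) -> None:
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    SeqIO.write(recs, str(path), "fasta")


def iter_reads(path: str | Path) -> Iterator[str]:
    """Yield raw read sequences from FASTA or FASTQ (by extension).

    Collapsed-FASTA headers of the form ``tag<id>_x<count>`` are expanded:
    the sequence is yielded ``count`` times so collapsing round-trips.
    """
    p = str(path)
    fmt = "fastq" if p.endswith((".fastq", ".fq")) else "fasta"
    for rec in SeqIO.parse(p, fmt):
        n = 1
        if fmt == "fasta" and "_x" in rec.id:
            tail = rec.id.rsplit("_x", 1)[1]
            if tail.isdigit():
                n = int(tail)
        seq = str(rec.seq)
        for _ in range(n):
            yield seq


def round_half_away(x: float) -> int:
    """Round half away from zero (report convention for percentages)."""
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


def percent(numerator: float, denominator: float) -> int:
    """Integer percentage, rounded half away from zero."""
    if denominator == 0:
        raise ValueError("percentage undefined: denominator is zero")
    return round_half_away(100.0 * numerator / denominator)


def truncated_mean(values: Iterable[float]) -> int:
    """Arithmetic mean truncated toward zero (report convention for
    average read counts)."""
    vals = list(values)
    if not vals:
        raise ValueError("mean of empty sequence")
    return int(sum(vals) / len(vals))
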