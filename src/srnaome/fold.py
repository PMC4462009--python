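"""Maximum base-pairing RNA secondary structure (Nussinov-style).

The hairpin evaluator needs a deterministic, dependency-free notion of
"how does this candidate precursor pair" rather than a thermodynamic
minimum-free-energy model: candidacy criteria are stated in terms of
paired/unpaired positions, so a maximum-matching structure under the
canonical pair set {AU, UA, GC, CG, GU, UG} with a minimum hairpin loop
of 3 is the contract.  The folder is pluggable (``evaluate_precursor``
accepts any callable with the same signature), but all tests and
defaults run against this one.

Maximum matching is highly degenerate; among all structures with the
maximal pair count the folder deterministically prefers those with the
most stacked pairs (contiguous helices), which resolves the
degeneracy toward the long stems real hairpins form.  The primary
objective — the pair count — is never traded for stacking.  Traceback
order is pair-the-ends, stacked continuation, then bifurcation at the
smallest split point.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from ._seq import encode

MIN_LOOP = 3
MIN_FOLD_LEN = 40
MAX_FOLD_LEN = 250

_PAIR_W = 256          # per-pair weight; dominates any stack-count delta
_NEG = -(1 << 28)

# pairing lookup over codes A=0 C=1 G=2 T=3 (N=4 never pairs)
_CAN_PAIR = np.zeros((5, 5), dtype=np.bool_)
for _a, _b in ((0, 3), (3, 0), (1, 2), (2, 1), (2, 3), (3, 2)):
    _CAN_PAIR[_a, _b] = True


@njit(cache=True)
def _fill(codes, pairable):  # pragma: no cover - exercised via fold()
    n = codes.shape[0]
    M = np.zeros((n, n), dtype=np.int32)
    H = np.full((n, n), _NEG, dtype=np.int32)   # value given (i,j) paired
    for span in range(MIN_LOOP + 1, n):
        for i in range(n - span):
            j = i + span
            if pairable[codes[i], codes[j]]:
                inner = M[i + 1, j - 1]
                stacked = H[i + 1, j - 1] + 1
                h = _PAIR_W + (stacked if stacked > inner else inner)
                H[i, j] = h
            best = M[i + 1, j]
            if M[i, j - 1] > best:
                best = M[i, j - 1]
            if H[i, j] > best:
                best = H[i, j]
            for k in range(i + MIN_LOOP + 1, j):
                v = M[i, k] + M[k + 1, j]
                if v > best:
                    best = v
            M[i, j] = best
    return M, H


def _traceback(M: np.ndarray, H: np.ndarray, codes: np.ndarray) -> list[int]:
    """Partner vector (-1 = unpaired) from the filled DP matrices."""
    n = codes.shape[0]
    partner = [-1] * n
    # entries: (i, j, forced_pair)
    stack = [(0, n - 1, False)]
    while stack:
        i, j, forced = stack.pop()
        if j - i <= MIN_LOOP:
            continue
        if forced:
            partner[i] = j
            partner[j] = i
            inner = M[i + 1, j - 1]
            stacked = H[i + 1, j - 1] + 1
            if stacked > inner:
                stack.append((i + 1, j - 1, True))
            else:
                stack.append((i + 1, j - 1, False))
            continue
        target = M[i, j]
        if target == 0:
            continue
        if H[i, j] == target:
            stack.append((i, j, True))
        elif target == M[i + 1, j]:
            stack.append((i + 1, j, False))
        elif target == M[i, j - 1]:
            stack.append((i, j - 1, False))
        else:
            for k in range(i + MIN_LOOP + 1, j):
                if target == M[i, k] + M[k + 1, j]:
                    stack.append((i, k, False))
                    stack.append((k + 1, j, False))
                    break
    return partner


def max_pair_structure(sequence: str) -> tuple[str, int, list[int]]:
    """Fold a sequence of any length; returns (dot-bracket, n_pairs,
    partner vector).

    Core routine without the precursor length gate; ``fold_hairpin`` is
    the spec-facing wrapper.
    """
    codes = encode(sequence)
    n = codes.shape[0]
    if n <= MIN_LOOP:
        return "." * n, 0, [-1] * n
    M, H = _fill(codes, _CAN_PAIR)
    partner = _traceback(M, H, codes)
    db = "".join(
        "(" if (p := partner[i]) > i else ")" if p != -1 else "."
        for i in range(n)
    )
    return db, int(M[0, n - 1]) // _PAIR_W, partner


def partner_from_dotbracket(structure: str) -> list[int]:
    """Partner vector from a dot-bracket string (no pseudoknots)."""
    partner = [-1] * len(structure)
    stack: list[int] = []
    for i, c in enumerate(structure):
        if c == "(":
            stack.append(i)
        elif c == ")":
            j = stack.pop()
            partner[i] = j
            partner[j] = i
    if stack:
        raise ValueError("unbalanced dot-bracket structure")
    return partner


def vienna_fold(sequence: str) -> tuple[str, int, list[int]]:
    """Pluggable external MFE folder (RNAfold), same signature as
    :func:`max_pair_structure`.

    Used as an independent cross-check; the built-in maximum-pairing
    folder remains the default and the tested contract.
    """
    import subprocess

    out = subprocess.run(
        ["RNAfold", "--noPS"], input=sequence + "\n", text=True,
        capture_output=True, check=True).stdout
    db = out.splitlines()[1].split()[0]
    partner = partner_from_dotbracket(db)
    return db, sum(1 for p in partner if p != -1) // 2, partner


def fold_hairpin(sequence: str) -> tuple[str, int]:
    """Fold a candidate precursor (40-250 nt); returns (dot-bracket,
    n_pairs)."""
    if not MIN_FOLD_LEN <= len(sequence) <= MAX_FOLD_LEN:
        raise ValueError(
            f"precursor fold requires {MIN_FOLD_LEN}-{MAX_FOLD_LEN} nt, "
            f"got {len(sequence)}"
        )
    db, n, _ = max_pair_structure(sequence)
    return db, n
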