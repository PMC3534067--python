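"""RNA secondary-structure prediction with a stacking-weighted pairing score.

The model is deliberately simple: canonical pairs (A-U, G-C, G-U) score by
how they sit in a helix, not by a full nearest-neighbor table.  A pair whose
inner neighbor (i+1, j-1) is also a pair counts as *stacked* and earns the
weight of its own pair type (G-C 3, A-U 2, G-U 1); any pair without a
stacked inner neighbor earns 1.  Hairpin loops keep at least 3 unpaired
bases.  The dynamic program maximizes the total score exactly (no heuristic
pruning); the reported ``energy`` is the negated optimum, so more negative
means more stably paired.  Absolute values are score units, not kcal/mol —
the downstream hairpin criteria depend on structure topology and score per
base, never on physical free energies.

Ties are broken deterministically toward 5'-most, outermost pairs.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .types import FoldResult

MIN_LOOP = 3
NEG = -(10 ** 6)

_ENC = np.full(256, -1, dtype=np.int8)
for _b, _v in zip("ACGT", range(4)):
    _ENC[ord(_b)] = _v

# pair weights for a *stacked* pair, indexed by encoded bases
_W = np.zeros((4, 4), dtype=np.int32)
_W[2, 1] = _W[1, 2] = 3  # G-C
_W[0, 3] = _W[3, 0] = 2  # A-U(T)
_W[2, 3] = _W[3, 2] = 1  # G-U(T)


def encode(seq: str) -> np.ndarray:
    """Uppercase, U->T, encode to 0..3; reject anything else."""
    s = seq.upper().replace("U", "T")
    arr = _ENC[np.frombuffer(s.encode("ascii"), dtype=np.uint8)]
    if (arr < 0).any():
        bad = sorted(set(s) - set("ACGT"))
        raise ValueError(f"non-ACGTU characters in sequence: {bad}")
    return arr.astype(np.int8)


@njit(cache=True)
def _fill(enc, w):  # pragma: no cover - exercised via fold_rna
    n = enc.shape[0]
    C = np.full((n, n), NEG, dtype=np.int32)   # best score, i paired with j
    Wx = np.zeros((n, n), dtype=np.int32)      # best score of i..j, (i,j) NOT paired together
    Wt = np.zeros((n, n), dtype=np.int32)      # best score of i..j
    for span in range(MIN_LOOP + 1, n):
        for i in range(0, n - span):
            j = i + span
            wij = w[enc[i], enc[j]]
            if wij > 0:
                # unstacked closing pair over any interior lacking the (i+1,j-1) pair
                best = 1 + Wx[i + 1, j - 1]
                # stacked on the (i+1, j-1) pair
                if C[i + 1, j - 1] > NEG:
                    alt = wij + C[i + 1, j - 1]
                    if alt > best:
                        best = alt
                C[i, j] = best
            # region best with (i,j) unpaired-to-each-other
            best = Wt[i, j - 1]
            for k in range(i + 1, j - MIN_LOOP):
                if C[k, j] > NEG:
                    left = Wt[i, k - 1] if k > i else 0
                    v = left + C[k, j]
                    if v > best:
                        best = v
            Wx[i, j] = best
            Wt[i, j] = best if best >= C[i, j] else C[i, j]
    return C, Wx, Wt


def _traceback(enc: np.ndarray, C: np.ndarray, Wx: np.ndarray, Wt: np.ndarray) -> list[tuple[int, int]]:
    n = enc.shape[0]
    pairs: list[tuple[int, int]] = []
    # stack of (i, j, mode); mode: 0 = free region, 1 = i paired with j
    todo = [(0, n - 1, 0)]
    while todo:
        i, j, mode = todo.pop()
        if j - i < MIN_LOOP + 1:
            continue
        if mode == 1:
            pairs.append((i, j))
            wij = int(_W[enc[i], enc[j]])
            # prefer the stacked continuation on ties (contiguous helices)
            if C[i + 1, j - 1] > NEG and wij + C[i + 1, j - 1] == C[i, j]:
                todo.append((i + 1, j - 1, 1))
            else:
                todo.append((i + 1, j - 1, 2))  # mode 2: region without (i+1,j-1) pair
            continue
        tab = Wt if mode == 0 else Wx
        target = int(tab[i, j])
        if target == 0:
            continue
        if mode == 0 and C[i, j] == target:
            todo.append((i, j, 1))
            continue
        done = False
        for k in range(i + 1, j - MIN_LOOP):  # 5'-most partner of j first
            if C[k, j] > NEG:
                left = int(Wt[i, k - 1]) if k > i else 0
                if left + int(C[k, j]) == target:
                    todo.append((k, j, 1))
                    if k > i:
                        todo.append((i, k - 1, 0))
                    done = True
                    break
        if not done:
            todo.append((i, j - 1, 0))
    return sorted(pairs)


def fold_rna(seq: str) -> FoldResult:
    """Fold one sequence, returning dot-bracket, energy, and the pair map.

    Raises ``ValueError`` on non-ACGTU input or sequences longer than 1000
    bases (the O(n^3) exact DP is meant for precursor-scale windows).
    """
    if not seq:
        raise ValueError("empty sequence")
    if len(seq) > 1000:
        raise ValueError(f"sequence of {len(seq)} bases exceeds the 1000-base fold limit")
    enc = encode(seq)
    n = len(seq)
    if n < MIN_LOOP + 2:
        return FoldResult("." * n, 0.0, {})
    C, Wx, Wt = _fill(enc, _W)
    pairs = _traceback(enc, C, Wx, Wt)
    pm: dict[int, int] = {}
    db = ["."] * n
    for i, j in pairs:
        pm[i] = j
        pm[j] = i
        db[i] = "("
        db[j] = ")"
    return FoldResult("".join(db), float(-Wt[0, n - 1]), pm)


def reverse_complement(seq: str) -> str:
    return seq.upper().replace("U", "T").translate(_RC)[::-1]


_RC = str.maketrans("ACGTN", "TGCAN")
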