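"""Independent oracles used by the test suite.

Everything here is deliberately naive — exhaustive enumeration, full
scans, explicit arithmetic — and shares no code path with the package
implementations it checks.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

PAIR_WEIGHTS = {
    frozenset("GC"): 3,
    frozenset("AT"): 2,
    frozenset("GT"): 1,
}


def revcomp(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


def pairable(a: str, b: str) -> bool:
    return frozenset((a, b)) in PAIR_WEIGHTS


def enumerate_structures(seq: str, i: int = 0, j: int | None = None):
    """Yield every valid nested pair set (loops >= 3) exactly once."""
    if j is None:
        j = len(seq) - 1
    if j - i < 4:
        yield frozenset()
        return
    for s in enumerate_structures(seq, i + 1, j):
        yield s
    for k in range(i + 4, j + 1):
        if pairable(seq[i], seq[k]):
            for left in enumerate_structures(seq, i + 1, k - 1):
                for right in enumerate_structures(seq, k + 1, j):
                    yield left | right | frozenset({(i, k)})


def score_structure(seq: str, pairs: frozenset) -> int:
    """Stacking score: a pair whose inner neighbor is paired earns its
    type weight (GC 3, AU 2, GU 1); otherwise 1."""
    total = 0
    for i, j in pairs:
        if (i + 1, j - 1) in pairs:
            total += PAIR_WEIGHTS[frozenset((seq[i], seq[j]))]
        else:
            total += 1
    return total


def best_score_by_enumeration(seq: str) -> int:
    return max(score_structure(seq, s) for s in enumerate_structures(seq))


def brute_force_hits(genome: dict[str, str], query: str, max_mm: int):
    """Every ungapped placement on either strand by full Hamming scan."""
    hits = []
    for strand, q in (("+", query), ("-", revcomp(query))):
        qa = np.frombuffer(q.encode(), dtype=np.uint8)
        for chrom, seq in genome.items():
            ga = np.frombuffer(seq.encode(), dtype=np.uint8)
            n = len(ga) - len(qa) + 1
            if n <= 0:
                continue
            mm = np.zeros(n, dtype=np.int32)
            for i in range(len(qa)):
                mm += ga[i:i + n] != qa[i]
            for p in np.nonzero(mm <= max_mm)[0]:
                hits.append((chrom, int(p), int(mm[p]), strand))
    return sorted(hits)


def exact_binomial_tail(n: int, k: int, period: int = 21) -> Fraction:
    """P[Bin(n, 1/period) >= k] with exact rational arithmetic."""
    p = Fraction(1, period)
    total = Fraction(0)
    from math import comb

    for j in range(k, n + 1):
        total += comb(n, j) * p ** j * (1 - p) ** (n - j)
    return total


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Dinucleotide-preserving shuffle via a random Eulerian walk."""
    edges: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    for a in edges:
        rng.shuffle(edges[a])
    stack = [seq[0]]
    trail = []
    work = {a: list(lst) for a, lst in edges.items()}
    while stack:
        v = stack[-1]
        if work.get(v):
            stack.append(work[v].pop())
        else:
            trail.append(stack.pop())
    trail.reverse()
    if len(trail) != len(seq):  # walk got stuck; fall back to the original
        return seq
    return "".join(trail)
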