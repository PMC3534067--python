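"""Trigger-site detection and 21-nt phasing on trans-acting siRNA loci.

A trigger miRNA cleaves its target transcript between miRNA positions 10
and 11; downstream dicing then releases products whose 5' ends fall every
21 bases from the cut.  Phasing is scored on *distinct* aligned 5'-end
positions (read counts would let abundance skew dominate): with n
positions and k of them in the modal register, the score is k/n and the
p-value is the exact binomial tail P[Bin(n, 1/21) >= k], Bonferroni
corrected for the 21 scanned registers.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from scipy.stats import binom

from .fold import reverse_complement as rc
from .types import Alignment, PhasingResult, TriggerSite

WC = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _site_matches(site: str, mirna: str) -> int:
    """Effective matches: Watson-Crick + wobble pairs at half weight (floored)."""
    wc = 0
    gu = 0
    for i, s in enumerate(site):
        m = mirna[len(mirna) - 1 - i]  # antiparallel partner
        if s == WC[m]:
            wc += 1
        elif (m == "G" and s == "T") or (m == "T" and s == "G"):
            gu += 1
    return wc + gu // 2


def find_trigger_site(
    transcript: str,
    mirna: str,
    min_matches: int = 17,
    transcript_id: str = "",
) -> list[TriggerSite]:
    """Every ungapped placement of the miRNA complement scoring >= min_matches.

    The cleavage position is the transcript coordinate of the first base
    3' of the cut, which falls between miRNA positions 10 and 11 counted
    from the miRNA 5' end.
    """
    t = transcript.upper().replace("U", "T")
    q = mirna.upper().replace("U", "T")
    L = len(q)
    n = len(t)
    if n < L:
        return []
    tenc = np.frombuffer(t.encode("ascii"), dtype=np.uint8)
    n_off = n - L + 1
    wc = np.zeros(n_off, dtype=np.int32)
    gu = np.zeros(n_off, dtype=np.int32)
    for i in range(L):
        m = q[L - 1 - i]  # antiparallel miRNA partner of site position i
        col = tenc[i:i + n_off]
        wc += col == ord(WC[m])
        if m == "G":
            gu += col == ord("T")
        elif m == "T":
            gu += col == ord("G")
    eff = wc + gu // 2
    sites = []
    for p in np.nonzero(eff >= min_matches)[0]:
        sites.append(TriggerSite(
            transcript_id=transcript_id,
            position=int(p),
            cleavage_pos=int(p) + L - 10,
            matches=int(eff[p]),
            mismatches=L - int(eff[p]),
        ))
    return sites


def collect_positions(
    alignments: Sequence[Alignment],
    cleavage_pos: int,
    region_start: int = 0,
) -> list[int]:
    """Distinct phase-relevant 5' positions downstream of the cut.

    Positions are transcript-relative.  Antisense alignments enter with a
    +2 offset on their leftmost coordinate — the 2-nt 3' overhang of the
    dicing duplex places the antisense 5' end two bases past the sense
    register.
    """
    pos = set()
    for aln in alignments:
        start = aln.locus.start - region_start
        p = start + 2 if aln.locus.strand == "-" else start
        if p >= cleavage_pos:
            pos.add(p)
    return sorted(pos)


def phase_register(
    positions: Sequence[int],
    cleavage_pos: int,
    period: int = 21,
    min_positions: int = 3,
) -> PhasingResult:
    """Register tallies modulo ``period`` with the Bonferroni binomial tail."""
    regs = [(p - cleavage_pos) % period for p in sorted(set(positions))]
    counts = [0] * period
    for r in regs:
        counts[r] += 1
    n = len(regs)
    if n < min_positions:
        return PhasingResult(counts, n, max(counts) if counts else 0, 0.0, 1.0, insufficient=True)
    k = max(counts)
    p = float(min(1.0, period * binom.sf(k - 1, n, 1.0 / period)))
    return PhasingResult(counts, n, k, k / n, p)


def phase_alignments(
    alignments: Sequence[Alignment],
    site: TriggerSite,
    region_start: int = 0,
    period: int = 21,
) -> PhasingResult:
    return phase_register(
        collect_positions(alignments, site.cleavage_pos, region_start), site.cleavage_pos, period
    )


def enumerate_phased_products(
    transcript: str,
    site: TriggerSite,
    signatures_by_seq: dict[str, dict[str, float]],
    alignments: Sequence[Alignment] = (),
    region_start: int = 0,
    period: int = 21,
) -> list[dict]:
    """Ordered phased product table (D1, D2, ...) downstream of the cut.

    Each full ``period``-base window in register 0 is listed with the
    signatures whose 5' ends start it (sense in register, antisense via
    the +2 duplex offset) and their per-library normalized counts; windows
    truncated by the transcript end are excluded.  The most-abundant
    product carries ``most_abundant=True``.
    """
    t = transcript.upper().replace("U", "T")
    aln_by_pos: dict[int, list[Alignment]] = {}
    for aln in alignments:
        start = aln.locus.start - region_start
        p = start + 2 if aln.locus.strand == "-" else start
        aln_by_pos.setdefault(p, []).append(aln)
    rows = []
    c = site.cleavage_pos
    idx = 1
    while c + (idx - 1) * period + period <= len(t):
        w_lo = c + (idx - 1) * period
        window = t[w_lo:w_lo + period]
        sigs = []
        total = 0.0
        cpm: dict[str, float] = {}
        for aln in aln_by_pos.get(w_lo, []):
            seq = window if aln.locus.strand == "+" else rc(t[w_lo - 2:w_lo - 2 + period])
            entry = signatures_by_seq.get(seq)
            sigs.append(seq)
            if entry:
                for lib, v in entry.items():
                    cpm[lib] = cpm.get(lib, 0.0) + v
                total += sum(entry.values())
        if sigs:
            rows.append({
                "phase": f"D{idx}",
                "offset": w_lo,
                "window": window,
                "signatures": sigs,
                "cpm": cpm,
                "total_cpm": total,
            })
        idx += 1
    best = max(rows, key=lambda r: r["total_cpm"], default=None)
    for r in rows:
        r["most_abundant"] = bool(r["total_cpm"]) and r is best
    return rows


def null_registers(
    rng: np.random.Generator, n_positions: int, span: int, n_clusters: int, period: int = 21
) -> np.ndarray:
    """Modal-register counts for clusters of uniform distinct positions.

    Utility for calibration studies: each row draws ``n_positions``
    distinct positions uniformly from ``span`` and returns the modal
    register count.
    """
    out = np.empty(n_clusters, dtype=int)
    for i in range(n_clusters):
        pos = rng.choice(span, size=n_positions, replace=False)
        counts = np.bincount(pos % period, minlength=period)
        out[i] = counts.max()
    return out
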