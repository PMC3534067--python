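"""miRNA locus validation by precursor folding.

A mapped signature is accepted as a miRNA when some ~200-base window
around its locus folds into a stem-loop in which the mature product sits
on one arm, paired across to the other: most mature bases paired, no
terminal-loop placement, a minimum fold score per base, and few internal
bulges.  The module also pairs 5p/3p products (testing the 2-nt 3'
stagger of Dicer duplexes) and groups members into miRNA families.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .fold import fold_rna
from .types import FoldResult, GenomeLocus, HairpinCandidate


@dataclass
class HairpinCriteria:
    """Acceptance thresholds for a folded precursor window."""

    min_paired: int = 16          # mature bases paired
    max_energy_per_base: float = -0.25
    max_bulge: int = 3            # unpaired bases internal to the mature span
    max_partner_spread: int = 6   # partner span may exceed the mature span by this
    window: int = 200
    stride: int = 20
    edge_margin: int = 10


def extract_precursor_windows(
    locus: GenomeLocus,
    genome: dict[str, str],
    criteria: HairpinCriteria = HairpinCriteria(),
) -> list[tuple[GenomeLocus, str, tuple[int, int]]]:
    """Candidate windows with the mature span scanned across each window.

    The mature signature is positioned at offsets ``edge_margin``,
    ``edge_margin + stride``, ... so windows cover both possible arms.
    Windows are clipped at chromosome ends but always contain the mature
    span.  Returns ``(window locus, window sequence, mature offsets)``.
    """
    chrom_seq = genome[locus.chrom]
    L = len(locus)
    w = criteria.window
    out = []
    offsets = range(criteria.edge_margin, max(w - L - criteria.edge_margin, criteria.edge_margin) + 1,
                    criteria.stride)
    seen = set()
    for o in offsets:
        start = max(locus.start - o, 0)
        end = min(start + w, len(chrom_seq))
        start = max(min(start, locus.start), 0)
        if end < locus.end:
            end = locus.end
        if (start, end) in seen:
            continue
        seen.add((start, end))
        out.append((
            GenomeLocus(locus.chrom, start, end, locus.strand),
            chrom_seq[start:end],
            (locus.start - start, locus.end - start),
        ))
    return out


def _mature_bulges(pair_map: dict[int, int], span: tuple[int, int]) -> int:
    """Unpaired bases strictly internal to the mature span (terminal runs excluded)."""
    lo, hi = span
    flags = [i in pair_map for i in range(lo, hi)]
    if not any(flags):
        return hi - lo
    first = flags.index(True)
    last = len(flags) - 1 - flags[::-1].index(True)
    return sum(1 for f in flags[first:last + 1] if not f)


def _check_window(
    fold: FoldResult, seq: str, span: tuple[int, int], criteria: HairpinCriteria
) -> tuple[bool, list[str], Optional[str]]:
    lo, hi = span
    partners = [fold.pair_map[i] for i in range(lo, hi) if i in fold.pair_map]
    reasons = []
    if len(partners) < criteria.min_paired:
        reasons.append(f"only {len(partners)} mature bases paired")
    arm: Optional[str] = None
    if partners:
        if all(p >= hi for p in partners):
            arm = "5p"
        elif all(p < lo for p in partners):
            arm = "3p"
        else:
            reasons.append("mature in loop")
        # a genuine duplex pairs the mature against one compact region
        if max(partners) - min(partners) + 1 > (hi - lo) + criteria.max_partner_spread:
            reasons.append("mature partners not contiguous")
    if fold.energy / max(len(seq), 1) > criteria.max_energy_per_base:
        reasons.append("fold too weak")
    if _mature_bulges(fold.pair_map, span) > criteria.max_bulge:
        reasons.append("too many bulges in mature span")
    return (not reasons and arm is not None), reasons, arm


def evaluate_hairpin(
    windows: Sequence[tuple[GenomeLocus, str, tuple[int, int]]],
    criteria: HairpinCriteria = HairpinCriteria(),
) -> Optional[HairpinCandidate]:
    """Fold every candidate window; best = lowest-energy passing window.

    When no window passes, the lowest-energy candidate is returned with
    its failure reasons so callers can report why a locus was rejected.
    """
    best_pass: Optional[HairpinCandidate] = None
    best_fail: Optional[HairpinCandidate] = None
    for locus, seq, span in windows:
        fold = fold_rna(seq)
        ok, reasons, arm = _check_window(fold, seq, span, criteria)
        cand = HairpinCandidate(
            window=locus, window_seq=seq, fold=fold, mature_span=span,
            arm=arm, verdict=ok, reasons=reasons,
        )
        if ok:
            if best_pass is None or fold.energy < best_pass.fold.energy:
                best_pass = cand
        elif best_fail is None or fold.energy < best_fail.fold.energy:
            best_fail = cand
    return best_pass or best_fail


def validate_locus(
    locus: GenomeLocus,
    genome: dict[str, str],
    criteria: HairpinCriteria = HairpinCriteria(),
) -> Optional[HairpinCandidate]:
    """Window scan + fold + criteria for one mapped mature locus."""
    return evaluate_hairpin(extract_precursor_windows(locus, genome, criteria), criteria)


@dataclass
class DuplexReport:
    major_arm: Optional[str] = None
    major_seq: Optional[str] = None
    major_count: int = 0
    star_seq: Optional[str] = None
    star_count: int = 0
    stagger: Optional[bool] = None


def pair_5p_3p(
    hairpin: HairpinCandidate,
    arm_products: Sequence[tuple[str, int, tuple[int, int]]],
) -> DuplexReport:
    """Dominant 5p/3p products and the 2-nt 3' stagger test.

    ``arm_products`` holds ``(seq, read count, window-offset span)`` for
    signatures mapped inside the hairpin window.  The duplex shows the
    canonical stagger when each product's 5' start pairs with the base two
    inside the partner's 3' end.
    """
    pm = hairpin.fold.pair_map
    by_arm: dict[str, list[tuple[str, int, tuple[int, int]]]] = {"5p": [], "3p": []}
    for seq, count, (lo, hi) in arm_products:
        partners = [pm[i] for i in range(lo, hi) if i in pm]
        if not partners:
            continue
        mid = (lo + hi) / 2
        by_arm["5p" if sum(partners) / len(partners) > mid else "3p"].append((seq, count, (lo, hi)))
    report = DuplexReport()
    tops = {
        arm: max(prods, key=lambda t: t[1]) for arm, prods in by_arm.items() if prods
    }
    if not tops:
        return report
    major_arm = max(tops, key=lambda a: tops[a][1])
    report.major_arm = major_arm
    report.major_seq, report.major_count = tops[major_arm][0], tops[major_arm][1]
    other = "3p" if major_arm == "5p" else "5p"
    if other in tops:
        report.star_seq, report.star_count = tops[other][0], tops[other][1]
        (a5, _, s5), (a3, _, s3) = tops.get("5p"), tops.get("3p")
        lo5, hi5 = s5
        lo3, hi3 = s3
        report.stagger = (pm.get(lo5) == hi3 - 3) and (pm.get(lo3) == hi5 - 3)
    return report


_FAMILY_RE = re.compile(r"(miR)[-]?(\d+)", re.IGNORECASE)


def family_key(annotation: str) -> Optional[str]:
    """Annotation base name with letter/arm suffixes stripped (miR156a -> miR156)."""
    m = _FAMILY_RE.search(annotation)
    if not m:
        return None
    return f"miR{m.group(2)}"


def _variant_linked(u: str, v: str) -> bool:
    """<= 1 substitution with <= 2-base terminal shift between two matures."""
    if abs(len(u) - len(v)) > 2:
        return False
    for shift in range(-2, 3):
        lo_u = max(0, shift)
        lo_v = max(0, -shift)
        overlap = min(len(u) - lo_u, len(v) - lo_v)
        if overlap < max(len(u), len(v)) - 2:
            continue
        mm = sum(1 for a, b in zip(u[lo_u:lo_u + overlap], v[lo_v:lo_v + overlap]) if a != b)
        if mm <= 1:
            return True
    return False


@dataclass
class Family:
    name: str
    members: list[str] = field(default_factory=list)  # distinct sequences
    authentic: Optional[str] = None                   # most abundant member


def group_families(
    annotated: Sequence[tuple[str, str, int]],
    novel: Sequence[tuple[str, int]] = (),
) -> list[Family]:
    """Group mature sequences into families.

    ``annotated``: (seq, annotation, total reads) — family from the
    annotation base name.  ``novel``: (seq, total reads) hairpin-validated
    but unannotated sequences, clustered by single linkage at <= 1
    substitution and <= 2-base terminal shift.  The most-abundant member
    of each family is flagged as the putative authentic mature.
    """
    fams: dict[str, dict[str, int]] = {}
    for seq, ann, count in annotated:
        key = family_key(ann) or ann
        fams.setdefault(key, {})
        fams[key][seq] = fams[key].get(seq, 0) + count
    # union-find over novel sequences
    novel_list = [(s, c) for s, c in novel]
    parent = list(range(len(novel_list)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(len(novel_list)):
        for j in range(i + 1, len(novel_list)):
            if _variant_linked(novel_list[i][0], novel_list[j][0]):
                parent[find(i)] = find(j)
    clusters: dict[int, dict[str, int]] = {}
    for i, (seq, count) in enumerate(novel_list):
        root = find(i)
        clusters.setdefault(root, {})
        clusters[root][seq] = clusters[root].get(seq, 0) + count
    for n, members in enumerate(clusters.values(), start=1):
        fams[f"novel-{n}"] = members
    out = []
    for name in sorted(fams):
        members = fams[name]
        fam = Family(name=name, members=sorted(members))
        fam.authentic = max(members, key=lambda s: (members[s], s))
        out.append(fam)
    return out
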