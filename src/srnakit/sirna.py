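"""siRNA-producing regions: broad, multi-signature alignment clusters.

What separates an siRNA region from a miRNA locus is breadth: dozens of
distinct signatures spread over hundreds of bases, frequently on both
strands, versus a single dominant ~21-mer with a hairpin.  The module
clusters recorded alignments, classifies clusters, tests whether a
cluster was processed from spliced mRNA (exon-only alignment), and
searches for a local inverted-repeat source.
"""

from __future__ import annotations

from typing import Optional, Sequence

from .fold import reverse_complement as rc
from .mapping import GeneModels
from .types import Alignment, GenomeLocus, SirnaCluster


def cluster_alignments(
    alignments: Sequence[Alignment], max_gap: int = 200
) -> list[SirnaCluster]:
    """Single-linkage merge of same-chromosome alignments within ``max_gap``.

    Strand is ignored during merging (dsRNA sources produce both strands);
    clusters come back sorted by distinct-signature count, descending.
    """
    by_chrom: dict[str, list[Alignment]] = {}
    for aln in alignments:
        by_chrom.setdefault(aln.locus.chrom, []).append(aln)
    clusters: list[SirnaCluster] = []
    for chrom, alns in by_chrom.items():
        alns.sort(key=lambda a: (a.locus.start, a.locus.end))
        group: list[Alignment] = []
        group_end = -1

        def flush() -> None:
            if not group:
                return
            start = min(a.locus.start for a in group)
            end = max(a.locus.end for a in group)
            covered: set[int] = set()
            strands = {"+": 0, "-": 0}
            sigs = set()
            for a in group:
                covered.update(range(a.locus.start, a.locus.end))
                strands[a.locus.strand] += 1
                sigs.add(a.signature_id)
            clusters.append(SirnaCluster(
                region=GenomeLocus(chrom, start, end),
                n_signatures=len(sigs),
                n_alignments=len(group),
                footprint=len(covered),
                strands=strands,
                signature_ids=sorted(sigs),
            ))

        for aln in alns:
            if group and aln.locus.start - group_end > max_gap:
                flush()
                group = []
            group.append(aln)
            group_end = max(group_end, aln.locus.end)
        flush()
    clusters.sort(key=lambda c: (-c.n_signatures, c.region.chrom, c.region.start))
    for c in clusters:
        c._alignments = [a for a in alignments if a.locus.chrom == c.region.chrom
                         and a.locus.start >= c.region.start and a.locus.end <= c.region.end]
    return clusters


class ClassifyThresholds:
    mirna_max_footprint = 30
    mirna_min_dominance = 0.80
    mirna_min_strand_bias = 0.90
    sirna_min_footprint = 100
    sirna_min_signatures = 10


def classify_cluster(
    cluster: SirnaCluster,
    signature_reads: dict[str, int],
    has_passing_hairpin: bool,
    thresholds: ClassifyThresholds = ClassifyThresholds(),
) -> str:
    """miRNA-like, siRNA, or ambiguous.

    miRNA-like needs a narrow footprint, one dominant sequence, strong
    strand bias, and an overlapping passing hairpin; siRNA needs breadth
    and signature diversity; everything else is ambiguous.
    """
    reads = [signature_reads.get(s, 0) for s in cluster.signature_ids]
    total = sum(reads)
    dominance = max(reads) / total if total else 0.0
    aligned = sum(cluster.strands.values())
    bias = max(cluster.strands.values()) / aligned if aligned else 0.0
    if (
        cluster.footprint <= thresholds.mirna_max_footprint
        and dominance >= thresholds.mirna_min_dominance
        and bias >= thresholds.mirna_min_strand_bias
        and has_passing_hairpin
    ):
        cluster.class_label = "miRNA-like"
    elif (
        cluster.footprint >= thresholds.sirna_min_footprint
        and cluster.n_signatures >= thresholds.sirna_min_signatures
    ):
        cluster.class_label = "siRNA"
    else:
        cluster.class_label = "ambiguous"
    return cluster.class_label


def exon_only_test(
    cluster: SirnaCluster,
    models: GeneModels,
    min_exon_fraction: float = 0.98,
) -> tuple[Optional[float], Optional[bool]]:
    """Fraction of aligned bases on exons of an overlapping intron-bearing gene.

    ``spliced_flag`` is true when at least ``min_exon_fraction`` of the
    cluster's aligned bases inside the gene span are exonic — the pattern
    left by siRNAs processed from spliced mRNA.  Genes without introns
    make the test inapplicable (both values ``None``).
    """
    gids = [g for g in models.overlapping_genes(cluster.region) if models.has_introns(g)]
    if not gids:
        cluster.exon_fraction = None
        cluster.spliced_flag = None
        return None, None
    gid = gids[0]
    chrom, gs, ge, _ = models.genes[gid]
    exonic = 0
    total = 0
    exons = models.exons.get(gid, [])
    for aln in getattr(cluster, "_alignments", []):
        lo = max(aln.locus.start, gs)
        hi = min(aln.locus.end, ge)
        if hi <= lo:
            continue
        total += hi - lo
        for es, ee in exons:
            o = min(hi, ee) - max(lo, es)
            if o > 0:
                exonic += o
    if total == 0:
        cluster.exon_fraction = None
        cluster.spliced_flag = None
        return None, None
    frac = exonic / total
    cluster.exon_fraction = frac
    cluster.spliced_flag = frac >= min_exon_fraction
    return frac, cluster.spliced_flag


def find_inverted_repeat_source(
    region: GenomeLocus,
    genome: dict[str, str],
    flank: int = 10_000,
    seed_len: int = 20,
    min_arm: int = 100,
    min_identity: float = 0.90,
    max_spacer: int = 5_000,
) -> list[dict]:
    """Inverted-repeat arm pairs near a cluster, by seeded self-comparison.

    Exact ``seed_len``-mers shared between the local sequence and its
    reverse complement are chained along diagonals into candidate arms,
    then each merged arm is verified base-by-base against the reverse
    complement of its partner.  Reported: arm length, identity, spacer.
    """
    chrom_seq = genome[region.chrom]
    lo = max(region.start - flank, 0)
    hi = min(region.end + flank, len(chrom_seq))
    seq = chrom_seq[lo:hi]
    n = len(seq)
    if n < 2 * min_arm:
        return []
    rseq = rc(seq)
    index: dict[str, list[int]] = {}
    for i in range(n - seed_len + 1):
        index.setdefault(rseq[i:i + seed_len], []).append(i)
    # hits (i, j): seq[i:i+k] == rseq[j:j+k]; same diagonal d = i - j chains runs
    diag_hits: dict[int, list[int]] = {}
    for i in range(0, n - seed_len + 1):
        for j in index.get(seq[i:i + seed_len], ()):
            diag_hits.setdefault(i - j, []).append(i)
    results = []
    for d, starts in diag_hits.items():
        starts.sort()
        run_start = starts[0]
        prev = starts[0]
        runs = []
        for s in starts[1:]:
            if s - prev <= seed_len:
                prev = s
            else:
                runs.append((run_start, prev + seed_len))
                run_start = prev = s
        runs.append((run_start, prev + seed_len))
        for a_lo, a_hi in runs:
            arm_len = a_hi - a_lo
            if arm_len < min_arm:
                continue
            # partner of seq[a_lo:a_hi] on the rc: rseq[a_lo-d : a_hi-d],
            # i.e. seq[n-(a_hi-d) : n-(a_lo-d)]
            b_lo = n - (a_hi - d)
            b_hi = n - (a_lo - d)
            if b_lo < a_hi:  # keep the left arm of each pair; skip self/overlap
                continue
            spacer = b_lo - a_hi
            if spacer > max_spacer:
                continue
            arm = seq[a_lo:a_hi]
            partner = seq[b_lo:b_hi]
            matches = sum(1 for x, y in zip(arm, rc(partner)) if x == y)
            identity = matches / arm_len
            if identity < min_identity:
                continue
            results.append({
                "arm_len": arm_len,
                "identity": identity,
                "spacer": spacer,
                "arm1": GenomeLocus(region.chrom, lo + a_lo, lo + a_hi),
                "arm2": GenomeLocus(region.chrom, lo + b_lo, lo + b_hi),
            })
    results.sort(key=lambda r: (-r["arm_len"], r["spacer"]))
    # drop nested duplicates of the same pair
    deduped: list[dict] = []
    for r in results:
        if any(r["arm1"].overlaps(q["arm1"]) and r["arm2"].overlaps(q["arm2"]) for q in deduped):
            continue
        deduped.append(r)
    return deduped
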