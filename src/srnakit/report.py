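"""Pipeline orchestration, the expanded signature table, and summaries.

``run_pipeline`` chains the stages — preprocess, map, annotate, miRNA
hairpin validation, siRNA clustering, phasing, repeat profiles — over a
dataset directory and returns every stage product plus a summary whose
numbers are all recomputable from the stage outputs.

``report-only`` helpers reproduce cross-library arithmetic (unique-read
sums, depth-scaled thresholds, CPM/raw conversions) from a published
library summary table when raw reads are not available.
"""

from __future__ import annotations

import logging
import os
import time
from dataclasses import dataclass, field
from glob import glob
from importlib import resources
from typing import Optional

import pandas as pd

from . import mirna, phasing, preprocess, repeats, sirna
from .mapping import (
    GeneModels,
    GenomeIndex,
    align_signature,
    annotate_signature,
    apply_multimap_policy,
)
from .types import Alignment, GenomeLocus, HairpinCandidate, Signature

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    adapter: str = preprocess.DEFAULT_ADAPTER
    k: Optional[int] = None           # None = auto from library depth
    max_mm: int = 4
    record_cap: int = 10
    hairpin: mirna.HairpinCriteria = field(default_factory=mirna.HairpinCriteria)
    max_gap: int = 200
    min_trigger_matches: int = 17
    phasing_alpha: float = 0.05
    te_min_identity: float = 0.95
    novel_candidate_limit: int = 150
    max_loci_for_hairpin: int = 3


@dataclass
class PipelineResult:
    libraries: dict
    signatures: list[Signature]
    size_table: pd.DataFrame
    alignments: dict[str, list[Alignment]]      # uncapped, per signature id
    recorded: list[Alignment]                   # below the multimap cap
    hairpins: dict[str, HairpinCandidate]       # per signature id (best window)
    duplexes: dict[str, mirna.DuplexReport]
    families: list[mirna.Family]
    clusters: list
    phased_loci: list[dict]
    te_profiles: dict
    te_aggregate: object
    te_assignments: dict[str, str]
    rdna_profile: Optional[pd.DataFrame]
    multimap: pd.DataFrame
    summary: dict


def _stage(name: str, t0: float) -> float:
    t1 = time.time()
    log.info("stage %-12s %6.1fs", name, t1 - t0)
    return t1


def run_pipeline(input_dir: str, config: PipelineConfig = PipelineConfig()) -> PipelineResult:
    """Run every stage over a dataset directory.

    Expects ``genome.fa`` and one ``<CODE>.fastq`` per library; optional
    ``reference_mirna.fa``, ``te_db.fa``, ``models.gff3``, ``repeats.bed``.
    Missing required inputs fail fast with the stage and path named.
    """
    t0 = time.time()
    genome_path = os.path.join(input_dir, "genome.fa")
    if not os.path.exists(genome_path):
        raise FileNotFoundError(f"[map] missing genome FASTA: {genome_path}")
    fastqs = sorted(glob(os.path.join(input_dir, "*.fastq")))
    if not fastqs:
        raise FileNotFoundError(f"[preprocess] no *.fastq libraries in {input_dir}")

    # --- preprocess ---------------------------------------------------
    libraries = {}
    per_lib_counts = {}
    for path in fastqs:
        code = os.path.splitext(os.path.basename(path))[0]
        spec, counts = preprocess.preprocess_library(path, code, config.adapter, config.k)
        libraries[code] = spec
        per_lib_counts[code] = counts
    signatures = preprocess.build_union_db(per_lib_counts, libraries)
    size_table = preprocess.size_distribution(signatures)
    t0 = _stage("preprocess", t0)

    # --- map ----------------------------------------------------------
    index = GenomeIndex.from_fasta(genome_path)
    alignments: dict[str, list[Alignment]] = {}
    recorded: list[Alignment] = []
    for sig in signatures:
        alns = align_signature(sig, index, max_mm=config.max_mm)
        alignments[sig.sig_id] = alns
        rec, count = apply_multimap_policy(alns, config.record_cap)
        sig.loci = [a.locus for a in rec]
        sig.location_count = count
        recorded.extend(rec)
    t0 = _stage("map", t0)

    # --- annotate -----------------------------------------------------
    ref_path = os.path.join(input_dir, "reference_mirna.fa")
    reference: dict[str, str] = {}
    if os.path.exists(ref_path):
        from Bio import SeqIO

        reference = {r.id: str(r.seq) for r in SeqIO.parse(ref_path, "fasta")}
        for sig in signatures:
            hit = annotate_signature(sig.seq, reference)
            if hit is not None:
                sig.annotation = hit[0]
    gff_path = os.path.join(input_dir, "models.gff3")
    models = GeneModels.from_gff3(gff_path) if os.path.exists(gff_path) else None
    if models is not None:
        for sig in signatures:
            gids = set()
            for locus in sig.loci:
                gids.update(models.overlapping_genes(locus))
            sig.gene_models = sorted(gids)
    t0 = _stage("annotate", t0)

    # --- miRNA hairpin validation ------------------------------------
    genome = index.sequences
    candidates = [s for s in signatures if s.annotation and s.loci]
    novel = [
        s for s in signatures
        if s.annotation is None and s.loci and 20 <= s.length <= 22
        and s.location_count <= config.max_loci_for_hairpin
    ]
    novel.sort(key=lambda s: -s.total_raw())
    candidates += novel[:config.novel_candidate_limit]
    hairpins: dict[str, HairpinCandidate] = {}
    for sig in candidates:
        # a mature can also align (imperfectly) to the opposite arm of its
        # own precursor: prefer passing folds at the fewest-mismatch locus
        recorded_alns = sorted(
            (a for a in alignments[sig.sig_id] if sig.loci),
            key=lambda a: a.mismatches,
        )[:config.max_loci_for_hairpin]
        best: Optional[HairpinCandidate] = None
        best_key = None
        for aln in recorded_alns:
            cand = mirna.validate_locus(aln.locus, genome, config.hairpin)
            if cand is None:
                continue
            key = (0 if cand.verdict else 1, aln.mismatches, cand.fold.energy)
            if best_key is None or key < best_key:
                best, best_key = cand, key
        if best is not None:
            hairpins[sig.sig_id] = best
    passing = {sid: h for sid, h in hairpins.items() if h.verdict}
    by_id = {s.sig_id: s for s in signatures}
    duplexes: dict[str, mirna.DuplexReport] = {}
    for sid, h in passing.items():
        window = h.window
        # one placement per signature: the fewest-mismatch one (a mature can
        # also align imperfectly to the opposite arm of its own stem)
        best_in_window: dict[str, Alignment] = {}
        for aln in recorded:
            if aln.locus.chrom == window.chrom and aln.locus.start >= window.start \
                    and aln.locus.end <= window.end:
                prev = best_in_window.get(aln.signature_id)
                if prev is None or aln.mismatches < prev.mismatches:
                    best_in_window[aln.signature_id] = aln
        prods = [
            (by_id[a.signature_id].seq, by_id[a.signature_id].total_raw(),
             (a.locus.start - window.start, a.locus.end - window.start))
            for a in best_in_window.values()
        ]
        duplexes[sid] = mirna.pair_5p_3p(h, prods)
    annotated_members = [
        (s.seq, s.annotation, s.total_raw()) for s in signatures if s.annotation
    ]
    novel_validated = [
        (by_id[sid].seq, by_id[sid].total_raw())
        for sid in passing if by_id[sid].annotation is None
    ]
    families = mirna.group_families(annotated_members, novel_validated)
    t0 = _stage("mirna", t0)

    # --- siRNA clusters -----------------------------------------------
    clusters = sirna.cluster_alignments(recorded, config.max_gap)
    sig_reads = {s.sig_id: s.total_raw() for s in signatures}
    passing_windows = [h.window for h in passing.values()]
    for cluster in clusters:
        has_hp = any(w.overlaps(cluster.region) for w in passing_windows)
        sirna.classify_cluster(cluster, sig_reads, has_hp)
        if models is not None:
            sirna.exon_only_test(cluster, models)
    t0 = _stage("sirna", t0)

    # --- phasing -------------------------------------------------------
    triggers = sorted({s.seq for s in signatures if s.annotation})
    phased_loci: list[dict] = []
    margin = 100
    for cluster in clusters:
        if cluster.n_signatures < 3 or cluster.class_label == "miRNA-like":
            continue
        chrom_seq = genome[cluster.region.chrom]
        lo = max(cluster.region.start - margin, 0)
        hi = min(cluster.region.end + margin, len(chrom_seq))
        transcript = chrom_seq[lo:hi]
        best_site = None
        best_trigger = None
        for trig in triggers:
            for site in phasing.find_trigger_site(
                transcript, trig, config.min_trigger_matches,
                transcript_id=f"{cluster.region.chrom}:{lo + 1}",
            ):
                if best_site is None or site.matches > best_site.matches:
                    best_site = site
                    best_trigger = trig
        if best_site is None:
            continue
        result = phasing.phase_alignments(
            cluster._alignments, best_site, region_start=lo)
        if not result.insufficient and result.p_value < config.phasing_alpha:
            sig_cpm = {by_id[a.signature_id].seq: by_id[a.signature_id].cpm
                       for a in cluster._alignments}
            products = phasing.enumerate_phased_products(
                transcript, best_site, sig_cpm, cluster._alignments, region_start=lo)
            phased_loci.append({
                "region": cluster.region,
                "trigger": best_trigger,
                "site": best_site,
                "result": result,
                "products": products,
            })
    t0 = _stage("phase", t0)

    # --- repeats -------------------------------------------------------
    te_path = os.path.join(input_dir, "te_db.fa")
    te_profiles: dict = {}
    te_aggregate = None
    te_assignments: dict[str, str] = {}
    if os.path.exists(te_path):
        db = repeats.TEDatabase.from_fasta(te_path)
        te_assignments = repeats.assign_families(signatures, db, config.te_min_identity)
        exclusions = {
            by_id[sid].seq for sid in passing
            if by_id[sid].annotation is not None and by_id[sid].seq in te_assignments
        }
        te_profiles, te_aggregate = repeats.family_size_profiles(
            te_assignments, signatures, exclusions=exclusions)
    rdna_profile = None
    bed_path = os.path.join(input_dir, "repeats.bed")
    if os.path.exists(bed_path):
        with open(bed_path) as fh:
            for line in fh:
                chrom, s, e, *_ = line.split("\t")
                region = GenomeLocus(chrom, int(s), int(e))
                all_alns = [a for alns in alignments.values() for a in alns]
                rdna_profile = repeats.region_size_profile(region, all_alns, signatures)
                break
    multimap = repeats.multimap_statistics(signatures)
    t0 = _stage("repeats", t0)

    # --- summary -------------------------------------------------------
    per_lib_uniques = {
        code: sum(1 for c in counts.values() if c >= libraries[code].k_threshold)
        for code, counts in per_lib_counts.items()
    }
    matched = sum(1 for s in signatures if s.location_count >= 1)
    summary = {
        "total_raw_reads": sum(l.total_reads for l in libraries.values()),
        "per_library_uniques": per_lib_uniques,
        "per_library_uniques_sum": sum(per_lib_uniques.values()),
        "union_db_size": len(signatures),
        "genome_matched": matched,
        "genome_matched_pct": matched / len(signatures) * 100 if signatures else 0.0,
        "n_annotated": sum(1 for s in signatures if s.annotation),
        "n_families": len(families),
        "n_passing_hairpins": len(passing),
        "n_clusters": len(clusters),
        "n_sirna_clusters": sum(1 for c in clusters if c.class_label == "siRNA"),
        "n_phased_loci": len(phased_loci),
        "te_matched": len(te_assignments),
    }
    return PipelineResult(
        libraries=libraries,
        signatures=signatures,
        size_table=size_table,
        alignments=alignments,
        recorded=recorded,
        hairpins=hairpins,
        duplexes=duplexes,
        families=families,
        clusters=clusters,
        phased_loci=phased_loci,
        te_profiles=te_profiles,
        te_aggregate=te_aggregate,
        te_assignments=te_assignments,
        rdna_profile=rdna_profile,
        multimap=multimap,
        summary=summary,
    )


# ---------------------------------------------------------------------------
# expanded signature table


def export_expanded_table(
    signatures: list[Signature], path: str, library_order: Optional[list[str]] = None
) -> pd.DataFrame:
    """One row per signature in fixed column order; TSV on disk.

    Loci are semicolon-joined 1-based ``chrom:start`` labels and stay
    empty for signatures whose placement count hit the recording cap.
    """
    if library_order is None:
        library_order = list(signatures[0].raw_counts) if signatures else []
    rows = []
    for sig in signatures:
        row: dict = {
            "id": sig.sig_id,
            "seq": sig.seq,
            "length": sig.length,
            "annotation": sig.annotation or "",
        }
        for code in library_order:
            row[f"raw_{code}"] = sig.raw_counts.get(code, 0)
        for code in library_order:
            row[f"cpm_{code}"] = round(sig.cpm.get(code, 0.0), 4)
        row["loci"] = ";".join(
            f"{l.chrom}:{l.start + 1}:{l.strand}" for l in sig.loci)
        row["gene_models"] = ";".join(sig.gene_models)
        row["location_count"] = sig.location_count
        rows.append(row)
    df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False)
    return df


def parse_expanded_table(path: str) -> list[Signature]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    raw_cols = [c for c in df.columns if c.startswith("raw_")]
    cpm_cols = [c for c in df.columns if c.startswith("cpm_")]
    sigs = []
    for _, row in df.iterrows():
        loci = []
        if row["loci"]:
            for item in str(row["loci"]).split(";"):
                chrom, start, strand = item.rsplit(":", 2)
                L = int(row["length"])
                loci.append(GenomeLocus(chrom, int(start) - 1, int(start) - 1 + L, strand))
        sigs.append(Signature(
            sig_id=row["id"],
            seq=row["seq"],
            raw_counts={c[4:]: int(row[c]) for c in raw_cols},
            cpm={c[4:]: float(row[c]) for c in cpm_cols},
            annotation=row["annotation"] or None,
            loci=loci,
            location_count=int(row["location_count"]),
            gene_models=[g for g in str(row["gene_models"]).split(";") if g],
        ))
    return sigs


# ---------------------------------------------------------------------------
# report-only mode over a published library summary table


def load_published_library_table(path: Optional[str] = None) -> pd.DataFrame:
    """Library summary table (code, tissue, total raw reads, unique reads).

    Defaults to the bundled eight-library soybean summary used by the
    worked examples.
    """
    if path is None:
        with resources.files("srnakit.data").joinpath("soy_library_summary.tsv").open() as fh:
            return pd.read_csv(fh, sep="\t")
    return pd.read_csv(path, sep="\t")


def cpm_to_raw(cpm: float, total_reads: int) -> float:
    """Invert CPM normalization: raw reads implied by a normalized count."""
    return cpm * total_reads / 1_000_000


def published_summary(table: Optional[pd.DataFrame] = None) -> dict:
    """Cross-library arithmetic recomputed from a published summary table."""
    if table is None:
        table = load_published_library_table()
    ks = {row["code"]: preprocess.choose_threshold(int(row["total_reads"]))
          for _, row in table.iterrows()}
    return {
        "per_library_uniques": dict(zip(table["code"], table["uniques"])),
        "per_library_uniques_sum": int(table["uniques"].sum()),
        "total_raw_reads": int(table["total_reads"].sum()),
        "total_raw_reads_millions": round(float(table["total_reads"].sum()) / 1e6, 1),
        "k_thresholds": ks,
    }
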