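"""Cluster construction, classification, exon-only test, IR search."""

import numpy as np
import pytest

from srnakit.fold import reverse_complement as rc
from srnakit.mapping import GeneModels
from srnakit.sirna import (
    classify_cluster,
    cluster_alignments,
    exon_only_test,
    find_inverted_repeat_source,
)
from srnakit.types import Alignment, GenomeLocus


def aln(sig, chrom, start, length=21, strand="+", mm=0):
    return Alignment(sig, GenomeLocus(chrom, start, start + length, strand), mm)


class TestClustering:
    def test_broad_two_strand_cluster(self, rng):
        """115 distinct signatures over a 1.5 kb span merge into one cluster."""
        alns = []
        for i in range(115):
            start = int(rng.integers(0, 1480))
            alns.append(aln(f"s{i}", "c1", 1000 + start, strand="+-"[i % 2]))
        clusters = cluster_alignments(alns, max_gap=200)
        assert len(clusters) == 1
        c = clusters[0]
        assert c.n_signatures == 115
        assert c.strands["+"] > 0 and c.strands["-"] > 0

    def test_isolated_alignment_is_singleton_cluster(self):
        clusters = cluster_alignments([aln("s", "c1", 500)])
        assert len(clusters) == 1
        assert clusters[0].n_signatures == 1
        assert clusters[0].footprint == 21

    def test_gap_boundary(self):
        # ends at 521; gap of 201 to 722 splits, gap of 200 merges
        split = cluster_alignments([aln("a", "c1", 500), aln("b", "c1", 722)], 200)
        merged = cluster_alignments([aln("a", "c1", 500), aln("b", "c1", 721)], 200)
        assert len(split) == 2
        assert len(merged) == 1

    def test_order_invariance(self, rng):
        alns = [aln(f"s{i}", "c1", int(rng.integers(0, 5000))) for i in range(60)]
        ref = cluster_alignments(alns)
        for _ in range(3):
            perm = [alns[i] for i in rng.permutation(len(alns))]
            got = cluster_alignments(perm)
            assert [(c.region, c.n_signatures, c.footprint, c.strands)
                    for c in got] == [(c.region, c.n_signatures, c.footprint, c.strands)
                                      for c in ref]

    def test_breadth_ratio_bounds(self, rng):
        alns = [aln(f"s{i}", "c1", int(rng.integers(0, 2000))) for i in range(30)]
        for c in cluster_alignments(alns):
            assert 0 <= c.breadth_ratio <= 1
            assert sum(c.strands.values()) == c.n_alignments


class TestClassification:
    def test_mirna_like(self):
        alns = [aln("m", "c1", 1000)] * 3
        c = cluster_alignments(alns)[0]
        assert classify_cluster(c, {"m": 1000}, has_passing_hairpin=True) == "miRNA-like"

    def test_mirna_like_needs_hairpin(self):
        c = cluster_alignments([aln("m", "c1", 1000)])[0]
        assert classify_cluster(c, {"m": 1000}, has_passing_hairpin=False) == "ambiguous"

    def test_sirna_breadth(self, rng):
        alns = [aln(f"s{i}", "c1", 1000 + int(rng.integers(0, 580)), strand="+-"[i % 2])
                for i in range(50)]
        c = cluster_alignments(alns)[0]
        assert classify_cluster(c, {f"s{i}": 10 for i in range(50)}, False) == "siRNA"

    def test_sparse_is_ambiguous(self):
        alns = [aln("a", "c1", 1000), aln("b", "c1", 1020), aln("c", "c1", 1040)]
        c = cluster_alignments(alns)[0]
        assert classify_cluster(c, {"a": 5, "b": 5, "c": 5}, False) == "ambiguous"


GFF = """##gff-version 3
c1\tsrc\tgene\t1001\t3000\t.\t+\t.\tID=g1
c1\tsrc\texon\t1001\t1500\t.\t+\t.\tID=g1.e1;Parent=g1
c1\tsrc\texon\t2501\t3000\t.\t+\t.\tID=g1.e2;Parent=g1
c1\tsrc\tgene\t5001\t5600\t.\t+\t.\tID=g2
c1\tsrc\texon\t5001\t5600\t.\t+\t.\tID=g2.e1;Parent=g2
"""


class TestExonOnly:
    @pytest.fixture()
    def models(self, tmp_path):
        p = tmp_path / "m.gff3"
        p.write_text(GFF)
        return GeneModels.from_gff3(str(p))

    def test_exonic_cluster_flagged_spliced(self, models, rng):
        alns = []
        for i in range(20):
            start = 1000 + int(rng.integers(0, 480))
            alns.append(aln(f"s{i}", "c1", start))
        for i in range(20, 40):
            start = 2500 + int(rng.integers(0, 480))
            alns.append(aln(f"s{i}", "c1", start))
        c = cluster_alignments(alns, max_gap=2000)[0]
        frac, flag = exon_only_test(c, models)
        assert frac == pytest.approx(1.0)
        assert flag is True

    def test_intronic_reads_lower_fraction(self, models):
        alns = [aln("e", "c1", 1100), aln("i", "c1", 1800)]  # one exonic, one intronic
        c = cluster_alignments(alns, max_gap=2000)[0]
        frac, flag = exon_only_test(c, models)
        assert frac == pytest.approx(0.5)
        assert flag is False

    def test_removing_intronic_alignment_cannot_decrease_fraction(self, models):
        with_intron = cluster_alignments(
            [aln("e", "c1", 1100), aln("e2", "c1", 1200), aln("i", "c1", 1800)], 2000)[0]
        without = cluster_alignments(
            [aln("e", "c1", 1100), aln("e2", "c1", 1200)], 2000)[0]
        f1, _ = exon_only_test(with_intron, models)
        f2, _ = exon_only_test(without, models)
        assert f2 >= f1

    def test_intronless_gene_not_applicable(self, models):
        c = cluster_alignments([aln("s", "c1", 5100)])[0]
        frac, flag = exon_only_test(c, models)
        assert frac is None and flag is None


class TestInvertedRepeat:
    def _genome(self, rng, arm_len, spacer_len, mutate=0):
        arm = "".join("ACGT"[i] for i in rng.integers(0, 4, arm_len))
        spacer = "".join("ACGT"[i] for i in rng.integers(0, 4, spacer_len))
        partner = list(rc(arm))
        for p in rng.choice(arm_len, size=mutate, replace=False):
            partner[p] = "ACGT"[(("ACGT".index(partner[p])) + 2) % 4]
        left = "".join("ACGT"[i] for i in rng.integers(0, 4, 2000))
        right = "".join("ACGT"[i] for i in rng.integers(0, 4, 2000))
        seq = left + arm + spacer + "".join(partner) + right
        return {"c1": seq}, GenomeLocus("c1", 2000, 2000 + arm_len)

    def test_planted_621_arm_with_1kb_spacer_detected(self, rng):
        genome, region = self._genome(rng, 621, 1000)
        found = find_inverted_repeat_source(region, genome)
        assert found
        best = found[0]
        assert abs(best["arm_len"] - 621) <= 25
        assert abs(best["spacer"] - 1000) <= 50
        assert best["identity"] >= 0.95

    def test_no_self_complementarity_empty(self, rng):
        seq = "".join("AC"[i] for i in rng.integers(0, 2, 6000))  # A/C cannot pair
        region = GenomeLocus("c1", 2500, 3000)
        assert find_inverted_repeat_source(region, {"c1": seq}) == []

    def test_low_identity_arms_rejected(self, rng):
        # ~11% divergence between arms -> below the 90% identity default
        genome, region = self._genome(rng, 300, 500, mutate=33)
        found = find_inverted_repeat_source(region, genome)
        assert all(r["identity"] >= 0.90 and r["arm_len"] >= 100 for r in found)
        assert not any(abs(r["arm_len"] - 300) < 50 for r in found)


def test_planted_ir_sources_recovered_from_dataset(default_dataset, pipeline_result):
    """Every planted inverted-repeat source yields an siRNA-classified cluster
    and the 621/1000 source is recovered by self-comparison."""
    feats = default_dataset["features"]
    genome = default_dataset["genome"]
    for f in feats:
        if f.kind != "sirna_inverted_repeat":
            continue
        labels = [c.class_label for c in pipeline_result.clusters
                  if c.region.overlaps(f.locus)]
        assert "siRNA" in labels
    ir0 = next(f for f in feats if f.kind == "sirna_inverted_repeat"
               and f.payload["arm_len"] == 621)
    found = find_inverted_repeat_source(ir0.locus, genome)
    assert found and abs(found[0]["arm_len"] - 621) <= 25
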