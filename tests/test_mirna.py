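"""Hairpin criteria, duplex geometry, and family grouping."""

import numpy as np
import pytest

from srnakit.fold import fold_rna, reverse_complement as rc
from srnakit.mirna import (
    DuplexReport,
    HairpinCriteria,
    evaluate_hairpin,
    extract_precursor_windows,
    family_key,
    group_families,
    pair_5p_3p,
    validate_locus,
)
from srnakit.types import GenomeLocus

from helpers import dinucleotide_shuffle


def perfect_hairpin(mature: str, pad5=6, pad3=8, loop="CAACAAAC"):
    stem5 = "ACGTAC"[:pad5] + mature + "GCTAGCTA"[:pad3]
    return stem5 + loop + rc(stem5), (pad5, pad5 + len(mature))


MATURE = "TGAAGCTGCCAGCATGATCTT"


class TestEvaluateHairpin:
    def test_planted_stem_passes_on_5p_arm(self):
        prec, span = perfect_hairpin(MATURE)
        cand = evaluate_hairpin([(GenomeLocus("c", 0, len(prec)), prec, span)])
        assert cand.verdict
        assert cand.arm == "5p"
        assert cand.reasons == []

    def test_mature_in_terminal_loop_fails(self):
        # long stem with the "mature" span sitting in a 24-base loop
        arm = "GCGCGCGAGCGCGGCATGCCGGCA"
        loop = "ATATTATATAATATTATATTATAA"
        seq = arm + loop + rc(arm)
        span = (len(arm) + 1, len(arm) + 22)
        cand = evaluate_hairpin([(GenomeLocus("c", 0, len(seq)), seq, span)])
        assert not cand.verdict
        assert any("loop" in r or "paired" in r for r in cand.reasons)

    def test_unstructured_window_fails_on_energy(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("AC"), 120))  # A/C only: no pairs at all
        cand = evaluate_hairpin([(GenomeLocus("c", 0, 120), seq, (50, 71))])
        assert not cand.verdict

    def test_shuffled_precursors_rarely_pass(self):
        """Dinucleotide-preserving shuffles of a real precursor: < 10% pass."""
        prec, span = perfect_hairpin(MATURE)
        rng = np.random.default_rng(99)
        passes = 0
        for _ in range(100):
            shuf = dinucleotide_shuffle(prec, rng)
            cand = evaluate_hairpin([(GenomeLocus("c", 0, len(shuf)), shuf, span)])
            if cand.verdict:
                passes += 1
        assert passes < 10

    def test_pass_implies_partners_on_one_arm(self):
        prec, span = perfect_hairpin(MATURE)
        cand = evaluate_hairpin([(GenomeLocus("c", 0, len(prec)), prec, span)])
        lo, hi = cand.mature_span
        partners = [cand.fold.pair_map[i] for i in range(lo, hi) if i in cand.fold.pair_map]
        assert all(p >= hi for p in partners) or all(p < lo for p in partners)


class TestWindows:
    def test_windows_contain_mature(self, rng):
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 100_000))
        locus = GenomeLocus("c", 5000, 5021)
        for wloc, wseq, (lo, hi) in extract_precursor_windows(locus, {"c": seq}):
            assert wloc.start + lo == 5000 and wloc.start + hi == 5021
            assert wseq[lo:hi] == seq[5000:5021]

    def test_clipped_at_chromosome_start(self, rng):
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 1000))
        locus = GenomeLocus("c", 5, 26)
        wins = extract_precursor_windows(locus, {"c": seq})
        assert wins
        for wloc, wseq, (lo, hi) in wins:
            assert wloc.start >= 0
            assert wseq[lo:hi] == seq[5:26]


class TestDuplex:
    def test_planted_duplex_has_2nt_stagger(self):
        prec, (m_lo, m_hi) = perfect_hairpin(MATURE)
        n = len(prec)
        s_lo, s_hi = n + 2 - m_lo - len(MATURE), n + 2 - m_lo
        cand = evaluate_hairpin([(GenomeLocus("c", 0, n), prec, (m_lo, m_hi))])
        star = prec[s_lo:s_hi]
        report = pair_5p_3p(cand, [
            (MATURE, 29_735, (m_lo, m_hi)),
            (star, 252, (s_lo, s_hi)),
        ])
        assert report.stagger is True
        assert report.major_seq == MATURE
        assert report.star_seq == star

    def test_major_arm_by_count(self):
        # 3p product dominates 29,735 : 252 — report major = 3p
        prec, (m_lo, m_hi) = perfect_hairpin(MATURE)
        n = len(prec)
        s_lo, s_hi = n + 2 - m_lo - len(MATURE), n + 2 - m_lo
        cand = evaluate_hairpin([(GenomeLocus("c", 0, n), prec, (m_lo, m_hi))])
        report = pair_5p_3p(cand, [
            (MATURE, 252, (m_lo, m_hi)),
            (prec[s_lo:s_hi], 29_735, (s_lo, s_hi)),
        ])
        assert report.major_arm == "3p"
        assert report.major_count == 29_735

    def test_single_arm_reports_no_star(self):
        prec, (m_lo, m_hi) = perfect_hairpin(MATURE)
        cand = evaluate_hairpin([(GenomeLocus("c", 0, len(prec)), prec, (m_lo, m_hi))])
        report = pair_5p_3p(cand, [(MATURE, 1000, (m_lo, m_hi))])
        assert report.major_arm == "5p"
        assert report.star_seq is None
        assert report.stagger is None

    def test_empty(self):
        prec, span = perfect_hairpin(MATURE)
        cand = evaluate_hairpin([(GenomeLocus("c", 0, len(prec)), prec, span)])
        assert pair_5p_3p(cand, []) == DuplexReport()


class TestFamilies:
    def test_family_key_strips_suffixes(self):
        assert family_key("gma-miR156b/f") == "miR156"
        assert family_key("gma-miR166a-3p") == "miR166"
        assert family_key("syn-miR104-5p") == "miR104"
        assert family_key("unrelated") is None

    def test_one_nt_variants_share_family_distinct_members(self):
        seqs = [
            ("TTGACAGAAGATAGAGAGCAC", "gma-miR156c/d/e/g", 14_252),
            ("TTGACAGAAGAGAGAGAGCAC", "gma-miR156b/f", 98_674),
        ]
        fams = group_families(seqs)
        assert len(fams) == 1
        assert fams[0].name == "miR156"
        assert len(fams[0].members) == 2
        assert fams[0].authentic == "TTGACAGAAGAGAGAGAGCAC"

    def test_identical_sequences_collapse_to_one_member(self):
        seqs = [
            ("TGACAGAAGAGAGTGAGCAC", "gma-miR156a", 100),
            ("TGACAGAAGAGAGTGAGCAC", "gma-miR156a", 200),
        ]
        fams = group_families(seqs)
        assert len(fams) == 1 and len(fams[0].members) == 1

    def test_novel_linkage_thresholds(self):
        a = "ACGTACGTACGTACGTACGTA"
        b = a[:10] + "C" + a[11:]          # 1 substitution -> linked
        c = "TTT" + a[3:]                   # 3 substitutions -> separate
        fams = group_families([], [(a, 10), (b, 5), (c, 2)])
        sizes = sorted(len(f.members) for f in fams)
        assert sizes == [1, 2]

    def test_terminal_shift_linkage(self):
        a = "ACGTACGTACGTACGTACGTA"
        shifted = a[2:] + "GG"  # 2-base shift, identical overlap
        fams = group_families([], [(a, 10), (shifted, 5)])
        assert len(fams) == 1


def test_validate_locus_on_background_mostly_fails(default_dataset):
    """False hairpin calls on 100 random background 21-mers stay <= 5."""
    genome = default_dataset["genome"]
    feats = default_dataset["features"]
    spans = {c: [] for c in genome}
    for f in feats:
        spans[f.locus.chrom].append((f.locus.start, f.locus.end))
    rng = np.random.default_rng(77)
    chroms = list(genome)
    passes = 0
    tried = 0
    while tried < 100:
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        p = int(rng.integers(0, len(genome[chrom]) - 21))
        if any(s - 21 < p < e for s, e in spans[chrom]):
            continue  # keep to intergenic background
        tried += 1
        cand = validate_locus(GenomeLocus(chrom, p, p + 21), genome)
        if cand is not None and cand.verdict:
            passes += 1
    assert passes <= 5
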