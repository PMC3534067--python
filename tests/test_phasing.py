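"""Trigger sites, register arithmetic, binomial tail, calibration."""

import numpy as np
import pytest
from scipy.stats import binom

from srnakit.fold import reverse_complement as rc
from srnakit.phasing import (
    collect_positions,
    enumerate_phased_products,
    find_trigger_site,
    null_registers,
    phase_register,
)
from srnakit.types import Alignment, GenomeLocus

from helpers import exact_binomial_tail

MIR = "AAGCTCAGGAGGGATAGCGCC"


def aln(start, length=21, strand="+"):
    return Alignment("s", GenomeLocus("t", start, start + length, strand), 0)


class TestTriggerSite:
    def test_perfect_complement_scores_full_length(self, rng):
        pad = "".join("ACGT"[i] for i in rng.integers(0, 4, 50))
        transcript = pad + rc(MIR) + pad
        sites = find_trigger_site(transcript, MIR, min_matches=21)
        assert len(sites) == 1
        site = sites[0]
        assert site.matches == 21 and site.mismatches == 0
        assert site.position == 50
        assert site.cleavage_pos == 50 + 21 - 10

    def test_gu_wobble_counts_half(self, rng):
        # replace two site bases with wobble partners of the miRNA base
        site = list(rc(MIR))
        changed = 0
        for i in range(len(site)):
            m = MIR[len(MIR) - 1 - i]
            if m in "GT" and changed < 2:
                site[i] = {"G": "T", "T": "G"}[m]
                changed += 1
        assert changed == 2
        transcript = "A" * 30 + "".join(site) + "A" * 30
        found = find_trigger_site(transcript, MIR, min_matches=1)
        best = max(found, key=lambda s: s.matches)
        assert best.matches == 19 + 2 // 2  # 19 WC + floor(2 GU / 2)

    def test_random_transcript_has_no_high_match_site(self, rng):
        transcript = "".join("ACGT"[i] for i in rng.integers(0, 4, 1000))
        q = "".join("ACGT"[i] for i in rng.integers(0, 4, 21))
        sites = find_trigger_site(transcript, q, min_matches=17)
        # brute-force oracle: per-placement scalar count
        from srnakit.phasing import _site_matches

        expected = [
            p for p in range(len(transcript) - 21 + 1)
            if _site_matches(transcript[p:p + 21], q) >= 17
        ]
        assert [s.position for s in sites] == expected
        assert sites == []


class TestPhaseRegister:
    def test_all_in_one_register_exact_p(self):
        r = phase_register([100, 121, 184], cleavage_pos=100)
        assert r.n == 3 and r.k == 3 and r.score == 1.0
        assert r.p_value == pytest.approx(21 * (1 / 21) ** 3)
        assert r.p_value == pytest.approx(1 / 441)

    def test_uniform_positions_capped_at_one(self):
        positions = [100 + i * 22 for i in range(21)]  # one per register
        r = phase_register(positions, cleavage_pos=100)
        assert r.k == 1
        assert r.score == pytest.approx(1 / 21)
        assert r.p_value == 1.0

    def test_shift_by_period_preserves_registers(self, rng):
        pos = sorted(int(p) for p in rng.choice(2000, size=30, replace=False))
        a = phase_register(pos, 0)
        b = phase_register([p + 21 for p in pos], 0)
        assert a.register_counts == b.register_counts

    def test_insufficient_positions_flagged(self):
        r = phase_register([100, 121], cleavage_pos=100)
        assert r.insufficient

    def test_register_counts_sum_to_n(self, rng):
        pos = [int(p) for p in rng.choice(500, size=40, replace=False)]
        r = phase_register(pos, 7)
        assert sum(r.register_counts) == r.n

    @pytest.mark.parametrize("n,k", [(3, 3), (5, 2), (8, 4), (10, 6)])
    def test_binomial_tail_matches_exact_enumeration(self, n, k):
        ours = float(min(1.0, 21 * binom.sf(k - 1, n, 1 / 21)))
        exact = float(min(1, 21 * exact_binomial_tail(n, k)))
        assert ours == pytest.approx(exact, rel=1e-10)

    def test_antisense_positions_enter_with_plus2_offset(self):
        c = 100
        alns = [aln(c), aln(c + 21), aln(c + 42 - 2, strand="-"), aln(c + 63)]
        positions = collect_positions(alns, c)
        r = phase_register(positions, c)
        assert r.k == 4 and r.register_counts[0] == 4


class TestCalibration:
    def test_type_one_error_near_alpha(self):
        """Uniform-register null: fraction with p < 0.05 within 0.05 +/- 0.03."""
        rng = np.random.default_rng(2024)
        n, span, reps = 20, 840, 500
        rejections = 0
        for _ in range(reps):
            pos = [int(p) for p in rng.choice(span, size=n, replace=False)]
            if phase_register(pos, 0).p_value < 0.05:
                rejections += 1
        assert 0.02 <= rejections / reps <= 0.08

    def test_binomial_matches_permutation_on_phased_cases(self):
        """Strongly phased clusters: Bonferroni binomial vs 1e4-shuffle
        permutation estimate within 3 Monte-Carlo standard errors."""
        rng = np.random.default_rng(31)
        span, shuffles = 840, 10_000
        cases = [(n, 7 if n <= 21 else 8) for n in range(15, 25)] * 2
        assert len(cases) == 20
        for n, k in cases:
            p_bin = float(min(1.0, 21 * binom.sf(k - 1, n, 1 / 21)))
            perm = null_registers(rng, n, span, shuffles)
            p_perm = float((perm >= k).mean())
            se = np.sqrt(p_bin * (1 - p_bin) / shuffles)
            assert abs(p_bin - p_perm) <= 3 * se + 1e-12


class TestEnumerateProducts:
    def _setup(self, n_products):
        rng = np.random.default_rng(5)
        mir = MIR
        pad = 30
        site_seq = rc(mir)
        c = pad + 21 - 10
        body = "".join("ACGT"[i] for i in rng.integers(0, 4, 21 * 10))
        transcript = "".join("ACGT"[i] for i in rng.integers(0, 4, pad)) + site_seq + body
        site = find_trigger_site(transcript, mir, min_matches=21)[0]
        alns = [aln(c + 21 * t) for t in range(n_products)]
        sig_cpm = {transcript[c + 21 * t:c + 42 + 21 * t - 21]: {"WS": float(t + 1)}
                   for t in range(n_products)}
        return transcript, site, alns, sig_cpm

    def test_phased_rows_in_order(self):
        transcript, site, alns, cpm = self._setup(8)
        rows = enumerate_phased_products(transcript, site, cpm, alns)
        assert [r["phase"] for r in rows] == [f"D{i}" for i in range(1, 9)]
        assert rows[-1]["most_abundant"] is True

    def test_no_signatures_gives_empty_table(self):
        transcript, site, _, _ = self._setup(0)
        assert enumerate_phased_products(transcript, site, {}, []) == []

    def test_window_truncated_at_transcript_end_excluded(self):
        transcript, site, alns, cpm = self._setup(8)
        short = transcript[:site.cleavage_pos + 30]  # room for one full window
        rows = enumerate_phased_products(short, site, cpm, alns[:2])
        assert [r["phase"] for r in rows] == ["D1"]


def test_planted_tas_locus_detected(default_dataset, pipeline_result):
    tas = next(f for f in default_dataset["features"] if f.kind == "tas_locus")
    hits = [pl for pl in pipeline_result.phased_loci if pl["region"].overlaps(tas.locus)]
    assert hits
    result = hits[0]["result"]
    assert result.p_value < 1e-6
    assert hits[0]["site"].matches >= 17
    assert hits[0]["trigger"] == tas.payload["trigger"]
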