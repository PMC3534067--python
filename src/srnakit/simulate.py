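"""Synthetic genomes and small-RNA libraries with machine-readable truth.

The generator plants every feature class the downstream stages detect —
miRNA hairpins with 5p/3p duplex geometry, inverted-repeat siRNA sources,
one trigger-driven locus producing 21-nt phased products, transposable
element families with internally divergent copies, an rDNA-like tandem
array, and spliced background genes — into an otherwise random genome,
then samples eight adapter-ligated 35-base read libraries from the planted
product pool.

Library design mirrors a seed-versus-vegetative tissue contrast: the five
seed libraries (whole seed, three seed coats, immature cotyledon) are rich
in 24-nt repeat-derived signatures, the three vegetative libraries
(germinating cotyledon, stem, leaf) in 21-nt signatures.  The contrast is
produced both by per-library length weights and by per-product tissue
multipliers (most transposon products are transcriptionally silent in
vegetative tissue), which is how the same contrast arises in real plant
small-RNA data.

Everything is deterministic under a fixed seed; truth tables record the
realized pre-error sampled count of every product in every library.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .fold import reverse_complement as rc
from .preprocess import DEFAULT_ADAPTER, READ_LENGTH
from .types import GenomeLocus

SEED_LIBS = ["WS", "SCR", "SCM", "SCW", "Cot"]
VEG_LIBS = ["GCot", "ST", "LE"]
ALL_LIBS = SEED_LIBS + VEG_LIBS

# 19-25-nt sampling weights; seed libraries peak at 24, vegetative at 21
SEED_PROFILE = {19: 0.03, 20: 0.05, 21: 0.20, 22: 0.18, 23: 0.07, 24: 0.40, 25: 0.07}
VEG_PROFILE = {19: 0.04, 20: 0.08, 21: 0.42, 22: 0.20, 23: 0.08, 24: 0.12, 25: 0.06}

# literature mature sequences used for the showcase hairpins
MATURE_MIR167_LIKE = "TGAAGCTGCCAGCATGATCTT"        # 21 nt, 5p showcase
MATURE_TRIGGER = "AAGCTCAGGAGGGATAGCGCC"            # 21 nt, phasing trigger
MATURE_SEEDCOAT_ONLY = "TAACTGAACATTCTTAGAGCAT"     # 22 nt, seed-coat-specific

HAIRPIN_LOOP = "CAACAAAC"
TE_CONSERVED_WINDOWS = [(50, 80), (300, 330)]

_TISSUE_MULT = {
    "ubiquitous": {c: 1.0 for c in ALL_LIBS},
    "seed_only": {**{c: 1.0 for c in SEED_LIBS}, **{c: 0.02 for c in VEG_LIBS}},
    "veg_biased": {**{c: 0.2 for c in SEED_LIBS}, **{c: 1.0 for c in VEG_LIBS}},
    "te_seed": {**{c: 1.0 for c in SEED_LIBS}, **{c: 0.0 for c in VEG_LIBS}},
    "te_broad": {**{c: 1.0 for c in SEED_LIBS}, **{c: 0.3 for c in VEG_LIBS}},
    "rdna": {**{c: 1.0 for c in ALL_LIBS}, "GCot": 1.6},
    "stem_high": {**{c: 1.0 for c in ALL_LIBS}, "ST": 2.0},
}


def default_library_profiles() -> dict[str, dict[int, float]]:
    return {
        c: dict(SEED_PROFILE if c in SEED_LIBS else VEG_PROFILE) for c in ALL_LIBS
    }


def default_te_copy_numbers() -> dict[str, int]:
    return {"Gypsy": 12, "Copia": 8, "Mutator": 6, "CACTA": 4}


@dataclass
class SimConfig:
    genome_length: int = 150_000
    n_chromosomes: int = 2
    n_mirna: int = 20
    n_sirna_sources: int = 5
    te_family_copy_numbers: dict[str, int] = field(default_factory=default_te_copy_numbers)
    rdna_copies: int = 8
    n_background_genes: int = 5
    library_profiles: dict[str, dict[int, float]] = field(default_factory=default_library_profiles)
    library_depths: dict[str, int] = field(default_factory=lambda: {c: 100_000 for c in ALL_LIBS})
    error_rate: float = 0.001
    background_fraction: float = 0.10
    adapter: str = DEFAULT_ADAPTER
    seed: int = 0

    def validate(self) -> None:
        for code, prof in self.library_profiles.items():
            total = sum(prof.values())
            if abs(total - 1.0) > 1e-6:
                raise ValueError(f"length weights for {code} sum to {total}, not 1")
        if any(d <= 0 for d in self.library_depths.values()):
            raise ValueError("library depths must be > 0")
        if not 0.0 <= self.error_rate <= 0.05:
            raise ValueError("error_rate must lie in [0, 0.05]")
        if not 0.0 <= self.background_fraction < 1.0:
            raise ValueError("background_fraction must lie in [0, 1)")

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        cfg = cls(**{k: v for k, v in d.items() if k in known})
        cfg.library_profiles = {
            c: {int(k): float(v) for k, v in prof.items()}
            for c, prof in cfg.library_profiles.items()
        }
        cfg.validate()
        return cfg


@dataclass
class PlantedFeature:
    feature_id: str
    kind: str  # mirna_hairpin | sirna_inverted_repeat | tas_locus | te_copy | rdna_unit | background_gene
    locus: GenomeLocus
    payload: dict = field(default_factory=dict)


@dataclass(frozen=True)
class Product:
    """One sampleable small-RNA product planted in the genome."""

    seq: str
    feature_id: str
    kind: str
    family: str
    locus: GenomeLocus
    weight: float
    mclass: str  # tissue-multiplier class name


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def _mutate(rng: np.random.Generator, seq: str, rate: float, keep: list[tuple[int, int]]) -> str:
    out = list(seq)
    protected = np.zeros(len(seq), dtype=bool)
    for s, e in keep:
        protected[s:e] = True
    for i in np.nonzero(rng.random(len(seq)) < rate)[0]:
        if protected[i]:
            continue
        out[i] = "ACGT"[(("ACGT".index(out[i])) + rng.integers(1, 4)) % 4]
    return "".join(out)


class _Block:
    """A feature sequence plus a finalizer run once its placement is known."""

    def __init__(self, seq: str, finalize) -> None:
        self.seq = seq
        self.finalize = finalize  # (chrom, start) -> (features, products)


def _build_hairpin(i: int, mature: str, arm: str, mclass: str, rng: np.random.Generator) -> _Block:
    """Near-perfect-stem precursor with the mature on the requested arm.

    The star is the opposite-arm duplex partner with the canonical 2-nt
    3' staggers: for a product at window offset x of length L on a
    perfect stem of total length N, the partner spans [N+2-x-L, N+2-x).
    Three interior bases of the arm *opposite* the mature are mutated to
    non-pairing bases, as in real precursors whose stems carry bulges —
    this also keeps the mature from aligning perfectly to the star arm.
    """
    pad_a, pad_b = _rand_seq(rng, 6), _rand_seq(rng, 8)
    lm = len(mature)
    if arm == "5p":
        stem5 = pad_a + mature + pad_b
    else:
        stem5 = pad_a + rc(mature) + pad_b
    prec_l = list(stem5 + HAIRPIN_LOOP + rc(stem5))
    n = len(prec_l)
    if arm == "5p":
        m_lo = len(pad_a)
    else:
        m_lo = n - len(pad_a) - lm
    m_hi = m_lo + lm
    for d in (5, 11, 16):  # interior mature offsets; duplex ends stay paired
        j = n - 1 - (m_lo + d)  # perfect-stem partner, on the opposite arm
        prec_l[j] = _mismatch_base(prec_l[m_lo + d])
    prec = "".join(prec_l)
    s_lo = n + 2 - m_lo - lm
    s_hi = n + 2 - m_lo
    assert prec[m_lo:m_hi] == mature
    star = prec[s_lo:s_hi]
    name = f"syn-miR{i + 101:03d}"

    def finalize(chrom: str, start: int):
        locus = GenomeLocus(chrom, start, start + n)
        feat = PlantedFeature(
            feature_id=f"mirna_{i:02d}",
            kind="mirna_hairpin",
            locus=locus,
            payload={
                "name": name,
                "mature": mature,
                "star": star,
                "arm": arm,
                "mature_span": (m_lo, m_hi),
                "star_span": (s_lo, s_hi),
            },
        )
        prods = [
            Product(mature, feat.feature_id, "mirna_hairpin", "",
                    GenomeLocus(chrom, start + m_lo, start + m_hi), 100.0, mclass),
            Product(star, feat.feature_id, "mirna_hairpin", "",
                    GenomeLocus(chrom, start + s_lo, start + s_hi), 8.0, mclass),
        ]
        return [feat], prods

    return _Block(prec, finalize)


def _window_products(
    rng: np.random.Generator,
    seq: str,
    plan: dict[int, int],
    weight: float,
    both_strands: bool,
    regions: Optional[list[tuple[int, int]]] = None,
) -> list[tuple[int, int, str]]:
    """(offset, length, strand) windows drawn from ``regions`` of ``seq``."""
    regions = regions or [(0, len(seq))]
    out = []
    for length, count in plan.items():
        for j in range(count):
            r_lo, r_hi = regions[int(rng.integers(0, len(regions)))]
            if r_hi - r_lo < length:
                continue
            off = int(rng.integers(r_lo, r_hi - length + 1))
            strand = "-" if (both_strands and j % 2 == 1) else "+"
            out.append((off, length, strand))
    return out


def _build_inverted_repeat(i: int, arm_len: int, spacer_len: int, rng: np.random.Generator) -> _Block:
    arm = _rand_seq(rng, arm_len)
    spacer = _rand_seq(rng, spacer_len)
    seq = arm + spacer + rc(arm)
    plan = {21: 6, 22: 5, 23: 2, 24: 8}
    windows = _window_products(
        rng, seq, plan, 6.0, both_strands=True,
        regions=[(0, arm_len), (arm_len + spacer_len, len(seq))],
    )

    def finalize(chrom: str, start: int):
        feat = PlantedFeature(
            feature_id=f"ir_{i:02d}",
            kind="sirna_inverted_repeat",
            locus=GenomeLocus(chrom, start, start + len(seq)),
            payload={"arm_len": arm_len, "spacer_len": spacer_len},
        )
        prods = []
        for off, length, strand in windows:
            sub = seq[off:off + length]
            prods.append(Product(
                sub if strand == "+" else rc(sub),
                feat.feature_id, feat.kind, "",
                GenomeLocus(chrom, start + off, start + off + length, strand),
                6.0, "ubiquitous",
            ))
        return [feat], prods

    return _Block(seq, finalize)


def _mismatch_base(target: str) -> str:
    """A base that neither Watson-Crick- nor wobble-pairs ``target``."""
    wc = {"A": "T", "C": "G", "G": "C", "T": "A"}[target]
    wobble = {"G": "T", "T": "G"}.get(target, "")
    for b in "ACGT":
        if b != wc and b != wobble and b != target:
            return b
    raise AssertionError


def _build_tas(trigger: str, rng: np.random.Generator, n_phases: int = 10) -> _Block:
    """Trigger-cleaved locus with products phased every 21 bases.

    The complementary trigger site carries 3 non-wobble mismatches (17-18
    match range seen at real trigger sites); the cut falls between trigger
    positions 10 and 11, and products D1.. start in register 0 downstream.
    The last two phased products are antisense duplex partners (start - 2)
    and one extra sense product sits off register.
    """
    lm = len(trigger)
    pad = 40
    site = list(rc(trigger))
    for p in sorted(rng.choice(lm, size=3, replace=False)):
        # position p of the site pairs trigger base lm-1-p
        site[p] = _mismatch_base(trigger[lm - 1 - p])
    site_seq = "".join(site)
    cleavage = pad + lm - 10  # first base of the 3' fragment
    body_len = cleavage + 21 * n_phases + 30
    body = _rand_seq(rng, body_len - pad - lm)
    seq = _rand_seq(rng, pad) + site_seq + body
    windows: list[tuple[int, int, str]] = []
    for t in range(n_phases - 2):
        windows.append((cleavage + 21 * t, 21, "+"))
    for t in (n_phases - 2, n_phases - 1):
        windows.append((cleavage + 21 * t - 2, 21, "-"))  # duplex partners
    off_register = cleavage + 21 * 3 + 10
    windows.append((off_register, 21, "+"))

    def finalize(chrom: str, start: int):
        feat = PlantedFeature(
            feature_id="tas_00",
            kind="tas_locus",
            locus=GenomeLocus(chrom, start, start + len(seq)),
            payload={
                "trigger": trigger,
                "site_offset": pad,
                "cleavage_offset": cleavage,
                "n_phases": n_phases,
                "phased_offsets": [cleavage + 21 * t for t in range(n_phases)],
            },
        )
        prods = []
        for j, (off, length, strand) in enumerate(windows):
            sub = seq[off:off + length]
            prods.append(Product(
                sub if strand == "+" else rc(sub),
                feat.feature_id, feat.kind, "",
                GenomeLocus(chrom, start + off, start + off + length, strand),
                40.0 if off != off_register else 12.0, "stem_high",
            ))
        return [feat], prods

    return _Block(seq, finalize)


TE_PRODUCT_PLANS = {
    "Gypsy": {22: 50, 24: 40, 21: 5, 23: 4},
    "CACTA": {22: 25, 24: 20, 21: 3, 23: 2},
    "Mutator": {24: 95, 22: 10, 21: 4, 23: 3},
    "Copia": {24: 120},  # plus the few-distinct high-copy 22-mers below
}
TE_UNIT_LEN = 600
TE_DIVERGENCE = 0.02


def _build_te_family(family: str, n_copies: int, rng: np.random.Generator) -> list[_Block]:
    """Divergent copies of one consensus; products from copies + conserved windows."""
    consensus = _rand_seq(rng, TE_UNIT_LEN)
    copies = [
        _mutate(rng, consensus, TE_DIVERGENCE, TE_CONSERVED_WINDOWS) for _ in range(n_copies)
    ]
    plan = dict(TE_PRODUCT_PLANS.get(family, {24: 15, 22: 8}))
    # windows in copy-local coordinates; each assigned to a source copy
    prods_local: list[tuple[int, int, int, str, float]] = []  # (copy, off, length, strand, weight)
    for length, count in plan.items():
        for j in range(count):
            ci = int(rng.integers(0, n_copies))
            off = int(rng.integers(0, TE_UNIT_LEN - length + 1))
            strand = "-" if j % 3 == 2 else "+"
            prods_local.append((ci, off, length, strand, 4.0))
    if family == "Copia":
        # few distinct, high-copy 22-mers: the unique-vs-reads inversion driver
        for j in range(6):
            ci = int(rng.integers(0, n_copies))
            off = int(rng.integers(0, TE_UNIT_LEN - 22 + 1))
            prods_local.append((ci, off, 22, "+", 300.0))
    # conserved-window products occur verbatim in every copy
    for (w_lo, w_hi), length in zip(TE_CONSERVED_WINDOWS, (24, 22)):
        off = int(rng.integers(w_lo, w_hi - length + 1)) if w_hi - w_lo >= length else w_lo
        prods_local.append((0, off, length, "+", 10.0))
    # most TE products are silent in vegetative tissue; the high-copy
    # 22-mers (last 8: Copia specials and/or conserved windows) stay broad
    veg_active = rng.random(len(prods_local)) < 0.1
    for j, (_, _, _, _, w) in enumerate(prods_local):
        if w > 4.0:
            veg_active[j] = True

    blocks = []
    placements: dict[int, tuple[str, int]] = {}
    done = {"count": 0}

    def make_finalize(ci: int):
        def finalize(chrom: str, start: int):
            placements[ci] = (chrom, start)
            feat = PlantedFeature(
                feature_id=f"te_{family}_{ci:02d}",
                kind="te_copy",
                locus=GenomeLocus(chrom, start, start + TE_UNIT_LEN),
                payload={"family": family, "copy": ci},
            )
            prods = []
            done["count"] += 1
            if done["count"] == len(copies):  # all copies placed: emit products
                for j, (pci, off, length, strand, w) in enumerate(prods_local):
                    pchrom, pstart = placements[pci]
                    sub = copies[pci][off:off + length]
                    prods.append(Product(
                        sub if strand == "+" else rc(sub),
                        f"te_{family}_{pci:02d}", "te_copy", family,
                        GenomeLocus(pchrom, pstart + off, pstart + off + length, strand),
                        w, "te_broad" if veg_active[j] else "te_seed",
                    ))
            return [feat], prods

        return finalize

    for ci, cseq in enumerate(copies):
        blocks.append(_Block(cseq, make_finalize(ci)))
    return blocks


RDNA_UNIT_LEN = 300


def _build_rdna(n_copies: int, rng: np.random.Generator) -> _Block:
    unit = _rand_seq(rng, RDNA_UNIT_LEN)
    seq = unit * n_copies
    plan = {21: 18, 22: 15, 20: 6, 23: 4}
    windows = _window_products(rng, unit, plan, 8.0, both_strands=True)

    def finalize(chrom: str, start: int):
        feat = PlantedFeature(
            feature_id="rdna_00",
            kind="rdna_unit",
            locus=GenomeLocus(chrom, start, start + len(seq)),
            payload={"unit_len": RDNA_UNIT_LEN, "copies": n_copies},
        )
        prods = []
        for off, length, strand in windows:
            sub = unit[off:off + length]
            prods.append(Product(
                sub if strand == "+" else rc(sub),
                feat.feature_id, feat.kind, "",
                GenomeLocus(chrom, start + off, start + off + length, strand),
                8.0, "rdna",
            ))
        return [feat], prods

    return _Block(seq, finalize)


GENE_EXONS = [(0, 400), (700, 1200), (1500, 1800)]
GENE_LEN = 1800


def _build_gene(i: int, rng: np.random.Generator, sirna_source: bool) -> _Block:
    seq = _rand_seq(rng, GENE_LEN)
    # windows kept clear of exon edges so every aligned base is exonic
    exon_interiors = [(s + 2, e - 2) for s, e in GENE_EXONS]
    if sirna_source:
        plan = {21: 22, 22: 18}
        weight = 10.0
    else:
        plan = {21: 8, 22: 6, 23: 3, 24: 5, 19: 2, 20: 3, 25: 2}
        weight = 4.0
    windows = _window_products(rng, seq, plan, weight, both_strands=True, regions=exon_interiors)

    def finalize(chrom: str, start: int):
        feat = PlantedFeature(
            feature_id=f"gene_{i:02d}",
            kind="background_gene",
            locus=GenomeLocus(chrom, start, start + GENE_LEN),
            payload={"exons": GENE_EXONS, "sirna_source": sirna_source},
        )
        prods = []
        for off, length, strand in windows:
            sub = seq[off:off + length]
            prods.append(Product(
                sub if strand == "+" else rc(sub),
                feat.feature_id, feat.kind, "",
                GenomeLocus(chrom, start + off, start + off + length, strand),
                weight, "seed_only" if sirna_source else "ubiquitous",
            ))
        return [feat], prods

    return _Block(seq, finalize)


def generate_genome(config: SimConfig) -> tuple[dict[str, str], list[PlantedFeature], list[Product]]:
    """Build the genome and return (sequences, truth features, product pool).

    Raises ``ValueError`` when ``genome_length`` cannot hold the requested
    features with minimal intergenic gaps.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    blocks: list[_Block] = []
    matures = [MATURE_MIR167_LIKE, MATURE_TRIGGER, MATURE_SEEDCOAT_ONLY]
    for i in range(config.n_mirna):
        if i < len(matures):
            mature = matures[i]
        else:
            mature = _rand_seq(rng, 21)
        arm = "5p" if i % 2 == 0 else "3p"
        mclass = "seed_only" if i == 2 else ("veg_biased" if i == 3 else "ubiquitous")
        blocks.append(_build_hairpin(i, mature, arm, mclass, rng))
    for i in range(config.n_sirna_sources):
        if i == 0:
            blocks.append(_build_inverted_repeat(i, 621, 1000, rng))
        else:
            blocks.append(_build_inverted_repeat(
                i, int(rng.integers(300, 420)), int(rng.integers(150, 400)), rng))
    if config.n_mirna >= 2:  # the trigger hairpin exists, so plant its target locus
        blocks.append(_build_tas(MATURE_TRIGGER, rng))
    for family, n_copies in config.te_family_copy_numbers.items():
        if n_copies > 0:
            blocks.extend(_build_te_family(family, n_copies, rng))
    if config.rdna_copies > 0:
        blocks.append(_build_rdna(config.rdna_copies, rng))
    for i in range(config.n_background_genes):
        blocks.append(_build_gene(i, rng, sirna_source=(i == 0)))

    total_feat = sum(len(b.seq) for b in blocks)
    min_gap = 20
    need = total_feat + min_gap * (len(blocks) + config.n_chromosomes)
    if need > config.genome_length:
        raise ValueError(
            f"genome_length {config.genome_length} too small for planted features "
            f"(needs >= {need} bases)"
        )

    order = rng.permutation(len(blocks))
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    per_chrom: list[list[_Block]] = [[] for _ in chrom_names]
    for rank, bi in enumerate(order):
        per_chrom[rank % config.n_chromosomes].append(blocks[bi])

    # spread the slack over the gaps
    slack = config.genome_length - need
    gap_budget = rng.multinomial(slack, np.ones(len(blocks) + config.n_chromosomes)
                                 / (len(blocks) + config.n_chromosomes))
    gi = 0
    genome: dict[str, str] = {}
    features: list[PlantedFeature] = []
    products: list[Product] = []
    for chrom, chrom_blocks in zip(chrom_names, per_chrom):
        parts: list[str] = []
        pos = 0
        for b in chrom_blocks:
            gap = min_gap + int(gap_budget[gi])
            gi += 1
            parts.append(_rand_seq(rng, gap))
            pos += gap
            feats, prods = b.finalize(chrom, pos)
            features.extend(feats)
            products.extend(prods)
            parts.append(b.seq)
            pos += len(b.seq)
        tail = min_gap + int(gap_budget[gi])
        gi += 1
        parts.append(_rand_seq(rng, tail))
        genome[chrom] = "".join(parts)

    # dedupe products on sequence (distinct-signature truth must be unambiguous)
    seen: dict[str, Product] = {}
    for p in products:
        seen.setdefault(p.seq, p)
    return genome, features, list(seen.values())


@dataclass
class SimResult:
    reads: dict[str, list[str]]                 # per-library raw 35-base reads
    truth_counts: pd.DataFrame                  # product rows x library count columns
    background_counts: dict[str, dict[str, int]]
    products: list[Product]
    config: SimConfig


def _apply_errors(rng: np.random.Generator, inserts: list[str], rate: float) -> list[str]:
    if rate <= 0:
        return inserts
    lens = np.array([len(s) for s in inserts])
    n_err = rng.binomial(lens, rate)
    out = list(inserts)
    for i in np.nonzero(n_err)[0]:
        s = list(out[i])
        for p in rng.choice(len(s), size=min(n_err[i], len(s)), replace=False):
            s[p] = "ACGT"[(("ACGT".index(s[p])) + rng.integers(1, 4)) % 4]
        out[i] = "".join(s)
    return out


def _make_read(insert: str, adapter: str, rng: np.random.Generator) -> str:
    read = insert + adapter
    if len(read) < READ_LENGTH:
        read += _rand_seq(rng, READ_LENGTH - len(read))
    return read[:READ_LENGTH]


def simulate_libraries(
    genome: dict[str, str],
    products: list[Product],
    config: SimConfig,
) -> SimResult:
    """Sample the eight libraries of raw adapter-bearing 35-base reads.

    Per library, a read is a background genome substring with probability
    ``background_fraction``, else a planted product drawn with probability
    proportional to base weight x length-profile weight x tissue
    multiplier.  Substitution errors apply to the insert, then the 3'
    adapter and random filler pad the read to exactly 35 bases.
    """
    config.validate()
    rng = np.random.default_rng((config.seed, 1))
    lens = np.array([len(p.seq) for p in products]) if products else np.empty(0, int)
    base_w = np.array([p.weight for p in products]) if products else np.empty(0)
    chroms = list(genome)
    chrom_lens = np.array([len(genome[c]) for c in chroms], dtype=float)
    reads: dict[str, list[str]] = {}
    truth = pd.DataFrame(
        0,
        index=[p.seq for p in products],
        columns=list(config.library_depths),
        dtype=int,
    )
    background_counts: dict[str, dict[str, int]] = {}
    for code, depth in config.library_depths.items():
        profile = config.library_profiles[code]
        if products:
            prof_w = np.array([profile.get(int(L), 0.0) for L in lens])
            mult = np.array([_TISSUE_MULT[p.mclass].get(code, 1.0) for p in products])
            w = base_w * prof_w * mult
            wsum = w.sum()
        else:
            wsum = 0.0
        n_bg = depth if wsum == 0 else int(rng.binomial(depth, config.background_fraction))
        n_feat = depth - n_bg
        inserts: list[str] = []
        if n_feat > 0:
            idx = rng.choice(len(products), size=n_feat, p=w / wsum)
            counts = np.bincount(idx, minlength=len(products))
            truth[code] = counts
            for pi in np.nonzero(counts)[0]:
                inserts.extend([products[pi].seq] * int(counts[pi]))
        bg: dict[str, int] = {}
        if n_bg > 0:
            lengths = list(profile)
            pw = np.array([profile[L] for L in lengths])
            bls = rng.choice(lengths, size=n_bg, p=pw / pw.sum())
            cis = rng.choice(len(chroms), size=n_bg, p=chrom_lens / chrom_lens.sum())
            strands = rng.random(n_bg) < 0.5
            for L, ci, minus in zip(bls, cis, strands):
                cseq = genome[chroms[ci]]
                s = int(rng.integers(0, len(cseq) - int(L)))
                sub = cseq[s:s + L]
                if minus:
                    sub = rc(sub)
                bg[sub] = bg.get(sub, 0) + 1
                inserts.append(sub)
        background_counts[code] = bg
        inserts = [inserts[i] for i in rng.permutation(len(inserts))]
        inserts = _apply_errors(rng, inserts, config.error_rate)
        reads[code] = [_make_read(s, config.adapter, rng) for s in inserts]
    return SimResult(reads, truth, background_counts, products, config)


# ---------------------------------------------------------------------------
# file emission


def write_genome_fasta(genome: dict[str, str], path: str) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")


def write_fastq(reads: list[str], code: str, path: str) -> None:
    qual = "I" * READ_LENGTH
    with open(path, "w") as fh:
        for i, seq in enumerate(reads):
            fh.write(f"@{code}_{i}\n{seq}\n+\n{qual}\n")


def write_reference_fasta(features: list[PlantedFeature], path: str) -> None:
    """miRBase-like reference set built from the planted matures and stars."""
    with open(path, "w") as fh:
        for feat in features:
            if feat.kind != "mirna_hairpin":
                continue
            name = feat.payload["name"]
            arm = feat.payload["arm"]
            other = "3p" if arm == "5p" else "5p"
            fh.write(f">{name}-{arm}\n{feat.payload['mature']}\n")
            fh.write(f">{name}-{other}\n{feat.payload['star']}\n")


def write_te_db_fasta(genome: dict[str, str], features: list[PlantedFeature], path: str) -> None:
    with open(path, "w") as fh:
        for feat in features:
            if feat.kind != "te_copy":
                continue
            seq = genome[feat.locus.chrom][feat.locus.start:feat.locus.end]
            fh.write(f">{feat.feature_id} family={feat.payload['family']}\n{seq}\n")


def write_gff3(features: list[PlantedFeature], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for feat in features:
            if feat.kind != "background_gene":
                continue
            loc = feat.locus
            gid = feat.feature_id
            fh.write(
                f"{loc.chrom}\tsrnakit\tgene\t{loc.start + 1}\t{loc.end}\t.\t+\t.\tID={gid}\n"
            )
            for k, (s, e) in enumerate(feat.payload["exons"], 1):
                fh.write(
                    f"{loc.chrom}\tsrnakit\texon\t{loc.start + s + 1}\t{loc.start + e}\t.\t+\t.\t"
                    f"ID={gid}.exon{k};Parent={gid}\n"
                )


def write_truth_tables(features: list[PlantedFeature], result: SimResult, outdir: str) -> None:
    import os

    rows = []
    for p in result.products:
        rows.append({
            "seq": p.seq,
            "feature_id": p.feature_id,
            "kind": p.kind,
            "family": p.family,
            "chrom": p.locus.chrom,
            "start": p.locus.start,
            "end": p.locus.end,
            "strand": p.locus.strand,
        })
    meta = pd.DataFrame(rows).set_index("seq")
    table = meta.join(result.truth_counts)
    table.to_csv(os.path.join(outdir, "truth_products.tsv"), sep="\t")
    frows = [
        {"feature_id": f.feature_id, "kind": f.kind, "chrom": f.locus.chrom,
         "start": f.locus.start, "end": f.locus.end}
        for f in features
    ]
    pd.DataFrame(frows).to_csv(os.path.join(outdir, "truth_features.tsv"), sep="\t", index=False)


def write_dataset(config: SimConfig, outdir: str) -> tuple[dict[str, str], list[PlantedFeature], SimResult]:
    """Generate and write the complete synthetic dataset under ``outdir``."""
    import os

    os.makedirs(outdir, exist_ok=True)
    genome, features, products = generate_genome(config)
    result = simulate_libraries(genome, products, config)
    write_genome_fasta(genome, os.path.join(outdir, "genome.fa"))
    write_reference_fasta(features, os.path.join(outdir, "reference_mirna.fa"))
    write_te_db_fasta(genome, features, os.path.join(outdir, "te_db.fa"))
    write_gff3(features, os.path.join(outdir, "models.gff3"))
    with open(os.path.join(outdir, "repeats.bed"), "w") as fh:
        for feat in features:
            if feat.kind == "rdna_unit":
                loc = feat.locus
                fh.write(f"{loc.chrom}\t{loc.start}\t{loc.end}\t{feat.feature_id}\n")
    for code, reads in result.reads.items():
        write_fastq(reads, code, os.path.join(outdir, f"{code}.fastq"))
    write_truth_tables(features, result, outdir)
    return genome, features, result
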