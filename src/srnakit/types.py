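"""Shared domain types for the small-RNA pipeline.

Coordinates are 0-based half-open internally; the ``chrom:start`` strings
written to reports are 1-based inclusive, matching the convention of
genome-browser style locus labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional


@dataclass(frozen=True, order=True)
class GenomeLocus:
    chrom: str
    start: int  # 0-based inclusive
    end: int    # 0-based exclusive
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"locus start {self.start} > end {self.end}")
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def label(self) -> str:
        """1-based ``chrom:start`` label used in exported tables."""
        return f"{self.chrom}:{self.start + 1}"

    def overlaps(self, other: "GenomeLocus") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end


@dataclass
class LibrarySpec:
    """One sequencing library: short code, raw read total, abundance cutoff k."""

    code: str
    total_reads: int
    k_threshold: int = 1

    def __post_init__(self) -> None:
        if self.total_reads <= 0:
            raise ValueError("total_reads must be > 0")
        if self.k_threshold < 1:
            raise ValueError("k_threshold must be >= 1")


@dataclass
class Signature:
    """A unique trimmed small-RNA sequence with per-library counts.

    The row unit of the expanded signature table: raw and normalized
    counts per library, optional annotation, recorded genomic loci and
    the uncapped genomic location count.
    """

    sig_id: str
    seq: str
    raw_counts: dict[str, int] = field(default_factory=dict)
    cpm: dict[str, float] = field(default_factory=dict)
    annotation: Optional[str] = None
    loci: list[GenomeLocus] = field(default_factory=list)
    location_count: int = 0
    gene_models: list[str] = field(default_factory=list)

    @property
    def length(self) -> int:
        return len(self.seq)

    def total_raw(self) -> int:
        return sum(self.raw_counts.values())


@dataclass(frozen=True)
class Alignment:
    signature_id: str
    locus: GenomeLocus
    mismatches: int


@dataclass
class FoldResult:
    """Secondary structure of one sequence from the stacking-score DP."""

    structure: str                 # dot-bracket
    energy: float                  # negated optimal score; <= 0
    pair_map: dict[int, int]       # symmetric position -> partner

    def paired(self, i: int) -> bool:
        return i in self.pair_map


@dataclass
class HairpinCandidate:
    window: GenomeLocus
    window_seq: str
    fold: FoldResult
    mature_span: tuple[int, int]   # offsets within window, half-open
    arm: Optional[str] = None      # "5p" | "3p"
    star_span: Optional[tuple[int, int]] = None
    verdict: bool = False
    reasons: list[str] = field(default_factory=list)


@dataclass
class SirnaCluster:
    region: GenomeLocus
    n_signatures: int
    n_alignments: int
    footprint: int
    strands: dict[str, int]
    class_label: str = "ambiguous"
    exon_fraction: Optional[float] = None
    spliced_flag: Optional[bool] = None
    signature_ids: list[str] = field(default_factory=list)

    @property
    def breadth_ratio(self) -> float:
        return self.footprint / max(len(self.region), 1)


@dataclass
class TriggerSite:
    transcript_id: str
    position: int        # 0-based start of the miRNA complement on the transcript
    cleavage_pos: int    # transcript coordinate of the first base 3' of the cut
    matches: int
    mismatches: int
    strand: str = "+"


@dataclass
class PhasingResult:
    register_counts: list[int]   # length == period
    n: int                       # distinct 5' positions tallied
    k: int                       # modal-register count
    score: float                 # k / n
    p_value: float               # Bonferroni-corrected binomial tail
    insufficient: bool = False


@dataclass
class TEFamilyProfile:
    family: str
    unique_by_length: dict[int, int] = field(default_factory=dict)
    reads_by_length: dict[int, int] = field(default_factory=dict)
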