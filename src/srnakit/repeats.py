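"""Transposable-element and repeat-region size-class profiles.

Signatures are attributed to TE families by ungapped placement against a
family-tagged TE database at >= 95% identity over the signature (for
20-35-mers that allows exactly one substitution; 19-mers and shorter must
match exactly).  Profiles separate distinct-signature counts from summed
read counts per length class — the two can disagree, e.g. when a family
emits few distinct but highly amplified 22-mers alongside many diverse
low-copy 24-mers.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Optional, Sequence

import pandas as pd

from .mapping import GenomeIndex, align_to_index
from .types import Alignment, GenomeLocus, Signature, TEFamilyProfile

log = logging.getLogger(__name__)


class TEDatabase:
    """Family-tagged TE records, indexed for mismatch-bounded lookup."""

    def __init__(self, records: Sequence[tuple[str, str, str]]):
        """``records``: (name, family, sequence)."""
        self.records = list(records)
        self.family_of = {name: family for name, family, _ in records}
        self.index = GenomeIndex({name: seq for name, _, seq in records})

    @classmethod
    def from_fasta(cls, path: str) -> "TEDatabase":
        """Family parsed from a ``family=<name>`` token or the second |-field."""
        from Bio import SeqIO

        records = []
        for rec in SeqIO.parse(str(path), "fasta"):
            family = "unknown"
            for token in rec.description.split():
                if token.startswith("family="):
                    family = token.split("=", 1)[1]
                    break
            else:
                if "|" in rec.id:
                    parts = rec.id.split("|")
                    if len(parts) > 1 and parts[1]:
                        family = parts[1]
            records.append((rec.id, family, str(rec.seq)))
        return cls(records)


def match_te_db(
    seq: str, db: TEDatabase, min_identity: float = 0.95
) -> Optional[tuple[str, float]]:
    """Best family for a signature, or None.

    A hit requires identity >= ``min_identity`` over the full signature at
    the best ungapped placement on either strand of any record.  Ties in
    mismatch count across different families are logged and reported as
    ``("ambiguous", identity)``.
    """
    L = len(seq)
    max_mm = math.floor(L * (1.0 - min_identity))
    hits = align_to_index(seq, db.index, max_mm=max_mm)
    if not hits:
        return None
    best_mm = min(h[2] for h in hits)
    families = {db.family_of[h[0]] for h in hits if h[2] == best_mm}
    identity = (L - best_mm) / L
    if len(families) > 1:
        log.info("signature %s ties across families %s at %d mm", seq, sorted(families), best_mm)
        return "ambiguous", identity
    return families.pop(), identity


def assign_families(
    signatures: Iterable[Signature], db: TEDatabase, min_identity: float = 0.95
) -> dict[str, str]:
    """seq -> family for every signature with a database hit."""
    out = {}
    for sig in signatures:
        hit = match_te_db(sig.seq, db, min_identity)
        if hit is not None:
            out[sig.seq] = hit[0]
    return out


def family_size_profiles(
    assignments: dict[str, str],
    signatures: Sequence[Signature],
    lengths: range = range(19, 26),
    exclusions: Optional[set[str]] = None,
) -> tuple[dict[str, TEFamilyProfile], TEFamilyProfile]:
    """Per-family and aggregate unique/read counts by length class.

    ``exclusions`` removes named sequences from the *aggregate* only —
    the mechanism for dropping, e.g., an extremely abundant miRNA whose
    incidental repeat match would distort the distribution.
    """
    exclusions = exclusions or set()
    profiles: dict[str, TEFamilyProfile] = {}
    aggregate = TEFamilyProfile(family="all")
    by_seq = {s.seq: s for s in signatures}
    for seq, family in assignments.items():
        sig = by_seq.get(seq)
        if sig is None:
            continue
        L = sig.length
        if L not in lengths:
            continue
        reads = sig.total_raw()
        prof = profiles.setdefault(family, TEFamilyProfile(family=family))
        prof.unique_by_length[L] = prof.unique_by_length.get(L, 0) + 1
        prof.reads_by_length[L] = prof.reads_by_length.get(L, 0) + reads
        if seq not in exclusions:
            aggregate.unique_by_length[L] = aggregate.unique_by_length.get(L, 0) + 1
            aggregate.reads_by_length[L] = aggregate.reads_by_length.get(L, 0) + reads
    return profiles, aggregate


def modal_length(profile: dict[int, int]) -> Optional[int]:
    if not profile:
        return None
    return max(sorted(profile), key=lambda L: profile[L])


def region_size_profile(
    region: GenomeLocus,
    alignments: Sequence[Alignment],
    signatures: Sequence[Signature],
    lengths: range = range(19, 26),
) -> pd.DataFrame:
    """Length histogram of reads from signatures aligning inside a region.

    Per-library columns hold the summed raw counts of region-aligned
    signatures by length; the ``all`` column is their row sum, so the
    per-library histograms partition the overall one.  ``attrs`` carries
    the fraction of each library's reads attributable to the region and
    the distinct-signature count.
    """
    by_id = {s.sig_id: s for s in signatures}
    in_region: set[str] = set()
    for aln in alignments:
        if aln.locus.overlaps(region) and aln.signature_id in by_id:
            in_region.add(aln.signature_id)
    codes = list(signatures[0].raw_counts) if signatures else []
    table = pd.DataFrame(0, index=list(lengths), columns=codes, dtype=int)
    for sid in in_region:
        sig = by_id[sid]
        if sig.length not in table.index:
            continue
        for code in codes:
            table.loc[sig.length, code] += sig.raw_counts.get(code, 0)
    table.insert(0, "all", table.sum(axis=1))
    fracs = {}
    for code in codes:
        lib_total = sum(s.raw_counts.get(code, 0) for s in signatures)
        lib_region = sum(by_id[sid].raw_counts.get(code, 0) for sid in in_region)
        fracs[code] = lib_region / lib_total if lib_total else 0.0
    table.attrs["library_fractions"] = fracs
    table.attrs["n_signatures"] = len(in_region)
    return table


MULTIMAP_BANDS = [(1, 1), (2, 10), (11, 103), (104, None)]


def multimap_statistics(signatures: Sequence[Signature]) -> pd.DataFrame:
    """Counts of genome-matched signatures by location-count band."""
    matched = [s for s in signatures if s.location_count >= 1]
    rows = []
    for lo, hi in MULTIMAP_BANDS:
        label = f"{lo}" if lo == hi else (f"{lo}-{hi}" if hi else f">{lo - 1}")
        n = sum(1 for s in matched if s.location_count >= lo and (hi is None or s.location_count <= hi))
        rows.append({"band": label, "count": n})
    df = pd.DataFrame(rows).set_index("band")
    total = len(matched)
    df["pct"] = df["count"] / total * 100 if total else 0.0
    return df
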