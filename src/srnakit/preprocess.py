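"""Raw 35-base reads -> thresholded, non-redundant, normalized signatures.

Stages: 3' adapter trimming on fixed-length reads, per-library collapsing
of identical inserts, abundance thresholding scaled to library depth, the
cross-library union database, counts-per-million normalization, and the
19-25-nt size-class distribution.
"""

from __future__ import annotations

import collections
from typing import Iterable, Iterator, Optional

import pandas as pd
import pysam

from .types import LibrarySpec, Signature

DEFAULT_ADAPTER = "TCGTATGCCGTCTTCTGCTTG"
READ_LENGTH = 35
MIN_INSERT = 15
MAX_INSERT = 35

#: sentinel returned by :func:`trim_adapter` for empty constructs / artifacts
DISCARD = None


def trim_adapter(read: str, adapter: str = DEFAULT_ADAPTER) -> Optional[str]:
    """Trim the 3' adapter from one fixed-length read.

    The insert is ``read[:i]`` for the leftmost ``i`` at which the read
    suffix exactly equals the adapter prefix over their full overlap (the
    adapter context disambiguates chance occurrences of its leading TCG).
    ``i == 0`` is an empty construct and inserts shorter than 15 bases are
    ligation artifacts; both are discarded (``None``).  Reads with no
    adapter hit are kept untrimmed as 35-mers, so insert lengths span
    15-35 bases.
    """
    read = read.upper().replace("U", "T")
    if len(read) != READ_LENGTH:
        raise ValueError(f"expected a {READ_LENGTH}-base read, got {len(read)} bases")
    if not adapter.startswith("TCG"):
        raise ValueError("adapter must start with TCG")
    n = len(read)
    for i in range(0, n):
        m = min(len(adapter), n - i)
        if read[i:i + m] == adapter[:m]:
            if i == 0:
                return DISCARD  # empty construct
            if i < MIN_INSERT:
                return DISCARD  # artifact
            return read[:i]
    return read  # no adapter: full-length 35-mer insert


def trim_reads(reads: Iterable[str], adapter: str = DEFAULT_ADAPTER) -> Iterator[str]:
    """Trim an iterable of raw reads, dropping discarded ones."""
    for read in reads:
        insert = trim_adapter(read, adapter)
        if insert is not None:
            yield insert


def read_fastq(path: str) -> Iterator[str]:
    """Yield read sequences from a FASTQ/FASTA file (plain or gzipped)."""
    with pysam.FastxFile(str(path)) as fh:
        for entry in fh:
            yield entry.sequence


def collapse(inserts: Iterable[str]) -> dict[str, int]:
    """Add up identical trimmed inserts into per-sequence raw counts."""
    return dict(collections.Counter(inserts))


def choose_threshold(total_reads: int) -> int:
    """Abundance cutoff k scaled to library depth.

    k=5 up to 3M raw reads, k=16 from 12M, k=10 in between — deeper
    libraries need a higher floor to reject the same artifact rate.
    """
    if total_reads <= 0:
        raise ValueError("total_reads must be > 0")
    if total_reads <= 3_000_000:
        return 5
    if total_reads >= 12_000_000:
        return 16
    return 10


def normalize_cpm(raw_count: int | float, library: LibrarySpec) -> float:
    """Reads per million: raw * 1e6 / library total raw reads."""
    if raw_count < 0:
        raise ValueError("raw_count must be >= 0")
    if library.total_reads == 0:
        raise ValueError("library total_reads is 0")
    return raw_count * 1_000_000 / library.total_reads


def build_union_db(
    per_library_counts: dict[str, dict[str, int]],
    libraries: dict[str, LibrarySpec],
) -> list[Signature]:
    """Union signature database across libraries.

    A sequence enters iff some library holds it at >= that library's k;
    once included, its raw counts from *every* library are stored, even
    sub-threshold ones.  CPM uses each library's raw read total.
    Signatures are ordered by total raw count (desc), then sequence.
    """
    included: set[str] = set()
    for code, counts in per_library_counts.items():
        k = libraries[code].k_threshold
        for seq, c in counts.items():
            if c >= k:
                included.add(seq)
    sigs: list[Signature] = []
    order = sorted(
        included,
        key=lambda s: (-sum(per_library_counts[c].get(s, 0) for c in per_library_counts), s),
    )
    for idx, seq in enumerate(order, start=1):
        raw = {c: per_library_counts[c].get(seq, 0) for c in per_library_counts}
        cpm = {c: normalize_cpm(raw[c], libraries[c]) for c in raw}
        sigs.append(Signature(sig_id=f"sig_{idx:06d}", seq=seq, raw_counts=raw, cpm=cpm))
    return sigs


def size_distribution(
    signatures: list[Signature],
    lengths: range = range(19, 26),
) -> pd.DataFrame:
    """Unique-signature counts and percentages per length class, per library.

    A signature counts as present in a library when its raw count there is
    >= 1.  Percentages are over the selected length range within each
    library, so they sum to 100 wherever any signature is present.
    """
    if not signatures:
        return pd.DataFrame(index=list(lengths))
    codes = list(signatures[0].raw_counts)
    counts = pd.DataFrame(0, index=list(lengths), columns=codes, dtype=int)
    for sig in signatures:
        if sig.length not in counts.index:
            continue
        for code in codes:
            if sig.raw_counts.get(code, 0) >= 1:
                counts.loc[sig.length, code] += 1
    pct = counts / counts.sum(axis=0).replace(0, pd.NA) * 100
    pct.columns = [f"{c}_pct" for c in codes]
    return pd.concat([counts, pct], axis=1)


def preprocess_library(
    path: str,
    code: str,
    adapter: str = DEFAULT_ADAPTER,
    k: Optional[int] = None,
) -> tuple[LibrarySpec, dict[str, int]]:
    """Trim and collapse one FASTQ library; auto-pick k from depth if unset."""
    total = 0

    def _gen() -> Iterator[str]:
        nonlocal total
        for seq in read_fastq(path):
            total += 1
            yield seq

    counts = collapse(trim_reads(_gen(), adapter))
    spec = LibrarySpec(code=code, total_reads=total, k_threshold=k or choose_threshold(total))
    return spec, counts


def write_collapsed_fasta(counts: dict[str, int], path: str) -> None:
    """Merged FASTA with the raw count in the header (``>sig_00001_x57``)."""
    with open(path, "w") as fh:
        for i, (seq, c) in enumerate(
            sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])), start=1
        ):
            fh.write(f">sig_{i:05d}_x{c}\n{seq}\n")
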