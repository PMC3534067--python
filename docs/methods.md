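# Methods

This note documents the models, parameter choices and numerical details
behind srnakit, and what the synthetic benchmark does and does not
establish about real data.

## Read preprocessing

Raw reads are fixed 35-base records carrying the insert, the 3′ adapter
(`TCGTATGCCGTCTTCTGCTTG` by default) and, for short constructs, filler.
Adapter identification requires the full-overlap exact prefix match at
the leftmost possible position, not merely the adapter's leading `TCG`
trinucleotide: `TCG` alone occurs by chance once per 64 positions, and
the surrounding adapter context is what makes the leftmost hit reliable.
Consequences of the rule: a hit at position 0 is an empty construct
(discarded), an insert shorter than 15 bases is a ligation artifact
(discarded), and a read with no hit is kept as a 35-base insert, so
insert lengths span 15–35. Input is case-folded and U→T on ingest.
Quality scores are ignored throughout (none of the decisions here use
them).

The abundance threshold *k* tracks library depth — 5 up to 3M raw
reads, 16 from 12M, 10 between — so that deeper libraries do not admit
proportionally more artifacts. The union database applies *k* per
library but, once a sequence is admitted anywhere, stores its counts
from every library including sub-threshold ones; tissue comparisons
need those low counts. CPM normalization divides by the library's total
raw reads (not post-filter reads): the bundled published table is
consistent with that denominator, e.g. 646,995 cpm in a 6.1M-read
library back-computes to the ~3.9M raw reads described for that
signature.

## Genome mapping

The mapper is exhaustive by construction: for ≤ m substitutions a
placement must contain one of m+1 contiguous exact segments
(pigeonhole), segment hits come from per-length k-mer position maps, and
candidates are verified by a vectorized Hamming comparison. Chromosomes
are concatenated with 40-base N runs (longer than any query) and any
window touching an N is rejected, so no cross-chromosome artifacts
arise. The default mismatch cap is 4; `max_mm=0` reduces to exact
lookup. Correctness is checked against a full-scan oracle in the test
suite at mm ∈ {0,1,2,4}.

Multi-mapping policy: placements are recorded as loci only when a
signature maps to fewer than 10 regions; the uncapped placement count is
always kept, because the repeat statistics (bands 1 / 2–10 / 11–103 /
>103) need it. Reference annotation matching is exhaustive over the
reference set and ungapped over the full overlap of signature and
reference (the shorter slid along the longer): 0 mismatches for
overlaps ≤ 18 bases, ≤ 1 above; ties break on fewest mismatches then
lexicographic reference name. Gene-model joining reports every gene
overlapping a recorded locus by ≥ 1 base together with the feature types
touched (exon, inferred intron, UTR).

## Folding model

Secondary structure uses a deliberately simple stacking-weighted score,
not a thermodynamic nearest-neighbor table: a pair whose inner neighbor
(i+1, j−1) is also a pair earns its own type weight (G-C 3, A-U 2,
G-U 1), any other pair earns 1, hairpin loops keep ≥ 3 unpaired bases.
The DP maximizes this score exactly (verified against exhaustive
structure enumeration for short sequences); energy is the negated
optimum in score units. Absolute free energies are out of scope — all
downstream criteria depend on topology and score per base only. Ties
break deterministically toward 5′-most, outermost pairs, with stacked
continuations preferred, so folds are reproducible. Note one model
property: the score is *not* invariant under reverse-complementing a
sequence, because a G:U pair maps to C:A (unpairable); this is inherent
to any wobble-containing model.

## Hairpin acceptance criteria

A mapped mature validates as a miRNA when some window (200 nt, mature
scanned across it at stride 20, 10-base edge margins, clipped at
chromosome ends) folds such that:

1. ≥ 16 mature bases are paired;
2. all partners lie on one side of the mature (not in the terminal
   loop) — this fixes the arm call (5p/3p);
3. the partners form one compact region: partner span ≤ mature span
   + 6 bases. Without this duplex-compactness requirement, random
   200-nt windows pass at ~35% because their matures pair piecemeal
   across scattered helices; with it, background 21-mers pass at ≤ 5%;
4. fold energy ≤ −0.25 score units per window base;
5. ≤ 3 unpaired bases internal to the mature span (terminal unpaired
   runs excluded).

All thresholds are config-exposed (`HairpinCriteria`); they are explicit
substitutes for the informal "stable hairpin" notion and were set so
that planted, literature-shaped precursors pass while dinucleotide
shuffles and random background fail. When several loci of one signature
fold, the pipeline prefers passing folds at the fewest-mismatch locus:
a mature also aligns, imperfectly, to the opposite arm of its own stem,
and mismatch ordering resolves the arm unambiguously.

Duplex reporting: per arm the most-read signature is taken; the duplex
shows the canonical Dicer geometry when each product's 5′ start pairs
with the base two inside the partner's 3′ end. Family grouping strips
letter/arm suffixes from annotations (miR156b/f → miR156); unannotated
hairpin-validated sequences cluster by single linkage at ≤ 1
substitution with ≤ 2-base terminal shift, and each family's most
abundant member is flagged as the putative authentic mature.

## siRNA clusters

Recorded alignments merge by single linkage within 200 bases on a
chromosome, strand-blind (double-stranded sources produce both
strands). A cluster is miRNA-like when it is narrow (≤ 30-base
footprint), dominated by one sequence (≥ 80% of reads), strand-biased
(≥ 90%) and overlaps a passing hairpin; it is siRNA when broad
(≥ 100-base footprint) with ≥ 10 distinct signatures; otherwise
ambiguous. The spliced-mRNA test computes the exonic fraction of
aligned bases within an overlapping intron-bearing gene; the flag
threshold is 0.98 rather than exactly zero intronic bases, tolerating a
single stray read at desk scale; intronless genes return null.
Inverted-repeat sources are sought ± 10 kb around a cluster by seeded
self-comparison against the local reverse complement (20-mer seeds
chained on diagonals), reporting arm pairs ≥ 100 bases at ≥ 90% arm
identity with spacers ≤ 5 kb.

## Phasing

The trigger search scans every ungapped placement of the miRNA's
complement; effective matches = Watson-Crick matches + ⌊wobble/2⌋, site
threshold 17 (the range observed at real trigger sites). Cleavage falls
between miRNA positions 10/11. Phasing is tallied over *distinct*
aligned 5′-end positions downstream of the cut — read counts would let
abundance skew dominate — with antisense alignments offset +2 by duplex
geometry. With n positions and modal-register count k, p = min(1, 21 ·
P[Bin(n, 1/21) ≥ k]) using the exact binomial tail; the ×21 corrects
for scanning the modal register. This Bonferroni tail is an upper bound
on the exact null probability of the modal statistic; it is tight for
strongly concentrated registers (the regime of reported loci, where it
agrees with permutation estimates within Monte-Carlo error) and
conservative for diffuse ones. Calibration on uniform-position null
clusters (n = 20 distinct positions over an 840-base span) gives an
achieved type-I rate of ≈ 0.04 at α = 0.05; discreteness moves the
achieved rate with n, which is why the calibration fixes the cluster
size. Product enumeration lists only full 21-base phase windows that
have matching signatures; windows truncated by the transcript end are
excluded.

## Repeat profiles

TE assignment requires ≥ 95% identity over the signature at the best
ungapped placement on either strand of any database record — for
20–35-mers exactly one substitution, for ≤ 19-mers none. The identity
denominator is the signature length, not the record length. Ties across
families at equal mismatches are reported as ambiguous and logged.
Profiles tabulate distinct signatures and summed reads per length
(19–25 reported by default); an exclusion list removes named sequences
from the aggregate only — the generalization of dropping a single
extremely abundant miRNA whose incidental repeat match would distort
the distribution. Region profiles (e.g. an rDNA array supplied as a
BED mask, since gene-model annotations over rDNA are unreliable) count
reads per length per library, so per-library histograms sum to the
overall one.

## Synthetic data: what it emulates, and what it does not

The generator plants, in an otherwise uniform-random genome (150 kb, 2
chromosomes by default): 20 miRNA hairpins (near-perfect stems, three
non-pairing mutations in the arm opposite the mature — real stems carry
bulges, and this keeps mature-vs-star alignment asymmetric), 5
inverted-repeat siRNA sources (one with the 621-base arm / ~1 kb spacer
geometry of a documented aquaporin locus), one trigger-cleaved locus
with products phased every 21 bases (8 sense, 2 antisense partners at
−2, 1 off-register), TE families with divergent copies (2% divergence,
two conserved windows shared verbatim by all copies so that high-copy
products exercise the 11–103 multimap band), an 8-copy rDNA-like tandem
array, and 5 spliced background genes, one of which sources exon-only
siRNAs. Library sampling draws a product with probability ∝ base weight
× per-library length-profile weight × tissue multiplier; 10% of reads
are random genome background. Seed libraries weight 24-nt sampling
heavily and carry the full TE product pool; vegetative libraries weight
21-nt and silence 90% of TE products — the two mechanisms that produce
the seed/vegetative size-class contrast in real tissue panels. One TE
family (Copia here) pairs many distinct low-weight 24-mers with six
high-weight 22-mers, reproducing the distinct-vs-read-count modal
inversion. Defaults: 10⁵ reads per library, substitution error rate
0.001 applied to inserts, reads = insert + adapter + random filler
truncated to 35 bases, dummy quality `I`. Truth tables record each
product's realized pre-error count per library, so with error rate 0
and no background the trimmed/collapsed counts must match truth
*exactly* — and do, which is the end-to-end identity test.

Not modeled: ligation bias, PCR duplication, cluster amplification,
quality-score structure, 5′ adapters/barcodes (reads begin at the
insert's first base), indel errors, and genome base composition.
Passing the synthetic benchmark therefore shows the algorithms are
correct and calibrated under clean abundance and error models, not that
thresholds are optimal for any particular real library; the
depth-scaled k rule, mismatch caps, and hairpin/cluster thresholds
remain config-exposed for that reason. Sequencing-error variants of
very abundant matures do enter the database above threshold (mirroring
the sequence-variant inflation seen in real miRNA families); family
grouping absorbs them.

## Problem sizes and determinism

Default study sizes (150 kb genome, 8 × 10⁵ reads, ≤ 4 mismatches,
~750-signature database) were chosen so a full simulate-plus-pipeline
pass completes in about a minute on one CPU; every stage scales to
larger inputs by the obvious knobs (`SimConfig`, `PipelineConfig`). All
randomness flows from explicit seeds (`numpy.random.default_rng`);
repeated runs are byte-identical, and the library simulation uses a
seed stream derived from the genome seed so the two stages stay
independently reproducible.
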