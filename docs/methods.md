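# Methods

## The nomination model

CIRCLE-seq evidence for a Cas9 cleavage event is a read pair with a
specific post-alignment signature: both mates mapped, properly paired, on
opposite strands, in the two concordant first/second-mate orientations —
SAM flag multisets {99, 147} (first mate forward) and {83, 163} (first
mate reverse). The pipeline takes that signature literally: a pair passes
only if its flag multiset is *exactly* one of those two, not merely
"properly paired with opposite strands". Two further pair-level screens
are applied first and last: a mean-base-quality screen (drop if either
mate's mean Phred < 20, strict inequality, so a mean of exactly 20 is
kept) and a deleted-region screen (drop if the deleted region is ≥ 20
bp). "Deleted region" is read as the largest single CIGAR `D` operation
across both mates — a deletion is one region, and circularization
artifacts present as a single gap; a `sum` metric is available via
`deletion_metric="sum"` for users who prefer the aggregate reading.
Pairs are attributed to the first failing stage (quality → flags →
deletion), so the filter report partitions its input exactly.

Nomination then proceeds on intervals. Coverage is the per-base count of
mate alignments whose reference-consuming CIGAR span (M/D/N/=/X, taken as
one contiguous block) covers the base; it is stored run-length encoded,
which is exactly the bedGraph representation. A peak is a maximal
interval with depth ≥ `min_height` (default 1; runs separated by ≤
`merge_gap` bases are merged, default 0), with height = maximal depth
inside and an `apex`, the leftmost base attaining it. Control
subtraction removes any sample peak overlapping (≥ 1 bp) any peak of the
untreated control — peak-level exclusion, not height arithmetic, because
what the control identifies is an artifact *locus*. Replicate
intersection returns the base-wise common intervals with height =
min(height_A, height_B): the conservative choice, and the one that makes
the operation commutative, idempotent and (for > 2 replicates, folded
pairwise) associative. Candidates are ranked by height descending, ties
broken by genomic coordinate for deterministic output, and reported with
log10(height), the customary plotting scale.

Annotation scans `[start − flank, end + flank)` (flank default 25 bp, so
a peak covering only one side of the cut still reaches the protospacer)
on both strands for 20-mers adjacent to a PAM-pattern match (IUPAC, `N`
wildcard; default NGG). The minimal-Hamming-distance hit wins; ties are
resolved by distance from the hit's inferred cut position to the peak
apex, then by coordinate, then by `+` strand (which also prevents double
counting at palindromic loci). The inferred cut sits `cut_offset` bp (
default 3, standard SpCas9 blunt-cut geometry) PAM-proximal of the
protospacer end. On-target labelling against a known cut coordinate uses
an inclusive ± 5 bp tolerance.

## The simulator and what it does (not) emulate

The simulator encodes the post-alignment contract of the assay rather
than the assay chemistry or the aligner. Cut-derived molecules are
emitted as concordant FR pairs whose fragment spans the cut — real
CIRCLE-seq junction reads map back-to-back *at* the cut, but the flag
contract downstream is identical, and this geometry makes the accepted
flag multisets literally true of the truth alignments. Per site the pair
count is Binomial(depth_per_site, cleave_prob); fragment lengths are
truncated normal (mean 300 bp, sd 30 bp — the assay states only the
mean; 10 % CV is typical of acoustic shearing — minimum = read length);
reads are 75 bp. A convenience map `max(0.05, 1 − 0.15k)` turns k spacer
mismatches into a default cleavage probability; it is a modelling
convenience, not an activity model, and per-site probabilities can be
given explicitly.

Background molecules are constructed to fail exactly one filter each:
a low-quality fraction (default 10 % of background) at mean Q15, half the
remainder with discordant flag pairs, half with a ≥ 20 bp CIGAR deletion.
Artifact loci (`background_site_rate`, an integer count, default 2) get
filter-passing pairs at half the per-site depth in *both* the sample and
the negative control; their coordinates derive from a dedicated RNG
stream of the seed so the two libraries place them identically, and they
are kept far enough from planted sites (2 × mean fragment + 12 × sd) that
an artifact footprint can never merge with a true site peak — otherwise
subtraction would delete genuine evidence through simple adjacency, which
is a property of the toy geometry, not of the method. Planted sites are
mutually separated by twice the mean fragment length and kept that far
from contig ends.

What the simulator does **not** emulate: sequencing errors beyond the
quality tiers, adapters, PCR duplicates, chimeric junction geometry,
repeat-induced multi-mapping, or any aligner behaviour. Passing tests
therefore demonstrate the correctness of the nomination logic under its
stated contract, not robustness to real-library pathologies upstream of
it.

## Reference study conditions

End-to-end verification uses one fixed set of conditions: a 50 kb
single-contig genome; nine planted sites — the on-target (0 mismatches,
cleavage probability 1.0) and eight off-targets with 1–6 mismatches at
probabilities 0.85 declining linearly to 0.10; depth 200 pairs per site;
300 background pairs; two artifact loci; two replicate experiments, each
with its own control. These sizes keep a 100-seed study around 15 s on
one core while leaving every stage non-trivially exercised (the weakest
"recoverable" site at p ≈ 0.21 still draws ~40 pairs). The recovery
property checked is: the top-ranked annotated candidate is the on-target,
every site with cleavage probability ≥ 0.2 is covered by a surviving
candidate peak, and no artifact-only locus survives subtraction +
intersection.

## Scalar metrics

Skipping efficiency is 100 × skipped/(skipped + unskipped); it is
scale-invariant, so the shared unit of the two amounts (copies or mass)
does not matter. Frame shift of a skipped exon set is Σ lengths mod 3,
restored iff 0. ddPCR copy loss is 100 × (1 − target/reference)
concentration; the assay measures the drop in amplifiable copies at the
cut site against an uncut reference locus. Values are clamped to
[0, 100], with a warning when target exceeds reference (measurement
noise). The ratio form of the copy-loss statistic is this package's
formalization of the assay's intent; output metadata (the CLI help)
documents it as such.

## Numerical and degenerate-input choices

Coordinates are 0-based half-open internally; SAM is written 1-based,
BED/bedGraph 0-based half-open. All randomness flows through
`numpy.random.default_rng` seeded from explicit integers (derived
per-replicate seeds stay below 2³¹), and all text artifacts are emitted
with stable ordering, so every output is byte-identical for a fixed
config + seed — the run log (which carries wall-clock timings) is the
one deliberate exception. Empty inputs are legal everywhere and yield
empty outputs with zeroed reports; `rank_sites` requires heights ≥ 1
(log10 of the minimum peak height is 0); peaks with start ≥ end,
malformed CIGARs, SAMs without `@SQ`, and zero/zero efficiency inputs
raise with the offending record named. An existing non-empty output
directory is refused unless `force` is set, and writability is probed
before any stage runs.

## Known limitations

Candidate selection beyond ranking (how many top sites to carry into
validation) is left to the user (`top_n`); no enrichment statistic is
computed because no null model is defined for the assay. Bulged
(insertion/deletion) protospacer alignments are not searched, and no
specificity score (CFD/MIT) is attached. The pair filters require both
mates mapped to the same name-groupable SAM; orphan records are counted
and excluded rather than rescued.
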