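"""Synthetic CIRCLE-seq assay simulator.

Generates a fully ground-truthed miniature experiment: a random reference,
planted on-/off-target protospacers with per-site cleavage probability,
cut-derived concordant read pairs centred on each cut, background pairs
constructed to fail the pipeline's filters, and shared "artifact" loci
emitted in both the sample and the Cas9/sgRNA-untreated negative control.

The generative model encodes the post-alignment contract of the assay, not
the aligner: real CIRCLE-seq junction pairs map back-to-back at the cut,
but here cut-derived pairs are emitted as concordant FR pairs spanning the
cut so that the accepted flag multisets {99,147}/{83,163} are literally
satisfiable by truth flags.  Fragments average 300 bp (truncated normal)
and reads are 75 bp paired-end, matching the assay the simulator emulates.

All outputs are byte-identical for a fixed seed and parameter set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .genome import IUPAC, ReferenceGenome, SgRNASpec, hamming, revcomp
from .samfilter import MateRecord, ReadPairRecord, pair_to_sam_lines, sam_header

_BASES = "ACGT"

# Stream tags mixed into the seed so sample, control and artifact-locus
# draws are independent yet reproducible.
_STREAM_SAMPLE = 1
_STREAM_CONTROL = 2
_STREAM_ARTIFACT_LOCI = 3

#: Flag pairs assigned to background molecules that must fail the flag rule.
_REJECTED_FLAG_PAIRS = ((97, 145), (65, 129), (81, 161), (113, 177))
#: Flag pairs carried by genuine cut-derived (and artifact) molecules.
_ACCEPTED_FLAG_PAIRS = ((99, 147), (83, 163))


def default_cleave_prob(mismatches: int) -> float:
    """Convenience mismatch->activity map: max(0.05, 1 - 0.15k)."""
    return max(0.05, 1.0 - 0.15 * mismatches)


@dataclass
class PlantedSite:
    """Ground truth for one planted cleavage locus."""

    contig: str
    cut_pos: int  # 0-based inter-base coordinate of the blunt cut
    strand: str
    protospacer: str  # spacer-strand orientation
    mismatches: int
    cleave_prob: float
    name: str = ""

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        if not 0.0 <= self.cleave_prob <= 1.0:
            raise ValueError("cleave_prob must be in [0, 1]")

    def to_bed6(self) -> str:
        """One BED6 line; the single-base interval marks the cut position."""
        score = round(1000 * self.cleave_prob)
        return (
            f"{self.contig}\t{self.cut_pos}\t{self.cut_pos + 1}"
            f"\t{self.name}\t{score}\t{self.strand}"
        )


@dataclass
class SimParams:
    """Simulation parameters; defaults are the assay's stated conditions
    (300 bp mean fragments, 75 bp paired-end reads)."""

    fragment_length_mean: int = 300
    fragment_length_sd: float = 30.0
    read_length: int = 75
    depth_per_site: int = 200
    background_pairs: int = 300
    background_site_rate: int = 2  # number of shared artifact loci
    low_quality_fraction: float = 0.1  # of background pairs
    seed: int = 0

    def __post_init__(self) -> None:
        if self.read_length > self.fragment_length_mean:
            raise ValueError("read_length must not exceed fragment_length_mean")
        for name in ("fragment_length_mean", "read_length", "depth_per_site",
                     "background_pairs", "background_site_rate"):
            if getattr(self, name) < 0 or (
                name in ("fragment_length_mean", "read_length")
                and getattr(self, name) == 0
            ):
                raise ValueError(f"{name} must be non-negative (lengths positive)")
        if not 0.0 <= self.low_quality_fraction <= 1.0:
            raise ValueError("low_quality_fraction must be in [0, 1]")


@dataclass
class SimReads:
    """Everything one simulation run produced, in memory.

    `pairs` are the truth alignments as ReadPairRecords; the text fields
    are the serialized FASTQ/SAM/BED artifacts.
    """

    pairs: list[ReadPairRecord]
    fastq_r1: str
    fastq_r2: str
    truth_sam: str
    truth_bed: str
    n_cut_pairs: int
    n_background_pairs: int
    n_artifact_pairs: int
    artifact_loci: list[tuple[str, int]] = field(default_factory=list)


def make_genome(seed: int, n_contigs: int, contig_length: int) -> ReferenceGenome:
    """Random i.i.d. reference; deterministic for a fixed seed."""
    if n_contigs < 1:
        raise ValueError("n_contigs must be >= 1")
    if contig_length < 1000:
        raise ValueError("contig_length must be >= 1000")
    rng = np.random.default_rng(seed)
    contigs = {}
    for i in range(n_contigs):
        draws = rng.integers(0, 4, size=contig_length)
        contigs[f"chr{i + 1}"] = "".join(_BASES[b] for b in draws)
    return ReferenceGenome(contigs)


def plant_sites(
    genome: ReferenceGenome,
    sgrna: SgRNASpec,
    mismatch_counts: Sequence[int],
    cleave_probs: Sequence[float] | None = None,
    seed: int = 0,
    min_separation: int = 600,
) -> tuple[ReferenceGenome, list[PlantedSite]]:
    """Overwrite the genome at disjoint random loci with protospacer+PAM.

    Each planted protospacer differs from the spacer at exactly the
    requested number of positions.  Sites are pairwise separated by at
    least `min_separation` bp (default twice the mean fragment length) and
    kept `min_separation` away from contig ends so whole fragments fit.
    Returns a new genome and the truth records; the input is not mutated.
    """
    if cleave_probs is None:
        cleave_probs = [default_cleave_prob(k) for k in mismatch_counts]
    if len(mismatch_counts) != len(cleave_probs):
        raise ValueError("mismatch_counts and cleave_probs must have equal length")
    rng = np.random.default_rng(seed)
    contigs = {name: list(seq) for name, seq in genome.contigs.items()}
    names = list(contigs)
    weights = np.array([len(contigs[n]) for n in names], dtype=float)
    weights /= weights.sum()
    plen = len(sgrna.pam)
    site_len = 20 + plen
    placed: list[tuple[str, int]] = []  # (contig, protospacer-region start)
    sites: list[PlantedSite] = []

    for idx, (k, p) in enumerate(zip(mismatch_counts, cleave_probs)):
        for _ in range(10_000):
            cname = names[rng.choice(len(names), p=weights)]
            clen = len(contigs[cname])
            lo, hi = min_separation, clen - min_separation - site_len
            if hi <= lo:
                continue
            pos = int(rng.integers(lo, hi))
            if all(c != cname or abs(pos - q) >= min_separation
                   for c, q in placed):
                break
        else:
            raise ValueError(
                f"could not place site {idx} disjointly; genome too small"
            )
        placed.append((cname, pos))

        proto = _mutate_spacer(sgrna.spacer, k, rng)
        pam = "".join(_concrete_base(c, rng) for c in sgrna.pam)
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "+":
            planted = proto + pam
            cut = pos + 20 - sgrna.cut_offset
        else:
            planted = revcomp(proto + pam)
            cut = pos + plen + sgrna.cut_offset
        contigs[cname][pos:pos + site_len] = planted
        sites.append(PlantedSite(
            contig=cname, cut_pos=cut, strand=strand, protospacer=proto,
            mismatches=k, cleave_prob=float(p), name=f"site{idx:02d}:mm{k}",
        ))
        assert hamming(sgrna.spacer, proto) == k

    new_genome = ReferenceGenome({n: "".join(s) for n, s in contigs.items()})
    return new_genome, sites


def _mutate_spacer(spacer: str, k: int, rng: np.random.Generator) -> str:
    if k < 0 or k > 20:
        raise ValueError("mismatch count must be in [0, 20]")
    proto = list(spacer)
    positions = rng.choice(20, size=k, replace=False)
    for j in sorted(int(x) for x in positions):
        alternatives = [b for b in _BASES if b != proto[j]]
        proto[j] = alternatives[int(rng.integers(3))]
    return "".join(proto)


def _concrete_base(iupac_code: str, rng: np.random.Generator) -> str:
    choices = IUPAC[iupac_code]
    return choices[int(rng.integers(len(choices)))]


def _draw_fragment_length(rng: np.random.Generator, params: SimParams) -> int:
    """Truncated-normal fragment length (min = read_length)."""
    for _ in range(100):
        length = int(round(rng.normal(params.fragment_length_mean,
                                      params.fragment_length_sd)))
        if length >= params.read_length:
            return length
    raise RuntimeError("fragment length sampling failed after 100 retries")


def _cut_spanning_pair(
    rng: np.random.Generator,
    genome: ReferenceGenome,
    contig: str,
    center: int,
    params: SimParams,
    qname: str,
    flags: tuple[int, int],
    qual_char: str,
) -> ReadPairRecord:
    """A concordant FR pair whose fragment spans `center`."""
    seq = genome.contigs[contig]
    clen = len(seq)
    frag = min(_draw_fragment_length(rng, params), clen)
    start = center - int(rng.integers(1, max(frag, 2)))
    start = min(max(start, 0), clen - frag)
    rl = params.read_length
    left_seq = seq[start:start + rl]
    right_seq = seq[start + frag - rl:start + frag]
    fwd_pos, rev_pos = start + 1, start + frag - rl + 1  # 1-based
    qual = qual_char * rl
    fwd = MateRecord(0, contig, fwd_pos, 60, f"{rl}M", left_seq, qual)
    rev = MateRecord(0, contig, rev_pos, 60, f"{rl}M", right_seq, qual)
    if flags == (99, 147):
        fwd.flag, rev.flag = 99, 147
        return ReadPairRecord(qname, fwd, rev)
    if flags == (83, 163):
        rev.flag, fwd.flag = 83, 163
        return ReadPairRecord(qname, rev, fwd)
    # background orientations: keep the same geometry, relabel the flags
    fwd.flag, rev.flag = flags
    return ReadPairRecord(qname, fwd, rev)


def _good_qual_char(rng: np.random.Generator) -> str:
    return chr(33 + int(rng.integers(30, 41)))  # Q30..Q40


def _pick_accepted_flags(rng: np.random.Generator) -> tuple[int, int]:
    return _ACCEPTED_FLAG_PAIRS[int(rng.integers(2))]


def _artifact_loci(
    genome: ReferenceGenome,
    params: SimParams,
    exclude_sites: Sequence[PlantedSite],
) -> list[tuple[str, int]]:
    """Shared artifact loci, derived from the seed alone so sample and
    control place them identically.  Loci avoid planted-site windows and
    each other by the worst-case coverage footprint (twice the mean
    fragment length plus the truncated-normal tail), so an artifact peak
    can never merge with — and thereby subtract away — a true site peak."""
    rng = np.random.default_rng([params.seed, _STREAM_ARTIFACT_LOCI])
    names = list(genome.contigs)
    weights = np.array([len(genome.contigs[n]) for n in names], dtype=float)
    weights /= weights.sum()
    sep = 2 * params.fragment_length_mean + int(12 * params.fragment_length_sd)
    taken = [(s.contig, s.cut_pos) for s in exclude_sites]
    loci: list[tuple[str, int]] = []
    for _ in range(params.background_site_rate):
        for _ in range(10_000):
            cname = names[rng.choice(len(names), p=weights)]
            clen = len(genome.contigs[cname])
            if clen <= 2 * sep:
                continue
            pos = int(rng.integers(sep, clen - sep))
            if all(c != cname or abs(pos - q) >= sep for c, q in taken):
                break
        else:
            raise ValueError("could not place artifact loci disjointly")
        taken.append((cname, pos))
        loci.append((cname, pos))
    return loci


def _background_pair(
    rng: np.random.Generator,
    genome: ReferenceGenome,
    params: SimParams,
    qname: str,
) -> ReadPairRecord:
    """One background molecule, built to fail exactly one filter stage."""
    names = list(genome.contigs)
    cname = names[int(rng.integers(len(names)))]
    clen = len(genome.contigs[cname])
    center = int(rng.integers(params.read_length, clen - params.read_length))
    u = rng.random()
    rl = params.read_length
    if u < params.low_quality_fraction:
        # mean quality below 20: fails the quality screen
        pair = _cut_spanning_pair(rng, genome, cname, center, params, qname,
                                  _pick_accepted_flags(rng), chr(33 + 15))
    elif u < params.low_quality_fraction + (1 - params.low_quality_fraction) / 2:
        # discordant orientation: fails the flag-pair rule
        flags = _REJECTED_FLAG_PAIRS[int(rng.integers(len(_REJECTED_FLAG_PAIRS)))]
        pair = _cut_spanning_pair(rng, genome, cname, center, params, qname,
                                  flags, _good_qual_char(rng))
    else:
        # deletion >= 20 bp in one mate's CIGAR: fails the deletion rule
        pair = _cut_spanning_pair(rng, genome, cname, center, params, qname,
                                  _pick_accepted_flags(rng),
                                  _good_qual_char(rng))
        d = int(rng.integers(20, 81))
        pair.mate1.cigar = f"20M{d}D{rl - 20}M"
    return pair


def _render(genome: ReferenceGenome, pairs: list[ReadPairRecord],
            sites: Sequence[PlantedSite]) -> tuple[str, str, str, str]:
    """Serialize pairs as FASTQ R1/R2 and truth SAM, and sites as BED6."""
    r1_lines: list[str] = []
    r2_lines: list[str] = []
    sam_lines = [sam_header(genome.lengths).rstrip("\n")]
    for pair in pairs:
        for mate in pair.mates():
            is_r1 = bool(mate.flag & 0x40)
            seq, qual = mate.seq, mate.qual
            if mate.flag & 0x10:  # store as sequenced, not reference-forward
                seq, qual = revcomp(seq), qual[::-1]
            block = [f"@{pair.qname}/{1 if is_r1 else 2}", seq, "+", qual]
            (r1_lines if is_r1 else r2_lines).extend(block)
        sam_lines.extend(pair_to_sam_lines(pair))
    bed = "".join(s.to_bed6() + "\n" for s in sites)
    nl = lambda lines: "\n".join(lines) + ("\n" if lines else "")
    return nl(r1_lines), nl(r2_lines), nl(sam_lines), bed


def simulate_reads(
    genome: ReferenceGenome,
    sites: Sequence[PlantedSite],
    params: SimParams,
    exclude_sites: Sequence[PlantedSite] | None = None,
) -> SimReads:
    """Simulate the Cas9-treated sample library.

    Per site, ~Binomial(depth_per_site, cleave_prob) cut-derived pairs are
    emitted with truth flags from {(99,147),(83,163)} and quality >= Q30.
    Background pairs fail the quality, flag, or deletion filter.  Artifact
    loci (count = background_site_rate) receive filter-passing pairs and
    recur at identical coordinates in the negative control.

    `exclude_sites` lists loci the artifact placement must avoid; it
    defaults to `sites` and must match the value the paired control run
    uses, or the two runs would place their shared artifacts differently.
    """
    if exclude_sites is None:
        exclude_sites = sites
    rng = np.random.default_rng([params.seed, _STREAM_SAMPLE])
    pairs: list[ReadPairRecord] = []
    n_cut = 0
    for i, site in enumerate(sites):
        n = int(rng.binomial(params.depth_per_site, site.cleave_prob))
        for j in range(n):
            pairs.append(_cut_spanning_pair(
                rng, genome, site.contig, site.cut_pos, params,
                f"cut:s{i:02d}:{j:05d}", _pick_accepted_flags(rng),
                _good_qual_char(rng)))
        n_cut += n
    loci = _artifact_loci(genome, params, exclude_sites)
    n_art = _emit_artifacts(rng, genome, params, loci, pairs)
    for j in range(params.background_pairs):
        pairs.append(_background_pair(rng, genome, params, f"bg:{j:05d}"))
    r1, r2, sam, bed = _render(genome, pairs, sites)
    return SimReads(pairs, r1, r2, sam, bed, n_cut,
                    params.background_pairs, n_art, loci)


def simulate_negative_control(
    genome: ReferenceGenome,
    params: SimParams,
    exclude_sites: Sequence[PlantedSite] = (),
) -> SimReads:
    """Simulate the Cas9/sgRNA-untreated control library.

    No cut-derived pairs at any planted site; the shared artifact loci
    appear at the same coordinates as in the sample (same seed), with
    independently drawn reads.  Pass the planted sites as `exclude_sites`
    exactly as in the paired `simulate_reads` call.
    """
    rng = np.random.default_rng([params.seed, _STREAM_CONTROL])
    pairs: list[ReadPairRecord] = []
    loci = _artifact_loci(genome, params, exclude_sites)
    n_art = _emit_artifacts(rng, genome, params, loci, pairs)
    for j in range(params.background_pairs):
        pairs.append(_background_pair(rng, genome, params, f"bg:{j:05d}"))
    r1, r2, sam, bed = _render(genome, pairs, ())
    return SimReads(pairs, r1, r2, sam, bed, 0,
                    params.background_pairs, n_art, loci)


def _emit_artifacts(rng, genome, params, loci, pairs) -> int:
    depth = max(1, params.depth_per_site // 2)
    n_art = 0
    for i, (cname, pos) in enumerate(loci):
        for j in range(depth):
            pairs.append(_cut_spanning_pair(
                rng, genome, cname, pos, params,
                f"art:a{i:02d}:{j:05d}", _pick_accepted_flags(rng),
                _good_qual_char(rng)))
            n_art += 1
    return n_art
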