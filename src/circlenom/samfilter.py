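"""Read-level filters for CIRCLE-seq alignments.

Three rules, applied per read pair in this order:

1. base quality — drop the pair if either mate's mean Phred score is
   strictly below a threshold (default 20);
2. flag pair — keep only pairs whose unordered SAM flag multiset is exactly
   {99, 147} or {83, 163}, the two concordant opposite-orientation
   first/second-mate combinations;
3. deleted region — drop the pair if the CIGAR deleted-region size reaches
   a threshold (default 20 bp).

Pairs are dropped at the first failing stage, so the FilterReport counts
partition the input.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import pysam

logger = logging.getLogger(__name__)

#: The only flag multisets accepted as CIRCLE-seq cut-evidence pairs.
ACCEPTED_FLAG_PAIRS = frozenset({(83, 163), (99, 147)})

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")

# CIGAR operations that consume reference bases.
_REF_OPS = set("MDN=X")
# CIGAR operations that consume query bases.
_QUERY_OPS = set("MIS=X")


@dataclass
class MateRecord:
    """One aligned mate: the SAM fields the pipeline needs."""

    flag: int
    rname: str
    pos: int  # 1-based leftmost mapped base, as in SAM
    mapq: int
    cigar: str
    seq: str
    qual: str

    @property
    def pos0(self) -> int:
        """0-based leftmost mapped position."""
        return self.pos - 1

    @property
    def ref_span(self) -> int:
        """Reference bases consumed by the alignment (M/D/N/=/X)."""
        return sum(n for n, op in parse_cigar(self.cigar) if op in _REF_OPS)

    @property
    def is_reverse(self) -> bool:
        return bool(self.flag & 0x10)


@dataclass
class ReadPairRecord:
    """Both mates of one template, sharing a query name."""

    qname: str
    mate1: MateRecord
    mate2: MateRecord

    def mates(self) -> tuple[MateRecord, MateRecord]:
        return self.mate1, self.mate2


@dataclass
class FilterReport:
    """Pair accounting across the three filter stages.

    Invariant: input = dropped_quality + dropped_flags + dropped_deletion
    + kept.
    """

    input: int = 0
    dropped_quality: int = 0
    dropped_flags: int = 0
    dropped_deletion: int = 0
    kept: int = 0
    unpaired: int = 0  # records with no mate; excluded from `input`

    def check(self) -> None:
        total = (
            self.dropped_quality + self.dropped_flags
            + self.dropped_deletion + self.kept
        )
        if total != self.input:
            raise AssertionError(
                f"FilterReport not conserved: {total} != input {self.input}"
            )

    def to_tsv(self) -> str:
        rows = [
            ("input_pairs", self.input),
            ("dropped_quality", self.dropped_quality),
            ("dropped_flags", self.dropped_flags),
            ("dropped_deletion", self.dropped_deletion),
            ("kept_pairs", self.kept),
            ("unpaired_records", self.unpaired),
        ]
        return "".join(f"{k}\t{v}\n" for k, v in rows)


def parse_cigar(cigar: str) -> list[tuple[int, str]]:
    """Parse a CIGAR string into (length, op) tuples.

    Raises ValueError on malformed input ('*' is treated as no alignment
    information and returns an empty list).
    """
    if cigar == "*":
        return []
    ops = _CIGAR_RE.findall(cigar)
    if "".join(f"{n}{op}" for n, op in ops) != cigar:
        raise ValueError(f"malformed CIGAR string: {cigar!r}")
    return [(int(n), op) for n, op in ops]


def mean_quality(qual: str) -> float:
    """Arithmetic mean Phred score of a Phred+33 quality string."""
    if not qual:
        raise ValueError("empty quality string")
    return sum(ord(c) - 33 for c in qual) / len(qual)


def flag_pair_pass(flag1: int, flag2: int) -> bool:
    """True iff the unordered flag multiset is exactly {83,163} or {99,147}."""
    return tuple(sorted((flag1, flag2))) in ACCEPTED_FLAG_PAIRS


def deleted_region_size(cigar1: str, cigar2: str, metric: str = "max") -> int:
    """Deleted-region size of a pair, from its two CIGAR strings.

    With ``metric="max"`` (default) this is the largest single D operation
    across both mates — one deletion is one "deleted region".  With
    ``metric="sum"`` all D lengths are summed.
    """
    if metric not in ("max", "sum"):
        raise ValueError(f"deletion metric must be 'max' or 'sum', got {metric!r}")
    dels = [
        n
        for cigar in (cigar1, cigar2)
        for n, op in parse_cigar(cigar)
        if op == "D"
    ]
    if not dels:
        return 0
    return max(dels) if metric == "max" else sum(dels)


def pair_passes(
    pair: ReadPairRecord,
    min_mean_q: float = 20.0,
    max_deletion: int = 20,
    deletion_metric: str = "max",
) -> str:
    """Classify one pair: 'quality', 'flags', 'deletion', or 'kept'.

    Stages are evaluated in the pipeline order so each pair is attributed
    to exactly one drop reason.
    """
    m1, m2 = pair.mates()
    if mean_quality(m1.qual) < min_mean_q or mean_quality(m2.qual) < min_mean_q:
        return "quality"
    if not flag_pair_pass(m1.flag, m2.flag):
        return "flags"
    if deleted_region_size(m1.cigar, m2.cigar, deletion_metric) >= max_deletion:
        return "deletion"
    return "kept"


def filter_pairs(
    pairs: Iterable[ReadPairRecord],
    min_mean_q: float = 20.0,
    max_deletion: int = 20,
    deletion_metric: str = "max",
) -> tuple[list[ReadPairRecord], FilterReport]:
    """Apply the three filters to a stream of read pairs.

    Returns the kept pairs (input order preserved) and the stage report.
    """
    report = FilterReport()
    kept: list[ReadPairRecord] = []
    for pair in pairs:
        report.input += 1
        verdict = pair_passes(pair, min_mean_q, max_deletion, deletion_metric)
        if verdict == "kept":
            report.kept += 1
            kept.append(pair)
        elif verdict == "quality":
            report.dropped_quality += 1
        elif verdict == "flags":
            report.dropped_flags += 1
        else:
            report.dropped_deletion += 1
    report.check()
    return kept, report


def read_sam_pairs(path: str) -> Iterator[ReadPairRecord]:
    """Group a SAM file into ReadPairRecords by query name.

    Secondary and supplementary alignments (0x100/0x800) are discarded
    before pairing.  Records whose mate never appears are logged and
    skipped (they do not enter the pair count).  Memory is bounded by the
    number of qnames whose mate has not yet been seen.
    """
    try:
        handle = pysam.AlignmentFile(path, "r", check_sq=True)
    except ValueError as exc:
        raise ValueError(f"SAM file lacks @SQ header lines: {path}") from exc
    with handle as fh:
        if not fh.references:
            raise ValueError(f"SAM file has no @SQ header lines: {path}")
        pending: dict[str, MateRecord] = {}
        orphans = 0
        for rec in fh:
            if rec.is_secondary or rec.is_supplementary:
                continue
            mate = MateRecord(
                flag=rec.flag,
                rname=rec.reference_name or "*",
                pos=(rec.reference_start or 0) + 1,
                mapq=rec.mapping_quality,
                cigar=rec.cigarstring or "*",
                seq=rec.query_sequence or "",
                qual=_qual_str(rec),
            )
            if rec.query_name in pending:
                first = pending.pop(rec.query_name)
                yield ReadPairRecord(rec.query_name, first, mate)
            else:
                pending[rec.query_name] = mate
        orphans = len(pending)
        if orphans:
            logger.warning("%d unpaired records (mate never found) in %s",
                           orphans, path)


def _qual_str(rec: pysam.AlignedSegment) -> str:
    if rec.query_qualities is None:
        return ""
    return "".join(chr(q + 33) for q in rec.query_qualities)


def sam_header(contig_lengths: dict[str, int]) -> str:
    lines = ["@HD\tVN:1.6\tSO:unsorted"]
    for name, length in contig_lengths.items():
        lines.append(f"@SQ\tSN:{name}\tLN:{length}")
    return "\n".join(lines) + "\n"


def pair_to_sam_lines(pair: ReadPairRecord) -> list[str]:
    """Render both mates as SAM records with RNEXT/PNEXT/TLEN filled."""
    m1, m2 = pair.mates()
    lines = []
    for mate, other in ((m1, m2), (m2, m1)):
        left = min(m1.pos0, m2.pos0)
        right = max(m1.pos0 + m1.ref_span, m2.pos0 + m2.ref_span)
        tlen = right - left
        if mate.pos0 > other.pos0 or (mate.pos0 == other.pos0 and mate.is_reverse):
            tlen = -tlen
        rnext = "=" if other.rname == mate.rname else other.rname
        lines.append("\t".join(str(x) for x in (
            pair.qname, mate.flag, mate.rname, mate.pos, mate.mapq,
            mate.cigar, rnext, other.pos, tlen, mate.seq, mate.qual,
        )))
    return lines


def write_sam(
    pairs: Iterable[ReadPairRecord],
    contig_lengths: dict[str, int],
    path: str,
) -> None:
    """Write pairs to a plain-text SAM file (header preserved)."""
    with open(path, "w") as out:
        out.write(sam_header(contig_lengths))
        for pair in pairs:
            for line in pair_to_sam_lines(pair):
                out.write(line + "\n")
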