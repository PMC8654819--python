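"""Coverage tracks and peak nomination.

The nomination core: per-base depth of the kept read pairs as a
run-length-encoded track (the bedGraph), maximal above-threshold intervals
as peaks, removal of peaks overlapping the negative control, base-wise
intersection of replicate peak sets, and ranking by log10 height.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import pandas as pd

from .samfilter import ReadPairRecord


@dataclass
class Peak:
    """Half-open genomic interval with its maximal coverage depth.

    `apex` is the leftmost 0-based position at which the maximal depth is
    attained; it anchors the annotation step's tie-breaking.
    """

    contig: str
    start: int
    end: int
    height: int
    apex: int = -1

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("peak must have start < end")
        if self.apex < 0:
            self.apex = (self.start + self.end) // 2


@dataclass
class CoverageTrack:
    """Per-contig run-length-encoded depth; only nonzero runs are stored.

    Runs are (start, end, depth) with 0-based half-open coordinates,
    sorted and non-overlapping.
    """

    runs: dict[str, list[tuple[int, int, int]]] = field(default_factory=dict)
    contig_lengths: dict[str, int] = field(default_factory=dict)

    def total_covered_bases(self) -> int:
        """Sum of depth x run-length over the whole track."""
        return sum(d * (e - s)
                   for runs in self.runs.values()
                   for s, e, d in runs)

    def to_bedgraph(self) -> str:
        lines = []
        for contig in self.runs:
            for s, e, d in self.runs[contig]:
                lines.append(f"{contig}\t{s}\t{e}\t{d}")
        return "\n".join(lines) + ("\n" if lines else "")


def _mate_spans(pair: ReadPairRecord) -> Iterable[tuple[str, int, int]]:
    """Contiguous reference spans covered by each mate (M/D/N/=/X)."""
    for mate in pair.mates():
        span = mate.ref_span
        if span > 0:
            yield mate.rname, mate.pos0, mate.pos0 + span


def coverage(
    kept_pairs: Iterable[ReadPairRecord],
    contig_lengths: dict[str, int],
) -> CoverageTrack:
    """Per-base depth of the kept pairs, as an RLE track.

    Depth at base b counts mate alignments whose reference-consuming span
    covers b; both mates contribute.  Built by a boundary sweep over the
    +1/-1 events at span ends (no per-base array).
    """
    events: dict[str, list[tuple[int, int]]] = {}
    for pair in kept_pairs:
        for contig, s, e in _mate_spans(pair):
            if contig not in contig_lengths:
                raise ValueError(
                    f"read {pair.qname}: unknown contig {contig!r}")
            if e > contig_lengths[contig]:
                raise ValueError(
                    f"read {pair.qname}: alignment [{s},{e}) exceeds "
                    f"contig {contig} length {contig_lengths[contig]}")
            events.setdefault(contig, []).append((s, 1))
            events[contig].append((e, -1))
    track = CoverageTrack(contig_lengths=dict(contig_lengths))
    for contig in sorted(events):
        evs = sorted(events[contig])
        runs: list[tuple[int, int, int]] = []
        depth = 0
        prev = None
        for pos, delta in evs:
            if prev is not None and depth > 0 and pos > prev:
                if runs and runs[-1][1] == prev and runs[-1][2] == depth:
                    runs[-1] = (runs[-1][0], pos, depth)
                else:
                    runs.append((prev, pos, depth))
            depth += delta
            prev = pos
        track.runs[contig] = runs
    return track


def call_peaks(
    track: CoverageTrack,
    min_height: int = 1,
    merge_gap: int = 0,
) -> list[Peak]:
    """Maximal intervals with depth >= min_height.

    Qualifying runs separated by <= merge_gap uncovered-or-subthreshold
    bases are merged into one peak; the peak's height is the maximal depth
    inside and its apex the leftmost base attaining it.
    """
    if min_height < 1:
        raise ValueError("min_height must be >= 1")
    if merge_gap < 0:
        raise ValueError("merge_gap must be >= 0")
    peaks: list[Peak] = []
    for contig in track.runs:
        current: Peak | None = None
        for s, e, d in track.runs[contig]:
            if d < min_height:
                continue
            if current is not None and s - current.end <= merge_gap:
                current.end = e
                if d > current.height:
                    current.height = d
                    current.apex = s
            else:
                if current is not None:
                    peaks.append(current)
                current = Peak(contig, s, e, d, apex=s)
        if current is not None:
            peaks.append(current)
    return peaks


def _by_contig(peaks: Sequence[Peak]) -> dict[str, list[Peak]]:
    out: dict[str, list[Peak]] = {}
    for p in peaks:
        out.setdefault(p.contig, []).append(p)
    for plist in out.values():
        plist.sort(key=lambda p: (p.start, p.end))
    return out


def subtract_control(
    sample: Sequence[Peak],
    control: Sequence[Peak],
) -> list[Peak]:
    """Remove every sample peak overlapping (>= 1 bp) any control peak.

    Mirrors bedtools `intersect -v`: surviving peaks pass through
    unmodified; there is no height arithmetic.
    """
    ctrl = _by_contig(control)
    kept: list[Peak] = []
    for p in sample:
        hits = ctrl.get(p.contig, ())
        if any(c.start < p.end and p.start < c.end for c in hits):
            continue
        kept.append(p)
    return kept


def intersect_replicates(
    rep_a: Sequence[Peak],
    rep_b: Sequence[Peak],
) -> list[Peak]:
    """Base-wise intersection of two replicate peak sets.

    Each overlapping pair (a, b) contributes the interval
    [max(starts), min(ends)) with height = min(a.height, b.height) —
    conservative evidence, and the rule that makes the operation
    commutative and idempotent.  The apex is inherited from the
    lower-height peak, clamped into the output interval.
    """
    out: list[Peak] = []
    b_by_contig = _by_contig(rep_b)
    for a in sorted(rep_a, key=lambda p: (p.contig, p.start, p.end)):
        for b in b_by_contig.get(a.contig, ()):
            s, e = max(a.start, b.start), min(a.end, b.end)
            if s >= e:
                continue
            # ties on height pick the smaller apex, keeping the operation
            # commutative
            lower = a if (a.height, a.apex) <= (b.height, b.apex) else b
            apex = min(max(lower.apex, s), e - 1)
            out.append(Peak(a.contig, s, e, min(a.height, b.height), apex))
    out.sort(key=lambda p: (p.contig, p.start, p.end))
    return out


def rank_sites(peaks: Sequence[Peak]) -> pd.DataFrame:
    """Rank peaks by height (descending), ties by genomic coordinate.

    Adds log10(height), the scale on which peak heights are plotted along
    the chromosome.  Returns a DataFrame with columns contig, start, end,
    height, apex, log10_height, rank.
    """
    if any(p.height < 1 for p in peaks):
        raise ValueError("peak heights must be >= 1 for log10 ranking")
    ordered = sorted(peaks, key=lambda p: (-p.height, p.contig, p.start))
    return pd.DataFrame(
        {
            "contig": [p.contig for p in ordered],
            "start": [p.start for p in ordered],
            "end": [p.end for p in ordered],
            "height": [p.height for p in ordered],
            "apex": [p.apex for p in ordered],
            "log10_height": [math.log10(p.height) for p in ordered],
            "rank": list(range(1, len(ordered) + 1)),
        }
    )


def peaks_to_bedgraph(peaks: Sequence[Peak]) -> str:
    ordered = sorted(peaks, key=lambda p: (p.contig, p.start, p.end))
    lines = [f"{p.contig}\t{p.start}\t{p.end}\t{p.height}" for p in ordered]
    return "\n".join(lines) + ("\n" if lines else "")
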