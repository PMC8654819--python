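"""Candidate-site annotation.

Scans the sequence under each surviving peak for the protospacer best
matching the guide: every 20-mer adjacent to a PAM-pattern match on either
strand is scored by Hamming distance to the spacer, and the
minimal-mismatch hit (ties: closest inferred cut to the peak apex, then
coordinate, then '+' strand) becomes the candidate annotation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .genome import ReferenceGenome, SgRNASpec, hamming, matches_iupac, revcomp
from .peaks import Peak

logger = logging.getLogger(__name__)


@dataclass
class CandidateSite:
    """A peak annotated with its best protospacer match."""

    peak: Peak
    matched_protospacer: str
    match_strand: str
    mismatches: int
    pam_observed: str
    cut_pos: int  # inferred 0-based inter-base cut coordinate
    is_on_target: bool = False


def _pam_hits(window: str, sgrna: SgRNASpec) -> list[tuple[int, str]]:
    """(offset, strand) of every PAM-pattern match inside the window.

    '+' offsets index the PAM's first base; '-' offsets index the first
    base of the reverse-complemented PAM as written on the forward strand.
    """
    plen = len(sgrna.pam)
    rc_pam = revcomp(sgrna.pam)
    hits = []
    for j in range(len(window) - plen + 1):
        chunk = window[j:j + plen]
        if matches_iupac(sgrna.pam, chunk):
            hits.append((j, "+"))
        if matches_iupac(rc_pam, chunk):
            hits.append((j, "-"))
    return hits


def find_protospacer(
    genome: ReferenceGenome,
    peak: Peak,
    sgrna: SgRNASpec,
    flank: int = 25,
) -> CandidateSite | None:
    """Best protospacer hit in [start - flank, end + flank), both strands.

    Returns None when no PAM-adjacent 20-mer exists in the window.  The
    returned mismatch count is globally minimal over the window; at
    palindromic loci where both strands score equally, '+' wins so no hit
    is double counted.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    seq = genome.contigs[peak.contig]
    lo = peak.start - flank
    hi = peak.end + flank
    if lo < 0 or hi > len(seq):
        logger.warning(
            "annotation window [%d,%d) clipped to contig %s bounds",
            lo, hi, peak.contig)
        lo, hi = max(lo, 0), min(hi, len(seq))
    window = seq[lo:hi]
    plen = len(sgrna.pam)
    best: tuple[tuple[int, int, int, int], CandidateSite] | None = None
    for j, strand in _pam_hits(window, sgrna):
        if strand == "+":
            # protospacer immediately 5' of the PAM on the forward strand
            p = j - 20
            if p < 0:
                continue
            proto = window[p:p + 20]
            pam_obs = window[j:j + plen]
            cut = lo + j - sgrna.cut_offset
        else:
            # forward-strand layout: revcomp(PAM) then revcomp(protospacer)
            p = j + plen
            if p + 20 > len(window):
                continue
            proto = revcomp(window[p:p + 20])
            pam_obs = revcomp(window[j:j + plen])
            cut = lo + p + sgrna.cut_offset
        mm = hamming(sgrna.spacer, proto)
        key = (mm, abs(cut - peak.apex), cut, 0 if strand == "+" else 1)
        if best is None or key < best[0]:
            best = (key, CandidateSite(
                peak=peak, matched_protospacer=proto, match_strand=strand,
                mismatches=mm, pam_observed=pam_obs, cut_pos=cut,
                is_on_target=(mm == 0),
            ))
    return best[1] if best else None


def label_on_target(
    site: CandidateSite,
    truth_cut: tuple[str, int],
    tolerance: int = 5,
) -> CandidateSite:
    """Set is_on_target from the known on-target cut coordinate.

    True iff the inferred cut lies within +/- tolerance bp (inclusive) of
    the truth cut on the same contig.  Peak geometry is never altered.
    """
    contig, cut = truth_cut
    site.is_on_target = (
        site.peak.contig == contig and abs(site.cut_pos - cut) <= tolerance
    )
    return site
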