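"""Reference genome and sgRNA containers.

Coordinates are 0-based half-open throughout the library; SAM output is
1-based and BED/bedGraph output 0-based half-open, per those formats.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

#: IUPAC nucleotide codes -> the set of concrete bases each matches.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string."""
    return seq.translate(_COMPLEMENT)[::-1]


def matches_iupac(pattern: str, seq: str) -> bool:
    """True iff `seq` matches the IUPAC `pattern` position by position."""
    if len(pattern) != len(seq):
        return False
    return all(b in IUPAC[p] for p, b in zip(pattern.upper(), seq.upper()))


def hamming(a: str, b: str) -> int:
    """Number of mismatching positions between equal-length strings."""
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal-length strings")
    return sum(x != y for x, y in zip(a, b))


@dataclass
class ReferenceGenome:
    """Named contigs of A/C/G/T sequence.

    Substrate for planting cleavage sites and for mapping coordinates of
    simulated reads and candidate-site annotation.
    """

    contigs: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen = set()
        for name, seq in self.contigs.items():
            if not name:
                raise ValueError("contig names must be non-empty")
            if name in seen:
                raise ValueError(f"duplicate contig name: {name}")
            seen.add(name)
            bad = set(seq) - set("ACGT")
            if bad:
                raise ValueError(f"contig {name}: non-ACGT characters {sorted(bad)}")

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.contigs.items()}

    def to_fasta(self, handle_or_path) -> None:
        """Write as FASTA, 60-column wrapped."""
        records = [
            SeqRecord(Seq(seq), id=name, description="")
            for name, seq in self.contigs.items()
        ]
        SeqIO.write(records, handle_or_path, "fasta")

    def to_fasta_str(self) -> str:
        buf = io.StringIO()
        self.to_fasta(buf)
        return buf.getvalue()

    @classmethod
    def from_fasta(cls, handle_or_path) -> "ReferenceGenome":
        contigs = {
            rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(handle_or_path, "fasta")
        }
        return cls(contigs)


@dataclass
class SgRNASpec:
    """A single-guide RNA: 20-nt spacer, PAM pattern, and cut geometry.

    `cut_offset` is the blunt-cut distance in bp from the PAM-proximal end
    of the protospacer (3 for SpCas9: the cut falls between spacer
    positions 17 and 18).
    """

    spacer: str
    pam: str = "NGG"
    cut_offset: int = 3

    def __post_init__(self) -> None:
        self.spacer = self.spacer.upper()
        self.pam = self.pam.upper()
        if len(self.spacer) != 20:
            raise ValueError("spacer must be exactly 20 nt")
        if set(self.spacer) - set("ACGT"):
            raise ValueError("spacer must be A/C/G/T only")
        if len(self.pam) < 2:
            raise ValueError("PAM pattern must be at least 2 nt")
        if any(c not in IUPAC for c in self.pam):
            raise ValueError("PAM pattern must use IUPAC nucleotide codes")
        if not (0 < self.cut_offset < 20):
            raise ValueError("cut_offset must be in (0, 20)")
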