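"""Scalar assay metrics: exon-skipping efficiency, reading-frame
arithmetic for multi-exon skips, and ddPCR copy-number loss.

Exon skipping is therapeutic for dystrophin when the total removed exonic
length is a multiple of 3, restoring the downstream reading frame (e.g. a
transcript lacking exon 44, 148 bp, is out of frame; additionally skipping
exon 45, 176 bp, removes 324 bp in total and restores it).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd


@dataclass
class SkippingMeasurement:
    """Skipped and unskipped product amounts, in any shared unit."""

    skipped_amount: float
    unskipped_amount: float

    def __post_init__(self) -> None:
        if self.skipped_amount < 0 or self.unskipped_amount < 0:
            raise ValueError("product amounts must be non-negative")


@dataclass
class ExonModel:
    """Ordered exon lengths (bp), optionally labelled."""

    lengths: list[int]
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        if any(n < 1 for n in self.lengths):
            raise ValueError("exon lengths must be >= 1 bp")
        if self.labels is not None:
            if len(self.labels) != len(self.lengths):
                raise ValueError("labels and lengths must have equal length")
            if len(set(self.labels)) != len(self.labels):
                raise ValueError("exon labels must be unique")

    def length_of(self, label: str) -> int:
        if self.labels is None:
            raise ValueError("exon model has no labels")
        try:
            return self.lengths[self.labels.index(label)]
        except ValueError:
            raise ValueError(f"unknown exon label: {label!r}") from None

    @classmethod
    def from_tsv(cls, path) -> "ExonModel":
        """Two-column TSV: exon label, length in bp (header optional)."""
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         names=["label", "length"])
        if df.iloc[0]["label"] in ("label", "exon"):
            df = df.iloc[1:]
        return cls(lengths=[int(x) for x in df["length"]],
                   labels=[str(x) for x in df["label"]])


def skipping_efficiency(m: SkippingMeasurement) -> float:
    """Percent skipped: 100 x skipped / (skipped + unskipped)."""
    total = m.skipped_amount + m.unskipped_amount
    if total <= 0:
        raise ValueError(
            "skipping efficiency undefined: both product amounts are zero")
    return 100.0 * m.skipped_amount / total


def frame_shift(
    exons: ExonModel,
    removed: Iterable[str],
) -> tuple[int, bool]:
    """Reading-frame shift caused by removing a set of exons.

    Returns (shift, frame_restored) where shift = sum of removed lengths
    mod 3 and the frame is restored iff shift == 0.
    """
    total = sum(exons.length_of(label) for label in set(removed))
    shift = total % 3
    return shift, shift == 0


def ddpcr_copy_loss(target_conc: float, reference_conc: float) -> float:
    """Percent copy loss at the cut site: 100 x (1 - target/reference).

    `target_conc` is the ddPCR concentration (copies/uL) of the amplicon
    spanning the sgRNA target site, `reference_conc` that of an uncut
    reference locus from the same droplet run.  Values are clamped to
    [0, 100]; a target exceeding the reference warns (measurement noise).
    """
    if reference_conc <= 0:
        raise ValueError("reference concentration must be > 0")
    if target_conc < 0:
        raise ValueError("target concentration must be >= 0")
    loss = 100.0 * (1.0 - target_conc / reference_conc)
    if loss < 0:
        warnings.warn(
            "target concentration exceeds reference; copy loss clamped to 0",
            stacklevel=2)
        return 0.0
    return min(loss, 100.0)


def skipping_table(rows: Sequence[tuple[str, float, float]]) -> pd.DataFrame:
    """Batch helper: (sample, skipped, unskipped) -> efficiency table."""
    return pd.DataFrame(
        {
            "sample": [r[0] for r in rows],
            "skipped": [r[1] for r in rows],
            "unskipped": [r[2] for r in rows],
            "efficiency_percent": [
                skipping_efficiency(SkippingMeasurement(r[1], r[2]))
                for r in rows
            ],
        }
    )
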