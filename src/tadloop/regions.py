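"""Genomic intervals and peak records.

Coordinates are 0-based, half-open throughout (BED convention): a region
``chrX:100-200`` covers positions 100..199.  Bin *i* of a map with bin size
``b`` anchored at ``start`` covers ``[start + i*b, start + (i+1)*b)``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

_REGION_RE = re.compile(r"^([^:]+):([\d,]+)-([\d,]+)$")


@dataclass(frozen=True, order=True)
class GenomicRegion:
    """Half-open genomic interval ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got {self.chrom}:{self.start}-{self.end}"
            )

    @classmethod
    def parse(cls, text: str) -> "GenomicRegion":
        """Parse ``chrom:start-end`` (commas in numbers allowed)."""
        m = _REGION_RE.match(text.strip())
        if m is None:
            raise ValueError(f"cannot parse region {text!r}")
        chrom, start, end = m.groups()
        return cls(chrom, int(start.replace(",", "")), int(end.replace(",", "")))

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2

    def overlaps(self, other: "GenomicRegion") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicRegion") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def pad(self, bp: int) -> "GenomicRegion":
        """Symmetric padding, clipped at 0."""
        return GenomicRegion(self.chrom, max(0, self.start - bp), self.end + bp)

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass(frozen=True)
class PeakRecord:
    """A called peak (e.g. CTCF ChIP-seq) with optional score and strand."""

    region: GenomicRegion
    score: float = 0.0
    strand: str = "unknown"  # one of {"+", "-", "unknown"}

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-", "unknown"):
            raise ValueError(f"bad strand {self.strand!r}")


def read_bed_peaks(path: str | Path) -> list[PeakRecord]:
    """Read BED3/BED6 into peak records; strand column optional.

    Column 5 (score) and column 6 (strand) are used when present; BED
    strand "." maps to "unknown".
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    peaks = []
    for row in df.itertuples(index=False):
        fields = list(row)
        region = GenomicRegion(str(fields[0]), int(fields[1]), int(fields[2]))
        score = float(fields[4]) if len(fields) > 4 and fields[4] not in (None, ".") else 0.0
        strand = "unknown"
        if len(fields) > 5 and fields[5] in ("+", "-"):
            strand = str(fields[5])
        peaks.append(PeakRecord(region, score, strand))
    return peaks


def write_bed(records: Iterable[tuple[GenomicRegion, float]], path: str | Path,
              name: str = "feature") -> None:
    """Write (region, score) pairs as BED5."""
    with open(path, "w") as fh:
        for i, (region, score) in enumerate(records):
            fh.write(
                f"{region.chrom}\t{region.start}\t{region.end}\t{name}_{i}\t{score:g}\n"
            )
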