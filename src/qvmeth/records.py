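"""Core record types shared across the package.

Coordinates are 0-based, intervals half-open, matching BED/bedMethyl.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


@dataclass
class MethylationRecord:
    """One per-strand CpG locus with its methylation level.

    ``level`` is the methylation fraction in [0, 1] — either the label from a
    methylation caller's locus table or a model prediction.  ``score`` is the
    bedMethyl column-5 confidence score (0–1000); ``depth`` the read count.
    """

    chrom: str
    start: int
    strand: str
    level: float
    depth: int = 0
    score: int = 0

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not (0.0 <= self.level <= 1.0) or math.isnan(self.level):
            raise ValueError(f"level must be in [0, 1], got {self.level}")
        if not (0 <= self.score <= 1000):
            raise ValueError(f"score must be in [0, 1000], got {self.score}")
        if self.depth < 0:
            raise ValueError(f"depth must be >= 0, got {self.depth}")

    @property
    def end(self) -> int:
        return self.start + 1

    def key(self) -> tuple[str, int, str]:
        return (self.chrom, self.start, self.strand)


@dataclass
class Region:
    """Half-open genomic interval [start, end) with an optional label."""

    chrom: str
    start: int
    end: int
    name: str | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"region start must be < end, got [{self.start}, {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass
class RegionSummary:
    """Trimmed-mean methylation summary of one region."""

    region: Region
    n_total: int
    n_used: int
    mean_level: float  # NaN when n_used == 0
    method: str
    variance: float = float("nan")
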