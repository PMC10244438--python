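"""Core genomic domain types.

All coordinates are 0-based, half-open (BED native) everywhere inside the
package; formats using other conventions are converted at the I/O boundary.
Chromosome names are taken verbatim — no ``chr``-prefix normalization is
applied unless explicitly requested at read time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "GenomicInterval",
    "PeakSet",
    "GeneModel",
    "DEGRecord",
]

STRANDS = ("+", "-", ".")


@dataclass(slots=True)
class GenomicInterval:
    """A 0-based half-open genomic region ``[start, end)``.

    Parameters
    ----------
    chrom
        Chromosome name, taken verbatim.
    start
        0-based inclusive start (bp), ``>= 0``.
    end
        0-based exclusive end (bp), ``> start``.
    strand
        One of ``+``, ``-`` or ``.`` (unstranded).
    name
        Optional label (e.g. a peak id).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be a non-empty string")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start: {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        """Integer midpoint, ``floor((start + end) / 2)``."""
        return (self.start + self.end) // 2

    def sort_key(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)

    def overlap_len(self, other: "GenomicInterval") -> int:
        """Number of shared base pairs with *other* (0 if different chromosomes)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.overlap_len(other) > 0

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass(slots=True)
class PeakSet:
    """A sorted collection of peaks from one dataset/marker.

    Intervals are sorted by ``(chrom, start, end)`` on construction, so the
    sortedness invariant cannot be violated by callers.
    """

    intervals: list[GenomicInterval] = field(default_factory=list)
    source: str = ""
    marker: str = ""

    def __post_init__(self) -> None:
        self.intervals = sorted(self.intervals, key=GenomicInterval.sort_key)

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def __getitem__(self, i):
        return self.intervals[i]

    def chromosomes(self) -> list[str]:
        seen: dict[str, None] = {}
        for iv in self.intervals:
            seen.setdefault(iv.chrom, None)
        return list(seen)


@dataclass(slots=True)
class GeneModel:
    """A gene with a strand-aware transcription start site.

    The TSS is the ``start`` coordinate for ``+``-strand genes and ``end - 1``
    for ``-``-strand genes (the last covered base in half-open coordinates).
    """

    gene_id: str
    interval: GenomicInterval

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")
        if self.interval.strand not in ("+", "-"):
            raise ValueError(
                f"gene {self.gene_id!r} needs an explicit strand (+/-), "
                f"got {self.interval.strand!r}"
            )

    @property
    def tss(self) -> int:
        iv = self.interval
        return iv.start if iv.strand == "+" else iv.end - 1

    @property
    def chrom(self) -> str:
        return self.interval.chrom


@dataclass(slots=True)
class DEGRecord:
    """One row of a differential-expression table.

    At least one of ``pvalue`` / ``qvalue`` must be present; a missing q-value
    is left as ``None`` at parse time and filled by BH adjustment downstream.
    """

    gene_id: str
    log2fc: float
    pvalue: float | None = None
    qvalue: float | None = None

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")
        import math

        if not math.isfinite(self.log2fc):
            raise ValueError(f"log2fc must be finite for gene {self.gene_id!r}")
        if self.pvalue is None and self.qvalue is None:
            raise ValueError(
                f"gene {self.gene_id!r}: at least one of pvalue/qvalue required"
            )
        for label, v in (("pvalue", self.pvalue), ("qvalue", self.qvalue)):
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError(f"{label} must be in [0, 1], got {v}")
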