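"""Genomic interval primitives.

Coordinates are 0-based, half-open, with strand stored explicitly; intervals
on the reverse strand are kept in forward-strand coordinates (BED-compatible).
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class GenomicInterval:
    """A strand-aware interval on a named contig, 0-based half-open."""

    contig: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 0 or self.end < self.start:
            raise ValueError(f"invalid interval bounds [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True if the two intervals share at least one base on the same contig
        (strand is ignored; callers compare strands where direction matters)."""
        return (
            self.contig == other.contig
            and self.start < other.end
            and other.start < self.end
        )
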