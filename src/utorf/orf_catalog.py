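"""Comprehensive cataloguing of potential ORFs from genome and transcript
sequences.

A *potential ORF* is a maximal contiguous span of amino-acid-coding codons in
one of the six reading frames; spans are broken at stop codons and at codons
containing an ambiguous (N) or soft-masked (lowercase) base, so translation
runs over the repeat-masked sequence only. Potential ORFs need not begin with
a start codon: the stop-free spans form a superset of all coding exons, which
is what makes a six-frame database usable for proteogenomic search without
knowing the splice structure.

Retention rules: spans of at least 8 residues are kept; spans that never
contain an in-frame ATG-encoded methionine must reach 20 residues.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set

import numpy as np

from .intervals import GenomicInterval

STOP_CODONS = {"TAA", "TAG", "TGA"}
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

# Standard nuclear genetic code; the mitochondrial code is deliberately not
# implemented — callers flag and skip non-nuclear contigs.
CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

VALID_NT = set("ACGTNacgtn")


def reverse_complement(seq: str) -> str:
    """Reverse-complement preserving soft-mask case."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class NucleotideRecord:
    """A genome contig or transcript sequence.

    Lowercase bases mark soft-masked (repeat) sequence; codons touching them
    are treated as non-coding, mirroring translation of a repeat-masked
    assembly.
    """

    id: str
    sequence: str
    kind: str = "genome-contig"  # or "transcript"

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.id!r} has an empty sequence")
        bad = set(self.sequence) - VALID_NT
        if bad:
            raise ValueError(
                f"record {self.id!r} contains invalid symbols {sorted(bad)!r}"
            )
        if self.kind not in ("genome-contig", "transcript"):
            raise ValueError(f"unknown record kind {self.kind!r}")


@dataclass(frozen=True)
class PotentialOrf:
    """A stop-free codon span with its forward-strand genomic interval."""

    id: str
    aa_sequence: str
    source_id: str
    frame: int  # +1,+2,+3 forward; -1,-2,-3 reverse
    interval: GenomicInterval
    contains_canonical_start: bool
    first_start_offset: Optional[int]  # aa offset of the first ATG-encoded M
    length_aa: int

    def __post_init__(self) -> None:
        if "*" in self.aa_sequence:
            raise ValueError("potential ORF contains a stop symbol")
        if self.length_aa != len(self.aa_sequence):
            raise ValueError("length_aa inconsistent with aa_sequence")
        if len(self.interval) != 3 * self.length_aa:
            raise ValueError("interval length is not 3 x length_aa")


@dataclass
class OrfCatalog:
    """Deduplicated potential-ORF catalogue keyed by exact amino-acid string."""

    entries: Dict[str, List[PotentialOrf]] = field(default_factory=dict)

    @property
    def n_unique(self) -> int:
        return len(self.entries)


def _coding_codon(codon: str) -> bool:
    """A codon participates in translation only if fully unmasked and
    unambiguous."""
    return len(codon) == 3 and all(c in "ACGT" for c in codon)


def enumerate_potential_orfs(
    records: Iterable[NucleotideRecord],
    min_len: int = 8,
    min_len_no_start: int = 20,
) -> List[PotentialOrf]:
    """Enumerate every maximal stop-free codon span in all six frames.

    Spans are broken at stop codons (TAA/TAG/TGA) and at codons containing N
    or a soft-masked base. A span is retained if it has at least ``min_len``
    residues; spans without any in-frame ATG must have at least
    ``min_len_no_start`` residues. "Contains a canonical start" means any
    in-frame ATG within the span, not only at its first codon.
    """
    if min_len > min_len_no_start:
        raise ValueError("min_len must be <= min_len_no_start")
    out: List[PotentialOrf] = []
    for rec in records:
        n = len(rec.sequence)
        for strand in "+-":
            seq = rec.sequence if strand == "+" else reverse_complement(rec.sequence)
            for offset in range(3):
                frame = (offset + 1) if strand == "+" else -(offset + 1)
                span_start: Optional[int] = None
                aas: List[str] = []
                starts: List[int] = []  # aa offsets of ATG codons in span
                for pos in range(offset, n - 2, 3):
                    codon = seq[pos : pos + 3]
                    if not _coding_codon(codon) or codon in STOP_CODONS:
                        if span_start is not None:
                            _emit(out, rec, strand, frame, n, span_start, aas,
                                  starts, min_len, min_len_no_start)
                        span_start, aas, starts = None, [], []
                        continue
                    if span_start is None:
                        span_start = pos
                    if codon == "ATG":
                        starts.append(len(aas))
                    aas.append(CODON_TABLE[codon])
                if span_start is not None:
                    _emit(out, rec, strand, frame, n, span_start, aas,
                          starts, min_len, min_len_no_start)
    return out


def _emit(
    out: List[PotentialOrf],
    rec: NucleotideRecord,
    strand: str,
    frame: int,
    n: int,
    span_start: int,
    aas: List[str],
    starts: List[int],
    min_len: int,
    min_len_no_start: int,
) -> None:
    length = len(aas)
    has_start = bool(starts)
    if length < min_len:
        return
    if not has_start and length < min_len_no_start:
        return
    span_end = span_start + 3 * length
    if strand == "+":
        fwd_start, fwd_end = span_start, span_end
    else:
        fwd_start, fwd_end = n - span_end, n - span_start
    interval = GenomicInterval(rec.id, fwd_start, fwd_end, strand)
    out.append(
        PotentialOrf(
            id=f"{rec.id}:{fwd_start}-{fwd_end}({strand}){frame:+d}",
            aa_sequence="".join(aas),
            source_id=rec.id,
            frame=frame,
            interval=interval,
            contains_canonical_start=has_start,
            first_start_offset=starts[0] if has_start else None,
            length_aa=length,
        )
    )


def translate_interval(orf: PotentialOrf, records: Mapping[str, str]) -> str:
    """Re-translate an ORF's interval from its source sequence (round-trip
    check helper)."""
    seq = records[orf.source_id][orf.interval.start : orf.interval.end]
    if orf.interval.strand == "-":
        seq = reverse_complement(seq)
    return "".join(CODON_TABLE[seq[i : i + 3]] for i in range(0, len(seq), 3))


def deduplicate(orfs: Iterable[PotentialOrf]) -> OrfCatalog:
    """Collapse potential ORFs on exact amino-acid string equality, keeping
    every source occurrence."""
    catalog = OrfCatalog()
    for orf in orfs:
        catalog.entries.setdefault(orf.aa_sequence, []).append(orf)
    return catalog


def gc_content(interval: GenomicInterval, genome: Mapping[str, str]) -> float:
    """GC fraction of an interval, case-insensitive; N bases are excluded from
    both numerator and denominator."""
    if len(interval) == 0:
        raise ValueError("empty interval")
    seq = genome[interval.contig][interval.start : interval.end].upper()
    counts = Counter(seq)
    denom = len(seq) - counts["N"]
    if denom == 0:
        raise ValueError("interval contains only N bases")
    return (counts["G"] + counts["C"]) / denom


def aa_composition(sequences: Sequence[str]) -> Dict[str, float]:
    """Amino-acid frequency vector over the 20 standard residues."""
    if not sequences:
        raise ValueError("empty input")
    counts = Counter()
    for seq in sequences:
        counts.update(seq)
    total = sum(counts[a] for a in AA_ALPHABET)
    if total == 0:
        raise ValueError("no standard residues in input")
    return {a: counts[a] / total for a in AA_ALPHABET}


@dataclass(frozen=True)
class GeneAnnotation:
    """A minimal annotated-gene interval for location classification."""

    gene_id: str
    interval: GenomicInterval


@dataclass(frozen=True)
class LocationCall:
    """Genomic location class of a locus relative to the annotation.

    ``sense`` and ``antisense`` may co-occur (a locus overlapping genes on
    both strands); ``intergenic`` is exclusive and holds iff neither applies.
    """

    categories: frozenset

    def __post_init__(self) -> None:
        if "intergenic" in self.categories and len(self.categories) > 1:
            raise ValueError("intergenic is exclusive with sense/antisense")
        if not self.categories:
            raise ValueError("empty location call")


def classify_location(
    interval: GenomicInterval, annotation: Iterable[GeneAnnotation]
) -> LocationCall:
    """Sense if any same-strand annotated-gene overlap, antisense if any
    opposite-strand overlap; intergenic iff neither."""
    cats: Set[str] = set()
    for gene in annotation:
        if interval.overlaps(gene.interval):
            if gene.interval.strand == interval.strand:
                cats.add("sense")
            else:
                cats.add("antisense")
    if not cats:
        cats = {"intergenic"}
    return LocationCall(frozenset(cats))


def track_mean(
    interval: GenomicInterval, per_base_scores: Mapping[str, np.ndarray]
) -> float:
    """Arithmetic mean of defined per-base scores (e.g. phastCons or phyloP)
    over the interval; undefined positions are NaN. Returns NaN if no
    position in the interval carries a score."""
    track = np.asarray(per_base_scores[interval.contig], dtype=float)
    window = track[interval.start : interval.end]
    if window.size == 0 or np.all(np.isnan(window)):
        return float("nan")
    return float(np.nanmean(window))


def catalog_summary(lengths_aa: Sequence[int]) -> Dict[str, float]:
    """Entry count plus median and mean amino-acid length of a sequence set;
    used to summarize a utORF database file."""
    arr = np.asarray(list(lengths_aa), dtype=float)
    if arr.size == 0:
        raise ValueError("empty catalogue")
    return {
        "n": int(arr.size),
        "median_length_aa": float(np.median(arr)),
        "mean_length_aa": float(arr.mean()),
    }
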