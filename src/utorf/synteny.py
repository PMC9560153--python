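"""Synteny-anchored protein similarity scoring.

Orthologous sequence for a locus is taken from a whole-genome multiple
sequence alignment rather than found by homology search: the MSA block(s)
covering the locus (plus 9 bp of flank on each side) provide, for every
species, the sequence that occupies the syntenic position. That per-species
sequence is translated in all three reading frames (stops kept as '*') and
scored against the reference ORF with a Smith–Waterman local alignment under
BLOSUM62 with zero gap penalties; the raw score is normalized by the
reference ORF length and the best frame kept. Scores above a calibrated
threshold (2.5 points per reference residue by default) indicate a
significant ortholog; genomic homology without a significant protein score
is the signature used downstream for de novo origin calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .alignment import zero_gap_local_score
from .intervals import GenomicInterval
from .orf_catalog import CODON_TABLE

DEFAULT_THRESHOLD = 2.5
DEFAULT_FLANK = 9
DEFAULT_MIN_COVERAGE = 0.5

# Proteome-like amino-acid composition (fly proteome; fractions sum to 1).
# Used as the default residue distribution of the simulated null.
PROTEOME_AA_FREQUENCIES: Dict[str, float] = {
    "A": 0.0739, "C": 0.0190, "D": 0.0519, "E": 0.0639, "F": 0.0340,
    "G": 0.0619, "H": 0.0270, "I": 0.0479, "K": 0.0559, "L": 0.0899,
    "M": 0.0230, "N": 0.0479, "P": 0.0559, "Q": 0.0529, "R": 0.0549,
    "S": 0.0849, "T": 0.0569, "V": 0.0589, "W": 0.0100, "Y": 0.0290,
}
_total = sum(PROTEOME_AA_FREQUENCIES.values())
PROTEOME_AA_FREQUENCIES = {k: v / _total for k, v in PROTEOME_AA_FREQUENCIES.items()}


@dataclass
class MsaBlock:
    """Aligned rows for one reference interval; all rows equal length,
    '-' marks gaps, absent species are simply missing from ``rows``."""

    reference_interval: GenomicInterval
    rows: Dict[str, str]
    reference_species: str

    def __post_init__(self) -> None:
        if self.reference_species not in self.rows:
            raise ValueError("reference species missing from block rows")
        lengths = {len(r) for r in self.rows.values()}
        if len(lengths) > 1:
            raise ValueError("MSA rows have unequal lengths")
        ref_nt = sum(c != "-" for c in self.rows[self.reference_species])
        if ref_nt != len(self.reference_interval):
            raise ValueError("reference row non-gap length != interval length")

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.rows.values())))


@dataclass(frozen=True)
class SimilarityScore:
    """Length-normalized protein similarity of one species to the reference
    ORF (points per reference residue; >= 0 by local alignment)."""

    species: str
    score: float
    best_frame: Optional[int]
    reference_length_aa: int
    homology_flag: bool


@dataclass(frozen=True)
class NullModel:
    """Simulated null of the similarity score on random sequence pairs."""

    n_pairs: int
    length_range: Tuple[int, int]
    mean: float
    sd: float
    threshold: float
    seed: int


def extract_locus_alignment(
    blocks: Sequence[MsaBlock],
    interval: GenomicInterval,
    flank: int = DEFAULT_FLANK,
) -> MsaBlock:
    """Per-species gapped slice of the MSA spanning ``interval`` plus
    ``flank`` reference bases on each side, stitched across adjacent blocks.

    The core interval must be fully covered by the given blocks; flanks are
    clipped where the alignment (or contig) ends. Species absent from every
    covering block are absent from the result; species absent from some
    covering block contribute gap runs there.
    """
    want_start = max(0, interval.start - flank)
    want_end = interval.end + flank
    covering = sorted(
        (
            b
            for b in blocks
            if b.reference_interval.contig == interval.contig
            and b.reference_interval.start < want_end
            and want_start < b.reference_interval.end
        ),
        key=lambda b: b.reference_interval.start,
    )
    if not covering:
        raise ValueError("interval not covered by the alignment")
    # Verify that the core interval itself is contiguously covered.
    pos = interval.start
    for b in covering:
        if b.reference_interval.start > pos:
            break
        pos = max(pos, b.reference_interval.end)
    if pos < interval.end:
        raise ValueError("interval only partially covered by the alignment")

    species = sorted({s for b in covering for s in b.rows})
    pieces: Dict[str, List[str]] = {s: [] for s in species}
    got_start: Optional[int] = None
    got_end = want_start
    for b in covering:
        ref_row = b.rows[b.reference_species]
        # Map reference coordinates to column indices within this block.
        ref_pos = b.reference_interval.start
        col_lo = col_hi = None
        lo = max(want_start, b.reference_interval.start)
        hi = min(want_end, b.reference_interval.end)
        if lo >= hi:
            continue
        for col, ch in enumerate(ref_row):
            if ch != "-":
                if ref_pos == lo:
                    col_lo = col
                ref_pos += 1
                if ref_pos == hi:
                    col_hi = col + 1
                    break
        assert col_lo is not None and col_hi is not None
        width = col_hi - col_lo
        for s in species:
            row = b.rows.get(s)
            pieces[s].append(row[col_lo:col_hi] if row is not None else "-" * width)
        if got_start is None:
            got_start = lo
        got_end = hi

    rows = {s: "".join(p) for s, p in pieces.items()}
    ref_species = covering[0].reference_species
    return MsaBlock(
        reference_interval=GenomicInterval(
            interval.contig, got_start, got_end, interval.strand
        ),
        rows=rows,
        reference_species=ref_species,
    )


def genomic_identity(block: MsaBlock, species: str) -> Optional[Dict[str, float]]:
    """Column-wise nucleotide identity and coverage of one species against
    the reference row.

    identity = matching shared columns / columns where both rows are non-gap;
    coverage = shared columns / reference non-gap columns. Returns None for a
    species absent from the block.
    """
    if species not in block.rows:
        return None
    ref = block.rows[block.reference_species].upper()
    other = block.rows[species].upper()
    ref_nt = shared = match = 0
    for a, b in zip(ref, other):
        if a != "-":
            ref_nt += 1
            if b != "-":
                shared += 1
                if a == b:
                    match += 1
    if ref_nt == 0:
        return None
    return {
        "identity": match / shared if shared else 0.0,
        "coverage": shared / ref_nt,
    }


def translate_frames(nt: str) -> List[str]:
    """Three forward-frame translations, stops kept as '*', ambiguous codons
    as 'X'."""
    nt = nt.upper().replace("-", "")
    frames = []
    for off in range(3):
        aa = []
        for i in range(off, len(nt) - 2, 3):
            codon = nt[i : i + 3]
            aa.append(CODON_TABLE.get(codon, "X"))
        frames.append("".join(aa))
    return frames


def similarity_score(
    reference_aa: str,
    other_nt: str,
    species: str = "",
    homology_flag: bool = False,
) -> SimilarityScore:
    """Modified Smith–Waterman protein similarity of an orthologous
    nucleotide stretch against a reference ORF.

    The other species' sequence (gaps dropped) is translated in all three
    forward frames — MSA rows are orientation-consistent with the reference,
    so no reverse complement — and each frame is scored with the zero-gap
    local alignment; the raw score is divided by the reference ORF length
    and the best frame kept.
    """
    if not reference_aa:
        raise ValueError("empty reference ORF")
    frames = translate_frames(other_nt)
    best = 0.0
    best_frame: Optional[int] = None
    for k, aa in enumerate(frames):
        s = zero_gap_local_score(reference_aa, aa) / len(reference_aa)
        if best_frame is None or s > best:
            best, best_frame = s, k
    if not other_nt.replace("-", ""):
        best_frame = None
        homology_flag = False
    return SimilarityScore(
        species=species,
        score=best,
        best_frame=best_frame,
        reference_length_aa=len(reference_aa),
        homology_flag=homology_flag,
    )


def score_block(
    block: MsaBlock,
    reference_aa: str,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
) -> Dict[str, SimilarityScore]:
    """Per-species similarity scores for a locus block; the homology flag is
    genomic (alignment coverage >= ``min_coverage`` of the reference block),
    independent of the protein score."""
    out: Dict[str, SimilarityScore] = {}
    for species, row in block.rows.items():
        if species == block.reference_species:
            continue
        ident = genomic_identity(block, species)
        flag = ident is not None and ident["coverage"] >= min_coverage
        out[species] = similarity_score(reference_aa, row, species, flag)
    return out


def random_protein(rng: np.random.Generator, length: int,
                   frequencies: Mapping[str, float]) -> str:
    letters = list(frequencies)
    probs = np.array([frequencies[a] for a in letters])
    probs = probs / probs.sum()
    return "".join(rng.choice(letters, size=length, p=probs))


def calibrate_null(
    n_pairs: int = 10_000,
    length_range: Tuple[int, int] = (20, 150),
    aa_frequencies: Optional[Mapping[str, float]] = None,
    seed: int = 0,
    threshold: float = DEFAULT_THRESHOLD,
    equal_lengths: bool = True,
) -> NullModel:
    """Simulated null of the similarity score.

    Draws ``n_pairs`` independent pairs of random amino-acid sequences with
    lengths uniform on ``length_range`` and residues i.i.d. from
    ``aa_frequencies``; scores each pair with the zero-gap local alignment
    normalized by the first member's length. By default the two members of a
    pair share one drawn length — the null models a reference ORF against
    the syntenic stretch of the same extent, and the normalized score is then
    a per-residue rate whose spread is not inflated by length-ratio variance.
    Set ``equal_lengths=False`` for fully independent member lengths. The
    significance threshold is fixed a priori, not derived from the
    simulation.
    """
    if n_pairs <= 0:
        raise ValueError("n_pairs must be positive")
    freqs = dict(aa_frequencies or PROTEOME_AA_FREQUENCIES)
    total = sum(freqs.values())
    if abs(total - 1.0) > 1e-6:
        raise ValueError("aa_frequencies must sum to 1")
    rng = np.random.default_rng(seed)
    lo, hi = length_range
    scores = np.empty(n_pairs)
    for i in range(n_pairs):
        la = int(rng.integers(lo, hi + 1))
        lb = la if equal_lengths else int(rng.integers(lo, hi + 1))
        a = random_protein(rng, la, freqs)
        b = random_protein(rng, lb, freqs)
        scores[i] = zero_gap_local_score(a, b) / la
    return NullModel(
        n_pairs=n_pairs,
        length_range=(lo, hi),
        mean=float(scores.mean()),
        sd=float(scores.std(ddof=1)),
        threshold=threshold,
        seed=seed,
    )
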