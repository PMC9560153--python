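"""Peptide-level support logic for candidate ORFs.

Covers in-silico tryptic digestion, trie-based polymorphism screening
(minimum Hamming/Levenshtein distance from novel peptides to the annotated
peptidome), target-decoy FDR estimation with q-values, the two-round
discovery/verification selection, post-hoc curation filters, and the
retention-time support filter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np

VALID_AA = set("ACDEFGHIKLMNPQRSTVWY")


# ---------------------------------------------------------------------------
# Digestion


@dataclass(frozen=True)
class Peptide:
    aa_sequence: str
    parents: frozenset
    n_missed_cleavages: int


def tryptic_digest(
    protein: str,
    max_missed: int = 2,
    min_len: int = 7,
    parent_id: Optional[str] = None,
) -> List[Peptide]:
    """Tryptic peptides of a protein: cleavage C-terminal to K/R except
    before P, allowing 0..max_missed missed cleavages, length >= min_len.
    """
    if not protein:
        raise ValueError("empty protein")
    bad = set(protein) - VALID_AA
    if bad:
        raise ValueError(f"invalid residues {sorted(bad)!r}")
    # Fragment boundaries: cut after K/R unless the next residue is P.
    cuts = [0]
    for i in range(len(protein) - 1):
        if protein[i] in "KR" and protein[i + 1] != "P":
            cuts.append(i + 1)
    cuts.append(len(protein))
    fragments = [protein[cuts[i] : cuts[i + 1]] for i in range(len(cuts) - 1)]
    parents = frozenset([parent_id]) if parent_id else frozenset()
    out: List[Peptide] = []
    for i in range(len(fragments)):
        for m in range(0, max_missed + 1):
            if i + m >= len(fragments):
                break
            pep = "".join(fragments[i : i + m + 1])
            if len(pep) >= min_len:
                out.append(Peptide(pep, parents, m))
    return out


# ---------------------------------------------------------------------------
# Trie and minimum-distance screening


class TrieIndex:
    """Prefix tree over amino-acid strings supporting bounded minimum
    Hamming/Levenshtein distance queries.

    The polymorphism screen asks, for each novel peptide, how many
    substitutions (Hamming) or substitutions+indels (Levenshtein) separate it
    from the nearest peptide expected from the annotated proteome; a distance
    of 1–2 flags a peptide explainable by polymorphism rather than by a novel
    locus.
    """

    def __init__(self, peptides: Iterable[str] = ()) -> None:
        self._root: dict = {}
        self.size = 0
        for pep in peptides:
            self.insert(pep)

    def insert(self, peptide: str) -> None:
        node = self._root
        for ch in peptide:
            node = node.setdefault(ch, {})
        if "$" not in node:
            node["$"] = True
            self.size += 1

    def __contains__(self, peptide: str) -> bool:
        node = self._root
        for ch in peptide:
            if ch not in node:
                return False
            node = node[ch]
        return "$" in node

    def min_hamming(self, query: str, cap: int) -> Optional[int]:
        """Minimum Hamming distance to any same-length member, or None if it
        exceeds ``cap`` (Hamming is defined only between equal lengths)."""
        best: List[Optional[int]] = [None]

        def walk(node: dict, depth: int, dist: int) -> None:
            if dist > cap or (best[0] is not None and dist >= best[0]):
                return
            if depth == len(query):
                if "$" in node:
                    best[0] = dist if best[0] is None else min(best[0], dist)
                return
            for ch, child in node.items():
                if ch == "$":
                    continue
                walk(child, depth + 1, dist + (ch != query[depth]))

        walk(self._root, 0, 0)
        return best[0]

    def min_levenshtein(self, query: str, cap: int) -> Optional[int]:
        """Minimum edit distance (substitutions + indels) to any member, or
        None if it exceeds ``cap``; classic row-per-trie-node DP with band
        pruning."""
        best: List[Optional[int]] = [None]
        first_row = list(range(len(query) + 1))

        def walk(node: dict, row: List[int]) -> None:
            if best[0] is not None and min(row) >= best[0]:
                return
            if min(row) > cap:
                return
            if "$" in node:
                d = row[-1]
                if d <= cap and (best[0] is None or d < best[0]):
                    best[0] = d
            for ch, child in node.items():
                if ch == "$":
                    continue
                new = [row[0] + 1]
                for j in range(1, len(query) + 1):
                    new.append(
                        min(
                            new[j - 1] + 1,
                            row[j] + 1,
                            row[j - 1] + (query[j - 1] != ch),
                        )
                    )
                walk(child, new)

        walk(self._root, first_row)
        return best[0]


def build_trie(peptides: Iterable[str]) -> TrieIndex:
    return TrieIndex(peptides)


def min_distance(
    query: str, index: TrieIndex, metric: str = "levenshtein", cap: int = 2
) -> Optional[int]:
    """Minimum distance from ``query`` to any indexed peptide, or None when
    it exceeds ``cap``."""
    if cap < 0:
        raise ValueError("cap must be >= 0")
    if metric == "hamming":
        return index.min_hamming(query, cap)
    if metric == "levenshtein":
        return index.min_levenshtein(query, cap)
    raise ValueError(f"unknown metric {metric!r}")


# ---------------------------------------------------------------------------
# Target-decoy FDR


@dataclass(frozen=True)
class Psm:
    """A scored peptide-spectrum match (higher score = better)."""

    peptide: str
    score: float
    is_decoy: bool
    run_id: str = ""
    observed_rt: Optional[float] = None
    predicted_rt: Optional[float] = None
    parent_group: str = ""

    def __post_init__(self) -> None:
        if not math.isfinite(self.score):
            raise ValueError("PSM score must be finite")


@dataclass
class FdrResult:
    """Per-PSM q-values (input order), the accepted target indices at level
    alpha, and the chosen score cutoff."""

    q_values: np.ndarray
    accepted: List[int]
    cutoff: float
    alpha: float


def estimate_fdr(psms: Sequence[Psm], alpha: float = 0.01) -> FdrResult:
    """Target-decoy FDR with q-values.

    FDR(s) = #decoys with score >= s over #targets with score >= s; ties at a
    cutoff count decoys first (conservative). The q-value of a PSM is the
    running minimum of FDR from the worst score upward, clipped to [0, 1].
    """
    psms = list(psms)
    if not any(not p.is_decoy for p in psms):
        raise ValueError("no target PSMs")
    # Sort best-first; at score ties decoys come first so they are counted
    # at or above every tied target.
    order = sorted(range(len(psms)), key=lambda i: (-psms[i].score, not psms[i].is_decoy))
    n = len(psms)
    fdr = np.empty(n)
    d = t = 0
    for rank, i in enumerate(order):
        if psms[i].is_decoy:
            d += 1
        else:
            t += 1
        fdr[rank] = d / t if t else np.inf
    q_sorted = np.minimum.accumulate(fdr[::-1])[::-1]
    q_sorted = np.clip(q_sorted, 0.0, 1.0)
    q = np.empty(n)
    for rank, i in enumerate(order):
        q[i] = q_sorted[rank]
    accepted = [i for i in range(n) if not psms[i].is_decoy and q[i] <= alpha]
    cutoff = min((psms[i].score for i in accepted), default=np.inf)
    return FdrResult(q_values=q, accepted=accepted, cutoff=cutoff, alpha=alpha)


def _group_level_accept(
    psms: Sequence[Psm], alpha: float, restrict_to: Optional[Set[str]] = None
) -> Set[str]:
    """Group-level FDR on best-PSM-per-group scores; returns accepted target
    group ids."""
    best: Dict[Tuple[str, bool], Psm] = {}
    for p in psms:
        key = (p.parent_group, p.is_decoy)
        if key not in best or p.score > best[key].score:
            best[key] = p
    group_psms = list(best.values())
    res = estimate_fdr(group_psms, alpha=alpha)
    accepted = {group_psms[i].parent_group for i in res.accepted}
    if restrict_to is not None:
        accepted &= restrict_to
    return accepted


def two_round_select(
    round1: Sequence[Psm],
    full_db_ids: Set[str],
    round2: Sequence[Psm],
    fdr1: float = 0.2,
    fdr2: float = 0.01,
    annotated_ids: Optional[Set[str]] = None,
) -> Set[str]:
    """Two-round discovery/verification selection.

    Round 1 ("discovery") is scored against the full potential-ORF database at
    a permissive FDR (default 0.2) at both the peptide and the protein-group
    level; surviving candidate groups define a reduced search set. Round 2
    ("verification") re-scores against survivors plus the annotated proteome
    at a strict FDR (default 0.01), again at both levels. The returned set
    contains the verified unannotated candidate ids.
    """
    if not 0 < fdr2 <= fdr1 <= 1:
        raise ValueError("require 0 < fdr2 <= fdr1 <= 1")
    annotated = annotated_ids or set()
    unknown = {p.parent_group for p in round1 if not p.is_decoy} - full_db_ids - annotated
    if unknown:
        raise ValueError(f"round-1 PSMs reference ids outside the database: {sorted(unknown)[:3]}")

    pep_res1 = estimate_fdr(round1, alpha=fdr1)
    pep_ok1 = {round1[i].parent_group for i in pep_res1.accepted}
    grp_ok1 = _group_level_accept(round1, fdr1)
    survivors = (pep_ok1 & grp_ok1) - annotated

    bad = {
        p.parent_group
        for p in round2
        if not p.is_decoy and p.parent_group not in survivors and p.parent_group not in annotated
    }
    if bad:
        raise ValueError(
            f"round-2 PSMs reference non-survivor candidates: {sorted(bad)[:3]}"
        )
    if not survivors or not any(not p.is_decoy for p in round2):
        return set()

    # Verification FDR is computed jointly with annotated proteins by default
    # (the annotated hits stabilize the score-to-FDR mapping).
    pep_res2 = estimate_fdr(round2, alpha=fdr2)
    pep_ok2 = {round2[i].parent_group for i in pep_res2.accepted}
    grp_ok2 = _group_level_accept(round2, fdr2)
    return (pep_ok2 & grp_ok2) - annotated


# ---------------------------------------------------------------------------
# Curation and retention-time support


@dataclass(frozen=True)
class Candidate:
    id: str
    length_aa: int
    homology_flag: bool
    protein_group: str


def curate(candidates: Iterable[Candidate], min_length: int = 14) -> Set[str]:
    """Post-verification curation: drop candidates shorter than ``min_length``
    residues, drop candidates flagged as homologous to annotated proteins,
    and within each protein group keep only the longest survivor (ties break
    to the lexicographically smallest id)."""
    survivors = [
        c for c in candidates if c.length_aa >= min_length and not c.homology_flag
    ]
    by_group: Dict[str, Candidate] = {}
    for c in survivors:
        cur = by_group.get(c.protein_group)
        if cur is None or (c.length_aa, cur.id) > (cur.length_aa, c.id):
            by_group[c.protein_group] = c
    return {c.id for c in by_group.values()}


def rt_support(
    annotated_psms: Sequence[Psm],
    utorf_psms: Sequence[Psm],
    percentile: float = 95.0,
) -> Set[str]:
    """Retention-time support filter.

    The threshold is the 95th percentile (linear interpolation between order
    statistics) of |observed - predicted| retention time over all PSMs of
    annotated proteins; a candidate peptide is supported if any of its PSMs
    has a delta at or below that threshold.
    """
    deltas = [
        abs(p.observed_rt - p.predicted_rt)
        for p in annotated_psms
        if p.observed_rt is not None and p.predicted_rt is not None
    ]
    if not deltas:
        raise ValueError("no annotated PSMs with observed and predicted RTs")
    threshold = float(np.percentile(deltas, percentile))
    supported: Set[str] = set()
    for p in utorf_psms:
        if p.observed_rt is None or p.predicted_rt is None:
            continue
        if abs(p.observed_rt - p.predicted_rt) <= threshold:
            supported.add(p.peptide)
    return supported
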