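"""Shared fixtures and independent oracle implementations.

Oracles here deliberately use naive algorithms (brute-force enumeration,
recursive search, direct formula evaluation) so that agreement with the
library is informative.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction
from functools import lru_cache
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pytest

from utorf.alignment import blosum62_matrix, ALPHABET

# ---------------------------------------------------------------------------
# Fixtures


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


EIGHT_LEAF_NEWICK = (
    "(((a:1,b:1):1,(c:1,d:1):1):1,((e:1,f:1):1,(g:1,h:1):1):1);"
)


@pytest.fixture
def eight_leaf_tree():
    from utorf.phylo import SpeciesTree

    return SpeciesTree.from_newick(EIGHT_LEAF_NEWICK, "a")


# ---------------------------------------------------------------------------
# Alignment oracle: exhaustive monotone pairing


def _pair_score(a: str, b: str) -> float:
    S = blosum62_matrix()
    return float(S[ALPHABET.index(a), ALPHABET.index(b)])


def pairing_oracle(a: str, b: str) -> float:
    """Best total substitution score over all monotone residue pairings
    (equivalently a zero-gap-penalty local alignment), by plain recursion."""

    @lru_cache(maxsize=None)
    def rec(i: int, j: int) -> float:
        if i == len(a) or j == len(b):
            return 0.0
        return max(
            rec(i + 1, j),
            rec(i, j + 1),
            _pair_score(a[i], b[j]) + rec(i + 1, j + 1),
        )

    return max(rec(0, 0), 0.0)


# ---------------------------------------------------------------------------
# ORF enumeration oracle: independent six-frame scan


def orf_scan_oracle(seq: str, min_len: int = 8, min_len_no_start: int = 20):
    """Set of (aa, start, end, strand, frame) tuples via a direct scan."""
    from utorf.orf_catalog import CODON_TABLE, STOP_CODONS, reverse_complement

    found = set()
    n = len(seq)
    for strand in "+-":
        s = seq if strand == "+" else reverse_complement(seq)
        for off in range(3):
            frame = off + 1 if strand == "+" else -(off + 1)
            i = off
            span: List[Tuple[int, str]] = []
            while i + 3 <= n:
                codon = s[i : i + 3]
                ok = all(c in "ACGT" for c in codon) and codon not in STOP_CODONS
                if ok:
                    span.append((i, codon))
                if not ok or i + 6 > n:
                    if span:
                        aa = "".join(CODON_TABLE[c] for _, c in span)
                        has_atg = any(c == "ATG" for _, c in span)
                        keep = len(aa) >= min_len and (
                            has_atg or len(aa) >= min_len_no_start
                        )
                        if keep:
                            lo, hi = span[0][0], span[-1][0] + 3
                            if strand == "-":
                                lo, hi = n - hi, n - lo
                            found.add((aa, lo, hi, strand, frame))
                    span = []
                i += 3
    return found


# ---------------------------------------------------------------------------
# Digestion oracle: enumerate runs of fragments


def digest_oracle(protein: str, max_missed: int, min_len: int) -> Set[Tuple[str, int]]:
    sites = [
        i + 1
        for i in range(len(protein) - 1)
        if protein[i] in "KR" and protein[i + 1] != "P"
    ]
    bounds = [0] + sites + [len(protein)]
    out = set()
    for i in range(len(bounds) - 1):
        for j in range(i + 1, len(bounds)):
            missed = j - i - 1
            if missed > max_missed:
                break
            pep = protein[bounds[i] : bounds[j]]
            if len(pep) >= min_len:
                out.add((pep, missed))
    return out


# ---------------------------------------------------------------------------
# Edit-distance oracles: full DP per member


def levenshtein_dp(a: str, b: str) -> int:
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(cur[-1] + 1, prev[j] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def min_distance_oracle(
    query: str, members: Sequence[str], metric: str, cap: int
) -> Optional[int]:
    best = None
    for m in members:
        if metric == "hamming":
            if len(m) != len(query):
                continue
            d = sum(x != y for x, y in zip(m, query))
        else:
            d = levenshtein_dp(query, m)
        if best is None or d < best:
            best = d
    return best if best is not None and best <= cap else None


# ---------------------------------------------------------------------------
# FDR sweep oracle


def fdr_sweep_oracle(scores_t: Sequence[float], scores_d: Sequence[float]):
    """FDR at every distinct score threshold, decoys counted first at ties;
    returns dict threshold -> fdr, where fdr = #decoys>=s / #targets>=s."""
    out = {}
    for s in sorted(set(scores_t) | set(scores_d)):
        d = sum(x >= s for x in scores_d)
        t = sum(x >= s for x in scores_t)
        out[s] = d / t if t else math.inf
    return out


# ---------------------------------------------------------------------------
# Loss-count oracle: exhaustive subtree cover


def all_subtree_leafsets(node) -> List[frozenset]:
    """Leaf sets of every subtree (node plus all descendants' subtrees)."""
    if node.is_leaf():
        return [frozenset({node.label})]
    out = [frozenset(node.leaf_labels())]
    for c in node.children:
        out.extend(all_subtree_leafsets(c))
    return out


def loss_cover_oracle(
    origin, lost: Set[str], data_bearing: Set[str]
) -> int:
    """Minimum number of subtrees of ``origin`` covering all lost leaves such
    that each chosen subtree contains no data-bearing non-lost leaf, by
    exhaustive search over subtree combinations."""
    if not lost:
        return 0
    candidates = [
        ls
        for ls in set(all_subtree_leafsets(origin))
        if not (ls & data_bearing - lost)
    ]
    for k in range(1, len(candidates) + 1):
        for combo in itertools.combinations(candidates, k):
            covered = set().union(*combo)
            if lost <= covered:
                return k
    raise AssertionError("lost leaves not coverable")


def random_tree_newick(rng: np.random.Generator, labels: List[str]) -> str:
    """Random rooted binary tree over the given leaf labels."""

    def build(labs: List[str]) -> str:
        if len(labs) == 1:
            return f"{labs[0]}:1"
        k = int(rng.integers(1, len(labs)))
        return f"({build(labs[:k])},{build(labs[k:])}):1"

    labs = list(labels)
    rng.shuffle(labs)
    return build(labs) + ";"


# ---------------------------------------------------------------------------
# Exact framing tail


def binom_tail_exact(n0: int, n: int) -> Fraction:
    """P(X >= n0) for X ~ Binomial(n, 1/3), exact rational arithmetic."""
    total = Fraction(0)
    for k in range(n0, n + 1):
        total += (
            math.comb(n, k) * Fraction(1, 3) ** k * Fraction(2, 3) ** (n - k)
        )
    return total
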