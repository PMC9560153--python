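"""Phylostratigraphy, de novo origin calls, and loss counting.

A locus's age is the last common ancestor of the reference species and the
most distantly related species with a significant protein similarity score
(score > threshold). A de novo origin is called when outgroup species —
species outside the origin clade — retain genomic homology at the syntenic
position but score below the protein threshold; requiring at least two such
outgroups from distinct first-branching outgroup lineages guards against a
single homology-detection failure. Losses after origin are counted by
Dollo-style parsimony (one birth, any number of losses): the minimum number
of subtrees whose data-bearing leaves are all "lost" that covers every lost
leaf. Missing alignment data is always "unknown" and never forces an event.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import dendropy
import numpy as np
from scipy import stats

from .synteny import SimilarityScore

DEFAULT_THRESHOLD = 2.5


class Node:
    """Light rooted-tree node (built from a dendropy parse)."""

    __slots__ = ("label", "children", "parent")

    def __init__(self, label: Optional[str] = None):
        self.label = label
        self.children: List["Node"] = []
        self.parent: Optional["Node"] = None

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> List["Node"]:
        if self.is_leaf():
            return [self]
        out: List[Node] = []
        stack = [self]
        while stack:
            n = stack.pop()
            if n.is_leaf():
                out.append(n)
            else:
                stack.extend(n.children)
        return out

    def leaf_labels(self) -> Set[str]:
        return {n.label for n in self.leaves()}


class SpeciesTree:
    """Rooted species tree with a designated reference leaf.

    ``strata`` are the ancestors of the reference leaf ordered leaf-to-root;
    stratum index 0 is the reference-specific stratum (the leaf itself),
    larger indices are older.
    """

    def __init__(self, root: Node, reference_leaf: str):
        self.root = root
        self.leaf_by_label: Dict[str, Node] = {}
        for leaf in root.leaves():
            if leaf.label in self.leaf_by_label:
                raise ValueError(f"duplicate leaf label {leaf.label!r}")
            self.leaf_by_label[leaf.label] = leaf
        if reference_leaf not in self.leaf_by_label:
            raise ValueError(f"reference leaf {reference_leaf!r} not in tree")
        self.reference_leaf = reference_leaf
        self.strata: List[Node] = []
        n: Optional[Node] = self.leaf_by_label[reference_leaf]
        while n is not None:
            self.strata.append(n)
            n = n.parent

    @classmethod
    def from_newick(cls, newick: str, reference_leaf: str) -> "SpeciesTree":
        try:
            dtree = dendropy.Tree.get(data=newick, schema="newick")
        except Exception as e:  # dendropy raises several parse error types
            raise ValueError(f"invalid newick: {e}") from e

        def convert(dnode) -> Node:
            node = Node(label=dnode.taxon.label if dnode.taxon else None)
            for child in dnode.child_nodes():
                c = convert(child)
                c.parent = node
                node.children.append(c)
            return node

        return cls(convert(dtree.seed_node), reference_leaf)

    @property
    def leaf_labels(self) -> Set[str]:
        return set(self.leaf_by_label)

    def _ancestors(self, node: Node) -> List[Node]:
        out = []
        n: Optional[Node] = node
        while n is not None:
            out.append(n)
            n = n.parent
        return out

    def mrca(self, labels: Iterable[str]) -> Node:
        labels = list(labels)
        if not labels:
            raise ValueError("mrca of empty set")
        paths = []
        for lab in labels:
            if lab not in self.leaf_by_label:
                raise ValueError(f"unknown leaf {lab!r}")
            paths.append(self._ancestors(self.leaf_by_label[lab]))
        common = set(id(n) for n in paths[0])
        for p in paths[1:]:
            common &= {id(n) for n in p}
        # deepest (closest to leaves) common ancestor = first on any path
        for n in paths[0]:
            if id(n) in common:
                return n
        raise RuntimeError("disconnected tree")

    def stratum_index(self, node: Node) -> int:
        for i, s in enumerate(self.strata):
            if s is node:
                return i
        raise ValueError("node is not an ancestor of the reference leaf")


@dataclass(frozen=True)
class OrthologyProfile:
    """Per-species similarity outcome for one locus.

    ``scores`` maps species to points-per-residue scores; species absent from
    the map have missing data. ``homology`` maps species to the genomic
    homology flag (syntenic alignment coverage above the configured minimum).
    """

    scores: Mapping[str, float]
    homology: Mapping[str, bool]

    @classmethod
    def from_similarity(
        cls, scores: Mapping[str, SimilarityScore], reference: str,
        reference_score: float,
    ) -> "OrthologyProfile":
        sc = {sp: s.score for sp, s in scores.items()}
        hm = {sp: s.homology_flag for sp, s in scores.items()}
        sc[reference] = reference_score
        hm[reference] = True
        return cls(sc, hm)


@dataclass(frozen=True)
class AgeCall:
    most_distant_significant: Optional[str]
    origin_stratum: int  # index into tree.strata, 0 = reference-specific
    monophyletic: bool


@dataclass(frozen=True)
class DeNovoCall:
    is_de_novo: bool
    supporting_outgroups: Tuple[str, ...]
    n_supporting: int
    n_distinct_clades: int


@dataclass(frozen=True)
class LossCount:
    n_losses: int
    lost_leaf_sets: Tuple[FrozenSet[str], ...]


def significant_species(
    profile: OrthologyProfile, threshold: float = DEFAULT_THRESHOLD
) -> Set[str]:
    """Species with a similarity score strictly above the threshold."""
    return {sp for sp, s in profile.scores.items() if s > threshold}


def infer_age(
    profile: OrthologyProfile,
    tree: SpeciesTree,
    threshold: float = DEFAULT_THRESHOLD,
) -> AgeCall:
    """Phylostratigraphic age: the LCA of the reference with all species
    carrying a significant score (equivalently with the most distant one;
    ties between equally distant species in different clades resolve to
    their joint LCA)."""
    if not profile.scores:
        raise ValueError("profile carries no scores")
    if tree.reference_leaf not in profile.scores:
        raise ValueError("reference species score missing")
    sig = significant_species(profile, threshold) & tree.leaf_labels
    sig.add(tree.reference_leaf)
    origin = tree.mrca(sig)
    stratum = tree.stratum_index(origin)
    most_distant = None
    if len(sig) > 1:
        best = -1
        for sp in sorted(sig - {tree.reference_leaf}):
            idx = tree.stratum_index(tree.mrca([tree.reference_leaf, sp]))
            if idx > best:
                best, most_distant = idx, sp
    data_bearing = set(profile.scores) & tree.leaf_labels
    mono = _is_monophyletic(sig, data_bearing, tree)
    return AgeCall(
        most_distant_significant=most_distant,
        origin_stratum=stratum,
        monophyletic=mono,
    )


def _is_monophyletic(
    significant: Set[str], data_bearing: Set[str], tree: SpeciesTree
) -> bool:
    mrca = tree.mrca(significant)
    subtree_data = mrca.leaf_labels() & data_bearing
    return subtree_data == (significant & data_bearing)


def is_monophyletic(
    significant_leaves: Set[str],
    tree: SpeciesTree,
    data_bearing: Optional[Set[str]] = None,
) -> bool:
    """True iff the significant leaves are exactly the data-bearing leaves of
    the subtree rooted at their LCA (leaves without data are ignored)."""
    if not significant_leaves:
        raise ValueError("empty significant set")
    if data_bearing is None:
        data_bearing = tree.leaf_labels
    return _is_monophyletic(set(significant_leaves), data_bearing, tree)


def _first_branching_lineage(
    tree: SpeciesTree, origin: Node, leaf_label: str
) -> int:
    """Identify the sibling subtree (off the reference path, above the origin
    node) that a given outgroup leaf belongs to; returns a stable integer id.

    Two outgroups support independent lineages iff they attach to the
    reference path through different sibling subtrees.
    """
    leaf = tree.leaf_by_label[leaf_label]
    # Walk up from origin to root; at each step the off-path children are the
    # first-branching outgroup lineages.
    path = []
    n: Optional[Node] = origin
    while n is not None:
        path.append(n)
        n = n.parent
    lineage_id = 0
    for depth in range(1, len(path)):
        parent = path[depth]
        on_path_child = path[depth - 1]
        for child in parent.children:
            if child is on_path_child:
                continue
            lineage_id += 1
            if leaf_label in child.leaf_labels():
                return lineage_id
    raise ValueError(f"{leaf_label!r} is not an outgroup of the origin clade")


def call_de_novo(
    profile: OrthologyProfile,
    age: AgeCall,
    tree: SpeciesTree,
    threshold: float = DEFAULT_THRESHOLD,
    min_outgroups: int = 2,
    min_clades: int = 2,
) -> DeNovoCall:
    """De novo origin call.

    Supporting outgroups are species outside the origin clade whose syntenic
    block retains genomic homology (homology flag true) but whose protein
    score is below the significance threshold. The call requires at least
    ``min_outgroups`` such species spanning at least ``min_clades`` distinct
    first-branching outgroup lineages.
    """
    origin = tree.strata[age.origin_stratum]
    inside = origin.leaf_labels()
    supporting = []
    for sp in sorted(set(profile.scores) & tree.leaf_labels):
        if sp in inside:
            continue
        if profile.homology.get(sp) and profile.scores[sp] < threshold:
            supporting.append(sp)
    clades = {_first_branching_lineage(tree, origin, sp) for sp in supporting}
    return DeNovoCall(
        is_de_novo=len(supporting) >= min_outgroups and len(clades) >= min_clades,
        supporting_outgroups=tuple(supporting),
        n_supporting=len(supporting),
        n_distinct_clades=len(clades),
    )


def count_losses(
    profile: OrthologyProfile,
    origin_stratum: int,
    tree: SpeciesTree,
    threshold: float = DEFAULT_THRESHOLD,
) -> LossCount:
    """Dollo-style loss count after origin.

    Among leaves descending from the origin node (excluding the reference),
    a leaf is "lost" if it has genomic homology but a sub-threshold score;
    leaves with missing data are unknown and never force an event. The count
    is the number of maximal subtrees whose data-bearing leaves are all lost,
    which equals the minimum subtree cover of the lost leaves.
    """
    if origin_stratum < 0 or origin_stratum >= len(tree.strata):
        raise ValueError("origin stratum is not an ancestor of the reference")
    origin = tree.strata[origin_stratum]
    lost: Set[str] = set()
    data_bearing: Set[str] = {tree.reference_leaf}
    for sp in origin.leaf_labels():
        if sp == tree.reference_leaf or sp not in profile.scores:
            continue
        data_bearing.add(sp)
        if profile.homology.get(sp) and profile.scores[sp] < threshold:
            lost.add(sp)

    sets: List[FrozenSet[str]] = []

    def walk(node: Node) -> Tuple[bool, Set[str]]:
        """Returns (all data-bearing leaves under node are lost, lost leaves
        under node); emits maximal all-lost subtrees."""
        if node.is_leaf():
            if node.label in lost:
                return True, {node.label}
            if node.label in data_bearing:
                return False, set()
            return True, set()  # unknown leaves never block an all-lost subtree
        child_results = [walk(c) for c in node.children]
        all_lost = all(r[0] for r in child_results)
        lost_here = set().union(*(r[1] for r in child_results))
        if not all_lost:
            # emit children that were maximal all-lost subtrees
            for (ok, leaves), child in zip(child_results, node.children):
                if ok and leaves:
                    sets.append(frozenset(leaves))
        return all_lost, lost_here

    ok, leaves = walk(origin)
    if ok and leaves:
        sets.append(frozenset(leaves))
    return LossCount(n_losses=len(sets), lost_leaf_sets=tuple(sorted(sets, key=sorted)))


# ---------------------------------------------------------------------------
# Length-matched empirical null and Fisher combination


def empirical_percentile(
    value: float,
    controls: Sequence[float],
) -> float:
    """Midrank empirical percentile of ``value`` among its controls, floored
    at the add-one estimate 1/(n+1) so it is never zero."""
    arr = np.asarray(controls, dtype=float)
    n = arr.size
    if n == 0:
        raise ValueError("no controls")
    less = int((arr < value).sum())
    equal = int((arr == value).sum())
    p = (less + 0.5 * equal) / n
    return max(p, 1.0 / (n + 1))


def fisher_combined(p_values: Sequence[float]) -> Tuple[float, float]:
    """Fisher's method: statistic -2*sum(ln p) against chi-square with 2k
    degrees of freedom; returns (statistic, combined p)."""
    ps = np.asarray(p_values, dtype=float)
    if ps.size == 0:
        raise ValueError("no p-values to combine")
    stat = float(-2.0 * np.log(ps).sum())
    return stat, float(stats.chi2.sf(stat, 2 * ps.size))


def empirical_percentile_fisher(
    values: Mapping[str, float],
    lengths: Mapping[str, int],
    control_pool: Mapping[int, Sequence[float]],
    n_draws: int = 250,
    seed: int = 0,
    max_tolerance: int = 64,
) -> Dict[str, object]:
    """Per-locus empirical percentile against length-matched controls plus a
    Fisher combination.

    For each locus, ``n_draws`` control values are drawn without replacement
    from the pool entries whose length matches the locus; if a length bin is
    too small the tolerance widens geometrically (±1, ±2, ±4, ... up to
    ``max_tolerance``) before erroring.
    """
    rng = np.random.default_rng(seed)
    per_locus: Dict[str, float] = {}
    for locus in sorted(values):
        L = lengths[locus]
        tol = 0
        while True:
            pool = [
                v
                for length, vs in control_pool.items()
                if abs(length - L) <= tol
                for v in vs
            ]
            if len(pool) >= n_draws:
                break
            tol = 1 if tol == 0 else tol * 2
            if tol > max_tolerance:
                raise ValueError(
                    f"insufficient controls for locus {locus!r} (length {L})"
                )
        controls = rng.choice(np.asarray(pool), size=n_draws, replace=False)
        per_locus[locus] = empirical_percentile(values[locus], controls)
    stat, combined = fisher_combined(list(per_locus.values()))
    return {"per_locus_p": per_locus, "statistic": stat, "combined_p": combined}
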