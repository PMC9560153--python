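"""Synthetic-data generators with planted ground truth.

Every input the pipeline consumes can be generated here: MSA blocks evolved
along a species tree with planted de novo births and losses, PSM score
mixtures with known true/false labels, categorical tables from a known
latent-class model, expression matrices with planted specificity, and
ribosome-footprint frame counts with planted bias. All generators are
bit-reproducible under a fixed seed and emit their truth alongside the data;
downstream recovery tests consume only the data and compare only against the
truth.

The sequence simulator uses a uniform (Jukes–Cantor-like) substitution model
with geometric-length deletions; insertions are not simulated, so alignment
columns remain in root coordinates. De novo origin is planted by shuffling
the nucleotide order of the ORF region in every lineage outside the origin
clade (one shared ancestral permutation): this destroys the codon structure
and protein-level similarity while preserving composition and syntenic
alignability. Losses are planted on chosen branches as a frameshift
(single-base deletion) plus a shared nucleotide shuffle of the ORF.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Set, Tuple, Union

import dendropy
import numpy as np
import pandas as pd

from .expression import FrameCounts
from .intervals import GenomicInterval
from .orf_catalog import CODON_TABLE, STOP_CODONS
from .proteomics import Psm
from .synteny import MsaBlock

# A synthetic 27-leaf insect-like phylogeny (topology and branch lengths are
# invented stand-ins for a drosophilid tree with dipteran/holometabolan
# outgroups; they are not estimates).
DEFAULT_TREE_NEWICK = (
    "((((((((((dmel:0.02,(dsim:0.01,dsec:0.01):0.01):0.01,"
    "(dyak:0.02,dere:0.02):0.01):0.02,(dbia:0.03,dsuz:0.03):0.02):0.02,"
    "(dtak:0.04,(dele:0.03,drho:0.03):0.01):0.02):0.01,"
    "(deug:0.05,dkik:0.05):0.01):0.02,dfic:0.07):0.01,"
    "(dana:0.05,dbip:0.05):0.03):0.03,"
    "((dpse:0.01,dper:0.01):0.01,dmir:0.02):0.08):0.02,"
    "(dwil:0.12,((dvir:0.06,dmoj:0.06):0.02,(dalb:0.07,dgri:0.07):0.01):0.04):0.02):0.15,"
    "(mdom:0.35,(agam:0.45,(amel:0.5,tcas:0.55):0.05):0.05):0.05);"
)
DEFAULT_REFERENCE = "dmel"

# Melanogaster-subgroup clade used as the default planted origin of de novo
# loci (dmel + sister species through dere).
DEFAULT_ORIGIN_CLADE = frozenset({"dmel", "dsim", "dsec", "dyak", "dere"})

NON_STOP_CODONS = sorted(set(CODON_TABLE) - STOP_CODONS)
BASES = "ACGT"


# ---------------------------------------------------------------------------
# Config and truth containers


@dataclass(frozen=True)
class Scenario:
    """Per-locus evolutionary scenario.

    kind: "conserved" | "denovo" | "loss".
    origin_clade: leaf set of the clade in which the ORF is genic (denovo).
    loss_clades: leaf sets of subtrees whose parent branch carries a loss.
    """

    kind: str
    origin_clade: Optional[FrozenSet[str]] = None
    loss_clades: Tuple[FrozenSet[str], ...] = ()


@dataclass
class SimConfig:
    """Study conditions for the synthetic inputs."""

    seed: int = 0
    tree_newick: str = DEFAULT_TREE_NEWICK
    reference: str = DEFAULT_REFERENCE
    substitution_rate: float = 0.15  # expected subs/site per unit branch length
    deletion_rate: float = 0.01  # expected deletion events/site per unit length
    deletion_geom_p: float = 0.4  # geometric length parameter
    n_loci: int = 30
    orf_length_range: Tuple[int, int] = (25, 60)
    flank_nt: int = 30
    scenario_mix: Tuple[float, float, float] = (0.4, 0.4, 0.2)  # conserved/denovo/loss
    # PSM mixture
    n_true_targets: int = 300
    n_false_targets: int = 300
    n_decoys: int = 600
    true_score_mean: float = 4.0
    null_score_mean: float = 0.0
    score_sd: float = 1.0
    # latent classes
    lca_K: int = 3
    lca_pi: Tuple[float, ...] = (0.5, 0.3, 0.2)
    lca_concentration: float = 0.8  # probability mass on the class's own level
    lca_levels: Tuple[int, ...] = (3, 2, 3, 2)
    lca_n: int = 2000
    # expression
    tissues: Tuple[str, ...] = ("brain", "testis", "ovary", "gut", "muscle", "embryo")
    expression_scale: float = 20.0
    # footprints
    footprint_frame_prob: float = 1.0 / 3.0
    footprint_mean_count: float = 8.0


@dataclass
class LocusTruth:
    locus_id: str
    scenario: Scenario
    orf_aa: str
    orf_interval: GenomicInterval
    is_de_novo: bool
    n_losses: int


# ---------------------------------------------------------------------------
# Tree with branch lengths (simulation-side)


class _SimNode:
    __slots__ = ("label", "length", "children")

    def __init__(self, label: Optional[str], length: float):
        self.label = label
        self.length = length
        self.children: List["_SimNode"] = []

    def leaf_labels(self) -> Set[str]:
        if not self.children:
            return {self.label}
        out: Set[str] = set()
        for c in self.children:
            out |= c.leaf_labels()
        return out


def _parse_tree(newick: str) -> _SimNode:
    try:
        dtree = dendropy.Tree.get(data=newick, schema="newick")
    except Exception as e:
        raise ValueError(f"invalid newick: {e}") from e

    def convert(dnode) -> _SimNode:
        node = _SimNode(
            label=dnode.taxon.label.replace(" ", "_") if dnode.taxon else None,
            length=dnode.edge.length or 0.0,
        )
        for child in dnode.child_nodes():
            node.children.append(convert(child))
        return node

    return convert(dtree.seed_node)


# ---------------------------------------------------------------------------
# MSA locus simulation


_CODONS_BY_AA: Dict[str, List[str]] = {}
for _codon, _aa in CODON_TABLE.items():
    if _aa != "*":
        _CODONS_BY_AA.setdefault(_aa, []).append(_codon)


def _random_orf_nt(rng: np.random.Generator, length_aa: int) -> str:
    """ATG followed by codons for residues drawn from the proteome-like
    composition (random synonymous codon per residue)."""
    from .synteny import PROTEOME_AA_FREQUENCIES

    letters = sorted(PROTEOME_AA_FREQUENCIES)
    probs = np.array([PROTEOME_AA_FREQUENCIES[a] for a in letters])
    probs /= probs.sum()
    codons = ["ATG"]
    for a in rng.choice(letters, size=length_aa - 1, p=probs):
        syn = _CODONS_BY_AA[a]
        codons.append(syn[rng.integers(0, len(syn))])
    return "".join(codons)


def _random_nt(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=n))


def _translate(nt: str) -> str:
    return "".join(
        CODON_TABLE[nt[i : i + 3]] for i in range(0, len(nt) - len(nt) % 3, 3)
    )


def _evolve_branch(
    seq: np.ndarray,
    length: float,
    rng: np.random.Generator,
    cfg: SimConfig,
    protected: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Apply substitutions and geometric-length deletions to an aligned
    sequence (root-coordinate array of single characters, '-' = deleted).
    ``protected`` positions are exempt (reference-lineage ORF columns)."""
    out = seq.copy()
    alive = out != "-"
    editable = alive if protected is None else (alive & ~protected)
    idx = np.flatnonzero(editable)
    if idx.size == 0 or length <= 0:
        return out
    p_sub = 1.0 - np.exp(-cfg.substitution_rate * length)
    hit = idx[rng.random(idx.size) < p_sub]
    for i in hit:
        choices = [b for b in BASES if b != out[i]]
        out[i] = choices[rng.integers(0, 3)]
    n_del = rng.poisson(cfg.deletion_rate * length * idx.size)
    for _ in range(n_del):
        start = int(rng.choice(idx))
        span = int(rng.geometric(cfg.deletion_geom_p))
        stop = min(start + span, len(out))
        sl = np.arange(start, stop)
        mask = editable[sl]
        out[sl[mask]] = "-"
    return out


def _shuffle_columns(
    seq: np.ndarray,
    cols: np.ndarray,
    perm: np.ndarray,
) -> np.ndarray:
    """Permute individual ORF columns (root coordinates), moving whatever
    characters (including gaps) occupy them. A nucleotide-level shuffle
    destroys both the codon structure and the protein-level similarity while
    preserving composition and syntenic alignability."""
    out = seq.copy()
    out[cols] = seq[cols[perm]]
    return out


def simulate_msa_loci(
    config: SimConfig,
) -> Tuple[List[MsaBlock], "object", List[LocusTruth]]:
    """Simulate per-locus MSA blocks with planted conserved / de novo / lost
    ORFs; returns (blocks, SpeciesTree, truth per locus)."""
    from .phylo import SpeciesTree

    root_node = _parse_tree(config.tree_newick)
    species_tree = SpeciesTree.from_newick(config.tree_newick, config.reference)
    rng = np.random.default_rng(config.seed)
    leaves = sorted(root_node.leaf_labels())
    if config.reference not in leaves:
        raise ValueError("reference species missing from the tree")

    kinds = ["conserved", "denovo", "loss"]
    probs = np.asarray(config.scenario_mix, dtype=float)
    probs = probs / probs.sum()

    # Default loss clades: a few mid-depth drosophilid subtrees (fall back to
    # single leaves on small custom trees).
    candidate_losses: List[FrozenSet[str]] = []
    for cand in ({"dyak", "dere"}, {"dpse", "dper", "dmir"}, {"dvir", "dmoj"}):
        if cand <= set(leaves):
            candidate_losses.append(frozenset(cand))
    if not candidate_losses:
        candidate_losses = [
            frozenset({l}) for l in leaves if l != config.reference
        ][:3]
    origin_clade = (
        DEFAULT_ORIGIN_CLADE
        if DEFAULT_ORIGIN_CLADE <= set(leaves)
        else frozenset({config.reference})
    )

    blocks: List[MsaBlock] = []
    truths: List[LocusTruth] = []
    for locus_idx in range(config.n_loci):
        kind = kinds[rng.choice(3, p=probs)]
        if kind == "denovo":
            scenario = Scenario("denovo", origin_clade=origin_clade)
        elif kind == "loss":
            n = int(rng.integers(1, len(candidate_losses) + 1))
            picked = rng.choice(len(candidate_losses), size=n, replace=False)
            scenario = Scenario(
                "loss",
                loss_clades=tuple(candidate_losses[i] for i in sorted(picked)),
            )
        else:
            scenario = Scenario("conserved")
        block, truth = _simulate_locus(
            locus_idx, scenario, root_node, config, rng
        )
        blocks.append(block)
        truths.append(truth)
    return blocks, species_tree, truths


def _simulate_locus(
    locus_idx: int,
    scenario: Scenario,
    root_node: _SimNode,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> Tuple[MsaBlock, LocusTruth]:
    L = int(rng.integers(cfg.orf_length_range[0], cfg.orf_length_range[1] + 1))
    orf_nt = _random_orf_nt(rng, L)
    root_seq = _random_nt(rng, cfg.flank_nt) + orf_nt + _random_nt(rng, cfg.flank_nt)
    n = len(root_seq)
    orf_cols = np.arange(cfg.flank_nt, cfg.flank_nt + 3 * L)

    # Protect the ORF on the path root -> reference so the reference keeps an
    # intact ORF (the utORF is observed translated in the reference).
    protected = np.zeros(n, dtype=bool)
    protected[orf_cols] = True

    ref_path_nodes: Set[int] = set()

    def mark_path(node: _SimNode) -> bool:
        if not node.children:
            on = node.label == cfg.reference
        else:
            on = any(mark_path(c) for c in node.children)
        if on:
            ref_path_nodes.add(id(node))
        return on

    mark_path(root_node)

    rows: Dict[str, np.ndarray] = {}

    def descend(node: _SimNode, seq: np.ndarray) -> None:
        for child in node.children:
            prot = protected if id(child) in ref_path_nodes else None
            child_seq = _evolve_branch(seq, child.length, rng, cfg, protected=prot)
            if child.children:
                descend(child, child_seq)
            else:
                rows[child.label] = child_seq

    root_arr = np.array(list(root_seq))
    if root_node.children:
        descend(root_node, root_arr)
    else:
        rows[root_node.label] = root_arr

    # Plant the scenario.
    is_de_novo = False
    n_losses = 0
    if scenario.kind == "denovo":
        assert scenario.origin_clade is not None
        # one shared ancestral nucleotide shuffle of the ORF region outside
        # the origin clade
        perm = rng.permutation(orf_cols.size)
        for sp in rows:
            if sp not in scenario.origin_clade:
                rows[sp] = _shuffle_columns(rows[sp], orf_cols, perm)
        is_de_novo = True
    elif scenario.kind == "loss":
        for clade in scenario.loss_clades:
            # shared ancestral disruption of the lost subtree: a frameshifting
            # single-base deletion plus a nucleotide shuffle of the ORF
            perm = rng.permutation(orf_cols.size)
            shift_col = int(orf_cols[3 * (L // 2)])
            for sp in clade:
                if sp not in rows:
                    continue
                seq = _shuffle_columns(rows[sp], orf_cols, perm)
                seq[shift_col] = "-"
                rows[sp] = seq
            n_losses += 1

    contig = f"locus_{locus_idx}"
    ref_row = "".join(rows[cfg.reference])
    ref_len = sum(c != "-" for c in ref_row)
    rows_str = {sp: "".join(arr) for sp, arr in rows.items()}
    block = MsaBlock(
        reference_interval=GenomicInterval(contig, 0, ref_len, "+"),
        rows=rows_str,
        reference_species=cfg.reference,
    )
    # Reference coordinates of the ORF: count reference non-gap positions
    # before/within the ORF columns.
    ref_arr = rows[cfg.reference]
    nongap_before = int((ref_arr[: orf_cols[0]] != "-").sum())
    orf_interval = GenomicInterval(contig, nongap_before, nongap_before + 3 * L, "+")
    truth = LocusTruth(
        locus_id=contig,
        scenario=scenario,
        orf_aa=_translate(orf_nt),
        orf_interval=orf_interval,
        is_de_novo=is_de_novo,
        n_losses=n_losses,
    )
    return block, truth


# ---------------------------------------------------------------------------
# PSM mixtures


def simulate_psm_table(
    config: SimConfig, seed: Optional[int] = None
) -> Tuple[List[Psm], np.ndarray]:
    """Scored target/decoy PSMs with known truth.

    True-target scores come from the shifted distribution, false-target and
    decoy scores from the null. Returns (psms, is_true_label per psm; decoys
    are always False).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    psms: List[Psm] = []
    labels: List[bool] = []
    for i in range(config.n_true_targets):
        score = rng.normal(config.true_score_mean, config.score_sd)
        psms.append(Psm(f"TRUEPEP{i}", float(score), False, parent_group=f"true_{i}"))
        labels.append(True)
    for i in range(config.n_false_targets):
        score = rng.normal(config.null_score_mean, config.score_sd)
        psms.append(Psm(f"FALSEPEP{i}", float(score), False, parent_group=f"false_{i}"))
        labels.append(False)
    for i in range(config.n_decoys):
        score = rng.normal(config.null_score_mean, config.score_sd)
        psms.append(Psm(f"DECOYPEP{i}", float(score), True, parent_group=f"decoy_{i}"))
        labels.append(False)
    return psms, np.asarray(labels)


def simulate_two_round_tables(
    config: SimConfig, seed: Optional[int] = None, n_candidates: int = 2000
) -> Dict[str, object]:
    """Inputs for the two-round selection with planted truth.

    The full database holds ``n_candidates`` candidate ids of which
    ``config.n_true_targets`` are genuinely translated. Round 1 scores one
    PSM per true candidate plus null PSMs for a random subset of false
    candidates (with matched decoys); round 2 rescores round-1 survivors
    (fresh draws) with matched decoys.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n_true = config.n_true_targets
    true_ids = {f"cand_{i}" for i in range(n_true)}
    full_db = {f"cand_{i}" for i in range(n_candidates)}
    round1: List[Psm] = []
    for cid in sorted(true_ids):
        round1.append(
            Psm(
                f"{cid}_pep",
                float(rng.normal(config.true_score_mean, config.score_sd)),
                False,
                parent_group=cid,
            )
        )
    false_sample = sorted(full_db - true_ids)[: config.n_false_targets]
    for cid in false_sample:
        round1.append(
            Psm(
                f"{cid}_pep",
                float(rng.normal(config.null_score_mean, config.score_sd)),
                False,
                parent_group=cid,
            )
        )
    for i in range(config.n_decoys):
        round1.append(
            Psm(
                f"decoy1_{i}",
                float(rng.normal(config.null_score_mean, config.score_sd)),
                True,
                parent_group=f"decoy1_{i}",
            )
        )

    from .proteomics import estimate_fdr, _group_level_accept

    pep1 = estimate_fdr(round1, alpha=0.2)
    surv_pep = {round1[i].parent_group for i in pep1.accepted}
    surv_grp = _group_level_accept(round1, 0.2)
    survivors = surv_pep & surv_grp

    round2: List[Psm] = []
    n_decoy2 = 0
    for cid in sorted(survivors):
        genuine = cid in true_ids
        mean = config.true_score_mean if genuine else config.null_score_mean
        round2.append(
            Psm(
                f"{cid}_pep",
                float(rng.normal(mean, config.score_sd)),
                False,
                parent_group=cid,
            )
        )
        n_decoy2 += 1
    for i in range(n_decoy2):
        round2.append(
            Psm(
                f"decoy2_{i}",
                float(rng.normal(config.null_score_mean, config.score_sd)),
                True,
                parent_group=f"decoy2_{i}",
            )
        )
    return {
        "round1": round1,
        "round2": round2,
        "full_db_ids": full_db,
        "true_ids": true_ids,
        "survivors": survivors,
    }


# ---------------------------------------------------------------------------
# Latent-class tables


def default_lca_rho(config: SimConfig) -> List[np.ndarray]:
    """Concentrated conditionals with maximally separated class patterns.

    Class k puts ``lca_concentration`` on its preferred level of each
    indicator, the rest uniform. Preferred levels are distinct across classes
    whenever the indicator has enough levels; indicators with fewer levels
    than classes necessarily merge some classes, and the merged pair is
    rotated across such indicators so that every pair of classes is separated
    by as many indicators as possible (a naive "k mod L" assignment can give
    two classes identical preferences on every small indicator, making them
    nearly unidentifiable).
    """
    K = config.lca_K
    rho = []
    n_small = 0
    for L in config.lca_levels:
        r = np.full((K, L), 0.0)
        for k in range(K):
            if L >= K:
                own = k
            else:
                own = min((k + n_small) % K, L - 1)
            r[k] = (1.0 - config.lca_concentration) / (L - 1) if L > 1 else 1.0
            r[k, own] = config.lca_concentration if L > 1 else 1.0
        if L < K:
            n_small += 1
        rho.append(r)
    return rho


def simulate_lca_table(
    config: SimConfig,
    seed: Optional[int] = None,
    n: Optional[int] = None,
    rho: Optional[List[np.ndarray]] = None,
) -> Tuple[pd.DataFrame, np.ndarray]:
    """Categorical table drawn class-then-levels independently; returns
    (table, true class labels)."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    pi = np.asarray(config.lca_pi, dtype=float)
    if len(pi) != config.lca_K or abs(pi.sum() - 1.0) > 1e-9:
        raise ValueError("lca_pi must be a length-K simplex vector")
    rho = default_lca_rho(config) if rho is None else rho
    n = config.lca_n if n is None else n
    classes = rng.choice(config.lca_K, size=n, p=pi)
    cols = {}
    for j, r in enumerate(rho):
        levels = np.empty(n, dtype=int)
        for k in range(config.lca_K):
            mask = classes == k
            levels[mask] = rng.choice(r.shape[1], size=int(mask.sum()), p=r[k])
        cols[f"ind{j}"] = levels
    return pd.DataFrame(cols), classes


# ---------------------------------------------------------------------------
# Expression and footprints


def simulate_expression(
    config: SimConfig,
    n_loci: int,
    seed: Optional[int] = None,
    profiles: Optional[Sequence[str]] = None,
) -> Tuple[pd.DataFrame, pd.Series, pd.Series]:
    """TPM matrix with planted specificity.

    Each locus is one of: "one_hot" (expression in a single random tissue,
    tau = 1), "uniform" (equal everywhere, tau = 0), or "noisy" (lognormal
    noise around a random profile). Returns (matrix, realized tau, profile
    kind per locus).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    tissues = list(config.tissues)
    kinds = (
        list(profiles)
        if profiles is not None
        else [["one_hot", "uniform", "noisy"][i % 3] for i in range(n_loci)]
    )
    from .expression import tau as tau_fn

    data = np.zeros((n_loci, len(tissues)))
    for i, kind in enumerate(kinds):
        if kind == "one_hot":
            data[i, rng.integers(0, len(tissues))] = config.expression_scale
        elif kind == "uniform":
            data[i, :] = config.expression_scale / 2.0
        elif kind == "noisy":
            base = rng.random(len(tissues)) * config.expression_scale
            data[i, :] = base * rng.lognormal(0.0, 0.25, size=len(tissues))
        else:
            raise ValueError(f"unknown profile kind {kind!r}")
    index = [f"locus_{i}" for i in range(n_loci)]
    matrix = pd.DataFrame(data, index=index, columns=tissues)
    realized = pd.Series(
        [tau_fn(data[i]) for i in range(n_loci)], index=index, name="tau"
    )
    return matrix, realized, pd.Series(kinds, index=index, name="profile")


def simulate_footprints(
    config: SimConfig,
    n_loci: int,
    seed: Optional[int] = None,
    frame_prob: Optional[float] = None,
) -> Tuple[List[FrameCounts], np.ndarray]:
    """Frame counts with planted bias: each footprint lands in frame 0 with
    probability p, otherwise uniformly in frames 1/2. Returns (counts, true p
    per locus)."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    p = config.footprint_frame_prob if frame_prob is None else frame_prob
    if not 0.0 <= p <= 1.0:
        raise ValueError("frame probability must be in [0, 1]")
    out: List[FrameCounts] = []
    truth = np.full(n_loci, p)
    for _ in range(n_loci):
        n = int(rng.poisson(config.footprint_mean_count))
        in_frame = int(rng.binomial(n, p))
        rest = n - in_frame
        f1 = int(rng.binomial(rest, 0.5))
        out.append(FrameCounts(in_frame, f1, rest - f1, n_unique=n))
    return out, truth
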