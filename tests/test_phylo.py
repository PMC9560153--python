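import numpy as np
import pytest
from scipy import stats

from conftest import (
    EIGHT_LEAF_NEWICK,
    loss_cover_oracle,
    random_tree_newick,
)
from utorf.phylo import (
    OrthologyProfile,
    SpeciesTree,
    call_de_novo,
    count_losses,
    empirical_percentile,
    empirical_percentile_fisher,
    fisher_combined,
    infer_age,
    is_monophyletic,
)

LEAVES = list("abcdefgh")


def profile(scores, homology=None):
    if homology is None:
        homology = {sp: True for sp in scores}
    return OrthologyProfile(scores=scores, homology=homology)


def full_profile(sig, others=1.0, leaves=LEAVES):
    scores = {sp: (4.0 if sp in sig else others) for sp in leaves}
    return profile(scores)


class TestInferAge:
    def test_reference_only(self, eight_leaf_tree):
        age = infer_age(full_profile({"a"}), eight_leaf_tree)
        assert age.origin_stratum == 0
        assert age.most_distant_significant is None

    def test_all_leaves_root(self, eight_leaf_tree):
        age = infer_age(full_profile(set(LEAVES)), eight_leaf_tree)
        assert age.origin_stratum == len(eight_leaf_tree.strata) - 1

    def test_lca_oracle_one_distant(self, eight_leaf_tree):
        # a with e: the LCA is the root (a in left half, e in right half).
        age = infer_age(full_profile({"a", "e"}), eight_leaf_tree)
        assert age.origin_stratum == 3  # a -> (a,b) -> (abcd) -> root
        assert age.most_distant_significant == "e"

    def test_sister_pair(self, eight_leaf_tree):
        age = infer_age(full_profile({"a", "b"}), eight_leaf_tree)
        assert age.origin_stratum == 1

    def test_monotone_adding_species(self, eight_leaf_tree):
        sig = {"a"}
        prev = 0
        for sp in ["b", "c", "e"]:
            sig.add(sp)
            age = infer_age(full_profile(sig), eight_leaf_tree)
            assert age.origin_stratum >= prev
            prev = age.origin_stratum

    def test_threshold_window_robustness(self, eight_leaf_tree):
        prof = full_profile({"a", "b", "c"}, others=1.0)
        # No species score lies in (1.0, 4.0): any threshold there gives the
        # same age call.
        calls = {
            infer_age(prof, eight_leaf_tree, threshold=t).origin_stratum
            for t in (1.5, 2.0, 2.5, 3.0, 3.9)
        }
        assert len(calls) == 1

    def test_missing_reference_errors(self, eight_leaf_tree):
        with pytest.raises(ValueError):
            infer_age(profile({"b": 4.0}), eight_leaf_tree)


class TestMonophyly:
    def test_single_leaf(self, eight_leaf_tree):
        assert is_monophyletic({"a"}, eight_leaf_tree)

    def test_full_clade(self, eight_leaf_tree):
        assert is_monophyletic({"a", "b"}, eight_leaf_tree)
        assert is_monophyletic({"a", "b", "c", "d"}, eight_leaf_tree)

    def test_skipping_data_bearing_leaf(self, eight_leaf_tree):
        assert not is_monophyletic({"a", "c"}, eight_leaf_tree)

    def test_all_leaves(self, eight_leaf_tree):
        assert is_monophyletic(set(LEAVES), eight_leaf_tree)

    def test_missing_data_ignored(self, eight_leaf_tree):
        # b has no data: {a, c, d} spans (abcd) but b is unknown -> monophyletic.
        assert is_monophyletic(
            {"a", "c", "d"}, eight_leaf_tree, data_bearing={"a", "c", "d"}
        )


class TestDeNovo:
    def _age(self, tree, prof, **kw):
        return infer_age(prof, tree, **kw)

    def test_no_homologous_outgroup_guard(self, eight_leaf_tree):
        scores = {sp: (4.0 if sp in {"a", "b"} else 1.0) for sp in LEAVES}
        hom = {sp: sp in {"a", "b"} for sp in LEAVES}
        prof = profile(scores, hom)
        age = self._age(eight_leaf_tree, prof)
        dn = call_de_novo(prof, age, eight_leaf_tree)
        assert not dn.is_de_novo
        assert dn.n_supporting == 0

    def test_two_outgroups_two_lineages(self, eight_leaf_tree):
        scores = {"a": 4.0, "b": 4.0, "c": 1.0, "e": 1.0}
        prof = profile(scores)
        age = self._age(eight_leaf_tree, prof)
        dn = call_de_novo(prof, age, eight_leaf_tree)
        assert dn.is_de_novo
        assert dn.n_supporting == 2
        assert dn.n_distinct_clades == 2

    def test_one_lineage_insufficient(self, eight_leaf_tree):
        scores = {"a": 4.0, "b": 4.0, "c": 1.0, "d": 1.0}
        prof = profile(scores)
        age = self._age(eight_leaf_tree, prof)
        dn = call_de_novo(prof, age, eight_leaf_tree)
        assert dn.n_supporting == 2
        assert dn.n_distinct_clades == 1
        assert not dn.is_de_novo

    def test_significant_outgroups_do_not_support(self, eight_leaf_tree):
        prof = full_profile(set(LEAVES))  # everything significant
        age = self._age(eight_leaf_tree, prof)
        dn = call_de_novo(prof, age, eight_leaf_tree)
        assert not dn.is_de_novo


class TestCountLosses:
    def test_all_significant_zero(self, eight_leaf_tree):
        prof = full_profile(set(LEAVES))
        got = count_losses(prof, len(eight_leaf_tree.strata) - 1, eight_leaf_tree)
        assert got.n_losses == 0

    def test_single_lost_leaf(self, eight_leaf_tree):
        scores = {sp: (1.0 if sp == "b" else 4.0) for sp in LEAVES}
        prof = profile(scores)
        got = count_losses(prof, len(eight_leaf_tree.strata) - 1, eight_leaf_tree)
        assert got.n_losses == 1
        assert got.lost_leaf_sets == (frozenset({"b"}),)

    def test_lost_clade_counts_once(self, eight_leaf_tree):
        scores = {sp: (1.0 if sp in {"c", "d"} else 4.0) for sp in LEAVES}
        prof = profile(scores)
        got = count_losses(prof, len(eight_leaf_tree.strata) - 1, eight_leaf_tree)
        assert got.n_losses == 1
        assert got.lost_leaf_sets == (frozenset({"c", "d"}),)

    def test_unknown_leaves_bridge(self, eight_leaf_tree):
        # c lost, d unknown: the (c,d) subtree is all-lost among data-bearing
        # leaves, so one event.
        scores = {sp: 4.0 for sp in LEAVES if sp != "d"}
        scores["c"] = 1.0
        prof = profile(scores)
        got = count_losses(prof, len(eight_leaf_tree.strata) - 1, eight_leaf_tree)
        assert got.n_losses == 1

    def test_invalid_stratum(self, eight_leaf_tree):
        with pytest.raises(ValueError):
            count_losses(full_profile({"a"}), 99, eight_leaf_tree)

    def test_exhaustive_cover_oracle(self, rng):
        for trial in range(500):
            n_leaves = int(rng.integers(3, 9))
            labels = [f"s{i}" for i in range(n_leaves)]
            newick = random_tree_newick(rng, labels)
            ref = labels[0]
            tree = SpeciesTree.from_newick(newick, ref)
            scores = {}
            hom = {}
            for sp in labels:
                r = rng.random()
                if sp != ref and r < 0.2:
                    continue  # missing data
                scores[sp] = 1.0 if (sp != ref and r < 0.55) else 4.0
                hom[sp] = True
            prof = OrthologyProfile(scores=scores, homology=hom)
            origin = len(tree.strata) - 1
            got = count_losses(prof, origin, tree)
            lost = {
                sp for sp, s in scores.items()
                if sp != ref and s < 2.5
            }
            data_bearing = set(scores)
            want = loss_cover_oracle(tree.root, lost, data_bearing)
            assert got.n_losses == want, (newick, scores)


class TestEmpiricalPercentile:
    def test_all_equal_midrank(self):
        assert empirical_percentile(1.0, [1.0] * 250) == pytest.approx(0.5)

    def test_below_everything_add_one_floor(self):
        assert empirical_percentile(-5.0, list(range(250))) == pytest.approx(
            1 / 251
        )

    def test_above_everything(self):
        assert empirical_percentile(99.0, list(range(10))) == 1.0

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            empirical_percentile(1.0, [])


class TestFisher:
    def test_two_half_pvalues(self):
        stat, p = fisher_combined([0.5, 0.5])
        assert stat == pytest.approx(-2 * np.log(0.25), abs=1e-4)
        assert stat == pytest.approx(2.7726, abs=1e-3)
        # chi2 sf at df=4: e^{-x/2} (1 + x/2)
        want = np.exp(-stat / 2) * (1 + stat / 2)
        assert p == pytest.approx(want)
        assert p == pytest.approx(0.597, abs=1e-3)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            fisher_combined([])

    def test_combined_pipeline(self, rng):
        values = {f"l{i}": float(rng.random() * 5) for i in range(5)}
        lengths = {k: 30 for k in values}
        pool = {30: list(rng.random(400) * 5)}
        res = empirical_percentile_fisher(values, lengths, pool, n_draws=250, seed=1)
        assert set(res["per_locus_p"]) == set(values)
        stat, p = fisher_combined(list(res["per_locus_p"].values()))
        assert res["statistic"] == pytest.approx(stat)
        assert res["combined_p"] == pytest.approx(p)

    def test_length_tolerance_widens(self, rng):
        values = {"x": 1.0}
        lengths = {"x": 30}
        pool = {28: list(rng.random(300))}
        res = empirical_percentile_fisher(values, lengths, pool, n_draws=250)
        assert 0 < res["per_locus_p"]["x"] <= 1

    def test_insufficient_controls_error(self):
        with pytest.raises(ValueError):
            empirical_percentile_fisher(
                {"x": 1.0}, {"x": 30}, {500: [1.0] * 300}, n_draws=250
            )
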