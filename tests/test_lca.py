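import numpy as np
import pandas as pd
import pytest

from utorf.lca import (
    BinningRules,
    bin_features,
    fit_lca,
    information_criteria,
    log_likelihood,
    n_parameters,
    posterior_assign,
    select_classes,
    align_labels,
)
from utorf.simulate import SimConfig, default_lca_rho, simulate_lca_table


class TestBinning:
    def test_half_open_length_convention(self):
        raw = pd.DataFrame({"length_aa": [19, 20, 49, 50]})
        got = bin_features(raw)["length_aa"].tolist()
        assert got == [0, 1, 1, 2]

    def test_phastcons_bins(self):
        raw = pd.DataFrame({"phastcons": [0.0, 0.19, 0.2, 0.79, 0.8, 1.0]})
        got = bin_features(raw)["phastcons"].tolist()
        assert got == [0, 0, 1, 1, 2, 2]

    def test_binary_cuts(self):
        raw = pd.DataFrame({"max_tpm": [0.1, 0.11], "tissue_tau": [0.8, 0.81]})
        got = bin_features(raw)
        assert got["max_tpm"].tolist() == [0, 1]
        assert got["tissue_tau"].tolist() == [0, 1]

    def test_per_cell_rule_oracle(self, rng):
        rules = BinningRules()
        raw = pd.DataFrame(
            {
                "phastcons": rng.random(50),
                "length_aa": rng.integers(1, 100, 50).astype(float),
                "max_tpm": rng.random(50) * 2,
            }
        )
        got = bin_features(raw, rules)
        for i in range(50):
            pc = raw["phastcons"][i]
            want = 0 if pc < 0.2 else (1 if pc < 0.8 else 2)
            assert got["phastcons"][i] == want
            ln = raw["length_aa"][i]
            want = 0 if ln < 20 else (1 if ln < 50 else 2)
            assert got["length_aa"][i] == want
            assert got["max_tpm"][i] == (1 if raw["max_tpm"][i] > 0.1 else 0)

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            bin_features(pd.DataFrame({"phastcons": [1.2]}))
        with pytest.raises(ValueError):
            bin_features(pd.DataFrame({"tissue_tau": [-0.1]}))

    def test_nan_passthrough(self):
        got = bin_features(pd.DataFrame({"max_tpm": [np.nan, 0.5]}))
        assert np.isnan(got["max_tpm"][0])
        assert got["max_tpm"][1] == 1


def small_table(rng, n=200):
    return pd.DataFrame(
        {
            "x": rng.integers(0, 3, n),
            "y": rng.integers(0, 2, n),
        }
    )


class TestFit:
    def test_k1_closed_form(self, rng):
        table = small_table(rng)
        m = fit_lca(table, 1, n_restarts=3, seed=0)
        # K=1: conditionals are the observed marginals; logL is the sum of
        # log marginal probabilities.
        n = len(table)
        want_ll = 0.0
        for j, col in enumerate(table.columns):
            freqs = table[col].value_counts(normalize=True).sort_index()
            assert np.allclose(m.rho[j][0], freqs.to_numpy(), atol=1e-6)
            counts = table[col].value_counts().sort_index()
            want_ll += float((counts * np.log(freqs)).sum())
        assert m.log_likelihood == pytest.approx(want_ll, abs=1e-6)

    def test_likelihood_oracle(self, rng):
        table = small_table(rng)
        m = fit_lca(table, 2, n_restarts=5, seed=0)
        assert m.log_likelihood == pytest.approx(
            log_likelihood(m.pi, m.rho, table), abs=1e-6
        )

    def test_pi_sums_to_one_and_sorted(self, rng):
        m = fit_lca(small_table(rng), 3, n_restarts=5, seed=0)
        assert m.pi.sum() == pytest.approx(1.0)
        assert all(a >= b for a, b in zip(m.pi, m.pi[1:]))

    def test_k_exceeds_patterns_errors(self):
        table = pd.DataFrame({"x": [0, 1, 0, 1], "y": [0, 0, 0, 0]})
        with pytest.raises(ValueError):
            fit_lca(table, 3)

    def test_missing_values_error(self):
        table = pd.DataFrame({"x": [0.0, np.nan]})
        with pytest.raises(ValueError):
            fit_lca(table, 1)

    def test_two_class_recovery(self):
        cfg = SimConfig(
            seed=5, lca_K=2, lca_pi=(0.6, 0.4), lca_levels=(3, 2, 3, 2),
            lca_n=2000, lca_concentration=0.8,
        )
        table, _ = simulate_lca_table(cfg)
        m = fit_lca(table, 2, n_restarts=30, seed=0)
        true_rho = default_lca_rho(cfg)
        # align fitted classes to truth by pi (0.6 vs 0.4 are distinct)
        assert np.allclose(sorted(m.pi, reverse=True), [0.6, 0.4], atol=0.05)
        for j in range(4):
            assert np.allclose(m.rho[j], true_rho[j], atol=0.05)


class TestInformationCriteria:
    def test_binary_k1_closed_form(self):
        assert n_parameters(1, [2]) == 1
        aic = -2 * (-6.0) + 2 * 1
        bic = -2 * (-6.0) + 1 * np.log(10)
        assert aic == 14.0
        assert bic == pytest.approx(12 + np.log(10))
        assert bic == pytest.approx(14.303, abs=1e-3)

    def test_counting_formula(self):
        assert n_parameters(2, [3, 3]) == 1 + 2 * (2 + 2)

    def test_formula_oracle(self, rng):
        m = fit_lca(small_table(rng), 2, n_restarts=3, seed=0)
        ic = information_criteria(m)
        assert ic["AIC"] == pytest.approx(-2 * m.log_likelihood + 2 * m.n_params)
        assert ic["BIC"] == pytest.approx(
            -2 * m.log_likelihood + m.n_params * np.log(m.n_obs)
        )
        assert m.aic == pytest.approx(ic["AIC"])
        assert m.bic == pytest.approx(ic["BIC"])


class TestSelect:
    def test_single_candidate(self, rng):
        m = fit_lca(small_table(rng), 1, n_restarts=3, seed=0)
        chosen, report = select_classes({1: m})
        assert chosen == 1
        assert report.loc[1, "chosen"]

    def test_under_identified_excluded(self, rng):
        m1 = fit_lca(small_table(rng), 1, n_restarts=3, seed=0)
        m2 = fit_lca(small_table(rng), 2, n_restarts=3, seed=0)
        m2.n_distinct_optima = 2
        chosen, report = select_classes({1: m1, 2: m2})
        assert chosen == 1
        assert not report.loc[2, "eligible"]

    def test_no_eligible_errors(self, rng):
        m = fit_lca(small_table(rng), 1, n_restarts=3, seed=0)
        m.converged = False
        with pytest.raises(ValueError):
            select_classes({1: m})


class TestPosterior:
    def test_rows_sum_to_one(self, rng):
        table = small_table(rng)
        m = fit_lca(table, 2, n_restarts=5, seed=0)
        post = posterior_assign(m, table)
        assert np.allclose(post.posteriors.sum(axis=1), 1.0, atol=1e-12)

    def test_symmetric_model_tie_break(self):
        from utorf.lca import LcaModel

        rho = [np.array([[0.5, 0.5], [0.5, 0.5]])]
        m = LcaModel(
            K=2, pi=np.array([0.5, 0.5]), rho=rho, log_likelihood=0.0,
            n_params=3, aic=0, bic=0, n_obs=1, converged=True,
            n_distinct_optima=1, columns=("x",),
        )
        table = pd.DataFrame({"x": [0, 1]})
        post = posterior_assign(m, table)
        assert np.allclose(post.posteriors.to_numpy(), 0.5)
        assert (post.modal_class == 0).all()  # ties -> lowest class index

    def test_bayes_oracle(self, rng):
        table = small_table(rng, 50)
        m = fit_lca(table, 2, n_restarts=5, seed=0)
        post = posterior_assign(m, table)
        for i in range(10):
            x = table.iloc[i]
            joint = np.array([
                m.pi[k]
                * np.prod([m.rho[j][k, int(x[c])]
                           for j, c in enumerate(table.columns)])
                for k in range(2)
            ])
            want = joint / joint.sum()
            assert np.allclose(post.posteriors.iloc[i].to_numpy(), want, atol=1e-9)

    def test_deterministic_conditionals_one_hot(self):
        from utorf.lca import LcaModel

        rho = [np.array([[1.0, 0.0], [0.0, 1.0]])]
        m = LcaModel(
            K=2, pi=np.array([0.5, 0.5]), rho=rho, log_likelihood=0.0,
            n_params=3, aic=0, bic=0, n_obs=1, converged=True,
            n_distinct_optima=1, columns=("x",),
        )
        post = posterior_assign(m, pd.DataFrame({"x": [0, 1]}))
        got = post.posteriors.to_numpy()
        assert np.allclose(got, [[1, 0], [0, 1]], atol=1e-9)

    def test_unseen_level_errors(self, rng):
        table = small_table(rng)
        m = fit_lca(table, 2, n_restarts=3, seed=0)
        bad = pd.DataFrame({"x": [5], "y": [0]})
        with pytest.raises(ValueError):
            posterior_assign(m, bad)


class TestLabelPermutation:
    def test_permutation_leaves_ic_unchanged(self, rng):
        table = small_table(rng)
        m = fit_lca(table, 2, n_restarts=5, seed=0)
        perm = [1, 0]
        pi_p = m.pi[perm]
        rho_p = [r[perm] for r in m.rho]
        assert log_likelihood(pi_p, rho_p, table) == pytest.approx(
            m.log_likelihood, abs=1e-9
        )

    def test_align_labels(self):
        true = np.array([0, 0, 1, 1, 2])
        pred = np.array([2, 2, 0, 0, 1])
        aligned = align_labels(true, pred, 3)
        assert (aligned == true).all()
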