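import numpy as np
import pytest

from conftest import (
    digest_oracle,
    fdr_sweep_oracle,
    min_distance_oracle,
)
from utorf.proteomics import (
    Candidate,
    Psm,
    build_trie,
    curate,
    estimate_fdr,
    min_distance,
    rt_support,
    tryptic_digest,
    two_round_select,
)

AA = list("ACDEFGHIKLMNPQRSTVWY")


def random_protein(rng, n):
    return "".join(rng.choice(AA, size=n))


class TestDigest:
    def test_basic_cleavage(self):
        peps = {p.aa_sequence for p in tryptic_digest("MKR", 0, 1)}
        assert peps == {"MK", "R"}

    def test_proline_blocks(self):
        peps = {p.aa_sequence for p in tryptic_digest("MKPR", 0, 1)}
        assert peps == {"MKPR"}

    def test_brute_force_oracle(self, rng):
        prot = random_protein(rng, 50)
        got = {(p.aa_sequence, p.n_missed_cleavages)
               for p in tryptic_digest(prot, 2, 7)}
        assert got == digest_oracle(prot, 2, 7)

    def test_missed_cleavage_superset(self, rng):
        prot = random_protein(rng, 60)
        for m in range(1, 3):
            lo = {p.aa_sequence for p in tryptic_digest(prot, m - 1, 1)}
            hi = {p.aa_sequence for p in tryptic_digest(prot, m, 1)}
            assert lo <= hi

    def test_empty_and_invalid(self):
        with pytest.raises(ValueError):
            tryptic_digest("")
        with pytest.raises(ValueError):
            tryptic_digest("MKX")


class TestTrie:
    def test_exact_membership(self):
        trie = build_trie(["PEPTIDE"])
        assert min_distance("PEPTIDE", trie) == 0
        assert "PEPTIDE" in trie

    def test_empty_index(self):
        trie = build_trie([])
        assert min_distance("ANY", trie) is None

    def test_hamming_one(self):
        trie = build_trie(["AAAA"])
        assert min_distance("AAAC", trie, metric="hamming") == 1

    def test_levenshtein_deletion(self):
        trie = build_trie(["AAAA"])
        assert min_distance("AAA", trie, metric="levenshtein") == 1

    def test_zero_iff_member(self, rng):
        members = {random_protein(rng, int(rng.integers(6, 12))) for _ in range(50)}
        trie = build_trie(members)
        for m in list(members)[:10]:
            assert min_distance(m, trie) == 0
        outside = "W" * 15
        assert outside not in members
        assert min_distance(outside, trie) != 0

    @pytest.mark.parametrize("metric", ["hamming", "levenshtein"])
    def test_linear_scan_oracle(self, rng, metric):
        members = [random_protein(rng, int(rng.integers(7, 12)))
                   for _ in range(200)]
        trie = build_trie(members)
        for _ in range(50):
            q = random_protein(rng, int(rng.integers(7, 12)))
            assert min_distance(q, trie, metric=metric, cap=2) == \
                min_distance_oracle(q, members, metric, 2)

    def test_invalid_metric_and_cap(self):
        trie = build_trie(["AAAA"])
        with pytest.raises(ValueError):
            min_distance("AAAA", trie, metric="cosine")
        with pytest.raises(ValueError):
            min_distance("AAAA", trie, cap=-1)


def psm(score, decoy=False, group="", **kw):
    return Psm(peptide=f"p{score}", score=score, is_decoy=decoy,
               parent_group=group or f"g{score}{decoy}", **kw)


class TestFdr:
    def test_no_decoys_all_zero_q(self):
        res = estimate_fdr([psm(s) for s in (3.0, 2.0, 1.0)], alpha=0.01)
        assert np.all(res.q_values == 0.0)
        assert len(res.accepted) == 3

    def test_hand_enumeration(self):
        targets = [psm(s) for s in (10.0, 9.0, 8.0, 7.0)]
        decoys = [psm(s, decoy=True) for s in (8.5, 6.0)]
        res = estimate_fdr(targets + decoys, alpha=1.0)
        # At cutoff 8: targets {10, 9, 8}, decoys {8.5} -> FDR 1/3.
        sweep = fdr_sweep_oracle([10.0, 9.0, 8.0, 7.0], [8.5, 6.0])
        assert sweep[8.0] == pytest.approx(1 / 3)
        # The q-value at score 8 is the min FDR over cutoffs <= 8; cutoff 7
        # gives 1/4, so q = 1/4.
        i8 = next(i for i, p in enumerate(targets + decoys) if p.score == 8.0)
        assert res.q_values[i8] == pytest.approx(1 / 4)

    def test_threshold_sweep_oracle(self, rng):
        t_scores = list(np.round(rng.normal(2, 1, size=40), 2))
        d_scores = list(np.round(rng.normal(0, 1, size=40), 2))
        psms = [psm(s) for s in t_scores] + [psm(s, decoy=True) for s in d_scores]
        res = estimate_fdr(psms, alpha=1.0)
        sweep = fdr_sweep_oracle(t_scores, d_scores)
        # q-value of a target = min FDR over thresholds <= its score.
        for i, p in enumerate(psms):
            if p.is_decoy:
                continue
            want = min(
                min(f for s, f in sweep.items() if s <= p.score), 1.0
            )
            assert res.q_values[i] == pytest.approx(want)

    def test_q_monotone_in_score(self, rng):
        psms = [psm(float(s)) for s in rng.normal(1, 1, 50)] + [
            psm(float(s), decoy=True) for s in rng.normal(0, 1, 50)
        ]
        res = estimate_fdr(psms, alpha=1.0)
        order = sorted(range(len(psms)), key=lambda i: -psms[i].score)
        qs = [res.q_values[i] for i in order]
        assert all(a <= b + 1e-12 for a, b in zip(qs, qs[1:]))

    def test_acceptance_nested_across_alpha(self, rng):
        psms = [psm(float(s)) for s in rng.normal(1, 1, 50)] + [
            psm(float(s), decoy=True) for s in rng.normal(0, 1, 50)
        ]
        prev = set()
        for alpha in (0.01, 0.05, 0.2, 1.0):
            acc = set(estimate_fdr(psms, alpha=alpha).accepted)
            assert prev <= acc
            prev = acc

    def test_no_targets_errors(self):
        with pytest.raises(ValueError):
            estimate_fdr([psm(1.0, decoy=True)])


class TestTwoRound:
    def test_no_decoys_keeps_all(self):
        r1 = [psm(5.0 + i, group=f"c{i}") for i in range(5)]
        r2 = [psm(5.0 + i, group=f"c{i}") for i in range(5)]
        got = two_round_select(r1, {f"c{i}" for i in range(5)}, r2)
        assert got == {f"c{i}" for i in range(5)}

    def test_empty_survivors_empty_result(self):
        # Decoys outscore every target in round 1 -> no survivors.
        r1 = [psm(1.0, group="c0")] + [psm(9.0, decoy=True, group=f"d{i}")
                                       for i in range(10)]
        got = two_round_select(r1, {"c0"}, [])
        assert got == set()

    def test_fdr_order_validation(self):
        with pytest.raises(ValueError):
            two_round_select([psm(1.0, group="c0")], {"c0"}, [],
                             fdr1=0.01, fdr2=0.2)

    def test_unknown_candidate_errors(self):
        r1 = [psm(1.0, group="mystery")]
        with pytest.raises(ValueError):
            two_round_select(r1, {"c0"}, [])

    def test_round2_non_survivor_errors(self):
        r1 = [psm(5.0, group="c0")]
        r2 = [psm(5.0, group="never_seen")]
        with pytest.raises(ValueError):
            two_round_select(r1, {"c0", "never_seen"}, r2)

    def test_planted_truth_fdr_control(self):
        from utorf.simulate import SimConfig, simulate_two_round_tables

        cfg = SimConfig(seed=11)
        tab = simulate_two_round_tables(cfg)
        got = two_round_select(tab["round1"], tab["full_db_ids"], tab["round2"])
        false = len(got - tab["true_ids"])
        # Realized false fraction <= 2x nominal fdr2, within binomial error.
        assert false <= max(3, 2 * 0.01 * len(got) + 3 * np.sqrt(0.01 * len(got)))


class TestCurate:
    def test_short_dropped(self):
        assert curate([Candidate("a", 13, False, "g")]) == set()

    def test_homology_flag_dropped(self):
        assert curate([Candidate("a", 50, True, "g")]) == set()

    def test_longest_per_group(self):
        got = curate([
            Candidate("a", 20, False, "g"),
            Candidate("b", 30, False, "g"),
        ])
        assert got == {"b"}

    def test_tie_breaks_to_smallest_id(self):
        got = curate([
            Candidate("b", 30, False, "g"),
            Candidate("a", 30, False, "g"),
        ])
        assert got == {"a"}


class TestRtSupport:
    def _annotated(self):
        return [
            Psm(f"a{i}", 1.0, False, observed_rt=10.0 + d, predicted_rt=10.0)
            for i, d in enumerate([0.1, 0.2, 0.3, 0.5, 1.0])
        ]

    def test_delta_zero_supported(self):
        cand = [Psm("c", 1.0, False, observed_rt=5.0, predicted_rt=5.0)]
        assert rt_support(self._annotated(), cand) == {"c"}

    def test_huge_delta_unsupported(self):
        cand = [Psm("c", 1.0, False, observed_rt=100.0, predicted_rt=5.0)]
        assert rt_support(self._annotated(), cand) == set()

    def test_quantile_convention(self):
        deltas = [0.1, 0.2, 0.3, 0.5, 1.0]
        want = float(np.percentile(deltas, 95))
        below = Psm("lo", 1.0, False, observed_rt=want - 1e-6, predicted_rt=0.0)
        above = Psm("hi", 1.0, False, observed_rt=want + 1e-3, predicted_rt=0.0)
        got = rt_support(self._annotated(), [below, above])
        assert got == {"lo"}

    def test_no_annotated_rts_errors(self):
        with pytest.raises(ValueError):
            rt_support([Psm("a", 1.0, False)], [])
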