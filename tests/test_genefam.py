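import numpy as np
import pandas as pd
import pytest

from convphy.genefam import (
    BDIModel,
    bdi_transition_prob,
    branch_viterbi_pvalues,
    family_pvalue,
    fit_lambda,
    transition_matrix,
)
from convphy.simulate import gillespie_bdi, simulate_family_counts
from convphy.trees import PhyloTree

from oracles import enum_family_loglik_3tip


class TestTransitionProbability:
    def test_zero_time_freezes_the_chain(self):
        for s in (1, 3, 10):
            assert bdi_transition_prob(s, s, 0.0, 0.01) == 1.0
            assert bdi_transition_prob(s, s + 1, 0.0, 0.01) == 0.0

    def test_zero_state_is_absorbing(self):
        assert bdi_transition_prob(0, 0, 5.0, 0.01) == 1.0
        assert bdi_transition_prob(0, 2, 5.0, 0.01) == 0.0

    @pytest.mark.parametrize("s", [1, 5, 20])
    @pytest.mark.parametrize("lt", [0.05, 0.2, 0.5])
    def test_rows_normalize_over_generous_truncation(self, s, lt):
        lam = 0.002
        t = lt / lam
        total = sum(bdi_transition_prob(s, c, t, lam) for c in range(0, 400))
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_matrix_agrees_with_scalar_form(self):
        T = transition_matrix(25.0, 0.004, 30)
        for s in (1, 4, 12):
            row = np.array([bdi_transition_prob(s, c, 25.0, 0.004)
                            for c in range(31)])
            # rows are renormalized over the truncated support
            assert np.abs(T[s] - row / row.sum()).max() < 1e-12

    def test_truncation_renormalization_is_negligible(self):
        # cap = 2x the start keeps the clipped tail tiny at moderate lambda*t
        T = transition_matrix(50.0, 0.002, 40)
        for s in range(1, 21):
            raw = np.array([bdi_transition_prob(s, c, 50.0, 0.002)
                            for c in range(41)])
            assert np.abs(T[s] - raw).max() < 1e-6

    def test_agrees_with_gillespie_simulation(self):
        s, t, lam = 5, 50.0, 0.002
        rng = np.random.default_rng(99)
        n = 100_000
        draws = np.array([gillespie_bdi(s, t, lam, rng) for _ in range(n)])
        for c in (3, 4, 5, 6, 7):
            p_hat = np.mean(draws == c)
            p = bdi_transition_prob(s, c, t, lam)
            se = np.sqrt(p * (1 - p) / n)
            assert abs(p_hat - p) <= 3 * se + 1e-12

    def test_negative_arguments_rejected(self):
        with pytest.raises(ValueError):
            bdi_transition_prob(-1, 0, 1.0, 0.1)


class TestFitLambda:
    def test_constant_families_push_lambda_to_lower_bound(self, time_tree):
        counts = pd.DataFrame(
            np.full((30, 7), 4), columns=time_tree.tree.tip_labels,
            index=[f"f{i}" for i in range(30)])
        model, _ = fit_lambda(time_tree, counts)
        assert model.lam < 1e-5

    def test_recovery_within_stated_interval(self, time_tree):
        counts, _ = simulate_family_counts(time_tree, 0.002, 300,
                                           root_size_range=(1, 10), seed=3)
        model, _ = fit_lambda(time_tree, counts)
        assert 0.0013 <= model.lam <= 0.0031

    def test_optimum_beats_half_and_double(self, time_tree):
        from convphy.genefam import _family_logliks, _prep

        counts, _ = simulate_family_counts(time_tree, 0.003, 100,
                                           root_size_range=(1, 8), seed=5)
        model, lls = fit_lambda(time_tree, counts)
        t, mat = _prep(time_tree, counts)
        max_root = max(2 * int(mat.max()), 2)
        for factor in (0.5, 2.0):
            alt = _family_logliks(t, mat, model.lam * factor, model.cap,
                                  max_root).sum()
            assert lls.sum() >= alt - 1e-9

    def test_non_ultrametric_tree_rejected(self):
        t = PhyloTree.from_newick("((a:1,b:2):1,c:3);")
        counts = pd.DataFrame([[1, 1, 1]], columns=["a", "b", "c"])
        with pytest.raises(ValueError, match="ultrametric"):
            fit_lambda(t, counts)

    def test_pruning_equals_enumeration_on_3tip_tree(self):
        from convphy.genefam import _family_logliks

        t = PhyloTree.from_newick("((a:10,b:10):5,c:15);")
        lam, cap = 0.01, 8
        T = {v: transition_matrix(t.lengths[v], lam, cap)
             for v in t.branch_ids()}

        def trans(s, c, length):
            v = {10.0: None}  # branch lookup by length below
            for b in t.branch_ids():
                if t.lengths[b] == length:
                    return T[b][min(s, cap), min(c, cap)]
            raise KeyError(length)

        tip_counts = [2, 3, 1]
        max_root = 6
        expected = enum_family_loglik_3tip(tip_counts, t.lengths, lam, cap,
                                           max_root, trans)
        got = _family_logliks(t, np.array([tip_counts]), lam, cap, max_root)[0]
        assert got == pytest.approx(expected, abs=1e-10)


class TestFamilyPvalue:
    def test_add_one_estimator_never_returns_zero(self, time_tree):
        counts, _ = simulate_family_counts(time_tree, 0.002, 5,
                                           root_size_range=(2, 6), seed=11)
        model = BDIModel(lam=0.002, cap=20)
        p = family_pvalue(counts.iloc[0], model, time_tree,
                          n_montecarlo=150, seed=4)
        n = 150
        assert 1.0 / (n + 1) <= p <= 1.0

    def test_coarse_montecarlo_warns(self, time_tree):
        counts, _ = simulate_family_counts(time_tree, 0.002, 2,
                                           root_size_range=(2, 4), seed=12)
        model = BDIModel(lam=0.002, cap=16)
        with pytest.warns(UserWarning, match="coarse"):
            family_pvalue(counts.iloc[0], model, time_tree,
                          n_montecarlo=99, seed=1)

    def test_planted_jump_is_significant(self, time_tree):
        planted = {(0, "mallard"): 10}
        counts, _ = simulate_family_counts(time_tree, 0.002, 200,
                                           root_size_range=(10, 14), seed=21,
                                           planted_events=planted)
        model, _ = fit_lambda(time_tree, counts)
        p = family_pvalue(counts.iloc[0], model, time_tree,
                          n_montecarlo=300, seed=2)
        assert p < 0.05


class TestViterbi:
    def test_constant_family_has_no_calls(self, time_tree):
        model = BDIModel(lam=0.002, cap=16)
        row = pd.Series(4, index=time_tree.tree.tip_labels)
        calls = branch_viterbi_pvalues(row, model, time_tree)
        assert all(c.call == "none" and c.pvalue == 1.0 for c in calls)

    def test_planted_expansion_called_on_the_right_branch(self, time_tree):
        planted = {(0, "mallard"): 8}
        counts, _ = simulate_family_counts(time_tree, 0.002, 50,
                                           root_size_range=(8, 12), seed=31,
                                           planted_events=planted)
        model, _ = fit_lambda(time_tree, counts)
        calls = branch_viterbi_pvalues(counts.iloc[0], model, time_tree)
        mallard = next(c for c in calls if c.branch == "mallard")
        assert mallard.call == "expansion"
        assert mallard.pvalue < 0.05
        assert mallard.child_count > mallard.parent_count

    def test_expansion_call_implies_child_exceeds_parent(self, time_tree):
        counts, _ = simulate_family_counts(time_tree, 0.004, 40,
                                           root_size_range=(2, 10), seed=41)
        model, _ = fit_lambda(time_tree, counts)
        for i in range(len(counts)):
            for c in branch_viterbi_pvalues(counts.iloc[i], model, time_tree):
                if c.call == "expansion":
                    assert c.child_count > c.parent_count
                elif c.call == "contraction":
                    assert c.child_count < c.parent_count
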