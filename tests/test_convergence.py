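import numpy as np
import pytest

from convphy.asr import ProteinGammaModel, fit_branch_lengths_and_alpha, marginal_ancestral_states
from convphy.convergence import (
    PRESET_CONTROL_TRIO,
    detect_convergent_sites,
    random_trio_control,
    summarize_convergent_genes,
)
from convphy.simulate import inject_convergent_sites, simulate_protein_alignment


@pytest.fixture(scope="module")
def injected_case(seq_tree):
    """One gene with 6 injected convergent sites plus its reconstruction."""
    sim = simulate_protein_alignment(seq_tree, 500, alpha=0.7, seed=31)
    inj, truth = inject_convergent_sites(sim, seq_tree, 6, seed=32)
    fitted, alpha, _ = fit_branch_lengths_and_alpha(seq_tree.tree, inj.tip_seqs)
    rec = marginal_ancestral_states(fitted, inj.tip_seqs,
                                    ProteinGammaModel.jtt(alpha),
                                    outgroup=seq_tree.outgroup_tip)
    return inj, truth, rec


class TestDetect:
    def test_injected_columns_are_called_with_correct_residues(
            self, seq_tree, injected_case):
        inj, truth, rec = injected_case
        calls = detect_convergent_sites(inj.tip_seqs, rec, seq_tree)
        called = {c.column: c for c in calls}
        planted = truth.convergent_site_indices["__alignment__"]
        hits = [j for j in planted if j in called]
        assert len(hits) >= 5  # near-exact ASR recovers nearly all
        for j in hits:
            c = called[j]
            assert c.foreground_residue != c.background_residue
            fg_res = {inj.tip_seqs[s][j] for s in seq_tree.foreground_tips}
            assert c.foreground_residue in fg_res

    def test_reported_calls_pass_all_three_criteria(self, seq_tree, injected_case):
        inj, _, rec = injected_case
        for c in detect_convergent_sites(inj.tip_seqs, rec, seq_tree):
            j = c.column
            fg = {inj.tip_seqs[s][j] for s in seq_tree.foreground_tips}
            bg = {inj.tip_seqs[s][j] for s in seq_tree.background_tips}
            assert len(fg) == 1 and len(bg) == 1 and fg != bg

    def test_invariant_column_not_called(self, seq_tree, injected_case):
        inj, truth, rec = injected_case
        planted = set(truth.convergent_site_indices["__alignment__"])
        invariant = [
            j for j in range(500)
            if len({s[j] for s in inj.tip_seqs.values()}) == 1
        ]
        calls = {c.column for c in detect_convergent_sites(inj.tip_seqs, rec, seq_tree)}
        assert not (set(invariant) & calls)

    def test_background_contamination_blocks_the_call(self, seq_tree, injected_case):
        inj, truth, rec = injected_case
        j = truth.convergent_site_indices["__alignment__"][0]
        corrupted = dict(inj.tip_seqs)
        bg_tip = sorted(seq_tree.background_tips)[0]
        fg_tip = sorted(seq_tree.foreground_tips)[0]
        x = inj.tip_seqs[fg_tip][j]
        corrupted[bg_tip] = (corrupted[bg_tip][:j] + x + corrupted[bg_tip][j + 1:])
        calls = {c.column for c in
                 detect_convergent_sites(corrupted, rec, seq_tree)}
        assert j not in calls

    def test_overlapping_foreground_background_rejected(self, seq_tree, injected_case):
        inj, _, rec = injected_case
        with pytest.raises(ValueError, match="overlap"):
            detect_convergent_sites(inj.tip_seqs, rec, seq_tree,
                                    foreground={"kiwi", "mallard", "ibis"},
                                    background={"kiwi", "chicken", "egret"})

    def test_tightening_posterior_threshold_never_adds_calls(
            self, seq_tree, injected_case):
        inj, _, rec = injected_case
        loose = {c.column for c in detect_convergent_sites(
            inj.tip_seqs, rec, seq_tree, min_anc_posterior=0.5)}
        strict = {c.column for c in detect_convergent_sites(
            inj.tip_seqs, rec, seq_tree, min_anc_posterior=0.95)}
        assert strict <= loose

    def test_background_tip_order_is_irrelevant(self, seq_tree, injected_case):
        inj, _, rec = injected_case
        bg = sorted(seq_tree.background_tips)
        a = detect_convergent_sites(inj.tip_seqs, rec, seq_tree,
                                    background=set(bg))
        b = detect_convergent_sites(inj.tip_seqs, rec, seq_tree,
                                    background=set(reversed(bg)))
        assert [(c.column, c.foreground_residue) for c in a] == \
               [(c.column, c.foreground_residue) for c in b]

    def test_parents_mode_is_no_stricter_than_all_mode(self, seq_tree, injected_case):
        inj, _, rec = injected_case
        every = {c.column for c in detect_convergent_sites(
            inj.tip_seqs, rec, seq_tree, ancestor_mode="all")}
        parents = {c.column for c in detect_convergent_sites(
            inj.tip_seqs, rec, seq_tree, ancestor_mode="parents")}
        assert every <= parents


class TestTrioControl:
    def _dataset(self, seq_tree, seed, n_genes=4, inject=2):
        out = {}
        for i in range(n_genes):
            sim = simulate_protein_alignment(seq_tree, 300, alpha=0.7,
                                             seed=seed + i)
            if i < inject:
                sim, _ = inject_convergent_sites(sim, seq_tree, 3,
                                                 seed=seed + 50 + i)
            fitted, alpha, _ = fit_branch_lengths_and_alpha(
                seq_tree.tree, sim.tip_seqs)
            rec = marginal_ancestral_states(
                fitted, sim.tip_seqs, ProteinGammaModel.jtt(alpha),
                outgroup=seq_tree.outgroup_tip)
            out[f"g{i}"] = (sim.tip_seqs, rec, None)
        return out

    def test_trio_equal_to_true_tg_overlaps_totally(self, seq_tree):
        ds = self._dataset(seq_tree, seed=400)
        cmp = random_trio_control(ds, seq_tree,
                                  trio=set(seq_tree.foreground_tips))
        assert cmp.genes_trio == cmp.genes_true
        assert cmp.overlap_genes == cmp.genes_true
        for g, (a, b, shared) in cmp.site_overlap.items():
            assert a == b == shared

    def test_preset_control_trio_is_accepted(self, seq_tree):
        ds = self._dataset(seq_tree, seed=450, n_genes=2, inject=1)
        cmp = random_trio_control(ds, seq_tree, trio=set(PRESET_CONTROL_TRIO))
        assert cmp.trio == PRESET_CONTROL_TRIO

    def test_trio_containing_outgroup_rejected(self, seq_tree):
        ds = self._dataset(seq_tree, seed=470, n_genes=1, inject=0)
        with pytest.raises(ValueError, match="outgroup"):
            random_trio_control(ds, seq_tree,
                                trio={"ostrich", "chicken", "egret"})

    def test_gene_overlap_with_disjoint_sites_is_distinguished(self, seq_tree):
        # construct one gene carrying a TG-convergent column AND a
        # trio-convergent column at a different site
        sim = simulate_protein_alignment(seq_tree, 300, alpha=0.7, seed=480)
        inj, truth = inject_convergent_sites(sim, seq_tree, 2, seed=481)
        trio = set(PRESET_CONTROL_TRIO)
        trio_tree_view = [s for s in seq_tree.tree.tip_labels]
        # overwrite a conserved column for the trio species
        t = seq_tree.tree
        rows = [inj.tip_seqs[s] for s in trio_tree_view if s not in trio
                and s != seq_tree.outgroup_tip]
        rows += [inj.anc_seqs[t.labels[v]] for v in t.internal_ids()]
        rows += [inj.tip_seqs[seq_tree.outgroup_tip]]
        planted = set(truth.convergent_site_indices["__alignment__"])
        eligible = [j for j in range(300)
                    if len({r[j] for r in rows}) == 1 and j not in planted]
        j = eligible[0]
        y = rows[0][j]
        x = "W" if y != "W" else "Y"
        seqs = {k: (v[:j] + x + v[j + 1:]) if k in trio else v
                for k, v in inj.tip_seqs.items()}
        fitted, alpha, _ = fit_branch_lengths_and_alpha(t, seqs)
        rec = marginal_ancestral_states(fitted, seqs,
                                        ProteinGammaModel.jtt(alpha),
                                        outgroup=seq_tree.outgroup_tip)
        cmp = random_trio_control({"g": (seqs, rec, None)}, seq_tree, trio=trio,
                                  min_anc_posterior=0.6)
        assert "g" in cmp.overlap_genes
        tg_sites, trio_sites, shared = cmp.site_overlap["g"]
        assert j in trio_sites
        assert set(tg_sites) & planted
        assert not shared  # same gene, disjoint loci


class TestSummary:
    def test_empty_call_list_gives_empty_table(self):
        df = summarize_convergent_genes([])
        assert len(df) == 0
        assert list(df.columns) == ["gene", "n_sites", "sites"]

    def test_counts_and_ascending_site_lists(self, seq_tree, injected_case):
        inj, _, rec = injected_case
        calls = detect_convergent_sites(inj.tip_seqs, rec, seq_tree)
        df = summarize_convergent_genes(calls)
        assert df.loc[0, "n_sites"] == len(calls)
        sites = [int(s) for s in df.loc[0, "sites"].split(",")]
        assert sites == sorted(sites)

    def test_sorted_by_count_then_gene(self):
        from convphy.convergence import ConvergentSiteCall

        def call(gene, col):
            return ConvergentSiteCall(gene, col, "A", "S", ("N7",), 0.9)

        calls = [call("b", 1), call("a", 2), call("a", 5), call("c", 9)]
        df = summarize_convergent_genes(calls)
        assert list(df["gene"]) == ["a", "b", "c"]
        assert list(df["n_sites"]) == [2, 1, 1]
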