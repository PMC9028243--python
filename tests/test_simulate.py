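import numpy as np
import pytest

from convphy.codon import STOP_CODONS, ng86_counts, ng86_pairwise
from convphy.simulate import (
    ConvergenceShortfallError,
    gillespie_bdi,
    inject_convergent_sites,
    simulate_codon_alignment,
    simulate_family_counts,
    simulate_protein_alignment,
    simulate_similarity_graph,
    write_blast_tsv,
)
from convphy.substitution import AA_INDEX, jtt_model
from convphy.trees import PhyloTree, make_default_tree


class TestProteinSimulator:
    def test_same_seed_reproduces_bit_for_bit(self, seq_tree):
        a = simulate_protein_alignment(seq_tree, 200, alpha=0.7, seed=42)
        b = simulate_protein_alignment(seq_tree, 200, alpha=0.7, seed=42)
        assert a.tip_seqs == b.tip_seqs and a.anc_seqs == b.anc_seqs
        c = simulate_protein_alignment(seq_tree, 200, alpha=0.7, seed=43)
        assert c.tip_seqs != a.tip_seqs

    def test_zero_branch_lengths_freeze_the_root_sequence(self):
        t = make_default_tree("sequence", branch_length=0.0)
        sim = simulate_protein_alignment(t, 100, seed=7)
        root_label = t.tree.labels[t.tree.root]
        root = sim.anc_seqs[root_label]
        for seq in sim.tip_seqs.values():
            assert seq == root

    def test_tip_frequencies_match_jtt_stationary_within_3se(self, seq_tree):
        L = 10_000
        sim = simulate_protein_alignment(seq_tree, L, alpha=1.0, seed=5)
        pi = jtt_model().pi
        seqs = "".join(sim.tip_seqs.values())
        n = len(seqs)
        counts = np.zeros(20)
        for ch in seqs:
            counts[AA_INDEX[ch]] += 1
        freqs = counts / n
        # multinomial sampling error; tips are correlated through the tree,
        # so allow the full between-tip correlation factor of 7
        se = np.sqrt(pi * (1 - pi) / n) * np.sqrt(7)
        assert (np.abs(freqs - pi) <= 3 * se + 1e-3).all()

    def test_alignment_is_rectangular_and_gap_free(self, seq_tree):
        sim = simulate_protein_alignment(seq_tree, 123, seed=1)
        for seq in {**sim.tip_seqs, **sim.anc_seqs}.values():
            assert len(seq) == 123
            assert "-" not in seq

    def test_invalid_arguments_rejected(self, seq_tree):
        with pytest.raises(ValueError):
            simulate_protein_alignment(seq_tree, 0)
        with pytest.raises(ValueError):
            simulate_protein_alignment(seq_tree, 10, alpha=-1.0)


class TestConvergentInjection:
    def test_zero_sites_leaves_alignment_unchanged(self, seq_tree):
        sim = simulate_protein_alignment(seq_tree, 150, seed=3)
        out, truth = inject_convergent_sites(sim, seq_tree, 0, seed=4)
        assert out.tip_seqs == sim.tip_seqs
        assert truth.convergent_site_indices["__alignment__"] == []

    def test_bookkeeping_lists_exactly_n_distinct_columns(self, seq_tree):
        sim = simulate_protein_alignment(seq_tree, 400, seed=3)
        out, truth = inject_convergent_sites(sim, seq_tree, 5, seed=9)
        cols = truth.convergent_site_indices["__alignment__"]
        assert len(cols) == len(set(cols)) == 5
        assert all(0 <= c < 400 for c in cols)

    def test_injected_columns_satisfy_all_three_criteria_vs_truth(self, seq_tree):
        sim = simulate_protein_alignment(seq_tree, 400, seed=3)
        out, truth = inject_convergent_sites(sim, seq_tree, 5, seed=9)
        t = seq_tree.tree
        for j in truth.convergent_site_indices["__alignment__"]:
            fg = {out.tip_seqs[s][j] for s in seq_tree.foreground_tips}
            bg = {out.tip_seqs[s][j] for s in seq_tree.background_tips}
            anc = {out.anc_seqs[t.labels[v]][j] for v in t.internal_ids()}
            bg |= {out.tip_seqs[seq_tree.outgroup_tip][j]}
            assert len(fg) == 1 and len(bg | anc) == 1
            assert fg != bg

    def test_ancestral_truth_untouched(self, seq_tree):
        sim = simulate_protein_alignment(seq_tree, 300, seed=3)
        out, _ = inject_convergent_sites(sim, seq_tree, 5, seed=9)
        assert out.anc_seqs == sim.anc_seqs

    def test_shortfall_error_names_available_count(self, seq_tree):
        sim = simulate_protein_alignment(seq_tree, 10, seed=3)
        with pytest.raises(ConvergenceShortfallError) as err:
            inject_convergent_sites(sim, seq_tree, 10_000, seed=4)
        assert err.value.available < 10_000
        assert str(err.value.available) in str(err.value)


class TestCodonSimulator:
    def test_no_stop_codons_ever(self, codon_tree):
        sim = simulate_codon_alignment(codon_tree, 300, kappa=2.0, seed=11)
        for seq in {**sim.tip_seqs, **sim.anc_seqs}.values():
            codons = {seq[k : k + 3] for k in range(0, len(seq), 3)}
            assert not codons & set(STOP_CODONS)

    def test_omega_zero_means_no_nonsynonymous_differences(self, codon_tree):
        sim = simulate_codon_alignment(codon_tree, 200, omega_map=0.0, seed=2)
        tips = list(sim.tip_seqs.values())
        for i in range(len(tips)):
            for j in range(i + 1, len(tips)):
                _, _, sd, nd = (ng86_counts(tips[i], tips[j]))[:4]
                assert nd == 0.0

    def test_neutral_ng86_estimates_bracket_one(self):
        # at kappa=1 the NG86 site convention matches the uniform GY94
        # generator; instantaneous expectation is 1.0014 (flux/site ratio)
        t2 = PhyloTree.from_newick("(a:0.15,b:0.15);")
        est = []
        for s in range(5):
            sim = simulate_codon_alignment(t2, 3000, kappa=1.0, omega_map=1.0,
                                           seed=s)
            est.append(ng86_pairwise(sim.tip_seqs["a"], sim.tip_seqs["b"])[2])
        assert min(est) < 1.0 < max(est) or abs(np.mean(est) - 1.0) < 0.05

    def test_unknown_branch_name_rejected(self, codon_tree):
        with pytest.raises(ValueError, match="absent"):
            simulate_codon_alignment(codon_tree, 10, omega_map={"dodo": 2.0})


class TestFamilySimulator:
    def test_lambda_zero_freezes_counts_at_root_size(self, time_tree):
        counts, _ = simulate_family_counts(time_tree, 0.0, 20,
                                           root_size_range=(3, 9), seed=1)
        assert (counts.nunique(axis=1) == 1).all()
        assert counts.min().min() >= 3 and counts.max().max() <= 9

    def test_equal_rate_chain_is_a_martingale(self, time_tree):
        counts, _ = simulate_family_counts(time_tree, 0.002, 500,
                                           root_size_range=(1, 10), seed=8)
        mean_tip = counts.to_numpy().mean()
        mean_root = 5.5
        # Monte-Carlo oracle: SE of the mean tip count over 500 families
        se = counts.to_numpy().mean(axis=1).std(ddof=1) / np.sqrt(len(counts))
        assert abs(mean_tip - mean_root) <= 3 * se

    def test_planted_jump_bookkeeping(self, time_tree):
        planted = {(0, "kiwi"): 5}
        counts, truth = simulate_family_counts(
            time_tree, 0.002, 5, root_size_range=(5, 8), seed=3,
            planted_events=planted)
        assert truth.planted_family_events == {("fam0000", "kiwi"): 5}
        # deterministic jump: kiwi count = its parent's simulated count + 5
        parent_label = time_tree.tree.labels[
            time_tree.tree.parent[time_tree.tree.tip_index("kiwi")]
        ]
        parent_count = truth.extra["internal_counts"][0][parent_label]
        assert counts.loc["fam0000", "kiwi"] - parent_count == 5

    def test_no_family_extinct_everywhere(self, time_tree):
        counts, _ = simulate_family_counts(time_tree, 0.01, 100,
                                           root_size_range=(1, 2), seed=5)
        assert (counts.sum(axis=1) > 0).all()

    def test_empty_root_range_rejected(self, time_tree):
        with pytest.raises(ValueError):
            simulate_family_counts(time_tree, 0.002, 5, root_size_range=(5, 4))

    def test_gillespie_absorbs_at_zero(self, rng):
        assert gillespie_bdi(0, 100.0, 0.5, rng) == 0


class TestSimilarityGraph:
    def test_noise_free_components_equal_planted_families(self):
        members = {f"s{i}|g{j}": f"F{j}" for i in range(3) for j in range(4)}
        edges = simulate_similarity_graph(members, seed=1, between_noise_rate=0.0)
        import networkx as nx  # test-only dependency for the component oracle

        g = nx.Graph()
        g.add_nodes_from(members)
        g.add_edges_from(zip(edges["qseqid"], edges["sseqid"]))
        comps = {frozenset(c) for c in nx.connected_components(g)}
        planted = {frozenset(k for k, v in members.items() if v == f)
                   for f in set(members.values())}
        assert comps == planted

    def test_within_family_evalues_below_threshold(self):
        members = {f"s{i}|g{j}": f"F{j}" for i in range(3) for j in range(3)}
        edges = simulate_similarity_graph(members, seed=2, between_noise_rate=0.2)
        fam = {g: members[g] for g in members}
        within = edges[[fam[q] == fam[s] for q, s in
                        zip(edges["qseqid"], edges["sseqid"])]]
        between = edges[[fam[q] != fam[s] for q, s in
                         zip(edges["qseqid"], edges["sseqid"])]]
        assert (within["evalue"] < 1e-5).all()
        assert (between["evalue"] > 1e-5).all()

    def test_same_seed_gives_byte_identical_tsv(self, tmp_path):
        members = {f"s{i}|g{j}": f"F{j}" for i in range(2) for j in range(3)}
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_blast_tsv(simulate_similarity_graph(members, seed=9), p1)
        write_blast_tsv(simulate_similarity_graph(members, seed=9), p2)
        assert p1.read_bytes() == p2.read_bytes()
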