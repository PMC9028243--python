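"""End-to-end orchestration of the comparative-genomics pipeline.

A run either consumes a pre-built input bundle or simulates one with known
ground truth, then executes: proteome filtering -> MCL ortholog clustering
-> family classification and single-copy extraction -> per-gene ancestral
reconstruction and convergent-site calling (with the random-trio control)
-> per-gene branch-site and two-ratio selection tests -> birth-death
family-size evolution on the count table -> enrichment of the result gene
sets -> summary reports (per-species category tallies, per-branch
expansion/contraction counts, the selected-gene Venn counts and the
omega-difference ranking).

All randomness flows from one integer seed through a fixed spawn order, and
every output is plain TSV/JSON with fixed formatting, so identical configs
reproduce identical bytes.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .asr import ProteinGammaModel, fit_branch_lengths_and_alpha, marginal_ancestral_states, strip_gap_columns
from .convergence import (
    PRESET_CONTROL_TRIO,
    detect_convergent_sites,
    random_trio_control,
    summarize_convergent_genes,
)
from .enrichment import TermMap, hypergeom_enrich
from .genefam import analyze_family_evolution
from .io import read_fasta, write_fasta, write_newick, write_proteome_fasta
from .orthology import extract_single_copy, filter_proteome, mcl_cluster
from .selection import branch_site_lrt, group_omega_difference
from .simulate import (
    SimTruth,
    inject_convergent_sites,
    simulate_codon_alignment,
    simulate_family_counts,
    simulate_protein_alignment,
    simulate_similarity_graph,
    write_blast_tsv,
)
from .trees import make_default_tree


@dataclass
class Thresholds:
    lrt_p: float = 0.05
    omega_diff_p: float = 0.01
    family_p: float = 0.05
    viterbi_p: float = 0.05
    enrich_q: float = 0.05

    def __post_init__(self):
        for name, v in asdict(self).items():
            if not 0 < v < 1:
                raise ValueError(f"threshold {name} must lie in (0, 1)")


@dataclass
class RunConfig:
    """Study configuration for a synthetic end-to-end run."""

    out_dir: str = "run"
    seed: int = 1
    # synthetic bundle sizes
    n_single_copy: int = 8
    protein_length: int = 300
    codon_length: int = 150
    shift_codon_length: int = 300
    convergent_genes: int = 3
    convergent_sites_per_gene: int = 4
    positive_genes: int = 2
    positive_omega2: float = 4.0
    positive_fraction: float = 0.15
    shift_genes: int = 2
    omega_tg: float = 0.8
    omega_bg: float = 0.2
    base_omega: float = 0.3
    kappa: float = 2.0
    alpha: float = 0.7
    seq_branch_length: float = 0.05
    codon_branch_length: float = 0.2
    tree_depth: float = 111.0
    n_count_families: int = 80
    family_lambda: float = 0.002
    root_size_range: tuple = (4, 12)
    planted_family_events: tuple = ((0, "mallard", 8), (1, "egret", -6))
    # analysis settings
    n_montecarlo: int = 200
    selection_n_starts: int = 1
    m0_maxiter: int = 80
    min_anc_posterior: float = 0.8
    ancestor_mode: str = "all"
    trio: tuple = tuple(sorted(PRESET_CONTROL_TRIO))
    thresholds: Thresholds = field(default_factory=Thresholds)

    def __post_init__(self):
        if isinstance(self.thresholds, dict):
            self.thresholds = Thresholds(**self.thresholds)


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, float_format="%.6g", index=False):
    df.to_csv(path, sep="\t", float_format=float_format, index=index)


# --------------------------------------------------------------------------
# synthetic input bundle
# --------------------------------------------------------------------------

def simulate_bundle(config: RunConfig, out: Path) -> dict:
    """Write every pipeline input under ``out`` and return the ground truth."""
    rng_root = np.random.SeedSequence(config.seed)
    seeds = rng_root.spawn(8)
    seed_int = lambda ss: int(ss.generate_state(1)[0] % (2**31 - 1))

    tree_seq = make_default_tree("sequence", branch_length=config.seq_branch_length)
    tree_codon = make_default_tree("sequence", branch_length=config.codon_branch_length)
    tree_time = make_default_tree("time", depth=config.tree_depth)
    species = list(tree_seq.tree.tip_labels)
    write_newick(tree_seq.tree, out / "tree_sequence.nwk")
    write_newick(tree_codon.tree, out / "tree_codon.nwk")
    write_newick(tree_time.tree, out / "tree_time.nwk")

    truth = SimTruth(family_lambda=config.family_lambda)
    genes = [f"g{i:02d}" for i in range(config.n_single_copy)]
    conv_genes = genes[: config.convergent_genes]
    pos_genes = genes[config.convergent_genes:
                      config.convergent_genes + config.positive_genes]
    shift_genes = genes[config.convergent_genes + config.positive_genes:
                        config.convergent_genes + config.positive_genes
                        + config.shift_genes]
    if len(shift_genes) < config.shift_genes:
        raise ValueError("n_single_copy too small for the planted gene classes")

    # --- protein alignments (+ injected convergent sites)
    (out / "alignments").mkdir(exist_ok=True)
    prot_rng = np.random.default_rng(seed_int(seeds[0]))
    for g in genes:
        sim = simulate_protein_alignment(
            tree_seq, config.protein_length, alpha=config.alpha,
            seed=int(prot_rng.integers(0, 2**31 - 1)),
        )
        if g in conv_genes:
            sim, t = inject_convergent_sites(
                sim, tree_seq, config.convergent_sites_per_gene,
                seed=int(prot_rng.integers(0, 2**31 - 1)),
            )
            truth.convergent_site_indices[g] = t.convergent_site_indices["__alignment__"]
        write_fasta(sim.tip_seqs, out / "alignments" / f"prot_{g}.fasta")
        write_fasta(sim.anc_seqs, out / "alignments" / f"prot_{g}_ancestors.fasta")

    # --- codon alignments with planted selection regimes
    cod_rng = np.random.default_rng(seed_int(seeds[1]))
    fg_names = sorted(tree_seq.foreground_tips)
    for g in genes:
        s1 = int(cod_rng.integers(0, 2**31 - 1))
        s2 = int(cod_rng.integers(0, 2**31 - 1))
        if g in pos_genes:
            n_sel = int(round(config.codon_length * config.positive_fraction))
            base = simulate_codon_alignment(
                tree_codon, config.codon_length - n_sel, kappa=config.kappa,
                omega_map=config.base_omega, seed=s1)
            omega_map = {t: config.positive_omega2 for t in fg_names}
            omega_map["default"] = config.base_omega
            sel = simulate_codon_alignment(
                tree_codon, n_sel, kappa=config.kappa, omega_map=omega_map, seed=s2)
            seqs = {k: base.tip_seqs[k] + sel.tip_seqs[k] for k in base.tip_seqs}
            truth.foreground_omega[g] = config.positive_omega2
            truth.background_omega[g] = config.base_omega
        elif g in shift_genes:
            omega_map = {t: config.omega_tg for t in fg_names}
            omega_map["default"] = config.omega_bg
            sim = simulate_codon_alignment(
                tree_codon, config.shift_codon_length, kappa=config.kappa,
                omega_map=omega_map, seed=s1)
            seqs = sim.tip_seqs
            truth.foreground_omega[g] = config.omega_tg
            truth.background_omega[g] = config.omega_bg
        else:
            sim = simulate_codon_alignment(
                tree_codon, config.codon_length, kappa=config.kappa,
                omega_map=config.base_omega, seed=s1)
            seqs = sim.tip_seqs
            truth.foreground_omega[g] = config.base_omega
            truth.background_omega[g] = config.base_omega
        write_fasta(seqs, out / "alignments" / f"codon_{g}.fasta")

    # --- proteomes: single-copy genes + a multi-copy family + a unique
    # family + unclustered genes + records exercising the filters
    filler_rng = np.random.default_rng(seed_int(seeds[2]))
    mc = simulate_protein_alignment(tree_seq, 60, alpha=1.0,
                                    seed=int(filler_rng.integers(0, 2**31 - 1)))
    unc = simulate_protein_alignment(tree_seq, 50, alpha=1.0,
                                     seed=int(filler_rng.integers(0, 2**31 - 1)))
    memberships = {}
    for sp in species:
        records = []
        for g in genes:
            aln = read_fasta(out / "alignments" / f"prot_{g}.fasta")
            records.append((g, "t1", aln[sp]))
            memberships[f"{sp}|{g}"] = f"SC_{g}"
        records.append((genes[0], "t0", aln[sp][: config.protein_length // 2]))
        for copyname in ("a", "b"):
            records.append((f"gmc{copyname}", "t1", mc.tip_seqs[sp]))
            memberships[f"{sp}|gmc{copyname}"] = "MC0"
        records.append(("gunc", "t1", unc.tip_seqs[sp]))
        records.append(("gshort", "t1", "MKLV"))
        records.append(("gstop", "t1", "MKLV" + "A" * 40 + "*" + "KL" * 20))
        if sp == "mallard":
            for i in range(4):
                records.append((f"guq{i}", "t1", unc.tip_seqs[sp][::-1]))
                memberships[f"{sp}|guq{i}"] = "UQ0"
        write_proteome_fasta(sp, records, out / f"proteome_{sp}.fasta")

    edges = simulate_similarity_graph(memberships, seed=seed_int(seeds[3]))
    write_blast_tsv(edges, out / "edges.tsv")

    # --- family count table with planted jumps
    planted = {(f, b): j for f, b, j in config.planted_family_events}
    counts, fam_truth = simulate_family_counts(
        tree_time, config.family_lambda, config.n_count_families,
        root_size_range=tuple(config.root_size_range),
        seed=seed_int(seeds[4]), planted_events=planted,
    )
    counts.to_csv(out / "counts.tsv", sep="\t")
    truth.planted_family_events = fam_truth.planted_family_events
    truth.extra["count_redraws"] = fam_truth.extra["redraws"]

    # --- term map over the single-copy genes
    term_rng = np.random.default_rng(seed_int(seeds[5]))
    terms = {
        "T:CONV": set(conv_genes),
        "T:SEL": set(pos_genes) | set(shift_genes),
    }
    for i in range(3):
        size = max(2, len(genes) // 3)
        terms[f"T:RAND{i}"] = set(
            term_rng.choice(genes, size=size, replace=False).tolist()
        )
    tm = TermMap(
        terms=terms,
        names={"T:CONV": "planted convergence set", "T:SEL": "planted selection set",
               "T:RAND0": "random set 0", "T:RAND1": "random set 1",
               "T:RAND2": "random set 2"},
        categories={t: "Synthetic" for t in terms},
    )
    tm.to_tsv(out / "terms.tsv")

    truth.extra["genes"] = genes
    truth.extra["conv_genes"] = conv_genes
    truth.extra["pos_genes"] = pos_genes
    truth.extra["shift_genes"] = shift_genes
    with open(out / "truth.json", "w") as f:
        json.dump(
            {
                "convergent_site_indices": truth.convergent_site_indices,
                "foreground_omega": truth.foreground_omega,
                "background_omega": truth.background_omega,
                "family_lambda": truth.family_lambda,
                "planted_family_events": {
                    f"{fam}:{br}": j
                    for (fam, br), j in truth.planted_family_events.items()
                },
                "extra": {k: v for k, v in truth.extra.items()
                          if k != "internal_counts"},
            },
            f, indent=1, sort_keys=True,
        )
    return {"truth": truth, "tree_seq": tree_seq, "tree_codon": tree_codon,
            "tree_time": tree_time,
            "genes": genes, "species": species}


# --------------------------------------------------------------------------
# stages
# --------------------------------------------------------------------------

def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage; returns the manifest (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    inputs = out / "inputs"
    inputs.mkdir(exist_ok=True)
    manifest = {
        "package": "convphy",
        "version": __version__,
        "seed": config.seed,
        "config": json.loads(json.dumps(asdict(config), default=list)),
        "stages": {},
        "files": {},
    }
    stage = "simulate"
    try:
        bundle = simulate_bundle(config, inputs)
        tree_seq, tree_time = bundle["tree_seq"], bundle["tree_time"]
        tree_codon = bundle["tree_codon"]
        genes, species = bundle["genes"], bundle["species"]
        truth = bundle["truth"]
        manifest["stages"]["simulate"] = {
            "species": len(species), "foreground": len(tree_seq.foreground_tips),
            "genes": len(genes),
        }

        # ---- orthology
        stage = "orthology"
        odir = out / "orthology"
        odir.mkdir(exist_ok=True)
        kept_genes = []
        filter_counts = {}
        from .io import read_proteome_fasta

        for sp in species:
            spname, triples = read_proteome_fasta(inputs / f"proteome_{sp}.fasta")
            prot = filter_proteome(spname, triples)
            kept_genes += prot.kept_gene_ids()
            filter_counts[sp] = {
                s: sum(1 for r in prot.records if r.status == s)
                for s in ("kept", "too_short", "internal_stop", "not_longest")
            }
        from .simulate import read_blast_tsv

        edges = read_blast_tsv(inputs / "edges.tsv")
        catalogue = mcl_cluster(edges, genes=kept_genes, species_list=species)
        fam_rows = [
            {"family": f.family_id, "gene": g, "species": g.split("|", 1)[0]}
            for f in catalogue.families for g in sorted(f.members)
        ]
        _write_tsv(pd.DataFrame(fam_rows), odir / "families.tsv")
        _write_tsv(catalogue.tallies.rename_axis("species").reset_index(),
                   odir / "tallies.tsv")
        single_ids = extract_single_copy(catalogue)
        # map MCL families back to the underlying gene symbol (shared across
        # species in the synthetic bundle)
        single_genes = sorted({
            m.split("|", 1)[1]
            for f in catalogue.families if f.family_id in single_ids
            for m in f.members
            if m.split("|", 1)[1] in set(genes)
        })
        manifest["stages"]["orthology"] = {
            "kept_genes": len(kept_genes),
            "families": len(catalogue.families),
            "unclustered": len(catalogue.unclustered),
            "single_copy_families": len(single_ids),
            "filters": filter_counts,
        }

        # ---- ancestral reconstruction + convergence
        stage = "convergence"
        cdir = out / "convergence"
        cdir.mkdir(exist_ok=True)
        dataset = {}
        asr_rows = []
        for g in single_genes:
            aln = read_fasta(inputs / "alignments" / f"prot_{g}.fasta")
            stripped, kept_cols = strip_gap_columns(aln)
            fitted, alpha_hat, _ = fit_branch_lengths_and_alpha(
                tree_seq.tree, stripped)
            model = ProteinGammaModel.jtt(alpha_hat)
            rec = marginal_ancestral_states(fitted, stripped, model,
                                            outgroup=tree_seq.outgroup_tip)
            dataset[g] = (stripped, rec, kept_cols)
            for ni, lab in enumerate(rec.node_labels):
                for j in range(rec.map_codes.shape[1]):
                    asr_rows.append({
                        "gene": g, "node": lab, "site": int(kept_cols[j]),
                        "map_residue": rec.map_residue(lab, j),
                        "posterior": round(float(rec.map_prob[ni, j]), 6),
                        "outgroup_consistent": bool(rec.outgroup_consistent[j]),
                    })
        _write_tsv(pd.DataFrame(asr_rows), out / "asr_reconstruction.tsv")
        all_calls = []
        for g in single_genes:
            stripped, rec, kept_cols = dataset[g]
            all_calls += detect_convergent_sites(
                stripped, rec, tree_seq, gene=g, column_map=kept_cols,
                min_anc_posterior=config.min_anc_posterior,
                ancestor_mode=config.ancestor_mode,
            )
        call_df = pd.DataFrame(
            [{"gene": c.gene, "site": c.column, "fg_residue": c.foreground_residue,
              "bg_residue": c.background_residue,
              "min_anc_posterior": round(c.min_ancestor_posterior, 6)}
             for c in all_calls],
            columns=["gene", "site", "fg_residue", "bg_residue",
                     "min_anc_posterior"],
        )
        _write_tsv(call_df, cdir / "calls.tsv")
        gene_table = summarize_convergent_genes(all_calls)
        _write_tsv(gene_table, cdir / "genes.tsv")
        trio_cmp = random_trio_control(
            dataset, tree_seq, trio=set(config.trio),
            min_anc_posterior=config.min_anc_posterior,
            ancestor_mode=config.ancestor_mode,
        )
        trio_rows = [{
            "trio": "+".join(sorted(trio_cmp.trio)),
            "genes_true_tg": len(trio_cmp.genes_true),
            "genes_trio": len(trio_cmp.genes_trio),
            "overlap_genes": len(trio_cmp.overlap_genes),
            "overlap_sites": trio_cmp.n_shared_sites,
        }]
        _write_tsv(pd.DataFrame(trio_rows), cdir / "trio_comparison.tsv")
        manifest["stages"]["convergence"] = {
            "genes_scanned": len(single_genes),
            "calls": len(all_calls),
            "genes_with_calls": int(len(gene_table)),
            "trio_overlap_genes": len(trio_cmp.overlap_genes),
        }

        # ---- selection
        stage = "selection"
        sdir = out / "selection"
        sdir.mkdir(exist_ok=True)
        sel_rows = []
        for g in single_genes:
            aln = read_fasta(inputs / "alignments" / f"codon_{g}.fasta")
            bs = branch_site_lrt(
                tree_codon, aln, gene=g, n_starts=config.selection_n_starts,
                m0_maxiter=config.m0_maxiter,
                alpha_level=config.thresholds.lrt_p,
            )
            tr = group_omega_difference(
                tree_codon, aln, gene=g, m0_maxiter=config.m0_maxiter,
                alpha_level=config.thresholds.omega_diff_p,
            )
            sel_rows.append({
                "gene": g,
                "lnl_null": round(bs.lnl_null, 6), "lnl_alt": round(bs.lnl_alt, 6),
                "lrt": round(bs.lrt, 6), "lrt_p": round(bs.pvalue, 8),
                "positively_selected": bs.positively_selected,
                "omega_tg": round(tr.omega_tg, 6), "omega_bg": round(tr.omega_bg, 6),
                "omega_diff": round(tr.omega_diff, 6),
                "diff_p": round(tr.diff_pvalue, 8),
                "diff_significant": tr.diff_significant,
            })
        sel_df = pd.DataFrame(sel_rows)
        _write_tsv(sel_df, sdir / "results.tsv")
        manifest["stages"]["selection"] = {
            "genes_tested": len(sel_df),
            "positively_selected": int(sel_df["positively_selected"].sum()),
            "omega_diff_significant": int(sel_df["diff_significant"].sum()),
        }

        # ---- gene-family evolution
        stage = "family_evolution"
        fdir = out / "famevol"
        fdir.mkdir(exist_ok=True)
        counts = pd.read_csv(inputs / "counts.tsv", sep="\t", index_col=0)
        model, fam_results, tally = analyze_family_evolution(
            tree_time, counts, n_montecarlo=config.n_montecarlo,
            seed=config.seed,
            family_alpha=config.thresholds.family_p,
            branch_alpha=config.thresholds.viterbi_p,
        )
        fam_rows = []
        for r in fam_results:
            sig_branches = [b.branch for b in r.branch_results if b.call != "none"]
            fam_rows.append({
                "family": r.family, "loglik": round(r.loglik, 6),
                "family_p": round(r.family_pvalue, 6),
                "significant_branches": ",".join(sig_branches),
            })
        _write_tsv(pd.DataFrame(fam_rows), fdir / "families.tsv")
        _write_tsv(tally.rename_axis("branch").reset_index(),
                   fdir / "branch_tallies.tsv")
        with open(fdir / "model.json", "w") as f:
            json.dump({"lambda": model.lam, "cap": model.cap}, f, sort_keys=True)
        manifest["stages"]["family_evolution"] = {
            "families": len(fam_results),
            "lambda": round(model.lam, 8),
            "families_significant": int(
                sum(r.family_pvalue < config.thresholds.family_p
                    for r in fam_results)
            ),
        }

        # ---- enrichment
        stage = "enrichment"
        edir = out / "enrichment"
        edir.mkdir(exist_ok=True)
        tm = TermMap.from_tsv(inputs / "terms.tsv")
        universe = list(single_genes)
        conv_set = set(gene_table["gene"]) if len(gene_table) else set()
        pos_set = set(sel_df.loc[sel_df["positively_selected"], "gene"])
        for name, gs in (("convergent", conv_set), ("selected", pos_set)):
            table = hypergeom_enrich(gs & set(universe), tm, universe)
            _write_tsv(table, edir / f"enrich_{name}.tsv", float_format="%.6g")
        manifest["stages"]["enrichment"] = {
            "universe": len(universe),
            "convergent_set": len(conv_set),
            "selected_set": len(pos_set),
        }

        # ---- report
        stage = "report"
        rdir = out / "report"
        rdir.mkdir(exist_ok=True)
        diff_set = set(sel_df.loc[sel_df["diff_significant"], "gene"])
        report = write_report(
            rdir,
            tallies=catalogue.tallies,
            branch_tally=tally,
            selected=pos_set,
            omega_diff_genes=diff_set,
            omega_ranking=sel_df[["gene", "omega_diff", "diff_p"]],
        )
        manifest["stages"]["report"] = report
    except Exception as e:  # persist partial manifest, then re-raise
        manifest["failed_stage"] = stage
        with open(out / "manifest.json", "w") as f:
            json.dump(manifest, f, indent=1, sort_keys=True, default=str)
        raise PipelineStageError(stage, e) from e

    for p in sorted(out.rglob("*")):
        if p.is_file() and p.name != "manifest.json":
            manifest["files"][str(p.relative_to(out))] = _sha256(p)
    with open(out / "manifest.json", "w") as f:
        json.dump(manifest, f, indent=1, sort_keys=True, default=str)
    return manifest


def write_report(rdir: Path, tallies, branch_tally, selected,
                 omega_diff_genes, omega_ranking) -> dict:
    """Paper-shaped summary tables.

    (i) per-species five-category tallies; (ii) per-branch
    expansion/contraction counts; (iii) Venn counts between the
    positively-selected and omega-difference gene sets; (iv) genes ranked by
    omega(TG) - omega(BG), descending.
    """
    _write_tsv(tallies.rename_axis("species").reset_index(),
               rdir / "category_tallies.tsv")
    _write_tsv(branch_tally.rename_axis("branch").reset_index(),
               rdir / "branch_changes.tsv")
    a, b = set(selected), set(omega_diff_genes)
    venn = pd.DataFrame([{
        "positively_selected": len(a),
        "omega_diff_significant": len(b),
        "intersection": len(a & b),
    }])
    _write_tsv(venn, rdir / "venn_counts.tsv")
    ranking = omega_ranking.sort_values(
        ["omega_diff", "gene"], ascending=[False, True]
    ).reset_index(drop=True)
    _write_tsv(ranking, rdir / "omega_difference_ranking.tsv")
    return {
        "venn": venn.iloc[0].to_dict(),
        "ranking_rows": int(len(ranking)),
    }
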