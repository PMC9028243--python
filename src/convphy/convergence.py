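"""Convergent amino-acid substitution calling at conservative sites (CCS).

A column is called convergent when (1) every foreground tip carries one
shared residue X, (2) every background tip and the MAP reconstruction of
every inspected ancestral node carry one shared residue Y, and (3) X != Y.
Sites whose reconstruction disagrees with the outgroup are skipped.  The
random-trio control re-runs the caller with an arbitrary species trio as
foreground to gauge how many calls the criteria produce without any planted
biology.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .asr import AncestralReconstruction
from .trees import SpeciesTree


@dataclass
class ConvergentSiteCall:
    gene: str
    column: int  # original alignment coordinates
    foreground_residue: str
    background_residue: str
    ancestors_checked: tuple
    min_ancestor_posterior: float
    criteria: tuple = (True, True, True)


@dataclass
class TrioComparison:
    trio: frozenset
    genes_true: set
    genes_trio: set
    overlap_genes: set
    site_overlap: dict  # gene -> (sites under true TG, sites under trio, shared)

    @property
    def n_shared_sites(self) -> int:
        return sum(len(v[2]) for v in self.site_overlap.values())


def _ancestor_rows(tree: SpeciesTree, mode: str) -> list[int]:
    t = tree.tree
    if mode == "all":
        return list(t.internal_ids())
    if mode == "parents":
        return sorted({int(t.parent[t.tip_index(f)]) for f in tree.foreground_tips})
    raise ValueError(f"unknown ancestor mode {mode!r}")


def detect_convergent_sites(
    alignment: dict[str, str],
    reconstruction: AncestralReconstruction,
    tree: SpeciesTree,
    foreground: set[str] | None = None,
    background: set[str] | None = None,
    gene: str = "gene",
    min_anc_posterior: float = 0.8,
    ancestor_mode: str = "all",
    require_outgroup_consistency: bool = True,
    column_map: np.ndarray | None = None,
) -> list[ConvergentSiteCall]:
    """Apply the three CCS criteria to every column of a gap-free alignment.

    ``ancestor_mode="all"`` (default, the strict reading) requires every
    internal node's MAP residue to match the shared background residue;
    ``"parents"`` only inspects the parent nodes of the foreground branches.
    Ancestral states with MAP posterior below ``min_anc_posterior`` are not
    accepted, so the site cannot be called.  ``column_map`` translates
    stripped-column indices to original alignment coordinates.
    """
    fg = set(foreground) if foreground is not None else set(tree.foreground_tips)
    bg = set(background) if background is not None else set(tree.background_tips)
    if fg & bg:
        raise ValueError(f"foreground and background overlap: {sorted(fg & bg)}")
    t = tree.tree
    anc_rows = _ancestor_rows(
        SpeciesTree(t, frozenset(fg), tree.outgroup_tip), ancestor_mode
    )
    anc_labels = tuple(t.labels[v] for v in anc_rows)
    anc_idx = [reconstruction.node_labels.index(lab) for lab in anc_labels]
    L = reconstruction.map_codes.shape[1]
    if column_map is None:
        column_map = np.asarray(reconstruction.kept_columns)
    from .substitution import AA_ALPHABET

    calls = []
    for j in range(L):
        if require_outgroup_consistency and not reconstruction.outgroup_consistent[j]:
            continue
        fg_res = {alignment[s][j] for s in fg}
        if len(fg_res) != 1:
            continue
        x = next(iter(fg_res))
        bg_res = {alignment[s][j] for s in bg}
        if len(bg_res) != 1:
            continue
        y = next(iter(bg_res))
        anc_codes = reconstruction.map_codes[anc_idx, j]
        anc_probs = reconstruction.map_prob[anc_idx, j]
        if np.any(anc_probs < min_anc_posterior):
            continue
        anc_res = {AA_ALPHABET[int(c)] for c in anc_codes}
        if anc_res != {y}:
            continue
        if x == y:
            continue
        calls.append(
            ConvergentSiteCall(
                gene=gene,
                column=int(column_map[j]),
                foreground_residue=x,
                background_residue=y,
                ancestors_checked=anc_labels,
                min_ancestor_posterior=float(anc_probs.min()),
            )
        )
    return calls


#: the study's explicit control trio
PRESET_CONTROL_TRIO = frozenset({"ibis", "chicken", "tinamou"})


def random_trio_control(
    dataset: dict,
    tree: SpeciesTree,
    trio: set[str] | None = None,
    seed: int = 0,
    **detect_kwargs,
) -> TrioComparison:
    """Re-run the CCS caller with a species trio as ad-hoc foreground.

    ``dataset`` maps gene id to (gap-free alignment, reconstruction,
    column_map-or-None).  The remaining non-outgroup species form the
    background.  When ``trio`` is None, three non-outgroup species are
    drawn with the given seed.  Returns gene-level and site-level overlap
    with the true tactile-foreground run.
    """
    species = [s for s in tree.tree.tip_labels if s != tree.outgroup_tip]
    if trio is None:
        rng = np.random.default_rng(seed)
        trio = set(rng.choice(species, size=3, replace=False).tolist())
    trio = set(trio)
    if len(trio) != 3 or not trio <= set(tree.tree.tip_labels):
        raise ValueError("trio must be three species of the tree")
    if tree.outgroup_tip in trio:
        raise ValueError("the outgroup cannot join a trio: it anchors ancestral polarity")
    rest = set(species) - trio

    def run(fg, bg):
        out = {}
        for gene, (aln, rec, cmap) in dataset.items():
            calls = detect_convergent_sites(
                aln, rec, tree, foreground=fg, background=bg, gene=gene,
                column_map=cmap, **detect_kwargs,
            )
            if calls:
                out[gene] = {c.column for c in calls}
        return out

    true_calls = run(set(tree.foreground_tips), set(tree.background_tips))
    trio_calls = run(trio, rest)
    overlap = set(true_calls) & set(trio_calls)
    site_overlap = {
        g: (sorted(true_calls[g]), sorted(trio_calls[g]),
            sorted(true_calls[g] & trio_calls[g]))
        for g in sorted(overlap)
    }
    return TrioComparison(
        trio=frozenset(trio),
        genes_true=set(true_calls),
        genes_trio=set(trio_calls),
        overlap_genes=overlap,
        site_overlap=site_overlap,
    )


def summarize_convergent_genes(calls) -> pd.DataFrame:
    """Per-gene table: number of called sites and the ascending site list,
    sorted by call count (descending) then gene id."""
    per_gene: dict[str, list[int]] = {}
    for c in calls:
        per_gene.setdefault(c.gene, []).append(c.column)
    rows = [
        {"gene": g, "n_sites": len(sites), "sites": ",".join(map(str, sorted(sites)))}
        for g, sites in per_gene.items()
    ]
    df = pd.DataFrame(rows, columns=["gene", "n_sites", "sites"])
    if len(df):
        df = df.sort_values(["n_sites", "gene"], ascending=[False, True]).reset_index(
            drop=True
        )
    return df
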