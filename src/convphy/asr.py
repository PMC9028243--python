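"""JTT+gamma likelihood and marginal ancestral sequence reconstruction.

Works on gap-free protein alignments over a fixed rooted topology.  Columns
containing gaps or ambiguity codes are removed up front (the column map is
retained so downstream site calls report original coordinates).  Branch
lengths and the gamma shape are fitted by bounded quasi-Newton maximization
of the pruning log-likelihood; because the model is time-reversible the two
branches flanking the root are tied to equal halves of their identifiable
sum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .likelihood import PruningEngine
from .substitution import (
    AA_ALPHABET,
    ReversibleModel,
    discrete_gamma_rates,
    encode_protein,
    jtt_model,
    load_jtt,
)
from .trees import PhyloTree

GAP_CHARS = set("-.*?XBZJUO")

MIN_BRANCH = 1e-8
ALPHA_BOUNDS = (0.05, 50.0)


def strip_gap_columns(alignment: dict[str, str]) -> tuple[dict[str, str], np.ndarray]:
    """Drop every column containing a gap or ambiguity character in any row.

    Returns the stripped alignment and the original 0-based indices of the
    kept columns.
    """
    seqs = list(alignment.values())
    if not seqs:
        raise ValueError("empty alignment")
    L = len(seqs[0])
    if any(len(s) != L for s in seqs):
        raise ValueError("ragged alignment")
    keep = [
        j for j in range(L) if not any(s[j] in GAP_CHARS for s in seqs)
    ]
    kept = np.array(keep, dtype=int)
    out = {k: "".join(v[j] for j in keep) for k, v in alignment.items()}
    return out, kept


@dataclass
class ProteinGammaModel:
    """JTT (optionally +F) with K equal-probability gamma rate categories."""

    base: ReversibleModel
    alpha: float
    n_categories: int = 4

    def __post_init__(self):
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")

    @property
    def rates(self) -> np.ndarray:
        return discrete_gamma_rates(self.alpha, self.n_categories)

    @property
    def weights(self) -> np.ndarray:
        return np.full(self.n_categories, 1.0 / self.n_categories)

    @classmethod
    def jtt(cls, alpha: float = 1.0, n_categories: int = 4,
            observed_frequencies: np.ndarray | None = None) -> "ProteinGammaModel":
        if observed_frequencies is None:
            base = jtt_model()
        else:
            S, _ = load_jtt()
            base = ReversibleModel.from_exchangeabilities(S, observed_frequencies)
        return cls(base=base, alpha=alpha, n_categories=n_categories)

    def with_alpha(self, alpha: float) -> "ProteinGammaModel":
        return ProteinGammaModel(self.base, alpha, self.n_categories)

    def P_stack(self, lengths: np.ndarray) -> np.ndarray:
        """(K, n_nodes, 20, 20) transition matrices, category rates applied."""
        return np.stack([self.base.transitions(lengths * r) for r in self.rates])


def _engine(tree: PhyloTree, alignment: dict[str, str]) -> PruningEngine:
    missing = [t for t in tree.tip_labels if t not in alignment]
    if missing:
        raise ValueError(f"alignment rows missing for tips: {missing}")
    codes = np.stack([encode_protein(alignment[t]) for t in tree.tip_labels])
    return PruningEngine(tree, codes)


def log_likelihood(tree: PhyloTree, alignment: dict[str, str],
                   model: ProteinGammaModel) -> float:
    """Total pruning log-likelihood, gamma categories averaged per site."""
    eng = _engine(tree, alignment)
    P = model.P_stack(tree.lengths)
    return eng.loglik(P, model.weights, model.base.pi)


def fit_branch_lengths_and_alpha(
    tree: PhyloTree,
    alignment: dict[str, str],
    n_categories: int = 4,
    alpha0: float = 1.0,
    observed_frequencies: np.ndarray | None = None,
    gtol: float = 1e-6,
) -> tuple[PhyloTree, float, float]:
    """Maximize the JTT+gamma likelihood over branch lengths and alpha.

    Returns (fitted tree, alpha_hat, log-likelihood).  Root-flanking
    branches are constrained equal (their sum alone is identifiable under a
    reversible model).
    """
    if len(alignment) < 2:
        raise ValueError("need at least two sequences")
    eng = _engine(tree, alignment)
    if eng.L == 0:
        raise ValueError("alignment empty after gap stripping")
    model0 = ProteinGammaModel.jtt(alpha0, n_categories, observed_frequencies)

    root_kids = tree.children[tree.root]
    free = [v for v in tree.branch_ids() if v not in root_kids]
    span0 = max(sum(tree.lengths[c] for c in root_kids), 2 * MIN_BRANCH)

    def unpack(x):
        lengths = np.zeros(tree.n_nodes)
        for i, v in enumerate(free):
            lengths[v] = np.exp(x[i])
        half = np.exp(x[len(free)]) / 2.0
        for c in root_kids:
            lengths[c] = half
        return lengths, np.exp(x[-1])

    def negloglik(x):
        lengths, alpha = unpack(x)
        model = model0.with_alpha(alpha)
        return -eng.loglik(model.P_stack(lengths), model.weights, model0.base.pi)

    x0 = np.concatenate([
        np.log(np.maximum(tree.lengths[free], 10 * MIN_BRANCH)),
        [np.log(span0)],
        [np.log(alpha0)],
    ])
    bounds = (
        [(np.log(MIN_BRANCH), np.log(10.0))] * len(free)
        + [(np.log(2 * MIN_BRANCH), np.log(20.0))]
        + [(np.log(ALPHA_BOUNDS[0]), np.log(ALPHA_BOUNDS[1]))]
    )
    res = minimize(negloglik, x0, method="L-BFGS-B", bounds=bounds,
                   options={"maxiter": 500, "ftol": 1e-12, "gtol": gtol})
    if not np.isfinite(res.fun):
        raise RuntimeError(f"branch-length optimization failed: {res.message}; "
                           f"best parameters {res.x}")
    lengths, alpha = unpack(res.x)
    return tree.with_lengths(lengths), float(alpha), float(-res.fun)


@dataclass
class AncestralReconstruction:
    """Marginal posteriors and MAP states at every internal node.

    ``posteriors`` has shape (n_internal, n_sites, 20) in stripped-column
    coordinates; ``kept_columns`` maps those sites back to the original
    alignment.  ``outgroup_consistent`` flags sites where the MAP state at
    the outgroup's attachment node agrees with the outgroup tip residue
    (all True when no outgroup was supplied).
    """

    tree: PhyloTree
    node_labels: list[str]
    posteriors: np.ndarray
    map_codes: np.ndarray
    map_prob: np.ndarray
    kept_columns: np.ndarray
    outgroup_consistent: np.ndarray
    site_logliks: np.ndarray = field(default=None)

    def map_residue(self, node_label: str, site: int) -> str:
        k = self.node_labels.index(node_label)
        return AA_ALPHABET[int(self.map_codes[k, site])]


def marginal_ancestral_states(
    tree: PhyloTree,
    alignment: dict[str, str],
    model: ProteinGammaModel,
    outgroup: str | None = None,
) -> AncestralReconstruction:
    """Marginal (per-node, per-site) ancestral state posteriors.

    The posterior at node v is proportional to the partial likelihood below
    v times the partial likelihood of the rest of the tree, mixed over the
    gamma categories by their per-site posterior weight.
    """
    eng = _engine(tree, alignment)
    P = model.P_stack(tree.lengths)
    post_pat, site_ll_pat = eng.node_marginals(P, model.weights, model.base.pi)
    post = eng.expand(post_pat)  # (n_int, L, 20)
    site_ll = site_ll_pat[eng.inverse]
    map_codes = post.argmax(axis=2)
    map_prob = np.take_along_axis(post, map_codes[:, :, None], axis=2)[:, :, 0]
    labels = [tree.labels[v] for v in tree.internal_ids()]
    L = post.shape[1]
    if outgroup is not None:
        og = tree.tip_index(outgroup)
        anc = tree.parent[og]
        anc_row = anc - tree.n_tips
        og_codes = encode_protein(alignment[outgroup])
        consistent = map_codes[anc_row] == og_codes
    else:
        consistent = np.ones(L, dtype=bool)
    return AncestralReconstruction(
        tree=tree,
        node_labels=labels,
        posteriors=post,
        map_codes=map_codes,
        map_prob=map_prob,
        kept_columns=np.arange(L),
        outgroup_consistent=consistent,
        site_logliks=site_ll,
    )
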