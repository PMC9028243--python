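"""Codon-level selection inference on the species tree.

Implements the GY94 pruning likelihood with per-branch omega classes and a
branch-site site-class mixture, and the two tests the study applies to every
single-copy gene: the branch-site positive-selection LRT on the common
tactile foreground (Model A vs its omega2=1 null, chi-square with 1 df,
p < 0.05) and the foreground/background omega comparison realized as a
two-ratio vs one-ratio LRT reporting omega(TG), omega(BG) and their
difference (p < 0.01).

Branch lengths and kappa are estimated once per gene under the one-ratio
(M0) model and held fixed in the class fits; the class parameters are then
optimized from several deterministic starts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.stats import chi2

from .codon import encode_codons, f3x4_frequencies, gy94_model
from .likelihood import PruningEngine
from .trees import PhyloTree, SpeciesTree

MIN_BRANCH = 1e-7


@dataclass
class CodonModel:
    """GY94 with one omega per branch class, or a site-class mixture.

    ``components`` is a list of (proportion, {branch_id: omega}) pairs; a
    plain branch model is a single component with proportion 1.
    """

    kappa: float
    pi: np.ndarray
    components: list

    def __post_init__(self):
        w = sum(p for p, _ in self.components)
        if not np.isclose(w, 1.0):
            raise ValueError("mixture proportions must sum to 1")


@dataclass
class SelectionResult:
    gene: str
    lnl_null: float = np.nan
    lnl_alt: float = np.nan
    lrt: float = np.nan
    pvalue: float = np.nan
    omega_tg: float = np.nan
    omega_bg: float = np.nan
    omega_diff: float = np.nan
    diff_pvalue: float = np.nan
    kappa: float = np.nan
    positively_selected: bool = False
    diff_significant: bool = False


def _engine(tree: PhyloTree, alignment: dict[str, str]) -> PruningEngine:
    missing = [t for t in tree.tip_labels if t not in alignment]
    if missing:
        raise ValueError(f"alignment rows missing for tips: {missing}")
    codes = np.stack([encode_codons(alignment[t]) for t in tree.tip_labels])
    return PruningEngine(tree, codes)


def _P_stack(tree: PhyloTree, lengths, model: CodonModel) -> np.ndarray:
    n = 61
    P = np.zeros((len(model.components), tree.n_nodes, n, n))
    cache_model = {}
    cache_P = {}
    for m, (_, omega_of) in enumerate(model.components):
        for v in tree.branch_ids():
            w = float(omega_of[v])
            key = (w, v)
            if key not in cache_P:
                if w not in cache_model:
                    cache_model[w] = gy94_model(model.kappa, w, model.pi)
                cache_P[key] = cache_model[w].transition(float(lengths[v]))
            P[m, v] = cache_P[key]
    return P


def codon_log_likelihood(
    tree: PhyloTree, alignment: dict[str, str], model: CodonModel
) -> float:
    """Pruning log-likelihood of an in-frame codon alignment; site-class
    mixtures are summed at the site level."""
    eng = _engine(tree, alignment)
    weights = np.array([p for p, _ in model.components])
    P = _P_stack(tree, tree.lengths, model)
    return eng.loglik(P, weights, model.pi)


def _uniform_omega(tree: PhyloTree, w: float) -> dict:
    return {v: w for v in tree.branch_ids()}


def fit_m0(
    tree: PhyloTree,
    alignment: dict[str, str],
    kappa0: float = 2.0,
    omega0: float = 0.4,
    maxiter: int = 120,
) -> tuple[PhyloTree, float, float, float]:
    """One-ratio GY94 fit of branch lengths, kappa and omega.

    Returns (fitted tree, kappa, omega, lnL).  Root-flanking branches are
    tied (only their sum is identifiable under a reversible model).
    """
    eng = _engine(tree, alignment)
    pi = f3x4_frequencies(alignment)
    root_kids = tree.children[tree.root]
    free = [v for v in tree.branch_ids() if v not in root_kids]

    def unpack(x):
        lengths = np.zeros(tree.n_nodes)
        lengths[free] = np.exp(x[: len(free)])
        half = np.exp(x[len(free)]) / 2.0
        for c in root_kids:
            lengths[c] = half
        return lengths, np.exp(x[-2]), np.exp(x[-1])

    def nll(x):
        lengths, kappa, omega = unpack(x)
        model = CodonModel(kappa, pi, [(1.0, _uniform_omega(tree, omega))])
        P = _P_stack(tree, lengths, model)
        return -eng.loglik(P, np.array([1.0]), pi)

    x0 = np.concatenate([
        np.log(np.maximum(tree.lengths[free], 1e-3)),
        [np.log(max(2 * np.mean(tree.lengths[free]) if free else 0.1, 2e-3))],
        [np.log(kappa0), np.log(omega0)],
    ])
    bounds = (
        [(np.log(MIN_BRANCH), np.log(30.0))] * len(free)
        + [(np.log(2 * MIN_BRANCH), np.log(60.0))]
        + [(np.log(0.05), np.log(50.0))]
        + [(np.log(1e-4), np.log(30.0))]
    )
    res = minimize(nll, x0, method="L-BFGS-B", bounds=bounds,
                   options={"maxiter": maxiter, "ftol": 1e-10})
    lengths, kappa, omega = unpack(res.x)
    return tree.with_lengths(lengths), float(kappa), float(omega), float(-res.fun)


def _model_a_components(tree, fg, params):
    """Branch-site Model A components from (p0, p1, omega0, omega2).

    Classes: 0 -> omega0 everywhere; 1 -> 1 everywhere; 2a -> omega2 on
    foreground, omega0 on background; 2b -> omega2 on foreground, 1 on
    background.  p2a/p2b split (1-p0-p1) in proportion p0:p1.
    """
    p0, p1, w0, w2 = params
    fg = set(fg)
    bg_of = lambda wbg: {
        v: (w2 if v in fg else wbg) for v in tree.branch_ids()
    }
    p2 = max(1.0 - p0 - p1, 0.0)
    denom = max(p0 + p1, 1e-12)
    return [
        (p0, _uniform_omega(tree, w0)),
        (p1, _uniform_omega(tree, 1.0)),
        (p2 * p0 / denom, bg_of(w0)),
        (p2 * p1 / denom, bg_of(1.0)),
    ]


def _fit_model_a(eng, tree, pi, kappa, lengths, fg, fix_omega2, starts):
    """Maximize the Model A likelihood over (p0, p1, omega0[, omega2])."""

    def unpack(x):
        a, b = x[0], x[1]
        ea, eb = np.exp(a), np.exp(b)
        denom = 1.0 + ea + eb
        p0, p1 = ea / denom, eb / denom
        w0 = np.exp(x[2])
        w2 = 1.0 if fix_omega2 else 1.0 + np.exp(x[3])
        return p0, p1, w0, w2

    def nll(x):
        p0, p1, w0, w2 = unpack(x)
        comps = _model_a_components(tree, fg, (p0, p1, w0, w2))
        model = CodonModel(kappa, pi, comps)
        P = _P_stack(tree, lengths, model)
        w = np.array([p for p, _ in comps])
        s = w.sum()
        if s <= 0:
            return 1e10
        return -eng.loglik(P, w / s, pi)

    best = None
    for x0 in starts:
        x0 = x0 if not fix_omega2 else x0[:3]
        bounds = [(-12, 12), (-12, 12), (np.log(1e-4), 0.0)]
        if not fix_omega2:
            bounds.append((np.log(1e-4), np.log(60.0)))
        res = minimize(nll, x0, method="L-BFGS-B", bounds=bounds,
                       options={"maxiter": 200, "ftol": 1e-10})
        if best is None or res.fun < best.fun:
            best = res
    p0, p1, w0, w2 = unpack(best.x)
    return {
        "lnl": float(-best.fun),
        "p0": float(p0), "p1": float(p1),
        "omega0": float(w0), "omega2": float(w2),
    }


_MODEL_A_STARTS = [
    np.array([0.7, 0.0, np.log(0.2), np.log(3.0)]),
    np.array([0.0, -0.7, np.log(0.05), np.log(0.5)]),
    np.array([1.5, 0.7, np.log(0.5), np.log(9.0)]),
]


def branch_site_lrt(
    tree: SpeciesTree | PhyloTree,
    alignment: dict[str, str],
    foreground_branches: list[int] | None = None,
    gene: str = "gene",
    n_starts: int = 3,
    m0_maxiter: int = 120,
    alpha_level: float = 0.05,
) -> SelectionResult:
    """Branch-site positive-selection test on the foreground branches.

    Fits Model A (site classes 0/1/2a/2b with omega2 >= 1 free on the
    foreground) and its null (omega2 = 1); p-value from chi2 with 1 df on
    the clamped statistic 2*(lnL_alt - lnL_null).
    """
    if isinstance(tree, SpeciesTree):
        fg = foreground_branches or tree.foreground_branch_ids()
        t = tree.tree
    else:
        t = tree
        fg = foreground_branches
    if not fg:
        raise ValueError("foreground branch set must be non-empty")
    eng = _engine(t, alignment)
    pi = f3x4_frequencies(alignment)
    fitted, kappa, _, _ = fit_m0(t, alignment, maxiter=m0_maxiter)
    starts = _MODEL_A_STARTS[: max(1, n_starts)]
    null = _fit_model_a(eng, t, pi, kappa, fitted.lengths, fg, True, starts)
    # seed the alternative from the null optimum (omega2 barely above 1) so
    # the nested-model inequality lnL_alt >= lnL_null holds by construction
    p2 = max(1.0 - null["p0"] - null["p1"], 1e-9)
    null_start = np.array([
        np.log(max(null["p0"], 1e-9) / p2),
        np.log(max(null["p1"], 1e-9) / p2),
        np.log(max(null["omega0"], 1e-4)),
        np.log(1e-4),
    ])
    alt = _fit_model_a(eng, t, pi, kappa, fitted.lengths, fg, False,
                       list(starts) + [null_start])
    lnl_null, lnl_alt = null["lnl"], alt["lnl"]
    if lnl_alt < lnl_null:
        # nested models: alt can never be truly worse; keep the better optimum
        lnl_alt = lnl_null
    lrt = max(2.0 * (lnl_alt - lnl_null), 0.0)
    p = float(chi2.sf(lrt, df=1))
    return SelectionResult(
        gene=gene, lnl_null=lnl_null, lnl_alt=lnl_alt, lrt=lrt, pvalue=p,
        kappa=kappa, positively_selected=p < alpha_level,
    )


def group_omega_difference(
    tree: SpeciesTree | PhyloTree,
    alignment: dict[str, str],
    tg_branches: list[int] | None = None,
    bg_branches: list[int] | None = None,
    gene: str = "gene",
    m0_maxiter: int = 120,
    alpha_level: float = 0.01,
) -> SelectionResult:
    """Two-ratio fit: one omega on the tactile branches, one elsewhere.

    Reports omega(TG), omega(BG), their difference and a chi2(1 df) LRT
    p-value against the one-ratio model.
    """
    if isinstance(tree, SpeciesTree):
        tg = tg_branches or tree.foreground_branch_ids()
        t = tree.tree
    else:
        t = tree
        tg = tg_branches or []
    bg = bg_branches if bg_branches is not None else [
        v for v in t.branch_ids() if v not in set(tg)
    ]
    if set(tg) & set(bg):
        raise ValueError("TG and BG branch sets overlap")
    eng = _engine(t, alignment)
    pi = f3x4_frequencies(alignment)
    fitted, kappa, omega_one, lnl_one = fit_m0(t, alignment, maxiter=m0_maxiter)
    tg = set(tg)

    # two-ratio fit: branch lengths re-optimized jointly with the two
    # omegas (kappa inherited from the one-ratio fit); with lengths free,
    # the nonsynonymous/synonymous composition identifies each omega while
    # the lengths absorb per-branch rate differences
    root_kids = t.children[t.root]
    free = [v for v in t.branch_ids() if v not in root_kids]

    def unpack(x):
        lengths = np.zeros(t.n_nodes)
        lengths[free] = np.exp(x[: len(free)])
        half = np.exp(x[len(free)]) / 2.0
        for c in root_kids:
            lengths[c] = half
        return lengths, np.exp(x[-2]), np.exp(x[-1])

    def nll(x):
        lengths, w_tg, w_bg = unpack(x)
        omega_of = {v: (w_tg if v in tg else w_bg) for v in t.branch_ids()}
        model = CodonModel(kappa, pi, [(1.0, omega_of)])
        P = _P_stack(t, lengths, model)
        return -eng.loglik(P, np.array([1.0]), pi)

    span0 = max(sum(fitted.lengths[c] for c in root_kids), 2 * MIN_BRANCH)
    x0 = np.concatenate([
        np.log(np.maximum(fitted.lengths[free], 1e-4)),
        [np.log(span0)],
        [np.log(max(omega_one, 1e-3))] * 2,
    ])
    bounds = (
        [(np.log(MIN_BRANCH), np.log(30.0))] * len(free)
        + [(np.log(2 * MIN_BRANCH), np.log(60.0))]
        + [(np.log(1e-4), np.log(30.0))] * 2
    )
    res = minimize(nll, x0, method="L-BFGS-B", bounds=bounds,
                   options={"maxiter": m0_maxiter, "ftol": 1e-10})
    _, w_tg, w_bg = unpack(res.x)
    lnl_two = float(-res.fun)
    if lnl_two < lnl_one:
        lnl_two = lnl_one
    lrt = max(2.0 * (lnl_two - lnl_one), 0.0)
    p = float(chi2.sf(lrt, df=1))
    return SelectionResult(
        gene=gene, lnl_null=lnl_one, lnl_alt=lnl_two, lrt=lrt,
        omega_tg=float(w_tg), omega_bg=float(w_bg),
        omega_diff=float(w_tg - w_bg), diff_pvalue=p, kappa=kappa,
        diff_significant=p < alpha_level,
    )
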