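"""Felsenstein pruning over site patterns, generic in the state space.

Used by the amino-acid (20-state JTT+gamma) and codon (61-state GY94)
machinery.  Mixture components (gamma rate categories, branch-site classes)
enter as stacks of per-branch transition matrices with component weights.
Per-node rescaling keeps site likelihoods in range; all bookkeeping is done
on unique site patterns with multiplicities.
"""

from __future__ import annotations

import numpy as np

from .trees import PhyloTree

_TINY = 1e-300


def compress_patterns(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unique alignment columns. Returns (patterns[n_tips, P], counts[P],
    inverse[L]) with ``patterns[:, inverse] == codes``."""
    cols, inverse, counts = np.unique(
        codes.T, axis=0, return_inverse=True, return_counts=True
    )
    return cols.T.copy(), counts.astype(float), inverse


class PruningEngine:
    """Pruning likelihood and marginal posteriors on a fixed tree + data.

    Parameters
    ----------
    tree : PhyloTree
    codes : int array (n_tips, L), state index per tip and column; the row
        order must follow ``tree`` tip ids.
    """

    def __init__(self, tree: PhyloTree, codes: np.ndarray):
        if codes.shape[0] != tree.n_tips:
            raise ValueError("codes rows must match tree tips")
        self.tree = tree
        self.codes = np.asarray(codes, dtype=np.int64)
        self.patterns, self.counts, self.inverse = compress_patterns(self.codes)
        self.n_patterns = self.patterns.shape[1]
        self.L = self.codes.shape[1]

    # ---------------------------------------------------------- down pass
    def _down(self, P: np.ndarray):
        """One mixture component.  P: (n_nodes, S, S) transition matrix on
        the branch above each node (root entry unused).

        Returns (D, msgs, logscale_total) where D[v] are scaled partials at
        internal nodes, msgs[c] the scaled message child c sends its parent,
        and logscale_total the per-pattern sum of scaling logs.
        """
        t = self.tree
        Lp = self.n_patterns
        S = P.shape[-1]
        D = {}
        msgs = {}
        logscale = np.zeros(Lp)
        for v in t.internal_ids():
            prod = np.ones((Lp, S))
            for c in t.children[v]:
                if c < t.n_tips:
                    msg = P[c].T[self.patterns[c], :]  # P[i, x_tip] over i
                else:
                    msg = D[c] @ P[c].T
                msgs[c] = msg
                prod *= msg
            scale = prod.max(axis=1)
            np.maximum(scale, _TINY, out=scale)
            prod /= scale[:, None]
            D[v] = prod
            logscale += np.log(scale)
        return D, msgs, logscale

    # ----------------------------------------------------------- loglik
    def pattern_logliks(self, P: np.ndarray, comp_weights: np.ndarray, pi: np.ndarray):
        """Per-pattern log-likelihoods mixed over components.

        P: (n_comp, n_nodes, S, S); comp_weights sums to 1.
        """
        root = self.tree.root
        per_comp = np.empty((len(comp_weights), self.n_patterns))
        for m in range(len(comp_weights)):
            D, _, logscale = self._down(P[m])
            lik = D[root] @ pi
            per_comp[m] = np.log(np.maximum(lik, _TINY)) + logscale
        mx = per_comp.max(axis=0)
        mixed = mx + np.log(
            np.sum(np.asarray(comp_weights)[:, None] * np.exp(per_comp - mx[None, :]), axis=0)
        )
        return mixed

    def loglik(self, P: np.ndarray, comp_weights: np.ndarray, pi: np.ndarray) -> float:
        return float(np.dot(self.pattern_logliks(P, comp_weights, pi), self.counts))

    # ------------------------------------------------------ marginal ASR
    def node_marginals(self, P: np.ndarray, comp_weights: np.ndarray, pi: np.ndarray):
        """Marginal posterior state distributions at every internal node.

        Returns (post, pattern_logliks): post has shape
        (n_internal, n_patterns, S), rows normalized over states with the
        mixture components integrated out (weighted by per-site category
        posterior); internal node v maps to row v - n_tips.
        """
        t = self.tree
        n_comp = len(comp_weights)
        Lp, S = self.n_patterns, P.shape[-1]
        n_int = t.n_nodes - t.n_tips

        joint = np.zeros((n_comp, n_int, Lp, S))  # scaled M*D per component
        logB = np.zeros((n_comp, n_int, Lp))  # log scale offsets per node
        for m in range(n_comp):
            D, msgs, _ = self._down(P[m])
            # cumulative below-node scale logs
            cb = {v: np.zeros(Lp) for v in range(t.n_nodes)}
            sc_own = {}
            for v in t.internal_ids():
                # recompute own scale factor from unscaled product of msgs
                prod = np.ones((Lp, S))
                for c in t.children[v]:
                    prod *= msgs[c]
                sc = prod.max(axis=1)
                np.maximum(sc, _TINY, out=sc)
                sc_own[v] = np.log(sc)
                cb[v] = sc_own[v] + sum(
                    (cb[c] for c in t.children[v] if c >= t.n_tips), np.zeros(Lp)
                )
            # up pass
            M = {t.root: np.broadcast_to(pi, (Lp, S)).copy()}
            cu = {t.root: np.zeros(Lp)}
            order = [t.root]
            i = 0
            while i < len(order):
                v = order[i]
                i += 1
                kids = t.children[v]
                for c in kids:
                    if c < t.n_tips:
                        continue
                    U = M[v].copy()
                    extra = np.zeros(Lp)
                    for s in kids:
                        if s == c:
                            continue
                        U *= msgs[s]
                        if s >= t.n_tips:
                            extra += cb[s]
                    us = U.max(axis=1)
                    np.maximum(us, _TINY, out=us)
                    U /= us[:, None]
                    M[c] = U @ P[m][c]
                    cu[c] = cu[v] + np.log(us) + extra
                    order.append(c)
            for v in t.internal_ids():
                k = v - t.n_tips
                joint[m, k] = M[v] * D[v]
                logB[m, k] = cu[v] + cb[v]

        # mix components per node/pattern with stable scaling
        post = np.zeros((n_int, Lp, S))
        for k in range(n_int):
            mx = logB[:, k, :].max(axis=0)
            f = np.exp(logB[:, k, :] - mx[None, :])
            mixed = np.einsum("m,mps,mp->ps", np.asarray(comp_weights), joint[:, k], f)
            tot = mixed.sum(axis=1)
            np.maximum(tot, _TINY, out=tot)
            post[k] = mixed / tot[:, None]
        return post, self.pattern_logliks(P, comp_weights, pi)

    def expand(self, per_pattern: np.ndarray) -> np.ndarray:
        """Map a per-pattern array back to original column order (last axis
        indexes patterns)."""
        return np.take(per_pattern, self.inverse, axis=-2 if per_pattern.ndim > 1 else 0)
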