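"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's pruning/recursion code paths: they
build the dense joint distribution over all internal-node states (or
enumerate substitution pathways explicitly) and sum it.
"""

from itertools import permutations

import numpy as np

from convphy.codon import AA_OF, NUCS, SENSE_CODONS, STOP_CODONS


def enum_loglik_3taxon(pi, P_by_node, tips, parent, n_tips=3):
    """Log-likelihood of one site on a rooted 3-taxon tree by dense joint
    enumeration.  Node ids follow the package layout: tips 0..2, internal
    3 (cherry), root 4; ``P_by_node[v]`` is the matrix on the branch above
    v, ``tips[v]`` the observed state.  Works for any state count."""
    S = len(pi)
    cherry_tips = [v for v in range(n_tips) if parent[v] == 3]
    root_tips = [v for v in range(n_tips) if parent[v] == 4]
    # joint[r, u]: root state r, cherry-ancestor state u
    joint = pi[:, None] * P_by_node[3]
    for v in cherry_tips:
        joint = joint * P_by_node[v][None, :, tips[v]]
    for v in root_tips:
        joint = joint * P_by_node[v][:, tips[v]][:, None]
    return float(np.log(joint.sum()))


def enum_loglik_4taxon_balanced(pi, P_by_node, tips):
    """Same, for the balanced rooted 4-taxon tree ((t0,t1),(t2,t3)) with
    internal nodes 4, 5 and root 6 (package id layout)."""
    # joint[r, u, v]: root r, left ancestor u, right ancestor v
    joint = (
        pi[:, None, None]
        * P_by_node[4][:, :, None]
        * P_by_node[5][:, None, :]
    )
    joint = joint * (P_by_node[0][:, tips[0]] * P_by_node[1][:, tips[1]])[None, :, None]
    joint = joint * (P_by_node[2][:, tips[2]] * P_by_node[3][:, tips[3]])[None, None, :]
    return float(np.log(joint.sum()))


def enum_marginals_3taxon(pi, P_by_node, tips, parent):
    """Per-internal-node posterior state distributions for one site on a
    rooted 3-taxon tree, by Bayes rule on the dense joint."""
    S = len(pi)
    cherry_tips = [v for v in range(3) if parent[v] == 3]
    root_tips = [v for v in range(3) if parent[v] == 4]
    joint = pi[:, None] * P_by_node[3]
    for v in cherry_tips:
        joint = joint * P_by_node[v][None, :, tips[v]]
    for v in root_tips:
        joint = joint * P_by_node[v][:, tips[v]][:, None]
    total = joint.sum()
    return joint.sum(axis=0) / total, joint.sum(axis=1) / total  # (cherry, root)


# ---------------------------------------------------------------- NG86

def ng86_site_counts_oracle(codon: str):
    """(S sites, N sites) for one codon: at each position, the fraction of
    the three possible changes that are synonymous, excluding changes to
    stops from the fraction's denominator; N complements to 3."""
    s_total = 0.0
    for p in range(3):
        syn, valid = 0, 0
        for n in NUCS:
            if n == codon[p]:
                continue
            alt = codon[:p] + n + codon[p + 1 :]
            if alt in STOP_CODONS:
                continue
            valid += 1
            if AA_OF[alt] == AA_OF[codon]:
                syn += 1
        if valid:
            s_total += syn / valid
    return s_total, 3.0 - s_total


def ng86_diff_counts_oracle(cod_a: str, cod_b: str):
    """(synonymous, nonsynonymous) difference counts between two codons by
    explicit enumeration of every ordering of the differing positions,
    dropping orderings through stop codons."""
    positions = [k for k in range(3) if cod_a[k] != cod_b[k]]
    if not positions:
        return 0.0, 0.0
    outcomes = []
    for order in permutations(positions):
        cur, sd, nd, ok = cod_a, 0, 0, True
        for p in order:
            nxt = cur[:p] + cod_b[p] + cur[p + 1 :]
            if nxt in STOP_CODONS:
                ok = False
                break
            if AA_OF[cur] == AA_OF[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            outcomes.append((sd, nd))
    if not outcomes:
        return 0.0, float(len(positions))
    return (
        sum(o[0] for o in outcomes) / len(outcomes),
        sum(o[1] for o in outcomes) / len(outcomes),
    )


# ----------------------------------------------------- family birth-death

def enum_family_loglik_3tip(tip_counts, lengths, lam, cap, max_root, trans):
    """Family log-likelihood on a rooted 3-tip tree ((t0,t1),t2) by explicit
    summation over the cherry-ancestor and root counts.

    ``trans(s, c, t)`` supplies transition probabilities (pass the package's
    own scalar function or an independent one); the root is uniform on
    1..max_root and the result is conditioned on >= 1 surviving tip.
    """
    prior = 1.0 / max_root
    like = 0.0
    norm = 0.0
    for r in range(1, max_root + 1):
        for u in range(cap + 1):
            p_path = trans(r, u, lengths[3]) * trans(u, tip_counts[0], lengths[0]) \
                * trans(u, tip_counts[1], lengths[1])
            like += prior * p_path * trans(r, tip_counts[2], lengths[2])
        # survival conditioning: 1 - P(all tips zero | root r)
        dead = 0.0
        for u in range(cap + 1):
            dead += trans(r, u, lengths[3]) * trans(u, 0, lengths[0]) \
                * trans(u, 0, lengths[1])
        dead *= trans(r, 0, lengths[2])
        norm += prior * (1.0 - dead)
    return float(np.log(like) - np.log(norm))
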