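"""Rooted species trees for the seven-bird study design.

The study system is three tactile-foraging birds (northern brown kiwi,
mallard, crested ibis) each paired with a non-tactile sister species
(white-throated tinamou, chicken, little egret), with the common ostrich as
outgroup.  The tactile trio forms the foreground (TG) used by the selection
and convergence analyses; everything else is background (BG).

Trees are stored in an array form convenient for dynamic programming: node
ids are assigned so that tips come first (0..n_tips-1) and internal nodes
follow in postorder, root last, so any loop over ids ``n_tips..n_nodes-1``
visits children before parents.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
import numpy as np

SPECIES = ("ostrich", "kiwi", "tinamou", "chicken", "mallard", "egret", "ibis")
FOREGROUND = frozenset({"kiwi", "mallard", "ibis"})
BACKGROUND = frozenset({"tinamou", "chicken", "egret"})
OUTGROUP = "ostrich"

#: widely accepted topology: palaeognaths (ostrich, kiwi+tinamou) vs
#: neognaths (chicken+mallard, egret+ibis)
DEFAULT_TOPOLOGY = "((ostrich,(kiwi,tinamou)),((chicken,mallard),(egret,ibis)));"

# relative node ages (fraction of root age) for the ultrametric default
_REL_AGES = {
    "root": 1.00,
    "palaeognath": 0.80,
    "kiwi+tinamou": 0.60,
    "neognath": 0.85,
    "chicken+mallard": 0.70,
    "egret+ibis": 0.55,
}


class PhyloTree:
    """Rooted (binary or multifurcating) tree with branch lengths.

    Attributes
    ----------
    n_tips, n_nodes : int
    parent : int array, parent id per node (-1 at root)
    children : list of lists of child ids
    lengths : float array, branch length above each node (0.0 at root)
    labels : list of node labels (tip names; internal nodes auto-named
        ``N<id>`` when the source tree leaves them unnamed)
    """

    def __init__(self, parent, children, lengths, labels, n_tips):
        self.parent = np.asarray(parent, dtype=int)
        self.children = [list(c) for c in children]
        self.lengths = np.asarray(lengths, dtype=float)
        self.labels = list(labels)
        self.n_tips = int(n_tips)
        self.n_nodes = len(self.labels)
        self.root = self.n_nodes - 1
        if np.any(self.lengths[: self.n_nodes - 1] < 0):
            raise ValueError("negative branch length")
        self._tip_index = {self.labels[i]: i for i in range(self.n_tips)}

    # ------------------------------------------------------------------ io
    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        dt = dendropy.Tree.get(data=newick, schema="newick")
        return cls.from_dendropy(dt)

    @classmethod
    def from_dendropy(cls, dt: dendropy.Tree) -> "PhyloTree":
        nodes = list(dt.postorder_node_iter())
        tips = [nd for nd in nodes if nd.is_leaf()]
        internals = [nd for nd in nodes if not nd.is_leaf()]
        order = tips + internals  # tips keep postorder encounter order
        ids = {id(nd): i for i, nd in enumerate(order)}
        parent, children, lengths, labels = [], [], [], []
        for i, nd in enumerate(order):
            parent.append(ids[id(nd.parent_node)] if nd.parent_node else -1)
            children.append([ids[id(c)] for c in nd.child_nodes()])
            lengths.append(nd.edge.length if nd.edge.length is not None else 0.0)
            if nd.is_leaf():
                labels.append(nd.taxon.label.replace(" ", "_"))
            elif nd.label:
                labels.append(nd.label)
            else:
                labels.append(f"N{i}")
        n_tips = len(tips)
        if len(set(labels[:n_tips])) != n_tips:
            raise ValueError("duplicate tip labels")
        return cls(parent, children, lengths, labels, n_tips)

    def to_newick(self) -> str:
        def rec(v: int) -> str:
            if v < self.n_tips:
                core = self.labels[v]
            else:
                core = "(" + ",".join(rec(c) for c in self.children[v]) + ")" + self.labels[v]
            if v == self.root:
                return core
            return f"{core}:{self.lengths[v]:.10g}"

        return rec(self.root) + ";"

    # ------------------------------------------------------------- queries
    def tip_index(self, name: str) -> int:
        return self._tip_index[name]

    @property
    def tip_labels(self):
        return self.labels[: self.n_tips]

    def internal_ids(self):
        return range(self.n_tips, self.n_nodes)

    def branch_ids(self):
        """Every node id with a branch above it (all but the root)."""
        return [v for v in range(self.n_nodes) if v != self.root]

    def depths(self) -> np.ndarray:
        """Root-to-node path lengths."""
        d = np.zeros(self.n_nodes)
        stack = [self.root]
        while stack:
            v = stack.pop()
            for c in self.children[v]:
                d[c] = d[v] + self.lengths[c]
                stack.append(c)
        return d

    def is_ultrametric(self, rel_tol: float = 1e-6) -> bool:
        d = self.depths()[: self.n_tips]
        return bool(np.max(d) - np.min(d) <= rel_tol * max(np.max(d), 1e-300))

    def with_lengths(self, lengths) -> "PhyloTree":
        return PhyloTree(self.parent, self.children, lengths, self.labels, self.n_tips)

    def subtree_tips(self, v: int) -> list[int]:
        if v < self.n_tips:
            return [v]
        out, stack = [], [v]
        while stack:
            u = stack.pop()
            for c in self.children[u]:
                if c < self.n_tips:
                    out.append(c)
                else:
                    stack.append(c)
        return sorted(out)


@dataclass(frozen=True)
class SpeciesTree:
    """A :class:`PhyloTree` plus the TG/BG partition and the outgroup."""

    tree: PhyloTree
    foreground_tips: frozenset = field(default_factory=lambda: FOREGROUND)
    outgroup_tip: str = OUTGROUP

    def __post_init__(self):
        tips = set(self.tree.tip_labels)
        unknown = set(self.foreground_tips) - tips
        if unknown:
            raise ValueError(f"foreground tips not in tree: {sorted(unknown)}")
        if self.outgroup_tip is not None and self.outgroup_tip not in tips:
            raise ValueError(f"outgroup {self.outgroup_tip!r} not in tree")
        if self.outgroup_tip in self.foreground_tips:
            raise ValueError("outgroup may not be a foreground tip")

    @property
    def background_tips(self) -> frozenset:
        return frozenset(
            t
            for t in self.tree.tip_labels
            if t not in self.foreground_tips and t != self.outgroup_tip
        )

    def foreground_branch_ids(self) -> list[int]:
        """Pendant-branch node ids of the foreground tips (the three
        independent tactile branches are terminal branches)."""
        return sorted(self.tree.tip_index(t) for t in self.foreground_tips)


def make_default_tree(
    mode: str,
    depth: float = 111.0,
    branch_length: float = 0.1,
    foreground=FOREGROUND,
    outgroup: str = OUTGROUP,
) -> SpeciesTree:
    """Fixed 7-taxon study tree.

    ``mode="time"`` returns an ultrametric tree of the given root ``depth``
    (time units); ``mode="sequence"`` returns the same topology with every
    branch set to ``branch_length`` expected substitutions/site.
    """
    if mode not in ("time", "sequence"):
        raise ValueError(f"unknown mode {mode!r}: expected 'time' or 'sequence'")
    if mode == "sequence":
        if branch_length < 0:
            raise ValueError("branch_length must be >= 0")
        t = PhyloTree.from_newick(DEFAULT_TOPOLOGY)
        lengths = np.full(t.n_nodes, float(branch_length))
        lengths[t.root] = 0.0
        return SpeciesTree(t.with_lengths(lengths), frozenset(foreground), outgroup)
    if depth <= 0:
        raise ValueError("depth must be > 0")
    a = {k: v * depth for k, v in _REL_AGES.items()}
    nwk = (
        f"((ostrich:{a['palaeognath']:.10g},"
        f"(kiwi:{a['kiwi+tinamou']:.10g},tinamou:{a['kiwi+tinamou']:.10g})"
        f":{a['palaeognath'] - a['kiwi+tinamou']:.10g})"
        f":{a['root'] - a['palaeognath']:.10g},"
        f"((chicken:{a['chicken+mallard']:.10g},mallard:{a['chicken+mallard']:.10g})"
        f":{a['neognath'] - a['chicken+mallard']:.10g},"
        f"(egret:{a['egret+ibis']:.10g},ibis:{a['egret+ibis']:.10g})"
        f":{a['neognath'] - a['egret+ibis']:.10g})"
        f":{a['root'] - a['neognath']:.10g});"
    )
    t = PhyloTree.from_newick(nwk)
    return SpeciesTree(t, frozenset(foreground), outgroup)
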