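"""Synthetic data with known ground truth for the 7-species study design.

Every generator is a pure function of its arguments plus an integer seed
(bit-reproducible).  Together they produce all pipeline inputs: protein
alignments with true ancestral sequences and injected convergent sites,
in-frame codon alignments under branch-specific dN/dS, gene-family count
tables evolved as an equal-rate birth-death chain (exact Gillespie
stepping), and a BLAST-tabular similarity edge table over planted families.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .codon import SENSE_CODONS, decode_codons, gy94_model, uniform_codon_frequencies
from .substitution import decode_protein, discrete_gamma_rates, jtt_model
from .trees import PhyloTree, SpeciesTree


@dataclass
class SimTruth:
    """Ground-truth ledger carried alongside simulated data."""

    convergent_site_indices: dict = field(default_factory=dict)  # gene -> [cols]
    foreground_omega: dict = field(default_factory=dict)  # gene -> omega
    background_omega: dict = field(default_factory=dict)
    family_lambda: float | None = None
    planted_family_events: dict = field(default_factory=dict)  # (family, branch) -> jump
    extra: dict = field(default_factory=dict)


@dataclass
class SimulatedAlignment:
    """Gap-free simulated alignment with true ancestral sequences."""

    tree: PhyloTree
    tip_seqs: dict  # tip label -> str
    anc_seqs: dict  # internal node label -> str
    site_categories: np.ndarray  # gamma category index per site

    @property
    def length(self) -> int:
        return len(next(iter(self.tip_seqs.values())))


def _sample_rows(P_rows: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draw one categorical sample per row of a (n, S) probability array."""
    cum = np.cumsum(P_rows, axis=1)
    cum[:, -1] = 1.0
    u = rng.random(P_rows.shape[0])
    return (u[:, None] > cum).sum(axis=1)


def _evolve_down(tree: PhyloTree, root_codes, models_per_site, rng):
    """Generic top-down CTMC sampling.  ``models_per_site`` maps a node id
    to a list of (site_index_array, transition_matrix)."""
    states = {tree.root: np.asarray(root_codes)}
    order = [tree.root]
    i = 0
    while i < len(order):
        v = order[i]
        i += 1
        for c in tree.children[v]:
            child = np.empty_like(states[v])
            for sites, P in models_per_site(c):
                child[sites] = _sample_rows(P[states[v][sites]], rng)
            states[c] = child
            if c >= tree.n_tips:
                order.append(c)
    return states


def simulate_protein_alignment(
    tree: SpeciesTree | PhyloTree,
    length: int,
    alpha: float = 1.0,
    n_categories: int = 4,
    seed: int = 0,
) -> SimulatedAlignment:
    """Evolve a gap-free protein alignment under JTT + discrete gamma.

    The root sequence is drawn from the JTT stationary frequencies; each
    site draws one of the K equal-probability category rates, and every
    branch applies exp(Q * t * r_k).  True ancestral sequences are kept.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    t = tree.tree if isinstance(tree, SpeciesTree) else tree
    model = jtt_model()
    rates = discrete_gamma_rates(alpha, n_categories)
    rng = np.random.default_rng(seed)
    cats = rng.integers(0, n_categories, size=length)
    root = _sample_rows(np.tile(model.pi, (length, 1)), rng)
    site_groups = [np.flatnonzero(cats == k) for k in range(n_categories)]

    Pcache = {}

    def models(c):
        out = []
        for k in range(n_categories):
            if len(site_groups[k]) == 0:
                continue
            key = (c, k)
            if key not in Pcache:
                Pcache[key] = model.transition(t.lengths[c] * rates[k])
            out.append((site_groups[k], Pcache[key]))
        return out

    states = _evolve_down(t, root, models, rng)
    tips = {t.labels[v]: decode_protein(states[v]) for v in range(t.n_tips)}
    ancs = {t.labels[v]: decode_protein(states[v]) for v in t.internal_ids()}
    return SimulatedAlignment(tree=t, tip_seqs=tips, anc_seqs=ancs, site_categories=cats)


class ConvergenceShortfallError(ValueError):
    """Raised when fewer eligible columns exist than requested."""

    def __init__(self, available: int, requested: int):
        self.available = available
        self.requested = requested
        super().__init__(
            f"only {available} columns eligible for convergent-site injection "
            f"(requested {requested})"
        )


def inject_convergent_sites(
    sim: SimulatedAlignment,
    tree: SpeciesTree,
    n_sites: int,
    seed: int = 0,
) -> tuple[SimulatedAlignment, SimTruth]:
    """Overwrite foreground tips with a shared novel residue at eligible
    columns.

    A column is eligible when every background tip, the outgroup tip and
    every true ancestral sequence already share one residue Y; the three
    foreground tips are then set to a common residue X != Y.  Ancestors are
    left untouched, so all three convergence criteria hold by construction
    whenever the reconstruction recovers the truth.
    """
    if n_sites < 0:
        raise ValueError("n_sites must be >= 0")
    rng = np.random.default_rng(seed)
    truth = SimTruth(convergent_site_indices={"__alignment__": []})
    if n_sites == 0:
        return sim, truth
    t = tree.tree
    conserved_rows = [sim.tip_seqs[b] for b in sorted(tree.background_tips)]
    conserved_rows.append(sim.tip_seqs[tree.outgroup_tip])
    conserved_rows += [sim.anc_seqs[t.labels[v]] for v in t.internal_ids()]
    L = sim.length
    eligible = [
        j
        for j in range(L)
        if len({row[j] for row in conserved_rows}) == 1
    ]
    if len(eligible) < n_sites:
        raise ConvergenceShortfallError(len(eligible), n_sites)
    chosen = sorted(rng.choice(len(eligible), size=n_sites, replace=False).tolist())
    cols = [eligible[i] for i in chosen]
    alphabet = "ARNDCQEGHILKMFPSTWYV"
    new_tips = {k: list(v) for k, v in sim.tip_seqs.items()}
    for j in cols:
        y = conserved_rows[0][j]
        others = [a for a in alphabet if a != y]
        x = others[int(rng.integers(0, len(others)))]
        for fg in tree.foreground_tips:
            new_tips[fg][j] = x
    out = SimulatedAlignment(
        tree=t,
        tip_seqs={k: "".join(v) for k, v in new_tips.items()},
        anc_seqs=dict(sim.anc_seqs),
        site_categories=sim.site_categories,
    )
    truth.convergent_site_indices["__alignment__"] = cols
    return out, truth


def simulate_codon_alignment(
    tree: SpeciesTree | PhyloTree,
    length_codons: int,
    kappa: float = 2.0,
    omega_map: dict | float = 1.0,
    seed: int = 0,
    pi: np.ndarray | None = None,
) -> SimulatedAlignment:
    """Evolve an in-frame codon alignment under GY94 with branch-specific
    omega.

    ``omega_map`` is either one omega for every branch or a mapping from
    branch names (= child node labels) to omega; unnamed branches fall back
    to the entry under ``"default"`` or 1.0.  Stop codons are never emitted
    (61-state chain).
    """
    if length_codons < 1:
        raise ValueError("length_codons must be >= 1")
    if kappa <= 0:
        raise ValueError("kappa must be > 0")
    t = tree.tree if isinstance(tree, SpeciesTree) else tree
    if pi is None:
        pi = uniform_codon_frequencies()
    if isinstance(omega_map, dict):
        known = set(t.labels)
        bad = [k for k in omega_map if k != "default" and k not in known]
        if bad:
            raise ValueError(f"omega_map names absent from the tree: {sorted(bad)}")
        omega_of = {
            v: float(omega_map.get(t.labels[v], omega_map.get("default", 1.0)))
            for v in t.branch_ids()
        }
    else:
        omega_of = {v: float(omega_map) for v in t.branch_ids()}
    if any(w < 0 for w in omega_of.values()):
        raise ValueError("all omega values must be >= 0")

    models = {}
    for w in set(omega_of.values()):
        models[w] = gy94_model(kappa, w, pi)
    rng = np.random.default_rng(seed)
    root = _sample_rows(np.tile(pi, (length_codons, 1)), rng)
    all_sites = np.arange(length_codons)

    Pcache = {}

    def branch_models(c):
        key = c
        if key not in Pcache:
            Pcache[key] = models[omega_of[c]].transition(t.lengths[c])
        return [(all_sites, Pcache[key])]

    states = _evolve_down(t, root, branch_models, rng)
    tips = {t.labels[v]: decode_codons(states[v]) for v in range(t.n_tips)}
    ancs = {t.labels[v]: decode_codons(states[v]) for v in t.internal_ids()}
    return SimulatedAlignment(
        tree=t, tip_seqs=tips, anc_seqs=ancs,
        site_categories=np.zeros(length_codons, dtype=int),
    )


# --------------------------------------------------------------------------
# gene-family birth-death simulation
# --------------------------------------------------------------------------

def gillespie_bdi(n0: int, t: float, lam: float, rng: np.random.Generator) -> int:
    """Exact simulation of a linear birth-death chain with equal per-capita
    birth and death rate lam over time t, started at n0 copies."""
    n = int(n0)
    clock = 0.0
    while n > 0:
        total = 2.0 * lam * n
        if total <= 0:
            break
        clock += rng.exponential(1.0 / total)
        if clock >= t:
            break
        n += 1 if rng.random() < 0.5 else -1
    return n


def simulate_family_counts(
    tree: SpeciesTree | PhyloTree,
    lambda_rate: float,
    n_families: int,
    root_size_range: tuple[int, int] = (1, 10),
    seed: int = 0,
    planted_events: dict | None = None,
) -> tuple[pd.DataFrame, SimTruth]:
    """Evolve gene-family sizes down the time tree.

    Each family draws a root size uniformly from ``root_size_range`` and
    evolves along every branch as an equal-rate birth-death chain simulated
    event by event.  ``planted_events`` maps ``(family_index, branch_name)``
    to an integer jump; on a planted branch the child count is set
    deterministically to ``max(parent + jump, 0)`` in place of stochastic
    evolution, so the jump is recovered exactly in the bookkeeping.
    Families extinct in all species are redrawn; the redraw count is logged
    in the truth ledger.
    """
    if lambda_rate < 0:
        raise ValueError("lambda must be >= 0")
    lo, hi = root_size_range
    if lo > hi or lo < 1:
        raise ValueError("root_size_range must be a nonempty range with lo >= 1")
    t = tree.tree if isinstance(tree, SpeciesTree) else tree
    planted_events = dict(planted_events or {})
    label_of = {t.labels[v]: v for v in t.branch_ids()}
    for (fam, branch) in planted_events:
        if branch not in label_of:
            raise ValueError(f"planted event names unknown branch {branch!r}")
    rng = np.random.default_rng(seed)
    rows = []
    internal_rows = []
    redraws = 0
    fam = 0
    while fam < n_families:
        root_size = int(rng.integers(lo, hi + 1))
        counts = {t.root: root_size}
        order = [t.root]
        i = 0
        while i < len(order):
            v = order[i]
            i += 1
            for c in t.children[v]:
                jump = planted_events.get((fam, t.labels[c]))
                if jump is not None:
                    counts[c] = max(counts[v] + int(jump), 0)
                else:
                    counts[c] = gillespie_bdi(counts[v], t.lengths[c], lambda_rate, rng)
                if c >= t.n_tips:
                    order.append(c)
        tip_counts = [counts[v] for v in range(t.n_tips)]
        if sum(tip_counts) == 0:
            redraws += 1
            continue
        rows.append(tip_counts)
        internal_rows.append({t.labels[v]: counts[v] for v in t.internal_ids()})
        fam += 1
    table = pd.DataFrame(
        rows,
        index=[f"fam{f:04d}" for f in range(n_families)],
        columns=t.tip_labels,
    )
    truth = SimTruth(
        family_lambda=lambda_rate,
        planted_family_events={
            (f"fam{f:04d}", b): j for (f, b), j in planted_events.items()
        },
        extra={"redraws": redraws, "internal_counts": internal_rows},
    )
    return table, truth


# --------------------------------------------------------------------------
# similarity-graph simulation (all-vs-all search stand-in)
# --------------------------------------------------------------------------

BLAST_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def simulate_similarity_graph(
    memberships: dict[str, str],
    seed: int = 0,
    within_evalue_exponents: tuple[float, float] = (20.0, 120.0),
    between_noise_rate: float = 0.01,
    noise_evalue_exponents: tuple[float, float] = (0.0, 4.0),
) -> pd.DataFrame:
    """BLAST-tabular-style edge table over planted gene families.

    Every within-family gene pair gets reciprocal high-scoring hits with
    e-value 10**-u, u drawn from ``within_evalue_exponents`` (all below the
    1e-5 clustering threshold); between-family pairs get reciprocal noise
    hits with probability ``between_noise_rate`` whose e-values 10**-u with
    u in ``noise_evalue_exponents`` all sit above the threshold.
    """
    if not 0 <= between_noise_rate < 1:
        raise ValueError("noise rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    genes = sorted(memberships)
    rows = []

    def hit(a, b, exponent):
        evalue = 10.0 ** (-exponent)
        bitscore = round(30.0 + 2.0 * exponent, 1)
        aln = int(100 + (exponent * 3) % 200)
        pident = round(min(35.0 + exponent * 0.5, 99.9), 1)
        return [a, b, pident, aln, int(aln * (1 - pident / 100)), 0,
                1, aln, 1, aln, evalue, bitscore]

    for i, a in enumerate(genes):
        for b in genes[i + 1 :]:
            if memberships[a] == memberships[b]:
                u = rng.uniform(*within_evalue_exponents)
                rows.append(hit(a, b, u))
                rows.append(hit(b, a, u * (1 + 1e-3)))
            elif between_noise_rate > 0 and rng.random() < between_noise_rate:
                u = rng.uniform(*noise_evalue_exponents)
                rows.append(hit(a, b, u))
                rows.append(hit(b, a, u))
    return pd.DataFrame(rows, columns=BLAST_COLUMNS)


def write_blast_tsv(table: pd.DataFrame, path) -> None:
    """Deterministic 12-column TSV (fixed float formatting)."""
    with open(path, "w") as f:
        for row in table.itertuples(index=False):
            f.write(
                f"{row.qseqid}\t{row.sseqid}\t{row.pident:.1f}\t{row.length}\t"
                f"{row.mismatch}\t{row.gapopen}\t{row.qstart}\t{row.qend}\t"
                f"{row.sstart}\t{row.send}\t{row.evalue:.3e}\t{row.bitscore:.1f}\n"
            )


def read_blast_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", names=BLAST_COLUMNS)
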