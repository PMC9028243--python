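"""Proteome filtering, Markov clustering of the similarity graph, and
gene-family classification.

Mirrors the ortholog-identification stage of the study: transcripts shorter
than 30 residues or containing internal stops are dropped, only the longest
transcript per gene is kept, genes are clustered from an all-vs-all
similarity table (e-value cutoff 1e-5) with MCL at inflation 1.5, and each
species' kept genes are partitioned into single-copy / multiple-copy /
unique / other / unclustered categories.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MIN_PROTEIN_LENGTH = 30
CATEGORIES = ("single_copy", "multiple_copy", "unique", "other", "unclustered")


@dataclass
class ProteinRecord:
    gene: str
    transcript: str
    sequence: str
    status: str = "kept"  # kept | too_short | internal_stop | not_longest


@dataclass
class AnnotatedProteome:
    species: str
    records: list

    @property
    def kept(self) -> list:
        return [r for r in self.records if r.status == "kept"]

    def kept_gene_ids(self) -> list[str]:
        return [f"{self.species}|{r.gene}" for r in self.kept]


def filter_proteome(species: str, records) -> AnnotatedProteome:
    """Apply the length / internal-stop / longest-transcript filters.

    ``records`` yields (gene id, transcript id, amino-acid sequence).
    A trailing ``*`` (translated terminal stop) is tolerated and removed;
    any other ``*`` marks an internal stop.  Among a gene's surviving
    transcripts exactly the longest is kept (ties broken by transcript id
    for determinism).
    """
    seen = set()
    recs = []
    for gene, transcript, seq in records:
        if (gene, transcript) in seen:
            raise ValueError(f"duplicate (gene, transcript) pair: ({gene}, {transcript})")
        seen.add((gene, transcript))
        seq = seq.rstrip("*")
        r = ProteinRecord(gene=gene, transcript=transcript, sequence=seq)
        if "*" in seq:
            r.status = "internal_stop"
        elif len(seq) < MIN_PROTEIN_LENGTH:
            r.status = "too_short"
        recs.append(r)
    by_gene: dict[str, list[ProteinRecord]] = {}
    for r in recs:
        if r.status == "kept":
            by_gene.setdefault(r.gene, []).append(r)
    for gene, cands in by_gene.items():
        best = max(cands, key=lambda r: (len(r.sequence), r.transcript))
        for r in cands:
            if r is not best:
                r.status = "not_longest"
    return AnnotatedProteome(species=species, records=recs)


@dataclass
class GeneFamily:
    family_id: str
    members: list[str]  # gene ids formatted species|gene

    def copy_counts(self, species_list) -> dict[str, int]:
        counts = {s: 0 for s in species_list}
        for g in self.members:
            counts[g.split("|", 1)[0]] += 1
        return counts


@dataclass
class FamilyCatalogue:
    families: list
    unclustered: list[str]
    species_list: list[str]
    tallies: pd.DataFrame | None = None
    iterations: int = 0

    def count_matrix(self) -> pd.DataFrame:
        rows = {
            f.family_id: f.copy_counts(self.species_list) for f in self.families
        }
        return pd.DataFrame.from_dict(rows, orient="index")[self.species_list]


class MCLConvergenceError(RuntimeError):
    def __init__(self, iterations, residual):
        self.iterations = iterations
        self.residual = residual
        super().__init__(
            f"MCL failed to converge in {iterations} iterations "
            f"(last max entry change {residual:.3e})"
        )


def _mcl_matrix(W: np.ndarray, inflation: float, prune: float, tol: float,
                max_iter: int) -> tuple[np.ndarray, int]:
    n = W.shape[0]
    M = W.astype(float).copy()
    # self-loops at the maximum incident weight (standard regularization)
    loops = M.max(axis=0)
    loops[loops <= 0] = 1.0
    np.fill_diagonal(M, loops)
    M /= M.sum(axis=0, keepdims=True)
    for it in range(1, max_iter + 1):
        prev = M
        M = M @ M  # expansion
        np.power(M, inflation, out=M)  # inflation
        M[M < prune] = 0.0
        colsum = M.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        M /= colsum
        residual = np.abs(M - prev).max()
        if residual < tol:
            return M, it
    raise MCLConvergenceError(max_iter, residual)


def _clusters_from_matrix(M: np.ndarray, tau: float = 1e-6) -> list[list[int]]:
    """Read clusters off attractor rows; overlapping attractor supports are
    merged (standard MCL interpretation on the column-stochastic limit)."""
    n = M.shape[0]
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    attractors = [i for i in range(n) if M[i, i] > tau]
    for i in attractors:
        for j in np.flatnonzero(M[i] > tau):
            union(i, int(j))
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return sorted(groups.values(), key=lambda g: (-len(g), g[0]))


def mcl_cluster(
    edges: pd.DataFrame,
    genes: list[str] | None = None,
    inflation: float = 1.5,
    evalue_cutoff: float = 1e-5,
    weight: str = "evalue",
    prune: float = 1e-6,
    tol: float = 1e-8,
    max_iter: int = 200,
    species_list: list[str] | None = None,
) -> FamilyCatalogue:
    """Cluster genes from a 12-column BLAST-tabular edge table with MCL.

    Edge weight is -log10(e-value) capped at 200 (or the bit score with
    ``weight="bitscore"``), averaged over the two hit directions.  Genes in
    ``genes`` with no edge passing the e-value cutoff are reported as
    unclustered; gene ids are expected in ``species|gene`` form.
    """
    if inflation <= 1:
        raise ValueError("inflation must be > 1")
    if weight not in ("evalue", "bitscore"):
        raise ValueError("weight must be 'evalue' or 'bitscore'")
    keep = edges[edges["evalue"] <= evalue_cutoff]
    keep = keep[keep["qseqid"] != keep["sseqid"]]
    pair_w: dict[tuple[str, str], list[float]] = {}
    for q, s, ev, bs in zip(keep["qseqid"], keep["sseqid"], keep["evalue"],
                            keep["bitscore"]):
        if weight == "evalue":
            w = min(-np.log10(max(float(ev), 1e-300)), 200.0) if ev > 0 else 200.0
        else:
            w = float(bs)
        key = (q, s) if q <= s else (s, q)
        pair_w.setdefault(key, []).append(w)
    connected = sorted({g for pair in pair_w for g in pair})
    idx = {g: i for i, g in enumerate(connected)}
    n = len(connected)
    W = np.zeros((n, n))
    for (a, b), ws in pair_w.items():
        w = float(np.mean(ws))
        W[idx[a], idx[b]] = w
        W[idx[b], idx[a]] = w
    if n:
        M, iterations = _mcl_matrix(W, inflation, prune, tol, max_iter)
        clusters = _clusters_from_matrix(M)
    else:
        clusters, iterations = [], 0
    families = [
        GeneFamily(
            family_id=f"F{k:05d}",
            members=sorted(connected[i] for i in cl),
        )
        for k, cl in enumerate(clusters)
    ]
    all_genes = list(genes) if genes is not None else connected
    clustered = {g for f in families for g in f.members}
    unclustered = sorted(set(all_genes) - clustered)
    if species_list is None:
        species_list = sorted({g.split("|", 1)[0] for g in all_genes})
    cat = FamilyCatalogue(
        families=families,
        unclustered=unclustered,
        species_list=list(species_list),
        iterations=iterations,
    )
    cat.tallies = classify_families(cat, cat.species_list)
    return cat


def classify_families(catalogue: FamilyCatalogue, species_list) -> pd.DataFrame:
    """Per-species gene tallies over the five family categories.

    single-copy: gene's family has exactly one member in every species;
    multiple-copy: family present in all species and this species has >= 2
    copies; unique: all family members belong to this species; unclustered:
    gene joined no family; other: remaining clustered genes.  Per species
    the five tallies sum to its kept gene count.
    """
    species_list = list(species_list)
    tallies = pd.DataFrame(
        0, index=species_list, columns=list(CATEGORIES), dtype=int
    )
    for fam in catalogue.families:
        counts = fam.copy_counts(species_list)
        nz = [s for s, c in counts.items() if c > 0]
        in_all = len(nz) == len(species_list)
        single = in_all and all(c == 1 for c in counts.values())
        for s in species_list:
            c = counts[s]
            if c == 0:
                continue
            if single:
                tallies.loc[s, "single_copy"] += c
            elif len(nz) == 1:
                tallies.loc[s, "unique"] += c
            elif in_all and c >= 2:
                tallies.loc[s, "multiple_copy"] += c
            else:
                tallies.loc[s, "other"] += c
    for g in catalogue.unclustered:
        sp = g.split("|", 1)[0]
        if sp in tallies.index:
            tallies.loc[sp, "unclustered"] += 1
    return tallies


def extract_single_copy(catalogue: FamilyCatalogue) -> list[str]:
    """Family ids with exactly one member in every species (1:1 orthologs)."""
    out = []
    for fam in catalogue.families:
        counts = fam.copy_counts(catalogue.species_list)
        if all(c == 1 for c in counts.values()):
            out.append(fam.family_id)
    return out
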