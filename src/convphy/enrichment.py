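"""Over-representation statistics for gene sets against term maps.

One-sided hypergeometric tests (upper tail on the overlap) with
Benjamini-Hochberg control across all tested terms, matching the
q < 0.05 / FDR-style reporting used for GO and KEGG term tables.  The term
databases themselves are user-supplied TSV maps; no ontology propagation is
performed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom


@dataclass
class TermMap:
    """Term-to-gene annotation map.

    ``terms`` maps term id -> set of member gene ids; ``names`` and
    ``categories`` carry the display name and category label (for example
    "Molecular Function") per term id.
    """

    terms: dict
    names: dict = field(default_factory=dict)
    categories: dict = field(default_factory=dict)

    @classmethod
    def from_tsv(cls, path) -> "TermMap":
        """Read a 4-column TSV: term id, term name, category, gene id."""
        df = pd.read_csv(path, sep="\t", header=None,
                         names=["term", "name", "category", "gene"])
        terms: dict = {}
        names: dict = {}
        cats: dict = {}
        for row in df.itertuples(index=False):
            terms.setdefault(row.term, set()).add(row.gene)
            names[row.term] = row.name
            cats[row.term] = row.category
        return cls(terms=terms, names=names, categories=cats)

    def to_tsv(self, path) -> None:
        with open(path, "w") as f:
            for term in sorted(self.terms):
                for gene in sorted(self.terms[term]):
                    f.write(f"{term}\t{self.names.get(term, term)}\t"
                            f"{self.categories.get(term, 'NA')}\t{gene}\n")


def benjamini_hochberg(pvalues: np.ndarray) -> np.ndarray:
    """Step-up BH adjusted q-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(ranked, 1.0)
    return q


def hypergeom_enrich(
    gene_set,
    term_map: TermMap,
    universe,
) -> pd.DataFrame:
    """Per-term enrichment table for ``gene_set`` drawn from ``universe``.

    For a term with K annotated genes in a universe of size M and a query
    of size n overlapping it in k genes, p = P[X >= k] under
    Hypergeom(M, K, n).  Terms with zero overlap report p = 1.  Columns:
    term, name, category, overlap, term_size, p, q; sorted by q then p.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    gene_set = set(gene_set)
    stray = gene_set - universe
    if stray:
        raise ValueError(f"gene set members outside the universe: {sorted(stray)[:5]}")
    M, n = len(universe), len(gene_set)
    rows = []
    for term in sorted(term_map.terms):
        members = term_map.terms[term] & universe
        K = len(members)
        k = len(members & gene_set)
        if K == 0:
            continue
        p = 1.0 if k == 0 else float(hypergeom.sf(k - 1, M, K, n))
        rows.append({
            "term": term,
            "name": term_map.names.get(term, term),
            "category": term_map.categories.get(term, "NA"),
            "overlap": k,
            "term_size": K,
            "p": min(p, 1.0),
        })
    df = pd.DataFrame(rows)
    if len(df):
        df["q"] = benjamini_hochberg(df["p"].to_numpy())
        df = df.sort_values(["q", "p", "term"]).reset_index(drop=True)
    else:
        df["q"] = []
    return df
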