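#!/usr/bin/env python
"""Term enrichment of the detected gene sets.

Tests the convergent-gene set and the positively-selected set against the
synthetic term map with one-sided hypergeometric tests and BH-FDR, the
universe being the single-copy genes.  Tables land in
results/analysis/enrichment/.
"""

from pathlib import Path

import pandas as pd

from convphy.enrichment import TermMap, hypergeom_enrich

IN = Path("results/analysis")
OUT = Path("results/analysis/enrichment")


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    tm = TermMap.from_tsv(IN / "inputs" / "terms.tsv")
    sel = pd.read_csv(IN / "selection" / "results.tsv", sep="\t")
    universe = sorted(sel["gene"])
    sets = {
        "convergent": set(pd.read_csv(IN / "convergence" /
                                      "convergent_genes.tsv", sep="\t")["gene"])
        if (IN / "convergence" / "convergent_genes.tsv").stat().st_size > 20
        else set(),
        "selected": set(sel.loc[sel["positively_selected"], "gene"]),
    }
    for name, gs in sets.items():
        out = hypergeom_enrich(gs & set(universe), tm, universe)
        out.to_csv(OUT / f"enrich_{name}.tsv", sep="\t", index=False)
        hits = out[out["q"] < 0.05] if len(out) else out
        print(f"{name} set ({len(gs)} genes): "
              f"{len(hits)} term(s) at q < 0.05")
        if len(hits):
            print(hits[["term", "name", "overlap", "term_size", "q"]]
                  .to_string(index=False))


if __name__ == "__main__":
    main()
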