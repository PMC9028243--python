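#!/usr/bin/env python
"""Filter the proteomes and cluster the similarity graph into families.

Applies the 30-residue / internal-stop / longest-transcript filters, runs
MCL at inflation 1.5 over edges passing e-value 1e-5, classifies each
species' genes into the five family categories, and extracts the 1:1
single-copy families.  Tables land in results/analysis/orthology/.
"""

from pathlib import Path

import pandas as pd

from convphy.io import read_proteome_fasta
from convphy.orthology import extract_single_copy, filter_proteome, mcl_cluster
from convphy.simulate import read_blast_tsv
from convphy.trees import SPECIES

IN = Path("results/analysis/inputs")
OUT = Path("results/analysis/orthology")


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    kept = []
    for sp in SPECIES:
        species, triples = read_proteome_fasta(IN / f"proteome_{sp}.fasta")
        prot = filter_proteome(species, triples)
        removed = len(prot.records) - len(prot.kept)
        print(f"{sp}: kept {len(prot.kept)} of {len(prot.records)} "
              f"records ({removed} filtered)")
        kept += prot.kept_gene_ids()
    cat = mcl_cluster(read_blast_tsv(IN / "edges.tsv"), genes=kept,
                      species_list=list(SPECIES))
    cat.tallies.rename_axis("species").reset_index().to_csv(
        OUT / "category_tallies.tsv", sep="\t", index=False)
    rows = [{"family": f.family_id, "gene": g}
            for f in cat.families for g in sorted(f.members)]
    pd.DataFrame(rows).to_csv(OUT / "families.tsv", sep="\t", index=False)
    singles = extract_single_copy(cat)
    print(f"{len(cat.families)} families ({len(singles)} single-copy 1:1), "
          f"{len(cat.unclustered)} unclustered genes")
    print(cat.tallies)


if __name__ == "__main__":
    main()
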