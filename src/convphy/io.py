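"""File I/O: FASTA alignments, proteome FASTA with structured ids, trees.

Proteome records use ids formatted ``species|gene|transcript``; alignment
records are keyed by tip label.  Everything is plain text so pipeline runs
diff cleanly.
"""

from __future__ import annotations

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .trees import PhyloTree


def read_fasta(path) -> dict[str, str]:
    """FASTA -> {id: sequence} preserving file order."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path) -> None:
    records = [
        SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_proteome_fasta(path):
    """Yield (gene, transcript, sequence) triples from a
    ``species|gene|transcript``-keyed FASTA; returns (species, triples)."""
    species = None
    triples = []
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.id.split("|")
        if len(parts) != 3:
            raise ValueError(
                f"proteome record id {rec.id!r} not in species|gene|transcript form"
            )
        sp, gene, transcript = parts
        if species is None:
            species = sp
        elif sp != species:
            raise ValueError(f"mixed species in one proteome file: {species}, {sp}")
        triples.append((gene, transcript, str(rec.seq)))
    return species, triples


def write_proteome_fasta(species: str, records, path) -> None:
    seqs = {
        f"{species}|{gene}|{transcript}": seq for gene, transcript, seq in records
    }
    write_fasta(seqs, path)


def read_newick(path) -> PhyloTree:
    with open(path) as f:
        return PhyloTree.from_newick(f.read())


def write_newick(tree: PhyloTree, path) -> None:
    with open(path, "w") as f:
        f.write(tree.to_newick() + "\n")
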