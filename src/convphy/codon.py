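"""Codon-level models: the 61-state GY94 substitution model and NG86 counting.

The sense-codon state space is the standard genetic code minus the three
stop codons (TAA, TAG, TGA).  GY94 rates between codons differing at one
nucleotide are pi_j scaled by kappa for transitions and omega for
nonsynonymous changes; multi-nucleotide changes have rate zero.  The model
is time-reversible for any codon frequency vector, so transition matrices
come from the shared spectral machinery.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import permutations

import numpy as np
from Bio.Data.CodonTable import standard_dna_table

from .substitution import ReversibleModel

NUCS = "TCAG"
STOP_CODONS = tuple(sorted(standard_dna_table.stop_codons))  # TAA, TAG, TGA
SENSE_CODONS = tuple(
    a + b + c
    for a in NUCS
    for b in NUCS
    for c in NUCS
    if a + b + c not in STOP_CODONS
)
CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}
AA_OF = {c: standard_dna_table.forward_table[c] for c in SENSE_CODONS}

_PURINES = {"A", "G"}


def is_transition(n1: str, n2: str) -> bool:
    return n1 != n2 and ((n1 in _PURINES) == (n2 in _PURINES))


@lru_cache(maxsize=1)
def _change_tables():
    """(diff_pos, transition, synonymous) arrays over 61x61 codon pairs;
    diff_pos = -1 where codons differ at != 1 position."""
    n = len(SENSE_CODONS)
    pos = np.full((n, n), -1, dtype=int)
    ts = np.zeros((n, n), dtype=bool)
    syn = np.zeros((n, n), dtype=bool)
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            diffs = [k for k in range(3) if ci[k] != cj[k]]
            if len(diffs) == 1:
                k = diffs[0]
                pos[i, j] = k
                ts[i, j] = is_transition(ci[k], cj[k])
                syn[i, j] = AA_OF[ci] == AA_OF[cj]
    return pos, ts, syn


def gy94_exchangeabilities(kappa: float, omega: float) -> np.ndarray:
    """Symmetric GY94 factor matrix: kappa^(is transition) * omega^(is
    nonsynonymous) on single-nucleotide neighbors, 0 elsewhere."""
    if kappa <= 0 or omega < 0:
        raise ValueError("kappa must be > 0 and omega >= 0")
    pos, ts, syn = _change_tables()
    S = np.where(pos >= 0, 1.0, 0.0)
    S = S * np.where(ts, kappa, 1.0) * np.where(syn, 1.0, omega)
    return S


def neutral_rate_scale(kappa: float, pi: np.ndarray) -> float:
    """Mean instantaneous rate of the neutral (omega=1) GY94 generator."""
    pi = np.asarray(pi, dtype=float)
    pi = pi / pi.sum()
    S = gy94_exchangeabilities(kappa, 1.0)
    Q = S * pi[None, :]
    np.fill_diagonal(Q, 0.0)
    return float(np.dot(pi, Q.sum(axis=1)))


def gy94_model(kappa: float, omega: float, pi: np.ndarray) -> ReversibleModel:
    """Reversible GY94 model on the neutral time scale.

    All (kappa, omega) matrices for a given kappa share the normalization
    constant of the omega=1 model, so one unit of branch length is one
    expected substitution per codon under neutrality and omega > 1 classes
    genuinely evolve faster (the convention of codeml's branch-site
    machinery, which the positive-selection LRT relies on)."""
    return ReversibleModel.from_exchangeabilities(
        gy94_exchangeabilities(kappa, omega),
        np.asarray(pi, dtype=float),
        rate_scale=neutral_rate_scale(kappa, np.asarray(pi, dtype=float)),
    )


def uniform_codon_frequencies() -> np.ndarray:
    return np.full(len(SENSE_CODONS), 1.0 / len(SENSE_CODONS))


def f3x4_frequencies(alignment: dict[str, str], floor: float = 1e-6) -> np.ndarray:
    """F3x4 codon frequencies: products of position-specific nucleotide
    frequencies, restricted to sense codons and renormalized.  Zero
    nucleotide counts are floored before renormalization."""
    counts = np.zeros((3, 4))
    nuc_idx = {n: i for i, n in enumerate(NUCS)}
    for seq in alignment.values():
        if len(seq) % 3:
            raise ValueError("codon sequence length not a multiple of 3")
        for k in range(0, len(seq), 3):
            cod = seq[k : k + 3]
            if "-" in cod or any(n not in nuc_idx for n in cod):
                continue
            for p in range(3):
                counts[p, nuc_idx[cod[p]]] += 1
    freqs = np.maximum(counts, 0.0)
    freqs = freqs / np.maximum(freqs.sum(axis=1, keepdims=True), 1.0)
    freqs = np.maximum(freqs, floor)
    freqs = freqs / freqs.sum(axis=1, keepdims=True)
    pi = np.array(
        [freqs[0, nuc_idx[c[0]]] * freqs[1, nuc_idx[c[1]]] * freqs[2, nuc_idx[c[2]]]
         for c in SENSE_CODONS]
    )
    return pi / pi.sum()


def encode_codons(seq: str) -> np.ndarray:
    if len(seq) % 3:
        raise ValueError("sequence length not a multiple of 3")
    codes = []
    for k in range(0, len(seq), 3):
        cod = seq[k : k + 3]
        if cod in STOP_CODONS:
            raise ValueError(f"stop codon {cod} at nucleotide position {k}")
        if cod not in CODON_INDEX:
            raise ValueError(f"unrecognized codon {cod!r} at position {k}")
        codes.append(CODON_INDEX[cod])
    return np.array(codes, dtype=np.int64)


def decode_codons(codes: np.ndarray) -> str:
    return "".join(SENSE_CODONS[int(c)] for c in codes)


# --------------------------------------------------------------------------
# NG86 (Nei & Gojobori 1986) pairwise dN/dS
# --------------------------------------------------------------------------

@lru_cache(maxsize=1)
def _ng86_site_table() -> np.ndarray:
    """Per-codon (synonymous, nonsynonymous) site counts.

    Each of the 3 positions contributes fractionally: the fraction of the
    three possible nucleotide changes that are synonymous; changes to stop
    codons are excluded from the denominator.
    """
    table = np.zeros((len(SENSE_CODONS), 2))
    for i, cod in enumerate(SENSE_CODONS):
        s = 0.0
        for p in range(3):
            syn = tot = 0
            for n in NUCS:
                if n == cod[p]:
                    continue
                alt = cod[:p] + n + cod[p + 1 :]
                if alt in STOP_CODONS:
                    continue
                tot += 1
                if AA_OF[alt] == AA_OF[cod]:
                    syn += 1
            if tot:
                s += syn / tot
        table[i] = (s, 3.0 - s)
    return table


def _pathway_differences(cod_a: str, cod_b: str) -> tuple[float, float]:
    """Average (synonymous, nonsynonymous) difference counts over all
    orderings of the single-nucleotide steps from cod_a to cod_b, skipping
    orderings that pass through a stop codon."""
    diffs = [k for k in range(3) if cod_a[k] != cod_b[k]]
    if not diffs:
        return 0.0, 0.0
    results = []
    for order in permutations(diffs):
        cur = cod_a
        sd = nd = 0
        ok = True
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
            results.append((sd, nd))
    if not results:  # all pathways blocked by stops: count direct aa change
        return 0.0, float(len(diffs))
    s = sum(r[0] for r in results) / len(results)
    n = sum(r[1] for r in results) / len(results)
    return s, n


NG86_UNDEFINED = float("nan")


def ng86_pairwise(seq_a: str, seq_b: str) -> tuple[float, float, float]:
    """NG86 estimates (dN, dS, omega) for one in-frame codon sequence pair.

    Sites are counted per codon (averaged over the two sequences),
    differences are pathway-averaged, and both proportions receive the
    Jukes-Cantor multiple-hit correction.  omega is NaN when dS is zero or
    a proportion exceeds the JC domain.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences differ in length")
    codes_a, codes_b = encode_codons(seq_a), encode_codons(seq_b)
    table = _ng86_site_table()
    sites = (table[codes_a] + table[codes_b]) / 2.0
    S_sites, N_sites = sites[:, 0].sum(), sites[:, 1].sum()
    Sd = Nd = 0.0
    for ca, cb in zip(codes_a, codes_b):
        if ca == cb:
            continue
        s, n = _pathway_differences(SENSE_CODONS[ca], SENSE_CODONS[cb])
        Sd += s
        Nd += n

    def jc(p):
        if p <= 0:
            return 0.0
        if p >= 0.75:
            return np.inf
        return -0.75 * np.log(1.0 - 4.0 * p / 3.0)

    dS = jc(Sd / S_sites) if S_sites > 0 else 0.0
    dN = jc(Nd / N_sites) if N_sites > 0 else 0.0
    omega = dN / dS if (dS > 0 and np.isfinite(dS) and np.isfinite(dN)) else NG86_UNDEFINED
    return float(dN), float(dS), float(omega)


def ng86_counts(seq_a: str, seq_b: str) -> tuple[float, float, float, float]:
    """Raw NG86 counts (S sites, N sites, synonymous diffs, nonsynonymous
    diffs) before distance correction."""
    codes_a, codes_b = encode_codons(seq_a), encode_codons(seq_b)
    table = _ng86_site_table()
    sites = (table[codes_a] + table[codes_b]) / 2.0
    Sd = Nd = 0.0
    for ca, cb in zip(codes_a, codes_b):
        if ca != cb:
            s, n = _pathway_differences(SENSE_CODONS[ca], SENSE_CODONS[cb])
            Sd += s
            Nd += n
    return float(sites[:, 0].sum()), float(sites[:, 1].sum()), float(Sd), float(Nd)
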