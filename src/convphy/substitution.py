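"""Reversible substitution models and discrete-gamma rate heterogeneity.

The amino-acid model is JTT (Jones-Taylor-Thornton 1992), read from the
packaged table of published exchangeabilities and stationary frequencies.
Rate matrices are normalized to one expected substitution per unit branch
length; transition matrices come from the eigendecomposition of the
pi-symmetrized generator, which is exact for any reversible model.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
from scipy.special import gammainc
from scipy.stats import gamma as _gamma_dist

AA_ALPHABET = "ARNDCQEGHILKMFPSTWYV"
AA_INDEX = {a: i for i, a in enumerate(AA_ALPHABET)}


def load_jtt() -> tuple[np.ndarray, np.ndarray]:
    """Return (S, pi): the symmetric 20x20 JTT exchangeability matrix and
    stationary frequencies, amino acids in order ARNDCQEGHILKMFPSTWYV."""
    text = resources.files("convphy.data").joinpath("jtt.dat").read_text()
    vals = [float(x) for x in text.splitlines() if x and not x.startswith("#")]
    q, pi = np.array(vals[:190]), np.array(vals[190:210])
    S = np.zeros((20, 20))
    iu, ju = np.triu_indices(20, 1)  # ordered by row then column
    S[ju, iu] = q  # fills the lower triangle column-major, matching the table
    S = S + S.T
    pi = pi / pi.sum()
    return S, pi


@dataclass
class ReversibleModel:
    """Time-reversible CTMC over ``n`` states, normalized to mean rate 1.

    Holds the spectral decomposition of the generator so that
    ``P(t) = left @ diag(exp(eigs * t)) @ right`` for any t >= 0.
    """

    pi: np.ndarray
    Q: np.ndarray
    eigs: np.ndarray
    left: np.ndarray
    right: np.ndarray

    @classmethod
    def from_exchangeabilities(
        cls, S: np.ndarray, pi: np.ndarray, rate_scale: float | None = None
    ) -> "ReversibleModel":
        """Build the model; ``rate_scale=None`` self-normalizes to mean rate
        1, a float divides the generator by that constant instead (used to
        put related models on one shared time scale)."""
        pi = np.asarray(pi, dtype=float)
        pi = pi / pi.sum()
        Q = S * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mu = -np.dot(pi, np.diag(Q)) if rate_scale is None else float(rate_scale)
        if mu <= 0:
            raise ValueError("degenerate rate matrix")
        Q = Q / mu
        sq = np.sqrt(pi)
        B = Q * sq[:, None] / sq[None, :]
        B = (B + B.T) / 2.0  # symmetric up to roundoff for reversible Q
        eigs, V = np.linalg.eigh(B)
        left = V / sq[:, None]
        right = V.T * sq[None, :]
        return cls(pi=pi, Q=Q, eigs=eigs, left=left, right=right)

    def transition(self, t: float) -> np.ndarray:
        """P(t); rows sum to 1, entries clipped at 0 against roundoff."""
        P = (self.left * np.exp(self.eigs * t)[None, :]) @ self.right
        np.clip(P, 0.0, None, out=P)
        return P

    def transitions(self, ts: np.ndarray) -> np.ndarray:
        """Stack of P(t) for a vector of times: shape (len(ts), n, n)."""
        ts = np.asarray(ts, dtype=float)
        E = np.exp(np.multiply.outer(ts, self.eigs))  # (m, n)
        P = np.einsum("ij,mj,jk->mik", self.left, E, self.right, optimize=True)
        np.clip(P, 0.0, None, out=P)
        return P


def jtt_model() -> ReversibleModel:
    S, pi = load_jtt()
    return ReversibleModel.from_exchangeabilities(S, pi)


def discrete_gamma_rates(alpha: float, n_categories: int = 4) -> np.ndarray:
    """Mean rates of K equal-probability categories of a Gamma(alpha, mean 1).

    Category k spans quantiles (k/K, (k+1)/K); its mean is
    K * [I(alpha+1, b_{k+1}*alpha) - I(alpha+1, b_k*alpha)] with I the
    regularized lower incomplete gamma and b the category boundaries.
    Rates are rescaled so their mean is exactly 1.
    """
    if alpha <= 0:
        raise ValueError("gamma shape alpha must be > 0")
    if n_categories < 1:
        raise ValueError("need at least one rate category")
    K = int(n_categories)
    if K == 1:
        return np.ones(1)
    bounds = _gamma_dist.ppf(np.arange(1, K) / K, a=alpha, scale=1.0 / alpha)
    upper = np.concatenate([bounds * alpha, [np.inf]])
    lower = np.concatenate([[0.0], bounds * alpha])
    mass = gammainc(alpha + 1.0, np.where(np.isinf(upper), 1e30, upper)) - gammainc(
        alpha + 1.0, lower
    )
    rates = K * mass
    return rates / rates.mean()


def encode_protein(seq: str) -> np.ndarray:
    try:
        return np.array([AA_INDEX[c] for c in seq], dtype=np.int64)
    except KeyError as e:  # pragma: no cover - defensive
        raise ValueError(f"non-standard residue {e.args[0]!r}") from None


def decode_protein(codes: np.ndarray) -> str:
    return "".join(AA_ALPHABET[int(c)] for c in codes)
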