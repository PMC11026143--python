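"""Empirical amino-acid substitution model (Dayhoff) and transition matrices.

The continuous-time Markov chain is parameterized the standard way for
empirical protein models: a symmetric exchangeability matrix ``S`` and
equilibrium frequencies ``pi`` give the rate matrix

    Q_ij = S_ij * pi_j   (i != j),    Q_ii = -sum_{j != i} Q_ij,

rescaled so that the mean instantaneous rate ``-sum_i pi_i Q_ii`` equals 1,
i.e. branch lengths are expected substitutions per site.  The chain is
reversible (detailed balance ``pi_i Q_ij = pi_j Q_ji`` holds by construction),
which lets transition matrices ``P(t) = expm(Q t)`` be computed through a
symmetric eigendecomposition done once per model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["AMINO_ACIDS", "SubstitutionModel", "dayhoff_model", "transition_matrix"]

#: fixed alphabet order (the standard PAML/phylogenetics ordering)
AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"

# Dayhoff exchangeabilities, lower triangle in column-major order over the
# alphabet above: s(R,A), s(N,A), ..., s(V,A), s(N,R), ..., s(V,Y).
# These are the classic published integer rates (identical to PAML's
# dayhoff.dat and to the matrix shipped with R phangorn).
_DAYHOFF_LOWER_COLMAJOR = np.array([
    27, 98, 120, 36, 89, 198, 240, 23, 65, 41, 26, 72, 18, 250, 409, 371, 0,
    24, 208, 32, 0, 23, 246, 1, 9, 240, 64, 15, 464, 90, 14, 103, 154, 26,
    201, 8, 24, 905, 0, 103, 148, 139, 535, 77, 34, 318, 1, 14, 42, 495,
    229, 23, 95, 15, 0, 134, 1153, 125, 86, 24, 0, 71, 0, 0, 13, 95, 66, 0,
    0, 18, 0, 0, 11, 28, 44, 0, 0, 0, 0, 19, 161, 16, 0, 96, 49, 716, 28,
    606, 18, 73, 153, 114, 0, 153, 56, 53, 0, 0, 35, 81, 43, 61, 11, 83, 30,
    0, 51, 79, 34, 0, 22, 37, 10, 0, 7, 27, 17, 15, 34, 234, 30, 0, 0, 54,
    7, 44, 26, 0, 48, 94, 35, 22, 27, 127, 44, 257, 46, 336, 196, 12, 24,
    192, 0, 37, 889, 18, 527, 157, 32, 17, 33, 46, 28, 175, 243, 0, 33, 96,
    136, 0, 13, 10, 92, 17, 62, 104, 0, 0, 258, 11, 46, 13, 76, 698, 12,
    245, 78, 0, 0, 48, 550, 75, 34, 30, 0, 42, 157, 61, 0, 28,
], dtype=float)

# Dayhoff model equilibrium frequencies (same source, same order)
_DAYHOFF_FREQS = np.array([
    0.087126912873087131, 0.040903959096040908, 0.040431959568040438,
    0.046871953128046873, 0.033473966526033475, 0.038254961745038257,
    0.049529950470049530, 0.088611911388088618, 0.033617966382033626,
    0.036885963114036892, 0.085356914643085369, 0.080481919518080480,
    0.014752985247014754, 0.039771960228039777, 0.050679949320050689,
    0.069576930423069588, 0.058541941458058543, 0.010493989506010494,
    0.029915970084029919, 0.064717935282064723,
])


@dataclass(frozen=True)
class SubstitutionModel:
    """A normalized reversible amino-acid rate matrix with its ingredients."""

    alphabet: str
    exchangeabilities: np.ndarray  # (20, 20) symmetric, zero diagonal
    pi: np.ndarray                 # (20,) equilibrium frequencies, sums to 1
    Q: np.ndarray                  # (20, 20) rate matrix, mean rate 1
    # eigendecomposition of the symmetrized generator, for fast expm(Q t):
    # Q = D^{-1/2} U diag(lam) U^T D^{1/2} with D = diag(pi)
    _eigvals: np.ndarray = field(repr=False, default=None)
    _left: np.ndarray = field(repr=False, default=None)   # D^{-1/2} U
    _right: np.ndarray = field(repr=False, default=None)  # U^T D^{1/2}

    @property
    def n_states(self) -> int:
        return len(self.alphabet)

    def encode(self, sequence: str) -> np.ndarray:
        """Map a sequence over the model alphabet to integer state indices."""
        lut = np.full(128, -1, dtype=np.int64)
        for i, aa in enumerate(self.alphabet):
            lut[ord(aa)] = i
        arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
        idx = lut[arr]
        if (idx < 0).any():
            bad = sorted({sequence[i] for i in np.nonzero(idx < 0)[0]})
            raise ValueError(f"symbols outside the model alphabet: {bad}")
        return idx

    def decode(self, states: np.ndarray) -> str:
        return "".join(self.alphabet[s] for s in states)


def _build(exchangeabilities: np.ndarray, pi: np.ndarray, alphabet: str) -> SubstitutionModel:
    S = np.asarray(exchangeabilities, dtype=float)
    pi = np.asarray(pi, dtype=float)
    pi = pi / pi.sum()
    Q = S * pi[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = -np.dot(pi, np.diag(Q))
    Q = Q / mu
    sqrt_pi = np.sqrt(pi)
    B = (sqrt_pi[:, None] * Q) / sqrt_pi[None, :]
    B = 0.5 * (B + B.T)  # symmetric up to rounding
    eigvals, U = np.linalg.eigh(B)
    left = U / sqrt_pi[:, None]
    right = U.T * sqrt_pi[None, :]
    return SubstitutionModel(
        alphabet=alphabet, exchangeabilities=S, pi=pi, Q=Q,
        _eigvals=eigvals, _left=left, _right=right,
    )


def dayhoff_model() -> SubstitutionModel:
    """The Dayhoff empirical model, normalized to one substitution/site/unit time."""
    n = len(AMINO_ACIDS)
    S = np.zeros((n, n))
    idx = 0
    for j in range(n - 1):
        col = _DAYHOFF_LOWER_COLMAJOR[idx : idx + n - 1 - j]
        idx += n - 1 - j
        S[j + 1 :, j] = col
        S[j, j + 1 :] = col
    return _build(S, _DAYHOFF_FREQS, AMINO_ACIDS)


def transition_matrix(model: SubstitutionModel, t: float) -> np.ndarray:
    """Transition probabilities ``P(t) = expm(Q t)`` for branch length ``t``.

    Entries are clipped at zero (eigendecomposition rounding can produce
    values like -1e-17); rows sum to 1 to within ~1e-12.
    """
    t = float(t)
    if not np.isfinite(t) or t < 0:
        raise ValueError(f"branch length must be finite and >= 0, got {t}")
    P = (model._left * np.exp(model._eigvals * t)) @ model._right
    return np.clip(P, 0.0, None)
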