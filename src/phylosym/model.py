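"""The symmetry-preserving topology classifier.

Architecture (per-site weight sharing throughout):

* ``alpha`` — an embedding table mapping each amino acid to an ``m``-vector;
  applied independently at every site of every sequence.
* ``beta`` — a shallow dense residual block ``x + W2 relu(W1 x + b1) + b2``
  applied to every site slice; the symmetric pair map is
  ``beta(alpha(s_i) + alpha(s'_i))``.
* Per-class descriptors — for a class whose tree pairs taxa ``(p, q)`` and
  ``(u, v)``, the descriptor is ``pair(p, q) + pair(u, v)``, an ``L x m``
  array.  Because vector addition commutes, each descriptor is *exactly*
  invariant under within-pair and between-pair swaps, and a permutation of
  the input slots permutes the ``K`` descriptors according to the induced
  action on classes.  Equivariance is therefore architectural: it holds at
  random initialization, bitwise.
* ``psi`` — a stacked LSTM consuming the ``L`` slices in order; the last
  output slice feeds a one-hidden-layer ReLU head producing a scalar score.
  The same ``psi`` scores every class; softmax over the ``K`` scores gives
  class probabilities.

Only the six (quartet) / ten (quintet) unordered pair maps are evaluated per
forward pass and shared across descriptors, which is what makes the model
cheaper than augmenting the training data with all leaf permutations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .autodiff import Tensor
from .io import Alignment
from .substitution import AMINO_ACIDS
from .topology import QUARTET_PAIRS, quintet_class_structure

__all__ = ["Hyperparams", "ScoreVector", "TopologyClassifier",
           "quartet_hyperparams", "quintet_hyperparams", "cross_entropy"]

CLASS_CONVENTION = "phylosym-v1"  # tag stored in checkpoints


@dataclass(frozen=True)
class Hyperparams:
    m: int = 80                   # embedding dimension
    lstm_hidden: int = 20
    lstm_layers: int = 3
    dropout: float = 0.2          # between LSTM layers, training mode only
    head_hidden: int | None = None  # defaults to lstm_hidden
    beta_depth: int = 1           # residual blocks in the slice map

    def __post_init__(self):
        if self.m < 1 or self.lstm_hidden < 1 or self.lstm_layers < 1:
            raise ValueError("dimensions must be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")

    @property
    def head_width(self) -> int:
        return self.head_hidden if self.head_hidden is not None else self.lstm_hidden


def quartet_hyperparams() -> Hyperparams:
    """Defaults used for 4-taxon training (m=80, hidden=20, 3 layers)."""
    return Hyperparams()


def quintet_hyperparams() -> Hyperparams:
    """Defaults used for 5-taxon training (m=160, hidden=40, 6 layers)."""
    return Hyperparams(m=160, lstm_hidden=40, lstm_layers=6)


@dataclass(frozen=True)
class ScoreVector:
    scores: np.ndarray  # (K,) raw scores
    probs: np.ndarray   # (K,) softmax probabilities


def _class_pairs(n_taxa: int) -> list[tuple[tuple[int, int], tuple[int, int]]]:
    if n_taxa == 4:
        return list(QUARTET_PAIRS)
    if n_taxa == 5:
        return [pairs for pairs, _middle in quintet_class_structure()]
    raise ValueError("classifier supports 4 or 5 taxa")


class TopologyClassifier:
    """Permutation-equivariant quartet/quintet topology classifier."""

    def __init__(self, n_taxa: int = 4, hp: Hyperparams | None = None,
                 seed: int = 0, alphabet: str = AMINO_ACIDS):
        if n_taxa not in (4, 5):
            raise ValueError("n_taxa must be 4 or 5")
        self.n_taxa = n_taxa
        self.hp = hp if hp is not None else (
            quartet_hyperparams() if n_taxa == 4 else quintet_hyperparams())
        self.alphabet = alphabet
        self.class_pairs = _class_pairs(n_taxa)
        self.n_classes = len(self.class_pairs)
        self.params: dict[str, Tensor] = {}
        self._init_params(np.random.default_rng(seed))
        self.pair_evals = 0  # count of distinct pair-map evaluations (diagnostics)

    # ------------------------------------------------------------------ setup

    def _param(self, name: str, data: np.ndarray) -> Tensor:
        t = Tensor(data, requires_grad=True)
        self.params[name] = t
        return t

    def _init_params(self, rng: np.random.Generator) -> None:
        hp = self.hp
        m, h = hp.m, hp.lstm_hidden
        self._param("emb", rng.normal(0.0, 1.0, size=(len(self.alphabet), m)))
        for d in range(hp.beta_depth):
            bound = 1.0 / np.sqrt(m)
            self._param(f"beta{d}.W1", rng.uniform(-bound, bound, (m, m)))
            self._param(f"beta{d}.b1", np.zeros(m))
            self._param(f"beta{d}.W2", rng.uniform(-bound, bound, (m, m)))
            self._param(f"beta{d}.b2", np.zeros(m))
        for layer in range(hp.lstm_layers):
            in_dim = m if layer == 0 else h
            bound = 1.0 / np.sqrt(h)
            self._param(f"lstm{layer}.Wx", rng.uniform(-bound, bound, (in_dim, 4 * h)))
            self._param(f"lstm{layer}.Wh", rng.uniform(-bound, bound, (h, 4 * h)))
            self._param(f"lstm{layer}.b", rng.uniform(-bound, bound, 4 * h))
        w = hp.head_width
        bound = 1.0 / np.sqrt(h)
        self._param("head.W1", rng.uniform(-bound, bound, (h, w)))
        self._param("head.b1", np.zeros(w))
        bound = 1.0 / np.sqrt(w)
        self._param("head.W2", rng.uniform(-bound, bound, (w, 1)))
        self._param("head.b2", np.zeros(1))

    # --------------------------------------------------------------- encoding

    def encode(self, sequence: str) -> np.ndarray:
        lut = {aa: i for i, aa in enumerate(self.alphabet)}
        try:
            return np.array([lut[ch] for ch in sequence], dtype=np.int64)
        except KeyError as exc:
            raise ValueError(f"symbol outside the model alphabet: {exc}") from exc

    def encode_batch(self, alignments: list[Alignment]) -> np.ndarray:
        """Stack alignments into a (B, n_taxa, L) integer array."""
        return np.stack([
            np.stack([self.encode(s) for s in a.sequences]) for a in alignments
        ])

    # ------------------------------------------------------------ graph parts

    def _beta(self, x: Tensor) -> Tensor:
        for d in range(self.hp.beta_depth):
            p = self.params
            inner = x.linear(p[f"beta{d}.W1"], p[f"beta{d}.b1"]).relu()
            x = x + inner.linear(p[f"beta{d}.W2"], p[f"beta{d}.b2"])
        return x

    def _pair_maps(self, embedded: dict[int, Tensor]) -> dict[frozenset, Tensor]:
        """beta(alpha(s_i) + alpha(s_j)) for every unordered slot pair, once."""
        out = {}
        for i in range(self.n_taxa):
            for j in range(i + 1, self.n_taxa):
                out[frozenset((i, j))] = self._beta(embedded[i] + embedded[j])
                self.pair_evals += 1
        return out

    def _descriptor_stack(self, idx: np.ndarray) -> Tensor:
        """Per-class descriptors for a batch, concatenated to (K*B, L, m)."""
        embedded = {s: Tensor.embedding(self.params["emb"], idx[:, s, :])
                    for s in range(self.n_taxa)}
        pairs = self._pair_maps(embedded)
        descriptors = [pairs[frozenset(p1)] + pairs[frozenset(p2)]
                       for p1, p2 in self.class_pairs]
        return Tensor.concat(descriptors, axis=0)

    def _lstm(self, x: Tensor, train: bool, rng: np.random.Generator | None) -> Tensor:
        """Run the LSTM stack over axis 1 of (N, L, m); return last hidden state."""
        hp = self.hp
        N, L = x.shape[0], x.shape[1]
        seq = [x[(slice(None), t)] for t in range(L)]
        for layer in range(hp.lstm_layers):
            Wx = self.params[f"lstm{layer}.Wx"]
            Wh = self.params[f"lstm{layer}.Wh"]
            b = self.params[f"lstm{layer}.b"]
            h = Tensor(np.zeros((N, hp.lstm_hidden)))
            c = Tensor(np.zeros((N, hp.lstm_hidden)))
            outputs = []
            for x_t in seq:
                z = x_t.linear(Wx, b) + h.linear(Wh)
                H = hp.lstm_hidden
                i_g = z[(slice(None), slice(0, H))].sigmoid()
                f_g = z[(slice(None), slice(H, 2 * H))].sigmoid()
                g_g = z[(slice(None), slice(2 * H, 3 * H))].tanh()
                o_g = z[(slice(None), slice(3 * H, 4 * H))].sigmoid()
                c = f_g * c + i_g * g_g
                h = o_g * c.tanh()
                outputs.append(h)
            if train and hp.dropout > 0 and layer < hp.lstm_layers - 1:
                outputs = [o.dropout(hp.dropout, rng) for o in outputs]
            seq = outputs
        return seq[-1]

    def _head(self, h: Tensor) -> Tensor:
        p = self.params
        hidden = h.linear(p["head.W1"], p["head.b1"]).relu()
        return hidden.linear(p["head.W2"], p["head.b2"])

    # ---------------------------------------------------------------- forward

    def forward_scores(self, idx: np.ndarray, train: bool = False,
                       rng: np.random.Generator | None = None) -> Tensor:
        """Raw class scores for a batch of index-encoded alignments.

        ``idx`` has shape (B, n_taxa, L); the result is a (B, K) tensor.
        All K descriptors are scored in one batched recurrent pass (the
        cheaper of the two equivalent scoring layouts).
        """
        if idx.ndim != 3 or idx.shape[1] != self.n_taxa:
            raise ValueError(f"expected (B, {self.n_taxa}, L) indices, got {idx.shape}")
        if train and self.hp.dropout > 0 and rng is None:
            raise ValueError("training mode with dropout needs an rng")
        B = idx.shape[0]
        stacked = self._descriptor_stack(idx)               # (K*B, L, m)
        last = self._lstm(stacked, train, rng)              # (K*B, h)
        scores = self._head(last)                           # (K*B, 1)
        return scores.reshape(self.n_classes, B).transpose(1, 0)

    def forward(self, sequences) -> ScoreVector:
        """Score one alignment (list of sequences or :class:`Alignment`)."""
        seqs = sequences.sequences if isinstance(sequences, Alignment) else list(sequences)
        if len(seqs) != self.n_taxa:
            raise ValueError(f"expected {self.n_taxa} sequences, got {len(seqs)}")
        if len({len(s) for s in seqs}) != 1:
            raise ValueError("sequences must have equal lengths")
        idx = np.stack([self.encode(s) for s in seqs])[None]
        scores = self.forward_scores(idx).data[0]
        z = scores - scores.max()
        probs = np.exp(z) / np.exp(z).sum()
        return ScoreVector(scores=scores, probs=probs)

    def predict(self, sequences) -> tuple[int, np.ndarray]:
        """Most probable class (1-based) and the probability vector."""
        sv = self.forward(sequences)
        return int(np.argmax(sv.probs)) + 1, sv.probs

    # -------------------------------------- spec-level operations (eval mode)

    def embed(self, sequence: str) -> np.ndarray:
        """alpha applied per site: (L, m) embedding of one sequence."""
        return self.params["emb"].data[self.encode(sequence)]

    def pair_descriptor(self, s: str, s_prime: str) -> np.ndarray:
        """beta(alpha(s_i) + alpha(s'_i)) per site — symmetric in its arguments."""
        if len(s) != len(s_prime):
            raise ValueError("sequences must have equal lengths")
        x = Tensor(self.embed(s) + self.embed(s_prime))
        return self._beta(x).data

    def descriptors_quartet(self, sA: str, sB: str, sC: str, sD: str):
        return self._descriptors([sA, sB, sC, sD], 4)

    def descriptors_quintet(self, sA: str, sB: str, sC: str, sD: str, sE: str):
        return self._descriptors([sA, sB, sC, sD, sE], 5)

    def _descriptors(self, seqs: list[str], n: int):
        if self.n_taxa != n:
            raise ValueError(f"model was built for {self.n_taxa} taxa")
        if len({len(s) for s in seqs}) != 1:
            raise ValueError("sequences must have equal lengths")
        pairs = {}
        for i in range(n):
            for j in range(i + 1, n):
                pairs[frozenset((i, j))] = self.pair_descriptor(seqs[i], seqs[j])
        return tuple(pairs[frozenset(p1)] + pairs[frozenset(p2)]
                     for p1, p2 in self.class_pairs)

    def score(self, descriptor: np.ndarray) -> float:
        """psi applied to one L x m descriptor (the per-class scoring path)."""
        descriptor = np.asarray(descriptor, dtype=float)
        if descriptor.ndim != 2 or descriptor.shape[1] != self.hp.m:
            raise ValueError(f"descriptor must be (L, {self.hp.m})")
        last = self._lstm(Tensor(descriptor[None]), train=False, rng=None)
        return float(self._head(last).data[0, 0])

    # ------------------------------------------------------------- checkpoint

    def save(self, path: str | Path) -> None:
        path = Path(path)
        meta = {
            "n_taxa": self.n_taxa,
            "hyperparams": asdict(self.hp),
            "alphabet": self.alphabet,
            "class_convention": CLASS_CONVENTION,
        }
        np.savez(path, __meta__=json.dumps(meta),
                 **{k: t.data for k, t in self.params.items()})

    @classmethod
    def load(cls, path: str | Path) -> "TopologyClassifier":
        with np.load(path, allow_pickle=False) as archive:
            meta = json.loads(str(archive["__meta__"]))
            if meta["class_convention"] != CLASS_CONVENTION:
                raise ValueError("checkpoint uses an incompatible class convention")
            model = cls(n_taxa=meta["n_taxa"],
                        hp=Hyperparams(**meta["hyperparams"]),
                        alphabet=meta["alphabet"])
            for k, t in model.params.items():
                t.data = archive[k].astype(float)
        return model

    def state_copy(self) -> dict[str, np.ndarray]:
        return {k: t.data.copy() for k, t in self.params.items()}

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        for k, t in self.params.items():
            t.data = state[k].copy()


def cross_entropy(scores: Tensor, labels: np.ndarray, reduction: str = "mean") -> Tensor:
    """Multiclass cross-entropy from raw scores; labels are 1-based classes."""
    labels = np.asarray(labels)
    K = scores.shape[-1]
    if labels.min() < 1 or labels.max() > K:
        raise ValueError(f"labels must be in 1..{K}")
    logp = scores.log_softmax()
    picked = logp[(np.arange(len(labels)), labels - 1)]
    total = picked.sum().scale(-1.0)
    if reduction == "mean":
        return total.scale(1.0 / len(labels))
    if reduction == "sum":
        return total
    raise ValueError("reduction must be 'mean' or 'sum'")


def cross_entropy_from_probs(probs: np.ndarray, labels: np.ndarray,
                             reduction: str = "mean") -> float:
    """Cross-entropy evaluated directly on probability vectors (no gradient)."""
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels)
    if labels.min() < 1 or labels.max() > probs.shape[-1]:
        raise ValueError(f"labels must be in 1..{probs.shape[-1]}")
    picked = probs[np.arange(len(labels)), labels - 1]
    nll = -np.log(np.clip(picked, 1e-300, None))
    if reduction == "mean":
        return float(nll.mean())
    if reduction == "sum":
        return float(nll.sum())
    raise ValueError("reduction must be 'mean' or 'sum'")
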