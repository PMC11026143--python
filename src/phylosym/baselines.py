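"""Distance-based baseline: neighbor joining on Dayhoff ML pairwise distances.

The pairwise distance between two aligned sequences is the maximum-likelihood
branch length under the substitution model,

    t_hat = argmax_t  sum_sites log( pi[x_i] * P[x_i, y_i](t) ),

found by bounded scalar optimization on ``[0, cap]``.  When the two
sequences are (near-)saturated the likelihood increases monotonically in
``t`` and the estimate is returned as the cap — the same finite ceiling
distance software applies when the ML distance diverges.  Neighbor joining
is the standard Saitou–Nei agglomeration on the Q-criterion with a
deterministic lowest-index tie-break.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .io import Alignment
from .substitution import SubstitutionModel, dayhoff_model, transition_matrix
from .topology import TaxonSet, UnrootedTopology, _freeze_split, class_index

__all__ = [
    "DistanceMatrix",
    "ml_pairwise_distance",
    "pairwise_distances",
    "neighbor_joining",
    "classify_nj",
    "DEFAULT_CAP",
]

DEFAULT_CAP = 10.0   # substitutions/site ceiling for diverged pairs
_OPT_TOL = 1e-6      # optimizer tolerance on t
_CAP_SNAP = 1e-3     # within this of the cap counts as saturated


def _pattern_counts(x: np.ndarray, y: np.ndarray, k: int) -> np.ndarray:
    counts = np.zeros((k, k))
    np.add.at(counts, (x, y), 1.0)
    return counts


def ml_pairwise_distance(s: str, s_prime: str,
                         model: SubstitutionModel | None = None,
                         cap: float = DEFAULT_CAP) -> float:
    """ML evolutionary distance between two aligned sequences.

    Returns ``cap`` when the likelihood keeps increasing up to the cap
    (saturation) and ``0.0`` for identical sequences.
    """
    if len(s) == 0 or len(s_prime) == 0:
        raise ValueError("empty sequences")
    if len(s) != len(s_prime):
        raise ValueError("sequences must have equal lengths")
    model = dayhoff_model() if model is None else model
    x = model.encode(s)
    y = model.encode(s_prime)
    if np.array_equal(x, y):
        return 0.0
    counts = _pattern_counts(x, y, model.n_states)

    def neg_ll(t: float) -> float:
        P = np.clip(transition_matrix(model, t), 1e-300, None)
        return -float((counts * np.log(P)).sum())

    res = minimize_scalar(neg_ll, bounds=(0.0, cap), method="bounded",
                          options={"xatol": _OPT_TOL})
    t_hat = float(res.x)
    # golden-section never lands on the boundary; snap saturated estimates
    if cap - t_hat <= _CAP_SNAP and neg_ll(cap) <= res.fun + 1e-9:
        return cap
    if t_hat <= _OPT_TOL and neg_ll(0.0 + 1e-12) <= res.fun + 1e-9:
        return 0.0
    return t_hat


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise distances between the taxa, capped at ``cap``."""

    taxa: tuple[str, ...]
    d: np.ndarray
    cap: float = DEFAULT_CAP

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        n = len(self.taxa)
        if d.shape != (n, n):
            raise ValueError(f"distance matrix must be {n}x{n}")
        if not np.allclose(d, d.T):
            raise ValueError("distance matrix must be symmetric")
        if np.diag(d).any():
            raise ValueError("diagonal must be zero")
        if (d < 0).any() or (d > self.cap + 1e-12).any():
            raise ValueError("entries must lie in [0, cap]")


def pairwise_distances(alignment: Alignment,
                       model: SubstitutionModel | None = None,
                       cap: float = DEFAULT_CAP) -> DistanceMatrix:
    """All pairwise ML distances of an alignment."""
    model = dayhoff_model() if model is None else model
    n = alignment.n_taxa
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = ml_pairwise_distance(
                alignment.sequences[i], alignment.sequences[j], model, cap)
    return DistanceMatrix(taxa=alignment.names, d=d, cap=cap)


def neighbor_joining(dm: DistanceMatrix | np.ndarray,
                     taxa: TaxonSet | tuple[str, ...] | None = None) -> UnrootedTopology:
    """Saitou–Nei neighbor joining; returns the topology (splits only).

    Ties on the Q-criterion are broken by joining the pair with the lowest
    indices (row-major), making the output deterministic.
    """
    if isinstance(dm, DistanceMatrix):
        labels = tuple(dm.taxa)
        d = np.array(dm.d, dtype=float)
    else:
        if taxa is None:
            raise ValueError("taxa are required with a raw matrix")
        labels = tuple(taxa.labels if isinstance(taxa, TaxonSet) else taxa)
        d = np.array(dm, dtype=float)
        if not np.allclose(d, d.T):
            raise ValueError("distance matrix must be symmetric")
    n = len(labels)
    if n < 4:
        raise ValueError("neighbor joining here needs n >= 4")

    clusters: list[frozenset[str]] = [frozenset((lb,)) for lb in labels]
    all_taxa = frozenset(labels)
    splits: set = set()
    while len(clusters) > 3:
        m = len(clusters)
        row_sums = d.sum(axis=1)
        q = (m - 2) * d - row_sums[:, None] - row_sums[None, :]
        np.fill_diagonal(q, np.inf)
        # lowest-index pair among minima (row-major argmin is exactly that)
        i, j = divmod(int(np.argmin(q)), m)
        if i > j:
            i, j = j, i
        merged = clusters[i] | clusters[j]
        other = all_taxa - merged
        if len(merged) >= 2 and len(other) >= 2:
            splits.add(_freeze_split(merged, other))
        # distances from the new node u to every remaining cluster k
        du = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        new_d = np.zeros((m - 1, m - 1))
        new_d[: m - 2, : m - 2] = d[np.ix_(keep, keep)]
        new_d[-1, : m - 2] = new_d[: m - 2, -1] = du[keep]
        clusters = [clusters[k] for k in keep] + [merged]
        d = new_d
    return UnrootedTopology(taxa=labels, splits=frozenset(splits))


def classify_nj(alignment: Alignment,
                model: SubstitutionModel | None = None,
                cap: float = DEFAULT_CAP) -> int:
    """Topology class (1-based, canonical convention) inferred by NJ."""
    if alignment.n_taxa not in (4, 5):
        raise ValueError("classification is defined for 4 or 5 taxa")
    dm = pairwise_distances(alignment, model, cap)
    return class_index(neighbor_joining(dm))
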