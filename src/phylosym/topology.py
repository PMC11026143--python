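"""Unrooted tree topologies, class indices, and the action of leaf permutations.

A topology on ``n`` labelled taxa is identified with its set of nontrivial
splits (bipartitions induced by internal edges).  For ``n = 4`` there are 3
topologies, for ``n = 5`` there are 15, and in general ``(2n - 5)!!``.

The classifier treats topologies as classes ``1..K`` under a fixed canonical
order (see :func:`enumerate_topologies`).  Permuting the input sequence slots
induces a permutation of the classes; :func:`induced_action` computes it, and
the neural model is equivariant with respect to it by construction.

Canonical class order
---------------------
For 4 taxa in slots ``(A, B, C, D)``::

    I  = {AB|CD},   II = {AC|BD},   III = {AD|BC}

For 5 taxa in slots ``(A, B, C, D, E)`` each topology is a pair of cherries
plus one "middle" taxon attached to the path between them.  Classes are
grouped by the middle taxon iterated in the order ``E, D, C, B, A``; within
each group the remaining four taxa, kept in slot order, take the three
quartet classes above.  So classes 1-3 have middle ``E`` (restricting to the
quartet classes on ``A,B,C,D``), classes 4-6 have middle ``D``, and so on.
This completion is the repository's fixed convention.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import dendropy

__all__ = [
    "TaxonSet",
    "UnrootedTopology",
    "LeafPermutation",
    "count_topologies",
    "enumerate_topologies",
    "quartet_class_pairs",
    "quintet_class_structure",
    "class_index",
    "induced_action",
    "compose",
    "read_newick",
    "write_newick",
]

#: slot pairs defining quartet classes I, II, III (0-based slots)
QUARTET_PAIRS: tuple[tuple[tuple[int, int], tuple[int, int]], ...] = (
    ((0, 1), (2, 3)),
    ((0, 2), (1, 3)),
    ((0, 3), (1, 2)),
)

_MAX_ENUMERATION_N = 8


@dataclass(frozen=True)
class TaxonSet:
    """An ordered collection of distinct taxon names; order defines input slots."""

    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("taxon labels must be distinct")
        if len(self.labels) < 3:
            raise ValueError("need at least 3 taxa")

    def __len__(self) -> int:
        return len(self.labels)

    def __iter__(self):
        return iter(self.labels)


def _freeze_split(side_a: Iterable[str], side_b: Iterable[str]) -> frozenset[frozenset[str]]:
    return frozenset((frozenset(side_a), frozenset(side_b)))


@dataclass(frozen=True)
class UnrootedTopology:
    """An unrooted binary topology represented by its nontrivial splits.

    Two topologies are equal iff their split sets are equal; branch lengths
    and rootings carry no class information and are never stored here.
    """

    taxa: tuple[str, ...]
    splits: frozenset[frozenset[frozenset[str]]]

    @property
    def n(self) -> int:
        return len(self.taxa)

    def relabel(self, mapping: dict[str, str]) -> "UnrootedTopology":
        """Rename every taxon through ``mapping`` (a bijection on the taxa)."""
        new_splits = frozenset(
            _freeze_split((mapping[t] for t in a), (mapping[t] for t in b))
            for a, b in self.splits
        )
        return UnrootedTopology(taxa=self.taxa, splits=new_splits)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, UnrootedTopology):
            return NotImplemented
        return self.splits == other.splits and set(self.taxa) == set(other.taxa)

    def __hash__(self) -> int:
        return hash((frozenset(self.taxa), self.splits))


# a leaf permutation is a tuple p with p[i] = new slot of the taxon in slot i
LeafPermutation = tuple[int, ...]


def compose(p: LeafPermutation, q: LeafPermutation) -> LeafPermutation:
    """Composition ``p after q``: slot i -> q[i] -> p[q[i]]."""
    return tuple(p[q[i]] for i in range(len(p)))


def count_topologies(n: int) -> int:
    """Number of unrooted binary topologies on ``n`` taxa: ``(2n - 5)!!``."""
    if n < 3:
        raise ValueError(f"n must be >= 3, got {n}")
    out = 1
    for k in range(3, 2 * n - 4, 2):
        out *= k
    return out


def _pairs_to_topology(taxa: Sequence[str], pairs, middle: int | None = None) -> UnrootedTopology:
    """Build a topology from cherry slot-pairs (quartet or quintet shape)."""
    labels = tuple(taxa)
    (i, j), (k, l) = pairs
    if middle is None:
        splits = frozenset({_freeze_split((labels[i], labels[j]), (labels[k], labels[l]))})
    else:
        rest1 = [labels[x] for x in range(len(labels)) if x not in (i, j)]
        rest2 = [labels[x] for x in range(len(labels)) if x not in (k, l)]
        splits = frozenset(
            {
                _freeze_split((labels[i], labels[j]), rest1),
                _freeze_split((labels[k], labels[l]), rest2),
            }
        )
    return UnrootedTopology(taxa=labels, splits=splits)


def quartet_class_pairs() -> tuple[tuple[tuple[int, int], tuple[int, int]], ...]:
    """Slot-pair structure of the three quartet classes, in class order."""
    return QUARTET_PAIRS


def quintet_class_structure() -> list[tuple[tuple[tuple[int, int], tuple[int, int]], int]]:
    """The 15 quintet classes as ``((cherry1, cherry2), middle_slot)``.

    Middle slot iterates 4, 3, 2, 1, 0 (taxa E, D, C, B, A); within each
    middle the remaining slots, in increasing order, take quartet classes
    I, II, III.
    """
    out = []
    for middle in (4, 3, 2, 1, 0):
        rest = [s for s in range(5) if s != middle]
        for (a, b), (c, d) in QUARTET_PAIRS:
            out.append((((rest[a], rest[b]), (rest[c], rest[d])), middle))
    return out


def _enumerate_by_insertion(labels: Sequence[str]) -> list[UnrootedTopology]:
    """Exhaustive enumeration by recursive edge insertion (deterministic order)."""
    # tree as a list of edges between node ids; leaves are ids >= 0 (slot
    # index), internal nodes are negative; start from the 3-leaf star
    trees = [[(-1, 0), (-1, 1), (-1, 2)]]
    next_internal = -2
    for leaf in range(3, len(labels)):
        new_trees = []
        for edges in trees:
            for e_idx, (u, v) in enumerate(edges):
                hub = next_internal
                new_edges = list(edges)
                new_edges[e_idx : e_idx + 1] = [(u, hub), (hub, v), (hub, leaf)]
                new_trees.append(new_edges)
        trees = new_trees
        next_internal -= 1
    return [_edges_to_topology(edges, labels) for edges in trees]


def _edges_to_topology(edges, labels: Sequence[str]) -> UnrootedTopology:
    adj: dict[int, list[int]] = {}
    for u, v in edges:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)
    n = len(labels)
    splits = set()
    for u, v in edges:
        if u >= 0 or v >= 0:  # pendant edge: trivial split
            continue
        # leaves reachable from u without crossing (u, v)
        seen = {u, v}
        stack = [u]
        side = set()
        while stack:
            x = stack.pop()
            for y in adj[x]:
                if y in seen:
                    continue
                seen.add(y)
                if y >= 0:
                    side.add(y)
                else:
                    stack.append(y)
        other = set(range(n)) - side
        if len(side) >= 2 and len(other) >= 2:
            splits.add(_freeze_split((labels[i] for i in side), (labels[i] for i in other)))
    return UnrootedTopology(taxa=tuple(labels), splits=frozenset(splits))


def enumerate_topologies(taxa: TaxonSet | Sequence[str]) -> list[UnrootedTopology]:
    """All unrooted topologies on ``taxa`` in the canonical class order.

    For n = 4 and n = 5 the order is the documented class-index convention;
    for 6 <= n <= 8 an exhaustive edge-insertion order is used (classes for
    those sizes are not part of the classifier's label space).
    """
    labels = tuple(taxa.labels if isinstance(taxa, TaxonSet) else taxa)
    n = len(labels)
    if n < 4 or n > _MAX_ENUMERATION_N:
        raise ValueError(f"enumeration supports 4 <= n <= {_MAX_ENUMERATION_N}, got {n}")
    if n == 4:
        return [_pairs_to_topology(labels, pairs) for pairs in QUARTET_PAIRS]
    if n == 5:
        return [
            _pairs_to_topology(labels, pairs, middle)
            for pairs, middle in quintet_class_structure()
        ]
    return _enumerate_by_insertion(labels)


def class_index(topology: UnrootedTopology) -> int:
    """1-based class index of a 4- or 5-taxon topology under the canonical order."""
    labels = tuple(sorted(topology.taxa))
    ordered = enumerate_topologies(labels)
    target = topology.splits
    for k, t in enumerate(ordered, start=1):
        if t.splits == target:
            return k
    raise ValueError("topology does not match any enumerated class (is it binary?)")


def induced_action(perm: LeafPermutation, n: int) -> tuple[int, ...]:
    """Class permutation induced by relabelling leaf slots through ``perm``.

    Returns a tuple ``action`` with ``action[k-1]`` = the class that class
    ``k`` becomes when the taxon in slot ``i`` moves to slot ``perm[i]``.
    The map is a group homomorphism from S_n to S_K.
    """
    if n not in (4, 5):
        raise ValueError("induced_action is defined for n in {4, 5}")
    if sorted(perm) != list(range(n)):
        raise ValueError(f"not a permutation of 0..{n - 1}: {perm}")
    labels = tuple("ABCDE"[:n])
    topologies = enumerate_topologies(labels)
    lookup = {t.splits: k for k, t in enumerate(topologies, start=1)}
    mapping = {labels[i]: labels[perm[i]] for i in range(n)}
    return tuple(lookup[t.relabel(mapping).splits] for t in topologies)


# ---------------------------------------------------------------------------
# Newick I/O


def read_newick(text: str, taxa: TaxonSet | Sequence[str] | None = None) -> UnrootedTopology:
    """Parse a Newick string into an :class:`UnrootedTopology`.

    Any rooting is discarded; branch lengths are ignored.  If ``taxa`` is
    given, the tree's leaf set must match it exactly.
    """
    try:
        tree = dendropy.Tree.get(data=text, schema="newick")
    except Exception as exc:  # dendropy raises several parse error types
        raise ValueError(f"malformed Newick: {exc}") from exc
    leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(set(leaves)) != len(leaves):
        raise ValueError("duplicate taxon labels in Newick")
    if taxa is not None:
        expected = set(taxa.labels if isinstance(taxa, TaxonSet) else taxa)
        if set(leaves) != expected:
            unknown = set(leaves) - expected
            raise ValueError(f"unknown taxa in Newick: {sorted(unknown)}" if unknown
                             else f"missing taxa: {sorted(expected - set(leaves))}")
    nset = set(leaves)
    splits = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        side = {lf.taxon.label for lf in node.leaf_iter()}
        other = nset - side
        if len(side) >= 2 and len(other) >= 2:
            splits.add(_freeze_split(side, other))
    return UnrootedTopology(taxa=tuple(leaves), splits=frozenset(splits))


def write_newick(topology: UnrootedTopology) -> str:
    """Serialize a 4- or 5-taxon topology as an unrooted Newick string."""
    labels = tuple(sorted(topology.taxa))
    n = len(labels)
    if n == 4:
        k = class_index(topology)
        (i, j), (u, v) = QUARTET_PAIRS[k - 1]
        return f"(({labels[i]},{labels[j]}),({labels[u]},{labels[v]}));"
    if n == 5:
        k = class_index(topology)
        (pair1, pair2), middle = quintet_class_structure()[k - 1]
        (i, j), (u, v) = pair1, pair2
        return (
            f"(({labels[i]},{labels[j]}),{labels[middle]},"
            f"({labels[u]},{labels[v]}));"
        )
    raise ValueError("Newick writing is supported for 4 or 5 taxa only")
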