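"""Molecular connectivity (chi) indices by subgraph enumeration.

The order-``m`` connectivity index of a molecule is the sum, over all
connected edge-subgraphs ("fragments") with ``m`` edges of a given type,
of the reciprocal square root of the product of the connectivity degrees
of the fragment's ``m + 1`` atoms:

    chi(m, k) = sum_j prod_i (delta_i)^(-1/2)

where the degrees are those of the atoms in the *whole* molecule.  The
zeroth-order index sums ``delta^(-1/2)`` over the atoms themselves.
Substituting the valence degree ``delta_v`` for ``delta`` gives the valence
variant, which differentiates heteroatoms.

Fragment types follow the standard Kier-Hall classification of the
edge-induced subgraph: *path* (acyclic, maximum within-fragment degree 2),
*cluster* (a star), *path-cluster* (acyclic, branched, not a star; first
occurs at m = 4) and *ring* (contains a cycle).  Ring fragments are counted
separately and never enter the path/cluster/path-cluster sums.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache
from typing import Literal, Sequence

from .molgraph import MolecularGraph, simple_delta, valence_delta

__all__ = [
    "Fragment",
    "ChiIndex",
    "FragmentTypeError",
    "enumerate_fragments",
    "chi",
    "brute_force_chi",
    "descriptor_row",
    "DESCRIPTOR_COLUMNS",
]

FragmentType = Literal["path", "cluster", "path-cluster", "ring"]

#: (m, type, valence) recipe for each Table-style descriptor column
DESCRIPTOR_COLUMNS: dict[str, tuple[int, FragmentType, bool]] = {
    "chi0": (0, "path", False),
    "chi1": (1, "path", False),
    "chi2": (2, "path", False),
    "chi3c": (3, "cluster", False),
    "chi4pc": (4, "path-cluster", False),
    "chi0v": (0, "path", True),
    "chi1v": (1, "path", True),
    "chi2v": (2, "path", True),
    "chi3cv": (3, "cluster", True),
    "chi4pcv": (4, "path-cluster", True),
}

_VALID_TYPES: dict[int, tuple[FragmentType, ...]] = {
    1: ("path",),
    2: ("path",),
    3: ("path", "cluster", "ring"),
    4: ("path", "cluster", "path-cluster", "ring"),
}


class FragmentTypeError(ValueError):
    """Raised for an unsupported (order, type) combination."""


@dataclass(frozen=True)
class Fragment:
    """A connected edge-subgraph of order ``m`` (= number of edges)."""

    atom_indices: frozenset[int]
    edges: frozenset[tuple[int, int]]
    order: int
    type: FragmentType


@dataclass(frozen=True)
class ChiIndex:
    """A single connectivity-index value."""

    order: int
    type: FragmentType
    valence: bool
    value: float


def _classify(edges: Sequence[tuple[int, int]]) -> FragmentType:
    """Classify a connected edge set by its within-fragment degrees."""
    m = len(edges)
    deg: dict[int, int] = {}
    for a, b in edges:
        deg[a] = deg.get(a, 0) + 1
        deg[b] = deg.get(b, 0) + 1
    if len(deg) <= m:  # connected with |V| <= |E| => contains a cycle
        return "ring"
    maxdeg = max(deg.values())
    if maxdeg <= 2:
        return "path"
    if maxdeg == m:  # one centre carries every edge
        return "cluster"
    return "path-cluster"


def _is_connected(edges: Sequence[tuple[int, int]]) -> bool:
    adj: dict[int, list[int]] = {}
    for a, b in edges:
        adj.setdefault(a, []).append(b)
        adj.setdefault(b, []).append(a)
    start = next(iter(adj))
    seen = {start}
    stack = [start]
    while stack:
        for j in adj[stack.pop()]:
            if j not in seen:
                seen.add(j)
                stack.append(j)
    return len(seen) == len(adj)


def _check_mk(m: int, k: FragmentType) -> None:
    if m not in _VALID_TYPES:
        raise FragmentTypeError(f"unsupported fragment order m={m} (supported: 1..4)")
    if k not in _VALID_TYPES[m]:
        raise FragmentTypeError(f"no {k!r} fragments exist at order m={m}")


# graphs are immutable (frozen dataclass), so enumerations can be memoized
@lru_cache(maxsize=2048)
def _connected_edge_sets(graph: MolecularGraph, m: int) -> set[frozenset[tuple[int, int]]]:
    """All connected edge-subsets of size ``m``, by depth-first growth.

    Each subset is grown from a seed edge by repeatedly adding an edge
    adjacent to the current fragment; only edges with index greater than
    the seed's are added, which prunes most duplicate orderings, and a
    final frozenset dedup removes the rest.
    """
    edges = graph.bonds
    incident: list[list[int]] = [[] for _ in range(graph.n_atoms)]
    for idx, (a, b) in enumerate(edges):
        incident[a].append(idx)
        incident[b].append(idx)

    found: set[frozenset[tuple[int, int]]] = set()

    def grow(seed: int, chosen: list[int], atoms: set[int]) -> None:
        if len(chosen) == m:
            found.add(frozenset(edges[i] for i in chosen))
            return
        frontier = {
            j
            for v in atoms
            for j in incident[v]
            if j > seed and j not in chosen
        }
        for j in frontier:
            a, b = edges[j]
            grow(seed, chosen + [j], atoms | {a, b})

    for seed in range(len(edges)):
        a, b = edges[seed]
        grow(seed, [seed], {a, b})
    return found


# graphs are immutable, so the classified enumeration can be memoized too
@lru_cache(maxsize=2048)
def _classified_fragments(
    graph: MolecularGraph, m: int
) -> tuple[tuple[frozenset[tuple[int, int]], FragmentType], ...]:
    out = [
        (edge_set, _classify(sorted(edge_set)))
        for edge_set in _connected_edge_sets(graph, m)
    ]
    out.sort(key=lambda item: sorted(item[0]))
    return tuple(out)


def enumerate_fragments(graph: MolecularGraph, m: int, k: FragmentType) -> list[Fragment]:
    """Enumerate the distinct order-``m`` fragments of type ``k``.

    Fragments are identified by their edge set; the returned list has no
    duplicates and is sorted for determinism.
    """
    _check_mk(m, k)
    out = []
    for edge_set, ftype in _classified_fragments(graph, m):
        if ftype == k:
            atoms = frozenset(v for e in edge_set for v in e)
            out.append(Fragment(atoms, edge_set, m, k))
    return out


def _deltas(graph: MolecularGraph, valence: bool) -> list[float]:
    if valence:
        return [valence_delta(a) for a in graph.atoms]
    return [float(simple_delta(graph, i)) for i in range(graph.n_atoms)]


def chi(graph: MolecularGraph, m: int, k: FragmentType = "path", valence: bool = False) -> ChiIndex:
    """Connectivity index of order ``m`` and type ``k``.

    ``m = 0`` sums ``delta^(-1/2)`` over atoms (``k`` is ignored); higher
    orders sum the degree products over enumerated fragments.  The result
    is independent of atom ordering.
    """
    delta = _deltas(graph, valence)
    if m == 0:
        value = sum(d ** -0.5 for d in delta)
        return ChiIndex(0, "path", valence, value)
    _check_mk(m, k)
    value = 0.0
    for edge_set, ftype in _classified_fragments(graph, m):
        if ftype != k:
            continue
        prod = 1.0
        for v in {v for e in edge_set for v in e}:
            prod *= delta[v]
        value += prod ** -0.5
    return ChiIndex(m, k, valence, value)


def brute_force_chi(
    graph: MolecularGraph, m: int, k: FragmentType = "path", valence: bool = False
) -> ChiIndex:
    """Exhaustive-oracle version of :func:`chi` for small graphs.

    Iterates over *all* C(E, m) edge subsets, keeping the connected ones of
    type ``k``.  Intended purely as an independent cross-check in tests;
    refuses graphs with more than 12 edges.
    """
    if graph.n_bonds > 12:
        raise ValueError(
            f"brute_force_chi is a testing oracle; graph has {graph.n_bonds} > 12 edges"
        )
    delta = _deltas(graph, valence)
    if m == 0:
        return ChiIndex(0, "path", valence, sum(d ** -0.5 for d in delta))
    _check_mk(m, k)
    value = 0.0
    for combo in itertools.combinations(graph.bonds, m):
        if not _is_connected(combo):
            continue
        if _classify(combo) != k:
            continue
        atoms = {v for e in combo for v in e}
        prod = 1.0
        for v in atoms:
            prod *= delta[v]
        value += prod ** -0.5
    return ChiIndex(m, k, valence, value)


@lru_cache(maxsize=2048)
def _descriptor_values(graph: MolecularGraph) -> tuple[float, ...]:
    return tuple(
        chi(graph, m, k, valence).value for m, k, valence in DESCRIPTOR_COLUMNS.values()
    )


def descriptor_row(graph: MolecularGraph) -> dict[str, float]:
    """The ten Table-style indices, keyed by column name.

    Columns: chi0, chi1, chi2, chi3c, chi4pc and their valence variants
    chi0v .. chi4pcv.
    """
    return dict(zip(DESCRIPTOR_COLUMNS, _descriptor_values(graph)))
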