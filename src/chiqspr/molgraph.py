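"""Hydrogen-suppressed molecular graphs and connectivity degrees.

The hydrogen-suppressed (heavy-atom) graph is the sole structural input to
molecular connectivity indices.  Each heavy atom carries its element, formal
charge and attached-hydrogen count; bonds are unordered pairs of atom
indices.  Bond order plays no role anywhere in this package: the simple
connectivity degree ``delta`` of an atom is its heavy-atom degree, and the
valence connectivity degree is

    delta_v = (Zv - h) / (Z - Zv - 1)

where ``Zv`` is the element's valence-electron count, ``Z`` its total
electron count and ``h`` the number of attached hydrogens.  For carbon the
denominator is 1 and ``delta_v = 4 - h``, i.e. the heavy-atom degree, so
simple and valence indices coincide on pure hydrocarbons.

Counterions (the chloride anions of the surfactant salts) are never part of
the graph: the descriptors describe the covalent dication only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable

import networkx as nx

__all__ = [
    "Atom",
    "MolecularGraph",
    "MolParseError",
    "MolValidationError",
    "parse_connection_table",
    "parse_smiles",
    "simple_delta",
    "valence_delta",
]


class MolParseError(ValueError):
    """Raised when a structure record cannot be parsed."""


class MolValidationError(ValueError):
    """Raised when a parsed structure violates valence or graph rules."""


#: electron counts (Z, Zv) for the supported elements
_ELECTRONS: dict[str, tuple[int, int]] = {
    "C": (6, 4),
    "N": (7, 5),
    "O": (8, 6),
}

#: standard valence (heavy degree + h) by element and formal charge
_VALENCE: dict[tuple[str, int], int] = {
    ("C", 0): 4,
    ("N", 0): 3,
    ("N", 1): 4,
    ("O", 0): 2,
}


@dataclass(frozen=True)
class Atom:
    """A heavy atom of the hydrogen-suppressed graph.

    Parameters
    ----------
    element : str
        Element symbol; ``C``, ``N`` or ``O``.
    h : int
        Number of attached hydrogen atoms.
    formal_charge : int
        Formal charge (0 or +1 for the quaternary/aromatic nitrogens of
        the cationic head groups).
    aromatic : bool
        Whether the atom was written as aromatic in the input.  Only used
        for hydrogen-count inference during parsing; indices ignore it.
    """

    element: str
    h: int = 0
    formal_charge: int = 0
    aromatic: bool = False

    @property
    def Z(self) -> int:
        return _ELECTRONS[self.element][0]

    @property
    def Zv(self) -> int:
        return _ELECTRONS[self.element][1]

    def __post_init__(self) -> None:
        if self.element not in _ELECTRONS:
            raise MolValidationError(f"unsupported element {self.element!r}")
        if self.h < 0:
            raise MolValidationError(f"negative hydrogen count on {self.element}")
        Z, Zv = _ELECTRONS[self.element]
        if Z - Zv - 1 < 1:
            raise MolValidationError(
                f"element {self.element}: Z - Zv - 1 = {Z - Zv - 1} < 1"
            )


@dataclass(frozen=True)
class MolecularGraph:
    """A validated, immutable hydrogen-suppressed molecular graph."""

    atoms: tuple[Atom, ...]
    bonds: tuple[tuple[int, int], ...]
    name: str = ""
    _adjacency: tuple[tuple[int, ...], ...] = field(
        init=False, repr=False, compare=False, default=()
    )

    def __post_init__(self) -> None:
        n = len(self.atoms)
        seen: set[tuple[int, int]] = set()
        adj: list[list[int]] = [[] for _ in range(n)]
        for i, j in self.bonds:
            if i == j:
                raise MolValidationError(f"self-loop on atom {i}")
            if not (0 <= i < n and 0 <= j < n):
                raise MolValidationError(f"bond ({i},{j}) references missing atom")
            key = (min(i, j), max(i, j))
            if key in seen:
                raise MolValidationError(f"duplicate bond ({i},{j})")
            seen.add(key)
            adj[i].append(j)
            adj[j].append(i)
        object.__setattr__(self, "_adjacency", tuple(tuple(a) for a in adj))
        self._validate(adj)

    def _validate(self, adj: list[list[int]]) -> None:
        n = len(self.atoms)
        if n == 0:
            raise MolValidationError("empty graph")
        # connectivity
        stack, seen = [0], {0}
        while stack:
            for j in adj[stack.pop()]:
                if j not in seen:
                    seen.add(j)
                    stack.append(j)
        if len(seen) != n:
            raise MolValidationError(
                f"graph {self.name!r} is disconnected ({len(seen)}/{n} atoms reachable)"
            )
        for idx, atom in enumerate(self.atoms):
            deg = len(adj[idx])
            if deg > 4:
                raise MolValidationError(f"atom {idx} ({atom.element}) has degree {deg} > 4")
            key = (atom.element, atom.formal_charge)
            if key not in _VALENCE:
                raise MolValidationError(
                    f"atom {idx}: unsupported element/charge {atom.element}{atom.formal_charge:+d}"
                )
            # aromatic atoms devote one valence to the ring pi system
            valence = _VALENCE[key] - (1 if atom.aromatic else 0)
            if deg + atom.h != valence:
                raise MolValidationError(
                    f"atom {idx} ({atom.element}{'+' if atom.formal_charge else ''}):"
                    f" degree {deg} + h {atom.h} != valence {valence}"
                )

    # -- accessors ---------------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_bonds(self) -> int:
        return len(self.bonds)

    def neighbors(self, i: int) -> tuple[int, ...]:
        return self._adjacency[i]

    def degree(self, i: int) -> int:
        return len(self._adjacency[i])

    def to_networkx(self) -> nx.Graph:
        """Export as a ``networkx.Graph`` with atom attributes on nodes."""
        g = nx.Graph(name=self.name)
        for i, a in enumerate(self.atoms):
            g.add_node(i, element=a.element, h=a.h, charge=a.formal_charge)
        g.add_edges_from(self.bonds)
        return g


def simple_delta(graph: MolecularGraph, atom_index: int) -> int:
    """Connectivity degree: number of heavy-atom neighbours."""
    return graph.degree(atom_index)


def valence_delta(atom: Atom) -> float:
    """Valence connectivity degree ``(Zv - h) / (Z - Zv - 1)``.

    Encodes heteroatom and hydrogen-count information: 4 - h for carbon,
    5 - h for nitrogen (δv = 5 on a quaternary N+), 6 - h for oxygen.
    """
    num = atom.Zv - atom.h
    den = atom.Z - atom.Zv - 1
    if num <= 0 or den <= 0:
        raise MolValidationError(
            f"valence delta undefined for {atom.element} (Zv-h={num}, Z-Zv-1={den})"
        )
    return num / den


def _infer_h(element: str, charge: int, degree: int, aromatic: bool, where: str) -> int:
    """Implicit-hydrogen count from standard valence minus heavy degree.

    Aromatic atoms spend one valence on the ring pi system, so an aromatic
    carbon of ring degree 2 carries a single hydrogen.
    """
    key = (element, charge)
    if key not in _VALENCE:
        raise MolValidationError(f"{where}: unsupported element/charge {element}{charge:+d}")
    valence = _VALENCE[key] - (1 if aromatic else 0)
    h = valence - degree
    if h < 0:
        raise MolValidationError(
            f"{where}: {element}{'+' if charge else ''} with degree {degree} exceeds valence"
        )
    return h


# ---------------------------------------------------------------------------
# connection-table parsing
# ---------------------------------------------------------------------------

def parse_connection_table(text: str | dict) -> MolecularGraph:
    """Parse a JSON connection-table record into a :class:`MolecularGraph`.

    The record is ``{"name": ..., "atoms": [{"element", "charge"?, "h"?}...],
    "bonds": [[i, j], ...]}`` with 0-based atom indices.  When ``h`` is
    omitted it is inferred from the element's standard valence minus the
    heavy-atom degree.
    """
    if isinstance(text, str):
        try:
            record = json.loads(text)
        except json.JSONDecodeError as exc:
            raise MolParseError(f"malformed connection table at line {exc.lineno}: {exc.msg}") from exc
    else:
        record = text
    if not isinstance(record, dict) or "atoms" not in record or "bonds" not in record:
        raise MolParseError("connection table must be an object with 'atoms' and 'bonds'")

    raw_atoms = record["atoms"]
    raw_bonds = record["bonds"]
    n = len(raw_atoms)
    degree = [0] * n
    for b in raw_bonds:
        if len(b) != 2:
            raise MolParseError(f"bond record {b!r} is not a pair")
        i, j = b
        if not (isinstance(i, int) and isinstance(j, int) and 0 <= i < n and 0 <= j < n):
            raise MolParseError(f"bond {b!r} references a missing atom (n={n})")
        degree[i] += 1
        degree[j] += 1

    atoms = []
    for idx, rec in enumerate(raw_atoms):
        element = rec.get("element")
        if element is None:
            raise MolParseError(f"atom {idx}: missing element")
        charge = int(rec.get("charge", 0))
        aromatic = bool(rec.get("aromatic", False))
        h = rec.get("h")
        if h is None:
            h = _infer_h(element, charge, degree[idx], aromatic, f"atom {idx}")
        atoms.append(Atom(element=element, h=int(h), formal_charge=charge, aromatic=aromatic))

    return MolecularGraph(
        atoms=tuple(atoms),
        bonds=tuple((min(i, j), max(i, j)) for i, j in raw_bonds),
        name=str(record.get("name", "")),
    )


# ---------------------------------------------------------------------------
# SMILES parsing (supported subset)
# ---------------------------------------------------------------------------

_ORGANIC = {"C", "N", "O"}
_AROMATIC = {"c", "n", "o"}


def parse_smiles(smiles: str, name: str = "") -> MolecularGraph:
    """Parse a SMILES string from the supported subset.

    Supported: organic-subset atoms C/N/O, bracket atoms with charge and
    explicit hydrogen count (e.g. ``[N+]``, ``[nH]``), branches, ring-bond
    digits (including ``%nn``), and aromatic lowercase for benzene/pyridine
    type rings.  Bond orders, stereo descriptors and isotopes are rejected
    with an explicit error — connectivity indices depend only on adjacency
    and hydrogen counts, but a silent misparse must never happen.
    """
    atoms: list[dict] = []          # element, charge, h(None=implicit), aromatic
    bonds: list[tuple[int, int]] = []
    stack: list[int] = []
    ring_open: dict[str, int] = {}
    prev: int | None = None

    def add_atom(element: str, charge: int, h, aromatic: bool) -> None:
        nonlocal prev
        idx = len(atoms)
        atoms.append({"element": element, "charge": charge, "h": h, "aromatic": aromatic})
        if prev is not None:
            bonds.append((prev, idx))
        prev = idx

    i, n = 0, len(smiles)
    while i < n:
        ch = smiles[i]
        if ch in _ORGANIC:
            add_atom(ch, 0, None, False)
            i += 1
        elif ch in _AROMATIC:
            add_atom(ch.upper(), 0, None, True)
            i += 1
        elif ch == "[":
            end = smiles.find("]", i)
            if end < 0:
                raise MolParseError(f"unclosed bracket atom at position {i}")
            body = smiles[i + 1 : end]
            add_atom(*_parse_bracket(body, i))
            i = end + 1
        elif ch == "(":
            if prev is None:
                raise MolParseError("branch before any atom")
            stack.append(prev)
            i += 1
        elif ch == ")":
            if not stack:
                raise MolParseError(f"unmatched ')' at position {i}")
            prev = stack.pop()
            i += 1
        elif ch.isdigit() or ch == "%":
            if ch == "%":
                label = smiles[i + 1 : i + 3]
                if len(label) != 2 or not label.isdigit():
                    raise MolParseError(f"bad ring-bond label at position {i}")
                i += 3
            else:
                label = ch
                i += 1
            if prev is None:
                raise MolParseError("ring-bond digit before any atom")
            if label in ring_open:
                j = ring_open.pop(label)
                if j == prev:
                    raise MolParseError(f"ring bond {label} closes onto its own atom")
                bonds.append((j, prev))
            else:
                ring_open[label] = prev
        elif ch == "-":
            i += 1  # explicit single bond: a no-op
        elif ch == ".":
            raise MolParseError(
                "disconnected components ('.') are unsupported; counterions must be omitted"
            )
        else:
            raise MolParseError(f"unsupported SMILES token {ch!r} at position {i}")

    if stack:
        raise MolParseError("unclosed branch '('")
    if ring_open:
        raise MolParseError(f"unclosed ring bond(s): {sorted(ring_open)}")

    degree = [0] * len(atoms)
    for a, b in bonds:
        degree[a] += 1
        degree[b] += 1
    final = []
    for idx, rec in enumerate(atoms):
        h = rec["h"]
        if h is None:
            h = _infer_h(rec["element"], rec["charge"], degree[idx], rec["aromatic"], f"atom {idx}")
        final.append(
            Atom(element=rec["element"], h=h, formal_charge=rec["charge"], aromatic=rec["aromatic"])
        )
    return MolecularGraph(atoms=tuple(final), bonds=tuple(bonds), name=name)


def _parse_bracket(body: str, pos: int) -> tuple[str, int, int | None, bool]:
    """Parse a bracket-atom body like ``N+``, ``NH4+``, ``n+`` or ``OH``."""
    i = 0
    if i < len(body) and body[i].isdigit():
        raise MolParseError(f"isotopes are unsupported (bracket atom at position {pos})")
    if i >= len(body):
        raise MolParseError(f"empty bracket atom at position {pos}")
    aromatic = body[i].islower()
    element = body[i].upper()
    i += 1
    if element not in _ORGANIC:
        raise MolParseError(f"unsupported bracket element {element!r} at position {pos}")
    h: int | None = 0  # bracket atoms default to zero hydrogens
    if i < len(body) and body[i] == "H":
        i += 1
        h = 1
        if i < len(body) and body[i].isdigit():
            h = int(body[i])
            i += 1
    charge = 0
    while i < len(body) and body[i] in "+-":
        charge += 1 if body[i] == "+" else -1
        i += 1
        if i < len(body) and body[i].isdigit():
            charge *= int(body[i])
            i += 1
    if i != len(body):
        raise MolParseError(f"unsupported bracket-atom feature {body[i:]!r} at position {pos}")
    return element, charge, h, aromatic


def parse_smiles_file(lines: Iterable[str]) -> list[MolecularGraph]:
    """Parse ``id<TAB>smiles`` lines into graphs (blank lines skipped)."""
    out = []
    for lineno, line in enumerate(lines, 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        try:
            name, smi = line.split("\t")
        except ValueError as exc:
            raise MolParseError(f"line {lineno}: expected 'id<TAB>smiles'") from exc
        out.append(parse_smiles(smi, name=name))
    return out
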