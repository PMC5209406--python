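"""Graph parsing, validation and connectivity degrees."""

import json

import networkx as nx
import pytest
from hypothesis import given, settings, strategies as st

from chiqspr.molgraph import (
    Atom,
    MolParseError,
    MolValidationError,
    parse_connection_table,
    parse_smiles,
    simple_delta,
    valence_delta,
)

from conftest import GEMINI_12_6_12


class TestConnectionTable:
    def test_ethane_with_inferred_hydrogens(self):
        g = parse_connection_table(
            {"name": "ethane", "atoms": [{"element": "C"}, {"element": "C"}], "bonds": [[0, 1]]}
        )
        assert g.n_atoms == 2
        assert all(simple_delta(g, i) == 1 for i in range(2))
        assert all(a.h == 3 for a in g.atoms)

    def test_neutral_nitrogen_with_four_neighbors_rejected(self):
        record = {
            "name": "bad-amine",
            "atoms": [{"element": "N"}] + [{"element": "C"}] * 4,
            "bonds": [[0, i] for i in range(1, 5)],
        }
        with pytest.raises(MolValidationError, match="atom 0"):
            parse_connection_table(record)

    def test_malformed_json_names_line(self):
        with pytest.raises(MolParseError, match="line"):
            parse_connection_table('{"name": "x", "atoms": [}')

    def test_bond_to_missing_atom(self):
        with pytest.raises(MolParseError, match="missing atom"):
            parse_connection_table(
                {"name": "x", "atoms": [{"element": "C"}], "bonds": [[0, 1]]}
            )

    def test_gemini_dication_connection_table(self, gemini_12_6_12):
        # (C12H25)(CH3)2N+(C6H12)N+(CH3)2(C12H25): 12+2+1+6+1+2+12 = 36 atoms
        record = {
            "name": "C12C6C12",
            "atoms": [
                {"element": a.element, "charge": a.formal_charge, "h": a.h}
                for a in gemini_12_6_12.atoms
            ],
            "bonds": [list(b) for b in gemini_12_6_12.bonds],
        }
        g = parse_connection_table(json.dumps(record))
        assert g.n_atoms == 36
        assert g.n_bonds == 35
        assert sum(1 for a in g.atoms if a.element == "N") == 2


class TestSmiles:
    def test_ethane(self):
        g = parse_smiles("CC")
        assert g.n_atoms == 2 and all(simple_delta(g, i) == 1 for i in range(2))

    def test_gemini_dication_atom_count_and_quaternary_nitrogens(self):
        g = parse_smiles(GEMINI_12_6_12)
        assert g.n_atoms == 36
        n_plus = [i for i, a in enumerate(g.atoms) if a.element == "N"]
        assert len(n_plus) == 2
        for i in n_plus:
            assert simple_delta(g, i) == 4
            assert g.atoms[i].formal_charge == 1
            assert g.atoms[i].h == 0

    def test_benzene_ring(self):
        g = parse_smiles("c1ccccc1")
        assert g.n_atoms == 6
        assert all(simple_delta(g, i) == 2 for i in range(6))
        assert all(a.h == 1 for a in g.atoms)

    def test_pyridinium_nitrogen_hydrogen_free(self):
        g = parse_smiles("C[n+]1ccccc1")
        n = next(i for i, a in enumerate(g.atoms) if a.element == "N")
        assert simple_delta(g, n) == 3 and g.atoms[n].h == 0

    @pytest.mark.parametrize("bad", ["C=C", "C#N", "CC(C)(C)(C)C", "C[Si]C", "C/C=C/C", "[13C]C", "CC.Cl"])
    def test_unsupported_features_raise_rather_than_misparse(self, bad):
        with pytest.raises((MolParseError, MolValidationError)):
            parse_smiles(bad)

    def test_parsers_agree_on_fixture_structures(self, structures):
        # SMILES-parsed fixtures vs their own connection-table round trip
        for name, g in structures.items():
            record = {
                "name": name,
                "atoms": [
                    {"element": a.element, "charge": a.formal_charge, "h": a.h,
                     "aromatic": a.aromatic}
                    for a in g.atoms
                ],
                "bonds": [list(b) for b in g.bonds],
            }
            g2 = parse_connection_table(record)
            matcher = nx.algorithms.isomorphism.categorical_node_match(
                ["element", "h", "charge"], [None, None, None]
            )
            assert nx.is_isomorphic(g.to_networkx(), g2.to_networkx(), node_match=matcher)

    def test_agrees_with_rdkit_on_fixture_structures(self, structures):
        pytest.importorskip("rdkit")
        from rdkit import Chem

        from chiqspr.dataset import _read_packaged  # packaged SMILES text

        text = _read_packaged("structures.smi").decode()
        for line in text.splitlines():
            if not line or line.startswith("#"):
                continue
            name, smi = line.split("\t")
            mol = Chem.MolFromSmiles(smi)
            assert mol is not None
            ours = structures[name]
            assert mol.GetNumAtoms() == ours.n_atoms
            assert mol.GetNumBonds() == ours.n_bonds
            ref_h = sorted(a.GetTotalNumHs() for a in mol.GetAtoms())
            assert ref_h == sorted(a.h for a in ours.atoms)


class TestDeltas:
    def test_simple_delta_counts_incident_bonds(self, gemini_12_6_12):
        g = gemini_12_6_12
        for i in range(g.n_atoms):
            assert simple_delta(g, i) == sum(1 for b in g.bonds if i in b)
            assert 1 <= simple_delta(g, i) <= 4

    @pytest.mark.parametrize(
        "atom, expected",
        [
            (Atom("C", h=2), 2.0),              # chain CH2: (4-2)/1
            (Atom("C", h=3), 1.0),              # terminal CH3
            (Atom("N", h=0, formal_charge=1), 5.0),  # quaternary N+: (5-0)/1
            (Atom("O", h=1), 5.0),              # hydroxyl: (6-1)/1
            (Atom("O", h=0), 6.0),              # ether
        ],
    )
    def test_valence_delta_values(self, atom, expected):
        assert valence_delta(atom) == pytest.approx(expected)

    def test_valence_delta_rejects_nonpositive_numerator(self):
        with pytest.raises(MolValidationError):
            valence_delta(Atom("O", h=6))

    def test_carbon_valence_delta_equals_degree(self, small_random_molecules):
        for g in small_random_molecules:
            for i, a in enumerate(g.atoms):
                if a.element == "C":
                    assert valence_delta(a) == pytest.approx(simple_delta(g, i))
                else:
                    assert valence_delta(a) >= simple_delta(g, i)


@settings(max_examples=30, deadline=None)
@given(n=st.integers(min_value=2, max_value=30))
def test_chain_connection_table_valences(n):
    """Unbranched chains always validate with inferred hydrogens 3,2,...,2,3."""
    g = parse_connection_table(
        {"atoms": [{"element": "C"}] * n, "bonds": [[i, i + 1] for i in range(n - 1)]}
    )
    expected = [3] + [2] * (n - 2) + [3] if n > 1 else [4]
    assert [a.h for a in g.atoms] == expected
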