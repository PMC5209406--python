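"""Fragment enumeration and connectivity-index values."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chiqspr.chi_indices import (
    DESCRIPTOR_COLUMNS,
    FragmentTypeError,
    brute_force_chi,
    chi,
    descriptor_row,
    enumerate_fragments,
)
from chiqspr.molgraph import MolecularGraph, parse_smiles


def chain(n):
    return parse_smiles("C" * n)


NEOPENTANE = parse_smiles("CC(C)(C)C")
TWO_METHYLBUTANE = parse_smiles("CCC(C)C")
CYCLOHEXANE = parse_smiles("C1CCCCC1")


class TestEnumeration:
    def test_butane_has_one_three_edge_path(self):
        frags = enumerate_fragments(chain(4), 3, "path")
        assert len(frags) == 1
        assert frags[0].atom_indices == frozenset(range(4))

    def test_neopentane_clusters_by_brute_combinatorics(self):
        # 3-edge stars at the quaternary centre: C(4,3) = 4
        assert len(enumerate_fragments(NEOPENTANE, 3, "cluster")) == 4

    def test_gemini_dication_cluster_count(self, gemini_12_6_12):
        # four 3-edge stars per degree-4 nitrogen
        assert len(enumerate_fragments(gemini_12_6_12, 3, "cluster")) == 8

    def test_fragment_counts_match_degree_combinatorics(self, small_random_molecules):
        for g in small_random_molecules[:50]:
            m1 = sum(len(enumerate_fragments(g, 1, k)) for k in ("path",))
            assert m1 == g.n_bonds
            m2 = len(enumerate_fragments(g, 2, "path"))
            assert m2 == sum(math.comb(g.degree(v), 2) for v in range(g.n_atoms))

    def test_no_triangles_in_cyclohexane(self):
        assert enumerate_fragments(CYCLOHEXANE, 3, "ring") == []
        assert chi(CYCLOHEXANE, 3, "ring").value == 0.0

    def test_six_ring_detected_at_order_six_is_out_of_scope(self):
        with pytest.raises(FragmentTypeError):
            enumerate_fragments(CYCLOHEXANE, 6, "ring")

    @pytest.mark.parametrize("m,k", [(1, "cluster"), (2, "ring"), (3, "path-cluster"), (5, "path")])
    def test_invalid_order_type_combinations(self, m, k):
        with pytest.raises(FragmentTypeError):
            enumerate_fragments(chain(6), m, k)


class TestChiValues:
    def test_chain_first_order_closed_form(self):
        # 1chi of an n-chain is (n-3)/2 + sqrt(2) from the 1,2,...,2,1 degrees
        for n in range(3, 15):
            assert chi(chain(n), 1).value == pytest.approx((n - 3) / 2 + math.sqrt(2))

    def test_pentane_second_order_hand_enumeration(self):
        # 2-edge paths with degree triples (1,2,2), (2,2,2), (2,2,1)
        expected = 2 * (1 * 2 * 2) ** -0.5 + (2 * 2 * 2) ** -0.5
        assert chi(chain(5), 2).value == pytest.approx(expected)
        assert expected == pytest.approx(1.35355, abs=5e-6)

    def test_two_methylbutane_path_cluster(self):
        # single T-shaped 4-edge fragment, degree product 1*3*2*1*1 = 6
        assert chi(TWO_METHYLBUTANE, 4, "path-cluster").value == pytest.approx(6**-0.5)

    def test_ethane_descriptor_row(self):
        row = descriptor_row(parse_smiles("CC"))
        assert row["chi0"] == pytest.approx(2.0)
        assert row["chi1"] == pytest.approx(1.0)
        for col in ("chi2", "chi3c", "chi4pc", "chi2v", "chi3cv", "chi4pcv"):
            assert row[col] == 0.0

    def test_gemini_dication_reproduces_printed_row(self, gemini_12_6_12, training):
        computed = descriptor_row(gemini_12_6_12)
        printed = training.row("C12C6C12").indices
        for col in DESCRIPTOR_COLUMNS:
            assert computed[col] == pytest.approx(printed[col], abs=2e-5), col

    def test_benzene_zeroth_and_ring_orders(self):
        g = parse_smiles("c1ccccc1")
        assert chi(g, 0).value == pytest.approx(6 / math.sqrt(2))
        # six 3-edge paths around the ring, no 3-ring fragments
        assert chi(g, 3, "path").value == pytest.approx(6 * (2**4) ** -0.5)

    def test_carbon_only_molecules_have_equal_simple_and_valence_rows(self):
        for smi in ("CCCCCC", "CC(C)CC(C)(C)C", "C1CCCCC1CC"):
            row = descriptor_row(parse_smiles(smi))
            for base in ("chi0", "chi1", "chi2", "chi3c", "chi4pc"):
                assert row[base] == pytest.approx(row[base + "v"])

    def test_valence_indices_bounded_by_simple_on_study_chemistry(self, training):
        # delta_v >= delta for C, N+, O, so every valence index <= simple one
        for r in training.rows:
            for base in ("chi0", "chi1", "chi2", "chi3c", "chi4pc"):
                assert r.indices[base + "v"] <= r.indices[base] + 1e-9, r.name


class TestOracleEquivalence:
    def test_chi_matches_brute_force_on_random_molecules(self, small_random_molecules):
        recipes = list(DESCRIPTOR_COLUMNS.values()) + [
            (3, "path", False), (3, "ring", True), (4, "ring", False), (4, "cluster", True)
        ]
        for g in small_random_molecules:
            for m, k, valence in recipes:
                fast = chi(g, m, k, valence).value
                slow = brute_force_chi(g, m, k, valence).value
                assert fast == pytest.approx(slow, abs=1e-12)

    def test_brute_force_refuses_large_graphs(self, gemini_12_6_12):
        with pytest.raises(ValueError, match="12"):
            brute_force_chi(gemini_12_6_12, 2)

    def test_empty_fragment_sets_give_zero(self):
        assert brute_force_chi(chain(4), 3, "cluster").value == 0.0
        assert chi(chain(4), 3, "cluster").value == 0.0


@settings(max_examples=50, deadline=None)
@given(seed=st.integers(min_value=0, max_value=10_000))
def test_atom_relabeling_invariance(seed):
    """chi is unchanged under random permutations of the atom numbering."""
    from chiqspr.synthetic_data import SynthesisConfig, random_molecule

    rng = np.random.default_rng(seed)
    g = random_molecule(SynthesisConfig(seed=seed, n_atoms_min=5, n_atoms_max=12, ring_prob=0.3), rng)
    perm = rng.permutation(g.n_atoms)
    inverse = np.argsort(perm)
    relabeled = MolecularGraph(
        atoms=tuple(g.atoms[int(inverse[i])] for i in range(g.n_atoms)),
        bonds=tuple((int(perm[a]), int(perm[b])) for a, b in g.bonds),
        name=g.name,
    )
    for col, (m, k, valence) in DESCRIPTOR_COLUMNS.items():
        assert chi(g, m, k, valence).value == pytest.approx(
            chi(relabeled, m, k, valence).value, abs=1e-12
        ), col


def test_terminal_atom_removal_monotonicity_of_zeroth_order_sum():
    """chi0 of the truncated molecule plus the removed term never drops below
    the full chi0: the ex-neighbour loses a degree, so its term only grows."""
    g = parse_smiles("CC(C)CCCC(C)C")
    full = chi(g, 0).value
    for v in range(g.n_atoms):
        if g.degree(v) != 1:
            continue
        keep = [i for i in range(g.n_atoms) if i != v]
        remap = {old: new for new, old in enumerate(keep)}
        sub = MolecularGraph(
            atoms=tuple(
                # the ex-neighbour gains a hydrogen in the truncated molecule
                a if i != g.neighbors(v)[0] else type(a)(a.element, a.h + 1, a.formal_charge)
                for i, a in enumerate(g.atoms)
                if i != v
            ),
            bonds=tuple(
                (remap[a], remap[b]) for a, b in g.bonds if v not in (a, b)
            ),
        )
        assert chi(sub, 0).value + g.degree(v) ** -0.5 >= full - 1e-12
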