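"""Topology graph, file dialect and bonded-term regeneration."""

import itertools

import networkx as nx
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import molkmc as mk
from molkmc.errors import (
    AtomReferenceError,
    TopologyParseError,
    UnsupportedElementError,
)
from molkmc.topology import Topology, write_topology

METHANE_FILE = """
[ atoms ]
; nr element type resnr resname charge mass
1 C CT 1 MET -0.24 12.011
2 H HC 1 MET 0.06 1.008
3 H HC 1 MET 0.06 1.008
4 H HC 1 MET 0.06 1.008
5 H HC 1 MET 0.06 1.008
[ bonds ]
1 2 1 1.09 50.0
1 3 1 1.09 50.0
1 4 1 1.09 50.0
1 5 1 1.09 50.0
"""


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------


def bfs_distance(adj, a, b):
    """Plain breadth-first search, independent of the implementation."""
    if a == b:
        return 0
    seen = {a}
    frontier = [a]
    d = 0
    while frontier:
        d += 1
        nxt = []
        for u in frontier:
            for v in adj[u]:
                if v == b:
                    return d
                if v not in seen:
                    seen.add(v)
                    nxt.append(v)
        frontier = nxt
    return None


def enumerate_terms(n, edges):
    """Exhaustive path enumeration of angles, proper dihedrals, 1-4 pairs."""
    eset = {frozenset(e) for e in edges}
    adj = {i: sorted(j for j in range(n) if frozenset((i, j)) in eset) for i in range(n)}
    angles = set()
    for i, j, k in itertools.permutations(range(n), 3):
        if frozenset((i, j)) in eset and frozenset((j, k)) in eset:
            angles.add((min(i, k), j, max(i, k)))
    dihedrals = set()
    for quad in itertools.permutations(range(n), 4):
        i, j, k, l = quad
        if (
            frozenset((i, j)) in eset
            and frozenset((j, k)) in eset
            and frozenset((k, l)) in eset
        ):
            dihedrals.add(min(quad, (l, k, j, i)))
    pairs = {
        (i, j)
        for i in range(n)
        for j in range(i + 1, n)
        if bfs_distance(adj, i, j) == 3
    }
    return angles, dihedrals, pairs


def random_molecule(rng, n):
    """Random connected graph on n atoms (tree plus extra edges)."""
    t = Topology()
    for _ in range(n):
        t.add_atom("C")
    for i in range(1, n):
        t.add_bond(int(rng.integers(0, i)), i)
    extra = int(rng.integers(0, max(1, n // 3) + 1))
    for _ in range(extra):
        i, j = rng.integers(0, n, size=2)
        if i != j and not t.has_bond(int(i), int(j)):
            t.add_bond(int(i), int(j))
    return t


# ---------------------------------------------------------------------------
# Parsing and writing
# ---------------------------------------------------------------------------


class TestParse:
    def test_methane_file(self):
        t = mk.parse_topology(METHANE_FILE)
        assert t.n_atoms == 5
        assert len(t.bonds) == 4
        assert len(t.angles) == 0
        assert t.atoms[0].element == "C"
        assert t.atoms[0].charge == pytest.approx(-0.24)

    def test_malformed_line_reports_line_number(self):
        bad = METHANE_FILE.replace("1 5 1 1.09 50.0", "1 5 garbage")
        with pytest.raises(TopologyParseError) as err:
            mk.parse_topology(bad)
        assert err.value.line is not None

    def test_bond_to_unknown_atom(self):
        bad = METHANE_FILE + "1 9\n"
        with pytest.raises((AtomReferenceError, TopologyParseError)):
            mk.parse_topology(bad)

    def test_missing_sections_rejected(self):
        with pytest.raises(TopologyParseError):
            mk.parse_topology("[ atoms ]\n1 C CT 1 MOL 0 12.011\n")

    @pytest.mark.parametrize("fixture", ["ethane", "octyl_radical", "dipeptide_water"])
    def test_write_parse_round_trip(self, fixture, request):
        t, _ = request.getfixturevalue(fixture)
        back = mk.parse_topology(write_topology(t))
        assert t.isclose(back)

    @given(
        n=st.integers(min_value=2, max_value=10),
        seed=st.integers(min_value=0, max_value=10_000),
    )
    def test_round_trip_random_graphs(self, n, seed):
        t = random_molecule(np.random.default_rng(seed), n)
        t = mk.regenerate_bonded_terms(t)
        assert t.isclose(mk.parse_topology(write_topology(t)))


# ---------------------------------------------------------------------------
# Bonded-term regeneration
# ---------------------------------------------------------------------------


class TestRegenerate:
    @pytest.mark.parametrize(
        "fixture, n_angles, n_dihedrals, n_pairs",
        [("methane", 6, 0, 0), ("ethane", 12, 9, 9)],
    )
    def test_small_alkanes(self, fixture, n_angles, n_dihedrals, n_pairs, request):
        t, _ = request.getfixturevalue(fixture)
        out = mk.regenerate_bonded_terms(t)
        assert len(out.angles) == n_angles
        assert len(out.dihedrals) == n_dihedrals
        assert len(out.pairs) == n_pairs

    def test_no_bonds_no_terms(self):
        t = Topology()
        for _ in range(4):
            t.add_atom("C")
        out = mk.regenerate_bonded_terms(t)
        assert (len(out.angles), len(out.dihedrals), len(out.pairs)) == (0, 0, 0)

    def test_matches_enumeration_oracle_on_random_molecules(self):
        rng = np.random.default_rng(20240901)
        for _ in range(20):
            n = int(rng.integers(3, 13))
            t = random_molecule(rng, n)
            out = mk.regenerate_bonded_terms(t)
            angles, dihedrals, pairs = enumerate_terms(n, list(t.bonds))
            assert set(out.angles) == angles
            assert set(out.dihedrals) == dihedrals
            assert out.pairs == pairs

    def test_idempotent(self, octyl_radical):
        t, _ = octyl_radical
        once = mk.regenerate_bonded_terms(t)
        twice = mk.regenerate_bonded_terms(once)
        assert once.isclose(twice)

    def test_parameters_preserved_for_surviving_terms(self, ethane):
        t, _ = ethane
        key = next(iter(t.angles))
        t = t.copy()
        t.angles[key].theta0 = 123.4
        out = mk.regenerate_bonded_terms(t)
        assert out.angles[key].theta0 == pytest.approx(123.4)


# ---------------------------------------------------------------------------
# Graph distance and radicals
# ---------------------------------------------------------------------------


class TestGraphDistance:
    def test_identity_is_zero(self, ethane):
        t, _ = ethane
        assert mk.graph_distance(t, 0, 0) == 0

    def test_octyl_terminal_to_c5(self, octyl_radical):
        t, _ = octyl_radical
        assert mk.graph_distance(t, 0, 4) == 4

    def test_different_molecules_unreachable(self, dipeptide_water):
        t, _ = dipeptide_water
        # water oxygen is in a different molecule than the backbone N-terminus
        assert mk.graph_distance(t, 0, 17) is None

    def test_invalid_index(self, ethane):
        t, _ = ethane
        with pytest.raises(AtomReferenceError):
            mk.graph_distance(t, 0, 99)

    def test_matches_bfs_oracle(self):
        rng = np.random.default_rng(7)
        t = random_molecule(rng, 11)
        adj = t.adjacency()
        for a in range(t.n_atoms):
            for b in range(t.n_atoms):
                assert mk.graph_distance(t, a, b) == bfs_distance(adj, a, b)


class TestFindRadicals:
    def test_saturated_octane_is_closed_shell(self, octane):
        t, _ = octane
        assert len(mk.find_radicals(t)) == 0

    def test_three_bond_carbon_is_radical(self, octyl_radical):
        t, _ = octyl_radical
        rads = mk.find_radicals(t)
        assert rads.counts == {0: 1}

    def test_hydroxyl_oxygen_after_h_abstraction(self):
        t = Topology()
        t.add_atom("C")
        t.add_atom("O")
        for _ in range(3):
            t.add_atom("H")
        t.add_bond(0, 1)
        for h in (2, 3, 4):
            t.add_bond(0, h)
        # C has 4 bonds, O only one: the oxygen is the radical
        assert mk.find_radicals(t).counts == {1: 1}

    def test_unsupported_element(self):
        t = Topology()
        t.add_atom("Xx")
        with pytest.raises(UnsupportedElementError):
            mk.find_radicals(t)

    @given(seed=st.integers(min_value=0, max_value=5_000))
    def test_permutation_equivariance(self, seed):
        """Radical membership commutes with atom relabelling."""
        rng = np.random.default_rng(seed)
        t, _ = mk.build_alkyl_radical(int(rng.integers(3, 9)), 0)
        perm = rng.permutation(t.n_atoms)
        t2 = Topology()
        for new_idx in np.argsort(perm):
            t2.add_atom(t.atoms[new_idx].element)
        for (i, j), bond in t.bonds.items():
            t2.add_bond(int(perm[i]), int(perm[j]), order=bond.order)
        mapped = {int(perm[i]) for i in mk.find_radicals(t).members}
        assert mapped == mk.find_radicals(t2).members


def test_molecule_membership_matches_components(dipeptide_water):
    t, _ = dipeptide_water
    comps = t.molecules()
    assert len(comps) == 2
    g = nx.Graph(list(t.bonds))
    g.add_nodes_from(range(t.n_atoms))
    assert sorted(map(sorted, comps)) == sorted(
        sorted(c) for c in nx.connected_components(g)
    )
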