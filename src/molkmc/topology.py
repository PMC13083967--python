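"""Molecular topology: atoms, bonds, angles, dihedrals and 1-4 pairs.

A :class:`Topology` is the editable substrate of every reaction. It stores a
bond graph plus the bonded terms an MM-style force field needs, and can
regenerate angles, proper dihedrals and 1-4 pairs from the bond graph alone —
which is exactly what has to happen after a reaction breaks or forms bonds.

File dialect
------------
Section-based text mirroring the familiar MD topology layout::

    [ atoms ]
    ; nr element type resnr resname charge mass
    1 C CT 1 MET -0.24 12.011
    [ bonds ]
    ; ai aj order r0 k
    1 2 1 1.07 100.0

Indices are 1-based on disk and 0-based in memory. Comment text after ``;``
is ignored. Angle, dihedral and pair sections are optional because they can
be regenerated. Bond order (default 1) feeds valence-deficit radical
detection; double bonds (order 2) keep carbonyl carbons from being
misidentified as radicals.
"""

from __future__ import annotations

import copy as _copy
import hashlib
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import networkx as nx

from .errors import (
    AtomReferenceError,
    TopologyParseError,
    UnsupportedElementError,
)

#: Nominal valences used for radical (valence-deficit) detection.
DEFAULT_VALENCE: dict[str, int] = {"H": 1, "C": 4, "N": 3, "O": 2, "S": 2, "P": 3}

#: Atomic masses, u.
ELEMENT_MASSES: dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "P": 30.974,
}


@dataclass
class Atom:
    """One atom; ``index`` equals its position in ``Topology.atoms``."""

    index: int
    element: str
    type_label: str = ""
    residue_index: int = 1
    residue_name: str = "MOL"
    charge: float = 0.0
    mass: float | None = None

    def __post_init__(self) -> None:
        if self.mass is None:
            self.mass = ELEMENT_MASSES.get(self.element, 12.0)
        if not self.type_label:
            self.type_label = self.element


@dataclass
class BondParams:
    """Harmonic bond: U = k (r - r0)^2. r0 in Å, k in kcal mol⁻¹ Å⁻²."""

    r0: float
    k: float


@dataclass
class AngleParams:
    """Harmonic angle: U = k (θ - θ0)^2. θ0 in degrees, k in kcal mol⁻¹ rad⁻²."""

    theta0: float
    k: float


@dataclass
class DihedralParams:
    """Periodic torsion: U = k (1 + cos(nφ - phase)). k kcal/mol, phase deg."""

    k: float
    n: int
    phase: float


@dataclass
class Bond:
    params: BondParams | None = None
    order: float = 1.0


@dataclass
class RadicalSet:
    """Atoms with at least one unpaired electron (valence deficit)."""

    counts: dict[int, int] = field(default_factory=dict)

    @property
    def members(self) -> set[int]:
        return set(self.counts)

    def __contains__(self, index: int) -> bool:
        return index in self.counts

    def __len__(self) -> int:
        return len(self.counts)

    def __iter__(self) -> Iterator[int]:
        return iter(sorted(self.counts))


def canonical_bond(i: int, j: int) -> tuple[int, int]:
    return (i, j) if i < j else (j, i)


def canonical_angle(i: int, j: int, k: int) -> tuple[int, int, int]:
    return (i, j, k) if i < k else (k, j, i)


def canonical_dihedral(i: int, j: int, k: int, l: int) -> tuple[int, int, int, int]:
    fwd = (i, j, k, l)
    rev = (l, k, j, i)
    return fwd if fwd <= rev else rev


class Topology:
    """Molecular graph plus bonded terms.

    Bonds are keyed by sorted index pairs, angles by (i, j, k) with i < k,
    proper dihedrals by the lexicographically smaller of the two orientations.
    Improper dihedrals are carried as parsed and never auto-generated.
    """

    def __init__(self, atoms: Iterable[Atom] = ()):
        self.atoms: list[Atom] = list(atoms)
        self.bonds: dict[tuple[int, int], Bond] = {}
        self.angles: dict[tuple[int, int, int], AngleParams | None] = {}
        self.dihedrals: dict[tuple[int, int, int, int], DihedralParams | None] = {}
        self.impropers: dict[tuple[int, int, int, int], DihedralParams | None] = {}
        self.pairs: set[tuple[int, int]] = set()

    # -- basic structure ---------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def check_index(self, i: int) -> None:
        if not (0 <= i < self.n_atoms):
            raise AtomReferenceError(f"atom index {i} out of range (n={self.n_atoms})")

    def add_atom(self, element: str, **kwargs) -> Atom:
        atom = Atom(index=self.n_atoms, element=element, **kwargs)
        self.atoms.append(atom)
        return atom

    def has_bond(self, i: int, j: int) -> bool:
        return canonical_bond(i, j) in self.bonds

    def add_bond(
        self,
        i: int,
        j: int,
        params: BondParams | None = None,
        order: float = 1.0,
    ) -> None:
        if i == j:
            raise AtomReferenceError(f"self-bond on atom {i}")
        self.check_index(i)
        self.check_index(j)
        key = canonical_bond(i, j)
        if key in self.bonds:
            raise AtomReferenceError(f"duplicate bond {key}")
        self.bonds[key] = Bond(params=params, order=order)

    def remove_bond(self, i: int, j: int) -> None:
        key = canonical_bond(i, j)
        if key not in self.bonds:
            raise AtomReferenceError(f"no bond {key} to remove")
        del self.bonds[key]

    def neighbors(self, i: int) -> list[int]:
        self.check_index(i)
        out = []
        for (a, b) in self.bonds:
            if a == i:
                out.append(b)
            elif b == i:
                out.append(a)
        return sorted(out)

    def adjacency(self) -> dict[int, list[int]]:
        adj: dict[int, list[int]] = {i: [] for i in range(self.n_atoms)}
        for (a, b) in self.bonds:
            adj[a].append(b)
            adj[b].append(a)
        for v in adj.values():
            v.sort()
        return adj

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_atoms))
        g.add_edges_from(self.bonds)
        return g

    def molecules(self) -> list[set[int]]:
        """Connected components of the bond graph, sorted by smallest member."""
        comps = [set(c) for c in nx.connected_components(self.graph())]
        return sorted(comps, key=min)

    def molecule_of(self, i: int) -> int:
        self.check_index(i)
        for m, comp in enumerate(self.molecules()):
            if i in comp:
                return m
        raise AtomReferenceError(f"atom {i} not in any molecule")  # pragma: no cover

    def bond_degree(self, i: int) -> float:
        """Sum of bond orders at atom i (valence actually used)."""
        deg = 0.0
        for (a, b), bond in self.bonds.items():
            if i in (a, b):
                deg += bond.order
        return deg

    def copy(self) -> "Topology":
        return _copy.deepcopy(self)

    # -- invariants --------------------------------------------------------

    def validate(self) -> list[str]:
        """Return a list of invariant violations (empty when consistent)."""
        violations: list[str] = []
        for pos, atom in enumerate(self.atoms):
            if atom.index != pos:
                violations.append(f"atom index {atom.index} at position {pos}")
        for (a, b) in self.bonds:
            if a == b:
                violations.append(f"self-bond {a}")
            if not (0 <= a < self.n_atoms and 0 <= b < self.n_atoms):
                violations.append(f"bond {(a, b)} references unknown atom")
        for (i, j, k) in self.angles:
            if not (self.has_bond(i, j) and self.has_bond(j, k)):
                violations.append(f"angle {(i, j, k)} not backed by bonds")
        for (i, j, k, l) in self.dihedrals:
            if not (
                self.has_bond(i, j) and self.has_bond(j, k) and self.has_bond(k, l)
            ):
                violations.append(f"dihedral {(i, j, k, l)} not backed by bonds")
        dist3 = _pairs_at_distance_3(self.adjacency())
        for p in self.pairs:
            if p not in dist3:
                violations.append(f"pair {p} not at bond-graph distance 3")
        return violations

    def digest(self) -> str:
        """Stable content hash of the full topology (for provenance records)."""
        return hashlib.sha256(write_topology(self).encode()).hexdigest()

    def isclose(self, other: "Topology", rtol: float = 1e-5) -> bool:
        """Structural and numeric equality up to relative tolerance."""

        def close(x, y):
            if x is None and y is None:
                return True
            if x is None or y is None:
                return False
            return abs(x - y) <= rtol * max(1.0, abs(x), abs(y))

        if self.n_atoms != other.n_atoms:
            return False
        for a, b in zip(self.atoms, other.atoms):
            if (a.element, a.type_label, a.residue_index, a.residue_name) != (
                b.element,
                b.type_label,
                b.residue_index,
                b.residue_name,
            ):
                return False
            if not (close(a.charge, b.charge) and close(a.mass, b.mass)):
                return False
        if set(self.bonds) != set(other.bonds):
            return False
        for key, bond in self.bonds.items():
            ob = other.bonds[key]
            if not close(bond.order, ob.order):
                return False
            if (bond.params is None) != (ob.params is None):
                return False
            if bond.params is not None and not (
                close(bond.params.r0, ob.params.r0)
                and close(bond.params.k, ob.params.k)
            ):
                return False
        for mine, theirs in (
            (self.angles, other.angles),
            (self.dihedrals, other.dihedrals),
            (self.impropers, other.impropers),
        ):
            if set(mine) != set(theirs):
                return False
            for key, p in mine.items():
                q = theirs[key]
                if (p is None) != (q is None):
                    return False
                if p is None:
                    continue
                fields_p = [getattr(p, f) for f in ("k",)]
                fields_q = [getattr(q, f) for f in ("k",)]
                if hasattr(p, "theta0"):
                    fields_p.append(p.theta0)
                    fields_q.append(q.theta0)
                if hasattr(p, "phase"):
                    fields_p += [p.n, p.phase]
                    fields_q += [q.n, q.phase]
                if not all(close(x, y) for x, y in zip(fields_p, fields_q)):
                    return False
        return self.pairs == other.pairs


# ---------------------------------------------------------------------------
# Bonded-term regeneration
# ---------------------------------------------------------------------------


def _pairs_at_distance_3(adj: dict[int, list[int]]) -> set[tuple[int, int]]:
    """All atom pairs whose shortest bond-graph distance is exactly 3."""
    out: set[tuple[int, int]] = set()
    for src in adj:
        dist = {src: 0}
        frontier = [src]
        for d in (1, 2, 3):
            nxt = []
            for u in frontier:
                for v in adj[u]:
                    if v not in dist:
                        dist[v] = d
                        nxt.append(v)
            frontier = nxt
        for v, d in dist.items():
            if d == 3 and src < v:
                out.add((src, v))
    return out


def regenerate_bonded_terms(t: Topology) -> Topology:
    """Rebuild angles, proper dihedrals and 1-4 pairs from the bond graph.

    Angles are all length-2 simple bond paths, proper dihedrals all length-3
    simple bond paths, pairs all atom pairs at shortest bond-graph distance
    exactly 3. Parameters of terms that survive the edit are preserved; new
    terms are parameterized generically. Improper dihedrals pass through
    untouched. Idempotent.
    """
    out = t.copy()
    adj = out.adjacency()

    angles: dict[tuple[int, int, int], AngleParams | None] = {}
    for j, nbrs in adj.items():
        for ii in range(len(nbrs)):
            for kk in range(ii + 1, len(nbrs)):
                key = canonical_angle(nbrs[ii], j, nbrs[kk])
                angles[key] = t.angles.get(key)

    dihedrals: dict[tuple[int, int, int, int], DihedralParams | None] = {}
    for (j, k) in out.bonds:
        for i in adj[j]:
            if i == k:
                continue
            for l in adj[k]:
                if l == j or l == i:
                    continue
                key = canonical_dihedral(i, j, k, l)
                dihedrals[key] = t.dihedrals.get(key)

    out.angles = dict(sorted(angles.items()))
    out.dihedrals = dict(sorted(dihedrals.items()))
    out.pairs = _pairs_at_distance_3(adj)

    from .forcefield import assign_generic_parameters  # deferred: avoids cycle

    return assign_generic_parameters(out)


def graph_distance(t: Topology, a: int, b: int) -> int | None:
    """Minimal number of bonds between a and b; None when disconnected."""
    t.check_index(a)
    t.check_index(b)
    if a == b:
        return 0
    try:
        return nx.shortest_path_length(t.graph(), a, b)
    except nx.NetworkXNoPath:
        return None


def find_radicals(
    t: Topology, valence_table: dict[str, int] | None = None
) -> RadicalSet:
    """Detect radicals as valence deficits of the bond graph.

    An atom is a radical iff its bond-order sum is below the nominal valence
    of its element; the unpaired-electron count is the deficit. Over-bonded
    atoms (possible after ring-forming recipes) clamp at zero and are not
    members.
    """
    table = DEFAULT_VALENCE if valence_table is None else valence_table
    counts: dict[int, int] = {}
    for atom in t.atoms:
        if atom.element not in table:
            raise UnsupportedElementError(
                f"element {atom.element!r} not in valence table"
            )
        deficit = int(round(table[atom.element] - t.bond_degree(atom.index)))
        if deficit >= 1:
            counts[atom.index] = deficit
    return RadicalSet(counts)


# ---------------------------------------------------------------------------
# Reading and writing
# ---------------------------------------------------------------------------

_SECTION_ORDER = ("atoms", "bonds", "pairs", "angles", "dihedrals")


def _fmt(x: float) -> str:
    return f"{x:.6g}"


def write_topology(t: Topology) -> str:
    lines: list[str] = []
    lines.append("[ atoms ]")
    lines.append("; nr element type resnr resname charge mass")
    for a in t.atoms:
        lines.append(
            f"{a.index + 1} {a.element} {a.type_label} {a.residue_index} "
            f"{a.residue_name} {_fmt(a.charge)} {_fmt(a.mass)}"
        )
    lines.append("[ bonds ]")
    lines.append("; ai aj order [r0 k]")
    for (i, j) in sorted(t.bonds):
        bond = t.bonds[(i, j)]
        row = f"{i + 1} {j + 1} {_fmt(bond.order)}"
        if bond.params is not None:
            row += f" {_fmt(bond.params.r0)} {_fmt(bond.params.k)}"
        lines.append(row)
    if t.pairs:
        lines.append("[ pairs ]")
        lines.append("; ai aj")
        for (i, j) in sorted(t.pairs):
            lines.append(f"{i + 1} {j + 1}")
    if t.angles:
        lines.append("[ angles ]")
        lines.append("; ai aj ak [theta0 k]")
        for key in sorted(t.angles):
            p = t.angles[key]
            row = " ".join(str(x + 1) for x in key)
            if p is not None:
                row += f" {_fmt(p.theta0)} {_fmt(p.k)}"
            lines.append(row)
    if t.dihedrals or t.impropers:
        lines.append("[ dihedrals ]")
        lines.append("; ai aj ak al kind [k n phase]")
        for store, kind in ((t.dihedrals, "p"), (t.impropers, "i")):
            for key in sorted(store):
                p = store[key]
                row = " ".join(str(x + 1) for x in key) + f" {kind}"
                if p is not None:
                    row += f" {_fmt(p.k)} {p.n} {_fmt(p.phase)}"
                lines.append(row)
    return "\n".join(lines) + "\n"


def _parse_index(tok: str, n_atoms: int, lineno: int) -> int:
    try:
        idx = int(tok)
    except ValueError as exc:
        raise TopologyParseError(f"bad atom index {tok!r}", lineno) from exc
    if not (1 <= idx <= n_atoms):
        raise AtomReferenceError(
            f"line {lineno}: atom index {idx} references unknown atom"
        )
    return idx - 1


def _parse_float(tok: str, lineno: int, what: str) -> float:
    try:
        return float(tok)
    except ValueError as exc:
        raise TopologyParseError(f"bad {what} {tok!r}", lineno) from exc


def parse_topology(text: str) -> Topology:
    """Parse the section-based dialect described in the module docstring."""
    t = Topology()
    section: str | None = None
    seen_atoms = False
    seen_bonds = False
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split(";", 1)[0].strip()
        if not line:
            continue
        if line.startswith("["):
            name = line.strip("[] \t").lower()
            if name not in _SECTION_ORDER:
                raise TopologyParseError(f"unknown section {name!r}", lineno)
            section = name
            seen_atoms = seen_atoms or name == "atoms"
            seen_bonds = seen_bonds or name == "bonds"
            continue
        toks = line.split()
        if section == "atoms":
            if len(toks) not in (5, 7):
                raise TopologyParseError(
                    "atom line needs 5 or 7 fields "
                    "(nr element type resnr resname [charge mass])",
                    lineno,
                )
            nr = int(toks[0])
            if nr != t.n_atoms + 1:
                raise TopologyParseError(
                    f"atom numbers must be contiguous, got {nr}", lineno
                )
            charge = _parse_float(toks[5], lineno, "charge") if len(toks) == 7 else 0.0
            mass = _parse_float(toks[6], lineno, "mass") if len(toks) == 7 else None
            t.atoms.append(
                Atom(
                    index=nr - 1,
                    element=toks[1],
                    type_label=toks[2],
                    residue_index=int(toks[3]),
                    residue_name=toks[4],
                    charge=charge,
                    mass=mass,
                )
            )
        elif section == "bonds":
            if len(toks) not in (2, 3, 5):
                raise TopologyParseError(
                    "bond line needs 2, 3 or 5 fields (ai aj [order [r0 k]])", lineno
                )
            i = _parse_index(toks[0], t.n_atoms, lineno)
            j = _parse_index(toks[1], t.n_atoms, lineno)
            order = _parse_float(toks[2], lineno, "order") if len(toks) >= 3 else 1.0
            params = None
            if len(toks) == 5:
                params = BondParams(
                    r0=_parse_float(toks[3], lineno, "r0"),
                    k=_parse_float(toks[4], lineno, "k"),
                )
            try:
                t.add_bond(i, j, params=params, order=order)
            except AtomReferenceError as exc:
                raise TopologyParseError(str(exc), lineno) from exc
        elif section == "pairs":
            if len(toks) != 2:
                raise TopologyParseError("pair line needs 2 fields", lineno)
            i = _parse_index(toks[0], t.n_atoms, lineno)
            j = _parse_index(toks[1], t.n_atoms, lineno)
            t.pairs.add(canonical_bond(i, j))
        elif section == "angles":
            if len(toks) not in (3, 5):
                raise TopologyParseError(
                    "angle line needs 3 or 5 fields (ai aj ak [theta0 k])", lineno
                )
            idx = tuple(_parse_index(x, t.n_atoms, lineno) for x in toks[:3])
            params = None
            if len(toks) == 5:
                params = AngleParams(
                    theta0=_parse_float(toks[3], lineno, "theta0"),
                    k=_parse_float(toks[4], lineno, "k"),
                )
            t.angles[canonical_angle(*idx)] = params
        elif section == "dihedrals":
            if len(toks) not in (5, 8):
                raise TopologyParseError(
                    "dihedral line needs 5 or 8 fields (ai aj ak al kind [k n phase])",
                    lineno,
                )
            idx = tuple(_parse_index(x, t.n_atoms, lineno) for x in toks[:4])
            kind = toks[4].lower()
            if kind not in ("p", "i"):
                raise TopologyParseError(f"dihedral kind must be p or i, got {kind!r}", lineno)
            params = None
            if len(toks) == 8:
                params = DihedralParams(
                    k=_parse_float(toks[5], lineno, "k"),
                    n=int(toks[6]),
                    phase=_parse_float(toks[7], lineno, "phase"),
                )
            if kind == "p":
                t.dihedrals[canonical_dihedral(*idx)] = params
            else:
                t.impropers[idx] = params
        else:
            raise TopologyParseError("content outside any section", lineno)
    if not seen_atoms or not seen_bonds:
        raise TopologyParseError("topology must contain atoms and bonds sections")
    return t


def read_topology(path) -> Topology:
    with open(path) as fh:
        return parse_topology(fh.read())


def save_topology(t: Topology, path) -> None:
    with open(path, "w") as fh:
        fh.write(write_topology(t))
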