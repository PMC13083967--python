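"""Built-in molecular fixtures.

Deterministic generators for the systems the package is exercised on:
n-alkanes and alkane-derived radicals (3-8 carbons), a glycylglycine-like
dipeptide with one explicit water for hydrolysis, and a stacked thymine
pair for dimerization. Geometries are idealised (tetrahedral carbons,
planar rings), tidied by a short deterministic minimisation; the graphs,
bond orders and element assignments are the chemically meaningful part.
"""

from __future__ import annotations

import numpy as np

from .ensemble import Frame
from .errors import MolkmcError
from .forcefield import ToyForceField, assign_generic_parameters, minimize
from .topology import Topology, regenerate_bonded_terms

CC_BOND = 1.526
CH_BOND = 1.09
TETRA = 109.5  # deg


def _finish(t: Topology, pos: np.ndarray, relax_steps: int = 60) -> tuple[Topology, Frame]:
    t = regenerate_bonded_terms(t)
    t = assign_generic_parameters(t)
    if relax_steps:
        pos = minimize(ToyForceField(t), pos, n_steps=relax_steps, max_step=0.05)
    return t, Frame(positions=pos)


def _terminal_h_dirs(u: np.ndarray, n_h: int, phase: float = 0.0) -> list[np.ndarray]:
    """Directions making the tetrahedral angle with bond direction ``u``."""
    u = u / np.linalg.norm(u)
    ref = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(ref, u)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    p = np.cross(u, ref)
    p /= np.linalg.norm(p)
    q = np.cross(u, p)
    cos_t = np.cos(np.deg2rad(180.0 - TETRA))  # component along -u
    sin_t = np.sin(np.deg2rad(180.0 - TETRA))
    dirs = []
    for k in range(n_h):
        gamma = phase + 2.0 * np.pi * k / max(n_h, 1)
        d = -cos_t * u + sin_t * (np.cos(gamma) * p + np.sin(gamma) * q)
        dirs.append(d / np.linalg.norm(d))
    return dirs


def _interior_h_dirs(u1: np.ndarray, u2: np.ndarray) -> list[np.ndarray]:
    """Two directions completing an approximate tetrahedron around a centre
    already bonded along unit vectors u1 and u2."""
    s = -(u1 + u2)
    ns = np.linalg.norm(s)
    s = s / ns if ns > 1e-8 else np.array([0.0, 0.0, 1.0])
    p = np.cross(u1, u2)
    np_ = np.linalg.norm(p)
    if np_ < 1e-8:
        p = np.cross(u1, np.array([0.0, 0.0, 1.0]))
        np_ = np.linalg.norm(p)
    p /= np_
    d1 = s + 1.15 * p
    d2 = s - 1.15 * p
    return [d1 / np.linalg.norm(d1), d2 / np.linalg.norm(d2)]


def _build_alkane_graph(n_carbons: int, skip_h_on: int | None = None):
    """All-trans alkane topology and idealised coordinates.

    ``skip_h_on`` omits one hydrogen on that carbon (radical site).
    """
    t = Topology()
    half = np.deg2rad((180.0 - 112.0) / 2.0)
    step = np.array([np.cos(half), np.sin(half), 0.0]) * CC_BOND
    carbons = []
    pos_list: list[np.ndarray] = []
    p = np.zeros(3)
    for i in range(n_carbons):
        a = t.add_atom("C", type_label="CT", residue_name="ALK")
        carbons.append(a.index)
        pos_list.append(p.copy())
        p = p + step * np.array([1.0, (-1.0) ** i, 1.0])
    for i in range(n_carbons - 1):
        t.add_bond(carbons[i], carbons[i + 1])

    for ci, c in enumerate(carbons):
        n_existing = []
        if ci > 0:
            n_existing.append(pos_list[carbons[ci - 1]] - pos_list[c])
        if ci < n_carbons - 1:
            n_existing.append(pos_list[carbons[ci + 1]] - pos_list[c])
        n_h_full = 4 - len(n_existing)
        n_h = n_h_full - (1 if c == skip_h_on else 0)
        if len(n_existing) == 0:  # methane
            dirs = [
                np.array(v) / np.sqrt(3.0)
                for v in (
                    (1, 1, 1),
                    (1, -1, -1),
                    (-1, 1, -1),
                    (-1, -1, 1),
                )
            ][:n_h]
        elif len(n_existing) == 1:
            dirs = _terminal_h_dirs(n_existing[0] / np.linalg.norm(n_existing[0]), n_h)
        else:
            u1 = n_existing[0] / np.linalg.norm(n_existing[0])
            u2 = n_existing[1] / np.linalg.norm(n_existing[1])
            dirs = _interior_h_dirs(u1, u2)[:n_h]
        for d in dirs:
            h = t.add_atom("H", type_label="HC", residue_name="ALK")
            t.add_bond(c, h.index)
            pos_list.append(pos_list[c] + CH_BOND * d)
    return t, np.array(pos_list), carbons


def build_alkane(n_carbons: int, seed: int = 0) -> tuple[Topology, Frame]:
    """Saturated n-alkane (1-8 carbons) with idealised all-trans geometry."""
    if not (1 <= n_carbons <= 8):
        raise MolkmcError("n_carbons must be in 1..8")
    t, pos, _ = _build_alkane_graph(n_carbons)
    rng = np.random.default_rng(seed)
    pos = pos + rng.normal(0.0, 0.01, size=pos.shape)
    return _finish(t, pos)


def build_alkyl_radical(
    n_carbons: int, radical_carbon: int = 0, seed: int = 0
) -> tuple[Topology, Frame]:
    """n-Alkyl radical: an all-trans alkane with one hydrogen removed.

    ``radical_carbon`` is the zero-based carbon index along the chain (the
    1-alkyl radical is ``radical_carbon=0``). Exactly that carbon carries
    one unpaired electron afterwards.
    """
    if not (3 <= n_carbons <= 8):
        raise MolkmcError("n_carbons must be in 3..8")
    if not (0 <= radical_carbon < n_carbons):
        raise MolkmcError(
            f"radical_carbon must be in 0..{n_carbons - 1}, got {radical_carbon}"
        )
    t, pos, carbons = _build_alkane_graph(
        n_carbons, skip_h_on=radical_carbon
    )
    rng = np.random.default_rng(seed)
    pos = pos + rng.normal(0.0, 0.01, size=pos.shape)
    return _finish(t, pos)


def build_dipeptide_with_water(seed: int = 0) -> tuple[Topology, Frame]:
    """Glycylglycine-like dipeptide plus one explicit water.

    Backbone: H2N-CH2-C(=O)-NH-CH2-COOH; the carbonyl and carboxyl oxygens
    carry order-2 bonds so the molecule is closed-shell under valence-deficit
    radical detection. The water sits near the amide bond, ready for the
    hydrolysis recipe.
    """
    t = Topology()
    pos: list[tuple[float, float, float]] = []

    def add(elem, x, y, z, residue_name="GG"):
        a = t.add_atom(elem, residue_name=residue_name)
        pos.append((x, y, z))
        return a.index

    n1 = add("N", 0.0, 0.0, 0.0)
    h_n1a = add("H", -0.5, 0.8, 0.0)
    h_n1b = add("H", -0.5, -0.8, 0.0)
    ca1 = add("C", 1.45, 0.0, 0.0)
    h_ca1a = add("H", 1.8, 0.5, 0.9)
    h_ca1b = add("H", 1.8, 0.5, -0.9)
    c1 = add("C", 2.0, -1.4, 0.0)  # carbonyl
    o1 = add("O", 1.3, -2.4, 0.0)
    n2 = add("N", 3.35, -1.5, 0.0)
    h_n2 = add("H", 3.9, -0.7, 0.0)
    ca2 = add("C", 4.05, -2.8, 0.0)
    h_ca2a = add("H", 3.8, -3.35, 0.9)
    h_ca2b = add("H", 3.8, -3.35, -0.9)
    c2 = add("C", 5.55, -2.6, 0.0)  # carboxyl
    o2 = add("O", 6.3, -3.55, 0.0)
    oxt = add("O", 6.05, -1.35, 0.0)
    h_oxt = add("H", 7.0, -1.3, 0.0)
    ow = add("O", 3.0, -1.0, 3.0, residue_name="HOH")
    hw1 = add("H", 3.55, -0.25, 3.2, residue_name="HOH")
    hw2 = add("H", 2.25, -0.9, 3.6, residue_name="HOH")

    for i, j, order in [
        (n1, h_n1a, 1), (n1, h_n1b, 1), (n1, ca1, 1),
        (ca1, h_ca1a, 1), (ca1, h_ca1b, 1), (ca1, c1, 1),
        (c1, o1, 2), (c1, n2, 1),
        (n2, h_n2, 1), (n2, ca2, 1),
        (ca2, h_ca2a, 1), (ca2, h_ca2b, 1), (ca2, c2, 1),
        (c2, o2, 2), (c2, oxt, 1), (oxt, h_oxt, 1),
        (ow, hw1, 1), (ow, hw2, 1),
    ]:
        t.add_bond(i, j, order=order)

    rng = np.random.default_rng(seed)
    arr = np.array(pos) + rng.normal(0.0, 0.01, size=(len(pos), 3))
    return _finish(t, arr)


def _add_thymine(t: Topology, pos: list, z: float, rot: float = 0.0) -> dict[str, int]:
    """One thymine ring in the plane at height ``z``; returns atom roles."""
    r_ring = 1.39
    names = ["N1", "C2", "N3", "C4", "C5", "C6"]
    elems = ["N", "C", "N", "C", "C", "C"]
    idx: dict[str, int] = {}
    for k, (nm, el) in enumerate(zip(names, elems)):
        ang = rot + np.deg2rad(60.0 * k)
        a = t.add_atom(el, type_label=nm, residue_name="THY")
        idx[nm] = a.index
        pos.append((r_ring * np.cos(ang), r_ring * np.sin(ang), z))

    def radial(nm, dist, dz=0.0):
        ang = rot + np.deg2rad(60.0 * names.index(nm))
        base = np.array([np.cos(ang), np.sin(ang), 0.0])
        ring = np.array(pos[idx[nm]])
        return tuple(ring + dist * base + np.array([0.0, 0.0, dz]))

    for nm, el, dist in [("O2", "O", 1.22), ("O4", "O", 1.22), ("C7", "C", 1.50)]:
        src = {"O2": "C2", "O4": "C4", "C7": "C5"}[nm]
        a = t.add_atom(el, type_label=nm, residue_name="THY")
        idx[nm] = a.index
        ang = rot + np.deg2rad(60.0 * names.index(src))
        ring = np.array(pos[idx[src]])
        pos.append(tuple(ring + dist * np.array([np.cos(ang), np.sin(ang), 0.0])))
    for nm, src, dist in [("H1", "N1", 1.01), ("H3", "N3", 1.01), ("H6", "C6", 1.09)]:
        a = t.add_atom("H", type_label=nm, residue_name="THY")
        idx[nm] = a.index
        ang = rot + np.deg2rad(60.0 * names.index(src))
        ring = np.array(pos[idx[src]])
        pos.append(tuple(ring + dist * np.array([np.cos(ang), np.sin(ang), 0.0])))
    c7 = np.array(pos[idx["C7"]])
    u = c7 - np.array(pos[idx["C5"]])
    for k, d in enumerate(_terminal_h_dirs(u, 3)):
        a = t.add_atom("H", type_label=f"H7{k}", residue_name="THY")
        idx[f"H7{k}"] = a.index
        pos.append(tuple(c7 + CH_BOND * d))

    for i, j, order in [
        (idx["N1"], idx["C2"], 1), (idx["C2"], idx["N3"], 1),
        (idx["N3"], idx["C4"], 1), (idx["C4"], idx["C5"], 1),
        (idx["C5"], idx["C6"], 2), (idx["C6"], idx["N1"], 1),
        (idx["C2"], idx["O2"], 2), (idx["C4"], idx["O4"], 2),
        (idx["C5"], idx["C7"], 1),
        (idx["N1"], idx["H1"], 1), (idx["N3"], idx["H3"], 1),
        (idx["C6"], idx["H6"], 1),
        (idx["C7"], idx["H70"], 1), (idx["C7"], idx["H71"], 1),
        (idx["C7"], idx["H72"], 1),
    ]:
        t.add_bond(i, j, order=order)
    return idx


def build_thymine_pair(
    separation: float = 3.6, seed: int = 0
) -> tuple[Topology, Frame, dict[str, int]]:
    """Two stacked thymines; returns (topology, frame, sites).

    ``sites`` maps c5a/c6a/c5b/c6b to the reactive double-bond carbons.
    The stacking separation (Å) is the distance between ring planes.
    """
    t = Topology()
    pos: list = []
    a = _add_thymine(t, pos, z=0.0)
    b = _add_thymine(t, pos, z=separation)
    sites = {"c5a": a["C5"], "c6a": a["C6"], "c5b": b["C5"], "c6b": b["C6"]}
    rng = np.random.default_rng(seed)
    arr = np.array(pos) + rng.normal(0.0, 0.005, size=(len(pos), 3))
    topo, frame = _finish(t, arr, relax_steps=0)
    return topo, frame, sites


def find_cc_double_bonds(t: Topology) -> list[tuple[int, int]]:
    """Sorted list of order-2 carbon-carbon bonds (dimerization sites)."""
    out = []
    for (i, j), bond in t.bonds.items():
        if bond.order == 2 and t.atoms[i].element == "C" and t.atoms[j].element == "C":
            out.append((i, j))
    return sorted(out)
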