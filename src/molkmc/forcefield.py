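"""Generic parameter assignment and the toy force field.

The assigner fills in harmonic bond/angle and periodic dihedral parameters
from small element-based tables whenever a regenerated term has none — the
stand-in for a proper force-field reparametrisation step after a reaction.

The toy force field used for ensemble generation and relaxation is
deliberately minimal: harmonic bonds, harmonic angles and a purely repulsive
pairwise penalty between topologically distant atoms that prevents chain
collapse without any Lennard-Jones machinery. Torsions are unrestrained,
which makes conformational mixing fast — desirable for a sampler whose only
contract is the stationary (Boltzmann) distribution, not realistic dynamics.
"""

from __future__ import annotations

import numpy as np

from .errors import ParameterizationError
from .topology import (
    AngleParams,
    BondParams,
    DihedralParams,
    Topology,
)

#: Covalent radii (Å) for generic equilibrium bond lengths (sum of radii).
COVALENT_RADII: dict[str, float] = {
    "H": 0.31,
    "C": 0.76,
    "N": 0.71,
    "O": 0.66,
    "S": 1.05,
    "P": 1.07,
}

#: Generic equilibrium angles (deg) keyed by the central element.
GENERIC_ANGLES: dict[str, float] = {
    "C": 109.5,
    "N": 112.0,
    "O": 104.5,
    "S": 96.0,
    "P": 95.0,
}

DEFAULT_BOND_K = 50.0  # kcal mol^-1 Å^-2
DEFAULT_ANGLE_K = 15.0  # kcal mol^-1 rad^-2
DEFAULT_DIHEDRAL = DihedralParams(k=0.3, n=3, phase=0.0)

#: Repulsion between atoms at bond-graph distance >= 4 (or in different
#: molecules): U = k (r - r_c)^2 for r < r_c, zero otherwise.
REPULSION_CUTOFF = 2.5  # Å
REPULSION_K = 2.0  # kcal mol^-1 Å^-2; soft so bonded statistics stay unbiased


def generic_bond_length(elem_i: str, elem_j: str) -> float:
    return COVALENT_RADII.get(elem_i, 0.76) + COVALENT_RADII.get(elem_j, 0.76)


def assign_generic_parameters(t: Topology) -> Topology:
    """Fill missing bonded parameters in a copy of ``t``.

    Existing parameters are never overwritten, so force-field information
    survives reactions wherever the term itself survives.
    """
    out = t.copy()
    for (i, j), bond in out.bonds.items():
        if bond.params is None:
            bond.params = BondParams(
                r0=generic_bond_length(out.atoms[i].element, out.atoms[j].element),
                k=DEFAULT_BOND_K,
            )
    for key, params in out.angles.items():
        if params is None:
            center = out.atoms[key[1]].element
            out.angles[key] = AngleParams(
                theta0=GENERIC_ANGLES.get(center, 109.5), k=DEFAULT_ANGLE_K
            )
    for key, params in out.dihedrals.items():
        if params is None:
            out.dihedrals[key] = DihedralParams(
                k=DEFAULT_DIHEDRAL.k, n=DEFAULT_DIHEDRAL.n, phase=DEFAULT_DIHEDRAL.phase
            )
    return out


class ToyForceField:
    """Vectorised energies and forces on a fixed topology.

    Terms: harmonic bonds U = k (r - r0)^2, harmonic angles
    U = k (θ - θ0)^2, and the repulsive floor between atoms at bond-graph
    distance >= 4 or in different molecules. Dihedral parameters are carried
    by the topology but contribute no energy here.
    """

    def __init__(self, t: Topology):
        self.topology = t
        n = t.n_atoms

        bond_idx, bond_r0, bond_k = [], [], []
        for (i, j), bond in sorted(t.bonds.items()):
            if bond.params is None:
                raise ParameterizationError(f"bond {(i, j)} has no parameters")
            bond_idx.append((i, j))
            bond_r0.append(bond.params.r0)
            bond_k.append(bond.params.k)
        self.bond_idx = np.asarray(bond_idx, dtype=int).reshape(-1, 2)
        self.bond_r0 = np.asarray(bond_r0)
        self.bond_k = np.asarray(bond_k)

        ang_idx, ang_t0, ang_k = [], [], []
        for (i, j, k), params in sorted(t.angles.items()):
            if params is None:
                raise ParameterizationError(f"angle {(i, j, k)} has no parameters")
            ang_idx.append((i, j, k))
            ang_t0.append(np.deg2rad(params.theta0))
            ang_k.append(params.k)
        self.ang_idx = np.asarray(ang_idx, dtype=int).reshape(-1, 3)
        self.ang_t0 = np.asarray(ang_t0)
        self.ang_k = np.asarray(ang_k)

        # Pairs eligible for the repulsive floor: graph distance >= 4 or
        # different molecules, i.e. everything not within 3 bonds.
        adj = t.adjacency()
        near: set[tuple[int, int]] = set()
        for src in range(n):
            dist = {src: 0}
            frontier = [src]
            for _ in range(3):
                nxt = []
                for u in frontier:
                    for v in adj[u]:
                        if v not in dist:
                            dist[v] = 1
                            nxt.append(v)
                frontier = nxt
            for v in dist:
                if src < v:
                    near.add((src, v))
        rep = [
            (i, j)
            for i in range(n)
            for j in range(i + 1, n)
            if (i, j) not in near
        ]
        self.rep_idx = np.asarray(rep, dtype=int).reshape(-1, 2)

    def kernel_args(self) -> tuple:
        """Static term arrays for the jitted kernels."""
        return (
            self.bond_idx,
            self.bond_r0,
            self.bond_k,
            self.ang_idx,
            self.ang_t0,
            self.ang_k,
            self.rep_idx,
            REPULSION_CUTOFF,
            REPULSION_K,
        )

    # -- energies ----------------------------------------------------------

    def _bond_vectors(self, pos: np.ndarray):
        d = pos[self.bond_idx[:, 0]] - pos[self.bond_idx[:, 1]]
        r = np.sqrt(np.einsum("ij,ij->i", d, d))
        return d, r

    def bond_energies(self, pos: np.ndarray) -> np.ndarray:
        """Per-bond harmonic energies (kcal/mol)."""
        _, r = self._bond_vectors(pos)
        return self.bond_k * (r - self.bond_r0) ** 2

    def _angle_terms(self, pos: np.ndarray):
        i, j, k = self.ang_idx.T
        u = pos[i] - pos[j]
        v = pos[k] - pos[j]
        nu = np.sqrt(np.einsum("ij,ij->i", u, u))
        nv = np.sqrt(np.einsum("ij,ij->i", v, v))
        cos = np.einsum("ij,ij->i", u, v) / (nu * nv)
        cos = np.clip(cos, -1.0, 1.0)
        theta = np.arccos(cos)
        return u, v, nu, nv, cos, theta

    def energy(self, pos: np.ndarray) -> float:
        e = float(np.sum(self.bond_energies(pos)))
        if len(self.ang_idx):
            *_, theta = self._angle_terms(pos)
            e += float(np.sum(self.ang_k * (theta - self.ang_t0) ** 2))
        if len(self.rep_idx):
            d = pos[self.rep_idx[:, 0]] - pos[self.rep_idx[:, 1]]
            r = np.sqrt(np.einsum("ij,ij->i", d, d))
            pen = np.minimum(r - REPULSION_CUTOFF, 0.0)
            e += float(REPULSION_K * np.sum(pen**2))
        return e

    def forces(self, pos: np.ndarray) -> np.ndarray:
        f = np.zeros_like(pos)

        if len(self.bond_idx):
            d, r = self._bond_vectors(pos)
            coef = (-2.0 * self.bond_k * (r - self.bond_r0) / r)[:, None]
            np.add.at(f, self.bond_idx[:, 0], coef * d)
            np.add.at(f, self.bond_idx[:, 1], -coef * d)

        if len(self.ang_idx):
            i, j, k = self.ang_idx.T
            u, v, nu, nv, cos, theta = self._angle_terms(pos)
            sin = np.sqrt(np.maximum(1.0 - cos**2, 1e-12))
            dU = 2.0 * self.ang_k * (theta - self.ang_t0)  # dU/dθ
            uh = u / nu[:, None]
            vh = v / nv[:, None]
            # dθ/dr for the two flanking atoms; the centre balances both.
            dth_di = (cos[:, None] * uh - vh) / (nu * sin)[:, None]
            dth_dk = (cos[:, None] * vh - uh) / (nv * sin)[:, None]
            fi = -dU[:, None] * dth_di
            fk = -dU[:, None] * dth_dk
            np.add.at(f, i, fi)
            np.add.at(f, k, fk)
            np.add.at(f, j, -(fi + fk))

        if len(self.rep_idx):
            d = pos[self.rep_idx[:, 0]] - pos[self.rep_idx[:, 1]]
            r = np.sqrt(np.einsum("ij,ij->i", d, d))
            mask = r < REPULSION_CUTOFF
            if np.any(mask):
                sel = self.rep_idx[mask]
                rr = np.maximum(r[mask], 1e-8)
                coef = (-2.0 * REPULSION_K * (rr - REPULSION_CUTOFF) / rr)[:, None]
                np.add.at(f, sel[:, 0], coef * d[mask])
                np.add.at(f, sel[:, 1], -coef * d[mask])

        return f


# ---------------------------------------------------------------------------
# Jitted fast path (optional; numerically equivalent to the numpy reference)
# ---------------------------------------------------------------------------

try:
    from numba import njit as _njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a soft dependency
    HAVE_NUMBA = False

    def _njit(*args, **kwargs):
        def deco(fn):
            return fn

        return deco if not (args and callable(args[0])) else args[0]


@_njit(cache=False)
def _forces_kernel(
    pos,
    bond_idx,
    bond_r0,
    bond_k,
    ang_idx,
    ang_t0,
    ang_k,
    rep_idx,
    rep_cut,
    rep_k,
    out,
):
    out[:] = 0.0
    for b in range(bond_idx.shape[0]):
        i = bond_idx[b, 0]
        j = bond_idx[b, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        r = (dx * dx + dy * dy + dz * dz) ** 0.5
        c = -2.0 * bond_k[b] * (r - bond_r0[b]) / r
        out[i, 0] += c * dx
        out[i, 1] += c * dy
        out[i, 2] += c * dz
        out[j, 0] -= c * dx
        out[j, 1] -= c * dy
        out[j, 2] -= c * dz
    for a in range(ang_idx.shape[0]):
        i = ang_idx[a, 0]
        j = ang_idx[a, 1]
        k = ang_idx[a, 2]
        ux = pos[i, 0] - pos[j, 0]
        uy = pos[i, 1] - pos[j, 1]
        uz = pos[i, 2] - pos[j, 2]
        vx = pos[k, 0] - pos[j, 0]
        vy = pos[k, 1] - pos[j, 1]
        vz = pos[k, 2] - pos[j, 2]
        nu = (ux * ux + uy * uy + uz * uz) ** 0.5
        nv = (vx * vx + vy * vy + vz * vz) ** 0.5
        cos = (ux * vx + uy * vy + uz * vz) / (nu * nv)
        if cos > 1.0:
            cos = 1.0
        elif cos < -1.0:
            cos = -1.0
        theta = np.arccos(cos)
        sin2 = 1.0 - cos * cos
        if sin2 < 1e-12:
            sin2 = 1e-12
        sin = sin2**0.5
        dU = 2.0 * ang_k[a] * (theta - ang_t0[a])
        uhx, uhy, uhz = ux / nu, uy / nu, uz / nu
        vhx, vhy, vhz = vx / nv, vy / nv, vz / nv
        ci = 1.0 / (nu * sin)
        ck = 1.0 / (nv * sin)
        fix = -dU * (cos * uhx - vhx) * ci
        fiy = -dU * (cos * uhy - vhy) * ci
        fiz = -dU * (cos * uhz - vhz) * ci
        fkx = -dU * (cos * vhx - uhx) * ck
        fky = -dU * (cos * vhy - uhy) * ck
        fkz = -dU * (cos * vhz - uhz) * ck
        out[i, 0] += fix
        out[i, 1] += fiy
        out[i, 2] += fiz
        out[k, 0] += fkx
        out[k, 1] += fky
        out[k, 2] += fkz
        out[j, 0] -= fix + fkx
        out[j, 1] -= fiy + fky
        out[j, 2] -= fiz + fkz
    for p in range(rep_idx.shape[0]):
        i = rep_idx[p, 0]
        j = rep_idx[p, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        r = (dx * dx + dy * dy + dz * dz) ** 0.5
        if r < rep_cut:
            rr = r if r > 1e-8 else 1e-8
            c = -2.0 * rep_k * (rr - rep_cut) / rr
            out[i, 0] += c * dx
            out[i, 1] += c * dy
            out[i, 2] += c * dz
            out[j, 0] -= c * dx
            out[j, 1] -= c * dy
            out[j, 2] -= c * dz
    return out


@_njit(cache=False)
def _sd_chunk_kernel(
    pos,
    noise,
    mob_dt,
    sigma,
    stride,
    start_step,
    bond_idx,
    bond_r0,
    bond_k,
    ang_idx,
    ang_t0,
    ang_k,
    rep_idx,
    rep_cut,
    rep_k,
    frames_out,
    force_buf,
):
    """Integrate len(noise) Euler steps; record frames at global-stride hits.

    Returns (number of frames written, divergence step or -1).
    """
    n_written = 0
    for s in range(noise.shape[0]):
        _forces_kernel(
            pos,
            bond_idx,
            bond_r0,
            bond_k,
            ang_idx,
            ang_t0,
            ang_k,
            rep_idx,
            rep_cut,
            rep_k,
            force_buf,
        )
        for i in range(pos.shape[0]):
            for d in range(3):
                if not np.isfinite(force_buf[i, d]):
                    return n_written, start_step + s + 1
                pos[i, d] += (
                    mob_dt * force_buf[i, d] + sigma * noise[s, i, d]
                )
        if (start_step + s + 1) % stride == 0:
            frames_out[n_written] = pos
            n_written += 1
    return n_written, -1


def minimize(
    ff: ToyForceField,
    positions: np.ndarray,
    n_steps: int = 200,
    max_step: float = 0.02,
) -> np.ndarray:
    """Steepest-descent minimisation with a per-step displacement cap (Å).

    The default relaxation hook for recipe application: short, deterministic
    and robust on the toy force field.
    """
    x = np.array(positions, dtype=float)
    step = max_step
    e = ff.energy(x)
    for _ in range(n_steps):
        f = ff.forces(x)
        fmax = float(np.max(np.abs(f)))
        if fmax < 1e-8:
            break
        trial = x + f * (step / fmax)
        e_trial = ff.energy(trial)
        if e_trial < e:
            x, e = trial, e_trial
            step = min(step * 1.2, max_step)
        else:
            step *= 0.5
            if step < 1e-6:
                break
    return x
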