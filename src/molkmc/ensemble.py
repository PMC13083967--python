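"""Conformational ensembles and the toy stochastic-dynamics sampler.

The sampler integrates overdamped (position) Langevin dynamics on the toy
force field:

    x(t+dt) = x(t) + mu F dt + sqrt(2 kB T mu dt) xi,   xi ~ N(0, 1)

with a uniform mobility mu = 1/(m_mob * friction), m_mob = 3 u. Its
contract is the stationary Boltzmann distribution of the toy potential at
the requested temperature — not realistic dynamics. The stationary
distribution of overdamped Langevin dynamics is independent of the
mobilities, so using one light mobility mass for every atom (in the spirit
of hydrogen-mass repartitioning) is free: it equalises the stiffest modes,
admits a ~4 fs Euler step, and speeds conformational mixing several-fold
without touching the thermostat contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import DivergenceError, EmptyEnsembleError, ShapeError
from .forcefield import ToyForceField
from .topology import Topology
from .units import KB

#: Uniform mobility mass (u); see module docstring.
MOBILITY_MASS = 3.0


@dataclass
class Frame:
    """One coordinate snapshot (Å); ``time`` in ps is informational."""

    positions: np.ndarray
    time: float = 0.0
    box: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ShapeError(f"positions must be (n, 3), got {self.positions.shape}")
        if not np.all(np.isfinite(self.positions)):
            raise ShapeError("positions must be finite")

    def copy(self) -> "Frame":
        return Frame(
            positions=self.positions.copy(),
            time=self.time,
            box=None if self.box is None else np.array(self.box),
        )


@dataclass
class SamplerConfig:
    """Stochastic-dynamics settings.

    temperature in K, friction in ps^-1, timestep in ps; frames are recorded
    every ``stride`` steps (plus the initial frame). All randomness flows
    from ``seed``.
    """

    temperature: float = 300.0
    friction: float = 5.0
    timestep: float = 0.004
    n_steps: int = 1000
    stride: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.timestep <= 0:
            raise ValueError("timestep must be positive")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")
        if self.temperature < 0:
            raise ValueError("temperature must be non-negative")
        if self.friction <= 0:
            raise ValueError("friction must be positive")


@dataclass
class Ensemble:
    """Ordered frames sharing one topology, tagged with sampler provenance."""

    topology: Topology
    frames: list[Frame]
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.frames)

    def positions_array(self) -> np.ndarray:
        """(n_frames, n_atoms, 3) stacked coordinates."""
        if not self.frames:
            raise EmptyEnsembleError("ensemble has no frames")
        return np.stack([f.positions for f in self.frames])


def _check_frame(t: Topology, f: Frame) -> None:
    if f.positions.shape[0] != t.n_atoms:
        raise ShapeError(
            f"frame has {f.positions.shape[0]} atoms, topology has {t.n_atoms}"
        )


def toy_sd_sample(
    t: Topology,
    f0: Frame,
    cfg: SamplerConfig,
    forcefield: ToyForceField | None = None,
) -> Ensemble:
    """Overdamped Langevin trajectory on the toy force field.

    The returned ensemble holds the initial frame plus one frame every
    ``stride`` steps. Identical seeds give bitwise-identical trajectories.
    Raises ParameterizationError for missing bonded parameters and
    DivergenceError (with the step index) on non-finite forces.
    """
    _check_frame(t, f0)
    ff = forcefield if forcefield is not None else ToyForceField(t)

    mob = 1.0 / (MOBILITY_MASS * cfg.friction)
    kT = KB * cfg.temperature
    dt = cfg.timestep
    sigma = float(np.sqrt(2.0 * kT * mob * dt))
    mob_dt = mob * dt

    rng = np.random.default_rng(cfg.seed)
    x = f0.positions.copy()
    n = t.n_atoms
    frames = [Frame(positions=x.copy(), time=f0.time)]

    from .forcefield import HAVE_NUMBA, _sd_chunk_kernel

    if HAVE_NUMBA:
        args = ff.kernel_args()
        force_buf = np.empty_like(x)
        chunk = 1024
        step = 0
        while step < cfg.n_steps:
            todo = min(chunk, cfg.n_steps - step)
            noise = rng.standard_normal((todo, n, 3))
            frames_out = np.empty((todo // cfg.stride + 1, n, 3))
            n_written, diverged = _sd_chunk_kernel(
                x, noise, mob_dt, sigma, cfg.stride, step, *args,
                frames_out, force_buf,
            )
            for w in range(n_written):
                rec_step = ((step // cfg.stride) + 1 + w) * cfg.stride
                frames.append(
                    Frame(positions=frames_out[w].copy(), time=f0.time + rec_step * dt)
                )
            if diverged >= 0:
                raise DivergenceError(diverged)
            step += todo
    else:  # pure-numpy reference path
        for step in range(1, cfg.n_steps + 1):
            f = ff.forces(x)
            if not np.all(np.isfinite(f)):
                raise DivergenceError(step)
            x = x + mob_dt * f + sigma * rng.standard_normal((n, 3))
            if step % cfg.stride == 0:
                frames.append(Frame(positions=x.copy(), time=f0.time + step * dt))
    return Ensemble(
        topology=t,
        frames=frames,
        provenance=(
            f"toy-sd T={cfg.temperature}K friction={cfg.friction}/ps "
            f"dt={cfg.timestep}ps n={cfg.n_steps} stride={cfg.stride} seed={cfg.seed}"
        ),
    )


# ---------------------------------------------------------------------------
# Synthetic dimer-geometry ensembles
# ---------------------------------------------------------------------------


@dataclass
class GeometryEnsemble:
    """(distance, dihedral) feature samples for dimerization-rate models.

    Distances in Å (non-negative), dihedrals in degrees on (-180, 180].
    """

    distances: np.ndarray
    dihedrals: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=float)
        self.dihedrals = np.asarray(self.dihedrals, dtype=float)
        if self.distances.shape != self.dihedrals.shape:
            raise ShapeError("distances and dihedrals must have equal length")

    def __len__(self) -> int:
        return self.distances.size


def wrap_angle(theta) -> np.ndarray | float:
    """Wrap angles in degrees onto (-180, 180]."""
    w = ((np.asarray(theta, dtype=float) + 180.0) % 360.0) - 180.0
    w = np.where(w == -180.0, 180.0, w)
    return float(w) if np.isscalar(theta) else w


def synth_dimer_geometry_ensemble(
    d_mean: float,
    d_sd: float,
    theta_mean: float,
    theta_sd: float,
    n: int,
    seed: int,
) -> GeometryEnsemble:
    """Sample a synthetic (distance, dihedral) ensemble.

    Distances come from a normal truncated at zero, dihedrals from a wrapped
    normal on (-180, 180]. Emulates the double-bond distance / inter-bond
    dihedral feature distributions of stacked pyrimidine pairs; a stand-in
    for features measured on MD snapshots.
    """
    if n < 1:
        raise EmptyEnsembleError("need at least one sample")
    if d_sd < 0 or theta_sd < 0:
        raise ValueError("standard deviations must be non-negative")
    rng = np.random.default_rng(seed)
    if d_sd == 0:
        d = np.full(n, float(d_mean))
    else:
        # rejection sampling of the truncated normal; vectorised refills
        d = np.empty(0)
        while d.size < n:
            cand = rng.normal(d_mean, d_sd, size=2 * (n - d.size) + 16)
            d = np.concatenate([d, cand[cand >= 0.0]])
        d = d[:n]
    theta = wrap_angle(rng.normal(theta_mean, theta_sd, size=n)) if theta_sd > 0 else (
        np.full(n, wrap_angle(theta_mean))
    )
    return GeometryEnsemble(
        distances=d,
        dihedrals=np.asarray(theta),
        provenance={
            "d_mean": d_mean,
            "d_sd": d_sd,
            "theta_mean": theta_mean,
            "theta_sd": theta_sd,
            "n": n,
            "seed": seed,
        },
    )
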