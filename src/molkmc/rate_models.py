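"""Pluggable reaction-rate emulators.

Every reaction channel maps molecular features to a first-order rate in s⁻¹:

* ``eyring_rate`` — transition-state theory, k = (kB T / h) exp(-ΔG‡ / kB T),
  with ensemble averaging of per-frame rates (not barriers; the two differ
  by Jensen's gap, and averaging rates is what lets rarely-visited reactive
  conformations dominate).
* ``bell_rate`` — force-accelerated homolysis, k = k0 exp(F Δx / kB T).
* ``hydrolysis_rate`` — heuristic closed-shell peptide scission: a
  force-saturating exponential times a pH decade factor times a linear
  solvent-accessible-surface-area factor. The saturation reproduces the
  regime where hydrolysis tapers off under high force while homolysis keeps
  scaling.
* ``dimerization_rate`` — distance-and-angle heuristic for cyclobutane
  pyrimidine dimer formation; frames whose rate exceeds a threshold count as
  dimerisable, and the quantum yield is their fraction.
* ``surrogate_hat_barrier`` — a table-driven hydrogen-atom-transfer barrier
  emulator keyed by shift class, with a linear distance penalty. Any object
  with the same call signature plugs into the orchestrator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .ensemble import GeometryEnsemble, wrap_angle
from .errors import EmptyEnsembleError, MolkmcError, RecipeError
from .topology import Topology, find_radicals
from .units import DEFAULT_TEMPERATURE, KB, KCALMOL_TO_PN_ANGSTROM, PLANCK


@dataclass
class Constants:
    """Physical constants in project units (kcal/mol, K, s)."""

    kB: float = KB
    h: float = PLANCK
    T: float = DEFAULT_TEMPERATURE

    def __post_init__(self) -> None:
        if self.kB <= 0 or self.h <= 0 or self.T <= 0:
            raise ValueError("constants must be positive")

    @property
    def kBT(self) -> float:
        return self.kB * self.T


@dataclass
class BellParams:
    """Zero-force rate k0 (s⁻¹) and activation length Δx (Å)."""

    k0: float = 1e-15
    delta_x: float = 0.4

    def __post_init__(self) -> None:
        if self.k0 < 0 or self.delta_x < 0:
            raise ValueError("k0 and delta_x must be non-negative")


@dataclass
class HydrolysisParams:
    """Reference rate at (F_ref, pH_ref, sasa_ref) and its sensitivities.

    ``alpha`` (pN⁻¹) sets the low-force exponential slope; ``F_sat`` (pN)
    the saturation scale beyond which the force response flattens.
    """

    k_ref: float = 1e-7
    F_ref: float = 1000.0
    alpha: float = 0.006
    F_sat: float = 2000.0
    pH_ref: float = 7.0
    sasa_ref: float = 50.0

    def __post_init__(self) -> None:
        for name in ("k_ref", "F_ref", "alpha", "F_sat", "pH_ref", "sasa_ref"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class DimerParams:
    """Distance/angle heuristic: rate = A exp(-d/d0) cosθ within |θ|<=θ_max."""

    A: float = 1e12
    d0: float = 0.5
    theta_max: float = 60.0
    rate_threshold: float = 1e8

    def __post_init__(self) -> None:
        for name in ("A", "d0", "theta_max", "rate_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.theta_max > 90.0:
            raise ValueError("theta_max must be <= 90 degrees")


@dataclass
class BarrierTable:
    """Shift-class (or moiety-label) keyed HAT barriers, kcal/mol.

    ``slope`` is the linear distance penalty (kcal mol⁻¹ Å⁻¹) applied beyond
    the covalent H-acceptor distance of 1.1 Å. Missing labels fall back to
    the ``default`` entry.
    """

    entries: dict[str, float] = field(default_factory=dict)
    slope: float = 2.0

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.entries.values()):
            raise ValueError("barriers must be non-negative")
        if self.slope < 0:
            raise ValueError("slope must be non-negative")

    def lookup(self, label: str) -> float:
        if label in self.entries:
            return self.entries[label]
        if "default" in self.entries:
            return self.entries["default"]
        raise MolkmcError(f"no barrier entry for {label!r} and no default")


#: Shipped surrogate table. The ordering encodes transition-state ring
#: strain: 1-2 and 1-3 shifts (three- and four-membered ring transition
#: states) are the most strained and highest, the 1-5 shift (six-membered
#: ring) the most favourable.
DEFAULT_HAT_TABLE = BarrierTable(
    entries={
        "1-2": 36.0,
        "1-3": 33.0,
        "1-4": 25.0,
        "1-5": 21.0,
        "1-6": 23.0,
        "1-7": 25.0,
        "long-range": 26.0,
        "intermolecular": 24.0,
        "default": 28.0,
    },
    slope=2.0,
)


# ---------------------------------------------------------------------------
# Rate laws
# ---------------------------------------------------------------------------


def eyring_rate(barrier, c: Constants | None = None):
    """Transition-state-theory rate for a free-energy barrier in kcal/mol."""
    c = c or Constants()
    b = np.asarray(barrier, dtype=float)
    if np.any(b < 0):
        raise ValueError("barrier must be non-negative")
    k = (c.kBT / c.h) * np.exp(-b / c.kBT)
    return float(k) if np.isscalar(barrier) else k


def ensemble_average_rate(barriers, c: Constants | None = None) -> float:
    """Arithmetic mean of per-frame Eyring rates (average of rates, not
    of barriers)."""
    b = np.atleast_1d(np.asarray(barriers, dtype=float))
    if b.size == 0:
        raise EmptyEnsembleError("no barriers to average")
    return float(np.mean(eyring_rate(b, c)))


def bell_rate(force, p: BellParams, c: Constants | None = None):
    """Force-accelerated bond-rupture rate, k = k0 exp(F Δx / kB T).

    Force in pN; kB T is converted to pN·Å via 1 kcal/mol = 69.48 pN·Å.
    """
    c = c or Constants()
    kT_pn_a = c.kBT * KCALMOL_TO_PN_ANGSTROM
    f = np.asarray(force, dtype=float)
    k = p.k0 * np.exp(f * p.delta_x / kT_pn_a)
    return float(k) if np.isscalar(force) else k


def hydrolysis_rate(
    force,
    pH: float,
    sasa,
    p: HydrolysisParams,
    c: Constants | None = None,
):
    """Heuristic peptide hydrolysis rate.

    k = k_ref · exp(α (F - F_ref) / (1 + F/F_sat)) · 10^(pH - pH_ref)
      · (sasa / sasa_ref)

    Bounded in force (the exponent saturates at α·F_sat as F → ∞), one
    decade per pH unit (base catalysis), and linear in solvent-accessible
    surface area (zero area, zero rate).
    """
    f = np.asarray(force, dtype=float)
    s = np.asarray(sasa, dtype=float)
    if np.any(s < 0):
        raise ValueError("sasa must be non-negative")
    k = (
        p.k_ref
        * np.exp(p.alpha * (f - p.F_ref) / (1.0 + f / p.F_sat))
        * 10.0 ** (pH - p.pH_ref)
        * (s / p.sasa_ref)
    )
    scalar = np.isscalar(force) and np.isscalar(sasa)
    return float(k) if scalar else k


def dimerization_rate(d, theta, p: DimerParams):
    """Distance-and-angle heuristic dimerization rate.

    rate = A exp(-d/d0) max(0, cos θ) for |wrap(θ)| <= θ_max, else 0.
    """
    dd = np.asarray(d, dtype=float)
    if np.any(dd < 0):
        raise ValueError("distance must be non-negative")
    th = np.asarray(wrap_angle(theta), dtype=float)
    rate = (
        p.A
        * np.exp(-dd / p.d0)
        * np.maximum(0.0, np.cos(np.deg2rad(th)))
        * (np.abs(th) <= p.theta_max)
    )
    scalar = np.isscalar(d) and np.isscalar(theta)
    return float(rate) if scalar else rate


def is_dimerisable(rate, p: DimerParams):
    """Frames with rates above the threshold count as dimerisable."""
    out = np.asarray(rate, dtype=float) > p.rate_threshold
    return bool(out) if np.isscalar(rate) else out


def quantum_yield(samples: GeometryEnsemble, p: DimerParams) -> float:
    """Fraction of dimerisable configurations in a geometry ensemble."""
    if len(samples) == 0:
        raise EmptyEnsembleError("no geometry samples")
    rates = dimerization_rate(samples.distances, samples.dihedrals, p)
    return float(np.mean(is_dimerisable(rates, p)))


# ---------------------------------------------------------------------------
# Surrogate HAT barrier emulator
# ---------------------------------------------------------------------------


def hat_barrier_from_distance(label: str, d_ha, table: BarrierTable):
    """Shared barrier formula: table value plus linear distance penalty."""
    base = table.lookup(label)
    d = np.asarray(d_ha, dtype=float)
    b = base + table.slope * np.maximum(0.0, d - 1.1)
    return float(b) if np.isscalar(d_ha) else b


def surrogate_hat_barrier(
    t: Topology,
    h: int,
    acceptor: int,
    frame,
    table: BarrierTable | None = None,
    max_bonds: int = 6,
) -> float:
    """Emulated HAT barrier (kcal/mol) for one candidate in one frame.

    A stand-in for a learned barrier predictor: pure function of the shift
    class (via bond-graph distance between the radical acceptor and the
    hydrogen's heavy donor) and the frame's H-acceptor distance.
    """
    from .analysis import classify_shift

    table = table or DEFAULT_HAT_TABLE
    if t.atoms[h].element != "H":
        raise RecipeError(f"atom {h} is not a hydrogen")
    nbrs = t.neighbors(h)
    if len(nbrs) != 1:
        raise RecipeError(f"hydrogen {h} must have exactly one bond")
    if acceptor not in find_radicals(t):
        raise RecipeError(f"acceptor {acceptor} is not a radical")
    label = classify_shift(t, acceptor, nbrs[0], max_bonds=max_bonds)
    pos = np.asarray(frame.positions, dtype=float)
    d_ha = float(np.linalg.norm(pos[h] - pos[acceptor]))
    return hat_barrier_from_distance(label, d_ha, table)


def fold_change(barrier_low: float, barrier_high: float, c: Constants | None = None) -> float:
    """Rate ratio implied by a barrier difference (Eyring).

    exp((barrier_high - barrier_low) / kB T); e.g. a 4.5 kcal/mol advantage
    at 300 K is a ~1.9e3-fold acceleration.
    """
    c = c or Constants()
    return math.exp((barrier_high - barrier_low) / c.kBT)


# ---------------------------------------------------------------------------
# Plugin registry
# ---------------------------------------------------------------------------

_REGISTRY: dict[str, type] = {}


def register_rate_model(name: str):
    """Class decorator: make a reaction plugin discoverable by name."""

    def deco(cls):
        _REGISTRY[name] = cls
        cls.plugin_name = name
        return cls

    return deco


def get_rate_model(name: str) -> type:
    try:
        return _REGISTRY[name]
    except KeyError as exc:
        raise MolkmcError(
            f"unknown rate model {name!r}; available: {sorted(_REGISTRY)}"
        ) from exc


def available_rate_models() -> list[str]:
    return sorted(_REGISTRY)
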