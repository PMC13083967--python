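"""Reactions as ordered elementary topology edits.

A Recipe is an ordered list of steps — Break, Bind, Place, Relax — that
turns a reactant topology plus one coordinate snapshot into the product
state. Break and Bind edit the bond graph; Place overwrites one atom's
coordinates; Relax invokes a registered relaxation hook (default:
steepest-descent minimisation on the toy force field). Bonded terms are
regenerated once after all bond edits so product angles, dihedrals and 1-4
pairs always match the new graph.

Constructors for the four built-in chemistries are provided: hydrogen atom
transfer (HAT), homolysis, base-catalysed hydrolysis with an explicit water
(atom count conserved), and cyclobutane-forming dimerization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence, Union

import numpy as np

from .errors import RecipeError
from .topology import Topology, find_radicals


@dataclass(frozen=True)
class Break:
    i: int
    j: int


@dataclass(frozen=True)
class Bind:
    i: int
    j: int
    order: float = 1.0


@dataclass(frozen=True)
class Place:
    atom: int
    position: tuple[float, float, float]


@dataclass(frozen=True)
class Relax:
    pass


RecipeStep = Union[Break, Bind, Place, Relax]


@dataclass
class Recipe:
    """Ordered steps defining one reaction, plus provenance for replay."""

    steps: list[RecipeStep]
    reaction_type: str = ""
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.steps:
            raise RecipeError("recipe must contain at least one step")


# ---------------------------------------------------------------------------
# Validation and application
# ---------------------------------------------------------------------------


def validate_recipe(t: Topology, r: Recipe) -> list[str]:
    """Simulate the steps against ``t`` and collect violations.

    Violations are data, not exceptions: an empty list means the recipe is
    applicable. Bond existence is tracked stepwise, so a Bind directly after
    a Break of the same pair is legal.
    """
    violations: list[str] = []
    bonds = set(t.bonds)
    n = t.n_atoms
    for idx, step in enumerate(r.steps):
        if isinstance(step, Break):
            key = (min(step.i, step.j), max(step.i, step.j))
            if not (0 <= step.i < n and 0 <= step.j < n):
                violations.append(f"step {idx}: Break references unknown atom {key}")
            elif key not in bonds:
                violations.append(f"step {idx}: Break on nonexistent bond {key}")
            else:
                bonds.discard(key)
        elif isinstance(step, Bind):
            key = (min(step.i, step.j), max(step.i, step.j))
            if step.i == step.j:
                violations.append(f"step {idx}: Bind self-bond on atom {step.i}")
            elif not (0 <= step.i < n and 0 <= step.j < n):
                violations.append(f"step {idx}: Bind references unknown atom {key}")
            elif key in bonds:
                violations.append(f"step {idx}: Bind on already-bonded pair {key}")
            else:
                bonds.add(key)
        elif isinstance(step, Place):
            if not (0 <= step.atom < n):
                violations.append(f"step {idx}: Place on unknown atom {step.atom}")
            elif not np.all(np.isfinite(step.position)):
                violations.append(f"step {idx}: Place position not finite")
        elif isinstance(step, Relax):
            pass
        else:  # pragma: no cover - guarded by typing
            violations.append(f"step {idx}: unknown step kind {step!r}")
    return violations


def default_relax_hook(t: Topology, positions: np.ndarray) -> np.ndarray:
    """Steepest descent on the toy force field (200 steps, 0.02 Å cap)."""
    from .forcefield import ToyForceField, minimize

    return minimize(ToyForceField(t), positions, n_steps=200, max_step=0.02)


def apply_recipe(
    t: Topology,
    frame,
    r: Recipe,
    relax_hook: Callable[[Topology, np.ndarray], np.ndarray] | None = None,
):
    """Apply a validated recipe; returns the product ``(Topology, Frame)``.

    Bond edits happen in step order; angles/dihedrals/pairs are regenerated
    once after the last Break/Bind; each Relax step runs the hook on the
    (already regenerated and parameterized) product topology. Atom count is
    never changed.
    """
    from .ensemble import Frame  # local import: ensemble imports recipes' types
    from .topology import regenerate_bonded_terms

    violations = validate_recipe(t, r)
    if violations:
        raise RecipeError(f"recipe not applicable: {violations[0]}")

    hook = relax_hook if relax_hook is not None else default_relax_hook
    out = t.copy()
    pos = np.array(frame.positions, dtype=float)

    edited = False
    relax_requested = 0
    for step in r.steps:
        if isinstance(step, Break):
            out.remove_bond(step.i, step.j)
            edited = True
        elif isinstance(step, Bind):
            out.add_bond(step.i, step.j, params=None, order=step.order)
            edited = True
        elif isinstance(step, Place):
            pos[step.atom] = step.position
        elif isinstance(step, Relax):
            relax_requested += 1

    if edited:
        out = regenerate_bonded_terms(out)
    for _ in range(relax_requested):
        pos = hook(out, pos)

    return out, Frame(positions=pos, time=frame.time, box=frame.box)


def reversed_recipe(r: Recipe) -> Recipe:
    """Swap Break and Bind and reverse the order; drops Place/Relax.

    Applying a recipe followed by its reversal restores the original bond
    set (orders revert to 1 for re-formed bonds).
    """
    steps: list[RecipeStep] = []
    for step in reversed(r.steps):
        if isinstance(step, Break):
            steps.append(Bind(step.i, step.j))
        elif isinstance(step, Bind):
            steps.append(Break(step.i, step.j))
    if not steps:
        steps.append(Relax())
    return Recipe(steps=steps, reaction_type=f"reverse-{r.reaction_type}")


# ---------------------------------------------------------------------------
# Reaction constructors
# ---------------------------------------------------------------------------


def make_hat_recipe(t: Topology, h: int, acceptor: int, frame) -> Recipe:
    """Hydrogen atom transfer: Break(h, donor), Bind(h, acceptor), Place, Relax.

    The hydrogen is placed 1.1 Å from the acceptor on the donor side of the
    donor→acceptor axis; a degenerate (zero-length) axis falls back to the
    x unit vector.
    """
    t.check_index(h)
    t.check_index(acceptor)
    if t.atoms[h].element != "H":
        raise RecipeError(f"atom {h} is not a hydrogen")
    nbrs = t.neighbors(h)
    if len(nbrs) != 1:
        raise RecipeError(f"hydrogen {h} must have exactly one bond, has {len(nbrs)}")
    donor = nbrs[0]
    if acceptor not in find_radicals(t):
        raise RecipeError(f"acceptor {acceptor} is not a radical")
    if donor == acceptor:
        raise RecipeError("donor heavy atom equals acceptor (degenerate HAT)")

    pos = np.asarray(frame.positions, dtype=float)
    axis = pos[acceptor] - pos[donor]
    norm = float(np.linalg.norm(axis))
    unit = axis / norm if norm > 1e-8 else np.array([1.0, 0.0, 0.0])
    target = pos[acceptor] - 1.1 * unit

    return Recipe(
        steps=[
            Break(h, donor),
            Bind(h, acceptor),
            Place(h, tuple(float(x) for x in target)),
            Relax(),
        ],
        reaction_type="hat",
        provenance={"h": h, "donor": donor, "acceptor": acceptor},
    )


def make_homolysis_recipe(t: Topology, bond: Sequence[int]) -> Recipe:
    """Homolytic cleavage of one bond: Break then Relax; two radicals result."""
    i, j = bond
    if not t.has_bond(i, j):
        raise RecipeError(f"no bond {(i, j)} to cleave")
    return Recipe(
        steps=[Break(i, j), Relax()],
        reaction_type="homolysis",
        provenance={"bond": (min(i, j), max(i, j))},
    )


def make_hydrolysis_recipe(
    t: Topology, c: int, n: int, water_o: int, water_h: int
) -> Recipe:
    """Peptide-bond hydrolysis with an explicit water as atom donor.

    Break(C, N), Break(O_w, H_w), Bind(O_w, C), Bind(H_w, N): the water caps
    both fragments, conserving atoms and leaving no radicals.
    """
    for idx in (c, n, water_o, water_h):
        t.check_index(idx)
    roles = {
        c: ("C", "carbonyl carbon"),
        n: ("N", "amide nitrogen"),
        water_o: ("O", "water oxygen"),
        water_h: ("H", "water hydrogen"),
    }
    for idx, (elem, label) in roles.items():
        if t.atoms[idx].element != elem:
            raise RecipeError(
                f"{label} must be {elem}, atom {idx} is {t.atoms[idx].element}"
            )
    if not t.has_bond(c, n):
        raise RecipeError(f"no amide bond between {c} and {n}")
    if not t.has_bond(water_o, water_h):
        raise RecipeError(f"water hydrogen {water_h} not bonded to oxygen {water_o}")
    return Recipe(
        steps=[
            Break(c, n),
            Break(water_o, water_h),
            Bind(water_o, c),
            Bind(water_h, n),
            Relax(),
        ],
        reaction_type="hydrolysis",
        provenance={"c": c, "n": n, "water_o": water_o, "water_h": water_h},
    )


def make_dimerization_recipe(
    t: Topology, c5a: int, c6a: int, c5b: int, c6b: int
) -> Recipe:
    """Cyclobutane-forming dimerization: Bind(C5a, C5b), Bind(C6a, C6b), Relax."""
    for idx in (c5a, c6a, c5b, c6b):
        t.check_index(idx)
        if t.atoms[idx].element != "C":
            raise RecipeError(f"dimerization atom {idx} must be carbon")
    if not t.has_bond(c5a, c6a) or not t.has_bond(c5b, c6b):
        raise RecipeError("C5-C6 double bonds must exist on both partners")
    return Recipe(
        steps=[Bind(c5a, c5b), Bind(c6a, c6b), Relax()],
        reaction_type="dimerization",
        provenance={"sites": (c5a, c6a, c5b, c6b)},
    )


# ---------------------------------------------------------------------------
# Line-based serialization (1-based indices, matching the topology dialect)
# ---------------------------------------------------------------------------


def recipe_to_text(r: Recipe) -> str:
    lines = [f"# recipe type={r.reaction_type or 'unknown'}"]
    for step in r.steps:
        if isinstance(step, Break):
            lines.append(f"Break {step.i + 1} {step.j + 1}")
        elif isinstance(step, Bind):
            lines.append(f"Bind {step.i + 1} {step.j + 1} {step.order:.6g}")
        elif isinstance(step, Place):
            x, y, z = step.position
            lines.append(f"Place {step.atom + 1} {x:.6f} {y:.6f} {z:.6f}")
        elif isinstance(step, Relax):
            lines.append("Relax")
    return "\n".join(lines) + "\n"


def recipe_from_text(text: str) -> Recipe:
    steps: list[RecipeStep] = []
    reaction_type = ""
    for raw in text.splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            if "type=" in line:
                reaction_type = line.split("type=", 1)[1].strip()
            continue
        toks = line.split()
        kind = toks[0].lower()
        if kind == "break":
            steps.append(Break(int(toks[1]) - 1, int(toks[2]) - 1))
        elif kind == "bind":
            order = float(toks[3]) if len(toks) > 3 else 1.0
            steps.append(Bind(int(toks[1]) - 1, int(toks[2]) - 1, order))
        elif kind == "place":
            steps.append(
                Place(int(toks[1]) - 1, (float(toks[2]), float(toks[3]), float(toks[4])))
            )
        elif kind == "relax":
            steps.append(Relax())
        else:
            raise RecipeError(f"unknown recipe step {toks[0]!r}")
    return Recipe(steps=steps, reaction_type=reaction_type)
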