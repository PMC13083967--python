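"""The reaction-emulation cycle.

Each kMC step: generate a conformational ensemble of the current state with
the toy stochastic-dynamics sampler, ask every enabled reaction plugin for
candidate events with rates over that ensemble, select one event by
rejection-free kMC, apply its recipe to obtain the product topology and
coordinates, run a short equilibration, and append a provenance record. The
cycle is memoryless given the product ensemble (a Markov process over
chemical states), and the event list of a state is built only when the
state is actually visited (adaptive event-list generation).

Determinism: all randomness derives from the run seed. Per-cycle sampler
seeds are pure functions of (seed, cycle index); the kMC generator's state
is part of every checkpoint, so a restored run continues bitwise
identically.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import yaml

from .ensemble import Ensemble, Frame, SamplerConfig, toy_sd_sample
from .errors import CheckpointError, ConfigurationError, MolkmcError
from .kmc import Event, EventList, rf_kmc_step
from .rate_models import (
    BarrierTable,
    BellParams,
    Constants,
    DEFAULT_HAT_TABLE,
    DimerParams,
    HydrolysisParams,
    bell_rate,
    dimerization_rate,
    ensemble_average_rate,
    get_rate_model,
    hat_barrier_from_distance,
    hydrolysis_rate,
    register_rate_model,
)
from .recipes import (
    apply_recipe,
    make_dimerization_recipe,
    make_hat_recipe,
    make_homolysis_recipe,
    make_hydrolysis_recipe,
)
from .topology import Topology, find_radicals, parse_topology, write_topology

SCHEMA_VERSION = 1


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class PluginSpec:
    name: str
    params: dict = field(default_factory=dict)


@dataclass
class RunConfig:
    """Everything a run needs; serialisable to/from YAML (versioned schema).

    Exactly one of (``topology_path`` + ``coordinates_path``) or ``fixture``
    must describe the initial state. ``fixture`` is a built-in generator
    name with arguments, e.g. ``{"name": "alkyl_radical", "n_carbons": 8,
    "radical_carbon": 0}``.
    """

    topology_path: str | None = None
    coordinates_path: str | None = None
    fixture: dict | None = None
    temperature: float = 300.0
    friction: float = 5.0
    timestep: float = 0.004
    sample_steps: int = 4000
    sample_stride: int = 100
    equilibration_steps: int = 800
    burn_in_steps: int = 0
    plugins: list[PluginSpec] = field(default_factory=list)
    max_steps: int | None = None
    max_time: float | None = None
    seed: int = 0
    output_dir: str | None = None
    resample_retries: int = 2
    keep_states: bool = False
    schema_version: int = SCHEMA_VERSION

    def validate(self) -> None:
        if not self.plugins:
            raise ConfigurationError("at least one reaction plugin must be enabled")
        if self.max_steps is None and self.max_time is None:
            raise ConfigurationError("a stopping criterion is required "
                                     "(max_steps and/or max_time)")
        has_files = self.topology_path is not None and self.coordinates_path is not None
        if not (has_files or self.fixture):
            raise ConfigurationError(
                "initial state required: topology+coordinates paths or a fixture"
            )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        version = d.pop("schema_version", SCHEMA_VERSION)
        if version != SCHEMA_VERSION:
            raise ConfigurationError(
                f"unsupported config schema version {version} (expected {SCHEMA_VERSION})"
            )
        plugins = [
            p if isinstance(p, PluginSpec) else PluginSpec(**p)
            for p in d.pop("plugins", [])
        ]
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(plugins=plugins, **d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ConfigurationError("config file must be a YAML mapping")
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def _initial_state(config: RunConfig) -> tuple[Topology, Frame]:
    from . import fixtures as fx
    from .io import read_frames
    from .topology import read_topology

    if config.fixture:
        spec = dict(config.fixture)
        name = spec.pop("name", None)
        builders = {
            "alkane": fx.build_alkane,
            "alkyl_radical": fx.build_alkyl_radical,
            "dipeptide_water": fx.build_dipeptide_with_water,
            "thymine_pair": lambda **kw: fx.build_thymine_pair(**kw)[:2],
        }
        if name not in builders:
            raise ConfigurationError(
                f"unknown fixture {name!r}; available: {sorted(builders)}"
            )
        return builders[name](**spec)
    topo = read_topology(config.topology_path)
    ens = read_frames(config.coordinates_path, topo)
    return topo, ens.frames[0]


# ---------------------------------------------------------------------------
# Reaction plugins
# ---------------------------------------------------------------------------


class ReactionPlugin:
    """Plugin contract: propose candidate events for the current ensemble."""

    plugin_name = "abstract"

    def __init__(self, params: dict | None = None, constants: Constants | None = None):
        self.params = dict(params or {})
        self.constants = constants or Constants()

    def propose(self, topology: Topology, ensemble: Ensemble) -> list[Event]:
        raise NotImplementedError


@register_rate_model("hat")
class HATPlugin(ReactionPlugin):
    """Hydrogen atom transfer to radical acceptors.

    Candidates are (hydrogen, radical) pairs that approach within
    ``cutoff`` Å in at least one frame. Barriers come from the surrogate
    table keyed by shift class plus a linear distance penalty; the event
    rate is the ensemble mean of per-frame Eyring rates.
    """

    def __init__(self, params=None, constants=None):
        super().__init__(params, constants)
        table = self.params.get("table")
        if table is None:
            self.table = DEFAULT_HAT_TABLE
        elif isinstance(table, BarrierTable):
            self.table = table
        else:
            self.table = BarrierTable(
                entries=dict(table), slope=self.params.get("slope", 2.0)
            )
        self.cutoff = float(self.params.get("cutoff", 3.0))
        self.max_bonds = int(self.params.get("max_bonds", 6))

    def propose(self, topology: Topology, ensemble: Ensemble) -> list[Event]:
        from .analysis import classify_shift

        radicals = sorted(find_radicals(topology).members)
        if not radicals:
            return []
        hydrogens = [
            a.index
            for a in topology.atoms
            if a.element == "H" and len(topology.neighbors(a.index)) == 1
        ]
        pos = ensemble.positions_array()  # (F, n, 3)
        events: list[Event] = []
        for acc in radicals:
            for h in hydrogens:
                donor = topology.neighbors(h)[0]
                if donor == acc:
                    continue
                d = np.linalg.norm(pos[:, h, :] - pos[:, acc, :], axis=1)
                i_min = int(np.argmin(d))
                if d[i_min] > self.cutoff:
                    continue
                label = classify_shift(topology, acc, donor, self.max_bonds)
                barriers = hat_barrier_from_distance(label, d, self.table)
                rate = ensemble_average_rate(barriers, self.constants)
                recipe = make_hat_recipe(topology, h, acc, ensemble.frames[i_min])
                recipe.provenance.update(
                    {"frame_index": i_min, "d_min": float(d[i_min]), "label": label}
                )
                events.append(
                    Event(
                        recipe=recipe,
                        rate=rate,
                        metadata={
                            "reaction_type": "hat",
                            "atoms": (h, acc),
                            "label": label,
                        },
                    )
                )
        return events


@register_rate_model("homolysis")
class HomolysisPlugin(ReactionPlugin):
    """Force-dependent homolytic cleavage (Bell model) of selected bonds.

    ``params['elements']`` selects bonds by element pair (default C-C);
    ``params['force']`` is the per-bond tensile force in pN (scalar or
    mapping from "i-j" 1-based bond keys).
    """

    def __init__(self, params=None, constants=None):
        super().__init__(params, constants)
        self.bell = BellParams(
            k0=self.params.get("k0", BellParams().k0),
            delta_x=self.params.get("delta_x", BellParams().delta_x),
        )
        self.elements = tuple(sorted(self.params.get("elements", ("C", "C"))))
        self.force = self.params.get("force", 0.0)

    def _bond_force(self, i: int, j: int) -> float:
        if isinstance(self.force, dict):
            return float(self.force.get(f"{i + 1}-{j + 1}", 0.0))
        return float(self.force)

    def propose(self, topology: Topology, ensemble: Ensemble) -> list[Event]:
        events = []
        for (i, j) in sorted(topology.bonds):
            pair = tuple(
                sorted((topology.atoms[i].element, topology.atoms[j].element))
            )
            if pair != self.elements:
                continue
            rate = bell_rate(self._bond_force(i, j), self.bell, self.constants)
            events.append(
                Event(
                    recipe=make_homolysis_recipe(topology, (i, j)),
                    rate=rate,
                    metadata={"reaction_type": "homolysis", "atoms": (i, j)},
                )
            )
        return events


@register_rate_model("hydrolysis")
class HydrolysisPlugin(ReactionPlugin):
    """Heuristic base-catalysed scission of amide bonds with explicit water.

    Sites are amide C-N bonds where the carbon also carries an order-2
    oxygen; the nearest free water (O with exactly two H) donates the caps.
    Rate depends on force (saturating), pH (decade factor) and a per-site or
    global solvent-accessible surface area.
    """

    def __init__(self, params=None, constants=None):
        super().__init__(params, constants)
        defaults = HydrolysisParams()
        self.hp = HydrolysisParams(
            **{
                f.name: self.params.get(f.name, getattr(defaults, f.name))
                for f in dataclasses.fields(HydrolysisParams)
            }
        )
        self.force = float(self.params.get("force", 0.0))
        self.pH = float(self.params.get("pH", 7.0))
        self.sasa = float(self.params.get("sasa", self.hp.sasa_ref))

    @staticmethod
    def _amide_sites(t: Topology) -> list[tuple[int, int]]:
        sites = []
        for (i, j) in sorted(t.bonds):
            a, b = t.atoms[i], t.atoms[j]
            if {a.element, b.element} != {"C", "N"}:
                continue
            c, n = (i, j) if a.element == "C" else (j, i)
            has_carbonyl_o = any(
                t.atoms[nb].element == "O"
                and t.bonds[(min(c, nb), max(c, nb))].order == 2
                for nb in t.neighbors(c)
            )
            if has_carbonyl_o:
                sites.append((c, n))
        return sites

    @staticmethod
    def _waters(t: Topology) -> list[tuple[int, int]]:
        waters = []
        for a in t.atoms:
            if a.element != "O":
                continue
            nbrs = t.neighbors(a.index)
            if len(nbrs) == 2 and all(t.atoms[x].element == "H" for x in nbrs):
                waters.append((a.index, nbrs[0]))
        return waters

    def propose(self, topology: Topology, ensemble: Ensemble) -> list[Event]:
        waters = self._waters(topology)
        if not waters:
            return []
        last = ensemble.frames[-1].positions
        events = []
        for (c, n) in self._amide_sites(topology):
            ow, hw = min(
                waters, key=lambda w: float(np.linalg.norm(last[w[0]] - last[c]))
            )
            rate = hydrolysis_rate(
                self.force, self.pH, self.sasa, self.hp, self.constants
            )
            events.append(
                Event(
                    recipe=make_hydrolysis_recipe(topology, c, n, ow, hw),
                    rate=rate,
                    metadata={"reaction_type": "hydrolysis", "atoms": (c, n)},
                )
            )
        return events


def torsion_angle(p0, p1, p2, p3) -> float:
    """Dihedral p0-p1-p2-p3 in degrees, signed, on (-180, 180]."""
    b0 = np.asarray(p0) - np.asarray(p1)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    nb1 = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, nb1) * nb1
    w = b2 - np.dot(b2, nb1) * nb1
    x = np.dot(v, w)
    y = np.dot(np.cross(nb1, v), w)
    ang = float(np.degrees(np.arctan2(y, x)))
    return 180.0 if ang == -180.0 else ang


@register_rate_model("dimerization")
class DimerizationPlugin(ReactionPlugin):
    """Cyclobutane-forming dimerization of C=C double-bond pairs.

    For every pair of order-2 C-C bonds, the per-frame features are the
    distance between bond midpoints and the torsion across the two bonds;
    the event rate is the ensemble mean of the distance-and-angle heuristic.
    """

    def __init__(self, params=None, constants=None):
        super().__init__(params, constants)
        defaults = DimerParams()
        self.dp = DimerParams(
            **{
                f.name: self.params.get(f.name, getattr(defaults, f.name))
                for f in dataclasses.fields(DimerParams)
            }
        )

    def propose(self, topology: Topology, ensemble: Ensemble) -> list[Event]:
        from .fixtures import find_cc_double_bonds

        bonds = find_cc_double_bonds(topology)
        pos = ensemble.positions_array()
        events = []
        for bi in range(len(bonds)):
            for bj in range(bi + 1, len(bonds)):
                (c5a, c6a), (c5b, c6b) = bonds[bi], bonds[bj]
                mid_a = 0.5 * (pos[:, c5a, :] + pos[:, c6a, :])
                mid_b = 0.5 * (pos[:, c5b, :] + pos[:, c6b, :])
                d = np.linalg.norm(mid_a - mid_b, axis=1)
                theta = np.array(
                    [
                        torsion_angle(
                            pos[f, c5a], pos[f, c6a], pos[f, c6b], pos[f, c5b]
                        )
                        for f in range(pos.shape[0])
                    ]
                )
                rates = dimerization_rate(d, theta, self.dp)
                events.append(
                    Event(
                        recipe=make_dimerization_recipe(
                            topology, c5a, c6a, c5b, c6b
                        ),
                        rate=float(np.mean(rates)),
                        metadata={
                            "reaction_type": "dimerization",
                            "atoms": (c5a, c6a, c5b, c6b),
                        },
                    )
                )
        return events


# ---------------------------------------------------------------------------
# Records and run loop
# ---------------------------------------------------------------------------


@dataclass
class EventDigest:
    reaction_type: str
    atoms: tuple
    rate: float
    label: str | None = None


@dataclass
class RunRecord:
    """Provenance of one kMC step, sufficient for replay checks."""

    step: int
    events: list[EventDigest]
    chosen_index: int
    chosen: EventDigest
    u1: float
    u2: float
    delta_t: float
    time: float
    topology_digest: str

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d)


@dataclass
class RunResult:
    records: list[RunRecord]
    topology: Topology
    frame: Frame
    states: list[tuple[Topology, Frame]] | None = None


def _digest(event: Event) -> EventDigest:
    return EventDigest(
        reaction_type=event.metadata.get("reaction_type", "unknown"),
        atoms=tuple(event.metadata.get("atoms", ())),
        rate=event.rate,
        label=event.metadata.get("label"),
    )


def _cycle_seed(seed: int, cycle: int, stream: int) -> int:
    """Deterministic per-cycle sampler seed: pure function of the run seed."""
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(stream, cycle))
    return int(ss.generate_state(1)[0])


def _build_plugins(config: RunConfig) -> list[ReactionPlugin]:
    constants = Constants(T=config.temperature)
    plugins = []
    for spec in config.plugins:
        cls = get_rate_model(spec.name)
        plugins.append(cls(params=spec.params, constants=constants))
    return plugins


@dataclass
class _State:
    topology: Topology
    frame: Frame
    step: int
    time: float
    kmc_rng: np.random.Generator


def _sampler_cfg(config: RunConfig, n_steps: int, seed: int) -> SamplerConfig:
    return SamplerConfig(
        temperature=config.temperature,
        friction=config.friction,
        timestep=config.timestep,
        n_steps=n_steps,
        stride=config.sample_stride,
        seed=seed,
    )


def _run_loop(config: RunConfig, state: _State) -> RunResult:
    records: list[RunRecord] = []
    states: list[tuple[Topology, Frame]] = [] if config.keep_states else None
    plugins = _build_plugins(config)

    rates_rows: list[dict] = []

    if state.step == 0 and config.burn_in_steps > 0:
        ens = toy_sd_sample(
            state.topology,
            state.frame,
            _sampler_cfg(config, config.burn_in_steps, _cycle_seed(config.seed, 0, 9)),
        )
        state.frame = ens.frames[-1]

    while True:
        if config.max_steps is not None and state.step >= config.max_steps:
            break
        if config.max_time is not None and state.time >= config.max_time:
            break

        result = None
        events: list[Event] = []
        for attempt in range(config.resample_retries + 1):
            ens = toy_sd_sample(
                state.topology,
                state.frame,
                _sampler_cfg(
                    config,
                    config.sample_steps,
                    _cycle_seed(config.seed, state.step, 10 + attempt),
                ),
            )
            events = []
            for plugin in plugins:
                try:
                    events.extend(plugin.propose(state.topology, ens))
                except MolkmcError as exc:
                    raise MolkmcError(
                        f"plugin {plugin.plugin_name!r} failed at step "
                        f"{state.step}: {exc}"
                    ) from exc
            el = EventList(events)
            result = rf_kmc_step(el, state.kmc_rng)
            if result is not None:
                break
            state.frame = ens.frames[-1]
        if result is None:
            break  # no reactive event reachable; halt gracefully

        chosen_event = events[result.chosen_index]
        recipe = chosen_event.recipe
        frame_index = recipe.provenance.get("frame_index", len(ens.frames) - 1)
        new_topo, new_frame = apply_recipe(
            state.topology, ens.frames[frame_index], recipe
        )

        if config.equilibration_steps > 0:
            eq = toy_sd_sample(
                new_topo,
                new_frame,
                _sampler_cfg(
                    config,
                    config.equilibration_steps,
                    _cycle_seed(config.seed, state.step, 20),
                ),
            )
            new_frame = eq.frames[-1]

        state.topology = new_topo
        state.frame = new_frame
        state.time += result.delta_t

        record = RunRecord(
            step=state.step,
            events=[_digest(e) for e in events],
            chosen_index=result.chosen_index,
            chosen=_digest(chosen_event),
            u1=result.u1,
            u2=result.u2,
            delta_t=result.delta_t,
            time=state.time,
            topology_digest=new_topo.digest(),
        )
        records.append(record)
        if states is not None:
            states.append((new_topo.copy(), new_frame.copy()))
        for d in record.events:
            rates_rows.append(
                {
                    "step": record.step,
                    "reaction_type": d.reaction_type,
                    "atoms": "-".join(str(a + 1) for a in d.atoms),
                    "label": d.label or "",
                    "rate": d.rate,
                    "chosen": int(d is record.chosen),
                }
            )
        state.step += 1

    if config.output_dir:
        _write_outputs(config, records, rates_rows, state)

    return RunResult(
        records=records, topology=state.topology, frame=state.frame, states=states
    )


def _write_outputs(config, records, rates_rows, state) -> None:
    import pandas as pd

    from .topology import save_topology

    os.makedirs(config.output_dir, exist_ok=True)
    with open(os.path.join(config.output_dir, "records.jsonl"), "w") as fh:
        for rec in records:
            fh.write(rec.to_json() + "\n")
    pd.DataFrame(
        rates_rows,
        columns=["step", "reaction_type", "atoms", "label", "rate", "chosen"],
    ).to_csv(os.path.join(config.output_dir, "rates.tsv"), sep="\t", index=False)
    save_topology(state.topology, os.path.join(config.output_dir, "final.top"))
    from .io import write_frames

    write_frames(
        Ensemble(state.topology, [state.frame], provenance="final"),
        os.path.join(config.output_dir, "final.pdb"),
    )


def run(config: RunConfig) -> RunResult:
    """Execute a full reaction-emulation run from the configured state."""
    config.validate()
    topo, frame = _initial_state(config)
    violations = topo.validate()
    if violations:
        raise ConfigurationError(f"initial topology invalid: {violations[0]}")
    kmc_rng = np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(1,))
    )
    state = _State(topology=topo, frame=frame, step=0, time=0.0, kmc_rng=kmc_rng)
    return _run_loop(config, state)


# ---------------------------------------------------------------------------
# Checkpointing
# ---------------------------------------------------------------------------


def checkpoint(config: RunConfig, state: _State, path) -> None:
    """Serialise a resumable state (topology, frame, time, RNG) as JSON."""
    rng_state = state.kmc_rng.bit_generator.state
    payload = {
        "schema_version": SCHEMA_VERSION,
        "config": config.to_dict(),
        "step": state.step,
        "time": state.time,
        "topology": write_topology(state.topology),
        "positions": np.asarray(state.frame.positions).tolist(),
        "frame_time": state.frame.time,
        "rng_state": rng_state,
        "plugins": [spec.name for spec in config.plugins],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def restore(path, config: RunConfig | None = None) -> tuple[RunConfig, _State]:
    """Load a checkpoint; optionally verify it matches a given config."""
    try:
        with open(path) as fh:
            payload = json.load(fh)
        saved_config = RunConfig.from_dict(payload["config"])
        topo = parse_topology(payload["topology"])
        frame = Frame(
            positions=np.asarray(payload["positions"], dtype=float),
            time=payload.get("frame_time", 0.0),
        )
        rng = np.random.default_rng(0)
        rng.bit_generator.state = payload["rng_state"]
        state = _State(
            topology=topo,
            frame=frame,
            step=int(payload["step"]),
            time=float(payload["time"]),
            kmc_rng=rng,
        )
    except (KeyError, ValueError, TypeError, json.JSONDecodeError) as exc:
        raise CheckpointError(f"corrupt checkpoint {path}: {exc}") from exc
    if config is not None:
        want = [spec.name for spec in config.plugins]
        have = payload.get("plugins", [])
        if want != have:
            raise ConfigurationError(
                f"checkpoint plugin set {have} does not match config {want}"
            )
    return saved_config, state


def run_steps_and_checkpoint(config: RunConfig, n_steps: int, path) -> RunResult:
    """Run the first ``n_steps`` kMC steps, then write a checkpoint."""
    config.validate()
    topo, frame = _initial_state(config)
    kmc_rng = np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(1,))
    )
    state = _State(topology=topo, frame=frame, step=0, time=0.0, kmc_rng=kmc_rng)
    partial = dataclasses.replace(config, max_steps=n_steps)
    result = _run_loop(partial, state)
    checkpoint(config, state, path)
    return result


def restart(path, config: RunConfig | None = None) -> RunResult:
    """Continue a checkpointed run to its configured stopping criterion."""
    saved_config, state = restore(path, config=config)
    return _run_loop(saved_config, state)
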