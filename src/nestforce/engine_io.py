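"""Per-step orchestration, observers, text output, snapshots, run driver.

The step order follows the simulator's component sequence: lower-order
reactions first, then integration (first kick + drift + boundary), then
collision detection and the bimolecular force/reaction phase, then the
second velocity kick, and finally reporting.
"""
from __future__ import annotations

import csv
import json
import os
from dataclasses import asdict, dataclass, field
from typing import Any, Iterable

import numpy as np

from . import collision, forces, integrator, reactions
from .core_model import (MEDIUM, Domain, Model, ModelError, PhysicsParams,
                         SystemState)

__version__ = "0.1.0"


def _need_pair_phase(state: SystemState, any_mobile: bool) -> bool:
    if any(r.order == 2 for r in state.model.rules):
        return True
    if not any_mobile:
        return False
    if state.model.pair_contact:
        return True
    # contact disabled: only nested particles still need their shell force
    return len(state.children[MEDIUM]) < len(state.meta)


def step(state: SystemState, observers: Iterable["Observer"] = ()) -> float:
    """Advance the system by one adaptive step; returns the Δt used."""
    ph = state.physics
    dt = integrator.adaptive_timestep(state)

    # (1) lower-order reactions, growth ramps, division bookkeeping
    n_transitions = len(state.transitions)
    reactions.apply_lower_order(state, dt)
    if len(state.transitions) > n_transitions:
        # a division just started: re-derive the step so the first kick of
        # the division force cannot overshoot
        dt = min(dt, integrator.adaptive_timestep(state))

    # (2) deterministic + thermal forces at current positions, first kick
    slots = state.alive_slots()
    mob = slots[state.mobile[slots]]
    f_det = np.zeros_like(state.pos)
    forces.accumulate_field_forces(state, f_det, state.time)
    reactions.accumulate_division_forces(state, f_det)
    state.thermal[: state._n] = 0.0
    if mob.size:
        state.thermal[mob] = forces.thermal_forces(
            state.frictions(mob), ph.temperature, dt, state.rng, ph.dimension)
        integrator.kick(state, mob, f_det[mob] + state.pair_force[mob],
                        state.thermal[mob], dt / 2.0)
        integrator.drift(state, mob, dt)

    # (3) collision detection and pair forces / bimolecular reactions
    if _need_pair_phase(state, bool(mob.size)):
        pairs = collision.detect_overlaps(state)
        reactions.apply_pair_phase(state, pairs, dt)

    # (4) second kick with forces recomputed at the new positions
    slots = state.alive_slots()
    mob = slots[state.mobile[slots]]
    if mob.size:
        f_det = np.zeros_like(state.pos)
        forces.accumulate_field_forces(state, f_det, state.time)
        reactions.accumulate_division_forces(state, f_det)
        integrator.second_kick(state, mob, f_det[mob] + state.pair_force[mob],
                               state.thermal[mob], dt / 2.0)

    # (5) advance time, notify observers
    state.time += dt
    state.step_count += 1
    for obs in observers:
        obs.maybe_record(state)
    return dt


# ---------------------------------------------------------------------------
# observers
# ---------------------------------------------------------------------------

class Observer:
    """Read-only periodic recorder; must never mutate the state."""

    def __init__(self, name: str, every_steps: int = 1):
        if every_steps < 1:
            raise ModelError("observer interval must be >= 1 step")
        self.name = name
        self.every_steps = every_steps

    def maybe_record(self, state: SystemState) -> None:
        if state.step_count % self.every_steps == 0:
            self.record(state)

    def record(self, state: SystemState) -> None:  # pragma: no cover
        raise NotImplementedError


def species_counts(state: SystemState) -> dict[tuple[str, str], int]:
    """Counts keyed by (species, compartment context = parent species/medium)."""
    out: dict[tuple[str, str], int] = {}
    for pid, meta in state.meta.items():
        parent = meta.parent
        context = MEDIUM if parent == MEDIUM else state.meta[parent].species.name
        key = (meta.species.name, context)
        out[key] = out.get(key, 0) + 1
    return out


class CountsObserver(Observer):
    """Time series of per-species particle counts, split by compartment."""

    def __init__(self, every_steps: int = 1):
        super().__init__("counts", every_steps)
        self.rows: list[tuple[float, str, int, str]] = []

    def record(self, state: SystemState) -> None:
        for (species, context), n in sorted(species_counts(state).items()):
            self.rows.append((state.time, species, n, context))


class TrajectoryObserver(Observer):
    """Extended-XYZ-style frames: species, position, radius, parent id."""

    def __init__(self, every_steps: int = 1):
        super().__init__("trajectory", every_steps)
        self.frames: list[tuple[float, list[tuple]]] = []

    def record(self, state: SystemState) -> None:
        rows = []
        for pid in state.particle_ids():
            meta = state.meta[pid]
            x = state.pos[meta.slot]
            z = float(x[2]) if state.physics.dimension == 3 else 0.0
            parent = -1 if meta.parent == MEDIUM else int(meta.parent)
            rows.append((meta.species.name, float(x[0]), float(x[1]), z,
                         float(state.rad[meta.slot]), parent))
        self.frames.append((state.time, rows))


class PositionsObserver(Observer):
    """Dense position array per frame for one species (analysis helper)."""

    def __init__(self, species: str, every_steps: int = 1):
        super().__init__(f"positions[{species}]", every_steps)
        self.species = species
        self.times: list[float] = []
        self.frames: list[np.ndarray] = []

    def record(self, state: SystemState) -> None:
        slots = [state.meta[pid].slot for pid in state.particle_ids()
                 if state.meta[pid].species.name == self.species]
        self.times.append(state.time)
        self.frames.append(state.pos[slots].copy())


# ---------------------------------------------------------------------------
# text outputs
# ---------------------------------------------------------------------------

def write_counts(rows: list[tuple[float, str, int, str]], path: str) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["time", "species", "count", "compartment_context"])
        for time, species, count, context in rows:
            writer.writerow([repr(time), species, count, context])


def write_trajectory(frames: list[tuple[float, list[tuple]]], path: str) -> None:
    with open(path, "w") as fh:
        for time, rows in frames:
            fh.write(f"{len(rows)}\n")
            fh.write(f"time={time!r}\n")
            for species, x, y, z, radius, parent in rows:
                fh.write(f"{species} {x!r} {y!r} {z!r} {radius!r} {parent}\n")


def _domain_dict(domain: Domain) -> dict:
    return {"lo": list(domain.lo), "hi": list(domain.hi),
            "boundary": domain.boundary}


def _physics_dict(ph: PhysicsParams) -> dict:
    d = asdict(ph)
    d["domain"] = _domain_dict(ph.domain)
    return d


def _physics_from_dict(d: dict) -> PhysicsParams:
    dd = dict(d)
    dom = dd.pop("domain")
    domain = Domain(lo=tuple(dom["lo"]), hi=tuple(dom["hi"]),
                    boundary=dom["boundary"])
    return PhysicsParams(domain=domain, **dd)


def write_snapshot(state: SystemState, path: str) -> None:
    """Lossless JSON snapshot: particles, forest, transitions, RNG state."""
    particles = []
    for pid in state.particle_ids():
        meta = state.meta[pid]
        s = meta.slot
        particles.append({
            "id": pid,
            "species": meta.species.name,
            "position": [float(v) for v in state.pos[s]],
            "velocity": [float(v) for v in state.vel[s]],
            "radius": float(state.rad[s]),
            "target_radius": float(state.target_rad[s]),
            "grow_rate": float(state.grow_rate[s]),
            "density": float(state.dens[s]),
            "mobile": bool(state.mobile[s]),
            "parent": meta.parent if meta.parent == MEDIUM else int(meta.parent),
            "ignore": sorted(int(i) for i in meta.ignore),
            "attributes": meta.attributes,
            "pair_force": [float(v) for v in state.pair_force[s]],
        })
    transitions = []
    for tr in state.transitions:
        transitions.append({
            "kind": tr.kind,
            "participants": list(tr.participants),
            "axis": None if tr.axis is None else [float(v) for v in tr.axis],
            "start_time": tr.start_time,
            "steps": tr.steps,
            "child1": tr.child1, "child2": tr.child2,
            "half1": list(tr.half1), "half2": list(tr.half2),
            "r_start": tr.r_start, "rt1": tr.rt1, "rt2": tr.rt2,
            "a_division": tr.a_division, "settling": tr.settling,
        })
    crossing = sorted(getattr(state, "_crossing", set()))
    doc = {
        "format": "nestforce-snapshot",
        "version": __version__,
        "time": state.time,
        "step_count": state.step_count,
        "next_id": state.next_id,
        "physics": _physics_dict(state.physics),
        "spawn_fraction": state.spawn_fraction,
        "rng_state": state.rng.bit_generator.state,
        "particles": particles,
        "transitions": transitions,
        "crossing": crossing,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def load_snapshot(path: str, model: Model) -> SystemState:
    """Rebuild a state from a snapshot; the model must match the original."""
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("format") != "nestforce-snapshot":
        raise ModelError(f"{path} is not a nestforce snapshot")
    physics = _physics_from_dict(doc["physics"])
    state = SystemState(model, physics, seed=0)
    state.time = doc["time"]
    state.step_count = doc["step_count"]
    state.spawn_fraction = doc.get("spawn_fraction", state.spawn_fraction)
    # particles are stored sorted by id, so insertion order preserves the
    # slot-order == id-order property the engine relies on
    for rec in doc["particles"]:
        sp = model.species_def(rec["species"])
        pid = rec["id"]
        state.next_id = pid
        new = state.spawn_particle(sp, rec["position"], MEDIUM,
                                   radius=rec["radius"],
                                   density=rec["density"],
                                   velocity=rec["velocity"],
                                   attributes=rec["attributes"],
                                   mobile=rec["mobile"])
        assert new == pid
        slot = state.meta[pid].slot
        state.target_rad[slot] = rec["target_radius"]
        state.grow_rate[slot] = rec["grow_rate"]
        state.pair_force[slot] = rec["pair_force"]
        state.meta[pid].ignore = set(rec["ignore"])
    for rec in doc["particles"]:
        if rec["parent"] != MEDIUM:
            state.reparent(rec["id"], rec["parent"])
    state.next_id = doc["next_id"]
    state._crossing = set(doc.get("crossing", []))
    for rec in doc["transitions"]:
        tr = reactions.Transition(
            kind=rec["kind"], participants=list(rec["participants"]),
            axis=None if rec["axis"] is None else np.asarray(rec["axis"]),
            start_time=rec["start_time"], steps=rec["steps"],
            child1=rec["child1"], child2=rec["child2"],
            half1=list(rec["half1"]), half2=list(rec["half2"]),
            r_start=rec["r_start"], rt1=rec["rt1"], rt2=rec["rt2"],
            a_division=rec["a_division"],
            settling=rec.get("settling", False))
        state.transitions.append(tr)
        for pid in tr.participants:
            if pid in state.meta:
                state.meta[pid].transition = tr
    state.rng.bit_generator.state = doc["rng_state"]
    return state


# ---------------------------------------------------------------------------
# run driver
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """End-to-end run description; deterministic under (scenario, seed)."""

    scenario: str
    seed: int = 0
    t_end: float | None = None
    n_steps: int | None = None
    out_dir: str | None = None
    observe: tuple[str, ...] = ("counts",)
    observe_every: int = 10
    scenario_params: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.t_end is None) == (self.n_steps is None):
            raise ModelError("give exactly one of t_end / n_steps")


@dataclass
class RunResult:
    state: SystemState
    observers: dict[str, Observer]
    paths: dict[str, str]


def run(config: RunConfig) -> RunResult:
    """Build the scenario, run to the end condition, write text outputs."""
    from . import example_models

    spec = example_models.get_scenario(config.scenario)
    state = spec.builder(seed=config.seed, **config.scenario_params)

    observers: dict[str, Observer] = {}
    if "counts" in config.observe:
        observers["counts"] = CountsObserver(config.observe_every)
    if "trajectory" in config.observe:
        observers["trajectory"] = TrajectoryObserver(config.observe_every)
    obs = list(observers.values())
    for o in obs:  # frame at t=0
        o.record(state)

    if config.n_steps is not None:
        for _ in range(config.n_steps):
            step(state, obs)
    else:
        while state.time < config.t_end:
            step(state, obs)

    paths: dict[str, str] = {}
    if config.out_dir is not None:
        os.makedirs(config.out_dir, exist_ok=True)
        if "counts" in observers:
            paths["counts"] = os.path.join(config.out_dir, "counts.csv")
            write_counts(observers["counts"].rows, paths["counts"])
        if "trajectory" in observers:
            paths["trajectory"] = os.path.join(config.out_dir, "trajectory.xyz")
            write_trajectory(observers["trajectory"].frames, paths["trajectory"])
        paths["snapshot"] = os.path.join(config.out_dir, "snapshot.json")
        write_snapshot(state, paths["snapshot"])
        paths["log"] = os.path.join(config.out_dir, "run.log")
        with open(paths["log"], "w") as fh:
            fh.write(f"nestforce {__version__}\n")
            fh.write(f"scenario={config.scenario} seed={config.seed}\n")
            fh.write(f"t_end={config.t_end} n_steps={config.n_steps}\n")
            fh.write(f"params={json.dumps(config.scenario_params, sort_keys=True, default=str)}\n")
            fh.write(f"final_time={state.time!r} steps={state.step_count} "
                     f"particles={state.n_particles}\n")
    return RunResult(state=state, observers=observers, paths=paths)


def state_fingerprint(state: SystemState) -> tuple:
    """Hashable digest of the dynamic state (for observer-purity checks)."""
    slots = state.alive_slots()
    return (state.time, state.step_count, state.next_id,
            state.pos[slots].tobytes(), state.vel[slots].tobytes(),
            state.rad[slots].tobytes(),
            tuple(sorted((pid, m.parent if m.parent == MEDIUM else int(m.parent),
                          tuple(sorted(m.attributes.items())))
                         for pid, m in state.meta.items())))
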