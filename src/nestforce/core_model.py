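"""Species, particles, the containment forest, and derived physical quantities.

Particles are hollow spheres: they have a position, velocity, radius and
density, carry a typed attribute map defined by their species, and may
contain other particles.  The containment links form a forest rooted in the
surrounding medium.  All quantities are strict SI.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Callable, Iterable, Mapping, Sequence

import numpy as np

from .units import KB

#: Sentinel parent for particles suspended directly in the medium.
MEDIUM = "medium"

#: Fraction of the target radius at which reaction-created particles appear.
SPAWN_FRACTION = 0.01


class ModelError(Exception):
    """Base class for model specification and state errors."""


class RegistrationError(ModelError):
    """Duplicate or malformed species/rule registration."""


class SchemaError(ModelError):
    """Attribute map does not conform to the species schema."""


class PlacementError(ModelError):
    """A particle cannot be placed where requested."""


class StateCorruptionError(ModelError):
    """The containment forest or particle store is inconsistent."""


class NumericalBlowupError(ModelError):
    """Positions or velocities became non-finite."""


_KIND_CHECKS: dict[str, Callable[[Any], bool]] = {
    "number": lambda v: isinstance(v, (int, float, np.integer, np.floating))
    and not isinstance(v, (bool, np.bool_)),
    "integer": lambda v: isinstance(v, (int, np.integer))
    and not isinstance(v, (bool, np.bool_)),
    "boolean": lambda v: isinstance(v, (bool, np.bool_)),
    "string": lambda v: isinstance(v, str),
}

_KIND_DEFAULTS: dict[str, Any] = {
    "number": 0.0,
    "integer": 0,
    "boolean": False,
    "string": "",
}


@dataclass(frozen=True)
class SpeciesDef:
    """A named class of particles sharing an attribute schema and physics.

    Parameters
    ----------
    name:
        Unique species name within a model.
    attribute_schema:
        Sequence of ``(attribute_name, kind)`` pairs with kind one of
        ``number``, ``integer``, ``boolean``, ``string``.
    default_radius, default_density:
        Physical defaults used when spawning (m, kg/m^3); both must be > 0.
    interior_viscosity:
        Dynamic viscosity felt by the *contents* of particles of this
        species (Pa·s), or ``"inherit"`` to pass the enclosing value through.
    elastic_modulus, poisson_ratio:
        Young's modulus (Pa) and Poisson ratio used for contact forces.
        A ratio of exactly 0.5 is capped to 0.49 to keep the effective
        modulus finite.
    mobile:
        Immobile species skip spatial propagation entirely (e.g. yeast
        cells outside of division, a static lipid raft).
    attribute_defaults:
        Default attribute values; anything not listed falls back to the
        zero value of its kind.
    """

    name: str
    attribute_schema: tuple[tuple[str, str], ...] = ()
    default_radius: float = 1e-6
    default_density: float = 1000.0
    interior_viscosity: float | str = "inherit"
    elastic_modulus: float = 1e3
    poisson_ratio: float = 0.3
    mobile: bool = True
    attribute_defaults: Mapping[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.name:
            raise RegistrationError("species name must be non-empty")
        names = [n for n, _ in self.attribute_schema]
        if len(names) != len(set(names)):
            raise SchemaError(f"duplicate attribute names in schema of {self.name!r}")
        for n, kind in self.attribute_schema:
            if kind not in _KIND_CHECKS:
                raise SchemaError(
                    f"species {self.name!r}: unknown attribute kind {kind!r} for {n!r}"
                )
        if not self.default_radius > 0:
            raise ModelError(f"species {self.name!r}: radius must be > 0")
        if not self.default_density > 0:
            raise ModelError(f"species {self.name!r}: density must be > 0")
        if not self.elastic_modulus > 0:
            raise ModelError(f"species {self.name!r}: elastic modulus must be > 0")
        if self.poisson_ratio == 0.5:
            object.__setattr__(self, "poisson_ratio", 0.49)
        if not (0.0 <= self.poisson_ratio < 0.5):
            raise ModelError(f"species {self.name!r}: need 0 <= poisson_ratio < 0.5")
        if self.interior_viscosity != "inherit" and not self.interior_viscosity > 0:
            raise ModelError(f"species {self.name!r}: interior viscosity must be > 0")
        for key in self.attribute_defaults:
            if key not in dict(self.attribute_schema):
                raise SchemaError(
                    f"species {self.name!r}: default for unknown attribute {key!r}"
                )

    def schema_dict(self) -> dict[str, str]:
        return dict(self.attribute_schema)

    def new_attributes(self, overrides: Mapping[str, Any] | None = None) -> dict[str, Any]:
        """Build a fresh attribute map: schema zeros <- defaults <- overrides."""
        attrs = {n: _KIND_DEFAULTS[k] for n, k in self.attribute_schema}
        attrs.update(self.attribute_defaults)
        if overrides:
            attrs.update(overrides)
        validate_attributes(self, attrs)
        return attrs


def validate_attributes(species: SpeciesDef, attributes: Mapping[str, Any]) -> None:
    """Raise :class:`SchemaError` unless ``attributes`` matches the schema exactly."""
    schema = species.schema_dict()
    if set(attributes) != set(schema):
        raise SchemaError(
            f"attributes {sorted(attributes)} do not match schema "
            f"{sorted(schema)} of species {species.name!r}"
        )
    for name, value in attributes.items():
        if not _KIND_CHECKS[schema[name]](value):
            raise SchemaError(
                f"attribute {name!r} of species {species.name!r} must be "
                f"{schema[name]}, got {value!r}"
            )


@dataclass(frozen=True)
class Domain:
    """Axis-aligned simulation box with a boundary mode."""

    lo: tuple[float, ...]
    hi: tuple[float, ...]
    boundary: str = "reflective"

    def __post_init__(self) -> None:
        if self.boundary not in ("reflective", "absorbing", "periodic"):
            raise ModelError(f"unknown boundary mode {self.boundary!r}")
        if len(self.lo) != len(self.hi):
            raise ModelError("domain lo/hi dimensionality mismatch")
        if any(h <= l for l, h in zip(self.lo, self.hi)):
            raise ModelError("domain extents must be positive")

    @classmethod
    def box(cls, extents: Sequence[float] | float, dimension: int,
            boundary: str = "reflective") -> "Domain":
        """A box ``[0, L]^d`` (or per-axis extents) in ``dimension`` dims."""
        if np.isscalar(extents):
            ext = [float(extents)] * dimension
        else:
            ext = [float(e) for e in extents]
            if len(ext) != dimension:
                raise ModelError("extents do not match dimension")
        return cls(lo=tuple(0.0 for _ in ext), hi=tuple(ext), boundary=boundary)

    @property
    def dimension(self) -> int:
        return len(self.lo)

    @property
    def lengths(self) -> np.ndarray:
        return np.asarray(self.hi) - np.asarray(self.lo)

    @property
    def center(self) -> np.ndarray:
        return (np.asarray(self.hi) + np.asarray(self.lo)) / 2.0

    def contains(self, x: np.ndarray) -> bool:
        return bool(np.all(x >= self.lo) and np.all(x <= self.hi))


@dataclass
class PhysicsParams:
    """Global physical parameters of a simulation.

    ``granularity`` is the dimensionless precision parameter of the adaptive
    timestep Δt = r_min / (v_max · g); larger g means smaller steps.
    ``growth_time`` is the duration of continuous radius ramps, and
    ``tol_contain`` the slack allowed on the containment geometry
    invariant.
    """

    domain: Domain
    temperature: float = 310.0
    medium_viscosity: float = 1e-3
    boltzmann: float = KB
    dimension: int = 3
    granularity: float = 10.0
    max_timestep: float = 1e-3
    tol_contain: float = 1e-8
    growth_time: float = 1e-3
    semi_implicit_friction: bool = False

    def __post_init__(self) -> None:
        if self.dimension not in (2, 3):
            raise ModelError("dimension must be 2 or 3")
        if self.domain.dimension != self.dimension:
            raise ModelError("domain dimensionality does not match physics")
        if self.temperature < 0:
            raise ModelError("temperature must be >= 0")
        if not self.medium_viscosity > 0:
            raise ModelError("medium viscosity must be > 0")
        if not self.granularity >= 1:
            raise ModelError("granularity must be >= 1")
        for name in ("max_timestep", "tol_contain", "growth_time"):
            if not getattr(self, name) > 0:
                raise ModelError(f"{name} must be > 0")


class Model:
    """A model: species registry, reaction rules, and global force fields."""

    def __init__(self, name: str = "model"):
        self.name = name
        self.species: dict[str, SpeciesDef] = {}
        self.rules: list = []
        self.force_fields: list = []
        #: disable to simulate fully non-interacting (ideal) particles
        self.pair_contact: bool = True
        #: optional alternative contact law f(depth, r_eff, e_star) -> N
        self.contact_law: Callable[[float, float, float], float] | None = None

    def register_species(self, name: str,
                         attribute_schema: Iterable[tuple[str, str]] = (),
                         **defaults: Any) -> SpeciesDef:
        """Register a new species; keyword args feed :class:`SpeciesDef`."""
        if name in self.species:
            raise RegistrationError(f"species {name!r} already registered")
        sp = SpeciesDef(name=name, attribute_schema=tuple(
            (str(n), str(k)) for n, k in attribute_schema), **defaults)
        self.species[name] = sp
        return sp

    def species_def(self, name: str) -> SpeciesDef:
        try:
            return self.species[name]
        except KeyError:
            raise ModelError(f"unknown species {name!r}") from None

    def add_rule(self, rule) -> Any:
        names = {r.name for r in self.rules}
        if rule.name in names:
            raise RegistrationError(f"rule {rule.name!r} already registered")
        self.rules.append(rule)
        return rule

    def add_force_field(self, ff) -> Any:
        self.force_fields.append(ff)
        return ff


def mass(radius: float, density: float, dimension: int) -> float:
    """Mass of a particle treated as a solid sphere of its density.

    In 2D the particle is a disc of unit slab thickness (1 m).
    """
    if not radius > 0 or not density > 0:
        raise ModelError("mass requires radius > 0 and density > 0")
    if dimension == 3:
        return density * (4.0 / 3.0) * math.pi * radius**3
    return density * math.pi * radius**2  # * 1 m slab


@dataclass
class _Meta:
    """Per-particle bookkeeping that does not fit in numeric arrays."""

    id: int
    species: SpeciesDef
    attributes: dict[str, Any]
    parent: Any  # particle id or MEDIUM
    slot: int
    ignore: set[int] = field(default_factory=set)
    reacted: bool = False
    transition: Any = None  # Transition this particle takes part in, if any


class ParticleHandle:
    """Light view of one particle, handed to user rate/post functions.

    Reads go straight to the state arrays; writes go through validating
    setters.  Handles are cheap and transient — do not store them across
    steps (the particle may die or the store may compact).
    """

    __slots__ = ("state", "id")

    def __init__(self, state: "SystemState", pid: int):
        self.state = state
        self.id = pid

    def _slot(self) -> int:
        return self.state.meta[self.id].slot

    # --- identity -----------------------------------------------------
    @property
    def species(self) -> SpeciesDef:
        return self.state.meta[self.id].species

    @property
    def species_name(self) -> str:
        return self.state.meta[self.id].species.name

    @property
    def attributes(self) -> dict[str, Any]:
        return self.state.meta[self.id].attributes

    def set_attr(self, name: str, value: Any) -> None:
        meta = self.state.meta[self.id]
        new = dict(meta.attributes)
        new[name] = value
        validate_attributes(meta.species, new)
        meta.attributes[name] = value

    # --- geometry and motion -------------------------------------------
    @property
    def position(self) -> np.ndarray:
        return self.state.pos[self._slot()].copy()

    @position.setter
    def position(self, value) -> None:
        self.state.pos[self._slot()] = value

    @property
    def velocity(self) -> np.ndarray:
        return self.state.vel[self._slot()].copy()

    @velocity.setter
    def velocity(self, value) -> None:
        self.state.vel[self._slot()] = value

    @property
    def radius(self) -> float:
        return float(self.state.rad[self._slot()])

    @property
    def target_radius(self) -> float:
        return float(self.state.target_rad[self._slot()])

    @property
    def density(self) -> float:
        return float(self.state.dens[self._slot()])

    def retarget_radius(self, new_radius: float) -> None:
        """Schedule a continuous radius ramp toward ``new_radius``."""
        if not new_radius > 0:
            raise ModelError("target radius must be > 0")
        self.state.set_radius_target(self.id, new_radius)

    # --- containment ----------------------------------------------------
    @property
    def parent(self) -> Any:
        return self.state.meta[self.id].parent

    @property
    def content_ids(self) -> list[int]:
        return self.state.children_of(self.id)

    @property
    def content(self) -> list["ParticleHandle"]:
        return [ParticleHandle(self.state, c) for c in self.state.children_of(self.id)]

    # --- derived physics -------------------------------------------------
    @property
    def mass(self) -> float:
        return mass(self.radius, self.density, self.state.physics.dimension)

    @property
    def local_viscosity(self) -> float:
        return self.state.local_viscosity_of(self.id)

    @property
    def friction(self) -> float:
        return self.state.friction_coefficient(self.id)

    @property
    def diffusion(self) -> float:
        return self.state.diffusion_coefficient(self.id)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<Particle {self.id} {self.species_name} r={self.radius:.3g}>"


class SystemState:
    """The single mutable simulation object.

    Numeric per-particle data live in structure-of-arrays storage so the
    integrator can act on whole populations at once; identity, attributes
    and containment live in :class:`_Meta` records.  Particle ids are
    strictly increasing and slots are append-only (with occasional
    compaction), so ascending slot order equals ascending id order — the
    engine relies on this for reproducible RNG consumption.
    """

    def __init__(self, model: Model, physics: PhysicsParams, seed: int = 0):
        self.model = model
        self.physics = physics
        self.time = 0.0
        self.step_count = 0
        self.rng = np.random.default_rng(seed)
        self.next_id = 1
        self.meta: dict[int, _Meta] = {}
        self.children: dict[Any, set[int]] = {MEDIUM: set()}
        self.transitions: list = []
        #: reaction event log: tuples (time, rule_name, ids...)
        self.events: list[tuple] = []
        self.record_events = True
        #: fraction of the target radius at which ramped spawns start
        self.spawn_fraction = SPAWN_FRACTION
        self._n = 0  # high-water slot mark
        self._dead = 0
        self._alloc(64)

    # ------------------------------------------------------------------
    # storage
    # ------------------------------------------------------------------
    def _alloc(self, cap: int) -> None:
        d = self.physics.dimension
        self.pos = np.zeros((cap, d))
        self.vel = np.zeros((cap, d))
        self.rad = np.zeros(cap)
        self.target_rad = np.zeros(cap)
        self.grow_rate = np.zeros(cap)
        self.dens = np.zeros(cap)
        self.visc = np.zeros(cap)
        self.emod = np.zeros(cap)
        self.prat = np.zeros(cap)
        self.mobile = np.zeros(cap, dtype=bool)
        self.alive = np.zeros(cap, dtype=bool)
        self.ids = np.zeros(cap, dtype=np.int64)
        self.pair_force = np.zeros((cap, d))
        self.thermal = np.zeros((cap, d))

    def _ensure_capacity(self) -> None:
        cap = self.rad.shape[0]
        if self._n < cap:
            return
        new = 2 * cap
        for name in ("pos", "vel", "pair_force", "thermal"):
            arr = getattr(self, name)
            grown = np.zeros((new, arr.shape[1]))
            grown[:cap] = arr
            setattr(self, name, grown)
        for name, dtype in (("rad", float), ("target_rad", float),
                            ("grow_rate", float), ("dens", float),
                            ("visc", float), ("emod", float),
                            ("prat", float), ("mobile", bool),
                            ("alive", bool), ("ids", np.int64)):
            arr = getattr(self, name)
            grown = np.zeros(new, dtype=dtype)
            grown[:cap] = arr
            setattr(self, name, grown)

    def compact(self) -> None:
        """Drop dead slots, preserving ascending id order."""
        keep = np.flatnonzero(self.alive[: self._n])
        n = keep.size
        for name in ("pos", "vel", "pair_force", "thermal"):
            arr = getattr(self, name)
            arr[:n] = arr[keep]
            arr[n:] = 0.0
        for name in ("rad", "target_rad", "grow_rate", "dens", "visc",
                     "emod", "prat"):
            arr = getattr(self, name)
            arr[:n] = arr[keep]
            arr[n:] = 0.0
        self.mobile[:n] = self.mobile[keep]
        self.mobile[n:] = False
        self.alive[:n] = True
        self.alive[n:] = False
        self.ids[:n] = self.ids[keep]
        self.ids[n:] = 0
        for new_slot, pid in enumerate(self.ids[:n]):
            self.meta[int(pid)].slot = new_slot
        self._n = n
        self._dead = 0

    def _maybe_compact(self) -> None:
        if self._dead > 32 and self._dead > self._n // 2:
            self.compact()

    def alive_slots(self) -> np.ndarray:
        """Slots of live particles, ascending (== ascending particle id)."""
        return np.flatnonzero(self.alive[: self._n])

    @property
    def n_particles(self) -> int:
        return len(self.meta)

    def particle_ids(self) -> list[int]:
        return sorted(self.meta)

    def particle(self, pid: int) -> ParticleHandle:
        if pid not in self.meta:
            raise StateCorruptionError(f"unknown particle id {pid}")
        return ParticleHandle(self, pid)

    # ------------------------------------------------------------------
    # spawning / removal / reparenting
    # ------------------------------------------------------------------
    def spawn_particle(self, species: str | SpeciesDef, position,
                       parent: Any = MEDIUM, *,
                       radius: float | None = None,
                       density: float | None = None,
                       velocity=None,
                       attributes: Mapping[str, Any] | None = None,
                       ramp: bool = False,
                       mobile: bool | None = None) -> int:
        """Add a particle; returns its id.

        ``ramp=True`` is used by creation reactions: the particle starts at
        ``SPAWN_FRACTION`` of the requested radius and grows continuously to
        it over ``physics.growth_time``.
        """
        sp = species if isinstance(species, SpeciesDef) else self.model.species_def(species)
        d = self.physics.dimension
        x = np.asarray(position, dtype=float)
        if x.shape != (d,):
            raise PlacementError(f"position must be a {d}-vector")
        if not np.all(np.isfinite(x)):
            raise PlacementError("position must be finite")
        target = float(radius) if radius is not None else sp.default_radius
        if not target > 0:
            raise ModelError("radius must be > 0")
        rho = float(density) if density is not None else sp.default_density
        if parent == MEDIUM:
            if not self.physics.domain.contains(x):
                raise PlacementError(f"position {x} outside domain")
        else:
            if parent not in self.meta:
                raise PlacementError(f"unknown parent id {parent}")
            pmeta = self.meta[parent]
            pslot = pmeta.slot
            gap = float(np.linalg.norm(x - self.pos[pslot]))
            if gap + target > self.rad[pslot] * (1 + 1e-12) + self.physics.tol_contain:
                raise PlacementError(
                    f"particle of radius {target:g} at offset {gap:g} does not "
                    f"fit inside parent {parent} (radius {self.rad[pslot]:g})")
        attrs = sp.new_attributes(attributes)

        pid = self.next_id
        self.next_id += 1
        self._ensure_capacity()
        slot = self._n
        self._n += 1
        self.pos[slot] = x
        self.vel[slot] = 0.0 if velocity is None else np.asarray(velocity, dtype=float)
        start = target * self.spawn_fraction if ramp else target
        self.rad[slot] = start
        self.target_rad[slot] = target
        self.grow_rate[slot] = (target - start) / self.physics.growth_time if ramp else 0.0
        self.dens[slot] = rho
        self.emod[slot] = sp.elastic_modulus
        self.prat[slot] = sp.poisson_ratio
        self.mobile[slot] = sp.mobile if mobile is None else mobile
        self.alive[slot] = True
        self.ids[slot] = pid
        self.pair_force[slot] = 0.0
        self.thermal[slot] = 0.0
        self.meta[pid] = _Meta(id=pid, species=sp, attributes=attrs,
                               parent=parent, slot=slot)
        self.children.setdefault(parent, set()).add(pid)
        self.children[pid] = set()
        self.visc[slot] = self._resolve_viscosity(parent)
        return pid

    def remove_particle(self, pid: int) -> None:
        """Remove a particle and, recursively, all of its contents."""
        meta = self.meta.get(pid)
        if meta is None:
            raise StateCorruptionError(f"unknown particle id {pid}")
        for child in list(self.children.get(pid, ())):
            self.remove_particle(child)
        self.alive[meta.slot] = False
        self.pair_force[meta.slot] = 0.0
        self.children[meta.parent].discard(pid)
        del self.children[pid]
        del self.meta[pid]
        self._dead += 1
        self._maybe_compact()

    def reparent(self, pid: int, new_parent: Any) -> None:
        """Move a particle to a new parent in the containment forest."""
        meta = self.meta.get(pid)
        if meta is None:
            raise StateCorruptionError(f"unknown particle id {pid}")
        if new_parent != MEDIUM:
            if new_parent not in self.meta:
                raise StateCorruptionError(f"unknown parent id {new_parent}")
            if new_parent == pid or self.is_ancestor(pid, new_parent):
                raise StateCorruptionError(
                    f"reparenting {pid} under {new_parent} would create a cycle")
        self.children[meta.parent].discard(pid)
        meta.parent = new_parent
        self.children.setdefault(new_parent, set()).add(pid)
        self._refresh_viscosity(pid)

    def children_of(self, pid: Any) -> list[int]:
        return sorted(self.children.get(pid, ()))

    def is_ancestor(self, a: int, b: int) -> bool:
        """True if particle ``a`` encloses ``b`` (transitively)."""
        seen = set()
        cur = self.meta[b].parent if b in self.meta else MEDIUM
        while cur != MEDIUM:
            if cur == a:
                return True
            if cur in seen:
                raise StateCorruptionError("cycle in containment forest")
            seen.add(cur)
            cur = self.meta[cur].parent
        return False

    # ------------------------------------------------------------------
    # derived physics
    # ------------------------------------------------------------------
    def _resolve_viscosity(self, parent: Any) -> float:
        """Viscosity of the innermost enclosing particle that defines one."""
        seen = set()
        cur = parent
        while cur != MEDIUM:
            if cur not in self.meta:
                raise StateCorruptionError(f"broken parent link: {cur}")
            if cur in seen:
                raise StateCorruptionError("cycle in containment forest")
            seen.add(cur)
            eta = self.meta[cur].species.interior_viscosity
            if eta != "inherit":
                return float(eta)
            cur = self.meta[cur].parent
        return self.physics.medium_viscosity

    def _refresh_viscosity(self, pid: int) -> None:
        meta = self.meta[pid]
        self.visc[meta.slot] = self._resolve_viscosity(meta.parent)
        for child in self.children.get(pid, ()):
            self._refresh_viscosity(child)

    def local_viscosity_of(self, pid: int) -> float:
        return float(self.visc[self.meta[pid].slot])

    def friction_coefficient(self, pid: int) -> float:
        """Stokes drag γ = 6π η_local r (used in 2D as well, by convention)."""
        meta = self.meta[pid]
        return 6.0 * math.pi * float(self.visc[meta.slot]) * float(self.rad[meta.slot])

    def diffusion_coefficient(self, pid: int) -> float:
        """Stokes–Einstein D = k_B T / γ; D·γ == k_B·T exactly."""
        return self.physics.boltzmann * self.physics.temperature / \
            self.friction_coefficient(pid)

    def masses(self, slots: np.ndarray) -> np.ndarray:
        r = self.rad[slots]
        rho = self.dens[slots]
        if self.physics.dimension == 3:
            return rho * (4.0 / 3.0) * math.pi * r**3
        return rho * math.pi * r**2

    def frictions(self, slots: np.ndarray) -> np.ndarray:
        return 6.0 * math.pi * self.visc[slots] * self.rad[slots]

    def set_radius_target(self, pid: int, new_radius: float) -> None:
        """Begin a continuous radius ramp toward ``new_radius``."""
        slot = self.meta[pid].slot
        self.target_rad[slot] = new_radius
        self.grow_rate[slot] = abs(new_radius - self.rad[slot]) / self.physics.growth_time

    # ------------------------------------------------------------------
    # invariants
    # ------------------------------------------------------------------
    def validate_invariants(self) -> None:
        """Assert forest, containment, schema, and Stokes–Einstein invariants."""
        for pid, meta in self.meta.items():
            # forest: parents resolve, no cycles
            seen = set()
            cur = meta.parent
            while cur != MEDIUM:
                if cur not in self.meta:
                    raise StateCorruptionError(
                        f"particle {pid}: parent {cur} does not resolve")
                if cur in seen or cur == pid:
                    raise StateCorruptionError(f"containment cycle through {pid}")
                seen.add(cur)
                cur = self.meta[cur].parent
            if pid not in self.children.get(meta.parent, ()):
                raise StateCorruptionError(f"inverse link missing for {pid}")
            validate_attributes(meta.species, meta.attributes)
            if not self.rad[meta.slot] > 0:
                raise StateCorruptionError(f"particle {pid} has radius <= 0")
            # containment geometry, except during transitions
            if meta.parent != MEDIUM and meta.transition is None \
                    and self.meta[meta.parent].transition is None:
                pslot = self.meta[meta.parent].slot
                gap = float(np.linalg.norm(self.pos[meta.slot] - self.pos[pslot]))
                if gap + self.rad[meta.slot] > self.rad[pslot] + self.physics.tol_contain:
                    raise StateCorruptionError(
                        f"particle {pid} escapes parent {meta.parent}: "
                        f"|x-xp|+r = {gap + self.rad[meta.slot]:g} > "
                        f"{self.rad[pslot]:g} + tol")
            if meta.transition is None and meta.ignore:
                raise StateCorruptionError(
                    f"particle {pid} has a non-empty ignore set outside a transition")
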